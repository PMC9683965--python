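"""Turn a panel of expert importance ratings into FWZIC feature weights.

A simulated four-psychiatrist panel rates six clinical/behavioural
features on the 1-5 importance scale; FWZIC fuzzifies each expert's row,
averages over the panel, and normalizes the defuzzified values to a
unit-sum weight vector.
"""

from asdbench import fwzic_weights, simulate_expert_panel

features = [
    "Carry out orders",
    "Is there a language now?",
    "Pointing with the index finger",
    "Vitamin D3",
    "Jaundice",
    "Father age",
]

panel = simulate_expert_panel(features, n_experts=4, concordance=0.9, seed=42)
print("Expert decision matrix (rows = experts, Likert 1-5):")
print(panel.to_frame(), "\n")

weights = fwzic_weights(panel, provenance="example")
print("FWZIC weights (sum to 1; larger = panel deems more important):")
for feat, w in zip(weights.features, weights.weights):
    print(f"  {feat:32s} {w:.5f}")
print(f"  {'sum':32s} {sum(weights.weights):.5f}")
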