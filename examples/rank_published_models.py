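"""Rank the 15 published hybrid diagnosis models with FDOSM.

Loads the published 15-model x 7-criterion decision matrix, extracts the
ideal solution (minimum train/test time, maximum AUC/accuracy/F1/
precision/recall), derives surrogate difference-from-ideal opinions, and
prints the group ranking.  Lower opinion scores mean closer to ideal.

The published ranking itself came from three human experts, so the
surrogate scores differ from the published ones; the ideal solution and
the score arithmetic are identical.
"""

from asdbench import (
    auto_opinions,
    group_rank,
    ideal_solution,
    reference_decision_matrix,
)

dm = reference_decision_matrix()
ideal = ideal_solution(dm)
print("Ideal solution per criterion (cost -> column min, benefit -> max):")
print(ideal.to_string(), "\n")

opinions = [auto_opinions(dm, ideal, expert=f"auto{i + 1}") for i in range(3)]
result = group_rank(opinions)
report = result.report(dm.model_names).sort_values("rank")
print("Surrogate-expert FDOSM ranking (score: lower = closer to ideal):")
print(report.to_string(index=False))
best = result.scores.idxmin()
print(f"\nBest alternative: {best} = {dm.model_names[best]}")
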