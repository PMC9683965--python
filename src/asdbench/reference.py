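"""Published reference values for the 15 hybrid ASD diagnosis models.

``reference_decision_matrix`` loads the 15x7 evaluation of the hybrid
models reported for the original (non-public) clinical cohort.  It is a
fixture for the decision-analysis stages — ideal-solution extraction and
opinion-score ranking operate on it exactly as on a freshly computed
matrix.  Its cells are *inputs* here: recomputing them would require the
original cohort and expert panel.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .models import DecisionMatrix

__all__ = ["reference_decision_matrix", "REFERENCE_GROUP_SCORES"]


def reference_decision_matrix() -> DecisionMatrix:
    """The published 15-model, 7-criterion decision matrix."""
    with resources.files("asdbench.data").joinpath("reference_dm.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    names = df["model"].to_dict()
    return DecisionMatrix(df.drop(columns=["model"]).astype(float), model_names=names)


#: published group opinion scores of the 15 models (three-expert panel);
#: lower is better — A1 (ReF-decision tree) ranked first.
REFERENCE_GROUP_SCORES = {
    "A1": 0.157142829,
    "A2": 0.761111002,
    "A3": 0.576984072,
    "A4": 0.781745832,
    "A5": 0.350793653,
    "A6": 0.175396799,
    "A7": 0.761111002,
    "A8": 0.6007936,
    "A9": 0.797618813,
    "A10": 0.371428574,
    "A11": 0.294444441,
    "A12": 0.776983983,
    "A13": 0.6007936,
    "A14": 0.816666435,
    "A15": 0.400000007,
}
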