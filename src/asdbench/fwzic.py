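"""Fuzzy-weighted zero-inconsistency (FWZIC) criterion weighting.

FWZIC turns a panel of independent expert importance ratings into
normalized per-feature weights without pairwise comparisons, so there is
no consistency ratio to police.  The procedure:

1. each expert rates each feature on a five-point Likert scale;
2. ratings are fuzzified — each rating's TFN is divided by the fuzzy sum
   of that expert's ratings, so each expert contributes a fuzzy
   probability vector over features;
3. the fuzzified rows are averaged componentwise over experts;
4. each per-feature TFN is centroid-defuzzified and the crisp values are
   rescaled to sum to one.

Weights are computed independently for each feature-selection technique's
surviving feature set, so the same feature may carry different weights
under different selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fuzzy import IMPORTANCE5, TFN, LinguisticScale, likert_to_tfn, tfn_mean

__all__ = [
    "ExpertDecisionMatrix",
    "FeatureWeightSet",
    "fuzzify_edm",
    "aggregate_fuzzy_weights",
    "finalize_weights",
    "fwzic_weights",
]


@dataclass(frozen=True)
class ExpertDecisionMatrix:
    """Experts x features table of integer Likert importance ratings (1-5)."""

    experts: tuple[str, ...]
    criteria: tuple[str, ...]
    ratings: np.ndarray  # shape (m, n), ints in 1..5

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.ndim != 2 or r.shape != (len(self.experts), len(self.criteria)):
            raise ValueError(
                f"ratings shape {r.shape} does not match "
                f"{len(self.experts)} experts x {len(self.criteria)} criteria"
            )
        if r.size == 0:
            raise ValueError("EDM must have at least one expert and one criterion")
        if not np.issubdtype(r.dtype, np.integer):
            if not np.all(np.mod(r, 1) == 0):
                raise ValueError("ratings must be integers (no rounding is applied)")
            r = r.astype(int)
        if r.min() < 1 or r.max() > 5:
            raise ValueError(
                f"ratings must lie in 1..5, found range [{r.min()}, {r.max()}]"
            )
        object.__setattr__(self, "ratings", r)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpertDecisionMatrix":
        """Build from a DataFrame (index = experts, columns = features)."""
        if df.isna().any().any():
            raise ValueError("EDM has missing cells")
        return cls(
            experts=tuple(str(i) for i in df.index),
            criteria=tuple(str(c) for c in df.columns),
            ratings=df.to_numpy(),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ExpertDecisionMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ratings, index=list(self.experts), columns=list(self.criteria)
        )

    def restrict(self, features: list[str]) -> "ExpertDecisionMatrix":
        """Sub-matrix for a surviving feature set (order follows ``features``)."""
        missing = [f for f in features if f not in self.criteria]
        if missing:
            raise KeyError(f"EDM lacks ratings for features: {missing}")
        idx = [self.criteria.index(f) for f in features]
        return ExpertDecisionMatrix(
            self.experts, tuple(features), self.ratings[:, idx]
        )


@dataclass(frozen=True)
class FeatureWeightSet:
    """Normalized per-feature weights (sum to one) for one FS technique."""

    features: tuple[str, ...]
    weights: tuple[float, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.features) != len(self.weights):
            raise ValueError("one weight per feature is required")
        total = float(np.sum(self.weights))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.features), name="weight")

    def write_csv(self, path: str | Path) -> None:
        df = self.as_series().rename_axis("feature").reset_index()
        df.to_csv(path, index=False)
        meta = Path(path).with_suffix(".meta.txt")
        meta.write_text(f"provenance: {self.provenance}\n")

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "") -> "FeatureWeightSet":
        df = pd.read_csv(path)
        meta = Path(path).with_suffix(".meta.txt")
        if not provenance and meta.exists():
            provenance = meta.read_text().partition(":")[2].strip()
        return cls(
            tuple(df["feature"].astype(str)),
            tuple(df["weight"].astype(float)),
            provenance,
        )


def fuzzify_edm(
    edm: ExpertDecisionMatrix, scale: LinguisticScale = IMPORTANCE5
) -> list[list[TFN]]:
    """Fuzzify ratings: each cell's TFN divided by its expert's fuzzy row sum.

    The division is the extension-principle rule ``(a1/c2, b1/b2, c1/a2)``,
    so a fuzzified cell's components need not sum to anything crisp — the
    unit-sum property is restored after defuzzification.
    """
    out: list[list[TFN]] = []
    for i in range(len(edm.experts)):
        row = [likert_to_tfn(int(r), scale) for r in edm.ratings[i]]
        total = row[0]
        for t in row[1:]:
            total = total + t
        if total.a <= 0:
            raise ValueError(
                f"expert {edm.experts[i]!r}: fuzzy row sum has a non-positive "
                "component; cannot fuzzify"
            )
        out.append([t / total for t in row])
    return out


def aggregate_fuzzy_weights(fuzzy_edm: list[list[TFN]]) -> list[TFN]:
    """Per-criterion componentwise mean of the fuzzified ratings over experts."""
    if not fuzzy_edm:
        raise ValueError("empty fuzzy EDM")
    n = len(fuzzy_edm[0])
    return [tfn_mean([row[j] for row in fuzzy_edm]) for j in range(n)]


def finalize_weights(
    fuzzy_weights: list[TFN],
    features: tuple[str, ...] | list[str],
    provenance: str = "",
) -> FeatureWeightSet:
    """Centroid-defuzzify per-criterion TFNs and rescale to unit sum."""
    crisp = np.array([t.defuzzify() for t in fuzzy_weights], dtype=float)
    total = crisp.sum()
    if total <= 0:
        raise ValueError("defuzzified weights sum to zero; cannot rescale")
    return FeatureWeightSet(tuple(features), tuple(crisp / total), provenance)


def fwzic_weights(
    edm: ExpertDecisionMatrix,
    scale: LinguisticScale = IMPORTANCE5,
    provenance: str = "",
) -> FeatureWeightSet:
    """Run the full FWZIC chain: fuzzify, aggregate over experts, normalize."""
    fuzzy = fuzzify_edm(edm, scale)
    agg = aggregate_fuzzy_weights(fuzzy)
    return finalize_weights(agg, edm.criteria, provenance)
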