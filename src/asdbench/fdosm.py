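"""Fuzzy decision by opinion score method (FDOSM) ranking.

FDOSM ranks the alternatives of a decision matrix without explicit
criterion weights or normalization: an ideal solution is extracted
(column minimum for cost criteria, maximum for benefit, or a configured
critical value), experts judge how far each cell sits from the ideal on a
five-term linguistic difference scale, the terms are converted to TFNs,
averaged per alternative, and centroid-defuzzified into an opinion score.
Lower scores are better; group decisions average per-expert scores.

Every score lies in ``[centroid(No difference), centroid(Huge
difference)] = [0.1333.., 0.8833..]``.

Expert opinion matrices are first-class inputs (one delimited file per
expert); :func:`auto_opinions` is an explicitly synthetic surrogate that
maps normalized gaps from the ideal onto the linguistic scale so the
pipeline can run unattended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fuzzy import DIFFERENCE5, LinguisticScale, tfn_mean
from .models import DIRECTIONS, DecisionMatrix

__all__ = [
    "SCORE_BOUNDS",
    "DEFAULT_BIN_EDGES",
    "OpinionMatrix",
    "RankResult",
    "ideal_solution",
    "auto_opinions",
    "score_alternatives",
    "group_rank",
]

#: attainable opinion-score range: all-"No difference" .. all-"Huge difference"
SCORE_BOUNDS = (
    DIFFERENCE5.tfn_for_code(1).defuzzify(),
    DIFFERENCE5.tfn_for_code(5).defuzzify(),
)
#: normalized-gap cut points separating the five difference terms
DEFAULT_BIN_EDGES = (0.1, 0.3, 0.55, 0.8)


def ideal_solution(
    dm: DecisionMatrix, critical: dict[str, float] | None = None
) -> pd.Series:
    """Per-criterion reference value: column min (cost) / max (benefit).

    ``critical`` overrides selected criteria with a configured critical
    value (for criteria whose optimum is neither extreme).
    """
    if dm.data.empty:
        raise ValueError("empty decision matrix")
    critical = critical or {}
    ideal = {}
    for crit in dm.data.columns:
        if crit in critical:
            ideal[crit] = float(critical[crit])
        elif dm.directions[crit] == "cost":
            ideal[crit] = float(dm.data[crit].min())
        else:
            ideal[crit] = float(dm.data[crit].max())
    return pd.Series(ideal, name="ideal")


@dataclass(frozen=True)
class OpinionMatrix:
    """One expert's linguistic difference-from-ideal judgements."""

    expert: str
    terms: pd.DataFrame  # index alternatives, columns criteria, string cells

    def __post_init__(self) -> None:
        labels = {l.lower() for l in DIFFERENCE5.labels} | {
            str(c) for c in range(1, 6)
        }
        bad = sorted(
            {
                str(v)
                for v in self.terms.to_numpy().ravel()
                if str(v).strip().lower() not in labels
            }
        )
        if bad:
            raise ValueError(f"unknown linguistic terms: {bad}")

    def write_csv(self, path: str | Path) -> None:
        self.terms.rename_axis("alternative").to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, expert: str | None = None) -> "OpinionMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str)
        return cls(expert or Path(path).stem, df)


def auto_opinions(
    dm: DecisionMatrix,
    ideal: pd.Series | None = None,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    expert: str = "auto",
) -> OpinionMatrix:
    """Synthetic surrogate expert: bin normalized gaps into difference terms.

    For each cell the gap ``g = |v - ideal| / (col max - col min)`` in
    [0, 1] is mapped through ``bin_edges`` onto the five terms (``g = 0``
    -> "No difference", ``g = 1`` -> "Huge difference").  A constant
    column yields "No difference" everywhere.
    """
    if ideal is None:
        ideal = ideal_solution(dm)
    labels = DIFFERENCE5.labels
    cells = {}
    for crit in dm.data.columns:
        col = dm.data[crit]
        span = float(col.max() - col.min())
        if span == 0:
            cells[crit] = [labels[0]] * len(col)
            continue
        g = (col - ideal[crit]).abs() / span
        idx = np.searchsorted(np.asarray(bin_edges), g.to_numpy(), side="left")
        cells[crit] = [labels[i] for i in idx]
    return OpinionMatrix(
        expert, pd.DataFrame(cells, index=dm.data.index)
    )


def score_alternatives(
    opinions: OpinionMatrix, scale: LinguisticScale = DIFFERENCE5
) -> pd.Series:
    """Per-alternative opinion score: mean of term TFNs, centroid-defuzzified.

    By linearity of the centroid this equals the mean of per-term
    centroids, so aggregation order does not matter.
    """
    scores = {}
    for alt, row in opinions.terms.iterrows():
        tfns = [scale.tfn_for_label(v) for v in row]
        scores[alt] = tfn_mean(tfns).defuzzify()
    return pd.Series(scores, name=f"score[{opinions.expert}]")


@dataclass(frozen=True)
class RankResult:
    """Group opinion scores and ranks (1 = best = lowest score)."""

    scores: pd.Series          # group score per alternative
    ranks: pd.Series           # ordinal ranks, ties broken by alternative order
    dense_ranks: pd.Series     # dense ranks, ties share a rank
    per_expert: pd.DataFrame   # alternatives x experts individual scores

    def report(self, model_names: dict[str, str] | None = None) -> pd.DataFrame:
        names = model_names or {}
        return pd.DataFrame(
            {
                "alternative": self.scores.index,
                "model": [names.get(a, "") for a in self.scores.index],
                "score": [f"{s:.9f}" for s in self.scores],
                "rank": self.ranks.to_numpy(),
                "dense_rank": self.dense_ranks.to_numpy(),
            }
        )


def group_rank(
    opinions: list[OpinionMatrix], scale: LinguisticScale = DIFFERENCE5
) -> RankResult:
    """Aggregate per-expert opinion scores into a group ranking.

    Each expert's matrix is scored independently; group scores are the
    arithmetic mean over experts; rank 1 goes to the lowest group score.
    Ordinal ranks break ties by alternative order; dense ranks let tied
    alternatives share a rank.
    """
    if not opinions:
        raise ValueError("at least one expert opinion matrix is required")
    shape0 = opinions[0].terms.shape
    index0 = list(opinions[0].terms.index)
    for op in opinions[1:]:
        if op.terms.shape != shape0 or list(op.terms.index) != index0:
            raise ValueError(
                f"opinion matrix of expert {op.expert!r} does not match the "
                "first expert's shape/alternatives"
            )
    per_expert = pd.DataFrame(
        {op.expert: score_alternatives(op, scale) for op in opinions}
    )
    group = per_expert.mean(axis=1).rename("score")
    order = np.lexsort((np.arange(len(group)), group.to_numpy()))
    ranks = pd.Series(0, index=group.index, dtype=int, name="rank")
    ranks.iloc[order] = np.arange(1, len(group) + 1)
    dense = group.rank(method="dense").astype(int).rename("dense_rank")
    return RankResult(group, ranks, dense, per_expert)
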