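"""Filter feature selection: Chi-square, information gain, ReliefF.

All three scorers are learner-independent filters ranking features by
their association with the 3-level severity class.  Chi-square and
information gain work on discretized features (continuous columns are
equal-frequency binned); ReliefF works directly on the normalized table
using nearest hits and misses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, entropy
from sklearn.neighbors import NearestNeighbors

from .prep import CLASS_COLUMN

__all__ = [
    "score_chi2",
    "score_infogain",
    "score_relieff",
    "select_features",
    "score_table",
]

TECHNIQUES = ("chi2", "infogain", "relieff")


def _discretize(col: pd.Series, bins: int) -> np.ndarray:
    """Equal-frequency binning for continuous columns; low-cardinality
    columns pass through unchanged."""
    vals = col.to_numpy()
    if len(np.unique(vals)) <= bins:
        _, codes = np.unique(vals, return_inverse=True)
        return codes
    binned = pd.qcut(col, q=bins, duplicates="drop", labels=False)
    if binned.nunique() < 2:
        # mass concentrated on few values (e.g. a binary column with a
        # sprinkling of interpolated cells): fall back to equal-width bins
        binned = pd.cut(col, bins=bins, labels=False, include_lowest=True)
    return binned.to_numpy()


def _check_class(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("class column has zero variance; filters are undefined")


def _as_table(features: list[str], scores: np.ndarray, technique: str) -> pd.DataFrame:
    df = pd.DataFrame({"feature": features, "score": scores})
    df["rank"] = df["score"].rank(ascending=False, method="min").astype(int)
    df = df.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.attrs["technique"] = technique
    return df


def score_chi2(
    df: pd.DataFrame, class_column: str = CLASS_COLUMN, bins: int = 4
) -> pd.DataFrame:
    """Pearson chi-square statistic of each feature x class contingency table."""
    y = df[class_column].to_numpy()
    _check_class(y)
    feats = [c for c in df.columns if c != class_column]
    scores = np.empty(len(feats))
    for i, col in enumerate(feats):
        x = _discretize(df[col], bins)
        table = pd.crosstab(x, y).to_numpy()
        if table.shape[0] < 2:
            scores[i] = 0.0  # constant feature carries no association
            continue
        stat, _, _, _ = chi2_contingency(table, correction=False)
        scores[i] = stat
    return _as_table(feats, scores, "chi2")


def score_infogain(
    df: pd.DataFrame, class_column: str = CLASS_COLUMN, bins: int = 4
) -> pd.DataFrame:
    """Information gain H(class) - H(class | feature), in bits."""
    y = df[class_column].to_numpy()
    _check_class(y)
    h_class = entropy(pd.Series(y).value_counts().to_numpy(), base=2)
    feats = [c for c in df.columns if c != class_column]
    scores = np.empty(len(feats))
    for i, col in enumerate(feats):
        x = _discretize(df[col], bins)
        h_cond = 0.0
        for val, frac in pd.Series(x).value_counts(normalize=True).items():
            sub = y[x == val]
            h_cond += frac * entropy(pd.Series(sub).value_counts().to_numpy(), base=2)
        scores[i] = max(h_class - h_cond, 0.0)
    return _as_table(feats, scores, "infogain")


def score_relieff(
    df: pd.DataFrame,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
    class_column: str = CLASS_COLUMN,
) -> pd.DataFrame:
    """Multiclass ReliefF feature weights in [-1, 1].

    For each of ``m`` sampled instances (default: all rows, in order) the
    weight of feature ``f`` is decreased by the mean feature distance to
    the ``k`` nearest same-class neighbours (hits) and increased by the
    prior-weighted mean distance to the ``k`` nearest neighbours of each
    other class (misses):

        W[f] += -diff(f, x, hits)/m
                + sum_{c != class(x)} P(c)/(1 - P(class(x))) * diff(f, x, misses_c)/m

    ``diff`` is the absolute difference on [0,1]-normalized features, valid
    for both encoded categoricals and numerics after Phase-1 scaling.
    """
    y = df[class_column].to_numpy()
    _check_class(y)
    feats = [c for c in df.columns if c != class_column]
    X = df[feats].to_numpy(dtype=float)
    n = len(X)
    # diff() needs a [0,1] denominator; renormalize defensively
    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span[rng_span == 0] = 1.0

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    if counts.min() < k + 1:
        raise ValueError(
            f"every class needs >= {k + 1} members for k={k} ReliefF; "
            f"smallest class has {counts.min()}"
        )
    # batched per-class neighbour tables: global row ids of each instance's
    # k+1 nearest members of class c (k+1 so the self-hit can be dropped)
    neigh_tables: dict = {}
    for c in classes:
        idx = np.flatnonzero(y == c)
        q = min(k + 1, len(idx))
        nn = NearestNeighbors(n_neighbors=q).fit(X[idx])
        neigh_tables[c] = idx[nn.kneighbors(X, return_distance=False)]

    if m is None or m >= n:
        sample = np.arange(n)
    else:
        sample = np.random.default_rng(seed).choice(n, size=m, replace=False)
    m_eff = len(sample)

    W = np.zeros(len(feats))
    for i in sample:
        xi = X[i]
        ci = y[i]
        for c in classes:
            neigh = neigh_tables[c][i]
            if c == ci:
                neigh = neigh[neigh != i][:k]
                if len(neigh) == 0:
                    continue
                diffs = np.abs(X[neigh] - xi) / rng_span
                W -= diffs.mean(axis=0) / m_eff
            else:
                diffs = np.abs(X[neigh[:k]] - xi) / rng_span
                W += (priors[c] / (1.0 - priors[ci])) * diffs.mean(axis=0) / m_eff
    return _as_table(feats, W, "relieff")


def score_table(
    technique: str, df: pd.DataFrame, class_column: str = CLASS_COLUMN, **kwargs
) -> pd.DataFrame:
    """Dispatch to one of the three filter scorers by name."""
    if technique == "chi2":
        return score_chi2(df, class_column, **kwargs)
    if technique == "infogain":
        return score_infogain(df, class_column, **kwargs)
    if technique == "relieff":
        return score_relieff(df, class_column=class_column, **kwargs)
    raise ValueError(f"unknown FS technique {technique!r}; expected {TECHNIQUES}")


def select_features(
    scores: pd.DataFrame,
    rule: str = "positive",
    k: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Apply a selection rule to a score table and return surviving features.

    Rules: ``positive`` (score > 0, the default), ``top_k`` (requires
    ``k``), ``threshold`` (score > ``threshold``).  Ties at a top-k cutoff
    are broken by feature-name order so the selection is deterministic.
    """
    ordered = scores.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    )
    if rule == "positive":
        kept = ordered.loc[ordered["score"] > 0, "feature"].tolist()
    elif rule == "top_k":
        if k is None:
            raise ValueError("top_k rule requires k")
        kept = ordered["feature"].head(k).tolist()
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold")
        kept = ordered.loc[ordered["score"] > threshold, "feature"].tolist()
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if not kept:
        raise ValueError(f"selection rule {rule!r} kept no features")
    return kept
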