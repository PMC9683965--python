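"""Phase-1 preprocessing of the patient-feature table.

Fixed pipeline order: clean/encode -> mean imputation -> min-max
normalization -> SMOTE class balancing.  SMOTE's distance computations
need complete, commonly-scaled data, which fixes the order.

The table is a pandas DataFrame with one column per clinical or
sociodemographic feature and a 3-level ``severity`` class column
(light / medium / intense, encoded 0 / 1 / 2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CLASS_COLUMN",
    "CLASS_CODES",
    "SENTINELS",
    "clean_and_encode",
    "impute_mean",
    "minmax_normalize",
    "smote_balance",
    "preprocess",
    "write_codebook",
    "read_codebook",
]

CLASS_COLUMN = "severity"
#: class label -> integer code (medium is the majority class, coded 1)
CLASS_CODES = {"light": 0, "medium": 1, "intense": 2}
#: whole-cell sentinel symbols treated as missing during cleaning
SENTINELS = ("?", "/", "-")


def clean_and_encode(
    raw: pd.DataFrame, class_column: str = CLASS_COLUMN
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Strip sentinel symbols and encode categorical columns as integers.

    Whole-cell occurrences of ``?``, ``/`` and ``-`` become missing.
    Non-numeric feature columns are mapped through a deterministic
    codebook (categories sorted alphabetically within each column); the
    class column is encoded light=0, medium=1, intense=2.

    Returns the encoded table and the codebook
    ``{column: {category: code}}`` (the class mapping included).
    """
    if class_column not in raw.columns:
        raise KeyError(f"class column {class_column!r} absent from table")
    df = raw.copy()
    codebook: dict[str, dict[str, int]] = {}

    for col in df.columns:
        cleaned = df[col].map(
            lambda v: np.nan
            if (isinstance(v, str) and v.strip() in SENTINELS)
            else v
        )
        if col == class_column:
            labels = cleaned.dropna().astype(str).str.strip().str.lower()
            unknown = sorted(set(labels) - set(CLASS_CODES))
            if unknown:
                raise ValueError(f"unknown class labels {unknown} in {col!r}")
            if cleaned.isna().any():
                raise ValueError("class column has missing labels")
            df[col] = labels.map(CLASS_CODES).astype(int)
            codebook[col] = dict(CLASS_CODES)
            continue
        numeric = pd.to_numeric(cleaned, errors="coerce")
        non_numeric = cleaned.notna() & numeric.isna()
        if non_numeric.any():
            # categorical column: deterministic alphabetical codes
            cats = sorted(cleaned.dropna().astype(str).str.strip().unique())
            codes = {cat: i for i, cat in enumerate(cats)}
            codebook[col] = codes
            df[col] = cleaned.map(
                lambda v: codes[str(v).strip()] if pd.notna(v) else np.nan
            )
        else:
            df[col] = numeric
    return df, codebook


def impute_mean(df: pd.DataFrame, class_column: str = CLASS_COLUMN) -> pd.DataFrame:
    """Replace every missing cell by its column mean over observed cells."""
    out = df.copy()
    for col in out.columns:
        if col == class_column:
            continue
        if out[col].isna().all():
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        out[col] = out[col].fillna(out[col].mean())
    return out


def minmax_normalize(df: pd.DataFrame, class_column: str = CLASS_COLUMN) -> pd.DataFrame:
    """Rescale each feature column to [0, 1] via (x - min) / (max - min).

    The class column is untouched.  Constant columns map to 0 everywhere
    so degenerate inputs stay runnable.
    """
    out = df.copy()
    for col in out.columns:
        if col == class_column:
            continue
        if out[col].isna().any():
            raise ValueError(f"column {col!r} still has missing cells")
        lo, hi = out[col].min(), out[col].max()
        out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


def smote_balance(
    df: pd.DataFrame,
    k: int = 5,
    seed: int | np.random.Generator = 0,
    class_column: str = CLASS_COLUMN,
) -> pd.DataFrame:
    """Oversample every minority class to the majority count with SMOTE.

    Each synthetic row is a convex combination ``x + u * (nn - x)`` with
    ``u ~ Uniform(0, 1)`` of a randomly chosen minority row and one of its
    ``k`` nearest same-class neighbours (Euclidean distance on the
    normalized features).  Original rows are kept verbatim; synthetic rows
    are appended, so class blocks stay contiguous and the run is
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = df[class_column].value_counts()
    target = int(counts.max())
    feat_cols = [c for c in df.columns if c != class_column]
    pieces = [df]
    for cls in sorted(counts.index):
        need = target - int(counts[cls])
        if need == 0:
            continue
        members = df.loc[df[class_column] == cls, feat_cols].to_numpy(dtype=float)
        if len(members) < 2:
            raise ValueError(
                f"class {cls!r} has {len(members)} member(s); SMOTE needs >= 2"
            )
        k_eff = min(k, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        neigh = nn.kneighbors(members, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, len(members), size=need)
        pick = rng.integers(0, k_eff, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        base = members[base_idx]
        partner = members[neigh[base_idx, pick]]
        synth = base + u[:, None] * (partner - base)
        piece = pd.DataFrame(synth, columns=feat_cols)
        piece[class_column] = cls
        pieces.append(piece[df.columns])
    return pd.concat(pieces, ignore_index=True)


def preprocess(
    raw: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    class_column: str = CLASS_COLUMN,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Full Phase-1 pipeline: clean -> impute -> normalize -> SMOTE."""
    encoded, codebook = clean_and_encode(raw, class_column)
    imputed = impute_mean(encoded, class_column)
    normalized = minmax_normalize(imputed, class_column)
    balanced = smote_balance(normalized, k=k, seed=seed, class_column=class_column)
    return balanced, codebook


def write_codebook(codebook: dict[str, dict[str, int]], path: str | Path) -> None:
    lines = [
        f"{col}\t{cat}\t{code}"
        for col, codes in codebook.items()
        for cat, code in codes.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_codebook(path: str | Path) -> dict[str, dict[str, int]]:
    codebook: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        col, cat, code = line.split("\t")
        codebook.setdefault(col, {})[cat] = int(code)
    return codebook
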