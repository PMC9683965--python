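"""Synthetic ASD-like cohort and expert-panel generators.

The real clinical cohort behind this framework (538 children, 48 mixed
clinical and sociodemographic features, a 3-level severity class with
counts 241 light / 259 medium / 38 intense) is not publicly
distributable, so this module emulates its published shape: feature
names, kinds and value ranges, class counts, and missing-value symbols.

Signal is planted as class-conditional shifts: informative categorical
features get severity-dependent category probabilities (e.g. acquired
skills become rarer with increasing severity) and informative numeric
features get severity-shifted means.  Non-informative features are drawn
independently of the class.  This emulates the discriminative structure
real severity scales exhibit; it does not attempt clinically realistic
epidemiology or inter-feature correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fwzic import ExpertDecisionMatrix
from .prep import CLASS_COLUMN

__all__ = [
    "FeatureSpec",
    "GeneratorConfig",
    "DEFAULT_SCHEMA",
    "default_config",
    "generate_dataset",
    "simulate_expert_panel",
]

CLASS_LABELS = ("light", "medium", "intense")
_YN = ("No", "yes")
_BLOOD = ("A-", "A+", "B-", "B+", "O-", "O+", "AB-", "AB+")
_PNY = ("Previously", "no", "yes")


@dataclass(frozen=True)
class FeatureSpec:
    """One column of the cohort schema.

    ``kind`` is ``categorical`` or ``numeric``.  For categorical features
    ``categories`` lists the vocabulary and ``class_probs`` (optional)
    gives per-severity category probabilities; for numeric features
    ``lo``/``hi`` bound the range and ``class_means``/``sd`` (optional)
    plant a severity-shifted signal.  ``missing_rate`` is the fraction of
    cells replaced by a missing symbol.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    lo: float = 0.0
    hi: float = 1.0
    class_probs: dict[str, tuple[float, ...]] | None = None
    class_means: dict[str, float] | None = None
    sd: float = 0.0
    missing_rate: float = 0.0

    @property
    def informative(self) -> bool:
        return self.class_probs is not None or self.class_means is not None


def _skill(name: str, p_yes: tuple[float, float, float], miss: float = 0.0) -> FeatureSpec:
    """Yes/no feature whose P(yes) depends on severity (light, medium, intense)."""
    return FeatureSpec(
        name,
        "categorical",
        categories=_YN,
        class_probs={
            lab: (1.0 - p, p) for lab, p in zip(CLASS_LABELS, p_yes)
        },
        missing_rate=miss,
    )


def _cat(name: str, cats: tuple[str, ...], miss: float = 0.0) -> FeatureSpec:
    return FeatureSpec(name, "categorical", categories=cats, missing_rate=miss)


def _num(name: str, lo: float, hi: float, miss: float = 0.0, **kw) -> FeatureSpec:
    return FeatureSpec(name, "numeric", lo=lo, hi=hi, missing_rate=miss, **kw)


# Default 48-feature schema mirroring the published cohort description.
# Skills lost with severity carry (high, mid, low) P(yes); deficit
# behaviours the reverse.  Lab-test features default to 5% missing cells.
DEFAULT_SCHEMA: tuple[FeatureSpec, ...] = (
    _cat("Sex", ("Female", "Male")),
    _cat("The blood type of the patient", _BLOOD, miss=0.05),
    _cat("The blood type of the mother", _BLOOD, miss=0.05),
    _cat("The blood type of the father", _BLOOD, miss=0.05),
    _cat("Relative relation", _YN),
    _cat("Toxoplasmosis", _YN, miss=0.05),
    _cat("Unnatural medicines for mother", _YN, miss=0.05),
    _cat("Folic acid for mother", _YN, miss=0.05),
    _cat("Complications of childbirth for the mother", _YN),
    _cat("Premature baby", _YN),
    _cat("Jaundice", _YN, miss=0.05),
    _cat("Smell the food", _YN),
    _cat("Taste the food", _YN),
    _skill("He is afraid of loud sounds", (0.15, 0.5, 0.9)),
    _num("Degree", 85, 609, miss=0.05,
         class_means={"light": 450.0, "medium": 340.0, "intense": 200.0}, sd=60.0),
    _skill("Crying for no reason", (0.1, 0.5, 0.9)),
    _cat("Kisses with a sound", _YN),
    _cat("Escaping home when doors are open", _YN),
    _skill("Notice the sound of the bell", (0.9, 0.5, 0.1)),
    _cat("Diapers", _YN),
    _skill("Bathroom skills", (0.9, 0.5, 0.1)),
    _skill("Responds when parents call by name", (0.9, 0.55, 0.1)),
    _skill("Mind wandering", (0.1, 0.45, 0.9)),
    _num("Vitamin D3", 2.90, 102.1, miss=0.05),
    _num("Vitamin B12", 0.01, 2050, miss=0.05),
    _num("Vitamin zinc", 0.9, 292, miss=0.05),
    _cat("Marital relationship for parents", ("Not good", "yes", "separate", "dead")),
    _cat("Blood match", _YN, miss=0.05),
    _cat("Maternal diseases during pregnancy", _YN),
    _cat("Complications of childbirth for the child", _YN),
    _cat("Chewing food", _YN),
    _cat("Annoying from clothing tag", _YN),
    _cat("Waves", _YN),
    _cat("Patient moving at home", _YN),
    _skill("Patient moves around itself", (0.1, 0.5, 0.9)),
    _skill("Carry out orders", (0.9, 0.5, 0.1)),
    _skill("Laughing for no reason", (0.1, 0.5, 0.9)),
    _skill("Play with children", (0.9, 0.5, 0.1)),
    _skill("Is there a language now?", (0.9, 0.45, 0.05)),
    _skill("Pointing with the index finger", (0.9, 0.5, 0.1)),
    _skill("Notice his name", (0.9, 0.55, 0.1)),
    _cat("Arrange things in one row", _YN),
    _cat("Nodded", _PNY),
    _num("The age difference between the parents", 1, 28),
    _num("Duration of premature baby", 0, 39, miss=0.05),
    _cat("He plays with circle things", _PNY),
    _num("Father age", 22, 83),
    _num("Mother age", 16, 79),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; defaults reproduce the study shape."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: {"light": 241, "medium": 259, "intense": 38}
    )
    schema: tuple[FeatureSpec, ...] = DEFAULT_SCHEMA
    seed: int = 0

    @property
    def n_rows(self) -> int:
        return sum(self.class_counts.values())

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()) or self.n_rows == 0:
            raise ValueError("class counts must be non-negative and sum > 0")


def default_config(seed: int = 0, missing: bool = True) -> GeneratorConfig:
    """The study-shape configuration; ``missing=False`` zeroes all missing rates."""
    schema = DEFAULT_SCHEMA
    if not missing:
        schema = tuple(replace(f, missing_rate=0.0) for f in schema)
    return GeneratorConfig(schema=schema, seed=seed)


def _draw_feature(
    spec: FeatureSpec, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(labels)
    if spec.kind == "categorical":
        out = np.empty(n, dtype=object)
        if spec.class_probs is None:
            out[:] = rng.choice(spec.categories, size=n)
        else:
            for lab in CLASS_LABELS:
                mask = labels == lab
                if mask.any():
                    out[mask] = rng.choice(
                        spec.categories, size=mask.sum(), p=spec.class_probs[lab]
                    )
        return out
    if spec.class_means is None:
        vals = rng.uniform(spec.lo, spec.hi, size=n)
    else:
        vals = np.empty(n)
        for lab in CLASS_LABELS:
            mask = labels == lab
            if mask.any():
                vals[mask] = rng.normal(
                    spec.class_means[lab], spec.sd, size=mask.sum()
                )
        vals = np.clip(vals, spec.lo, spec.hi)
    return np.round(vals, 3).astype(object)


def generate_dataset(cfg: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a raw cohort table (strings/numbers, sentinel missing symbols).

    Exactly the configured per-class row counts; deterministic under the
    configured seed; missing cells appear as the whole-cell sentinel
    symbols "?" or "-" so the table exercises the cleaning stage.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(
        [lab for lab in CLASS_LABELS if lab in cfg.class_counts],
        [cfg.class_counts[lab] for lab in CLASS_LABELS if lab in cfg.class_counts],
    )
    rng.shuffle(labels)
    df = pd.DataFrame(index=range(len(labels)))
    for spec in cfg.schema:
        col = _draw_feature(spec, labels, rng)
        if spec.missing_rate > 0:
            holes = rng.random(len(col)) < spec.missing_rate
            col[holes] = rng.choice(["?", "-"], size=int(holes.sum()))
        df[spec.name] = col
    df[CLASS_COLUMN] = labels
    return df


def simulate_expert_panel(
    features: list[str] | tuple[str, ...],
    n_experts: int = 4,
    concordance: float = 0.8,
    seed: int = 0,
) -> ExpertDecisionMatrix:
    """Simulate a panel of Likert importance ratings over ``features``.

    A latent importance level in 1..5 is drawn per feature; each expert
    reports the latent level, perturbed by +/-1 with probability
    ``1 - concordance`` (clipped to 1..5).  ``concordance = 1`` yields a
    perfectly agreeing panel.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    if not 0.0 <= concordance <= 1.0:
        raise ValueError(f"concordance must be in [0, 1], got {concordance}")
    rng = np.random.default_rng(seed)
    latent = rng.integers(1, 6, size=len(features))
    ratings = np.tile(latent, (n_experts, 1))
    perturb = rng.random(ratings.shape) < (1.0 - concordance)
    signs = rng.choice([-1, 1], size=ratings.shape)
    ratings = np.clip(ratings + perturb * signs, 1, 5)
    return ExpertDecisionMatrix(
        experts=tuple(f"E{i + 1}" for i in range(n_experts)),
        criteria=tuple(features),
        ratings=ratings.astype(int),
    )
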