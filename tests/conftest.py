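import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from asdbench import default_config, generate_dataset, preprocess
from asdbench.synth import CLASS_LABELS, FeatureSpec, GeneratorConfig


@pytest.fixture(scope="session")
def raw_cohort() -> pd.DataFrame:
    """Study-shaped synthetic cohort (538 rows, 241/259/38 classes)."""
    return generate_dataset(default_config(seed=7))


@pytest.fixture(scope="session")
def balanced_cohort(raw_cohort) -> pd.DataFrame:
    """The same cohort after the full Phase-1 pipeline."""
    balanced, _ = preprocess(raw_cohort, seed=7)
    return balanced


def noise_only_config(seed: int, counts=None) -> GeneratorConfig:
    """A cohort config with every class-conditional signal stripped."""
    schema = tuple(
        FeatureSpec(
            f.name, f.kind, categories=f.categories, lo=f.lo, hi=f.hi,
            missing_rate=0.0,
        )
        for f in default_config().schema
    )
    counts = counts or {"light": 259, "medium": 259, "intense": 259}
    return GeneratorConfig(class_counts=counts, schema=schema, seed=seed)


@pytest.fixture()
def tiny_raw() -> pd.DataFrame:
    """A 6-row mixed table with sentinels, for unit-level prep tests."""
    return pd.DataFrame(
        {
            "color": ["red", "blue", "?", "red", "blue", "red"],
            "age": [10, "?", 30, 20, 40, 30],
            "score": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "severity": ["light", "medium", "intense", "light", "medium", "intense"],
        }
    )
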