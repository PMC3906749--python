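import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import msetkit as mk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study() -> mk.SyntheticStudy:
    """An 800-gene study with DE genes, modules, lists, and qPCR planted."""
    return mk.simulate_study(mk.SimConfig(n_genes=800, seed=11))


@pytest.fixture(scope="session")
def ranked_small(small_study) -> pd.DataFrame:
    return mk.rank_genes(small_study.expression)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_study(values: np.ndarray, symbols=None) -> mk.ExpressionStudy:
    """Tiny ExpressionStudy from a gene x sample array (first half virgin)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // 2
    samples = [f"V{i}" for i in range(n)] + [f"P{i}" for i in range(values.shape[1] - n)]
    if symbols is None:
        symbols = [f"g{i}" for i in range(values.shape[0])]
    return mk.ExpressionStudy(
        pd.DataFrame(values, index=symbols, columns=samples),
        pd.Series([mk.VIRGIN] * n + [mk.POSTPARTUM] * (values.shape[1] - n),
                  index=samples),
    )
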