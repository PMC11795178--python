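import numpy as np
import pandas as pd
import pytest

from symptomnet import SyntheticScenario, simulate_study
from symptomnet.ggm import GgmConfig


@pytest.fixture(scope="session")
def fast_ggm() -> GgmConfig:
    """Reduced penalty grid used by simulation-heavy tests."""
    return GgmConfig(n_lambda=20, lambda_min_ratio=0.05)


@pytest.fixture(scope="session")
def small_study():
    """One simulated two-group study (n=300/group) with its ground truth."""
    table, model = simulate_study(SyntheticScenario(n_per_group=300, seed=7))
    return table, model


@pytest.fixture(scope="session")
def medium_table():
    """A larger single-group table for estimator behaviour tests."""
    table, model = simulate_study(SyntheticScenario(n_per_group=1000, seed=11))
    return table[table["group"] == "school"].reset_index(drop=True), model


def items_with_total(total: int, k: int) -> list[int]:
    """Distribute a target total over k items, each in 0..3 (greedy fill)."""
    assert 0 <= total <= 3 * k
    out = []
    remaining = total
    for i in range(k):
        v = min(3, remaining)
        out.append(v)
        remaining -= v
    assert remaining == 0
    return out
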