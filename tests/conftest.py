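import numpy as np
import pandas as pd
import pytest

from cgbnet import CohortTable, SimConfig, simulate_cohort
from cgbnet.bn import Node


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort at modest size, reused across read-only tests."""
    cfg = SimConfig(n_individuals=400, n_null_cpgs=10, seed=7)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


def continuous_cohort(arrays: dict[str, np.ndarray]) -> CohortTable:
    """All-continuous cohort from named arrays."""
    return CohortTable(pd.DataFrame(arrays), {k: "continuous" for k in arrays})


def bivariate_cohort(n: int, r: float, seed: int) -> CohortTable:
    """X, Y bivariate Gaussian with correlation r."""
    g = np.random.default_rng(seed)
    x = g.normal(size=n)
    y = r * x + np.sqrt(1.0 - r**2) * g.normal(size=n)
    return continuous_cohort({"X": x, "Y": y})


def chain_cohort(n: int, seed: int) -> CohortTable:
    """Strong X -> Y -> Z chain."""
    g = np.random.default_rng(seed)
    x = g.normal(size=n)
    y = 0.9 * x + 0.4 * g.normal(size=n)
    z = 0.9 * y + 0.4 * g.normal(size=n)
    return continuous_cohort({"X": x, "Y": y, "Z": z})


def random_mixed_problem(seed: int, n_rows: int = 300) -> CohortTable:
    """Random 4-node structure-learning problem: one binary root D plus
    three continuous nodes with random parents and effect sizes."""
    g = np.random.default_rng(seed)
    d = g.integers(0, 2, size=n_rows)
    cols: dict[str, np.ndarray] = {"D": d}
    order = ["D", "A", "B", "C"]
    for i, name in enumerate(order[1:], start=1):
        val = g.normal(size=n_rows)
        for parent in order[:i]:
            if g.random() < 0.5:
                coef = g.uniform(0.4, 1.2) * g.choice([-1.0, 1.0])
                val = val + coef * np.asarray(cols[parent], dtype=float)
        cols[name] = val
    df = pd.DataFrame(cols)
    kinds = {"D": "discrete", "A": "continuous", "B": "continuous", "C": "continuous"}
    return CohortTable(df, kinds)


def make_nodes(**kinds) -> list[Node]:
    return [
        Node(name, kind, levels=("0", "1") if kind == "discrete" else None)
        for name, kind in kinds.items()
    ]
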