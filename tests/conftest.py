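import numpy as np
import pandas as pd
import pytest

from xlapipe.cohort import CohortConfig, generate_cohort
from xlapipe.kb import load_kb
from xlapipe.preprocess import preprocess_cohort

KB1_ATTRS = ("igm_pct", "igg_pct", "iga_pct", "age_ob")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def processed(default_cohort) -> pd.DataFrame:
    return preprocess_cohort(default_cohort)


@pytest.fixture(scope="session")
def clean_processed() -> pd.DataFrame:
    """Noise-free cohort: every record satisfies its generating course rule."""
    return preprocess_cohort(generate_cohort(CohortConfig(seed=1, noise_level=0.0)))


@pytest.fixture(scope="session")
def kb1():
    return load_kb("kb1_course_ig")


@pytest.fixture(scope="session")
def kb2():
    return load_kb("kb2_mutation_ig")


def random_table(rng: np.random.Generator, n_rows: int, n_attrs: int, n_classes: int = 2) -> pd.DataFrame:
    """Small random classification table for oracle comparisons."""
    data = {f"x{j}": rng.normal(size=n_rows).round(3) for j in range(n_attrs)}
    labels = [f"c{k}" for k in rng.integers(0, n_classes, size=n_rows)]
    data["y"] = labels
    return pd.DataFrame(data)


def brute_force_best_split(table: pd.DataFrame, target: str, attributes):
    """Independent exhaustive split search: every (attribute, midpoint) pair,
    plain-Python Gini arithmetic, ties by attribute order then lower
    threshold."""

    def gini(labels) -> float:
        n = len(labels)
        return 1.0 - sum((list(labels).count(c) / n) ** 2 for c in set(labels))

    y = list(table[target])
    parent = gini(y)
    best = None
    for attr in attributes:
        x = list(table[attr])
        for threshold in sorted(
            {(a + b) / 2 for a, b in zip(sorted(set(x))[:-1], sorted(set(x))[1:])}
        ):
            left = [lab for v, lab in zip(x, y) if v < threshold]
            right = [lab for v, lab in zip(x, y) if v >= threshold]
            gain = parent - (len(left) / len(y)) * gini(left) - (len(right) / len(y)) * gini(right)
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (attr, threshold, gain)
    return best
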