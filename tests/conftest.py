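import numpy as np
import pandas as pd
import pytest

from fishnet_kit import ComplexSet, synthesize_base_matrix


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """10 proteins x 6 samples with distinct, all-positive counts."""
    rng = np.random.default_rng(42)
    values = rng.integers(1, 200, size=(10, 6)).astype(float)
    return pd.DataFrame(
        values,
        index=[f"P{i:02d}" for i in range(10)],
        columns=[f"S{j}" for j in range(6)],
    )


@pytest.fixture
def tiny_classes(tiny_matrix) -> pd.Series:
    return pd.Series(["a", "a", "a", "b", "b", "b"], index=tiny_matrix.columns, name="class")


@pytest.fixture
def tiny_complexes(tiny_matrix) -> ComplexSet:
    prot = list(tiny_matrix.index)
    return ComplexSet({"C1": prot[:3], "C2": prot[3:7], "C3": prot[6:10]})


@pytest.fixture(scope="session")
def null_matrix() -> pd.DataFrame:
    """A no-effect spectral-count-like matrix, 300 proteins x 12 samples."""
    return synthesize_base_matrix(300, 12, seed=123)


def make_rank_fixture(
    members: list[str],
    n_proteins: int = 30,
    n_class1: int = 4,
    n_class2: int = 4,
    high: float = 1000.0,
    low: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Matrix where ``members`` are the top-ranked proteins in class-1 samples
    only; all other proteins have identical mid-range values in every sample."""
    proteins = [f"G{i:02d}" for i in range(n_proteins)]
    assert all(m in proteins for m in members)
    cols = [f"A{k}" for k in range(n_class1)] + [f"B{k}" for k in range(n_class2)]
    base = np.linspace(10, 100, n_proteins)
    matrix = pd.DataFrame(
        np.tile(base[:, None], (1, len(cols))), index=proteins, columns=cols
    )
    for m in members:
        matrix.loc[m, cols[:n_class1]] = high + proteins.index(m)
        matrix.loc[m, cols[n_class1:]] = low
    classes = pd.Series(["a"] * n_class1 + ["b"] * n_class2, index=cols, name="class")
    return matrix, classes
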