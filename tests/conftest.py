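import numpy as np
import pandas as pd
import pytest

from texscreen.core import CountMatrix, ExpressionMatrix
from texscreen.simulate import SimulationConfig, simulate

LIBS = ["f-hl", "f-fl", "af-hl", "m-hl"]


def make_samples(libs=None, targets=("f-hl",)):
    libs = libs or LIBS
    return pd.DataFrame(
        {"label": libs, "is_target": [lib in targets for lib in libs]},
        index=pd.Index(libs, name="library"),
    )


def make_expr(profiles: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    samples = samples if samples is not None else make_samples()
    values = pd.DataFrame.from_dict(
        profiles, orient="index", dtype=float, columns=samples.index
    )
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, samples=samples)


@pytest.fixture
def samples():
    return make_samples()


@pytest.fixture
def toy_expr():
    """The worked 5-gene example: g1 and g2 should pass all filters."""
    return make_expr(
        {
            "g1": [100, 0, 0, 0],
            "g2": [10, 1, 2, 1],
            "g3": [10, 1, 3, 1],
            "g4": [9, 0, 0, 0],
            "g5": [50, 50, 50, 50],
        }
    )


@pytest.fixture
def small_config():
    """A fast study-structured simulation for unit tests."""
    return SimulationConfig(n_genes=500, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale default study design (20,918 genes, 4 libraries)."""
    return simulate(SimulationConfig(seed=1))


def make_count_matrix(counts: dict[str, list[int]], samples=None) -> CountMatrix:
    samples = samples if samples is not None else make_samples()
    df = pd.DataFrame.from_dict(
        counts, orient="index", dtype=np.int64, columns=samples.index
    )
    df.index.name = "gene_id"
    return CountMatrix(counts=df, samples=samples)
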