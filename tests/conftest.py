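import numpy as np
import pytest

from debench import ExpressionMatrix, SimulationConfig, simulate_matrix

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_matrix(values, gene_ids=None, sample_ids=None, sorted_by_mean=False):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(s)]
    return ExpressionMatrix(
        np.asarray(gene_ids, dtype=object),
        np.asarray(sample_ids, dtype=object),
        values,
        sorted_by_mean,
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default-profile matrix plus cohort metadata (20,000 x 20)."""
    return simulate_matrix(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def benchmark_matrix():
    """Benchmark-profile matrix: most probes quantifiable (20,000 x 20)."""
    matrix, _ = simulate_matrix(SimulationConfig.benchmark_default(seed=11))
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
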