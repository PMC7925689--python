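import numpy as np
import pandas as pd
import pytest

from hypoxpipe import SimulationConfig, simulate
from hypoxpipe.nascent import RegionCountMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=1, n_genes=60)


@pytest.fixture(scope="session")
def gene_sim(small_config):
    return simulate.simulate_gene_models(small_config)


@pytest.fixture(scope="session")
def nascent_counts(gene_sim, small_config):
    return simulate.simulate_nascent_counts(gene_sim.truth, small_config)


def make_rcm(counts, lengths, region="tss", library_sizes=None, samples=None):
    """Convenience constructor for small hand-built count matrices."""
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    return RegionCountMatrix.from_counts(
        region, counts, np.asarray(lengths, dtype=float),
        samples=samples,
        library_sizes=None if library_sizes is None else pd.Series(
            np.asarray(library_sizes, dtype=float), index=counts.columns),
    )
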