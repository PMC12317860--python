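import numpy as np
import pandas as pd
import pytest

from clonekit import genio, sim
from clonekit.core import GenotypeMatrix, make_site_table


def complete_metadata(samples: pd.DataFrame, tmp_path) -> pd.DataFrame:
    """Route a raw sample table through the metadata reader so tests see
    exactly what the pipeline sees (name_key, is_unknown, ...)."""
    path = tmp_path / "meta.tsv"
    genio.write_sample_metadata(samples, path)
    return genio.read_sample_metadata(path)


@pytest.fixture
def meta(tmp_path):
    def _make(samples):
        return complete_metadata(samples, tmp_path)

    return _make


@pytest.fixture
def small_cohort():
    """Two pools, one F1 pair, three clone groups, mild noise: the
    smallest cohort on which every stage is exercised."""
    pools = sim.simulate_pools(k_pools=2, n_sites=3000, fst=0.3, seed=11)
    spec = sim.CohortSpec(
        n_per_pool=(6, 6),
        hybrids=[(0.5, 2)],
        clone_groups=[(0, 3), (7, 4), (3, 2)],
        n_sites=3000,
        noise=(0.05, 0.005, 0.05),
        seed=21,
    )
    G, samples, truth = sim.simulate_cohort(spec, pools)
    sites = sim.default_site_table(spec.n_sites)
    return G, samples, truth, sites


@pytest.fixture
def tiny_matrix():
    """Hand-built 4-sample x 5-site matrix with a missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 1, 2, 0, 1],
            [2, 1, 0, 2, -1],
            [2, 0, 0, 2, 2],
        ],
        dtype=np.int8,
    )
    G = GenotypeMatrix(calls, ["a", "b", "c", "d"])
    sites = make_site_table(
        ["1", "1", "1", "2", "2"],
        [100, 1500, 2600, 100, 5000],
        list("ACGTA"),
        list("TGCAC"),
    )
    return G, sites
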