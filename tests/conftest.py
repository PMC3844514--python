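import numpy as np
import pytest

from domestiscan.io_model import GenotypeMatrix, PopulationMap


def make_matrix(calls, pos=None, chrom="chr1", sample_prefix="S"):
    """Small GenotypeMatrix from a nested list of dosages (sites × samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    ref = np.array(["A"] * n_sites, dtype=object)
    alt = np.array(["G"] * n_sites, dtype=object)
    m = GenotypeMatrix(
        np.array([chrom] * n_sites, dtype=object), np.asarray(pos), ref, alt,
        calls, [f"{sample_prefix}{i}" for i in range(n_samples)],
    )
    m.validate()
    return m


@pytest.fixture
def three_pool_matrix():
    """6 sites × 6 samples: two samples per pool, varied polymorphism."""
    calls = [
        # W0 W1 L0 L1 E0 E1
        [0, 1, 0, 0, 0, 0],   # polymorphic in wild only
        [1, 1, 1, 1, 1, 1],   # het everywhere
        [0, 0, 0, 1, 0, 0],   # polymorphic in landrace only
        [0, 2, 0, 2, 0, 2],   # polymorphic in all three
        [2, 2, 2, 2, 2, 2],   # fixed alt everywhere (monomorphic)
        [0, 1, 1, 2, -1, 0],  # missing call in elite
    ]
    m = make_matrix(calls)
    pm = PopulationMap({"S0": "wild", "S1": "wild", "S2": "landrace",
                        "S3": "landrace", "S4": "elite", "S5": "elite"})
    return m, pm


@pytest.fixture(scope="session")
def default_panel():
    """One default simulated panel shared across tests (seed 7)."""
    from domestiscan.io_model import Interval
    from domestiscan.synthetic_data import (DemographyConfig, SweepSpec,
                                            simulate_panel)

    demo = DemographyConfig(seed=7, n_sites=20_000, chrom_length=1_250_000)
    sweeps = [
        SweepSpec(Interval("chr1", 300_000, 400_000), "domestication", 0.05),
        SweepSpec(Interval("chr1", 800_000, 900_000), "improvement", 0.05),
    ]
    return simulate_panel(demo, sweeps)
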