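import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrkit import Clonotype, Repertoire, SimulationConfig, simulate_repertoire

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_repertoire(records, sample_id="test"):
    """records: iterable of (cdr3, v, j, count)."""
    return Repertoire(
        sample_id=sample_id,
        clonotypes=[Clonotype(cdr3_aa=s, v_gene=v, j_gene=j, count=n) for s, v, j, n in records],
    )


@pytest.fixture
def small_rep():
    return make_repertoire(
        [
            ("CASSLGETQYF", "TRBV12-3", "TRBJ2-7", 10),
            ("CASSLDRGSEQYF", "TRBV5-1", "TRBJ2-7", 5),
            ("CASRRGDTEAFF", "TRBV2", "TRBJ1-1", 3),
            ("CASSPGQGAYEQYW", "TRBV2", "TRBJ2-7", 2),
        ]
    )


@pytest.fixture
def sim_rep():
    return simulate_repertoire(SimulationConfig(n_clones=300, seed=42), "sim300")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
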