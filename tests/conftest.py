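import numpy as np
import pytest

from bedcrypt import HEParams, build_signals
from bedcrypt.he import get_backend
from bedcrypt import dbstore, synth
from bedcrypt.server import LoopbackTransport, host_db


PARAMS_4096 = HEParams(poly_degree=4096)
PARAMS_8192 = HEParams(poly_degree=8192)


@pytest.fixture(scope="session")
def mock_backend():
    return get_backend("mock")


@pytest.fixture(scope="session")
def bfv_backend():
    return get_backend("bfv")


@pytest.fixture(scope="session")
def mock_keys(mock_backend):
    return mock_backend.keygen(PARAMS_4096, seed=1)


@pytest.fixture(scope="session")
def bfv_keys(bfv_backend):
    """Small-ring lattice keys for fast real-backend tests."""
    return bfv_backend.keygen(PARAMS_4096, seed=1)


@pytest.fixture(scope="session")
def bfv_keys_8192(bfv_backend):
    """Reference-parameter lattice keys (N=8192, 30-bit t, 218-bit chain)."""
    return bfv_backend.keygen(PARAMS_8192, seed=1)


@pytest.fixture(scope="session")
def worked_fixture():
    return synth.make_fixture()


class Pipeline:
    """Encrypted pipeline around a database track, for oracle comparisons."""

    def __init__(self, b, layout, backend, keys, chunk_size=None, seed=7,
                 epoch=0):
        self.layout = layout
        self.backend = backend
        self.keys = keys
        self.signals = build_signals(b, layout)
        self.db, self.manifest, self.perm = dbstore.build_database(
            self.signals, keys, backend, secret_seed=seed, epoch=epoch,
            chunk_size=chunk_size)
        self.handle = host_db(self.db, keys)
        self.transport = LoopbackTransport(self.handle)

    def run(self, spec, **kw):
        from bedcrypt.client import run_query
        return run_query(spec, self.layout, self.manifest, self.perm,
                         self.transport, self.keys, self.backend, **kw)


@pytest.fixture
def make_pipeline():
    return Pipeline


def random_instance(seed, L=10_000, max_n=200, min_len=5, max_len=40):
    """Seeded random (A, B, layout) pair for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(1, max_n + 1))
    n_b = int(rng.integers(1, max_n + 1))
    cfg_b = synth.SynthConfig(seed=seed * 2 + 1, n_intervals=n_b,
                              chrom_lengths={"chr1": L},
                              length_dist=("uniform", min_len, max_len))
    cfg_a = synth.SynthConfig(seed=seed * 2 + 2, n_intervals=n_a,
                              chrom_lengths={"chr1": L},
                              length_dist=("uniform", min_len, max_len))
    return (synth.generate_bed(cfg_a), synth.generate_bed(cfg_b),
            synth.layout_of(cfg_b))
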