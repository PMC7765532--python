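import numpy as np
import pytest

from p300decode import SimulationConfig, preprocess, simulate_session


@pytest.fixture(scope="session")
def small_config():
    """A short default-condition session: 5 symbols, 100 target flashes."""
    return SimulationConfig(n_symbols=5, min_target_flashes=100, seed=20250901)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def small_trimmed(small_recording):
    trimmed, _ = preprocess(small_recording)
    return trimmed


@pytest.fixture(scope="session")
def small_clean(small_recording):
    _, clean = preprocess(small_recording)
    return clean


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def cca_svd_oracle(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Independent CCA oracle: whiten both blocks via SVD, then take the
    singular values of the cross-product of the whitened bases."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    Up, _, _ = np.linalg.svd(Pc, full_matrices=False)
    Uq, _, _ = np.linalg.svd(Qc, full_matrices=False)
    return np.linalg.svd(Up.T @ Uq, compute_uv=False)
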