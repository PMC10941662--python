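import numpy as np
import pytest

from specmix import simulate as sim


@pytest.fixture(scope="session")
def scheme():
    return sim.default_scheme()


@pytest.fixture(scope="session")
def fluorophores():
    return sim.default_fluorophores()


@pytest.fixture(scope="session")
def af_spectrum(scheme):
    return sim.predict_response(sim.default_af_model(), scheme)


@pytest.fixture(scope="session")
def reference_and_peaks():
    """Noise-free 11-column reference matrix and per-column peak responses."""
    return sim.true_reference_matrix()


@pytest.fixture(scope="session")
def pair_reference():
    """Two-fluorophore + AF reference (redundant-detection channel pair)."""
    fl = sim.default_fluorophores()
    pair = [fl[3], fl[6]]  # F514 / F633: well separated, both overlap AF
    ref, peaks = sim.true_reference_matrix(pair)
    return pair, ref, peaks


def rng_instances(seed, n):
    """Independent child RNGs for repeated randomized test instances."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
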