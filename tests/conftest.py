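import numpy as np
import pytest

from undufiber import dspec_sim, encoding, substrate

GRID_A = (1.0, 2.0, 3.0)
GRID_LAM = (10.0, 20.0, 30.0, 40.0, 50.0)

#: muOD reference values for the 3x5 harmonic grid (printed to 2-3 figures).
MUOD_TABLE = {
    (1, 10): 0.16, (1, 20): 0.05, (1, 30): 0.02, (1, 40): 0.01, (1, 50): 0.008,
    (2, 10): 0.41, (2, 20): 0.16, (2, 30): 0.08, (2, 40): 0.05, (2, 50): 0.03,
    (3, 10): 0.59, (3, 20): 0.29, (3, 30): 0.16, (3, 40): 0.10, (3, 50): 0.07,
}


@pytest.fixture(scope="session")
def grid_spectra():
    """Gaussian-sampling spectra of the full 15-substrate harmonic grid at
    the default grids (dl = 0.1 um, D0 = 1.7 um^2/ms, t_max = 2 s)."""
    out = {}
    for a in GRID_A:
        for lam in GRID_LAM:
            traj, msd, spec = dspec_sim.simulate_harmonic_spectrum(a, lam)
            out[(a, lam)] = {
                "traj": traj,
                "msd": msd,
                "spec": spec,
                "mu_od": substrate.microscopic_orientation_dispersion(traj),
            }
    return out


@pytest.fixture(scope="session")
def protocol():
    """Encoding spectra of the four reference PGSE waveforms."""
    return [encoding.encoding_spectrum(w) for w in encoding.alexander_protocol()]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
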