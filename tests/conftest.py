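import numpy as np
import pytest

from metabolink.core_model import Spectrum
from metabolink.iokr import FingerprintVector, PrecomputedFingerprinter, fit_iokr
from metabolink.synthetic_data import fig2_fixture


@pytest.fixture(scope="session")
def fig2_bundle():
    return fig2_fixture()


@pytest.fixture(scope="session")
def fig2_occurrence(fig2_bundle):
    return fig2_bundle.occurrence()


def _toy_spectrum(sid, mz, intensity):
    return Spectrum(id=sid, peaks=tuple(zip(mz, intensity)))


@pytest.fixture
def toy_spectrum_factory():
    return _toy_spectrum


@pytest.fixture(scope="session")
def toy_training_set():
    """Five distinct 3-peak spectra paired with distinct 6-bit fingerprints."""
    rng = np.random.default_rng(42)
    pairs = []
    fps = [
        (1, 1, 0, 0, 1, 0),
        (0, 1, 1, 0, 0, 1),
        (1, 0, 1, 1, 0, 0),
        (0, 0, 1, 0, 1, 1),
        (1, 0, 0, 1, 1, 0),
    ]
    for i, bits in enumerate(fps):
        mz = np.sort(rng.uniform(100, 500, size=3))
        inten = rng.uniform(0.2, 1.0, size=3)
        pairs.append(
            (_toy_spectrum(f"toy_{i}", mz.tolist(), inten.tolist()),
             FingerprintVector(bits=bits))
        )
    return pairs


@pytest.fixture(scope="session")
def toy_model(toy_training_set):
    # unbounded peak-match tolerance so arbitrary query peaks are retained
    from metabolink.iokr import SpectrumKernelParams

    params = SpectrumKernelParams(sigma_mz=50.0, peak_match_tol=np.inf)
    return fit_iokr(toy_training_set, params=params, lambda_reg=1e-6)


@pytest.fixture
def precomputed_backend():
    return PrecomputedFingerprinter(
        {
            "KEYAAAAAAAAAA": FingerprintVector(bits=(1, 0, 1, 0)),
            "CCO": FingerprintVector(bits=(0, 1, 1, 0)),
        }
    )


def random_spectra(n, rng, n_peaks=(3, 12), mz_range=(100.0, 900.0)):
    """Random peak lists for kernel property tests."""
    out = []
    for i in range(n):
        k = int(rng.integers(*n_peaks))
        mz = np.sort(rng.uniform(*mz_range, size=k))
        inten = rng.uniform(0.05, 1.0, size=k)
        out.append(_toy_spectrum(f"rand_{i}", mz.tolist(), inten.tolist()))
    return out
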