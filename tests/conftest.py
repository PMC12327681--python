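import numpy as np
import pytest

from msmce.ms_io import Run, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_run(rng: np.random.Generator, n_spectra: int = 5, n_peaks: int = 20,
               label: str = "a", file_id: str = "run0",
               mz_range: tuple[float, float] = (100.0, 500.0)) -> Run:
    """A valid random Run for round-trip and property tests."""
    spectra = []
    for i in range(n_spectra):
        mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
        while np.any(np.diff(mz) <= 0):  # enforce strict monotonicity
            mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
        intensity = rng.lognormal(8.0, 1.0, size=n_peaks)
        spectra.append(Spectrum(mz, intensity, rt=float(i)))
    return Run(spectra, label=label, file_id=file_id)


@pytest.fixture
def make_run(rng):
    def _make(**kwargs):
        return random_run(rng, **kwargs)
    return _make
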