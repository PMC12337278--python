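import numpy as np
import pytest

from micromrs.spectra import Spectrum
from micromrs.synthdata import (
    CohortEffect,
    SynthConfig,
    generate_cohort,
    preset_config,
)
from micromrs.biomarkers import build_feature_table


def lorentzian(x, center, fwhm, amp):
    g = fwhm / 2.0
    return amp * g**2 / ((x - center) ** 2 + g**2)


@pytest.fixture
def axis():
    return np.linspace(0.0, 10.0, 4096)


@pytest.fixture
def water_spectrum(axis):
    """Noiseless referenced spectrum: water at 4.70 + one Saturate Lorentzian."""
    y = lorentzian(axis, 4.70, 0.08, 20.0) + lorentzian(axis, 1.30, 0.12, 1.0)
    return Spectrum(ppm=axis, intensity=y, metadata={"sample_id": "w0"},
                    referenced=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12+6 two-class cohort with the default planted effects (fast)."""
    cfg = preset_config("embryo61", seed=3)
    cfg.n_per_class = {"ARR": 12, "DEV": 6}
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    spectra, labels = small_cohort
    return build_feature_table(spectra, labels)


@pytest.fixture(scope="session")
def embryo_table():
    """Full embryo-shaped cohort (54 ARR / 7 DEV), default planted effects."""
    spectra, labels = generate_cohort(preset_config("embryo61", seed=0))
    return build_feature_table(spectra, labels)
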