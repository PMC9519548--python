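import numpy as np
import pytest

from eemqda.core import WavelengthAxes
from eemqda.synthetic import CohortSpec, Fluorophore, generate_cohort


def small_axes() -> WavelengthAxes:
    """Coarse grid (11 x 111) for fast tests; same wavelength ranges as the full grid."""
    return WavelengthAxes(np.arange(250.0, 351.0, 10.0), np.arange(300.0, 851.0, 5.0))


def small_spec(seed: int = 11, **overrides) -> CohortSpec:
    """A 20 AD / 30 HC cohort on the coarse grid."""
    defaults = dict(seed=seed, n_ad=20, n_hc=30, axes=small_axes())
    defaults.update(overrides)
    if "fluorophores" in defaults and "marker" not in overrides:
        defaults["marker"] = defaults["fluorophores"][0].name
    return CohortSpec(**defaults)


def clean_spec(seed: int = 5, **overrides) -> CohortSpec:
    """Noiseless, scatter-free, unit-gain cohort: exactly trilinear by construction."""
    defaults = dict(noise_sd=0.0, gain_cv=0.0, rayleigh1_amplitude=0.0,
                    rayleigh2_amplitude=0.0, raman_amplitude=0.0)
    defaults.update(overrides)
    return small_spec(seed=seed, **defaults)


@pytest.fixture
def tiny_cohort():
    """5-sample cohort with scatter and noise, full default grid."""
    spec = CohortSpec(seed=1, n_ad=2, n_hc=3)
    return generate_cohort(spec)


@pytest.fixture
def rank3_fluorophores():
    """Three well-separated Gaussian bands (linearly independent profiles)."""
    return (
        Fluorophore("f1", 270.0, 12.0, 320.0, 25.0),
        Fluorophore("f2", 310.0, 15.0, 420.0, 35.0),
        Fluorophore("f3", 345.0, 14.0, 540.0, 45.0),
    )
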