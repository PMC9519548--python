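"""Synthetic blood-plasma EEM cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* an exact trilinear signal — each sample is a non-negative mixture of a few
  Gaussian-band fluorophores (concentration x excitation profile x emission
  profile);
* log-normal concentrations with class-specific means, the disease effect
  implemented as a reduced mean of one designated marker component (an
  NADH-like band emitting near 465 nm, so diseased samples lose intensity in
  the ~360-470 nm emission region);
* first/second-order Rayleigh and water-Raman scatter ridges;
* a per-sample multiplicative gain and i.i.d. additive Gaussian noise.

Everything is reproducible from the mandatory seed, and the returned ground
truth carries the concentrations, profiles and the signal/noise sum-of-squares
bookkeeping used by recovery tests.  The default cohort matches the study
shape this package targets: 83 diseased + 147 control samples on an
excitation 250-350 nm (step 10) x emission 300-850 nm (step 1) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import EEMCube, SampleTable, WavelengthAxes
from .preprocess import raman_emission_nm


@dataclass(frozen=True)
class Fluorophore:
    """A Gaussian excitation/emission band pair."""

    name: str
    excitation_center_nm: float
    excitation_width_nm: float
    emission_center_nm: float
    emission_width_nm: float

    def __post_init__(self) -> None:
        if min(self.excitation_width_nm, self.emission_width_nm) <= 0:
            raise ValueError("band widths must be > 0")

    def profiles(self, axes: WavelengthAxes) -> tuple[np.ndarray, np.ndarray]:
        ex = np.exp(-0.5 * ((axes.excitation_nm - self.excitation_center_nm) / self.excitation_width_nm) ** 2)
        em = np.exp(-0.5 * ((axes.emission_nm - self.emission_center_nm) / self.emission_width_nm) ** 2)
        return ex, em


def default_fluorophores() -> list[Fluorophore]:
    """Plasma-inspired presets (placements only, not biological claims):
    a tyrosine-like band, a glycated-amyloid-like band, an NADH-like band
    (the disease marker), and a broad collagen/elastin-like band.

    The excitation bands are deliberately distinct: components sharing an
    identical excitation profile would violate the k-rank condition for
    trilinear uniqueness, making the mixture unrecoverable by construction.
    """
    return [
        Fluorophore("tyrosine_like", 275.0, 15.0, 305.0, 30.0),
        Fluorophore("glycated_ab_like", 335.0, 15.0, 399.0, 30.0),
        Fluorophore("nadh_like", 350.0, 18.0, 465.0, 30.0),
        Fluorophore("collagen_like", 310.0, 22.0, 400.0, 60.0),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for a two-class synthetic cohort.

    ``marker`` names the fluorophore whose diseased-class concentration mean
    is shifted down by ``marker_effect_sd`` standard deviations (SD =
    CV x control mean).  ``seed`` is mandatory.
    """

    seed: int
    n_ad: int = 83
    n_hc: int = 147
    axes: WavelengthAxes = field(default_factory=WavelengthAxes.default_grid)
    fluorophores: tuple[Fluorophore, ...] = field(default_factory=lambda: tuple(default_fluorophores()))
    concentration_means: tuple[float, ...] = (1.0, 0.6, 0.8, 0.5)
    concentration_cv: float = 0.25
    marker: str = "nadh_like"
    marker_effect_sd: float = 2.0
    gain_cv: float = 0.10
    noise_sd: float = 0.02
    # ridge widths follow the few-nm spectral bandwidth of a scanning
    # spectrofluorometer, so the standard excision half-widths (12/15/10 nm)
    # cover > 3 sigma of every ridge
    rayleigh1_amplitude: float = 3.0
    rayleigh1_width_nm: float = 4.0
    rayleigh2_amplitude: float = 1.0
    rayleigh2_width_nm: float = 5.0
    raman_amplitude: float = 0.5
    raman_width_nm: float = 3.5
    raman_shift_cm1: float = 3400.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.concentration_means) != len(self.fluorophores):
            raise ValueError("one concentration mean per fluorophore required")
        if min(self.concentration_means) < 0:
            raise ValueError("concentration means must be >= 0")
        if self.marker not in {f.name for f in self.fluorophores}:
            raise ValueError(f"marker {self.marker!r} not among fluorophores")
        if self.concentration_cv < 0 or self.gain_cv < 0 or self.noise_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.n_ad < 1 or self.n_hc < 1:
            raise ValueError("class sizes must be >= 1")


@dataclass
class GroundTruth:
    """What the generator knows: mixing weights, profiles, SS bookkeeping."""

    concentrations: np.ndarray       # (n_samples, n_fluorophores), gain included
    excitation_profiles: np.ndarray  # (J, n_fluorophores)
    emission_profiles: np.ndarray    # (K, n_fluorophores)
    gains: np.ndarray                # per-sample multiplicative gain
    ss_signal: float                 # trilinear signal sum of squares (gain applied)
    ss_scatter: float                # scatter ridge sum of squares
    ss_noise: float                  # additive noise sum of squares


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and coefficient of variation."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _scatter_field(spec: CohortSpec) -> np.ndarray:
    """Deterministic (J, K) scatter ridge template, unit concentration."""
    ex = spec.axes.excitation_nm[:, None]
    em = spec.axes.emission_nm[None, :]
    field_ = spec.rayleigh1_amplitude * np.exp(-0.5 * ((em - ex) / spec.rayleigh1_width_nm) ** 2)
    field_ += spec.rayleigh2_amplitude * np.exp(-0.5 * ((em - 2 * ex) / spec.rayleigh2_width_nm) ** 2)
    raman = raman_emission_nm(ex, spec.raman_shift_cm1)
    field_ += spec.raman_amplitude * np.exp(-0.5 * ((em - raman) / spec.raman_width_nm) ** 2)
    return field_


def generate_cohort(spec: CohortSpec) -> tuple[EEMCube, SampleTable, GroundTruth]:
    """Draw a cohort; diseased (AD) samples first, then controls (HC).

    The signal is exactly trilinear before scatter and noise, so with zero
    noise/gain-CV/scatter amplitudes the cube has rank equal to the number of
    fluorophores and PARAFAC at that rank fits it perfectly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ad + spec.n_hc
    names = [f.name for f in spec.fluorophores]
    marker_idx = names.index(spec.marker)

    # class-specific concentration means: marker mean reduced for AD
    means_hc = np.asarray(spec.concentration_means, dtype=float)
    means_ad = means_hc.copy()
    sd_marker = spec.concentration_cv * means_hc[marker_idx]
    means_ad[marker_idx] = max(means_hc[marker_idx] - spec.marker_effect_sd * sd_marker, 1e-6)

    conc = np.zeros((n, len(names)))
    for f in range(len(names)):
        for rows, mean in ((slice(0, spec.n_ad), means_ad[f]), (slice(spec.n_ad, n), means_hc[f])):
            if spec.concentration_cv == 0:
                conc[rows, f] = mean
            else:
                mu, sigma = _lognormal_params(mean, spec.concentration_cv)
                conc[rows, f] = rng.lognormal(mu, sigma, size=conc[rows, f].shape)

    ex_prof = np.stack([f.profiles(spec.axes)[0] for f in spec.fluorophores], axis=1)  # (J, F)
    em_prof = np.stack([f.profiles(spec.axes)[1] for f in spec.fluorophores], axis=1)  # (K, F)

    gains = np.ones(n)
    if spec.gain_cv > 0:
        mu, sigma = _lognormal_params(1.0, spec.gain_cv)
        gains = rng.lognormal(mu, sigma, size=n)
    eff_conc = conc * gains[:, None]  # gain commutes into the sample mode

    signal = np.einsum("if,jf,kf->ijk", eff_conc, ex_prof, em_prof)
    scatter = _scatter_field(spec)[None, :, :] * gains[:, None, None]
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else np.zeros_like(signal)

    cube = EEMCube(signal + scatter + noise, spec.axes)
    table = SampleTable(
        [f"AD{i:03d}" for i in range(spec.n_ad)] + [f"HC{i:03d}" for i in range(spec.n_hc)],
        ["AD"] * spec.n_ad + ["HC"] * spec.n_hc,
    )
    truth = GroundTruth(
        concentrations=eff_conc,
        excitation_profiles=ex_prof,
        emission_profiles=em_prof,
        gains=gains,
        ss_signal=float((signal**2).sum()),
        ss_scatter=float((scatter**2).sum()),
        ss_noise=float((noise**2).sum()),
    )
    return cube, table, truth


def effect_size_sweep(spec: CohortSpec, deltas) -> list[tuple[float, EEMCube, SampleTable, GroundTruth]]:
    """One cohort per effect size (marker mean shift in SD units).

    Each cohort uses a distinct child seed derived from ``spec.seed`` so that
    sweeps differ only in the effect size and the draw, never in structure.
    """
    out = []
    for i, d in enumerate(deltas):
        if d < 0:
            raise ValueError("deltas must be >= 0")
        sub = replace(spec, marker_effect_sd=float(d), seed=(spec.seed * 1000 + i) % (2**31 - 1))
        out.append((float(d), *generate_cohort(sub)))
    return out
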