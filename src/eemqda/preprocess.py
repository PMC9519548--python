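"""Spectral preprocessing: scatter excision, gap filling, and MSC.

First- and second-order Rayleigh scatter lies along emission = excitation and
emission = 2 x excitation; the water Raman band sits at a fixed wavenumber
shift below the excitation line, i.e. at emission wavelength

    raman_em(ex) = 1 / (1/ex - raman_shift_cm1 * 1e-7)   [nm]

These ridges carry no fluorophore information and would otherwise dominate a
trilinear fit, so cells within a half-width of each ridge are masked and then
interpolated along the emission axis.  Multiplicative scatter correction (MSC)
then regresses each sample's unfolded spectrum on a reference spectrum and
removes the fitted per-sample offset and gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import EEMCube

FillMode = Literal["interpolate", "missing", "zero_below_rayleigh1"]


@dataclass(frozen=True)
class ScatterParams:
    """Half-widths (nm) of the scatter bands and the water Raman shift.

    ``fill_mode`` governs the physically signal-free region below the first
    Rayleigh line (emission < excitation):

    * ``"zero_below_rayleigh1"`` (default) — set those cells to zero and leave
      them unmasked; only the ridges themselves are masked for interpolation.
    * ``"interpolate"`` — mask the region too, so the fill stage extends into it.
    * ``"missing"`` — mask it and leave it to the caller (no fill implied).
    """

    rayleigh1_halfwidth_nm: float = 12.0
    rayleigh2_halfwidth_nm: float = 15.0
    raman_shift_cm1: float = 3400.0
    raman_halfwidth_nm: float = 10.0
    fill_mode: FillMode = "zero_below_rayleigh1"

    def __post_init__(self) -> None:
        if min(self.rayleigh1_halfwidth_nm, self.rayleigh2_halfwidth_nm, self.raman_halfwidth_nm) < 0:
            raise ValueError("halfwidths must be >= 0")
        if self.raman_shift_cm1 <= 0:
            raise ValueError("raman_shift_cm1 must be > 0")
        if self.fill_mode not in ("interpolate", "missing", "zero_below_rayleigh1"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


def raman_emission_nm(excitation_nm: np.ndarray | float, raman_shift_cm1: float = 3400.0) -> np.ndarray:
    """Emission wavelength (nm) of the Raman band for a given excitation.

    Converts the fixed wavenumber shift (cm^-1) to the emission scale:
    1e7/em = 1e7/ex - shift.
    """
    ex = np.asarray(excitation_nm, dtype=float)
    return 1.0 / (1.0 / ex - raman_shift_cm1 * 1e-7)


def scatter_mask(cube_axes, params: ScatterParams) -> np.ndarray:
    """Boolean (J, K) mask of scatter-band cells; deterministic in axes+params."""
    ex = cube_axes.excitation_nm[:, None]  # (J, 1)
    em = cube_axes.emission_nm[None, :]    # (1, K)
    m = np.abs(em - ex) <= params.rayleigh1_halfwidth_nm
    m |= np.abs(em - 2.0 * ex) <= params.rayleigh2_halfwidth_nm
    m |= np.abs(em - raman_emission_nm(ex, params.raman_shift_cm1)) <= params.raman_halfwidth_nm
    return m


def excise_scatter(cube: EEMCube, params: ScatterParams = ScatterParams()) -> EEMCube:
    """Mask Rayleigh (1st/2nd order) and Raman scatter regions.

    Idempotent: the mask is a function of the wavelength axes and the
    parameters only.  Raises if some excitation's entire emission vector would
    be masked (interpolation would then be impossible).
    """
    band = scatter_mask(cube.axes, params)
    x = cube.intensities.copy()
    below = cube.axes.emission_nm[None, :] < cube.axes.excitation_nm[:, None]
    below &= ~band
    if params.fill_mode == "zero_below_rayleigh1":
        x[:, below] = 0.0
    else:  # masked together with the bands
        band = band | below

    dead = band.all(axis=1)
    if dead.any():
        ex_bad = cube.axes.excitation_nm[dead]
        raise ValueError(
            f"scatter mask covers the entire emission vector at excitation {ex_bad.tolist()} nm"
        )
    mask = np.broadcast_to(band, cube.shape).copy()
    if cube.mask is not None:
        mask |= cube.mask
    x[mask] = 0.0  # masked values are meaningless; keep the array finite
    return EEMCube(x, cube.axes, mask)


def fill_masked(cube: EEMCube) -> EEMCube:
    """Replace masked cells by monotone piecewise-cubic (PCHIP) interpolation.

    Interpolation runs along the emission axis per (sample, excitation)
    vector; masked runs beyond the observed support are extended with the
    nearest observed value.  Unmasked cells are untouched (bitwise); the mask
    is cleared.  Requires >= 2 observed points per vector.
    """
    if cube.mask is None or not cube.mask.any():
        return EEMCube(cube.intensities.copy(), cube.axes, None)
    x = cube.intensities.copy()
    em = cube.axes.emission_nm
    for i in range(cube.n_samples):
        for j in range(cube.shape[1]):
            miss = cube.mask[i, j]
            if not miss.any():
                continue
            obs = ~miss
            n_obs = int(obs.sum())
            if n_obs < 2:
                raise ValueError(
                    f"sample {i}, excitation {cube.axes.excitation_nm[j]} nm: "
                    f"{n_obs} unmasked emission point(s), need >= 2 to interpolate"
                )
            interp = PchipInterpolator(em[obs], x[i, j, obs], extrapolate=False)
            filled = interp(em[miss])
            # nearest-value constant extension outside the observed support
            lo, hi = em[obs][0], em[obs][-1]
            target = em[miss]
            filled[target < lo] = x[i, j, obs][0]
            filled[target > hi] = x[i, j, obs][-1]
            x[i, j, miss] = filled
    return EEMCube(x, cube.axes, None)


@dataclass
class MscCoefficients:
    """Per-sample offset/gain from the MSC regression, and the reference used."""

    offset: np.ndarray      # a_i
    slope: np.ndarray       # b_i
    reference: np.ndarray   # unfolded reference spectrum m


def msc_correct(
    cube: EEMCube,
    reference: np.ndarray | None = None,
    reference_samples: Sequence[int] | None = None,
) -> tuple[EEMCube, MscCoefficients]:
    """Multiplicative scatter correction on unfolded EEM vectors.

    Each sample's unfolded vector ``x_i`` is regressed on the reference ``m``
    by ordinary least squares, ``x_i ~ a_i + b_i m``, and corrected to
    ``(x_i - a_i) / b_i``.  This exactly inverts any per-sample affine
    distortion of the reference.

    ``reference`` defaults to the mean unfolded vector over
    ``reference_samples`` (typically the training set, to avoid test-set
    leakage) or over all samples when neither is given.
    """
    if not cube.is_complete:
        raise ValueError("MSC requires a complete cube; run fill_masked first")
    X = cube.unfold()
    if reference is None:
        sel = np.arange(cube.n_samples) if reference_samples is None else np.asarray(reference_samples)
        m = X[sel].mean(axis=0)
    else:
        m = np.asarray(reference, dtype=float).ravel()
        if m.size != X.shape[1]:
            raise ValueError("reference length does not match unfolded cube")

    mc = m - m.mean()
    denom = mc @ mc
    if denom == 0:
        raise ValueError("constant reference spectrum: MSC slope undefined")
    b = (X @ mc) / denom
    a = X.mean(axis=1) - b * m.mean()
    if np.any(np.abs(b) < 1e-12):
        bad = np.nonzero(np.abs(b) < 1e-12)[0]
        raise ValueError(f"MSC slope within 1e-12 of zero for sample(s) {bad.tolist()}")
    corrected = (X - a[:, None]) / b[:, None]
    out = EEMCube(corrected.reshape(cube.shape), cube.axes, None)
    return out, MscCoefficients(offset=a, slope=b, reference=m)
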