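"""Core containers: wavelength axes, the three-way EEM cube, and the sample table.

Orientation convention used everywhere in the package: ``intensities[i, j, k]``
is sample *i*, excitation wavelength *j*, emission wavelength *k*.  Indices are
0-based; wavelengths (nm) are the coordinate system exposed to users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the two class labels of the binary problem (Alzheimer's disease / healthy control)
LABELS = ("AD", "HC")

_SPACING_TOL = 1e-9  # nm


@dataclass(frozen=True)
class WavelengthAxes:
    """Excitation and emission wavelength grids in nm.

    Both axes must be strictly increasing and uniformly spaced (within
    1e-9 nm), matching how scanning spectrofluorometers export data.
    """

    excitation_nm: np.ndarray
    emission_nm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("excitation_nm", "emission_nm"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-D sequence")
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(d <= 0):
                    raise ValueError(f"{name} must be strictly increasing with no duplicates")
                if np.ptp(d) > _SPACING_TOL:
                    raise ValueError(f"{name} must be uniformly spaced (tolerance {_SPACING_TOL} nm)")
            object.__setattr__(self, name, ax)

    @property
    def shape(self) -> tuple[int, int]:
        return self.excitation_nm.size, self.emission_nm.size

    @classmethod
    def default_grid(cls) -> "WavelengthAxes":
        """Excitation 250-350 nm step 10, emission 300-850 nm step 1."""
        return cls(np.arange(250.0, 351.0, 10.0), np.arange(300.0, 851.0, 1.0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthAxes):
            return NotImplemented
        return (
            np.array_equal(self.excitation_nm, other.excitation_nm)
            and np.array_equal(self.emission_nm, other.emission_nm)
        )


@dataclass
class EEMCube:
    """Three-way fluorescence intensity array with its wavelength axes.

    Parameters
    ----------
    intensities
        Array of shape ``(n_samples, n_excitation, n_emission)`` in arbitrary
        fluorescence units.
    axes
        Wavelength grids for modes 1 and 2.
    mask
        Optional boolean array of the same shape; ``True`` marks excised or
        missing cells (e.g. scatter regions).  Intensities must be finite
        wherever the mask is ``False``.
    """

    intensities: np.ndarray
    axes: WavelengthAxes
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 3:
            raise ValueError("intensities must be a 3-way array (sample, excitation, emission)")
        j, k = self.axes.shape
        if x.shape[1:] != (j, k):
            raise ValueError(
                f"intensity shape {x.shape} inconsistent with axes lengths ({j}, {k})"
            )
        self.intensities = x
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != x.shape:
                raise ValueError("mask shape must match intensities")
            self.mask = m
        observed = x if self.mask is None else x[~self.mask]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-finite intensities outside the mask")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def is_complete(self) -> bool:
        return self.mask is None or not self.mask.any()

    def unfold(self) -> np.ndarray:
        """Unfold to (n_samples, n_excitation * n_emission), emission fastest."""
        return self.intensities.reshape(self.n_samples, -1)

    def take(self, indices: np.ndarray) -> "EEMCube":
        """Sub-cube with the given sample indices (axes shared)."""
        idx = np.asarray(indices)
        return EEMCube(
            self.intensities[idx].copy(),
            self.axes,
            None if self.mask is None else self.mask[idx].copy(),
        )


@dataclass
class SampleTable:
    """Sample identifiers and binary class labels, one row per cube sample."""

    sample_id: list[str]
    label: list[str]

    def __post_init__(self) -> None:
        self.sample_id = [str(s) for s in self.sample_id]
        self.label = [str(l) for l in self.label]
        if len(self.sample_id) != len(self.label):
            raise ValueError("sample_id and label must have equal length")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("sample ids must be unique")
        bad = sorted(set(self.label) - set(LABELS))
        if bad:
            raise ValueError(f"unknown labels {bad}; allowed: {LABELS}")

    def __len__(self) -> int:
        return len(self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_id, "label": self.label})

    def take(self, indices: np.ndarray) -> "SampleTable":
        idx = np.asarray(indices)
        return SampleTable(
            [self.sample_id[i] for i in idx], [self.label[i] for i in idx]
        )
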