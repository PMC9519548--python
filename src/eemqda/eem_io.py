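"""Reading and writing EEM cube archives.

The canonical interchange format is a directory archive:

* ``manifest.tsv`` — columns ``sample_id``, ``label``, ``file``; labels are
  ``AD`` or ``HC``.
* one CSV per sample, emission rows x excitation columns (long axis down):
  the first row holds the excitation axis (nm), the first column the emission
  axis (nm), and the top-left cell the literal ``em\\ex``.  Missing/excised
  cells carry the token ``NaN``.

A single-file HDF5 bundle (:func:`save_bundle` / :func:`load_bundle`) is
provided for speed; the CSV archive remains the canonical format.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEMCube, SampleTable, WavelengthAxes

MANIFEST_NAME = "manifest.tsv"
_CORNER = "em\\ex"


def save_cube(cube: EEMCube, table: SampleTable, archive_path: str | os.PathLike) -> Path:
    """Write a cube + sample table as a CSV directory archive.

    Numeric cells are written with 9+ significant digits; masked cells are
    written as ``NaN``.  Returns the archive path.
    """
    if len(table) == 0:
        raise ValueError("refusing to save an empty sample table")
    if len(table) != cube.n_samples:
        raise ValueError("sample table length does not match cube")
    root = Path(archive_path)
    root.mkdir(parents=True, exist_ok=True)
    ex, em = cube.axes.excitation_nm, cube.axes.emission_nm
    files = []
    for i, sid in enumerate(table.sample_id):
        fname = f"{sid}.csv"
        files.append(fname)
        plane = cube.intensities[i].copy()  # (J, K)
        if cube.mask is not None:
            plane[cube.mask[i]] = np.nan
        buf = io.StringIO()
        buf.write(_CORNER + "," + ",".join(repr(float(v)) for v in ex) + "\n")
        for k in range(em.size):
            row = plane[:, k]
            buf.write(repr(float(em[k])) + "," + ",".join("%.12g" % v for v in row) + "\n")
        (root / fname).write_text(buf.getvalue())
    pd.DataFrame(
        {"sample_id": table.sample_id, "label": table.label, "file": files}
    ).to_csv(root / MANIFEST_NAME, sep="\t", index=False)
    return root


def load_cube(archive_path: str | os.PathLike) -> tuple[EEMCube, SampleTable]:
    """Read a CSV directory archive written by :func:`save_cube`.

    Fails loudly on a missing manifest entry, ragged matrices, axis mismatch
    across samples, or non-numeric cells — never silently transposes.
    """
    root = Path(archive_path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {root}")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"sample_id", "label", "file"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if len(manifest) == 0:
        raise ValueError("empty manifest")

    axes: WavelengthAxes | None = None
    planes = []
    for _, rec in manifest.iterrows():
        fpath = root / rec["file"]
        if not fpath.is_file():
            raise FileNotFoundError(f"manifest entry {rec['sample_id']!r}: missing file {fpath}")
        ex, em, plane = _read_matrix(fpath)
        sample_axes = WavelengthAxes(ex, em)
        if axes is None:
            axes = sample_axes
        elif axes != sample_axes:
            raise ValueError(f"axis mismatch across samples at {fpath}")
        planes.append(plane)

    intensities = np.stack(planes)  # (I, J, K)
    mask = np.isnan(intensities)
    table = SampleTable(list(manifest["sample_id"]), list(manifest["label"]))
    cube = EEMCube(np.nan_to_num(intensities, nan=0.0), axes, mask if mask.any() else None)
    return cube, table


def _read_matrix(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse one per-sample CSV into (excitation, emission, plane[J, K])."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        try:
            ex = np.array([float(v) for v in header[1:]])
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric excitation header: {err}") from None
        em_vals, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(",")
            if len(cells) != ex.size + 1:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {ex.size + 1})")
            try:
                em_vals.append(float(cells[0]))
                rows.append([float(v) for v in cells[1:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell: {err}") from None
    em = np.array(em_vals)
    plane = np.array(rows).T  # rows are emission -> transpose to (J, K)
    return ex, em, plane


def save_bundle(cube: EEMCube, table: SampleTable, path: str | os.PathLike) -> Path:
    """Write cube + axes + table to a single HDF5 container."""
    import h5py

    if len(table) == 0:
        raise ValueError("refusing to save an empty sample table")
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("intensities", data=cube.intensities)
        h5.create_dataset("excitation_nm", data=cube.axes.excitation_nm)
        h5.create_dataset("emission_nm", data=cube.axes.emission_nm)
        if cube.mask is not None:
            h5.create_dataset("mask", data=cube.mask)
        h5.create_dataset("sample_id", data=np.array(table.sample_id, dtype="S"))
        h5.create_dataset("label", data=np.array(table.label, dtype="S"))
    return path


def load_bundle(path: str | os.PathLike) -> tuple[EEMCube, SampleTable]:
    import h5py

    with h5py.File(path, "r") as h5:
        axes = WavelengthAxes(h5["excitation_nm"][:], h5["emission_nm"][:])
        mask = h5["mask"][:].astype(bool) if "mask" in h5 else None
        cube = EEMCube(h5["intensities"][:], axes, mask)
        table = SampleTable(
            [s.decode() for s in h5["sample_id"][:]],
            [s.decode() for s in h5["label"][:]],
        )
    return cube, table
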