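"""Reading and writing spectra datasets.

Two plain-text CSV layouts are supported:

* wide — one row per spectrum; a ``label`` column plus one column per bin
  (named ``mz_<center>``), this is the layout classifier code consumes;
* long — ``spectrum_id, label, mz, intensity`` rows, one per profile
  point, the natural export of raw acquisitions.

An optional HDF5 container holds large matrices (``/matrix``, ``/labels``,
``/mz_edges``).  Round-tripping through either format is lossless up to
float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinGrid, RawSpectrum, SpectraDataset

__all__ = ["read_dataset", "write_dataset", "read_raw_long_csv", "write_raw_long_csv"]


def write_dataset(ds: SpectraDataset, path: str | Path) -> None:
    """Write a binned dataset as wide CSV (or HDF5 if the suffix is .h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(ds, path)
        return
    cols = {"sample_id": list(ds.sample_ids), "label": [ds.class_names[i] for i in ds.labels]}
    frame = pd.DataFrame(cols)
    centers = ds.grid.centers
    mat = pd.DataFrame(ds.matrix, columns=[f"mz_{c:.6g}" for c in centers])
    pd.concat([frame, mat], axis=1).to_csv(path, index=False)
    meta = {
        "mass_min": ds.grid.mass_min,
        "mass_max": ds.grid.mass_max,
        "bin_width": ds.grid.bin_width,
        "class_names": list(ds.class_names),
        "scaled": ds.scaled,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path, format: str = "wide_csv") -> SpectraDataset:
    """Read a dataset written by :func:`write_dataset` (wide CSV or HDF5)."""
    path = Path(path)
    if format not in ("wide_csv", "long_csv", "hdf5"):
        raise ValueError(f"unknown format {format!r}")
    if format == "long_csv":
        return read_raw_long_csv(path)
    if format == "hdf5" or path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValueError(f"{path}: missing 'label' column")
    mz_cols = [c for c in frame.columns if c.startswith("mz_")]
    matrix = frame[mz_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(np.any(matrix < 0, axis=1))
    if bad.size:
        raise ValueError(f"{path}: negative intensity in row {bad[0]}")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        class_names = meta["class_names"]
        grid = BinGrid(meta["mass_min"], meta["mass_max"], meta["bin_width"])
        scaled = bool(meta.get("scaled", False))
    else:
        centers = np.array([float(c[3:]) for c in mz_cols])
        width = float(np.median(np.diff(centers))) if len(centers) > 1 else 1.0
        grid = BinGrid(centers[0] - width / 2, centers[0] - width / 2 + width * len(centers), width)
        class_names = sorted(frame["label"].astype(str).unique())
        scaled = False
    name_to_idx = {n: i for i, n in enumerate(class_names)}
    try:
        labels = np.array([name_to_idx[str(v)] for v in frame["label"]])
    except KeyError as e:
        raise ValueError(f"{path}: label {e} not in class_names") from None
    ids = frame["sample_id"].astype(str).tolist() if "sample_id" in frame.columns else []
    return SpectraDataset(matrix, labels, class_names, grid, ids, scaled)


def write_raw_long_csv(spectra: Sequence[RawSpectrum], labels: Sequence[str], path) -> None:
    """Write raw profile spectra in long format (one point per row)."""
    rows = []
    for spec, lab in zip(spectra, labels, strict=True):
        rows.append(
            pd.DataFrame(
                {
                    "spectrum_id": spec.id,
                    "label": lab,
                    "mz": spec.mz,
                    "intensity": spec.intensity,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_raw_long_csv(path) -> tuple[list[RawSpectrum], list[str]]:
    """Read long-format CSV back into raw spectra + string labels."""
    frame = pd.read_csv(path)
    required = {"spectrum_id", "label", "mz", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra, labels = [], []
    for sid, grp in frame.groupby("spectrum_id", sort=False):
        mz = grp["mz"].to_numpy(dtype=float)
        if np.any(np.diff(mz) <= 0):
            raise ValueError(f"{path}: spectrum {sid!r} has non-increasing m/z")
        try:
            spectra.append(RawSpectrum(mz, grp["intensity"].to_numpy(dtype=float), str(sid)))
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from None
        labels.append(str(grp["label"].iloc[0]))
    return spectra, labels


def _write_hdf5(ds: SpectraDataset, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=ds.matrix)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("mz_edges", data=ds.grid.edges)
        f.attrs["class_names"] = json.dumps(list(ds.class_names))
        f.attrs["scaled"] = ds.scaled
        f.attrs["sample_ids"] = json.dumps(list(ds.sample_ids))


def _read_hdf5(path: Path) -> SpectraDataset:
    import h5py

    with h5py.File(path, "r") as f:
        matrix = f["matrix"][()]
        labels = f["labels"][()]
        edges = f["mz_edges"][()]
        class_names = json.loads(f.attrs["class_names"])
        scaled = bool(f.attrs["scaled"])
        ids = json.loads(f.attrs["sample_ids"])
    width = float(edges[1] - edges[0])
    grid = BinGrid(float(edges[0]), float(edges[-1]), width)
    return SpectraDataset(matrix, labels, class_names, grid, ids, scaled)
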