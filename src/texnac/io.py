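"""Readers and writers: NIfTI-1 series and masks, delimited tables.

Dynamic series are stored as one 3D NIfTI-1 file per patient with time
as the third axis; frame times (seconds) live in a JSON sidecar next to
the image (``<name>_times.json``).  When the sidecar is missing a
default 60-second grid is applied with a warning.  Masks are NIfTI-1
volumes with 0/1 voxels.  Tables are comma-separated UTF-8 with a header
row.
"""
from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import DynamicSeries
from .masks import RoiMask
from .phantom import PatientRecord

__all__ = [
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "read_cohort_table",
    "write_cohort_table",
    "atomic_write_text",
]

DEFAULT_DT = 60.0  # seconds, the protocol's nominal temporal resolution

COHORT_COLUMNS = ["patient_id", "response", "subtype", "er", "pgr", "ki67_high", "her2", "mass"]


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return p.with_name(name + "_times.json")


def write_series(series: DynamicSeries, path) -> None:
    """Write a dynamic series as (H, W, T) NIfTI-1 plus a times sidecar."""
    data = np.moveaxis(series.frames, 0, -1)  # (H, W, T)
    nib.save(nib.Nifti1Image(data.astype(np.float64), np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps({"times_s": series.times.tolist()}))


def read_series(path, times=None) -> DynamicSeries:
    """Load a dynamic series; times from argument, sidecar, or 60 s default."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume with time as the third axis, got ndim={data.ndim}"
        )
    if data.shape[2] < 2:
        raise ValueError(f"{path}: a dynamic series needs at least 2 frames")
    frames = np.moveaxis(data, -1, 0)
    if times is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            times = json.loads(sidecar.read_text())["times_s"]
        else:
            warnings.warn(
                f"{sidecar} missing: applying the default {DEFAULT_DT:.0f}-second grid",
                stacklevel=2,
            )
            times = np.arange(frames.shape[0]) * DEFAULT_DT
    return DynamicSeries(frames, np.asarray(times, dtype=float))


def write_mask(mask: RoiMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), np.eye(4)), str(path))


def read_mask(path, kind: str = "manual_lesion") -> RoiMask:
    data = np.asarray(nib.load(str(path)).dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D mask, got ndim={data.ndim}")
    return RoiMask(data > 0, kind=kind)


def write_feature_table(table: pd.DataFrame, path) -> None:
    atomic_write_text(path, table.to_csv(index=False))


def read_feature_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        if df[col].isna().any() and col in required:
            rows = df.index[df[col].isna()].tolist()
            raise ValueError(f"{path}: missing values in column {col!r} at rows {rows}")
    return df


def write_cohort_table(records, path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "response": r.response,
            "subtype": r.subtype,
            "er": int(r.er),
            "pgr": int(r.pgr),
            "ki67_high": int(r.ki67_high),
            "her2": int(r.her2),
            "mass": int(r.mass),
        }
        for r in records
    ]
    atomic_write_text(path, pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(index=False))


def read_cohort_table(path) -> list[PatientRecord]:
    df = read_feature_table(path, required=COHORT_COLUMNS)
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            response=str(row.response),
            subtype=str(row.subtype),
            er=bool(row.er),
            pgr=bool(row.pgr),
            ki67_high=bool(row.ki67_high),
            her2=bool(row.her2),
            mass=bool(row.mass),
        )
        for row in df.itertuples(index=False)
    ]


def atomic_write_text(path, text: str) -> None:
    """Write text to a temp file and rename, so outputs are never partial."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
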