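"""Readers and writers for the pipeline's image, mask and table artifacts.

Conventions (asserted in the test suite):

* voxel indexing is 0-based with axis order ``(x, y, z, t)``;
* volumes and masks are NIfTI-1; frame timing never comes from NIfTI
  headers (TR fields are unreliable for triggered dynamic series) but from
  a JSON sidecar written next to each volume, or from an explicit
  :class:`~dcekin.acquisition.AcquisitionSpec`;
* cohort tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec

__all__ = [
    "DynamicSeries",
    "RoiMask",
    "TIMEPOINTS",
    "read_dynamic",
    "write_dynamic",
    "read_mask",
    "write_mask",
    "masks_from_labels",
    "read_cohort_table",
    "write_aif_csv",
]

TIMEPOINTS = ("baseline", "week4", "week10")

MASK_ROLES = ("aorta_candidate", "tumour_candidate", "aorta_refined", "tumour_perfused")


@dataclass
class DynamicSeries:
    """A 4D dynamic acquisition: signal in arbitrary units over (x, y, z, t)."""

    data: np.ndarray
    frame_times: np.ndarray  # seconds relative to injection
    n_precontrast: int
    voxel_volume: float  # mm^3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D (x, y, z, t) array, got {self.data.ndim}D")
        if len(self.frame_times) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.frame_times)} frame times for {self.data.shape[3]} frames"
            )
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not 0 < self.n_precontrast < self.data.shape[3]:
            raise ValueError("n_precontrast must be in (0, n_frames)")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be > 0")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_dynamic(self) -> int:
        return self.data.shape[3] - self.n_precontrast

    def dynamic_times(self) -> np.ndarray:
        return self.frame_times[self.n_precontrast:]


@dataclass
class RoiMask:
    """A boolean region of interest on a series' spatial grid."""

    mask: np.ndarray
    role: str
    reader_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D (x, y, z) volume")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        if self.role.endswith("candidate") and not self.mask.any():
            raise ValueError(f"{self.role} mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_dynamic(series: DynamicSeries, path) -> Path:
    """Write a 4D series as NIfTI-1 plus a JSON timing sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "n_precontrast": series.n_precontrast,
        "voxel_volume_mm3": series.voxel_volume,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_dynamic(path, acquisition: AcquisitionSpec | None = None) -> DynamicSeries:
    """Read a 4D dynamic series.

    Timing is taken from the JSON sidecar written by :func:`write_dynamic`,
    or, if ``acquisition`` is given, rebuilt from that protocol and checked
    against the frame count on disk. Never inferred from NIfTI headers.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    n_frames = data.shape[3]
    if acquisition is not None:
        if acquisition.n_frames != n_frames:
            raise ValueError(
                f"{path}: file has {n_frames} frames but the acquisition spec "
                f"describes {acquisition.n_frames}"
            )
        return DynamicSeries(
            data=data,
            frame_times=acquisition.frame_times(),
            n_precontrast=acquisition.n_precontrast,
            voxel_volume=acquisition.voxel_volume,
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{path}: no timing metadata — provide an AcquisitionSpec or a sidecar "
            f"at {sidecar}"
        )
    meta = json.loads(sidecar.read_text())
    times = np.asarray(meta["frame_times_s"], dtype=float)
    if len(times) != n_frames:
        raise ValueError(
            f"{path}: file has {n_frames} frames but sidecar lists {len(times)} times"
        )
    return DynamicSeries(
        data=data,
        frame_times=times,
        n_precontrast=int(meta["n_precontrast"]),
        voxel_volume=float(meta["voxel_volume_mm3"]),
    )


def write_mask(mask: RoiMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"role": mask.role, "reader_id": mask.reader_id})
    )
    return path


def read_mask(path, grid_shape: tuple, role: str | None = None) -> RoiMask:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if tuple(data.shape) != tuple(grid_shape):
        raise ValueError(
            f"{path}: mask shape {tuple(data.shape)} does not match grid {tuple(grid_shape)}"
        )
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return RoiMask(
        mask=data > 0,
        role=role or meta.get("role", "tumour_candidate"),
        reader_id=meta.get("reader_id", ""),
    )


def masks_from_labels(path, grid_shape: tuple, labels: list[int], role: str) -> dict[int, RoiMask]:
    """Split an integer-labelled volume into one RoiMask per requested label."""
    path = Path(path)
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if tuple(data.shape) != tuple(grid_shape):
        raise ValueError(
            f"{path}: label volume shape {tuple(data.shape)} does not match grid "
            f"{tuple(grid_shape)}"
        )
    return {lab: RoiMask(mask=data == lab, role=role) for lab in labels}


def read_cohort_table(path) -> pd.DataFrame:
    """Read a lesion-level cohort table.

    Required columns: ``patient_id``, ``lesion_id``, ``organ``,
    ``progression``. A ``timepoint`` column, when present, must use the
    fixed three-level labels and the progression label must be constant
    within each patient.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "lesion_id", "organ", "progression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if "timepoint" in df.columns:
        bad = set(df["timepoint"].unique()) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"unknown timepoint labels: {sorted(bad)}")
    per_patient = df.groupby("patient_id")["progression"].nunique()
    if (per_patient > 1).any():
        bad = per_patient[per_patient > 1].index.tolist()
        raise ValueError(f"progression label varies within patient(s): {bad}")
    return df


def write_aif_csv(times: np.ndarray, values: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": times, "enhancement": values}).to_csv(path, index=False)
    return path
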