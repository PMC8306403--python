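"""Relative enhancement and arterial input function (AIF) extraction.

Contrast concentration is approximated by the relative signal change
E(t) = (S(t) - S0)/S0, with S0 the per-voxel mean of the pre-contrast
frames. The operator's coarse aorta ROI is refined by keeping only voxels
whose peak enhancement lies in the 95th-100th percentile band of the peaks
within the ROI — a reproducible rule that suppresses inflow and partial
volume effects — and the AIF is the frame-wise mean over the retained
voxels. No hematocrit correction is applied, so kinetic parameters are
blood-referenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import DynamicSeries, RoiMask

__all__ = [
    "EnhancementSeries",
    "AifCurve",
    "relative_enhancement",
    "refine_aif_roi",
    "extract_aif",
]

logger = logging.getLogger(__name__)


@dataclass
class EnhancementSeries:
    """Voxelwise relative enhancement over all frames of a dynamic series."""

    values: np.ndarray  # (x, y, z, t), dimensionless
    frame_times: np.ndarray  # seconds
    n_precontrast: int
    valid: np.ndarray = None  # voxels with a usable (S0 > 0) baseline
    voxel_volume: float = float("nan")  # mm^3, carried through for volumetry

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.values.shape[:3], dtype=bool)

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[:3]

    def dynamic_values(self) -> np.ndarray:
        return self.values[..., self.n_precontrast:]

    def dynamic_times(self) -> np.ndarray:
        return self.frame_times[self.n_precontrast:]


@dataclass
class AifCurve:
    """Arterial input enhancement per dynamic frame."""

    values: np.ndarray
    frame_times: np.ndarray
    n_voxels: int
    source_role: str = "aorta_refined"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.n_voxels < 1:
            raise ValueError("AIF must come from at least one voxel")
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have the same length")


def relative_enhancement(series: DynamicSeries) -> EnhancementSeries:
    """Convert signal to relative enhancement E(t) = (S(t) - S0)/S0.

    S0 is the per-voxel mean over the pre-contrast frames. Voxels with
    S0 <= 0 cannot be normalised; they are flagged invalid (E set to 0)
    and their count is logged rather than silently propagating NaN.
    """
    s = np.asarray(series.data, dtype=float)
    s0 = s[..., : series.n_precontrast].mean(axis=-1)
    valid = s0 > 0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("relative_enhancement: excluding %d voxels with S0 <= 0", n_bad)
    safe_s0 = np.where(valid, s0, 1.0)
    e = (s - safe_s0[..., None]) / safe_s0[..., None]
    e[~valid] = 0.0
    return EnhancementSeries(
        values=e,
        frame_times=series.frame_times,
        n_precontrast=series.n_precontrast,
        valid=valid,
        voxel_volume=series.voxel_volume,
    )


def peak_enhancement(enh: EnhancementSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel maximum enhancement over the dynamic frames only."""
    dyn = enh.dynamic_values()
    peaks = dyn.max(axis=-1)
    return peaks if mask is None else peaks[mask]


def refine_aif_roi(
    candidate: RoiMask, enh: EnhancementSeries, percentile_band: tuple = (95.0, 100.0)
) -> RoiMask:
    """Keep candidate voxels whose peak enhancement reaches the band's lower percentile.

    The threshold is the ``percentile_band[0]``-th percentile (linear
    interpolation between order statistics) of peak enhancements within
    the candidate; voxels with peak >= threshold are retained. The upper
    edge of the default band is the maximum, so it imposes no cut.
    """
    if not candidate.mask.any():
        raise ValueError("candidate aorta ROI is empty")
    if candidate.mask.shape != enh.grid_shape:
        raise ValueError("candidate mask does not match the enhancement grid")
    peaks = peak_enhancement(enh, candidate.mask)
    lo = np.percentile(peaks, percentile_band[0])
    keep = peaks >= lo
    refined = np.zeros_like(candidate.mask)
    refined[candidate.mask] = keep
    return RoiMask(mask=refined, role="aorta_refined", reader_id=candidate.reader_id)


def extract_aif(refined: RoiMask, enh: EnhancementSeries) -> AifCurve:
    """Frame-wise mean enhancement over the refined aorta voxels."""
    if not refined.mask.any():
        raise ValueError("refined aorta ROI is empty")
    dyn = enh.dynamic_values()
    vals = dyn[refined.mask].mean(axis=0)
    return AifCurve(
        values=vals,
        frame_times=enh.dynamic_times(),
        n_voxels=refined.n_voxels,
        source_role=refined.role,
    )
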