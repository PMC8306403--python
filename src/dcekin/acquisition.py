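"""Acquisition protocol description for dynamic contrast-enhanced series.

The default protocol is the abdominal DCE-MRI protocol the rest of the
package is built around: a short pre-contrast baseline (6 frames at 2 s
intervals) followed by a 4-minute dynamic acquisition (120 frames at 2.4 s
intervals) triggered at the moment of contrast injection, with a voxel
volume of 48.8 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

__all__ = ["AcquisitionSpec"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing and geometry of one dynamic series.

    Parameters
    ----------
    n_precontrast : int
        Number of pre-contrast baseline frames (default 6).
    dt_precontrast : float
        Interval between pre-contrast frames in seconds (default 2.0).
    n_dynamic : int
        Number of dynamic frames acquired after injection (default 120).
    dt_dynamic : float
        Interval between dynamic frames in seconds (default 2.4).
    voxel_volume : float
        Voxel volume in mm^3 (default 48.8).
    """

    n_precontrast: int = 6
    dt_precontrast: float = 2.0
    n_dynamic: int = 120
    dt_dynamic: float = 2.4
    voxel_volume: float = 48.8

    def __post_init__(self) -> None:
        if self.n_precontrast < 1 or self.n_dynamic < 1:
            raise ValueError("frame counts must be >= 1")
        if self.dt_precontrast <= 0 or self.dt_dynamic <= 0:
            raise ValueError("frame intervals must be > 0")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be > 0")

    @property
    def n_frames(self) -> int:
        return self.n_precontrast + self.n_dynamic

    def frame_times(self) -> np.ndarray:
        """Times of all frames in seconds, injection at t = 0.

        Pre-contrast frames precede the injection (the last one ends
        ``dt_precontrast`` seconds before t = 0); dynamic frame ``k`` is at
        ``k * dt_dynamic``, the first coinciding with the injection trigger.
        """
        pre = -self.dt_precontrast * np.arange(self.n_precontrast, 0, -1)
        dyn = self.dt_dynamic * np.arange(self.n_dynamic)
        return np.concatenate([pre, dyn])

    def dynamic_times(self) -> np.ndarray:
        """Times of the dynamic frames only (seconds after injection)."""
        return self.dt_dynamic * np.arange(self.n_dynamic)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
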