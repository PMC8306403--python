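"""Synthetic 4D DCE phantoms and longitudinal cohorts with known truth.

Every downstream stage of the pipeline is testable against these phantoms:
an aorta whose voxels follow a population bolus curve, spherical lesions
whose voxels follow the one-compartment tissue model for known
(Ktrans, ECV), a signal model S(t) = S0 * (1 + E(t)) with additive
Gaussian noise on the signal, and a cohort generator that emulates a
three-visit (baseline / week 4 / week 10) anti-angiogenic treatment study:
perfusion falls in everyone by week 4; in patients who will show
progressive disease at 6 months, Ktrans rebounds between weeks 4 and 10,
while in the others it stays flat or keeps falling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .io import DynamicSeries, RoiMask, TIMEPOINTS
from .kinetics import one_compartment_curve

__all__ = [
    "AifModelParams",
    "AortaSpec",
    "LesionSpec",
    "PhantomScene",
    "ProgressionEffect",
    "population_aif",
    "tissue_curve",
    "render_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class AifModelParams:
    """Population arterial input curve: gamma-variate bolus + recirculation tail.

    Units are relative enhancement; a peak aortic enhancement around 4 is
    typical of a standard-dose bolus at 1.5 T. The curve is identically
    zero before ``arrival_time_s``.
    """

    bolus_amplitude: float = 4.0  # peak enhancement of the first pass
    arrival_time_s: float = 10.0  # bolus transit from injection to aorta
    time_to_peak_s: float = 8.0  # from arrival to first-pass peak
    shape: float = 3.0  # gamma-variate sharpness (dimensionless)
    recirc_amplitude: float = 0.8  # recirculation / equilibrium tail
    recirc_rise_s: float = 25.0
    washout_tau_s: float = 220.0

    def __post_init__(self) -> None:
        if self.bolus_amplitude < 0 or self.recirc_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.time_to_peak_s <= 0 or self.shape <= 0:
            raise ValueError("time_to_peak_s and shape must be positive")
        if self.recirc_rise_s <= 0 or self.washout_tau_s <= 0:
            raise ValueError("recirculation time constants must be positive")


@dataclass(frozen=True)
class AortaSpec:
    """A cylindrical aorta segment along z, spanning the full grid depth."""

    centre_xy: tuple = (8, 8)
    radius: float = 3.0


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion with known kinetic ground truth.

    ``rim_width`` > 0 adds a shell of partially-enhancing voxels around the
    core (enhancement scaled by ``rim_scale``), emulating partial-volume
    periphery; the ground-truth mask and volume refer to the core only.
    """

    centre: tuple
    radius: float
    ktrans_true: float  # min^-1
    ecv_true: float  # mL / 100 mL
    organ_label: str = "kidney"
    rim_width: int = 0
    rim_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.ktrans_true <= 0:
            raise ValueError("ktrans_true must be > 0")
        if not 0 < self.ecv_true <= 100:
            raise ValueError("ecv_true must be in (0, 100]")


@dataclass(frozen=True)
class PhantomScene:
    """Everything needed to render one dynamic series deterministically."""

    grid_shape: tuple = (32, 32, 10)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    aif_params: AifModelParams = field(default_factory=AifModelParams)
    aorta: AortaSpec = field(default_factory=AortaSpec)
    lesions: tuple = ()
    noise_sd: float = 0.0  # fraction of S0, additive on signal
    s0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def population_aif(times: np.ndarray, params: AifModelParams) -> np.ndarray:
    """Evaluate the population input curve at the given times (seconds).

    Gamma-variate first pass normalised to peak ``bolus_amplitude`` at
    ``arrival + time_to_peak``, plus a recirculation term that rises with
    time constant ``recirc_rise_s`` and washes out with ``washout_tau_s``.
    Zero before arrival, non-negative everywhere.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1D array")
    tau = t - params.arrival_time_s
    out = np.zeros_like(t)
    post = tau > 0
    tp = tau[post]
    a = params.shape
    bolus = params.bolus_amplitude * (tp / params.time_to_peak_s) ** a * np.exp(
        a * (1.0 - tp / params.time_to_peak_s)
    )
    recirc = (
        params.recirc_amplitude
        * (1.0 - np.exp(-tp / params.recirc_rise_s))
        * np.exp(-tp / params.washout_tau_s)
    )
    out[post] = bolus + recirc
    return out


def tissue_curve(
    aif: np.ndarray, times: np.ndarray, ktrans: float, ecv: float
) -> np.ndarray:
    """One-compartment tissue curve for a sampled AIF (shared model core)."""
    return one_compartment_curve(aif, times, ktrans, ecv)


def _sphere_mask(grid_shape: tuple, centre: tuple, radius: float) -> np.ndarray:
    idx = np.indices(grid_shape)
    d2 = sum((idx[i] - centre[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def _cylinder_mask(grid_shape: tuple, centre_xy: tuple, radius: float) -> np.ndarray:
    idx = np.indices(grid_shape)
    d2 = (idx[0] - centre_xy[0]) ** 2 + (idx[1] - centre_xy[1]) ** 2
    return d2 <= radius**2


def scene_masks(scene: PhantomScene) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Aorta mask, per-lesion core masks and per-lesion rim masks."""
    aorta = _cylinder_mask(scene.grid_shape, scene.aorta.centre_xy, scene.aorta.radius)
    cores, rims = [], []
    for les in scene.lesions:
        core = _sphere_mask(scene.grid_shape, les.centre, les.radius)
        if not core.any():
            raise ValueError(f"lesion at {les.centre} contains no voxels")
        outer = _sphere_mask(scene.grid_shape, les.centre, les.radius + les.rim_width)
        rims.append(outer & ~core if les.rim_width > 0 else np.zeros_like(core))
        cores.append(core)
    return aorta, cores, rims


def render_phantom(scene: PhantomScene):
    """Render a scene to a dynamic series, label masks and a truth table.

    Returns ``(series, masks, truth)`` where ``masks`` maps ``"aorta"`` to
    the aorta RoiMask and ``"lesion_<i>"`` to each lesion's full extent
    (core + rim) as a tumour-candidate mask, and ``truth`` is a DataFrame
    with one row per lesion (true Ktrans, ECV and core volume in cm^3).

    Signal model: S(t) = S0 * (1 + E(t)) + N(0, (noise_sd * S0)^2), with
    background E = 0. Bit-identical for identical scenes (seed included).
    """
    aorta, cores, rims = scene_masks(scene)
    for i, core in enumerate(cores):
        full = core | rims[i]
        if (full & aorta).any():
            raise ValueError(f"lesion {i} overlaps the aorta")
        for j in range(i):
            if (full & (cores[j] | rims[j])).any():
                raise ValueError(f"lesions {j} and {i} overlap")

    times = scene.acquisition.frame_times()
    nt = len(times)
    enh = np.zeros(scene.grid_shape + (nt,), dtype=float)
    ca = population_aif(times, scene.aif_params)
    enh[aorta] = ca
    rows = []
    masks: dict[str, RoiMask] = {"aorta": RoiMask(mask=aorta, role="aorta_candidate")}
    vv = scene.acquisition.voxel_volume
    for i, les in enumerate(scene.lesions):
        ct = tissue_curve(ca, times, les.ktrans_true, les.ecv_true)
        enh[cores[i]] = ct
        if rims[i].any():
            enh[rims[i]] = les.rim_scale * ct
        masks[f"lesion_{i}"] = RoiMask(mask=cores[i] | rims[i], role="tumour_candidate")
        rows.append(
            {
                "lesion_id": i,
                "organ": les.organ_label,
                "ktrans_true": les.ktrans_true,
                "ecv_true": les.ecv_true,
                "volume_true_cm3": int(cores[i].sum()) * vv / 1000.0,
            }
        )

    signal = scene.s0 * (1.0 + enh)
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        signal = signal + rng.normal(0.0, scene.noise_sd * scene.s0, size=signal.shape)
    series = DynamicSeries(
        data=signal,
        frame_times=times,
        n_precontrast=scene.acquisition.n_precontrast,
        voxel_volume=vv,
    )
    return series, masks, pd.DataFrame(rows)


@dataclass(frozen=True)
class ProgressionEffect:
    """Week-4 -> week-10 effect separating progressors from non-progressors.

    ``ktrans_rise_factor`` multiplies a progressor's week-4 Ktrans to give
    its week-10 value (2.0 = doubling); ``volume_rise_factor`` does the
    same for lesion volume (progressing tumours re-perfuse and regrow).
    """

    ktrans_rise_factor: float = 2.0
    volume_rise_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.ktrans_rise_factor <= 0 or self.volume_rise_factor <= 0:
            raise ValueError("effect sizes must be > 0")


# Study conditions emulated by default: 14 patients, 3 of whom progress by
# 6 months; 1-5 lesions each; baseline Ktrans lognormal with mean ~0.96 and
# SD ~0.63 min^-1; universal fall by week 4 (mean factor ~0.4), then flat or
# falling to week 10 except in progressors.
_ORGAN_CYCLE = ("kidney", "nodal", "liver", "pancreas", "stomach", "spleen", "renal_bed")
# lesion centres pairwise > 9 voxels apart so max radii never overlap
_LESION_SLOTS = ((14, 14, 6), (14, 28, 6), (28, 14, 6), (28, 28, 6), (21, 21, 6))
_COHORT_GRID = (36, 36, 12)
_COHORT_AORTA = AortaSpec(centre_xy=(6, 6), radius=3.0)


def _lognormal_from_moments(rng, mean, sd, size=None):
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cohort(
    n_patients: int = 14,
    n_progressors: int = 3,
    effect: ProgressionEffect = ProgressionEffect(),
    seed: int = 0,
    noise_sd: float = 0.0,
    heterogeneity: float = 0.25,
    grid_shape: tuple = _COHORT_GRID,
    acquisition: AcquisitionSpec | None = None,
):
    """Generate per-patient scene triplets and the ground-truth table.

    Returns ``(scenes, truth)``: ``scenes[patient_id][timepoint]`` is a
    :class:`PhantomScene`, and ``truth`` is a tidy DataFrame with columns
    patient_id, lesion_id, organ, timepoint, ktrans_true, ecv_true,
    volume_true_cm3, progression.

    Per-lesion trajectories respect the group contract: every lesion's
    Ktrans falls from baseline to week 4; from week 4 to week 10 it rises
    by the configured effect in progressors and stays flat or falls in
    non-progressors. ``heterogeneity`` is the relative spread of the
    per-lesion week-4 response depth within a patient (inter-lesion
    response heterogeneity is real but of unknown magnitude, so it is an
    explicit knob rather than a claimed default).
    """
    if n_progressors > n_patients:
        raise ValueError("n_progressors cannot exceed n_patients")
    if effect.ktrans_rise_factor <= 0 or effect.volume_rise_factor <= 0:
        raise ValueError("effect sizes must be > 0")
    acquisition = acquisition or AcquisitionSpec()
    rng = np.random.default_rng(seed)
    progressors = set(rng.choice(n_patients, size=n_progressors, replace=False).tolist())

    scenes: dict[str, dict[str, PhantomScene]] = {}
    rows = []
    organ_i = 0
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        is_prog = p in progressors
        n_lesions = int(rng.integers(1, 6))
        fall_4_patient = rng.uniform(0.25, 0.55)  # everyone falls by week 4

        lesions_base = []
        for li in range(n_lesions):
            kt = float(np.clip(_lognormal_from_moments(rng, 0.96, 0.63), 0.1, 3.0))
            ecv = float(rng.uniform(20.0, 60.0))
            radius = float(rng.uniform(2.5, 4.0))
            organ = _ORGAN_CYCLE[organ_i % len(_ORGAN_CYCLE)]
            organ_i += 1
            # lesion-level response depth (heterogeneity within the patient)
            h = float(np.clip(rng.normal(1.0, heterogeneity), 0.4, 1.6))
            fall_4 = float(np.clip(fall_4_patient * h, 0.1, 0.9))
            if is_prog:
                k10_mult = effect.ktrans_rise_factor  # rebound
                v10_mult = effect.volume_rise_factor
            else:
                k10_mult = float(rng.uniform(0.7, 0.999))  # flat or falling
                v10_mult = float(rng.uniform(0.75, 0.999))
            vol_fall_4 = float(rng.uniform(0.3, 0.75))  # ~ -48% median
            lesions_base.append(
                (kt, ecv, radius, organ, fall_4, k10_mult, vol_fall_4, v10_mult)
            )

        scenes[pid] = {}
        for tp in TIMEPOINTS:
            specs = []
            for li, (kt, ecv, radius, organ, fall_4, k10_mult, vol_fall_4, v10_mult) in enumerate(
                lesions_base
            ):
                if tp == "baseline":
                    kt_tp, r_tp = kt, radius
                elif tp == "week4":
                    kt_tp, r_tp = kt * fall_4, radius * vol_fall_4 ** (1.0 / 3.0)
                else:
                    kt_tp = kt * fall_4 * k10_mult
                    r_tp = radius * (vol_fall_4 * v10_mult) ** (1.0 / 3.0)
                specs.append(
                    LesionSpec(
                        centre=_LESION_SLOTS[li],
                        radius=max(r_tp, 1.5),
                        ktrans_true=float(np.clip(kt_tp, 0.01, 9.0)),
                        ecv_true=ecv,
                        organ_label=organ,
                    )
                )
            scene = PhantomScene(
                grid_shape=grid_shape,
                acquisition=acquisition,
                aorta=_COHORT_AORTA,
                lesions=tuple(specs),
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scenes[pid][tp] = scene
            for li, spec in enumerate(specs):
                n_vox = int(_sphere_mask(grid_shape, spec.centre, spec.radius).sum())
                rows.append(
                    {
                        "patient_id": pid,
                        "lesion_id": li,
                        "organ": spec.organ_label,
                        "timepoint": tp,
                        "ktrans_true": spec.ktrans_true,
                        "ecv_true": spec.ecv_true,
                        "volume_true_cm3": n_vox * acquisition.voxel_volume / 1000.0,
                        "progression": "yes" if is_prog else "no",
                    }
                )
    truth = pd.DataFrame(rows)
    return scenes, truth
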