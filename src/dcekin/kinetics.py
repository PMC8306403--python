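"""Single-compartment (Kety/Tofts-type) tracer-kinetic model and fitting.

The tissue enhancement curve is modelled as

    Ct(t) = Ktrans * integral_0^t Ca(tau) * exp(-kep * (t - tau)) dtau,
    kep   = Ktrans / (ECV / 100),

with Ktrans the volume transfer constant in min^-1, ECV the extracellular
(distribution) volume in mL per 100 mL of tissue, and Ca the arterial input
function. Both Ca and Ct are relative signal enhancements; because a single
proportionality constant links enhancement to concentration for blood and
tissue, it cancels from the fit (scale invariance), and the derived mean
transit time is MTT = (ECV/100) / Ktrans converted to seconds.

The convolution is evaluated exactly for a piecewise-linear input sampled
on the acquisition grid (the standard exponential-convolution recursion),
so the only discretization error is the linear interpolation of Ca between
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OneCompartmentParams",
    "TissueCurve",
    "one_compartment_curve",
    "predict_curve",
    "roi_mean_curve",
    "fit_one_compartment",
    "mtt_from_params",
]

KTRANS_BOUNDS = (1e-6, 10.0)  # min^-1
ECV_BOUNDS = (1e-3, 100.0)  # mL / 100 mL
_X0 = (0.3, 30.0)
_MULTISTARTS = ((0.05, 10.0), (1.0, 50.0), (3.0, 80.0))


@dataclass(frozen=True)
class OneCompartmentParams:
    """Fitted kinetic parameters for one lesion.

    ``mtt`` is the extracellular mean transit time in seconds, derived as
    ``(ecv/100) / ktrans * 60``.
    """

    ktrans: float  # min^-1
    ecv: float  # mL / 100 mL tissue
    mtt: float  # s
    fit_rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not 0 < self.ecv <= 100:
            raise ValueError("ecv must be in (0, 100]")


@dataclass
class TissueCurve:
    """ROI-mean relative enhancement per dynamic frame."""

    values: np.ndarray
    frame_times: np.ndarray  # seconds after injection
    lesion: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have the same length")


def mtt_from_params(ktrans: float, ecv: float) -> float:
    """Extracellular mean transit time (s) = (ECV/100)/Ktrans with Ktrans in min^-1."""
    if ktrans <= 0:
        raise ValueError("MTT is undefined for ktrans <= 0")
    return (ecv / 100.0) / ktrans * 60.0


def _expconv(ca: np.ndarray, times: np.ndarray, k: float) -> np.ndarray:
    """integral_0^t ca(tau) exp(-k (t - tau)) dtau at the sample times.

    Exact for ``ca`` piecewise linear between samples. ``k`` in 1/s,
    ``times`` in seconds; ca is taken as its sampled value at t[0] before
    which no contribution is accumulated.
    """
    ca = np.asarray(ca, dtype=float)
    t = np.asarray(times, dtype=float)
    dt = np.diff(t)
    u = k * dt
    emu = np.exp(-u)
    small = u < 1e-6
    # interval integrals: int_0^dt ca(t_{i+1}-s) e^{-ks} ds with ca linear
    with np.errstate(divide="ignore", invalid="ignore"):
        w_next = np.where(small, dt / 2.0, (1.0 - emu) / k)
        w_slope = np.where(small, dt * dt / 6.0, (1.0 - emu * (1.0 + u)) / (k * k))
    m = (ca[1:] - ca[:-1]) / dt
    increments = ca[1:] * w_next - m * w_slope
    if dt.size and np.ptp(dt) < 1e-12 * dt[0]:
        # uniform grid: the recursion is a first-order IIR filter
        from scipy.signal import lfilter

        out = np.empty_like(ca)
        out[0] = 0.0
        out[1:] = lfilter([1.0], [1.0, -emu[0]], increments)
        return out
    out = np.empty_like(ca)
    out[0] = 0.0
    for i in range(len(dt)):
        out[i + 1] = out[i] * emu[i] + increments[i]
    return out


def one_compartment_curve(
    aif_values: np.ndarray, times: np.ndarray, ktrans: float, ecv: float
) -> np.ndarray:
    """Tissue enhancement predicted by the one-compartment model.

    Parameters
    ----------
    aif_values : array
        Arterial input enhancement sampled at ``times``.
    times : array
        Strictly increasing times in seconds.
    ktrans : float
        Transfer constant in min^-1 (>= 0).
    ecv : float
        Extracellular volume in mL/100 mL, in (0, 100].
    """
    times = np.asarray(times, dtype=float)
    aif_values = np.asarray(aif_values, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if ktrans < 0:
        raise ValueError("ktrans must be >= 0")
    if not 0 < ecv <= 100:
        raise ValueError("ecv must be in (0, 100] (kep undefined at ecv = 0)")
    if ktrans == 0:
        return np.zeros_like(aif_values)
    ktrans_s = ktrans / 60.0
    kep_s = ktrans_s / (ecv / 100.0)
    return ktrans_s * _expconv(aif_values, times, kep_s)


def predict_curve(aif, params: OneCompartmentParams, frame_times=None) -> TissueCurve:
    """Model tissue curve for an AIF and kinetic parameters.

    ``aif`` may be an :class:`~dcekin.aif.AifCurve` (times taken from it)
    or a plain array with ``frame_times`` given explicitly.
    """
    if frame_times is None:
        values, times = aif.values, aif.frame_times
    else:
        values, times = np.asarray(aif, dtype=float), np.asarray(frame_times, dtype=float)
    ct = one_compartment_curve(values, times, params.ktrans, params.ecv)
    return TissueCurve(values=ct, frame_times=times)


def roi_mean_curve(enh, roi) -> TissueCurve:
    """Frame-wise mean enhancement over the ROI's voxels (dynamic frames)."""
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    dyn = enh.dynamic_values()
    vals = dyn[roi.mask].mean(axis=0)
    return TissueCurve(values=vals, frame_times=enh.dynamic_times())


def fit_one_compartment(curve: TissueCurve, aif) -> OneCompartmentParams:
    """Nonlinear least-squares fit of Ktrans and ECV to a ROI-mean curve.

    Bounded trust-region least squares from (ktrans, ecv) = (0.3, 30),
    with three extra starts if the first does not converge. Never raises
    on non-convergence: the best parameters seen are returned with
    ``converged = False``.
    """
    obs = np.asarray(curve.values, dtype=float)
    t = np.asarray(curve.frame_times, dtype=float)
    ca = np.asarray(aif.values, dtype=float)
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(ca))):
        raise ValueError("non-finite values in tissue curve or AIF")
    if obs.shape != ca.shape:
        raise ValueError("tissue curve and AIF must share the frame grid")

    def resid(x):
        return one_compartment_curve(ca, t, x[0], x[1]) - obs

    lo = (KTRANS_BOUNDS[0], ECV_BOUNDS[0])
    hi = (KTRANS_BOUNDS[1], ECV_BOUNDS[1])
    best = None
    for x0 in (_X0,) + _MULTISTARTS:
        res = least_squares(resid, x0=x0, bounds=(lo, hi))
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
        if res.success:
            break
    rss, res = best
    ktrans, ecv = float(res.x[0]), float(res.x[1])
    converged = bool(res.success)
    # the objective is flat near zero uptake; prefer the boundary null model
    # outright when it fits at least as well as the optimizer's endpoint
    null_x = (KTRANS_BOUNDS[0], 1.0)
    null_rss = float(np.sum(resid(null_x) ** 2))
    if null_rss <= rss:
        ktrans, ecv, rss = null_x[0], null_x[1], null_rss
        converged = True
    return OneCompartmentParams(
        ktrans=ktrans,
        ecv=ecv,
        mtt=mtt_from_params(ktrans, ecv),
        fit_rss=rss,
        converged=converged,
    )
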