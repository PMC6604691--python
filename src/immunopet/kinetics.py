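"""Patlak graphical analysis of irreversible tracer uptake.

The tissue signal is modeled as ``SUV(t) = A*Cp(t) + B*AUC(t)`` where
``Cp`` is the plasma activity concentration (expressed as SUV) and
``AUC(t)`` its running integral from injection.  Dividing through by
``Cp(t)`` linearizes the model: plotting ``SUV/Cp`` against the
"normalized time" ``AUC(t)/Cp(t)`` yields a straight line with slope
``B`` (net irreversible internalization rate, 1/h) and intercept ``A``
(reversible distribution coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasmaCurve",
    "LesionTimeActivity",
    "PatlakFit",
    "interpolate_cp",
    "cumulative_auc",
    "patlak_points",
    "patlak_fit",
    "fit_lesion",
]

#: Default earliest scan time (hours) admitted into a Patlak fit; earlier
#: scans precede tissue/plasma equilibration of the reversible compartment.
DEFAULT_MIN_FIT_TIME_H = 24.0


@dataclass(frozen=True)
class PlasmaCurve:
    """Sampled plasma input function for one patient x administration.

    ``cp`` holds the decay-corrected activity concentration expressed as
    SUV; ``conc_unlabeled`` optionally carries the immunoassay drug
    concentration (ug/mL) at the same times.
    """

    patient_id: str
    administration: str  # "first" | "second"
    times: np.ndarray  # hours post-injection, strictly increasing
    cp: np.ndarray  # SUV
    conc_unlabeled: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cp", c)
        if self.conc_unlabeled is not None:
            u = np.asarray(self.conc_unlabeled, dtype=float)
            if u.shape != t.shape:
                raise ValueError("conc_unlabeled must align with times")
            object.__setattr__(self, "conc_unlabeled", u)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("plasma curve needs at least 3 samples")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if c.shape != t.shape:
            raise ValueError("cp must align with times")
        if np.any(c < 0):
            raise ValueError("cp must be non-negative")


@dataclass(frozen=True)
class LesionTimeActivity:
    """Per-lesion SUVpeak across scan times, with administration context.

    ``suv`` may contain NaN for unquantifiable entries (BLQ / not
    applicable); those points are excluded from fitting and summaries.
    """

    patient_id: str
    lesion_id: str
    tissue_class: str  # bone | soft-tissue | lung | lymph-node
    administration: str  # "first" | "second"
    dose_mg_kg: float  # total antibody mass dose for this administration
    scan_times: np.ndarray  # hours
    suv: np.ndarray  # SUVpeak, NaN = missing

    def __post_init__(self) -> None:
        t = np.asarray(self.scan_times, dtype=float)
        s = np.asarray(self.suv, dtype=float)
        object.__setattr__(self, "scan_times", t)
        object.__setattr__(self, "suv", s)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        if s.shape != t.shape:
            raise ValueError("suv must align with scan_times")

    @property
    def n_quantified(self) -> int:
        return int(np.sum(np.isfinite(self.suv)))


@dataclass(frozen=True)
class PatlakFit:
    """Ordinary least-squares line through Patlak-transformed points."""

    intercept_A: float  # dimensionless reversible coefficient
    slope_B: float  # 1/h, net irreversible uptake rate
    r_squared: float
    n_points: int
    x_values: np.ndarray = field(repr=False)  # AUC(t)/Cp(t), hours
    y_values: np.ndarray = field(repr=False)  # SUV/Cp(t)
    flags: tuple[str, ...] = ()


def interpolate_cp(curve: PlasmaCurve, t, *, method: str = "log-linear"):
    """Evaluate the input function at time(s) ``t`` within its support.

    Default interpolation is log-linear (exponential segments), the
    natural choice for multi-exponential antibody plasma decay; exact at
    sample points.  Segments touching a non-positive sample fall back to
    linear interpolation.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    tt, cc = curve.times, curve.cp
    if np.any(t_arr < tt[0] - 1e-12) or np.any(t_arr > tt[-1] + 1e-12):
        raise ValueError(
            f"time outside plasma support [{tt[0]}, {tt[-1]}]: refusing to extrapolate"
        )
    t_arr = np.clip(t_arr, tt[0], tt[-1])
    if method == "linear":
        out = np.interp(t_arr, tt, cc)
    elif method == "log-linear":
        if np.all(cc > 0):
            out = np.exp(np.interp(t_arr, tt, np.log(cc)))
        else:  # mixed: per-segment fallback where logs are undefined
            out = np.empty_like(t_arr)
            idx = np.clip(np.searchsorted(tt, t_arr, side="right") - 1, 0, tt.size - 2)
            for k, (ti, i) in enumerate(zip(t_arr, idx)):
                c0, c1 = cc[i], cc[i + 1]
                w = (ti - tt[i]) / (tt[i + 1] - tt[i])
                if c0 > 0 and c1 > 0:
                    out[k] = c0 * (c1 / c0) ** w
                else:
                    out[k] = c0 + w * (c1 - c0)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return float(out[0]) if scalar else out


def _segment_integral(t0, t1, c0, c1, method):
    """Integral of one interpolated segment on [t0, t1]."""
    dt = t1 - t0
    if dt == 0:
        return 0.0
    if method == "log-linear" and c0 > 0 and c1 > 0 and not np.isclose(c0, c1):
        lam = np.log(c1 / c0) / dt  # exact exponential-segment integral
        return (c1 - c0) / lam
    return 0.5 * (c0 + c1) * dt


def cumulative_auc(curve: PlasmaCurve, t: float, *, method: str = "log-linear") -> float:
    """Integral of the interpolated input function from 0 to ``t``.

    The first plasma sample is held constant back to t=0 (the short
    infusion period is not modeled; the contribution is negligible at
    the 48-120 h scan times that enter Patlak fits).
    """
    t = float(t)
    if t < 0:
        raise ValueError("t must be non-negative")
    tt, cc = curve.times, curve.cp
    if t > tt[-1] + 1e-12:
        raise ValueError(f"t={t} beyond plasma support (last sample {tt[-1]} h)")
    if t <= tt[0]:
        return cc[0] * t  # back-extrapolation: constant at first sample
    total = cc[0] * tt[0]
    for i in range(tt.size - 1):
        if tt[i + 1] <= t:
            total += _segment_integral(tt[i], tt[i + 1], cc[i], cc[i + 1], method)
        else:
            c_t = interpolate_cp(curve, t, method=method)
            total += _segment_integral(tt[i], t, cc[i], c_t, method)
            break
    return float(total)


def patlak_points(
    tac: LesionTimeActivity,
    plasma: PlasmaCurve,
    *,
    min_fit_time_h: float = DEFAULT_MIN_FIT_TIME_H,
    method: str = "log-linear",
) -> list[tuple[float, float]]:
    """Patlak-transform a lesion TAC: x = AUC(t)/Cp(t), y = SUV(t)/Cp(t).

    One point per non-missing scan time at or after ``min_fit_time_h``,
    ordered by time.  Points where Cp vanishes are dropped with a warning.
    """
    if (tac.patient_id, tac.administration) != (plasma.patient_id, plasma.administration):
        raise ValueError(
            "lesion TAC and plasma curve refer to different patient/administration"
        )
    pts: list[tuple[float, float]] = []
    for t, s in zip(tac.scan_times, tac.suv):
        if not np.isfinite(s) or t < min_fit_time_h:
            continue
        cp_t = interpolate_cp(plasma, t, method=method)
        if cp_t <= 0:
            warnings.warn(
                f"Cp(t={t} h) is zero for {tac.lesion_id}; Patlak point dropped",
                stacklevel=2,
            )
            continue
        pts.append((cumulative_auc(plasma, t, method=method) / cp_t, s / cp_t))
    return pts


def patlak_fit(points: list[tuple[float, float]]) -> PatlakFit:
    """Unweighted OLS line through Patlak points.

    With exactly two points the line is exact and r^2 = 1 by
    construction.  Negative slopes are retained but flagged so that
    downstream ratio statistics stay unbiased.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if x.size < 2:
        raise ValueError("Patlak fit requires at least 2 points")
    if np.ptp(x) <= 0:
        raise ValueError("Patlak fit requires distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if x.size == 2 or ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    flags = ("negative_slope",) if slope < 0 else ()
    return PatlakFit(
        intercept_A=float(intercept),
        slope_B=float(slope),
        r_squared=float(r2),
        n_points=int(x.size),
        x_values=x,
        y_values=y,
        flags=flags,
    )


def fit_lesion(
    tac: LesionTimeActivity,
    plasma: PlasmaCurve,
    *,
    min_fit_time_h: float = DEFAULT_MIN_FIT_TIME_H,
    method: str = "log-linear",
) -> PatlakFit:
    """Convenience: transform then fit one lesion x administration."""
    return patlak_fit(patlak_points(tac, plasma, min_fit_time_h=min_fit_time_h, method=method))
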