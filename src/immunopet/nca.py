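"""Noncompartmental pharmacokinetics of drug concentration curves.

Also checks consistency between the labeled (activity-derived) and
unlabeled (immunoassay) dispositions via their per-timepoint ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import PlasmaCurve

__all__ = ["NCAResult", "nca", "auc_trapezoid", "labeled_unlabeled_ratio"]


@dataclass(frozen=True)
class NCAResult:
    cmax: float  # ug/mL
    tmax_h: float  # an observed sample time (first occurrence on ties)
    auc_last: float  # h*ug/mL, linear trapezoid to t_last
    t_last_h: float
    flags: tuple[str, ...] = ()


def auc_trapezoid(times, conc, *, method: str = "linear", t_end: float | None = None) -> float:
    """AUC over observed points, linear trapezoid by default.

    ``method='log-linear-down'`` uses the log-trapezoid on strictly
    decreasing positive segments (standard "linear-up/log-down" rule).
    ``t_end`` truncates the window (interpolating the final segment).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size or t.size < 2:
        raise ValueError("need at least 2 aligned samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end is not None:
        if t_end <= t[0]:
            return 0.0
        if t_end < t[-1]:
            c_end = np.interp(t_end, t, c)
            keep = t < t_end
            t = np.append(t[keep], t_end)
            c = np.append(c[keep], c_end)
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        if method == "log-linear-down" and c[i] > c[i + 1] > 0:
            total += dt * (c[i] - c[i + 1]) / np.log(c[i] / c[i + 1])
        else:
            total += 0.5 * (c[i] + c[i + 1]) * dt
    return float(total)


def nca(times, conc, *, auc_method: str = "linear", t_end: float | None = None) -> NCAResult:
    """Cmax/Tmax from the observed maximum; AUClast by trapezoid."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("NCA needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    flags: tuple[str, ...] = ()
    if np.all(c == 0):
        flags = ("all_zero_curve",)
        return NCAResult(cmax=0.0, tmax_h=float(t[0]), auc_last=0.0, t_last_h=float(t[-1]), flags=flags)
    imax = int(np.argmax(c))  # argmax returns the first occurrence on ties
    return NCAResult(
        cmax=float(c[imax]),
        tmax_h=float(t[imax]),
        auc_last=auc_trapezoid(t, c, method=auc_method, t_end=t_end),
        t_last_h=float(t[-1] if t_end is None else min(t[-1], t_end)),
        flags=flags,
    )


def labeled_unlabeled_ratio(
    plasma: PlasmaCurve, administered_mass_mg: float, body_weight_kg: float
) -> dict[str, float]:
    """Per-timepoint ratio of activity-derived to immunoassay concentration.

    The radioactivity channel (SUV) is recalculated to mass
    concentration as SUV * mass/weight (mg/kg = ug/g = ug/mL at unit
    density).  Zero-denominator points are excluded with a warning.
    Returns mean and SD of the ratio over retained time points.
    """
    if plasma.conc_unlabeled is None:
        raise ValueError("plasma curve carries no unlabeled concentration channel")
    if administered_mass_mg <= 0 or body_weight_kg <= 0:
        raise ValueError("administered mass and body weight must be positive")
    activity_mass = plasma.cp * administered_mass_mg / body_weight_kg
    denom = plasma.conc_unlabeled
    ok = denom > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} time point(s) with zero immunoassay concentration excluded",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("no time points with positive immunoassay concentration")
    ratio = activity_mass[ok] / denom[ok]
    return {
        "mean_ratio": float(ratio.mean()),
        "sd": float(ratio.std(ddof=1)) if ratio.size > 1 else 0.0,
        "n": int(ratio.size),
    }
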