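"""Dose-dependent target-engagement modeling.

On-treatment Patlak slopes are normalized to each lesion's baseline
slope (baseline = 100%) and the pooled percentage ratios are fitted to
a saturation model

    R(dose) = [1 - dose/(dose + ID50)] * (100 - Rnsp) + Rnsp

whose constant term Rnsp captures nonspecific internalization (e.g.
pinocytosis).  ID50 is the mass dose halving the specific uptake rate;
the dose inhibiting a fraction q of the specific term follows
analytically as ID_q = ID50 * q/(100 - q), so ID90 = 9 * ID50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kinetics import PatlakFit

__all__ = [
    "SlopeRatio",
    "DoseInhibitionFit",
    "normalize_to_baseline",
    "predict_R",
    "fit_inhibition",
    "inhibitory_dose",
    "plot_inhibition",
]


@dataclass(frozen=True)
class SlopeRatio:
    """On-treatment internalization rate as percent of baseline."""

    patient_id: str
    lesion_id: str
    dose_mg_kg: float  # mass dose at the second administration
    ratio_pct: float  # 100 * B_second / B_first


@dataclass(frozen=True)
class DoseInhibitionFit:
    id50_mg_kg: float
    rnsp_pct: float
    id90_mg_kg: float  # = 9 * id50, exact identity of the model
    residual_sse: float
    converged: bool
    n_points: int
    flags: tuple[str, ...] = ()
    covariance: np.ndarray | None = field(default=None, repr=False)
    ci95_id50: tuple[float, float] | None = None
    ci95_rnsp: tuple[float, float] | None = None


class BaselineSlopeError(ValueError):
    """Baseline Patlak slope is non-positive; no ratio can be formed."""


def normalize_to_baseline(baseline: PatlakFit, treatment: PatlakFit, *,
                          patient_id: str = "", lesion_id: str = "",
                          dose_mg_kg: float = 0.0) -> SlopeRatio:
    """Express a treatment slope as a percentage of the baseline slope.

    A baseline fit normalized against itself yields 100% by definition.
    Raises :class:`BaselineSlopeError` for non-positive baseline slopes;
    callers exclude such lesions with a recorded reason.
    """
    if baseline.slope_B <= 0:
        raise BaselineSlopeError(
            f"baseline slope {baseline.slope_B:.4g}/h is not positive for "
            f"{patient_id}/{lesion_id}; lesion excluded"
        )
    return SlopeRatio(
        patient_id=patient_id,
        lesion_id=lesion_id,
        dose_mg_kg=dose_mg_kg,
        ratio_pct=100.0 * treatment.slope_B / baseline.slope_B,
    )


def predict_R(dose_mg_kg, id50_mg_kg: float, rnsp_pct: float):
    """Saturation-model ratio (percent of baseline) at a mass dose.

    R(0) = 100 exactly; strictly decreasing in dose for rnsp < 100 with
    asymptote rnsp.
    """
    if id50_mg_kg <= 0:
        raise ValueError("id50 must be positive")
    if not 0 <= rnsp_pct <= 100:
        raise ValueError("rnsp must lie in [0, 100]")
    dose = np.asarray(dose_mg_kg, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = (1.0 - dose / (dose + id50_mg_kg)) * (100.0 - rnsp_pct) + rnsp_pct
    return float(out) if out.ndim == 0 else out


def inhibitory_dose(fit_or_id50, q: float) -> float:
    """Dose at which the specific (dose-dependent) term is inhibited by q%.

    Analytic inversion of the hyperbolic term: dose = ID50 * q/(100-q).
    q=50 returns ID50 itself; q=90 returns 9*ID50.
    """
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    id50 = fit_or_id50.id50_mg_kg if isinstance(fit_or_id50, DoseInhibitionFit) else float(fit_or_id50)
    if id50 <= 0:
        raise ValueError("id50 must be positive")
    return id50 * q / (100.0 - q)


def fit_inhibition(
    ratios: list[SlopeRatio],
    *,
    include_baseline_anchor: bool = True,
    baseline_anchor_dose_mg_kg: float = 0.0,
    fix_rnsp: float | None = None,
) -> DoseInhibitionFit:
    """Nonlinear least squares of the saturation model on pooled ratios.

    Each lesion contributes one (dose, ratio%) point with equal weight.
    When ``include_baseline_anchor`` is set, every patient additionally
    contributes a (baseline dose, 100%) anchor, mirroring baseline
    studies normalized to 100%.  Bounds: id50 > 0, rnsp in [0, 100];
    ``fix_rnsp`` pins the nonspecific plateau.  Non-convergence or a
    flat (non-identifiable) response is flagged, never silently
    returned.
    """
    if not ratios:
        raise ValueError("no ratio points to fit")
    dose = np.array([r.dose_mg_kg for r in ratios], dtype=float)
    y = np.array([r.ratio_pct for r in ratios], dtype=float)
    if include_baseline_anchor:
        n_anchor = len({r.patient_id for r in ratios})
        dose = np.concatenate([dose, np.full(n_anchor, baseline_anchor_dose_mg_kg)])
        y = np.concatenate([y, np.full(n_anchor, 100.0)])

    n_free = 1 if fix_rnsp is not None else 2
    n_levels = np.unique(np.round(dose, 9)).size
    if n_levels < n_free + 1:
        raise ValueError(
            f"under-determined fit: {n_levels} distinct dose levels for "
            f"{n_free} free parameter(s) plus the curve shape"
        )

    flags: list[str] = []
    if np.ptp(y) < 1e-9:
        warnings.warn("ratios show no dose response; fit is non-identifiable", stacklevel=2)
        return DoseInhibitionFit(
            id50_mg_kg=float("nan"),
            rnsp_pct=float(np.clip(y[0], 0, 100)),
            id90_mg_kg=float("nan"),
            residual_sse=0.0,
            converged=False,
            n_points=int(y.size),
            flags=("non_identifiable", "flat_response"),
        )

    nonzero = dose[dose > 0]
    id50_0 = float(np.median(nonzero)) if nonzero.size else 1.0
    rnsp_0 = float(np.clip(y.min(), 0.0, 100.0))

    if fix_rnsp is not None:
        if not 0 <= fix_rnsp <= 100:
            raise ValueError("fix_rnsp must lie in [0, 100]")
        def resid(p):
            return predict_R(dose, p[0], fix_rnsp) - y
        p0, lo, hi = [id50_0], [1e-9], [np.inf]
    else:
        def resid(p):
            return predict_R(dose, p[0], p[1]) - y
        p0, lo, hi = [id50_0, rnsp_0], [1e-9, 0.0], [np.inf, 100.0]

    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    id50 = float(sol.x[0])
    rnsp = float(fix_rnsp) if fix_rnsp is not None else float(sol.x[1])
    sse = float(np.sum(sol.fun**2))
    converged = bool(sol.success)
    if not converged:
        flags.append("no_convergence")

    cov = None
    ci_id50 = ci_rnsp = None
    dof = y.size - len(sol.x)
    if converged and dof > 0:
        J = sol.jac
        JTJ = J.T @ J
        if np.linalg.matrix_rank(JTJ) == JTJ.shape[0]:
            cov = np.linalg.inv(JTJ) * sse / dof
            se = np.sqrt(np.diag(cov))
            ci_id50 = (id50 - 1.96 * se[0], id50 + 1.96 * se[0])
            if fix_rnsp is None:
                ci_rnsp = (rnsp - 1.96 * se[1], rnsp + 1.96 * se[1])
        else:
            flags.append("singular_jacobian")

    return DoseInhibitionFit(
        id50_mg_kg=id50,
        rnsp_pct=rnsp,
        id90_mg_kg=9.0 * id50,
        residual_sse=sse,
        converged=converged,
        n_points=int(y.size),
        flags=tuple(flags),
        covariance=cov,
        ci95_id50=ci_id50,
        ci95_rnsp=ci_rnsp,
    )


def plot_inhibition(ratios: list[SlopeRatio], fit: DoseInhibitionFit, path: str) -> None:
    """Save a ratio-vs-dose plot with the fitted curve and the
    nonspecific asymptote as a dotted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dose = np.array([r.dose_mg_kg for r in ratios])
    y = np.array([r.ratio_pct for r in ratios])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(dose, y, "o", color="k", label="lesion B-ratio")
    if np.isfinite(fit.id50_mg_kg):
        grid = np.linspace(0, max(dose.max() * 1.1, 1.0), 300)
        ax.plot(grid, predict_R(grid, fit.id50_mg_kg, fit.rnsp_pct), "-", color="tab:blue",
                label=f"fit: ID50={fit.id50_mg_kg:.2g} mg/kg")
        ax.axhline(fit.rnsp_pct, ls=":", color="gray", label=f"nonspecific {fit.rnsp_pct:.0f}%")
    ax.set_xlabel("mass dose (mg/kg)")
    ax.set_ylabel("internalization rate, % of baseline")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
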