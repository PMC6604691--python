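"""End-to-end orchestration: simulate -> quantify -> patlak -> engage -> nca.

Each stage reads/writes the plain-text interchange files so stages can
also be run individually from the CLI.  The final ``report.json``
carries the headline estimates plus provenance (seed, config hash,
package version).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .engagement import (
    BaselineSlopeError,
    SlopeRatio,
    fit_inhibition,
    normalize_to_baseline,
)
from .io import (
    read_lesions_csv,
    read_plasma_csv,
    write_lesions_csv,
    write_plasma_csv,
    write_truth_json,
)
from .kinetics import DEFAULT_MIN_FIT_TIME_H, fit_lesion
from .nca import labeled_unlabeled_ratio, nca
from .quantify import suv_table_summary
from .synthetic import StudyConfig, generate_study

__all__ = ["RunConfig", "StageError", "run_pipeline", "patlak_stage", "engage_stage", "nca_stage"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    out_dir: str = "run"
    seed: int = 0
    study: StudyConfig = StudyConfig()
    stages: tuple[str, ...] = ("simulate", "quantify", "patlak", "engage", "nca")
    min_fit_time_h: float = DEFAULT_MIN_FIT_TIME_H
    sphere_volume_ml: float = 1.0
    fix_rnsp: float | None = None
    include_baseline_anchor: bool = True
    make_plot: bool = False

    def config_hash(self) -> str:
        # identifies the analysis, not its location on disk
        payload = json.dumps(self.model_dump(exclude={"out_dir"}), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def patlak_stage(
    plasma_csv, lesions_csv, out_csv, *, min_fit_time_h: float = DEFAULT_MIN_FIT_TIME_H
) -> pd.DataFrame:
    """Fit the Patlak line for every lesion x administration."""
    plasma = {(pc.patient_id, pc.administration): pc for pc in read_plasma_csv(plasma_csv)}
    rows = []
    for tac in read_lesions_csv(lesions_csv):
        key = (tac.patient_id, tac.administration)
        if key not in plasma:
            raise ValueError(f"no plasma curve for lesion {tac.lesion_id} ({key})")
        usable = tac.n_quantified
        if usable < 2:
            warnings.warn(
                f"{tac.patient_id}/{tac.lesion_id}/{tac.administration}: "
                f"{usable} quantified point(s), skipping fit",
                stacklevel=2,
            )
            continue
        fit = fit_lesion(tac, plasma[key], min_fit_time_h=min_fit_time_h)
        rows.append(
            {
                "patient_id": tac.patient_id,
                "lesion_id": tac.lesion_id,
                "administration": tac.administration,
                "dose_mg_kg": tac.dose_mg_kg,
                "A": fit.intercept_A,
                "B_per_h": fit.slope_B,
                "r2": fit.r_squared,
                "n_points": fit.n_points,
                "flags": ";".join(fit.flags),
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def engage_stage(
    fits: pd.DataFrame,
    *,
    fix_rnsp: float | None = None,
    include_baseline_anchor: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Normalize slopes to baseline and fit the dose-inhibition model."""
    ratios: list[SlopeRatio] = []
    exclusions: list[dict] = []
    for (pid, lid), grp in fits.groupby(["patient_id", "lesion_id"]):
        by_adm = {row["administration"]: row for _, row in grp.iterrows()}
        if "first" not in by_adm or "second" not in by_adm:
            exclusions.append({"patient_id": pid, "lesion_id": lid, "reason": "missing administration"})
            continue
        base, treat = by_adm["first"], by_adm["second"]
        from .kinetics import PatlakFit

        def as_fit(row):
            return PatlakFit(
                intercept_A=row["A"], slope_B=row["B_per_h"], r_squared=row["r2"],
                n_points=int(row["n_points"]), x_values=np.empty(0), y_values=np.empty(0),
            )

        try:
            ratios.append(
                normalize_to_baseline(
                    as_fit(base), as_fit(treat),
                    patient_id=str(pid), lesion_id=str(lid),
                    dose_mg_kg=float(treat["dose_mg_kg"]),
                )
            )
        except BaselineSlopeError as exc:
            exclusions.append({"patient_id": pid, "lesion_id": lid, "reason": str(exc)})

    fit = fit_inhibition(
        ratios, include_baseline_anchor=include_baseline_anchor, fix_rnsp=fix_rnsp
    )
    result = {
        "id50_mg_kg": fit.id50_mg_kg,
        "rnsp_pct": fit.rnsp_pct,
        "id90_mg_kg": fit.id90_mg_kg if np.isfinite(fit.id50_mg_kg) else float("nan"),
        "residual_sse": fit.residual_sse,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "flags": list(fit.flags),
        "exclusions": exclusions,
    }
    if fit.ci95_id50 is not None:
        result["ci95_id50"] = list(fit.ci95_id50)
    if fit.ci95_rnsp is not None:
        result["ci95_rnsp"] = list(fit.ci95_rnsp)
    ratio_df = pd.DataFrame(
        [
            {"patient_id": r.patient_id, "lesion_id": r.lesion_id,
             "dose_mg_kg": r.dose_mg_kg, "ratio_pct": r.ratio_pct}
            for r in ratios
        ]
    )
    return result, ratio_df


def nca_stage(plasma_csv, out_csv, *, body_weight_kg: float, tracer_mass_mg: float) -> pd.DataFrame:
    """NCA of the unlabeled channel per patient x administration, plus
    the labeled/unlabeled ratio check."""
    rows = []
    for pc in read_plasma_csv(plasma_csv):
        if pc.conc_unlabeled is None or not np.any(pc.conc_unlabeled > 0):
            continue
        res = nca(pc.times, pc.conc_unlabeled)
        # infer administered mass from the stored channel (conc = SUV*mass/weight)
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_est = np.nanmedian(np.where(pc.cp > 0, pc.conc_unlabeled / pc.cp, np.nan))
        mass_mg = dose_est * body_weight_kg if np.isfinite(dose_est) and dose_est > 0 else tracer_mass_mg
        ratio = labeled_unlabeled_ratio(pc, mass_mg, body_weight_kg)
        rows.append(
            {
                "patient_id": pc.patient_id,
                "administration": pc.administration,
                "cmax_ug_ml": res.cmax,
                "tmax_h": res.tmax_h,
                "auc_last_h_ug_ml": res.auc_last,
                "t_last_h": res.t_last_h,
                "labeled_unlabeled_mean": ratio["mean_ratio"],
                "labeled_unlabeled_sd": ratio["sd"],
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }
    study_cfg = config.study.model_copy(update={"seed": config.seed})
    plasma_csv = out / "plasma.csv"
    lesions_csv = out / "lesions.csv"

    if "simulate" in config.stages:
        try:
            study = generate_study(study_cfg)
            write_plasma_csv(study.plasma_curves, plasma_csv)
            write_lesions_csv(study.lesion_tacs, lesions_csv)
            write_truth_json(study, out / "truth.json")
        except Exception as exc:
            raise StageError("simulate", exc) from exc

    if "quantify" in config.stages:
        try:
            tacs = read_lesions_csv(lesions_csv)
            report["suv_summary"] = {
                adm: suv_table_summary(tacs, adm) for adm in ("first", "second")
            }
        except Exception as exc:
            raise StageError("quantify", exc) from exc

    fits = None
    if "patlak" in config.stages:
        try:
            fits = patlak_stage(
                plasma_csv, lesions_csv, out / "patlak_fits.csv",
                min_fit_time_h=config.min_fit_time_h,
            )
            report["n_patlak_fits"] = int(len(fits))
            report["lesion_slopes"] = fits.to_dict(orient="records")
        except Exception as exc:
            raise StageError("patlak", exc) from exc

    if "engage" in config.stages:
        try:
            if fits is None:
                fits = pd.read_csv(out / "patlak_fits.csv")
            eng, ratio_df = engage_stage(
                fits, fix_rnsp=config.fix_rnsp,
                include_baseline_anchor=config.include_baseline_anchor,
            )
            ratio_df.to_csv(out / "ratios.csv", index=False)
            (out / "engagement.json").write_text(json.dumps(eng, indent=2))
            report["engagement"] = eng
            if config.make_plot and len(ratio_df):
                from .engagement import DoseInhibitionFit, plot_inhibition

                ratios = [
                    SlopeRatio(r.patient_id, r.lesion_id, r.dose_mg_kg, r.ratio_pct)
                    for r in ratio_df.itertuples()
                ]
                fit_obj = DoseInhibitionFit(
                    id50_mg_kg=eng["id50_mg_kg"], rnsp_pct=eng["rnsp_pct"],
                    id90_mg_kg=eng["id90_mg_kg"], residual_sse=eng["residual_sse"],
                    converged=eng["converged"], n_points=eng["n_points"],
                )
                plot_inhibition(ratios, fit_obj, str(out / "inhibition.png"))
        except Exception as exc:
            raise StageError("engage", exc) from exc

    if "nca" in config.stages:
        try:
            nca_df = nca_stage(
                plasma_csv, out / "nca.csv",
                body_weight_kg=study_cfg.body_weight_kg,
                tracer_mass_mg=study_cfg.tracer_mass_mg,
            )
            report["nca"] = nca_df.to_dict(orient="records")
        except Exception as exc:
            raise StageError("nca", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
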