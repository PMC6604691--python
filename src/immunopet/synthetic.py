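"""Synthetic immuno-PET study generator with known ground truth.

Emulates the two-administration study design: a tracer-only baseline,
then a predose of unlabeled antibody followed by a second tracer
administration two weeks later.  Plasma kinetics are biexponential with
a dose-dependent (saturable, TMDD-like) terminal elimination rate;
lesion time-activity follows the irreversible-uptake model with a
dose-dependent internalization slope given by the saturation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .kinetics import LesionTimeActivity, PlasmaCurve, cumulative_auc, interpolate_cp

__all__ = [
    "PKParams",
    "LesionParams",
    "EngagementParams",
    "StudyConfig",
    "SyntheticStudy",
    "simulate_plasma",
    "true_slope",
    "simulate_lesion_tac",
    "generate_study",
]

ZR89_HALF_LIFE_H = 78.4  # 3.3 d; used only by the raw-counts export mode


class PKParams(BaseModel):
    """Biexponential plasma model with saturable terminal clearance.

    Cp(t) = c0 * [f*exp(-lf*t) + (1-f)*exp(-ls(dose)*t)] where the slow
    rate ls(dose) = lambda_slow + lambda_slow_tmdd * D50/(dose + D50)
    decreases monotonically with mass dose, reproducing the slower
    clearance observed at higher predoses.
    """

    model_config = {"frozen": True}

    c0_suv: float = Field(20.0, gt=0, description="central SUV at t=0")
    frac_fast: float = Field(0.35, ge=0, le=1)
    lambda_fast_per_h: float = Field(0.15, gt=0)
    lambda_slow_per_h: float = Field(0.010, gt=0)
    lambda_slow_tmdd_per_h: float = Field(0.020, ge=0, description="saturable-clearance coefficient; 0 disables dose dependence")
    tmdd_d50_mg_kg: float = Field(2.0, gt=0)

    def terminal_rate(self, dose_mg_kg: float) -> float:
        return self.lambda_slow_per_h + self.lambda_slow_tmdd_per_h * self.tmdd_d50_mg_kg / (
            dose_mg_kg + self.tmdd_d50_mg_kg
        )

    def cp(self, t, dose_mg_kg: float):
        lam2 = self.terminal_rate(dose_mg_kg)
        t = np.asarray(t, dtype=float)
        return self.c0_suv * (
            self.frac_fast * np.exp(-self.lambda_fast_per_h * t)
            + (1.0 - self.frac_fast) * np.exp(-lam2 * t)
        )


class LesionParams(BaseModel):
    model_config = {"frozen": True}

    A: float = Field(1.5, ge=0, description="reversible distribution coefficient")
    B0_per_h: float = Field(0.004, ge=0, description="baseline internalization slope")
    lesion_cv_A: float = Field(0.0, ge=0, description="inter-lesion lognormal CV of A")
    lesion_cv_B0: float = Field(0.0, ge=0, description="inter-lesion lognormal CV of B0")


class EngagementParams(BaseModel):
    model_config = {"frozen": True}

    id50_mg_kg: float = Field(2.0, gt=0)
    rnsp_pct: float = Field(30.0, ge=0, le=100)


class StudyConfig(BaseModel):
    """Full design of one synthetic study (the generating truth)."""

    model_config = {"frozen": True}

    n_patients: int = Field(6, ge=1)
    lesions_per_patient: int = Field(2, ge=1)
    body_weight_kg: float = Field(75.0, gt=0)
    injected_activity_mbq: float = Field(37.0, gt=0)
    tracer_mass_mg: float = Field(8.0, gt=0)
    predose_levels_mg_kg: tuple[float, ...] = (0.5, 1.0, 30.0, 30.0, 0.32, 0.0)
    scan_times_h: tuple[float, ...] = (2.0, 48.0, 120.0)
    plasma_sample_times_h: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0)
    pk_params: PKParams = PKParams()
    lesion_params: LesionParams = LesionParams()
    engagement_params: EngagementParams = EngagementParams()
    noise_cv: float = Field(0.10, ge=0)
    include_tracer_mass_in_engagement_dose: bool = Field(
        False,
        description=(
            "If True, the engagement dose axis includes the tracer's own mass "
            "(in mg/kg) for both administrations; the default treats the "
            "tracer-only baseline as dose 0 on the saturation curve so the "
            "baseline ratio is exactly 100%."
        ),
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_times(self) -> "StudyConfig":
        for name in ("scan_times_h", "plasma_sample_times_h"):
            t = np.asarray(getattr(self, name), dtype=float)
            if np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be non-negative and strictly increasing")
        if len(self.scan_times_h) < 2:
            raise ValueError("scan_times_h must include at least 2 points")
        if any(d < 0 for d in self.predose_levels_mg_kg):
            raise ValueError("predose levels must be non-negative")
        return self

    @property
    def tracer_dose_mg_kg(self) -> float:
        return self.tracer_mass_mg / self.body_weight_kg


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated cohort plus the truth needed for recovery testing."""

    config: StudyConfig
    plasma_curves: list[PlasmaCurve]
    lesion_tacs: list[LesionTimeActivity]
    # (patient_id, lesion_id) -> {"A", "B0_per_h", "B_first_per_h", "B_second_per_h"}
    truth_lesions: dict[tuple[str, str], dict[str, float]]

    def plasma_for(self, patient_id: str, administration: str) -> PlasmaCurve:
        for pc in self.plasma_curves:
            if (pc.patient_id, pc.administration) == (patient_id, administration):
                return pc
        raise KeyError(f"no plasma curve for {patient_id}/{administration}")


def true_slope(dose_mg_kg: float, B0_per_h: float, id50_mg_kg: float, rnsp_pct: float) -> float:
    """Internalization slope at a given competing mass dose.

    B(dose) = B0 * ([1 - dose/(dose+ID50)] * (100 - Rnsp) + Rnsp) / 100.
    At dose 0 this is B0; at saturating dose it decays to the
    nonspecific fraction Rnsp/100 of B0.
    """
    if id50_mg_kg <= 0:
        raise ValueError("id50 must be positive")
    if not 0 <= rnsp_pct <= 100:
        raise ValueError("rnsp must lie in [0, 100]")
    if B0_per_h < 0:
        raise ValueError("B0 must be non-negative")
    specific = 1.0 - dose_mg_kg / (dose_mg_kg + id50_mg_kg)
    return B0_per_h * (specific * (100.0 - rnsp_pct) + rnsp_pct) / 100.0


def simulate_plasma(
    config: StudyConfig,
    dose_mg_kg: float,
    seed: int,
    *,
    patient_id: str = "P1",
    administration: str = "first",
) -> PlasmaCurve:
    """Sample the input function at plasma sample times plus scan times.

    ``dose_mg_kg`` is the total mass dose (tracer mass converted to
    mg/kg already added by the caller); it only affects the terminal
    elimination rate.  The curve itself is noise-free (gamma-counter
    plasma measurements are precise relative to PET); ``seed`` is kept
    in the signature so a noise model can be slotted in without an
    interface change.
    """
    if config.body_weight_kg <= 0 or config.injected_activity_mbq <= 0:
        raise ValueError("body weight and injected activity must be positive")
    if dose_mg_kg < 0:
        raise ValueError("dose must be non-negative")
    times = np.unique(np.concatenate([config.plasma_sample_times_h, config.scan_times_h]))
    cp = config.pk_params.cp(times, dose_mg_kg)
    # unlabeled mass concentration: SUV * (mg/kg) is ug/g = ug/mL at unit density
    conc = cp * dose_mg_kg
    return PlasmaCurve(
        patient_id=patient_id,
        administration=administration,
        times=times,
        cp=cp,
        conc_unlabeled=conc,
    )


def simulate_lesion_tac(
    plasma: PlasmaCurve,
    A: float,
    B_per_h: float,
    scan_times,
    noise_cv: float,
    seed: int,
    *,
    lesion_id: str = "L1",
    tissue_class: str = "soft-tissue",
    dose_mg_kg: float = 0.0,
) -> LesionTimeActivity:
    """Forward-simulate one lesion TAC from the irreversible-uptake model.

    Noise-free signal: SUV(t) = A*Cp(t) + B*AUC(t), with AUC evaluated
    by exact integration of the log-linearly interpolated plasma curve.
    Multiplicative lognormal noise with the given CV is applied per scan
    time (PET SUV noise is approximately proportional to the signal).
    """
    scan_times = np.asarray(scan_times, dtype=float)
    if np.any(scan_times < 0):
        raise ValueError("scan times must be non-negative")
    if np.any(scan_times > plasma.times[-1] + 1e-9):
        raise ValueError("scan time beyond plasma support")
    signal = np.array(
        [
            A * interpolate_cp(plasma, t) + B_per_h * cumulative_auc(plasma, t)
            for t in scan_times
        ]
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        signal = signal * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=signal.size)
    return LesionTimeActivity(
        patient_id=plasma.patient_id,
        lesion_id=lesion_id,
        tissue_class=tissue_class,
        administration=plasma.administration,
        dose_mg_kg=dose_mg_kg,
        scan_times=scan_times,
        suv=signal,
    )


_TISSUE_CYCLE = ("bone", "soft-tissue", "lung", "lymph-node")


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Build a full cohort: two administrations per patient.

    The first administration is tracer-only; the second adds the
    patient's assigned predose level.  Per-lesion baseline slopes (and
    optionally A) vary lognormally around the configured values; the
    realized slope at each administration follows the saturation model
    exactly, so downstream recovery can be checked against truth.
    """
    eng = config.engagement_params
    rng = np.random.default_rng(config.seed)
    tracer = config.tracer_dose_mg_kg

    plasma_curves: list[PlasmaCurve] = []
    lesion_tacs: list[LesionTimeActivity] = []
    truth: dict[tuple[str, str], dict[str, float]] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1}"
        predose = config.predose_levels_mg_kg[i % len(config.predose_levels_mg_kg)]
        # total circulating mass drives plasma clearance for both administrations
        admins = [("first", tracer, 0.0), ("second", predose + tracer, predose)]
        if config.include_tracer_mass_in_engagement_dose:
            admins = [("first", tracer, tracer), ("second", predose + tracer, predose + tracer)]

        curves = {
            adm: simulate_plasma(
                config, pk_dose, seed=config.seed, patient_id=pid, administration=adm
            )
            for adm, pk_dose, _ in admins
        }
        plasma_curves.extend(curves.values())

        for j in range(config.lesions_per_patient):
            lid = f"L{j + 1}"
            lp = config.lesion_params
            A = lp.A
            B0 = lp.B0_per_h
            if lp.lesion_cv_A > 0:
                sig = np.sqrt(np.log1p(lp.lesion_cv_A**2))
                A *= rng.lognormal(-0.5 * sig**2, sig)
            if lp.lesion_cv_B0 > 0:
                sig = np.sqrt(np.log1p(lp.lesion_cv_B0**2))
                B0 *= rng.lognormal(-0.5 * sig**2, sig)
            rec = {"A": A, "B0_per_h": B0}
            for adm, _, eng_dose in admins:
                B = true_slope(eng_dose, B0, eng.id50_mg_kg, eng.rnsp_pct)
                rec[f"B_{adm}_per_h"] = B
                noise_seed = int(rng.integers(0, 2**31 - 1))
                lesion_tacs.append(
                    simulate_lesion_tac(
                        curves[adm],
                        A,
                        B,
                        config.scan_times_h,
                        config.noise_cv,
                        noise_seed,
                        lesion_id=lid,
                        tissue_class=_TISSUE_CYCLE[j % len(_TISSUE_CYCLE)],
                        dose_mg_kg=eng_dose,
                    )
                )
            truth[(pid, lid)] = rec

    return SyntheticStudy(
        config=config,
        plasma_curves=plasma_curves,
        lesion_tacs=lesion_tacs,
        truth_lesions=truth,
    )
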