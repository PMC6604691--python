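"""CSV/JSON interchange for plasma curves and lesion tables.

Dialect: UTF-8, dot decimal, long format.  Unquantifiable SUV entries
are written as the explicit tokens ``BLQ`` (below limit of
quantification) or ``NA`` (not applicable); both are read back as
missing values.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import LesionTimeActivity, PlasmaCurve

__all__ = [
    "write_plasma_csv",
    "read_plasma_csv",
    "write_lesions_csv",
    "read_lesions_csv",
    "load_table2_lesions",
]

MISSING_TOKENS = ("BLQ", "NA", "")


def write_plasma_csv(curves: list[PlasmaCurve], path) -> None:
    rows = []
    for pc in curves:
        for i, t in enumerate(pc.times):
            rows.append(
                {
                    "patient_id": pc.patient_id,
                    "administration": pc.administration,
                    "time_h": t,
                    "suv": pc.cp[i],
                    "conc_ug_ml": pc.conc_unlabeled[i] if pc.conc_unlabeled is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plasma_csv(path) -> list[PlasmaCurve]:
    df = pd.read_csv(path)
    curves = []
    for (pid, adm), grp in df.groupby(["patient_id", "administration"], sort=True):
        grp = grp.sort_values("time_h")
        conc = None
        if "conc_ug_ml" in grp.columns and grp["conc_ug_ml"].notna().all():
            conc = grp["conc_ug_ml"].to_numpy(dtype=float)
        curves.append(
            PlasmaCurve(
                patient_id=str(pid),
                administration=str(adm),
                times=grp["time_h"].to_numpy(dtype=float),
                cp=grp["suv"].to_numpy(dtype=float),
                conc_unlabeled=conc,
            )
        )
    return curves


def write_lesions_csv(tacs: list[LesionTimeActivity], path) -> None:
    rows = []
    for tac in tacs:
        for t, s in zip(tac.scan_times, tac.suv):
            rows.append(
                {
                    "patient_id": tac.patient_id,
                    "lesion_id": tac.lesion_id,
                    "tissue_class": tac.tissue_class,
                    "administration": tac.administration,
                    "dose_mg_kg": tac.dose_mg_kg,
                    "time_h": t,
                    "suv_peak": s if np.isfinite(s) else "NA",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lesions_csv(path) -> list[LesionTimeActivity]:
    df = pd.read_csv(path, dtype={"suv_peak": str}, keep_default_na=False)
    tacs = []
    keys = ["patient_id", "lesion_id", "administration"]
    for (pid, lid, adm), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        suv = np.array(
            [
                np.nan if str(v).strip().upper() in MISSING_TOKENS else float(v)
                for v in grp["suv_peak"]
            ]
        )
        dose_raw = grp["dose_mg_kg"].iloc[0] if "dose_mg_kg" in grp.columns else ""
        try:
            dose = float(dose_raw)
        except (TypeError, ValueError):
            dose = float("nan")
        tacs.append(
            LesionTimeActivity(
                patient_id=str(pid),
                lesion_id=str(lid),
                tissue_class=str(grp["tissue_class"].iloc[0]),
                administration=str(adm),
                dose_mg_kg=dose,
                scan_times=grp["time_h"].to_numpy(dtype=float),
                suv=suv,
            )
        )
    return tacs


def load_table2_lesions() -> list[LesionTimeActivity]:
    """Packaged per-lesion SUVpeak table of the 6-patient study
    (both administrations, BLQ/NA entries preserved)."""
    ref = importlib.resources.files("immunopet").joinpath("data/table2_suvpeak.csv")
    with importlib.resources.as_file(ref) as p:
        return read_lesions_csv(p)


def write_truth_json(study, path) -> None:
    """Serialize a synthetic study's generating config and realized
    per-lesion parameters."""
    payload = {
        "config": study.config.model_dump(),
        "lesions": [
            {"patient_id": pid, "lesion_id": lid, **vals}
            for (pid, lid), vals in sorted(study.truth_lesions.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
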