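import numpy as np
import pytest

from immunopet import PlasmaCurve, StudyConfig


@pytest.fixture
def biexp_params():
    """Reference biexponential input function parameters."""
    return dict(c1=7.0, lam1=0.15, c2=13.0, lam2=0.02)


@pytest.fixture
def biexp_curve(biexp_params):
    p = biexp_params
    t = np.array([1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0])
    cp = p["c1"] * np.exp(-p["lam1"] * t) + p["c2"] * np.exp(-p["lam2"] * t)
    return PlasmaCurve(patient_id="P1", administration="first", times=t, cp=cp)


@pytest.fixture
def noise_free_config():
    return StudyConfig(
        n_patients=6,
        lesions_per_patient=2,
        predose_levels_mg_kg=(0.5, 1.0, 30.0, 30.0, 0.32, 0.0),
        noise_cv=0.0,
        seed=7,
    )
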