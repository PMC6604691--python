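import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from immunopet import (
    PKParams,
    StudyConfig,
    generate_study,
    simulate_lesion_tac,
    simulate_plasma,
    true_slope,
)
from immunopet.kinetics import cumulative_auc, interpolate_cp


class TestTrueSlope:
    def test_zero_dose_is_baseline(self):
        assert true_slope(0.0, 0.004, 2.0, 30.0) == pytest.approx(0.004)

    def test_at_id50(self):
        # (0.5*70 + 30)/100 = 0.65
        assert true_slope(2.0, 0.004, 2.0, 30.0) == pytest.approx(0.65 * 0.004)

    def test_asymptote_is_nonspecific_fraction(self):
        assert true_slope(1e9, 0.004, 2.0, 30.0) == pytest.approx(0.30 * 0.004, rel=1e-6)

    def test_invalid_id50(self):
        with pytest.raises(ValueError):
            true_slope(1.0, 0.004, 0.0, 30.0)

    @settings(max_examples=50, deadline=None)
    @given(
        d1=st.floats(0.0, 100.0),
        delta=st.floats(1e-3, 100.0),
        rnsp=st.floats(0.0, 99.0),
    )
    def test_strictly_decreasing_for_rnsp_below_100(self, d1, delta, rnsp):
        lo = true_slope(d1 + delta, 1.0, 2.0, rnsp)
        hi = true_slope(d1, 1.0, 2.0, rnsp)
        assert lo < hi

    @given(dose=st.floats(0.0, 1000.0))
    def test_constant_for_rnsp_100(self, dose):
        assert true_slope(dose, 1.0, 2.0, 100.0) == pytest.approx(1.0)


class TestSimulatePlasma:
    def test_higher_dose_slower_terminal_clearance(self):
        cfg = StudyConfig()
        lo = simulate_plasma(cfg, 0.1, seed=0)
        hi = simulate_plasma(cfg, 30.0, seed=0)
        assert hi.cp[-1] >= lo.cp[-1]  # terminal SUV at 120 h

    def test_tmdd_coefficient_zero_removes_dose_dependence(self):
        cfg = StudyConfig(pk_params=PKParams(lambda_slow_tmdd_per_h=0.0))
        a = simulate_plasma(cfg, 0.0, seed=0)
        b = simulate_plasma(cfg, 30.0, seed=0)
        np.testing.assert_allclose(a.cp, b.cp)

    def test_biexponential_auc_matches_closed_form(self):
        # oracle: AUC(inf) of c1*exp(-l1 t) + c2*exp(-l2 t) is c1/l1 + c2/l2
        pk = PKParams(lambda_slow_tmdd_per_h=0.0)
        c1 = pk.c0_suv * pk.frac_fast
        c2 = pk.c0_suv * (1 - pk.frac_fast)
        closed_form = c1 / pk.lambda_fast_per_h + c2 / pk.lambda_slow_per_h
        numeric, _ = quad(lambda t: pk.cp(t, 0.0), 0, np.inf)
        assert numeric == pytest.approx(closed_form, rel=5e-3)

    def test_values_positive_and_deterministic(self):
        cfg = StudyConfig()
        a = simulate_plasma(cfg, 1.0, seed=5)
        b = simulate_plasma(cfg, 1.0, seed=5)
        assert np.all(a.cp > 0)
        np.testing.assert_array_equal(a.cp, b.cp)

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            StudyConfig(body_weight_kg=-1.0)
        with pytest.raises(ValueError):
            simulate_plasma(StudyConfig(), -0.5, seed=0)


class TestSimulateLesionTac:
    def test_pure_reversible_signal(self, biexp_curve):
        tac = simulate_lesion_tac(biexp_curve, 2.0, 0.0, [24, 48, 120], 0.0, 0)
        ratios = [s / interpolate_cp(biexp_curve, t) for t, s in zip(tac.scan_times, tac.suv)]
        assert ratios == pytest.approx([2.0, 2.0, 2.0], rel=1e-9)

    def test_linear_accumulation_under_constant_cp(self):
        from immunopet import PlasmaCurve

        t = np.array([0.0, 30.0, 60.0, 130.0])
        curve = PlasmaCurve("P1", "first", t, np.full(4, 3.0))
        tac = simulate_lesion_tac(curve, 0.0, 0.002, [40, 120], 0.0, 0)
        assert tac.suv == pytest.approx([0.002 * 3.0 * 40, 0.002 * 3.0 * 120], rel=1e-9)

    def test_matches_quadrature_oracle(self, biexp_curve):
        A, B, t_eval = 1.0, 0.002, 120.0
        tac = simulate_lesion_tac(biexp_curve, A, B, [t_eval], 0.0, 0)
        grid = np.linspace(biexp_curve.times[0], t_eval, 50001)
        dense = interpolate_cp(biexp_curve, grid)
        auc = np.trapezoid(dense, grid) + biexp_curve.cp[0] * biexp_curve.times[0]
        oracle = A * interpolate_cp(biexp_curve, t_eval) + B * auc
        assert tac.suv[0] == pytest.approx(oracle, rel=1e-3)

    def test_scan_beyond_support_rejected(self, biexp_curve):
        with pytest.raises(ValueError, match="support"):
            simulate_lesion_tac(biexp_curve, 1.0, 0.001, [200.0], 0.0, 0)

    def test_noise_is_multiplicative_and_seeded(self, biexp_curve):
        a = simulate_lesion_tac(biexp_curve, 1.0, 0.002, [48, 120], 0.2, 42)
        b = simulate_lesion_tac(biexp_curve, 1.0, 0.002, [48, 120], 0.2, 42)
        c = simulate_lesion_tac(biexp_curve, 1.0, 0.002, [48, 120], 0.2, 43)
        np.testing.assert_array_equal(a.suv, b.suv)
        assert not np.array_equal(a.suv, c.suv)
        assert np.all(a.suv > 0)


class TestGenerateStudy:
    def test_two_plasma_curves_per_patient(self, noise_free_config):
        study = generate_study(noise_free_config)
        assert len(study.plasma_curves) == 2 * noise_free_config.n_patients
        assert len(study.lesion_tacs) == (
            2 * noise_free_config.n_patients * noise_free_config.lesions_per_patient
        )

    def test_every_tac_references_existing_plasma(self, noise_free_config):
        study = generate_study(noise_free_config)
        keys = {(pc.patient_id, pc.administration) for pc in study.plasma_curves}
        for tac in study.lesion_tacs:
            assert (tac.patient_id, tac.administration) in keys

    def test_truth_satisfies_saturation_model_exactly(self, noise_free_config):
        study = generate_study(noise_free_config)
        eng = noise_free_config.engagement_params
        for i in range(noise_free_config.n_patients):
            pid = f"P{i+1}"
            predose = noise_free_config.predose_levels_mg_kg[i]
            for (p, _lid), rec in study.truth_lesions.items():
                if p != pid:
                    continue
                assert rec["B_first_per_h"] == pytest.approx(rec["B0_per_h"])
                assert rec["B_second_per_h"] == pytest.approx(
                    true_slope(predose, rec["B0_per_h"], eng.id50_mg_kg, eng.rnsp_pct)
                )

    def test_same_seed_reproduces_identical_tables(self, tmp_path, noise_free_config):
        from immunopet.io import write_lesions_csv, write_plasma_csv

        cfg = noise_free_config.model_copy(update={"noise_cv": 0.15})
        for tag in ("a", "b"):
            study = generate_study(cfg)
            write_plasma_csv(study.plasma_curves, tmp_path / f"plasma_{tag}.csv")
            write_lesions_csv(study.lesion_tacs, tmp_path / f"lesions_{tag}.csv")
        assert (tmp_path / "plasma_a.csv").read_bytes() == (tmp_path / "plasma_b.csv").read_bytes()
        assert (tmp_path / "lesions_a.csv").read_bytes() == (tmp_path / "lesions_b.csv").read_bytes()

    def test_noise_free_downstream_recovers_truth_slopes(self, noise_free_config):
        from immunopet.kinetics import fit_lesion

        study = generate_study(noise_free_config)
        for tac in study.lesion_tacs:
            plasma = study.plasma_for(tac.patient_id, tac.administration)
            fit = fit_lesion(tac, plasma)
            truth = study.truth_lesions[(tac.patient_id, tac.lesion_id)]
            assert fit.slope_B == pytest.approx(
                truth[f"B_{tac.administration}_per_h"], rel=0.01
            )

    def test_lesion_variability_option(self):
        from immunopet import LesionParams

        cfg = StudyConfig(
            n_patients=2,
            lesion_params=LesionParams(lesion_cv_A=0.3, lesion_cv_B0=0.3),
            noise_cv=0.0,
            seed=3,
        )
        study = generate_study(cfg)
        b0s = [rec["B0_per_h"] for rec in study.truth_lesions.values()]
        assert len(set(np.round(b0s, 12))) > 1
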