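"""Patient-level NLME: structural model, FO likelihood against a
quadrature oracle, fitting, covariate selection and predictions."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import emaxdr as e
from emaxdr.patient import (CovariateLink, NlmeModelSpec,
                            PatientLevelEmaxModel, forward_select_covariates,
                            structural_prediction, validate_patient_data)

BASE = NlmeModelSpec(e0=1300.0, emax=185.0, ed50=19.0,
                     omega_e0=120.0, omega_emax=50.0, sigma=0.12)


def patient_frame(*rows):
    cols = ["patient_id", "study_id", "day", "dose_ug", "trough_fev1_ml",
            "baseline_fev1_ml"]
    return pd.DataFrame(list(rows), columns=cols)


class TestValidation:
    def test_patient_with_nonpositive_record_fully_excluded(self):
        df = patient_frame(
            ("p1", "S", 14, 150.0, 1400.0, 1300.0),
            ("p1", "S", 15, 150.0, -5.0, 1300.0),
            ("p2", "S", 14, 0.0, 1200.0, 1250.0),
        )
        with pytest.warns(UserWarning, match="excluded 1 patient"):
            valid, log = validate_patient_data(df)
        assert list(valid["patient_id"]) == ["p2"]
        assert set(log["rule"]) == {"nonpositive_fev1"}
        assert len(log) == 2  # both of p1's rows are logged

    @pytest.mark.parametrize("row, rule", [
        (("p9", "S", 14, -10.0, 1400.0, 1300.0), "bad_dose"),
        (("p9", "S", 7, 150.0, 1400.0, 1300.0), "bad_day"),
    ])
    def test_row_level_rules(self, row, rule):
        df = patient_frame(("p2", "S", 14, 0.0, 1200.0, 1250.0), row)
        valid, log = validate_patient_data(df)
        assert list(log["rule"]) == [rule]
        assert len(valid) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            validate_patient_data(patient_frame())


class TestStructuralPrediction:
    def test_placebo_prediction_is_e0(self):
        rec = {"dose_ug": 0.0}
        assert structural_prediction(BASE, (0.0, 0.0), rec) == 1300.0

    def test_printed_point_estimates_give_expected_effect(self):
        # 185 * 150 / (19 + 150) = 164.2 mL on top of E0
        rec = {"dose_ug": 150.0}
        got = structural_prediction(BASE, (0.0, 0.0), rec)
        assert got == pytest.approx(1300.0 + 185 * 150 / 169, rel=1e-12)

    def test_random_effect_cancelling_emax_leaves_e0_at_high_dose(self):
        rec = {"dose_ug": 1e9}
        got = structural_prediction(BASE, (7.0, -185.0), rec)
        assert got == pytest.approx(1307.0, rel=1e-6)

    def test_nonpositive_prediction_is_flagged(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            structural_prediction(BASE, (-2000.0, 0.0), {"dose_ug": 0.0})

    def test_covariate_links_shift_parameters(self):
        spec = BASE.with_link(CovariateLink("emax", "baseline_fev1_ml",
                                            "linear", ref=1300.0, beta=0.1))
        rec = {"dose_ug": 150.0, "baseline_fev1_ml": 1800.0}
        got = structural_prediction(spec, (0.0, 0.0), rec)
        assert got == pytest.approx(1300.0 + (185 + 50.0) * 150 / 169)

    def test_ed50_link_is_positivity_preserving(self):
        spec = BASE.with_link(CovariateLink("ed50", "baseline_fev1_ml",
                                            "linear", ref=1300.0, beta=-5e-3))
        rec = pd.DataFrame({"dose_ug": [19.0], "baseline_fev1_ml": [200.0]})
        from emaxdr.patient import _apply_links
        _, _, ed50 = _apply_links(spec, rec)
        assert ed50[0] == pytest.approx(19.0 * np.exp(-5e-3 * (200 - 1300)))
        assert ed50[0] > 0


def _quadrature_loglik(spec, df, n_nodes=51):
    """Exact marginal log-likelihood by 2-d Gauss-Hermite quadrature over
    the random effects, patient by patient (independent of the FO code)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / np.sqrt(2 * np.pi)
    L = np.linalg.cholesky(spec.omega_matrix() + 1e-300 * np.eye(2))
    E0, EM = np.meshgrid(nodes, nodes, indexing="ij")
    eta = L @ np.stack([E0.ravel(), EM.ravel()])
    ll = 0.0
    for _, grp in df.groupby("patient_id"):
        like = np.ones(eta.shape[1])
        for _, rec in grp.iterrows():
            f = structural_prediction(
                spec, (eta[0], eta[1]),
                pd.DataFrame([rec.to_dict()] * eta.shape[1]))
            like *= stats.norm.pdf(np.log(rec["trough_fev1_ml"]),
                                   np.log(f), spec.sigma)
        ll += np.log(np.einsum("ij,i,j->", like.reshape(E0.shape), w, w))
    return ll


@pytest.fixture(scope="module")
def tiny_data():
    truth = replace(e.PatientLevelTruth(),
                    spec=replace(BASE, omega_e0=80.0, omega_emax=40.0),
                    n_patients=3)
    return e.generate_patient_level(truth, seed=9)


class TestFoLikelihood:
    def test_zero_omega_reduces_to_independent_normal_loglik(self, tiny_data):
        spec = replace(BASE, omega_e0=0.0, omega_emax=0.0)
        m = PatientLevelEmaxModel(tiny_data, spec)
        got = m.fo_loglike(spec)
        pred = structural_prediction(spec, (0.0, 0.0), m._df)
        expected = stats.norm.logpdf(np.log(m._df["trough_fev1_ml"]),
                                     np.log(pred), spec.sigma).sum()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fo_approaches_quadrature_oracle_as_omega_shrinks(self, tiny_data):
        """The FO linearisation error vanishes with the random-effect
        magnitude: halving Omega repeatedly drives |FO - exact| to zero,
        and the error at full Omega is already within the bound the
        halving sequence establishes."""
        m = PatientLevelEmaxModel(tiny_data, BASE)
        errs = []
        for k in range(4):
            spec_k = replace(BASE, omega_e0=80.0 / 2**k,
                             omega_emax=40.0 / 2**k)
            fo = m.fo_loglike(spec_k)
            exact = _quadrature_loglik(spec_k, m._df)
            errs.append(abs(fo - exact))
        assert errs[0] < 0.2  # linearisation error, 3 patients x 2 days
        assert all(errs[k + 1] < errs[k] for k in range(3))
        assert errs[-1] < 1e-3

    def test_duplicating_single_day_records_doubles_loglik(self):
        truth = replace(e.PatientLevelTruth(), spec=BASE, n_patients=5,
                        days=(14,))
        df = e.generate_patient_level(truth, seed=4)
        dup = pd.concat([df, df.assign(patient_id=df["patient_id"] + "b")],
                        ignore_index=True)
        m1 = PatientLevelEmaxModel(df, BASE)
        m2 = PatientLevelEmaxModel(dup, BASE)
        assert m2.fo_loglike(BASE) == pytest.approx(2 * m1.fo_loglike(BASE),
                                                    rel=1e-12)

    def test_likelihood_invariant_to_row_order_and_id_labels(self):
        truth = replace(e.PatientLevelTruth(), spec=BASE, n_patients=12)
        df = e.generate_patient_level(truth, seed=6)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = df.assign(
            patient_id=df["patient_id"].map(lambda s: "zz" + s[::-1]))
        base = PatientLevelEmaxModel(df, BASE).fo_loglike(BASE)
        assert PatientLevelEmaxModel(shuffled, BASE).fo_loglike(BASE) \
            == pytest.approx(base, rel=1e-12)
        assert PatientLevelEmaxModel(relabeled, BASE).fo_loglike(BASE) \
            == pytest.approx(base, rel=1e-12)

    def test_hand_computed_loglik_on_deterministic_records(self):
        """On records equal to the structural prediction the residuals are
        zero and the FO likelihood reduces to its normalising constants."""
        spec = replace(BASE, omega_e0=50.0, omega_emax=25.0)
        rows = []
        for i, dose in enumerate((0.0, 75.0, 300.0)):
            f = 1300.0 + 185.0 * dose / (19.0 + dose)
            rows.append((f"p{i}", "S", 14, dose, f, 1300.0))
        df = patient_frame(*rows)
        m = PatientLevelEmaxModel(df, spec)
        got = m.fo_loglike(spec)
        expected = 0.0
        for dose in (0.0, 75.0, 300.0):
            fr = dose / (19.0 + dose)
            f = 1300.0 + 185.0 * fr
            v = (50.0**2 + 25.0**2 * fr**2) / f**2 + 0.12**2
            expected += -0.5 * np.log(2 * np.pi * v)
        assert got == pytest.approx(expected, rel=1e-12)


class TestFitting:
    def test_fit_without_random_effects_matches_log_scale_nls(self):
        """With Omega = 0 in the truth, the FO fit's fixed effects agree
        with an independent nonlinear least-squares fit on the log scale."""
        truth = replace(e.PatientLevelTruth(),
                        spec=replace(BASE, omega_e0=1e-3, omega_emax=1e-3),
                        n_patients=400)
        df = e.generate_patient_level(truth, seed=14)
        res = PatientLevelEmaxModel(df, BASE).fit(n_starts=1,
                                                  compute_se=False)

        z = np.log(df["trough_fev1_ml"].to_numpy())
        d = df["dose_ug"].to_numpy()

        def resid(th):
            return z - np.log(th[0] + th[1] * d / (np.exp(th[2]) + d))

        nls = optimize.least_squares(resid, [1200.0, 150.0, np.log(30.0)],
                                     method="lm")
        assert res.params["e0"] == pytest.approx(nls.x[0], rel=0.005)
        assert res.params["emax"] == pytest.approx(nls.x[1], rel=0.02)
        assert res.params["ed50"] == pytest.approx(np.exp(nls.x[2]), rel=0.05)

    def test_fit_is_deterministic(self, small_patient_data):
        r1 = PatientLevelEmaxModel(small_patient_data, BASE).fit(
            compute_se=False)
        r2 = PatientLevelEmaxModel(small_patient_data, BASE).fit(
            compute_se=False)
        np.testing.assert_array_equal(r1.theta, r2.theta)
        assert r1.minus2ll == r2.minus2ll

    def test_summary_reports_ordered_cis_and_finite_deviance(
            self, small_patient_data):
        res = PatientLevelEmaxModel(small_patient_data, BASE).fit(n_starts=1)
        tab = res.summary()
        assert np.isfinite(res.minus2ll)
        ok = tab.dropna()
        assert (ok["ci_lo"] <= ok["estimate"]).all()
        assert (ok["estimate"] <= ok["ci_hi"]).all()
        assert tab.loc["ed50", "estimate"] > 0

    def test_nonidentifiable_start_raises(self, small_patient_data):
        bad = replace(BASE, e0=-5000.0)  # nonpositive predictions
        with pytest.raises(ValueError, match="not finite"):
            PatientLevelEmaxModel(small_patient_data, bad).fit()


class TestForwardSelection:
    def test_empty_candidate_list_returns_base_fit(self, small_patient_data):
        res, trace = forward_select_covariates(
            small_patient_data, BASE, [], n_starts=1)
        assert len(trace) == 0
        direct = PatientLevelEmaxModel(small_patient_data, BASE).fit(
            n_starts=1, compute_se=False)
        assert res.minus2ll == pytest.approx(direct.minus2ll, abs=1e-6)
        assert not any(l.label != "e0~baseline_fev1_ml" for l in res.spec.links)

    def test_strong_covariate_enters_first_and_trace_is_reproducible(self):
        spec = replace(BASE, links=(
            CovariateLink("emax", "baseline_fev1_ml", "linear",
                          ref=1300.0, beta=0.25),))
        truth = replace(e.PatientLevelTruth(), spec=spec, n_patients=400)
        df = e.generate_patient_level(truth, seed=33)
        candidates = [
            CovariateLink("emax", "baseline_fev1_ml", "linear"),
            CovariateLink("emax", "sex", "linear"),
        ]
        res, trace = forward_select_covariates(df, BASE, candidates,
                                               alpha=0.01, n_starts=1)
        first = trace[trace["selected"]].iloc[0]
        assert first["candidate"] == "emax~baseline_fev1_ml"
        _, trace2 = forward_select_covariates(df, BASE, candidates,
                                              alpha=0.01, n_starts=1)
        pd.testing.assert_frame_equal(trace, trace2)

    def test_failed_candidate_is_skipped_with_log_entry(
            self, small_patient_data):
        candidates = [CovariateLink("emax", "no_such_column", "linear")]
        res, trace = forward_select_covariates(
            small_patient_data, BASE, candidates, n_starts=1)
        assert trace["status"].str.startswith("failed").all()
        assert not trace["selected"].any()


@pytest.fixture(scope="module")
def linked_fit():
    spec = e.PatientLevelTruth().spec  # has baseline and reversibility links
    truth = replace(e.PatientLevelTruth(), n_patients=500)
    df = e.generate_patient_level(truth, seed=17)
    return PatientLevelEmaxModel(df, spec).fit(n_starts=1, compute_se=False)


class TestPredictions:
    def test_zero_dose_improvement_is_zero_for_any_baseline(self, linked_fit):
        for b in (900.0, 1300.0, 2000.0):
            tab = linked_fit.predict_improvement(b, (0.0, 150.0))
            assert tab["improvement_ml"].iloc[0] == pytest.approx(0.0)

    def test_no_links_makes_curve_independent_of_baseline(
            self, small_patient_data):
        res = PatientLevelEmaxModel(small_patient_data, BASE).fit(
            n_starts=1, compute_se=False)
        a = res.predict_improvement(900.0, (75.0, 300.0))["improvement_ml"]
        b = res.predict_improvement(2000.0, (75.0, 300.0))["improvement_ml"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_positive_baseline_link_raises_improvement_with_baseline(
            self, linked_fit):
        doses = (37.5, 150.0, 600.0)
        lo = linked_fit.predict_improvement(900.0, doses)["improvement_ml"]
        hi = linked_fit.predict_improvement(1900.0, doses)["improvement_ml"]
        assert (hi.to_numpy() > lo.to_numpy()).all()

    def test_relative_improvement_is_percent_of_baseline(self, linked_fit):
        tab = linked_fit.relative_improvement(1300.0, (150.0,))
        assert tab["improvement_pct_baseline"].iloc[0] == pytest.approx(
            100 * tab["improvement_ml"].iloc[0] / 1300.0)

    def test_severity_groups_order_and_degenerate_cases(self, linked_fit):
        doses = (75.0, 300.0)
        mod = linked_fit.predict_by_severity("moderate", doses)
        sev = linked_fit.predict_by_severity("severe", doses)
        # moderate COPD (higher baseline) responds more at every dose
        assert (mod["improvement_ml"].to_numpy()
                > sev["improvement_ml"].to_numpy()).all()
        with pytest.raises(ValueError, match="no patients"):
            linked_fit.predict_by_severity("unknown-group", doses)

    def test_single_member_group_equals_that_patients_prediction(self):
        spec = e.PatientLevelTruth().spec
        truth = replace(e.PatientLevelTruth(), n_patients=40)
        df = e.generate_patient_level(truth, seed=18)
        one = df["patient_id"] == df["patient_id"].iloc[0]
        df.loc[one, "severity"] = "verysevere"
        res = PatientLevelEmaxModel(df, spec).fit(n_starts=1,
                                                  compute_se=False)
        grp = res.predict_by_severity("verysevere", (150.0,))
        b = df.loc[one, "baseline_fev1_ml"].iloc[0]
        rows = res._typical_row(np.r_[0.0, 150.0], baseline_fev1_ml=b,
                                reversibility_pct=df.loc[one, "reversibility_pct"].iloc[0])
        pred = structural_prediction(res.spec, (0.0, 0.0), rows)
        assert grp["improvement_ml"].iloc[0] == pytest.approx(
            pred[1] - pred[0], rel=1e-9)

    def test_extrapolated_baseline_warns(self, linked_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            linked_fit.predict_improvement(50000.0, (150.0,))
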