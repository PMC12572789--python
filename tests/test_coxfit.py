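"""Penalized spline Cox machinery: basis, likelihood, tuning, tests."""

import numpy as np
import pandas as pd
import pytest

from mupsurv import coxfit as cf
from mupsurv.coxfit import (
    SplineTermSpec,
    bh_adjust,
    build_basis,
    decompose,
    fit_cox_pspline,
    holm_adjust,
    ph_diagnose_and_stratify,
)
from mupsurv.simulate import EtaTruth, gen_exposure_cohort


class TestSplineBasis:
    def test_eight_basis_functions_give_twelve_knots(self):
        b = build_basis(np.linspace(0, 50, 100), n_basis=8)
        assert len(b.knots) == 12
        assert b.n_basis == 8
        assert b.order == 4

    def test_partition_of_unity(self):
        b = build_basis(np.linspace(0, 50, 100), 8)
        x = np.linspace(0, 50, 173)
        assert np.allclose(b.evaluate(x).sum(axis=1), 1.0, atol=1e-10)

    def test_reproduces_cubic_polynomial(self):
        b = build_basis(np.linspace(0, 50, 100), 8)
        x = np.linspace(0, 50, 300)
        target = 0.5 + 0.1 * x - 0.01 * x ** 2 + 2e-4 * x ** 3
        coef, *_ = np.linalg.lstsq(b.evaluate(x), target, rcond=None)
        assert np.allclose(b.evaluate(x) @ coef, target, atol=1e-9)

    def test_reproduces_linear_via_greville_centers(self):
        b = build_basis(np.linspace(0, 50, 100), 8)
        x = np.linspace(0, 50, 97)
        assert np.allclose(b.evaluate(x) @ b.centers, x, atol=1e-10)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_basis(np.full(10, 3.0))


class TestPartialLikelihood:
    def test_two_subject_one_event_closed_form(self):
        """l(beta) = beta*x1 - log(e^{beta*x1} + e^{beta*x2})."""
        X = np.array([[1.0], [0.0]])
        t = np.array([1.0, 2.0])
        e = np.array([1.0, 0.0])
        for beta in (np.array([0.0]), np.array([0.7]), np.array([-1.2])):
            ll, grad, hess = cf._stratum_quantities(beta, t, e.astype(bool), X, "breslow")
            b = beta[0]
            expected_ll = b - np.log(np.exp(b) + 1.0)
            p = np.exp(b) / (np.exp(b) + 1.0)
            assert ll == pytest.approx(expected_ll)
            assert grad[0] == pytest.approx(1.0 - p)
            assert hess[0, 0] == pytest.approx(p * (1 - p))

    def test_breslow_equals_efron_without_ties(self):
        df = gen_exposure_cohort(300, EtaTruth("linear", beta=0.03), seed=5)
        fb = fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")], ties="breslow")
        fe = fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")], ties="efron")
        assert np.allclose(fb.beta, fe.beta, atol=1e-8)

    def test_efron_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        n = 400
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(10, n) * np.exp(-0.4 * x)).clip(max=15)  # heavy ties
        e = (t < 15).astype(int)
        df = pd.DataFrame({"x": x, "time_years": t, "event": e})
        cph = lifelines.CoxPHFitter().fit(df.rename(columns={"time_years": "T"}),
                                          "T", "event")
        f = fit_cox_pspline(df, spline_terms=[SplineTermSpec("x", lambda_fixed=1e10)],
                            ties="efron")
        slope = decompose(f).slope["x"]
        assert slope == pytest.approx(cph.params_["x"], rel=1e-3)

    def test_penalized_loglik_nondecreasing(self):
        df = gen_exposure_cohort(500, EtaTruth("linear", beta=0.03), seed=9)
        f = fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")])
        # refit at the tuned lambda from cold start and inspect the trace
        X, names, ts, cs, bases, xo, pb = cf._design(
            df, [SplineTermSpec("exposure")], []
        )
        P = cf._penalty_matrix(X.shape[1], pb, [f.lambdas["exposure"]])
        sd = cf._prepare(df["time_years"].to_numpy(), df["event"].to_numpy(),
                         X, np.zeros(len(df), dtype=int))
        *_, trace = cf._newton(sd, P, X.shape[1], "breslow")
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestFit:
    def test_requires_two_events(self):
        df = gen_exposure_cohort(50, EtaTruth(), seed=1)
        df["event"] = 0
        with pytest.raises(ValueError, match="2 events"):
            fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")])

    def test_effective_df_hits_target(self):
        df = gen_exposure_cohort(1500, EtaTruth("linear", beta=0.02), seed=3)
        for target in (2.0, 4.0):
            f = fit_cox_pspline(
                df, spline_terms=[SplineTermSpec("exposure", target_df=target)]
            )
            assert f.edf["exposure"] == pytest.approx(target, abs=0.05)
            assert f.lambdas["exposure"] >= 0
            assert f.edf["exposure"] <= 8

    def test_covariance_symmetric_psd(self):
        df = gen_exposure_cohort(800, EtaTruth("linear", beta=0.02), seed=4)
        f = fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")])
        assert np.allclose(f.cov, f.cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(f.cov).min() > -1e-12

    def test_large_penalty_matches_linear_cox_oracle(self):
        """Effective df -> 1 collapses the curve to the straight-line fit."""
        lifelines = pytest.importorskip("lifelines")
        df = gen_exposure_cohort(1000, EtaTruth("linear", beta=0.02), seed=7)
        cph = lifelines.CoxPHFitter().fit(
            df[["exposure", "time_years", "event"]], "time_years", "event"
        )
        f = fit_cox_pspline(
            df, spline_terms=[SplineTermSpec("exposure", lambda_fixed=1e10)]
        )
        t = decompose(f)
        assert t.slope["exposure"] == pytest.approx(cph.params_["exposure"], rel=1e-3)
        assert t.slope_se["exposure"] == pytest.approx(
            cph.standard_errors_["exposure"], rel=1e-2
        )

    def test_degenerate_covariate_level_named(self):
        df = gen_exposure_cohort(200, EtaTruth(), seed=8)
        df["grp"] = pd.Categorical(["a"] * len(df), categories=["a", "b"])
        with pytest.raises(ValueError, match="grp"):
            fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")],
                            covariates=["grp"])


class TestDecompose:
    def test_linear_truth_recovers_slope_sign_and_uniform_nonlinear(self):
        hits = 0
        pnl = []
        rng = np.random.default_rng(0)
        for r in range(20):
            x = rng.normal(0, 1, 2000)
            df = gen_exposure_cohort(2000, EtaTruth("linear", beta=0.3),
                                     seed=300 + r, exposure=x)
            t = decompose(fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")]))
            hits += t.p_linear["exposure"] < 0.05
            pnl.append(t.p_nonlinear["exposure"])
        assert hits >= 16  # >= 80% power at this effect size
        assert (np.array(pnl) < 0.05).mean() <= 0.25

    def test_u_shaped_truth_flags_nonlinearity(self):
        hits = 0
        for r in range(5):
            df = gen_exposure_cohort(
                10000, EtaTruth("jshape", nadir=18.0), seed=500 + r
            )
            t = decompose(fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")]))
            hits += t.p_nonlinear["exposure"] < 0.05
        assert hits >= 4

    def test_null_fit_both_tests_nonsignificant(self):
        df = gen_exposure_cohort(3000, EtaTruth("null"), seed=42)
        t = decompose(fit_cox_pspline(df, spline_terms=[SplineTermSpec("exposure")]))
        assert t.p_linear["exposure"] > 0.01
        assert t.p_nonlinear["exposure"] > 0.01


class TestPhDiagnostics:
    @staticmethod
    def _planted(n, seed, hr_late=2.0, t_change=5.0):
        rng = np.random.default_rng(seed)
        z = rng.random(n) < 0.5
        lam0 = 0.02
        t1 = rng.exponential(1 / lam0, n)
        late = t_change + rng.exponential(1 / (lam0 * np.where(z, hr_late, 1.0)), n)
        t = np.where(t1 <= t_change, t1, late)
        return pd.DataFrame(
            {
                "time_years": np.minimum(t, 13.0),
                "event": (t <= 13.0).astype(int),
                "z": np.where(z, "yes", "no"),
                "exposure": rng.gamma(5, 4, n),
            }
        )

    def test_planted_violation_detected_and_stratified(self):
        detected = 0
        for r in range(5):
            d = self._planted(5000, 9500 + r)
            f = fit_cox_pspline(d, spline_terms=[SplineTermSpec("exposure")],
                                covariates=["z"])
            strata, refit, tests = ph_diagnose_and_stratify(f, d)
            if "z" in strata:
                detected += 1
                assert "z" in refit.strata_cols
                assert "z" not in refit.covariate_cols
        assert detected >= 4

    def test_ph_true_rarely_triggers(self):
        triggers = 0
        for r in range(10):
            rng = np.random.default_rng(800 + r)
            d = gen_exposure_cohort(1500, EtaTruth("null"), seed=900 + r)
            d["z"] = rng.choice(["a", "b"], len(d))
            f = fit_cox_pspline(d, spline_terms=[SplineTermSpec("exposure")],
                                covariates=["z"])
            strata, _, _ = ph_diagnose_and_stratify(f, d)
            triggers += bool(strata)
        assert triggers <= 2

    def test_single_covariate_holm_equals_raw(self):
        d = self._planted(1000, 77)
        f = fit_cox_pspline(d, spline_terms=[SplineTermSpec("exposure")],
                            covariates=["z"])
        _, _, tests = ph_diagnose_and_stratify(f, d)
        assert tests["p_holm"].iloc[0] == pytest.approx(tests["p"].iloc[0])


class TestMultipleTesting:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_holm_hand_calculation(self):
        adj = holm_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_bh_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_holm_monotone_and_clipped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bh_significant_set_shrinks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30) * 0.2
        assert set(np.where(bh_adjust(p) < 0.05)[0]) <= set(np.where(p < 0.05)[0])
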