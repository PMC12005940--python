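"""Conditional likelihood against enumeration, finite differences and
independent maximisers."""

import numpy as np
import pandas as pd
import pytest

import aerxover as ax
from aerxover.clogit import (ModelSpec, SeparationError, bspline_basis,
                             build_design_matrix, conditional_loglik,
                             fit_matrix, lr_test, nonlinearity_check)


def toy_problem(n_strata=20, n_days=6, p=2, seed=0, beta_true=None):
    """Random small matched-set problem; case drawn from the model."""
    rng = np.random.default_rng(seed)
    beta_true = np.zeros(p) if beta_true is None else np.asarray(beta_true)
    X, y, starts = [], [], []
    pos = 0
    for _ in range(n_strata):
        Xi = rng.normal(0, 1, (n_days, p))
        w = np.exp(Xi @ beta_true)
        case = rng.choice(n_days, p=w / w.sum())
        yi = np.zeros(n_days, int)
        yi[case] = 1
        X.append(Xi)
        y.append(yi)
        starts.append(pos)
        pos += n_days
    return np.concatenate(y), np.vstack(X), np.array(starts)


def toy_rows(n_strata, effect, seed=0, n_days=9):
    """Long-format strata with a scalar covariate and case prob softmax(effect(x))."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_strata):
        x = rng.uniform(0.0, 2.0, n_days)
        w = np.exp(effect(x) - effect(x).max())
        case = rng.choice(n_days, p=w / w.sum())
        frames.append(pd.DataFrame({
            "person_id": i, "pm10u": x,
            "case": (np.arange(n_days) == case).astype(int)}))
    return pd.concat(frames, ignore_index=True)


class TestConditionalLoglik:
    def test_value_at_zero_is_minus_sum_log_stratum_sizes(self):
        y, X, starts = toy_problem(n_strata=15, n_days=7, seed=1)
        ll, _, _ = conditional_loglik(np.zeros(X.shape[1]), y, X, starts)
        assert ll == pytest.approx(-15 * np.log(7), rel=1e-12)

    def test_two_day_stratum_closed_form(self):
        y = np.array([1, 0])
        X = np.array([[1.0], [0.0]])
        starts = np.array([0])
        for b in (-1.3, 0.0, 0.7, 2.5):
            ll, g, h = conditional_loglik(np.array([b]), y, X, starts)
            assert ll == pytest.approx(b - np.log1p(np.exp(b)), rel=1e-12)

    def test_gradient_and_hessian_match_finite_differences(self):
        y, X, starts = toy_problem(n_strata=12, n_days=5, p=3, seed=2,
                                   beta_true=[0.5, -0.3, 0.1])
        beta = np.array([0.2, -0.1, 0.4])
        ll, grad, hess = conditional_loglik(beta, y, X, starts)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            lp, gp, _ = conditional_loglik(beta + e, y, X, starts)
            lm, gm, _ = conditional_loglik(beta - e, y, X, starts)
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[j], rel=1e-6)
            np.testing.assert_allclose((gp - gm) / (2 * eps), hess[:, j],
                                       rtol=1e-5, atol=1e-8)

    def test_denominator_matches_direct_enumeration(self):
        """Per-stratum sum_j exp(x_j.b) by plain Python on <= 8-day strata."""
        y, X, starts = toy_problem(n_strata=10, n_days=8, p=2, seed=3)
        beta = np.array([0.8, -0.4])
        ll, _, _ = conditional_loglik(beta, y, X, starts)
        direct = 0.0
        for s in range(10):
            block = X[8 * s:8 * (s + 1)]
            yi = y[8 * s:8 * (s + 1)]
            direct += float(block[yi == 1][0] @ beta) - np.log(
                sum(np.exp(float(r @ beta)) for r in block))
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_nonfinite_covariates_rejected(self):
        rows = pd.DataFrame({"person_id": [0, 0], "case": [1, 0],
                             "pm10u": [np.nan, 1.0], "dow": [0, 3]})
        with pytest.raises(ValueError):
            build_design_matrix(rows, ModelSpec(covariates=("pm10u",),
                                                dow=False))


class TestFit:
    def test_matches_brute_force_maximiser_on_toy_problem(self):
        """Nested grid search over two coefficients as independent oracle."""
        y, X, starts = toy_problem(n_strata=20, n_days=6, p=2, seed=4,
                                   beta_true=[0.8, -0.5])
        res = fit_matrix(y, X, starts)

        def nll(b):
            return -conditional_loglik(np.asarray(b), y, X, starts)[0]

        center = np.zeros(2)
        half = 3.0
        for _ in range(12):   # 12 refinements of a 21x21 grid -> ~1e-5 cells
            g0 = np.linspace(center[0] - half, center[0] + half, 21)
            g1 = np.linspace(center[1] - half, center[1] + half, 21)
            vals = np.array([[nll((a, b)) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            center = np.array([g0[i], g1[j]])
            half *= 0.2
        np.testing.assert_allclose(res.beta, center, atol=1e-5)
        assert res.converged

    def test_day_order_permutation_leaves_fit_unchanged(self):
        y, X, starts = toy_problem(n_strata=10, n_days=5, p=2, seed=5,
                                   beta_true=[0.4, 0.2])
        res = fit_matrix(y, X, starts)
        rng = np.random.default_rng(0)
        Xp, yp = X.copy(), y.copy()
        for s in starts:
            perm = rng.permutation(5)
            Xp[s:s + 5] = X[s:s + 5][perm]
            yp[s:s + 5] = y[s:s + 5][perm]
        res_p = fit_matrix(yp, Xp, starts)
        np.testing.assert_allclose(res.beta, res_p.beta, atol=1e-9)
        assert res.loglik == pytest.approx(res_p.loglik, rel=1e-12)

    def test_stratum_constant_column_changes_nothing(self):
        """Fixed-effect elimination: appending a stratum-constant covariate
        leaves the likelihood surface over the original terms unchanged."""
        y, X, starts = toy_problem(n_strata=15, n_days=6, p=2, seed=6,
                                   beta_true=[0.6, -0.2])
        res = fit_matrix(y, X, starts)
        const = np.repeat(np.arange(15, dtype=float), 6)[:, None]
        ll_aug, _, _ = conditional_loglik(
            np.append(res.beta, 0.7), y, np.hstack([X, const]), starts)
        assert ll_aug == pytest.approx(res.loglik, rel=1e-12)

    def test_separation_is_detected(self):
        y = np.array([1, 0, 1, 0])
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        starts = np.array([0, 2])
        with pytest.raises(SeparationError):
            fit_matrix(y, X, starts)

    def test_no_informative_strata_rejected(self):
        y = np.array([1, 0])
        X = np.array([[2.0], [2.0]])
        with pytest.raises(ValueError):
            fit_matrix(y, X, np.array([0]))

    def test_null_simulation_has_no_spurious_signal(self):
        """5,000 strata at beta=0: all Wald |z| below 4 (fixed seed)."""
        y, X, starts = toy_problem(n_strata=5000, n_days=8, p=3, seed=7)
        res = fit_matrix(y, X, starts)
        z = res.beta / np.sqrt(np.diag(res.vcov))
        assert np.all(np.abs(z) < 4)

    def test_agrees_with_statsmodels_conditional_logit(self, design_rows):
        """Independent implementation on the same design matrix."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit
        spec = ModelSpec(interaction=("pm10u", "aer"))
        y, X, starts, names = build_design_matrix(design_rows, spec)
        groups = np.repeat(np.arange(len(starts)),
                           np.diff(np.append(starts, len(y))))
        ours = fit_matrix(y, X, starts, names)
        theirs = ConditionalLogit(y, X, groups=groups).fit(
            method="newton", tol=1e-10, disp=0)
        np.testing.assert_allclose(ours.beta, theirs.params, atol=2e-5)
        np.testing.assert_allclose(ours.loglik, theirs.llf, rtol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.vcov)),
                                   theirs.bse, rtol=1e-3)

    def test_vcov_symmetric_positive_definite(self, interaction_fit):
        v = interaction_fit.vcov
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(v) > 0)


class TestLRTest:
    def test_identical_models_give_zero_statistic_p_one(self, interaction_fit):
        out = lr_test(interaction_fit, interaction_fit)
        assert out.statistic == 0.0 and out.df == 0 and out.pvalue == 1.0

    def test_statistic_nonnegative_and_df_counts_parameters(self, design_rows):
        full = ax.fit_interaction(design_rows)
        reduced = ax.fit_main(design_rows)
        out = lr_test(full, reduced)
        assert out.statistic >= 0.0
        assert out.df == 1

    def test_non_nested_specs_rejected(self, design_rows):
        a = ax.fit(ModelSpec(covariates=("pm10u", "temp10u"), dow=False),
                   design_rows)
        b = ax.fit(ModelSpec(covariates=("pm10u", "rh10u"), dow=False),
                   design_rows)
        with pytest.raises(ValueError):
            lr_test(a, b)


class TestNonlinearityCheck:
    spec = ModelSpec(covariates=("pm10u",), dow=False)

    def test_strong_quadratic_effect_is_detected(self):
        rows = toy_rows(3000, lambda x: 0.1 * x + 0.8 * x * x, seed=8)
        out = nonlinearity_check(self.spec, rows, target="pm10u")
        assert out.pvalue < 0.05

    def test_linear_truth_rejection_rate_near_alpha(self):
        """Type-I calibration over 200 small replicates (fixed seeds)."""
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            rows = toy_rows(250, lambda x: 0.5 * x, seed=1000 + r)
            out = nonlinearity_check(self.spec, rows, target="pm10u")
            hits += out.pvalue < 0.05
        rate = hits / n_rep
        # 4-sigma binomial band around alpha = 0.05
        assert rate < 0.05 + 4 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_interaction_smooth_detects_linear_modification_as_linear(
            self, design_rows):
        spec = ModelSpec(interaction=("pm10u", "aer"))
        out = nonlinearity_check(spec, design_rows, target="aer_x_pm")
        assert 0.0 <= out.pvalue <= 1.0
        assert out.df == 6   # 4 interior knots, cubic, drop-first, minus linear

    def test_too_few_unique_values_for_knots(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            bspline_basis(x, n_knots=4)

    def test_basis_partition_of_unity(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 3, 200)
        B = bspline_basis(x, n_knots=4, drop_first=False)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert B.shape[1] == 8  # 4 interior knots + degree 3 + 1
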