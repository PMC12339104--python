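"""Transformations, mixed-model ladder, corrections, effect sizes, BCa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from segnav.inference import (
    ModelFit,
    ModelSpec,
    bca_ci,
    bodner_effect,
    box_cox,
    box_cox_inverse,
    cohens_f2,
    fit_ladder,
    holm_bonferroni,
    vif_screen,
    yeo_johnson,
    zscore,
)


class TestBoxCox:
    def test_fixed_lambda_forms(self):
        y = np.array([1.0, 2.0, np.e])
        out1, _ = box_cox(y, lam=1.0)
        np.testing.assert_allclose(out1, y - 1.0)
        out0, _ = box_cox(y, lam=0.0)
        assert out0[2] == pytest.approx(1.0)

    def test_profile_ml_recovers_log_scale(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(size=2000))
        _, lam = box_cox(y)
        assert abs(lam) < 0.15

    def test_agrees_with_scipy_mle(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(3.0, 2.0, size=500)
        _, lam = box_cox(y)
        _, lam_scipy = stats.boxcox(y)
        assert lam == pytest.approx(lam_scipy, abs=0.02)  # grid resolution

    def test_nonpositive_rejected_and_inverse_round_trips(self):
        with pytest.raises(ValueError):
            box_cox(np.array([1.0, 0.0]))
        y = np.array([0.5, 2.0, 7.0])
        for lam in (0.0, 0.5, -1.0):
            t, _ = box_cox(y, lam=lam)
            np.testing.assert_allclose(box_cox_inverse(t, lam), y, rtol=1e-12)


class TestYeoJohnson:
    def test_identity_and_fixed_point(self):
        y = np.array([-2.0, 0.0, 3.0])
        out, _ = yeo_johnson(y, lam=1.0)
        np.testing.assert_allclose(out, y, atol=1e-12)
        for lam in (-1.0, 0.0, 0.7, 2.0):
            assert yeo_johnson(np.array([0.0]), lam=lam)[0][0] == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-5, 5), st.floats(-1.5, 1.5))
    def test_negation_symmetry(self, y, lam):
        a, _ = yeo_johnson(np.array([-y]), lam=lam)
        b, _ = yeo_johnson(np.array([y]), lam=2.0 - lam)
        assert a[0] == pytest.approx(-b[0], rel=1e-9, abs=1e-9)

    def test_agrees_with_scipy_mle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1.0, 2.0, size=500) ** 3
        _, lam = yeo_johnson(y)
        _, lam_scipy = stats.yeojohnson(y)
        assert lam == pytest.approx(lam_scipy, abs=0.02)


class TestZscore:
    def test_standardizes(self):
        out = zscore([1.0, 2.0, 3.0])
        assert out.mean() == pytest.approx(0.0) and out.std() == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0])


class TestHolmBonferroni:
    def test_step_down_example(self):
        adjusted, reject = holm_bonferroni([0.001, 0.02, 0.04], alpha=0.05)
        np.testing.assert_allclose(adjusted, [0.003, 0.04, 0.04])
        assert reject.all()

    def test_edge_cases(self):
        adjusted, reject = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()
        adjusted, _ = holm_bonferroni([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.floats(0.01, 0.2),
    )
    def test_matches_statsmodels_and_ordering(self, pvals, alpha):
        from statsmodels.stats.multitest import multipletests

        adjusted, reject = holm_bonferroni(pvals, alpha=alpha)
        sm_reject, sm_adj, *_ = multipletests(pvals, alpha=alpha, method="holm")
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, sm_reject)
        # Holm sits between Bonferroni and no correction
        p = np.asarray(pvals)
        bonf = np.minimum(1.0, p * len(p)) <= alpha
        assert np.all(reject >= bonf)
        assert np.all(reject <= (p <= alpha))


class TestCohensF2:
    @pytest.mark.parametrize(
        "full,red,expected", [(0.2, 0.1, 0.125), (0.3, 0.3, 0.0), (0.5, 0.0, 1.0)]
    )
    def test_arithmetic(self, full, red, expected):
        assert cohens_f2(full, red) == pytest.approx(expected)

    @pytest.mark.parametrize("full,red", [(1.0, 0.5), (0.2, 0.3), (0.2, -0.1)])
    def test_domain_errors(self, full, red):
        with pytest.raises(ValueError):
            cohens_f2(full, red)


class TestVifScreen:
    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(3)
        # orthogonalize against the intercept too, so each R2_j is exactly 0
        q, _ = np.linalg.qr(np.column_stack([np.ones(50), rng.normal(size=(50, 3))]))
        out = vif_screen(pd.DataFrame(q[:, 1:], columns=list("abc")))
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-8)
        assert not out["flagged"].any()

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        out = vif_screen(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert np.isinf(out.loc[0, "vif"]) and out.loc[0, "flagged"]

    def test_near_collinear_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        noisy = x + rng.normal(scale=0.05, size=200)
        out = vif_screen(pd.DataFrame({"a": x, "b": noisy}))
        assert (out["vif"] > 5).all() and out["flagged"].all()


def _toy_trial_table(rng, n_subjects=40, n_trials=6, interaction=0.0):
    sub = np.repeat(np.arange(n_subjects), n_trials)
    x1 = np.repeat(rng.normal(size=n_subjects), n_trials)
    x2 = rng.normal(size=n_subjects * n_trials)
    u = np.repeat(rng.normal(scale=0.5, size=n_subjects), n_trials)
    y = 1.0 + 0.3 * x1 + 0.2 * x2 + interaction * x1 * x2 + u + rng.normal(
        size=n_subjects * n_trials
    )
    return pd.DataFrame({"subject_id": sub, "x1": x1, "x2": x2, "y": y})


class TestFitLadder:
    def _specs(self, terms_list):
        return [
            ModelSpec(dependent="y", fixed_terms=tuple(t), ladder_position=i)
            for i, t in enumerate(terms_list)
        ]

    def test_identical_specs_give_null_lrt(self):
        rng = np.random.default_rng(6)
        df = _toy_trial_table(rng)
        fits, lrts = fit_ladder(self._specs([["x1"], ["x1"]]), df)
        assert lrts[0].statistic == pytest.approx(0.0, abs=1e-6)
        assert lrts[0].p_value == 1.0

    def test_log_likelihood_monotone_in_terms(self):
        rng = np.random.default_rng(7)
        df = _toy_trial_table(rng)
        fits, _ = fit_ladder(
            self._specs([[], ["x1"], ["x1", "x2"], ["x1*x2"]]), df
        )
        lls = [f.log_likelihood for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_lrt_invariant_to_zscaling(self):
        rng = np.random.default_rng(8)
        df = _toy_trial_table(rng, interaction=0.3)
        specs = self._specs([["x1", "x2"], ["x1*x2"]])
        _, lrt_raw = fit_ladder(specs, df)
        scaled = df.assign(x1=zscore(df["x1"]), x2=zscore(df["x2"]))
        _, lrt_scaled = fit_ladder(specs, scaled)
        assert lrt_raw[0].statistic == pytest.approx(
            lrt_scaled[0].statistic, abs=1e-4
        )

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        df = _toy_trial_table(rng)
        with pytest.raises(ValueError, match="not nested"):
            fit_ladder(self._specs([["x1"], ["x2"]]), df)


class TestBodnerEffect:
    def _fit_with_t(self, tval, term="x1:x2", df_resid=200.0):
        idx = ["Intercept", "x1", "x2", term]
        t = pd.Series([5.0, 2.0, 1.0, tval], index=idx)
        return ModelFit(
            spec=ModelSpec(dependent="y"), log_likelihood=-100.0, n_params=6,
            n_fixed=4, coefficients=t * 0.1, std_errors=t * 0 + 0.1,
            tvalues=t, df_resid=df_resid, converged=True,
        )

    def test_formulas_sign_and_zero(self):
        fit = self._fit_with_t(3.0)
        delta = bodner_effect(fit, "x1:x2", "delta")
        rho = bodner_effect(fit, "x1:x2", "rho")
        assert delta.value == pytest.approx(2 * 3.0 / np.sqrt(200.0))
        assert rho.value == pytest.approx(3.0 / np.sqrt(9.0 + 200.0))
        assert bodner_effect(self._fit_with_t(0.0), "x1:x2", "delta").value == 0.0
        assert bodner_effect(self._fit_with_t(-3.0), "x1:x2", "rho").value == -rho.value

    def test_magnitude_monotone_in_t(self):
        vals = [
            abs(bodner_effect(self._fit_with_t(t), "x1:x2", "rho").value)
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert vals == sorted(vals)

    def test_near_zero_on_null_interaction_fit(self):
        rng = np.random.default_rng(10)
        df = _toy_trial_table(rng, n_subjects=250, n_trials=4, interaction=0.0)
        fits, _ = fit_ladder(
            [ModelSpec(dependent="y", fixed_terms=("x1*x2",))], df
        )
        est = bodner_effect(fits[0], "x1:x2", "rho")
        assert abs(est.value) < 0.05

    def test_missing_term_rejected(self):
        with pytest.raises(KeyError):
            bodner_effect(self._fit_with_t(1.0), "x1:x3", "rho")


class TestBcaCI:
    def test_symmetric_data_close_to_percentile(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=400)
        lo, hi = bca_ci(np.mean, data, n_boot=4000, seed=12)
        boot = np.array(
            [np.mean(rng.choice(data, size=400)) for _ in range(4000)]
        )
        plo, phi = np.quantile(boot, [0.025, 0.975])
        sd = data.std()
        assert abs(lo - plo) < 0.01 * sd and abs(hi - phi) < 0.01 * sd

    def test_agrees_with_scipy_bca(self):
        rng = np.random.default_rng(13)
        data = np.exp(rng.normal(size=80))
        lo, hi = bca_ci(np.mean, data, n_boot=4000, seed=14)
        res = stats.bootstrap(
            (data,), np.mean, n_resamples=4000, method="BCa",
            random_state=np.random.default_rng(15),
        )
        se = res.standard_error
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.15 * se * 4)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.15 * se * 4)

    def test_deterministic_under_seed(self):
        data = np.random.default_rng(16).normal(size=60)
        assert bca_ci(np.mean, data, seed=17) == bca_ci(np.mean, data, seed=17)

    def test_degenerate_distribution_collapses(self):
        lo, hi = bca_ci(np.median, np.full(30, 2.0), seed=18)
        assert lo == hi == 2.0

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bca_ci(np.mean, np.arange(10.0), n_boot=100, seed=0)
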