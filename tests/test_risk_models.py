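import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from chondrorisk import risk_models as rm
from chondrorisk import synthetic

# Printed (logLik, k) pairs of the four nested predictive models, n = 367.
PREDICTIVE_MODEL_FITS = [(-227.479, 2), (-210.299, 3), (-204.703, 4), (-202.578, 5)]
# Printed (logLik, k) pairs of the four nested mixed models, n = 367.
MIXED_MODEL_FITS = [(-197.06, 5), (-187.013, 6), (-182.139, 7), (-179.785, 8)]


class TestAicc:
    def test_printed_values(self):
        assert round(rm.aicc(-202.578, 5, 367), 1) == 415.3
        assert round(rm.aicc(-227.479, 2, 367), 1) == 459.0

    def test_large_n_reduces_to_aic(self):
        assert rm.aicc(0.0, 1, 10**9) == pytest.approx(2.0, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            rm.aicc(-10.0, 5, 6)

    def test_strictly_above_aic_and_monotone_in_n(self):
        aic = -2 * (-50.0) + 2 * 4
        vals = [rm.aicc(-50.0, 4, n) for n in (10, 50, 500, 5000)]
        assert all(v > aic for v in vals)
        assert vals == sorted(vals, reverse=True)


class TestAkaikeWeights:
    def test_two_equal(self):
        np.testing.assert_allclose(rm.akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_printed_full_model_weight(self):
        aiccs = [rm.aicc(ll, k, 367) for ll, k in PREDICTIVE_MODEL_FITS]
        w = rm.akaike_weights(aiccs)
        assert round(float(w[-1]), 3) == 0.748

    @given(st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=8),
           st.floats(min_value=-200, max_value=200))
    def test_sum_one_and_shift_invariance(self, vals, shift):
        w1 = rm.akaike_weights(vals)
        w2 = rm.akaike_weights([v + shift for v in vals])
        assert abs(w1.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(w1, w2, atol=1e-9)


class TestRelativeImportance:
    def _rows(self, entries, n=367):
        return rm.compare_models(entries, n)

    def test_in_every_model(self):
        rows = self._rows(
            [("m1", -227.479, 2, ("length",)), ("m2", -210.299, 3, ("length", "depth"))]
        )
        imp = rm.relative_importance(rows)
        assert imp["length"] == pytest.approx(1.0)

    def test_geographic_range_importance(self):
        variables = [
            ("length",),
            ("length", "min_depth"),
            ("length", "min_depth", "depth_range"),
            ("length", "min_depth", "depth_range", "geographic_range"),
        ]
        rows = self._rows(
            [(f"m{i}", ll, k, v) for i, ((ll, k), v) in enumerate(zip(MIXED_MODEL_FITS, variables))]
        )
        imp = rm.relative_importance(rows)
        assert 0.78 <= imp["geographic_range"] <= 0.79
        assert imp["length"] == pytest.approx(1.0)

    def test_absent_variable(self):
        rows = self._rows([("m1", -227.479, 2, ("length",))])
        assert rm.relative_importance(rows).get("depth", 0.0) == 0.0


class TestEffectSize:
    def test_zero_slope(self):
        for b0 in (-2.0, 0.0, 3.0):
            assert rm.effect_size_pct(b0, 0.0) == 0.0

    def test_direct_evaluation(self):
        assert rm.effect_size_pct(0.0, 1.0) == pytest.approx(0.14974, abs=1e-5)

    def test_antisymmetry_at_zero_intercept(self):
        assert rm.effect_size_pct(0.0, -1.0) == pytest.approx(-0.14974, abs=1e-5)


class TestR2Glmm:
    def test_components_arithmetic(self):
        d = rm.VarianceDecomposition(s2_fixed=1.0, s2_random=1.0)
        assert d.r2_marginal == pytest.approx(1.0 / (2.0 + math.pi**2 / 3), abs=1e-4)
        assert d.r2_conditional == pytest.approx(2.0 / (2.0 + math.pi**2 / 3), abs=1e-4)

    def test_zero_random_equalizes(self):
        d = rm.VarianceDecomposition(s2_fixed=0.7, s2_random=0.0)
        assert d.r2_marginal == d.r2_conditional

    def test_zero_fixed(self):
        d = rm.VarianceDecomposition(s2_fixed=0.0, s2_random=2.0)
        assert d.r2_marginal == 0.0

    def test_increases_with_effect_size(self, rng):
        x = rng.standard_normal(500)
        r2s = []
        for b in (0.2, 1.0, 3.0):
            y = (rng.random(500) < expit(b * x)).astype(float)
            d = rm.LogisticDesign(y=y, X=np.column_stack([np.ones(500), x]),
                                  columns=["(Intercept)", "x"])
            fit = rm.fit_logistic_glm(d)
            r2s.append(rm.r2_glmm(fit, d.X).r2_marginal)
        assert r2s == sorted(r2s)


def _grid_search_loglik(y, x, b0_range, b1_range, steps=61):
    best = (-np.inf, None, None)
    for b0 in np.linspace(*b0_range, steps):
        for b1 in np.linspace(*b1_range, steps):
            eta = b0 + b1 * x
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            if ll > best[0]:
                best = (ll, b0, b1)
    return best


class TestGlm:
    def test_intercept_only_closed_form(self):
        y = np.concatenate([np.ones(30), np.zeros(70)])
        d = rm.LogisticDesign(y=y, X=np.ones((100, 1)), columns=["(Intercept)"])
        fit = rm.fit_logistic_glm(d)
        assert fit.coef[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)
        assert fit.k == 1

    def test_matches_grid_search_oracle(self, rng):
        x = rng.standard_normal(20)
        y = (rng.random(20) < expit(0.5 + 1.2 * x)).astype(float)
        d = rm.LogisticDesign(y=y, X=np.column_stack([np.ones(20), x]),
                              columns=["(Intercept)", "x"])
        fit = rm.fit_logistic_glm(d)
        # iteratively refined independent grid search
        b0r, b1r = (-5.0, 5.0), (-5.0, 5.0)
        for _ in range(4):
            ll, b0, b1 = _grid_search_loglik(y, x, b0r, b1r)
            w0 = (b0r[1] - b0r[0]) / 10
            w1 = (b1r[1] - b1r[0]) / 10
            b0r, b1r = (b0 - w0, b0 + w0), (b1 - w1, b1 + w1)
        assert fit.coef[0] == pytest.approx(b0, abs=1e-3)
        assert fit.coef[1] == pytest.approx(b1, abs=1e-3)
        assert fit.loglik >= ll - 1e-6

    def test_constant_response_is_separation(self):
        d = rm.LogisticDesign(y=np.ones(10), X=np.ones((10, 1)), columns=["(Intercept)"])
        with pytest.raises(rm.SeparationError):
            rm.fit_logistic_glm(d)

    def test_perfectly_separating_covariate(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        d = rm.LogisticDesign(y=y, X=np.column_stack([np.ones(30), x]),
                              columns=["(Intercept)", "x"])
        with pytest.raises(rm.SeparationError, match="x"):
            rm.fit_logistic_glm(d)

    def test_rank_deficient_design(self):
        x = np.arange(10.0)
        d = rm.LogisticDesign(
            y=(x > 4).astype(float),
            X=np.column_stack([np.ones(10), x, 2 * x]),
            columns=["(Intercept)", "x", "x2"],
        )
        with pytest.raises(ValueError, match="rank deficient"):
            rm.fit_logistic_glm(d)

    def test_score_equations_satisfied(self, rng):
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        y = (rng.random(200) < expit(X @ np.array([0.2, 0.8, -0.5]))).astype(float)
        fit = rm.fit_logistic_glm(
            rm.LogisticDesign(y=y, X=X, columns=["(Intercept)", "a", "b"])
        )
        probs = fit.predict_proba(X)
        assert np.all((probs > 0) & (probs < 1))
        np.testing.assert_allclose(X.T @ (y - probs), 0.0, atol=1e-6)


def _glmm_design(seed, sigma_family=1.0, n=800):
    cfg = synthetic.SimulationConfig(
        n_species=n,
        dd_base_rate=0.0,
        dd_deep_increment=0.0,
        nonthreatened_split=(0, 1),
        sigma_family=sigma_family,
    )
    table, _ = synthetic.simulate_species(cfg, seed)
    return rm.build_design(
        table,
        ["max_length_cm", "min_depth_m", "depth_range_m"],
        random=("family",),
        log10_transform=True,
    )


class TestGlmm:
    def test_zero_variance_data_degenerates(self):
        d = _glmm_design(31, sigma_family=0.0)
        glm = rm.fit_logistic_glm(d)
        glmm = rm.fit_logistic_glmm(d)
        assert glmm.vcomp["family"] < 0.05
        np.testing.assert_array_less(
            np.abs(glmm.coef - glm.coef), 2.0 * glm.se + 1e-9
        )

    def test_pinned_zero_reduces_to_glm(self):
        d = _glmm_design(32)
        glm = rm.fit_logistic_glm(d)
        glmm = rm.fit_logistic_glmm(d, fix_sigma2={"family": 0.0})
        np.testing.assert_allclose(glmm.coef, glm.coef, atol=1e-4)
        assert glmm.vcomp == {"family": 0.0}
        assert glmm.method == "glmm"

    def test_glmm_beats_glm_with_strong_family_effects(self):
        d = _glmm_design(33, sigma_family=1.5)
        glm = rm.fit_logistic_glm(d)
        glmm = rm.fit_logistic_glmm(d)
        aic_glmm = -2 * glmm.loglik + 2 * glmm.k
        aic_glm = -2 * glm.loglik + 2 * glm.k
        assert aic_glmm - aic_glm < 0  # mirrors the negative printed deltas

    def test_recovers_variance_component(self):
        d = _glmm_design(34, sigma_family=1.0, n=2000)
        glmm = rm.fit_logistic_glmm(d)
        assert glmm.converged
        assert 0.4 < glmm.vcomp["family"] < 2.5

    def test_k_counts_variance_components(self):
        d = _glmm_design(35)
        glmm = rm.fit_logistic_glmm(d)
        assert glmm.k == d.X.shape[1] + 1  # fixed effects + one component

    def test_requires_groups(self):
        d = _glmm_design(36)
        d2 = rm.LogisticDesign(y=d.y, X=d.X, columns=d.columns)
        with pytest.raises(ValueError, match="grouping"):
            rm.fit_logistic_glmm(d2)


class TestBuildDesign:
    def test_standardized_columns(self):
        d = _glmm_design(40)
        assert abs(d.X[:, 1].mean()) < 1e-9
        assert d.X[:, 1].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_response_binary_and_complete(self):
        d = _glmm_design(41)
        assert set(np.unique(d.y)) <= {0.0, 1.0}
        assert np.isfinite(d.X).all()

    def test_nt_inclusive_coding(self):
        cfg = synthetic.SimulationConfig(n_species=400, dd_base_rate=0.0,
                                         dd_deep_increment=0.0)
        table, _ = synthetic.simulate_species(cfg, 77)
        d_base = rm.build_design(table, ["max_length_cm"], random=("family",))
        d_nt = rm.build_design(table, ["max_length_cm"], response="threatened_nt",
                               random=("family",))
        assert d_nt.n > d_base.n  # NT species enter the NT-inclusive coding
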