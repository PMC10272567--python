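import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from osmonet import diffexpr
from osmonet.diffexpr import Contrast
from osmonet.io import ExpressionMatrix, OsmonetError


def _matrix(values, samples, index=None):
    df = pd.DataFrame(values, columns=samples)
    if index is not None:
        df.index = index
    return ExpressionMatrix(df, scale_tag="raw")


def _log_matrix(values, samples):
    return ExpressionMatrix(pd.DataFrame(values, columns=samples), scale_tag="log2")


CONTRAST = Contrast("c", "leaf", "M82", ("a1", "a2", "a3"), ("b1", "b2", "b3"))
SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]


class TestLog2Transform:
    @pytest.mark.parametrize("x,expected", [(8.0, 3.0), (1.0, 0.0), (2.0, 1.0)])
    def test_values(self, x, expected):
        m = _matrix([[x]], ["s1"])
        out = diffexpr.log2_transform(m)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.scale_tag == "log2"

    def test_zero_errors_with_hint(self):
        m = _matrix([[0.0]], ["s1"])
        with pytest.raises(OsmonetError, match="log2\\(x\\+1\\)"):
            diffexpr.log2_transform(m)


class TestFitContrast:
    def test_exact_means(self):
        m = _log_matrix([[3, 3, 3, 1, 1, 1]], SAMPLES)
        fit = diffexpr.fit_contrast(m, CONTRAST)
        assert fit["lfc"].iloc[0] == pytest.approx(2.0)
        assert fit["s_sq"].iloc[0] == pytest.approx(0.0)
        assert fit["df_resid"].iloc[0] == 4
        assert fit["stderr_unit"].iloc[0] == pytest.approx(math.sqrt(2 / 3))

    def test_identical_groups_zero_lfc(self):
        m = _log_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], SAMPLES)
        fit = diffexpr.fit_contrast(m, CONTRAST)
        assert fit["lfc"].iloc[0] == pytest.approx(0.0)

    def test_reversing_contrast_negates_lfc(self, rng):
        m = _log_matrix(rng.normal(5, 1, (20, 6)), SAMPLES)
        fwd = diffexpr.fit_contrast(m, CONTRAST)
        rev = diffexpr.fit_contrast(m, CONTRAST.reversed())
        np.testing.assert_allclose(fwd["lfc"], -rev["lfc"])
        np.testing.assert_allclose(fwd["s_sq"], rev["s_sq"])

    def test_small_group_rejected(self):
        with pytest.raises(OsmonetError, match=">=2"):
            Contrast("c", "leaf", "M82", ("a1",), ("b1", "b2"))


class TestModerateVariances:
    def test_homogeneous_variances_give_infinite_d0(self):
        s_sq = np.full(100, 0.25)
        params, posterior = diffexpr.moderate_variances(s_sq, 4)
        assert math.isinf(params.d0)
        np.testing.assert_allclose(posterior, 0.25, rtol=1e-6)

    def test_zero_variance_gene_rescued(self, rng):
        s_sq = rng.chisquare(4, 500) / 4
        s_sq[0] = 0.0
        _, posterior = diffexpr.moderate_variances(s_sq, 4)
        assert posterior[0] > 0

    def test_hyperparameter_recovery(self):
        # s^2 ~ s0^2 * chi2_df / df with s0^2 = 1, df = 4: the generating
        # distribution is the oracle; d0 should be large/infinite and s0^2
        # recovered within 5%.
        gen = np.random.default_rng(42)
        s_sq = gen.chisquare(4, 10_000) / 4.0
        params, _ = diffexpr.moderate_variances(s_sq, 4)
        assert params.s0_sq == pytest.approx(1.0, rel=0.05)

    def test_finite_d0_recovery(self):
        # inverse-gamma heterogeneity: log s^2 spread exceeds trigamma(df/2)
        gen = np.random.default_rng(7)
        d0, s0 = 8.0, 0.5
        sigma_sq = d0 * s0 / gen.chisquare(d0, 20_000)
        s_sq = sigma_sq * gen.chisquare(4, 20_000) / 4.0
        params, _ = diffexpr.moderate_variances(s_sq, 4)
        assert params.d0 == pytest.approx(8.0, rel=0.25)
        assert params.s0_sq == pytest.approx(0.5, rel=0.1)

    def test_all_zero_variances_error(self):
        with pytest.raises(OsmonetError, match="zero"):
            diffexpr.moderate_variances(np.zeros(10), 4)


class TestModeratedT:
    def test_hand_computed_example(self):
        # lfc=2, posterior var 0.25, 3v3 (stderr_unit sqrt(2/3)), d0 inf
        t, p = diffexpr.moderated_t(
            np.array([2.0]), math.sqrt(2 / 3), np.array([0.25]), math.inf, 4
        )
        assert t[0] == pytest.approx(4.898979485566356)
        assert p[0] == pytest.approx(9.6336e-07, rel=1e-3)

    def test_zero_lfc(self):
        t, p = diffexpr.moderated_t(np.array([0.0]), 0.8165, np.array([0.25]), 10.0, 4)
        assert t[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_doubling_variance_scales_t(self):
        lfc = np.array([1.5])
        t1, _ = diffexpr.moderated_t(lfc, 0.8165, np.array([0.2]), 10.0, 4)
        t2, _ = diffexpr.moderated_t(lfc, 0.8165, np.array([0.4]), 10.0, 4)
        assert t2[0] == pytest.approx(t1[0] / math.sqrt(2))

    def test_equal_variance_limit_matches_pooled_t(self, rng):
        # with homogeneous gene variances the moderated t equals the
        # classical pooled two-sample t (scipy as independent oracle)
        data = rng.normal(8, 1, (50, 6))
        m = _log_matrix(data, SAMPLES)
        fit = diffexpr.fit_contrast(m, CONTRAST)
        s_sq = np.full(50, fit["s_sq"].mean())
        params, posterior = diffexpr.moderate_variances(s_sq, 4)
        t_mod, _ = diffexpr.moderated_t(
            fit["lfc"].to_numpy(), fit["stderr_unit"].iloc[0], posterior, params.d0, 4
        )
        pooled = fit["lfc"] / (np.sqrt(s_sq) * fit["stderr_unit"].iloc[0])
        np.testing.assert_allclose(t_mod, pooled, rtol=1e-9)


class TestBHAdjust:
    def test_toy_vector_step_up(self):
        # hand step-up: sorted p * m/i = (.04,.04,.04,.04), cummin from top
        out = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert diffexpr.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_ties_identity(self):
        out = diffexpr.bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(out, [0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(OsmonetError):
            diffexpr.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, ps):
        adj = diffexpr.bh_adjust(ps)
        assert (adj <= 1 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(diffexpr.bh_adjust(p), expected, rtol=1e-10)


class TestCallDets:
    @pytest.mark.parametrize(
        "adj_p,lfc,expected,direction",
        [
            (0.01, 1.0, True, "up"),     # inclusive lfc boundary
            (0.05, 3.0, False, "none"),  # strict alpha boundary
            (0.001, 0.99, False, "none"),
            (0.01, -1.0, True, "down"),
        ],
    )
    def test_boundaries(self, adj_p, lfc, expected, direction):
        df = pd.DataFrame({"adj_p": [adj_p], "lfc": [lfc]})
        out = diffexpr.call_dets(df)
        assert bool(out["is_det"].iloc[0]) is expected
        assert out["direction"].iloc[0] == direction


class TestRunDe:
    def test_global_null_calibration(self, tiny_design):
        # no planted effects: raw p < .05 fraction ~5%, DETs near zero
        gen = np.random.default_rng(123)
        vals = np.power(2.0, gen.normal(8, 0.5, (2000, 24)))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(2000)],
                         columns=tiny_design.sample_ids),
            scale_tag="raw",
        )
        contrasts = diffexpr.standard_contrasts(tiny_design)
        res = diffexpr.run_de(m, contrasts)
        frac = (res["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)
        assert int(res["is_det"].sum()) <= 5

    def test_adj_p_at_least_p(self, tiny_design, rng):
        vals = np.power(2.0, rng.normal(8, 0.5, (200, 24)))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(200)],
                         columns=tiny_design.sample_ids),
            scale_tag="raw",
        )
        res = diffexpr.run_de(m, diffexpr.standard_contrasts(tiny_design))
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
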