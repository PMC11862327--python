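"""Statistical core: bootstrap, BH, dz, JZS Bayes factor, Pillai, Fisher-z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hrvcross.inference import (
    BootstrapConfig,
    baseline_correct,
    bh_adjust,
    bootstrap_effect,
    cohens_dz,
    jzs_bayes_factor,
    manova_pillai,
    net_effect,
    side_correlation_test,
)


class TestTableOps:
    @staticmethod
    def toy_summary():
        rows = []
        for subj in ("S1", "S2"):
            for ses, (cond, side) in enumerate(
                [("taVNS", "left"), ("sham", "left"),
                 ("taVNS", "right"), ("sham", "right")], start=1
            ):
                for phase, rmssd in (("baseline", 40.0), ("stimulation", 36.0),
                                     ("caloric_load", 38.0)):
                    shift = -3.0 if (cond == "taVNS" and phase != "baseline") else 0.0
                    rows.append({"subject": subj, "session": ses, "condition": cond,
                                 "side": side, "phase": phase, "rmssd": rmssd + shift})
        return pd.DataFrame(rows)

    def test_baseline_correction_deltas(self):
        deltas = baseline_correct(self.toy_summary(), indices=("rmssd",))
        stim = deltas[(deltas["phase"] == "stimulation") & (deltas["condition"] == "taVNS")]
        assert np.allclose(stim["rmssd"], -7.0)  # (36-3) - 40
        sham = deltas[(deltas["phase"] == "stimulation") & (deltas["condition"] == "sham")]
        assert np.allclose(sham["rmssd"], -4.0)

    def test_missing_baseline_excludes_session(self):
        df = self.toy_summary()
        df = df[~((df["subject"] == "S1") & (df["session"] == 1)
                  & (df["phase"] == "baseline"))]
        deltas = baseline_correct(df, indices=("rmssd",))
        assert ("S1", 1, "taVNS", "left") in deltas.attrs["excluded_sessions"]

    def test_net_effect_pairwise_difference(self):
        deltas = baseline_correct(self.toy_summary(), indices=("rmssd",))
        net = net_effect(deltas, indices=("rmssd",))
        assert np.allclose(net["rmssd"], -3.0)  # injected taVNS - sham difference
        assert len(net) == 2 * 2 * 2  # subjects x sides x phases

    def test_identical_phases_zero_delta(self):
        df = self.toy_summary()
        df["rmssd"] = 40.0
        deltas = baseline_correct(df, indices=("rmssd",))
        assert np.allclose(deltas["rmssd"], 0.0)


class TestBootstrap:
    def test_all_zero_diffs(self):
        est = bootstrap_effect(np.zeros(10), BootstrapConfig(n_resamples=1000, seed=0))
        assert est.b == 0.0 and est.ci_lo == 0.0 and est.ci_hi == 0.0
        assert est.p_boot == 1.0

    def test_identical_nonzero_diffs_floor_p(self):
        cfg = BootstrapConfig(n_resamples=1000, seed=0)
        est = bootstrap_effect(np.full(8, -2.5), cfg)
        assert (est.ci_lo, est.ci_hi) == (-2.5, -2.5)
        assert est.p_boot == pytest.approx(1 / 1000)

    def test_clear_negative_effect_ci_excludes_zero(self):
        est = bootstrap_effect([-1.0, -2, -3, -4, -5],
                               BootstrapConfig(n_resamples=5000, seed=1))
        assert est.b == -3.0
        assert est.ci_hi < 0.0
        assert est.p_boot < 0.05

    def test_type_i_error_calibrated(self):
        # reduced version of the null calibration (full run in acceptance)
        rng = np.random.default_rng(99)
        rej = sum(
            bootstrap_effect(rng.standard_normal(36),
                             BootstrapConfig(n_resamples=1000, seed=i)).p_boot <= 0.05
            for i in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.09

    def test_p_and_ci_consistent(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            d = rng.normal(0.3, 1.0, 24)
            est = bootstrap_effect(d, BootstrapConfig(n_resamples=50_000, seed=i))
            excludes = est.ci_lo > 0 or est.ci_hi < 0
            if abs(est.p_boot - 0.05) > 0.005:  # outside resampling granularity
                assert (est.p_boot <= 0.05) == excludes

    def test_too_few_diffs_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            bootstrap_effect([1.0, 2.0, 3.0])


class TestBhAdjust:
    def test_hand_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_never_decreases_and_monotone(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_hand_rule_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(2, 15))
            m = p.size
            order = np.argsort(p)
            stepped = p[order] * m / np.arange(1, m + 1)
            hand = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(hand, 1.0)
            assert np.allclose(bh_adjust(p), expected)


class TestEffectSizes:
    def test_dz_definition(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-5, 10, 200)
        assert cohens_dz(d) == pytest.approx(d.mean() / d.std(ddof=1))

    def test_dz_antisymmetric(self):
        d = np.array([1.0, 3.0, -2.0, 0.5])
        assert cohens_dz(-d) == pytest.approx(-cohens_dz(d))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_dz(np.zeros(5))


class TestBayesFactor:
    def test_null_t_supports_null(self):
        assert jzs_bayes_factor(t=0.0, n=36) < 1.0

    def test_matches_fine_grid_quadrature(self):
        rng = np.random.default_rng(1)
        for n, loc in ((12, 0.0), (24, 0.4), (36, -0.6)):
            d = rng.normal(loc, 1.0, n)
            mine = jzs_bayes_factor(d, cauchy_scale=0.5)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            delta = np.linspace(-40, 40, 800001)
            prior = stats.cauchy.pdf(delta, 0, 0.5)
            alt = np.trapezoid(stats.nct.pdf(t, n - 1, delta * np.sqrt(n)) * prior, delta)
            oracle = alt / stats.t.pdf(t, n - 1)
            assert mine == pytest.approx(oracle, rel=1e-6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n in ((1.5, 20), (-2.8, 36), (0.3, 12)):
            mine = jzs_bayes_factor(t=t, n=n, cauchy_scale=0.5)
            ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.5))
            assert mine == pytest.approx(ref, rel=1e-4)

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bayes_factor(t=t, n=30) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(bfs) > 0)
        assert jzs_bayes_factor(t=-2.0, n=30) == pytest.approx(
            jzs_bayes_factor(t=2.0, n=30), rel=1e-9
        )


class TestManova:
    def test_single_dv_reduces_to_univariate_f(self):
        rng = np.random.default_rng(4)
        n = 40
        g = np.repeat([0.0, 1.0], n // 2)
        y = rng.standard_normal(n) + 0.6 * g
        X = np.column_stack([np.ones(n), g])
        res = manova_pillai(y[:, None], X, [1])
        f_uni = stats.f_oneway(y[g == 0], y[g == 1])
        assert res.f_stat == pytest.approx(f_uni.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(f_uni.pvalue, rel=1e-9)
        # V/(1-V) * (df2/df1) equals the univariate F
        V = res.pillai_v
        assert V / (1 - V) * res.df2 / res.df1 == pytest.approx(f_uni.statistic, rel=1e-9)

    def test_matches_statsmodels(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(6)
        n = 60
        g = np.repeat([0, 1], n // 2)
        Y = rng.standard_normal((n, 3))
        Y[g == 1] += [0.4, 0.1, -0.2]
        res = manova_pillai(Y, np.column_stack([np.ones(n), g]), [1])
        df = pd.DataFrame(Y, columns=["a", "b", "c"])
        df["g"] = g
        tab = sm_manova.MANOVA.from_formula("a + b + c ~ C(g)", data=df).mv_test()
        ref = tab.results["C(g)"]["stat"].loc["Pillai's trace"]
        assert res.pillai_v == pytest.approx(ref["Value"], rel=1e-8)
        assert res.f_stat == pytest.approx(ref["F Value"], rel=1e-8)
        assert res.p_value == pytest.approx(ref["Pr > F"], rel=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        n = 48
        g = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), g])
        pvals = [
            manova_pillai(rng.standard_normal((n, 4)), X, [1]).p_value
            for _ in range(500)
        ]
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.03 <= frac <= 0.07
        # Kolmogorov-Smirnov against uniformity
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicated_dv_rejected(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((30, 2))
        Y = np.column_stack([Y, Y[:, 0]])
        X = np.column_stack([np.ones(30), np.repeat([0.0, 1.0], 15)])
        with pytest.raises(ValueError, match="rank"):
            manova_pillai(Y, X, [1])

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="aliased"):
            manova_pillai(rng.standard_normal((20, 2)), X, [1])


class TestSideCorrelation:
    def test_fisher_z_values(self):
        assert np.arctanh(0.0) == 0.0
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_equal_correlations_null(self):
        r = np.array([0.2, 0.5, -0.1, 0.4])
        t, df, p = side_correlation_test(r, r)
        assert t == 0.0 and p == 1.0 and df == 3

    def test_matches_scipy_ttest_on_z(self):
        rng = np.random.default_rng(10)
        ra = rng.uniform(0.2, 0.8, 10)
        rr_ = rng.uniform(-0.2, 0.5, 10)
        t, df, p = side_correlation_test(ra, rr_)
        ref = stats.ttest_1samp(np.arctanh(ra) - np.arctanh(rr_), 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert df == 9

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            side_correlation_test([1.0, 0.5], [0.2, 0.1])


class TestSideConsistency:
    def test_consistent_active_changes_detected(self):
        from hrvcross.inference import side_consistency_test

        rng = np.random.default_rng(3)
        rows = []
        for s in range(20):
            subj_effect = rng.normal(-5, 3)  # shared across sides under taVNS
            for phase in ("stimulation", "caloric_load"):
                for cond in ("taVNS", "sham"):
                    for side in ("left", "right"):
                        val = (subj_effect + rng.normal(0, 1)) if cond == "taVNS" \
                            else rng.normal(0, 3)
                        rows.append({"subject": f"S{s}", "session": 1,
                                     "condition": cond, "side": side,
                                     "phase": phase, "rmssd": val, "hr": rng.normal()})
        deltas = pd.DataFrame(rows)
        res = side_consistency_test(deltas, indices=("rmssd", "hr"))
        assert len(res["labels"]) == 4  # 2 indices x 2 phases
        # taVNS rmssd changes correlate across sides; sham and hr do not
        assert res["r_active"][0] > res["r_reference"][0]

    def test_insufficient_pairs_rejected(self):
        from hrvcross.inference import side_consistency_test

        deltas = pd.DataFrame([
            {"subject": "S1", "condition": "taVNS", "side": "left",
             "phase": "stimulation", "rmssd": 1.0},
        ])
        with pytest.raises(ValueError, match="pairs"):
            side_consistency_test(deltas, indices=("rmssd",))
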