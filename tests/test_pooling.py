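import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stepmeta as sm

# ---------------------------------------------------------------------------
# independent brute-force oracle (plain Python, no shared code with stepmeta)


def oracle_fixed(thetas, ses):
    ws = [1.0 / s**2 for s in ses]
    sw = sum(ws)
    theta = sum(w * t for w, t in zip(ws, thetas)) / sw
    q = sum(w * (t - theta) ** 2 for w, t in zip(ws, thetas))
    return theta, sw ** -0.5, q


def oracle_dl(thetas, ses):
    theta_f, _, q = oracle_fixed(thetas, ses)
    ws = [1.0 / s**2 for s in ses]
    sw = sum(ws)
    c = sw - sum(w**2 for w in ws) / sw
    tau2 = max(0.0, (q - (len(thetas) - 1)) / c)
    wstar = [1.0 / (s**2 + tau2) for s in ses]
    sw = sum(wstar)
    theta = sum(w * t for w, t in zip(wstar, thetas)) / sw
    return theta, sw ** -0.5, tau2


def estimates_from(thetas, ses):
    return [sm.estimate_from_theta(t, s, 0.95, "ratio") for t, s in zip(thetas, ses)]


# ---------------------------------------------------------------------------


class TestFixedEffect:
    def test_single_study_identity(self):
        est = sm.make_estimate(1.4, 1.1, 1.8)
        res = sm.pool_fixed([est])
        assert res.k == 1 and res.df == 0
        assert res.Q == 0.0 and res.i_squared == 0.0
        assert res.pooled.theta == pytest.approx(est.theta)
        assert res.pooled.se == pytest.approx(est.se)
        assert "single-study" in res.flags

    def test_two_equal_weight_studies(self):
        res = sm.pool_fixed(estimates_from([0.0, 1.0], [1.0, 1.0]))
        assert res.pooled.theta == pytest.approx(0.5)
        assert res.pooled.se == pytest.approx(1 / math.sqrt(2))
        assert res.Q == pytest.approx(0.5)  # 0.25 + 0.25
        assert res.tau_squared == 0.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = rng.integers(2, 13)
            thetas = rng.normal(0.3, 0.5, k).tolist()
            ses = rng.uniform(0.05, 0.6, k).tolist()
            res = sm.pool_fixed(estimates_from(thetas, ses))
            t, s, q = oracle_fixed(thetas, ses)
            assert res.pooled.theta == pytest.approx(t, abs=1e-10)
            assert res.pooled.se == pytest.approx(s, abs=1e-10)
            assert res.Q == pytest.approx(q, abs=1e-10)

    def test_empty_and_mixed_kinds_raise(self):
        with pytest.raises(ValueError):
            sm.pool_fixed([])
        ratio = sm.make_estimate(1.4, 1.1, 1.8, 0.95, "ratio")
        diff = sm.make_estimate(0.4, 0.1, 0.8, 0.95, "difference")
        with pytest.raises(ValueError, match="mixed measure kinds"):
            sm.pool_fixed([ratio, diff])


class TestRandomEffectsDL:
    def test_homogeneous_inputs_collapse_to_fixed(self):
        ests = estimates_from([0.5, 0.5, 0.5], [0.2, 0.3, 0.25])
        re = sm.pool_random_dl(ests)
        fe = sm.pool_fixed(ests)
        assert re.tau_squared == 0.0
        assert re.Q == pytest.approx(0.0, abs=1e-20)
        assert re.pooled.theta == pytest.approx(fe.pooled.theta)
        assert re.pooled.se == pytest.approx(fe.pooled.se)

    def test_symmetric_heterogeneous_pair(self):
        # thetas {0, 2}, se = 1: Q = 2, df = 1, C = 1, tau2 = 1,
        # w* = 1/2 each, pooled theta = 1, pooled se = 1
        res = sm.pool_random_dl(estimates_from([0.0, 2.0], [1.0, 1.0]))
        assert res.Q == pytest.approx(2.0)
        assert res.tau_squared == pytest.approx(1.0)
        assert res.pooled.theta == pytest.approx(1.0)
        assert res.pooled.se == pytest.approx(1.0)

    def test_single_study_flagged(self):
        est = sm.make_estimate(1.4, 1.1, 1.8)
        res = sm.pool_random_dl([est])
        assert res.tau_squared == 0.0
        assert "single-study" in res.flags
        assert res.pooled.theta == pytest.approx(est.theta)

    def test_matches_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            k = rng.integers(2, 13)
            thetas = rng.normal(0.0, 0.8, k).tolist()
            ses = rng.uniform(0.05, 0.6, k).tolist()
            res = sm.pool_random_dl(estimates_from(thetas, ses))
            t, s, tau2 = oracle_dl(thetas, ses)
            assert res.pooled.theta == pytest.approx(t, abs=1e-10)
            assert res.pooled.se == pytest.approx(s, abs=1e-10)
            assert res.tau_squared == pytest.approx(tau2, abs=1e-10)


class TestHeterogeneity:
    def test_single_study(self):
        q, df, p_q, i2 = sm.heterogeneity([sm.make_estimate(1.4, 1.1, 1.8)])
        assert (q, df, p_q, i2) == (0.0, 0, 1.0, 0.0)

    def test_identical_estimates(self):
        q, df, _, i2 = sm.heterogeneity(estimates_from([0.3, 0.3], [0.2, 0.2]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0

    def test_i_squared_truncation_and_value(self):
        # i2 is a pure function of (Q, df): Q=0.5,df=1 -> 0; Q=4,df=1 -> 75
        def i2_of(q, df):
            return max(0.0, (q - df) / q) * 100.0

        assert i2_of(0.5, 1) == 0.0
        assert i2_of(4.0, 1) == 75.0
        # and the pipeline agrees on a case engineered to Q=4:
        res = sm.pool_fixed(estimates_from([0.0, 2 * math.sqrt(2)], [1.0, 1.0]))
        assert res.Q == pytest.approx(4.0)
        assert res.i_squared == pytest.approx(75.0)

    def test_p_q_is_chi2_tail(self):
        ests = estimates_from([0.0, 0.5, 1.2], [0.3, 0.2, 0.4])
        q, df, p_q, _ = sm.heterogeneity(ests)
        assert p_q == pytest.approx(float(stats.chi2.sf(q, df)), rel=1e-12)


@st.composite
def random_estimates(draw):
    k = draw(st.integers(2, 12))
    thetas = draw(
        st.lists(st.floats(-2, 2), min_size=k, max_size=k)
    )
    ses = draw(st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k))
    return estimates_from(thetas, ses)


class TestPoolingProperties:
    @given(ests=random_estimates())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_hull_se_ordering_and_tau_nonneg(self, ests):
        thetas = [e.theta for e in ests]
        fe = sm.pool_fixed(ests)
        re = sm.pool_random_dl(ests)
        for res in (fe, re):
            assert min(thetas) - 1e-12 <= res.pooled.theta <= max(thetas) + 1e-12
        assert re.pooled.se >= fe.pooled.se - 1e-12
        assert re.tau_squared >= 0.0
        assert fe.tau_squared == 0.0
        if re.Q <= re.df:
            assert re.tau_squared == 0.0
            assert re.i_squared == 0.0

    def test_tau2_monotone_in_q_for_fixed_weights(self):
        # stretch the spread of thetas holding ses fixed: Q grows, so must tau2
        ses = [0.2, 0.3, 0.25, 0.4]
        base = [-0.5, 0.1, 0.4, 0.9]
        tau2s, qs = [], []
        for scale in (0.5, 1.0, 2.0, 4.0):
            res = sm.pool_random_dl(estimates_from([scale * t for t in base], ses))
            qs.append(res.Q)
            tau2s.append(res.tau_squared)
        assert qs == sorted(qs)
        assert tau2s == sorted(tau2s)
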