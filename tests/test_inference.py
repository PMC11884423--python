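"""Selection-conditional tests and confidence intervals."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from seamsel import (DesignSpec, EstimateSet, TrialData, confidence_interval,
                     cond_pmf_ys, h_weights, p_values)
from seamsel.bivbin import _log_comb, binom_pmf_vector
from seamsel.simulate import Scenario, simulate_trials
from seamsel.estimators import cmae, mle


def _truth_estimates(s, xi, pi, rho):
    """An EstimateSet holding the true parameters (oracle plug-in)."""
    return EstimateSet("TRUTH", s, tuple(xi), {0: pi[0], s: pi[s]},
                       {0: rho, s: rho})


class TestHWeights:
    def test_vandermonde_reduction_single_group(self):
        """With no competition the weights are constant and h(k) = C(Ns, k)."""
        des = DesignSpec(G=1, n1=(10, 10), n2=(10, 10))
        data = TrialData(s=1, x1=(3, 5), x2={0: 4, 1: 6}, y={0: 6, 1: 13},
                        z={0: 2, 1: 8})
        es = _truth_estimates(1, [0.35, 0.55], [0.3, 0.65], 0.3)
        k, logh = h_weights(es, data, des)
        expected = _log_comb(20, k)
        # equality up to the constant Pr(Q=s)=1 factor
        assert np.allclose(logh, expected, atol=1e-10)

    def test_vandermonde_reduction_rho_zero(self):
        """rho-hat = 0 decouples long-term counts from selection, so the
        selection weight is constant in r and h(k) is proportional to C(Ns, k)."""
        des = DesignSpec(G=3, n1=(10, 10, 10, 10), n2=(10, 10, 10, 10))
        data = TrialData(s=2, x1=(3, 4, 7, 5), x2={0: 4, 2: 6},
                         y={0: 6, 2: 13}, z={0: 2, 2: 8})
        es = _truth_estimates(2, [0.35, 0.4, 0.6, 0.5], [0.3, 0.5, 0.65, 0.5],
                              0.0)
        k, logh = h_weights(es, data, des)
        diff = logh - _log_comb(20, k)
        assert np.allclose(diff, diff[0], atol=1e-10)

    def test_matches_tiny_trial_enumeration(self, tiny_design, tiny_enumerator):
        """Conditional law of Ys given (Q=s, T=t) at true parameters matches
        direct enumeration over the whole sample space."""
        xi = [0.5, 0.6, 0.6]
        pi = [0.45, 0.55, 0.55]
        rho = 0.4
        s = 1
        delta = math.log(pi[s] / (1 - pi[s])) - math.log(pi[0] / (1 - pi[0]))
        enum = tiny_enumerator(s, xi, pi, rho)
        pmf_y0 = binom_pmf_vector(4, pi[0])
        joint = {}
        for xo, t1, t2, p in enum.outcomes():
            ys = t1[1] + t2[1]
            for y0 in range(5):
                key = (ys, ys + y0)
                joint[key] = joint.get(key, 0.0) + p * pmf_y0[y0]
        es = _truth_estimates(s, xi, pi, rho)
        for t in range(1, 8):
            tot = sum(v for (ys, tt), v in joint.items() if tt == t)
            if tot == 0:
                continue
            ys_obs = max(0, t - 4)
            data = TrialData(s=s, x1=(0, 1, 0), x2={0: 0, s: 0},
                             y={0: t - ys_obs, s: ys_obs}, z={0: 0, s: 0})
            k, pmf = cond_pmf_ys(data, es, tiny_design, delta)
            enum_pmf = np.array([joint.get((kk, t), 0.0) / tot for kk in k])
            assert np.allclose(pmf, enum_pmf, atol=1e-10)


class TestCondPmf:
    def setup_method(self):
        self.des = DesignSpec(G=2, n1=(6, 6, 6), n2=(6, 6, 6))
        self.data = TrialData(s=1, x1=(2, 4, 3), x2={0: 2, 1: 4},
                              y={0: 4, 1: 7}, z={0: 2, 1: 5})
        self.es = _truth_estimates(1, [0.35, 0.6, 0.5], [0.35, 0.6, 0.5], 0.4)

    def test_normalization_across_delta(self):
        for delta in (-2.0, 0.0, 2.0):
            k, pmf = cond_pmf_ys(self.data, self.es, self.des, delta)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(pmf >= 0)

    def test_mass_shifts_right_with_delta(self):
        k, p_lo = cond_pmf_ys(self.data, self.es, self.des, -1.0)
        _, p_mid = cond_pmf_ys(self.data, self.es, self.des, 0.0)
        _, p_hi = cond_pmf_ys(self.data, self.es, self.des, 1.0)
        means = [float(k @ p) for p in (p_lo, p_mid, p_hi)]
        assert means[0] < means[1] < means[2]
        # and the upper tail is monotone in delta at every cut point
        for cut in k[1:]:
            tails = [float(p[k >= cut].sum()) for p in (p_lo, p_mid, p_hi)]
            assert tails[0] <= tails[1] + 1e-12 <= tails[2] + 2e-12


class TestPValues:
    def test_fisher_reduction(self):
        """G=1 and rho-hat=0: the exact p equals the one-sided Fisher exact
        p of the pooled 2x2 table (hypergeometric upper tail at Delta=0)."""
        des = DesignSpec(G=1, n1=(10, 10), n2=(10, 10))
        for ys, y0 in [(13, 6), (10, 10), (4, 12)]:
            data = TrialData(s=1, x1=(3, 5), x2={0: 4, 1: 6},
                             y={0: y0, 1: ys}, z={0: 2, 1: 4})
            es = _truth_estimates(1, [0.35, 0.55], [y0 / 20, ys / 20], 0.0)
            res = p_values(data, es, des)
            t = ys + y0
            p_fisher = float(hypergeom.sf(ys - 1, 40, t, 20))
            assert res.p_exact == pytest.approx(p_fisher, abs=1e-10)
            assert res.delta_at_sup_exact == pytest.approx(0.0)

    def test_minimum_support_gives_p_one(self):
        des = DesignSpec(G=1, n1=(5, 5), n2=(5, 5))
        data = TrialData(s=1, x1=(2, 3), x2={0: 2, 1: 2}, y={0: 8, 1: 0},
                         z={0: 2, 1: 0})
        es = _truth_estimates(1, [0.5, 0.5], [0.8, 0.05], 0.0)
        res = p_values(data, es, des)
        assert res.p_exact == pytest.approx(1.0)

    def test_midp_never_exceeds_exact(self, rng):
        sc = Scenario(id=1, G=3, N=20, tau=0.5, rho=0.4, baseline=0.3)
        des = sc.design()
        for trial in simulate_trials(sc, des, rng, 40):
            for est_fn in (mle, lambda d, dd: cmae(d, dd, profile_rho=False)):
                es = est_fn(trial, des)
                res = p_values(trial, es, des)
                assert 0.0 <= res.p_midp <= res.p_exact <= 1.0


class TestConfidenceInterval:
    def test_upper_limit_infinite_at_support_maximum(self):
        des = DesignSpec(G=1, n1=(5, 5), n2=(5, 5))
        data = TrialData(s=1, x1=(2, 3), x2={0: 2, 1: 2}, y={0: 0, 1: 7},
                         z={0: 0, 1: 3})
        es = _truth_estimates(1, [0.5, 0.5], [0.05, 0.7], 0.0)
        ci = confidence_interval(data, es, des, variant="exact")
        assert ci.upper == math.inf
        assert ci.lower > -math.inf

    def test_exact_interval_contains_midp_interval(self, rng):
        sc = Scenario(id=1, G=3, N=20, tau=0.5, rho=0.4, baseline=0.3)
        des = sc.design()
        for trial in simulate_trials(sc, des, rng, 25):
            es = mle(trial, des)
            ex = confidence_interval(trial, es, des, variant="exact")
            mp = confidence_interval(trial, es, des, variant="midp")
            assert ex.lower <= mp.lower + 1e-6
            assert mp.upper <= ex.upper + 1e-6

    def test_duality_with_midp_test(self, rng):
        """0 below the mid-p lower limit iff the one-sided mid-p p-value at
        Delta=0 is <= alpha/2, whenever the null supremum sits at 0."""
        sc = Scenario(id=5, G=2, N=20, tau=0.5, rho=0.2, delta=0.28)
        des = sc.design()
        checked = 0
        for trial in simulate_trials(sc, des, rng, 30):
            es = mle(trial, des)
            res = p_values(trial, es, des)
            if res.delta_at_sup_midp != 0.0:
                continue
            ci = confidence_interval(trial, es, des, level=0.95, variant="midp")
            if abs(res.p_midp - 0.025) < 1e-4:
                continue  # knife-edge: bisection tolerance dominates
            assert (ci.lower > 0) == (res.p_midp <= 0.025)
            checked += 1
        assert checked >= 20

    def test_fisher_interval_against_conditional_logistic(self):
        """G=1, rho=0: limits solve the noncentral hypergeometric tail
        equations; verify against a direct scipy-based inversion."""
        des = DesignSpec(G=1, n1=(10, 10), n2=(10, 10))
        ys, y0 = 13, 6
        data = TrialData(s=1, x1=(3, 5), x2={0: 4, 1: 6}, y={0: y0, 1: ys},
                         z={0: 2, 1: 4})
        es = _truth_estimates(1, [0.35, 0.55], [y0 / 20, ys / 20], 0.0)
        ci = confidence_interval(data, es, des, variant="exact")
        t = ys + y0
        k = np.arange(max(0, t - 20), min(t, 20) + 1)
        logkern = _log_comb(20, k) + _log_comb(20, t - k)

        def upper_tail(d):
            w = np.exp(logkern + k * d - (logkern + k * d).max())
            w /= w.sum()
            return w[k >= ys].sum()

        def lower_tail(d):
            w = np.exp(logkern + k * d - (logkern + k * d).max())
            w /= w.sum()
            return w[k <= ys].sum()

        from scipy.optimize import brentq
        lo = brentq(lambda d: upper_tail(d) - 0.025, -10, 10, xtol=1e-9)
        hi = brentq(lambda d: lower_tail(d) - 0.025, -10, 10, xtol=1e-9)
        assert ci.lower == pytest.approx(lo, abs=1e-4)
        assert ci.upper == pytest.approx(hi, abs=1e-4)
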