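"""TWIST score components against hand values and independent oracles."""

import numpy as np
import pytest
from scipy import stats

import twistest as tw
from conftest import random_survival_dataset
from twistest.estimators import nelson_aalen
from twistest.twist import score_logistic, score_survival, twist_test


class TestScoreLogistic:
    def test_hand_computed_example(self):
        """G1=(0,1,1,2), Z=(0,0,1,1): pi0=1/2, mean G1=1, so
        V = sum (G1-1)(Z-1/2) = 1/2 + 0 + 0 + 1/2 = 1 (equal to the
        uncentred sum G1*(Z-1/2)) and J = 1/4 * sum (G1-1)^2 = 1/2."""
        data = tw.dataset_from_arrays(
            time=[1.0, 2.0, 0.0, 0.0],
            event=[1, 1, 1, 1],
            pre_immune=[0, 0, 1, 1],
            allele_count=[0, 1, 1, 2],
        )
        v, j, flags = score_logistic(data)
        assert v == pytest.approx(1.0)
        assert j == pytest.approx(0.5)
        assert flags == ()

    def test_no_preimmune_is_degenerate(self):
        data = tw.dataset_from_arrays([1, 2], [1, 1], [0, 0], [0, 1])
        v, j, flags = score_logistic(data)
        assert (v, j) == (0.0, 0.0)
        assert "degenerate-logistic-part" in flags

    def test_monomorphic_is_degenerate(self):
        data = tw.dataset_from_arrays([0, 2], [1, 1], [1, 0], [1, 1])
        assert "degenerate-logistic-part" in score_logistic(data)[2]

    def test_permutation_null_law_is_chi2_1(self, rng):
        """Permuting Z leaves S1 with a chi-square(1) law."""
        n = 400
        counts = rng.binomial(2, 0.3, n)
        z = np.zeros(n, int)
        z[:60] = 1
        s1 = []
        for _ in range(600):
            zp = rng.permutation(z)
            x = np.where(zp == 1, 0.0, 1.0 + rng.random(n))
            data = tw.dataset_from_arrays(x, np.ones(n, int), zp, counts)
            v, j, _ = score_logistic(data)
            s1.append(v * v / j)
        s1 = np.sort(s1)
        for q in (0.90, 0.95, 0.99):
            emp = s1[int(q * len(s1)) - 1]
            assert emp == pytest.approx(stats.chi2.ppf(q, 1), rel=0.25)


class TestScoreSurvivalOracles:
    def test_unit_weights_match_lifelines_logrank(self, rng):
        """With W=1 the alpha-score is the classical logrank statistic.

        Checked on 50 random two-group, tie-free datasets against
        lifelines' independent implementation.
        """
        from lifelines.statistics import logrank_test

        for _ in range(50):
            data = random_survival_dataset(rng, n=rng.integers(20, 60), n_groups=2)
            comp = score_survival(data, nelson_aalen(data), unit_weights=True)
            chi2_mine = comp.u[0] ** 2 / comp.info[0, 0]
            g = data.g1
            res = logrank_test(
                data.time[g == 0], data.time[g == 1],
                event_observed_A=data.event[g == 0],
                event_observed_B=data.event[g == 1],
            )
            assert chi2_mine == pytest.approx(res.test_statistic, rel=1e-8)

    def test_information_matches_numeric_hessian(self, rng):
        """I-hat equals the observed information of the weighted partial
        likelihood at the null (numerical differentiation oracle).

        The survival part is the score of a Cox partial likelihood in the
        time-varying covariates W_a(t) * g_a; its analytic information at
        zero is the per-event weighted at-risk covariance, which the
        central-difference Hessian must reproduce to high accuracy.
        """
        for _ in range(8):
            data = random_survival_dataset(rng, n=int(rng.integers(25, 50)), n_groups=3)
            est = nelson_aalen(data)
            comp = score_survival(data, est)

            keep = data.pre_immune == 0
            x, d = data.time[keep], data.event[keep]
            g = np.column_stack([data.g1[keep], data.g2[keep]]).astype(float)
            w1, w2 = est.weight_pair(est.event_times, left=True)
            wmap = {0: w1, 1: w1, 2: w2, 3: w2}
            cmap = {0: 0, 1: 1, 2: 0, 3: 1}

            def lpl(theta):
                tot = 0.0
                for j, tj in enumerate(est.event_times):
                    eta = np.zeros(x.size)
                    for a in range(4):
                        eta += theta[a] * wmap[a][j] * g[:, cmap[a]]
                    at_risk = x >= tj
                    failed = (x == tj) & (d == 1)
                    tot += eta[failed].sum()
                    tot -= failed.sum() * np.log(np.exp(eta[at_risk]).sum())
                return tot

            h = 1e-4
            hess = np.empty((4, 4))
            e = np.eye(4)
            for a in range(4):
                for b in range(a, 4):
                    fpp = lpl(h * (e[a] + e[b]))
                    fpm = lpl(h * (e[a] - e[b]))
                    fmp = lpl(h * (e[b] - e[a]))
                    fmm = lpl(-h * (e[a] + e[b]))
                    hess[a, b] = hess[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
            scale = max(1.0, np.abs(comp.info).max())
            np.testing.assert_allclose(-hess, comp.info, atol=1e-4 * scale, rtol=1e-4)

    def test_score_matches_numeric_gradient(self, rng):
        """U-hat equals the first derivative of the partial likelihood."""
        data = random_survival_dataset(rng, n=30, n_groups=3)
        est = nelson_aalen(data)
        comp = score_survival(data, est)
        keep = data.pre_immune == 0
        x, d = data.time[keep], data.event[keep]
        g = np.column_stack([data.g1[keep], data.g2[keep]]).astype(float)
        w1, w2 = est.weight_pair(est.event_times, left=True)
        wmap = {0: w1, 1: w1, 2: w2, 3: w2}
        cmap = {0: 0, 1: 1, 2: 0, 3: 1}

        def lpl(theta):
            tot = 0.0
            for j, tj in enumerate(est.event_times):
                eta = np.zeros(x.size)
                for a in range(4):
                    eta += theta[a] * wmap[a][j] * g[:, cmap[a]]
                at_risk = x >= tj
                failed = (x == tj) & (d == 1)
                tot += eta[failed].sum() - failed.sum() * np.log(np.exp(eta[at_risk]).sum())
            return tot

        h = 1e-6
        grad = np.array(
            [(lpl(h * row) - lpl(-h * row)) / (2 * h) for row in np.eye(4)]
        )
        np.testing.assert_allclose(grad, comp.u, atol=1e-6 * max(1, np.abs(comp.u).max()))

    def test_monomorphic_genotype_is_rank_zero(self):
        data = tw.dataset_from_arrays([1.0, 2.0], [1, 1], [0, 0], [1, 1])
        comp = score_survival(data)
        assert comp.rank == 0
        res = twist_test(data)
        assert res.s2 == 0.0
        assert "rank-deficient-information" in res.flags


class TestTwistTest:
    def test_statistic_is_sum_of_parts(self, rng):
        data = random_survival_dataset(rng, 80, n_groups=3, preimmune=0.2)
        res = twist_test(data)
        assert res.statistic == pytest.approx(res.s1 + res.s2)
        assert res.df == 5
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 5))

    def test_invariant_to_common_time_rescaling(self, rng):
        data = random_survival_dataset(rng, 60, n_groups=3, preimmune=0.15)
        scaled = tw.dataset_from_arrays(
            data.time * 37.5, data.event, data.pre_immune, data.allele_count
        )
        r1, r2 = twist_test(data), twist_test(scaled)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_invariant_to_allele_relabeling_after_orientation(self, rng):
        """Flipping which allele is counted, then re-orienting, changes nothing."""
        data = random_survival_dataset(rng, 70, n_groups=3, preimmune=0.15)
        flipped, _ = tw.orient_alleles(2 - data.allele_count)
        oriented, _ = tw.orient_alleles(data.allele_count)
        d1 = tw.dataset_from_arrays(data.time, data.event, data.pre_immune, oriented)
        d2 = tw.dataset_from_arrays(data.time, data.event, data.pre_immune, flipped)
        assert twist_test(d1).statistic == pytest.approx(twist_test(d2).statistic)

    def test_study_scale_smoke(self, rng):
        """A cohort-sized dataset (469 subjects, 3.6% pre-immune) returns a
        finite 5-df statistic."""
        n = 469
        counts = rng.binomial(2, 0.25, n)
        z = np.zeros(n, int)
        z[rng.choice(n, 17, replace=False)] = 1
        t = rng.exponential(4.0, n)
        c = np.minimum(rng.uniform(6, 12, n), 12.0)
        x = np.where(z == 1, 0.0, np.minimum(t, c))
        d = np.where(z == 1, 1, (t <= c).astype(int))
        data = tw.dataset_from_arrays(x, d, z, counts)
        res = twist_test(data)
        assert np.isfinite(res.statistic) and res.df == 5
        assert 0.0 <= res.p_value <= 1.0
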