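"""Statistical kernel vs independent oracles (enumeration, brute force, lifelines)."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from reosig.io_model import ReosigError, SurvivalData
from reosig.stats_core import (
    ConstantInputError,
    bh_adjust,
    binom_upper_tail,
    c_index,
    cox_multivariate,
    cox_univariate,
    fisher_exact_2x2,
    hypergeom_enrich,
    km_estimate,
    logrank,
    spearman,
    wilcoxon_ranksum,
)

rng = np.random.default_rng(2024)


# --- independent oracles ----------------------------------------------------


def fisher_oracle(table):
    """Two-sided p by enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))


def hypergeom_oracle(hits, set_size, hits_total, universe):
    """Upper tail by direct combinatorics."""
    total = comb(universe, set_size)
    return sum(
        comb(hits_total, i) * comb(universe - hits_total, set_size - i)
        for i in range(hits, min(set_size, hits_total) + 1)
    ) / total


def binom_oracle(s, k, p):
    return sum(comb(k, i) * p**i * (1 - p) ** (k - i) for i in range(s, k + 1))


def bh_oracle(pvals):
    """Hand-computed step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p in the sorted order
        running = min(running, pvals[idx] * m / i)
        adj[idx] = running
    return adj


def ranksum_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p over all group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = [
        np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


def c_index_oracle(time, event, score):
    """Direct double loop over the permissible-pair definition."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i]:
                earlier = True
            elif time[i] == time[j] and event[i] and not event[j]:
                earlier = True
            else:
                earlier = False
            if not earlier:
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError
    return num / den


# --- spearman ---------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r.effect == pytest.approx(1.0)
        r = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert r.effect == pytest.approx(-1.0)

    def test_t_approximation_close_to_permutation(self):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        perm = np.mean(
            [
                abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= obs - 1e-12
                for _ in range(10_000)
            ]
        )
        assert abs(res.p_value - perm) < 0.02

    def test_exact_small_n_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        res = spearman(x, y, method="exact")
        # enumerate all 720 permutations directly
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, ry[list(p)])[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res.p_value == pytest.approx(hits / math.factorial(6))

    def test_constant_input_flagged(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# --- rank-sum ---------------------------------------------------------------


class TestWilcoxonRanksum:
    def test_identical_groups_uninformative(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_ranksum(a, a).p_value >= 0.9

    def test_exhaustive_enumeration_small_groups(self):
        res = wilcoxon_ranksum([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exact_oracle_on_random_instances(self, trial):
        r = np.random.default_rng(100 + trial)
        n1, n2 = r.integers(3, 9, size=2)
        a = r.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
        assert wilcoxon_ranksum(a, b).p_value == pytest.approx(
            ranksum_exact_oracle(a, b)
        )

    def test_planted_shift_detected(self):
        r = np.random.default_rng(5)
        a = r.normal(3.0, 1.0, 200)
        b = r.normal(0.0, 1.0, 200)
        assert wilcoxon_ranksum(a, b).p_value < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ReosigError):
            wilcoxon_ranksum([], [1.0])


# --- exact 2x2 and enrichment ----------------------------------------------


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_enumeration_oracle(self, trial):
        r = np.random.default_rng(trial)
        t = r.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_oracle(t), rel=1e-9
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ReosigError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestHypergeomEnrich:
    def test_small_urn(self):
        assert hypergeom_enrich(2, 2, 2, 4).p_value == pytest.approx(1 / 6)

    def test_zero_hits_certain(self):
        assert hypergeom_enrich(0, 3, 5, 10).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_combinatorial_oracle(self, trial):
        r = np.random.default_rng(1000 + trial)
        universe = int(r.integers(4, 30))
        set_size = int(r.integers(1, universe))
        hits_total = int(r.integers(1, universe))
        hits = int(r.integers(0, min(set_size, hits_total) + 1))
        assert hypergeom_enrich(hits, set_size, hits_total, universe).p_value == pytest.approx(
            hypergeom_oracle(hits, set_size, hits_total, universe), rel=1e-9
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ReosigError):
            hypergeom_enrich(5, 3, 4, 10)


class TestBinomUpperTail:
    def test_eight_of_ten(self):
        # all 2^10 equiprobable sign vectors: 56/1024
        assert binom_upper_tail(8, 10, 0.5) == pytest.approx(0.0546875)

    def test_boundaries(self):
        assert binom_upper_tail(0, 7, 0.5) == pytest.approx(1.0)
        assert binom_upper_tail(20, 20, 0.5) == pytest.approx(2.0**-20)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_summation_oracle(self, trial):
        r = np.random.default_rng(2000 + trial)
        k = int(r.integers(1, 25))
        s = int(r.integers(0, k + 1))
        p = float(r.uniform(0.05, 0.95))
        assert binom_upper_tail(s, k, p) == pytest.approx(binom_oracle(s, k, p), rel=1e-9)

    def test_bad_probability_rejected(self):
        with pytest.raises(ReosigError):
            binom_upper_tail(1, 2, 1.5)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_hand_oracle(self, trial):
        r = np.random.default_rng(3000 + trial)
        p = r.uniform(size=int(r.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_bounded_and_order_preserving(self):
        p = np.random.default_rng(1).uniform(size=30)
        once = bh_adjust(p)
        assert once.min() >= p.min()
        assert once.max() <= 1.0
        assert np.all(once >= p)
        # adjusted values keep the ordering of the raw p-values
        assert np.all(np.diff(once[np.argsort(p, kind="stable")]) >= -1e-15)

    def test_rejection_set_equals_step_up_rule(self):
        r = np.random.default_rng(9)
        p = r.uniform(size=50)
        for q in (0.05, 0.2, 0.5):
            adj = bh_adjust(p)
            # classic step-up: largest k with p_(k) <= k q / m
            srt = np.sort(p)
            ks = np.nonzero(srt <= (np.arange(1, 51) * q / 50))[0]
            k_star = (ks.max() + 1) if ks.size else 0
            rejected_rule = set(np.argsort(p, kind="stable")[:k_star])
            assert set(np.nonzero(adj <= q)[0]) == rejected_rule

    def test_out_of_range_rejected(self):
        with pytest.raises(ReosigError):
            bh_adjust([0.5, 1.2])


# --- survival ---------------------------------------------------------------


class TestKaplanMeierAndLogrank:
    def test_hand_computed_product_limit(self):
        surv = SurvivalData(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 0, 1])
        km = km_estimate(surv)
        assert km.evaluate(0.5) == pytest.approx(1.0)
        assert km.evaluate(1.0) == pytest.approx(2 / 3)
        assert km.evaluate(3.0) == pytest.approx(0.0)

    def test_identical_groups_uninformative(self):
        r = np.random.default_rng(2)
        t = r.exponential(10, 40)
        surv = SurvivalData([f"s{i}" for i in range(80)], np.concatenate([t, t]),
                            np.ones(80, dtype=int))
        labels = np.array([0] * 40 + [1] * 40)
        assert logrank(surv, labels).p_value >= 0.9

    def test_separated_groups_detected(self):
        r = np.random.default_rng(3)
        t = np.concatenate([r.exponential(2, 50), r.exponential(30, 50)])
        surv = SurvivalData([f"s{i}" for i in range(100)], t, np.ones(100, dtype=int))
        labels = np.array([1] * 50 + [0] * 50)
        assert logrank(surv, labels).p_value < 0.001

    def test_single_group_rejected(self):
        surv = SurvivalData(["a", "b"], [1.0, 2.0], [1, 1])
        with pytest.raises(ReosigError):
            logrank(surv, [1, 1])


def _random_survival(r, n, frac_event=0.6, with_ties=False):
    t = r.exponential(10, n)
    if with_ties:
        t = np.round(t)+ 1.0
    e = (r.uniform(size=n) < frac_event).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return SurvivalData([f"s{i}" for i in range(n)], t, e)


class TestCox:
    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_lifelines(self, with_ties):
        import pandas as pd
        from lifelines import CoxPHFitter

        r = np.random.default_rng(11 if with_ties else 12)
        surv = _random_survival(r, 120, with_ties=with_ties)
        x = r.normal(size=120) + 0.5 * surv.event
        fit = cox_univariate(surv, x)
        df = pd.DataFrame({"t": surv.time, "e": surv.event, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-5)

    def test_multivariate_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        r = np.random.default_rng(13)
        surv = _random_survival(r, 150, with_ties=True)
        X = pd.DataFrame(
            {"x1": r.normal(size=150), "x2": (r.uniform(size=150) > 0.5).astype(float)}
        )
        fits = cox_multivariate(surv, X)
        df = pd.DataFrame({"t": surv.time, "e": surv.event, "x1": X["x1"], "x2": X["x2"]})
        ref = CoxPHFitter().fit(df, "t", "e")
        for fit, name in zip(fits, ["x1", "x2"]):
            assert fit.beta == pytest.approx(ref.params_[name], abs=1e-5)

    def test_null_covariate_uninformative(self):
        r = np.random.default_rng(14)
        betas, pvals = [], []
        for _ in range(20):
            surv = _random_survival(r, 200)
            x = r.normal(size=200)
            fit = cox_univariate(surv, x)
            betas.append(fit.beta)
            pvals.append(fit.p_value)
        assert abs(np.mean(betas)) < 0.05
        # p-values roughly uniform: about half above 0.5
        assert 4 <= sum(p > 0.5 for p in pvals) <= 16

    def test_sign_agrees_with_nelson_aalen_ratio(self):
        # binary covariate: the fitted sign matches the cumulative-hazard ratio
        r = np.random.default_rng(15)
        n = 2000
        x = (r.uniform(size=n) > 0.5).astype(float)
        t = r.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        surv = SurvivalData([f"s{i}" for i in range(n)], t, np.ones(n, dtype=int))
        fit = cox_univariate(surv, x)
        na1 = surv.event[x == 1].sum() / t[x == 1].sum()
        na0 = surv.event[x == 0].sum() / t[x == 0].sum()
        assert np.sign(fit.beta) == np.sign(np.log(na1 / na0))

    def test_separation_flagged_not_crashed(self):
        # covariate perfectly splits early events from late censoring
        t = np.concatenate([np.arange(1.0, 21.0), np.arange(100.0, 120.0)])
        e = np.array([1] * 20 + [0] * 20)
        x = np.array([1.0] * 20 + [0.0] * 20)
        surv = SurvivalData([f"s{i}" for i in range(40)], t, e)
        fit = cox_univariate(surv, x)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        surv = SurvivalData(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ReosigError):
            cox_univariate(surv, [2.0, 2.0, 2.0])

    def test_multivariate_constant_column_named(self):
        import pandas as pd

        r = np.random.default_rng(16)
        surv = _random_survival(r, 50)
        X = pd.DataFrame({"x1": r.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ReosigError, match="flat"):
            cox_multivariate(surv, X)

    def test_multivariate_collinear_rejected(self):
        import pandas as pd

        r = np.random.default_rng(17)
        surv = _random_survival(r, 50)
        x = r.normal(size=50)
        X = pd.DataFrame({"x1": x, "x2": 2 * x + 1})
        with pytest.raises(ReosigError, match="collinear"):
            cox_multivariate(surv, X)

    def test_single_column_consistent_with_univariate(self):
        import pandas as pd

        r = np.random.default_rng(18)
        surv = _random_survival(r, 100)
        x = r.normal(size=100)
        uni = cox_univariate(surv, x)
        multi = cox_multivariate(surv, pd.DataFrame({"x": x}))[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-10)

    def test_only_prognostic_covariate_is_significant(self):
        import pandas as pd

        r = np.random.default_rng(19)
        n = 400
        x1 = r.normal(size=n)
        x2 = r.normal(size=n)
        t = r.exponential(1.0 / (0.05 * np.exp(1.0 * x1)))
        surv = SurvivalData([f"s{i}" for i in range(n)], t, np.ones(n, dtype=int))
        f1, f2 = cox_multivariate(surv, pd.DataFrame({"x1": x1, "x2": x2}))
        assert f1.p_value < 1e-6
        assert f2.p_value > 0.01


class TestCIndex:
    def test_perfect_ranking(self):
        surv = SurvivalData(list("abcd"), [1.0, 2.0, 10.0, 12.0], [1, 1, 1, 1])
        assert c_index(surv, [4.0, 3.0, 2.0, 1.0]) == pytest.approx(1.0)

    def test_binary_separation_two_vs_two(self):
        # between-group pairs all concordant; the two within-group pairs are
        # permissible with tied scores and credit 0.5 each: (4 + 2*0.5)/6
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.array([1, 1, 1, 1])
        s = np.array([1.0, 1.0, 0.0, 0.0])
        surv = SurvivalData(list("abcd"), t, e)
        assert c_index(surv, s) == pytest.approx(5 / 6)
        assert c_index(surv, s) == pytest.approx(c_index_oracle(t, e, s))

    def test_all_scores_tied(self):
        surv = SurvivalData(list("abcd"), [1.0, 2.0, 10.0, 12.0], [1, 1, 1, 1])
        assert c_index(surv, [3.0] * 4) == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_double_loop_oracle(self, trial):
        r = np.random.default_rng(4000 + trial)
        n = int(r.integers(5, 30))
        t = np.round(r.exponential(5, n), 0) + 1
        e = (r.uniform(size=n) < 0.7).astype(int)
        if e.sum() == 0:
            e[0] = 1
        s = np.round(r.normal(size=n), 1)
        surv = SurvivalData([f"s{i}" for i in range(n)], t, e)
        assert c_index(surv, s) == pytest.approx(c_index_oracle(t, e, s), rel=1e-12)

    def test_invariant_to_monotone_transform_of_scores(self):
        r = np.random.default_rng(21)
        surv = _random_survival(r, 60)
        s = r.normal(size=60)
        base = c_index(surv, s)
        assert c_index(surv, np.exp(s)) == pytest.approx(base)
        assert c_index(surv, 3 * s + 7) == pytest.approx(base)

    def test_no_permissible_pairs_rejected(self):
        surv = SurvivalData(["a", "b"], [5.0, 5.0], [1, 1])
        with pytest.raises(ReosigError):
            c_index(surv, [1.0, 0.0])
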