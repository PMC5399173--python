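"""Statistical kernel shared by every pipeline stage.

Rank correlation, rank-sum and exact 2x2 tests, hypergeometric enrichment,
cumulative binomial tails and Benjamini-Hochberg adjustment delegate to
scipy/statsmodels.  The Cox proportional-hazards fitter (Newton-Raphson on
the partial likelihood, Efron tie handling, Breslow selectable) and Harrell's
concordance index are implemented here directly: the pair screen runs
thousands of small single-covariate fits, and the permissible-pair policy of
the C-index is pinned down explicitly (see below).

Two-sided p-values throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io_model import ReosigError, SurvivalData

_Z975 = 1.959963984540054


class ConstantInputError(ReosigError):
    """A test input has no variation; the caller should skip this feature."""


@dataclass
class TestResult:
    """Generic hypothesis-test outcome.

    ``effect`` is test-specific: Spearman rho, odds ratio, proportion
    difference, ...; extras (CI bounds, group means) live in ``metadata``.
    """

    statistic: float
    p_value: float
    effect: float
    n_used: int
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ReosigError(f"p-value {self.p_value} outside [0,1]")
        if self.n_used < 0:
            raise ReosigError("n_used must be >= 0")


@dataclass
class CoxFit:
    """One coefficient of a Cox proportional-hazards fit."""

    beta: float
    se: float
    hr: float
    ci95: Tuple[float, float]
    p_value: float
    converged: bool
    n_used: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.hr <= 0:
                raise ReosigError("hazard ratio must be positive")
            if not (self.ci95[0] <= self.hr <= self.ci95[1]):
                raise ReosigError("HR outside its own 95% CI")


# ---------------------------------------------------------------------------
# Rank statistics and exact tests (scipy/statsmodels backed)
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float], method: str = "t") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    ``method='t'`` uses the t-approximation (default); ``'exact'`` enumerates
    all permutations and is limited to n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ReosigError("spearman expects two equal-length vectors")
    if len(x) < 4:
        raise ReosigError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if method == "exact":
        n = len(x)
        if n > 10:
            raise ReosigError("exact permutation p limited to n <= 10")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        n_ge = 0
        n_tot = 0
        it = itertools.permutations(range(n))
        while True:
            chunk = np.array(list(itertools.islice(it, 100_000)), dtype=np.intp)
            if chunk.size == 0:
                break
            stats_chunk = np.abs(ry_c[chunk] @ rx_c) / denom
            n_ge += int(np.sum(stats_chunk >= obs - 1e-12))
            n_tot += len(chunk)
        p = n_ge / n_tot
    return TestResult(statistic=float(rho), p_value=float(p), effect=float(rho), n_used=len(x))


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 12 observations and no ties
    across the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ReosigError("wilcoxon_ranksum requires two non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if a.size <= 12 and b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    effect = float(np.median(a) - np.median(b))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect=effect,
        n_used=int(a.size + b.size),
        metadata={"method": 0.0 if method == "exact" else 1.0},
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test, two-sided by summing tables with probability
    <= the observed one (the R convention); odds ratio as the effect."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ReosigError("fisher_exact_2x2 expects a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, t.astype(int)):
        raise ReosigError("fisher_exact_2x2 expects nonnegative integer counts")
    t = t.astype(int)
    if (t < 0).any():
        raise ReosigError("negative count in 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), effect=float(odds), n_used=int(t.sum()))


def hypergeom_enrich(hits_in_set: int, set_size: int, hits_total: int, universe: int) -> TestResult:
    """Upper-tail hypergeometric enrichment: P(X >= hits_in_set) when
    ``set_size`` genes are drawn from a ``universe`` containing
    ``hits_total`` marked genes."""
    if not (0 <= hits_in_set <= min(set_size, hits_total)):
        raise ReosigError("hits_in_set must lie in [0, min(set_size, hits_total)]")
    if max(set_size, hits_total) > universe:
        raise ReosigError("set_size and hits_total must not exceed the universe")
    p = float(sps.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    expected = set_size * hits_total / universe if universe else 0.0
    fold = hits_in_set / expected if expected > 0 else np.inf
    return TestResult(
        statistic=float(hits_in_set), p_value=min(p, 1.0), effect=float(fold), n_used=universe
    )


def binom_upper_tail(s: int, k: int, p_e: float = 0.5) -> float:
    """P(X >= s) for X ~ Binomial(k, p_e): sum_{i=s}^{k} C(k,i) p^i (1-p)^(k-i)."""
    if not (0.0 <= p_e <= 1.0):
        raise ReosigError("p_e must lie in [0,1]")
    if not (0 <= s <= k):
        raise ReosigError("require 0 <= s <= k")
    return float(sps.binom.sf(s - 1, k, p_e))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ReosigError("p-values must lie in [0,1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Survival statistics
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit curve: right-continuous, S(0) = 1."""

    event_times: np.ndarray     # distinct times with >= 1 event, ascending
    survival: np.ndarray        # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(surv: SurvivalData) -> KMEstimate:
    """Kaplan-Meier estimate of the survival function."""
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order]
    times, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float))
    removed = np.bincount(inv).astype(float)
    at_risk = len(t) - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    keep = d > 0
    surv_prob = np.cumprod(1.0 - d[keep] / at_risk[keep])
    return KMEstimate(
        event_times=times[keep],
        survival=surv_prob,
        n_at_risk=at_risk[keep],
        n_events=d[keep],
    )


def logrank(surv: SurvivalData, labels: Sequence[int]) -> TestResult:
    """Two-group log-rank test (chi-square statistic, two-sided p)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ReosigError("logrank requires exactly two groups")
    if surv.event.sum() == 0:
        raise ReosigError("logrank requires at least one event")
    from lifelines.statistics import logrank_test

    m0 = labels == groups[0]
    res = logrank_test(
        surv.time[m0], surv.time[~m0], event_observed_A=surv.event[m0], event_observed_B=surv.event[~m0]
    )
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        effect=float("nan"),
        n_used=len(surv),
    )


# --- Cox proportional hazards ----------------------------------------------


def _cox_sums(t: np.ndarray, e: np.ndarray, X: np.ndarray, eta: np.ndarray, ties: str):
    """Log partial likelihood, score and information for Cox regression.

    Arrays must be sorted by ascending time.  Efron tie handling by default;
    ``ties='breslow'`` drops the within-tie correction.
    """
    n, p = X.shape
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    utimes, inv = np.unique(t, return_inverse=True)
    nu = len(utimes)
    start = np.searchsorted(t, utimes, side="left")
    # risk-set sums: everyone with time >= each unique time
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    S0g, S1g, S2g = S0[start], S1[start], S2[start]

    ev = e == 1
    d = np.bincount(inv[ev], minlength=nu).astype(int)
    has = d > 0
    if not has.any():
        raise ReosigError("no events: Cox model undefined")
    D0 = np.bincount(inv[ev], weights=w[ev], minlength=nu)
    D1 = np.stack(
        [np.bincount(inv[ev], weights=wX[ev, j], minlength=nu) for j in range(p)], axis=1
    )
    D2 = np.stack(
        [
            np.stack(
                [np.bincount(inv[ev], weights=wXX[ev, j, k], minlength=nu) for k in range(p)],
                axis=1,
            )
            for j in range(p)
        ],
        axis=1,
    )  # -> (nu, p, p)
    xsum = np.stack(
        [np.bincount(inv[ev], weights=X[ev, j], minlength=nu) for j in range(p)], axis=1
    )
    eta_sum = np.bincount(inv[ev], weights=eta[ev], minlength=nu)

    gi = np.nonzero(has)[0]
    dg = d[gi]
    slots = np.repeat(gi, dg)
    offs = np.concatenate([np.arange(k) for k in dg]) if len(dg) else np.array([])
    frac = (offs / np.repeat(dg, dg)) if ties == "efron" else np.zeros(len(slots))

    denom = S0g[slots] - frac * D0[slots]
    num1 = S1g[slots] - frac[:, None] * D1[slots]
    num2 = S2g[slots] - frac[:, None, None] * D2[slots]

    loglik = float(eta_sum[gi].sum() - np.log(denom).sum())
    grad = xsum[gi].sum(axis=0) - (num1 / denom[:, None]).sum(axis=0)
    r = num1 / denom[:, None]
    info = (num2 / denom[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", r, num1 / denom[:, None])
    return loglik, grad, info


def _cox_newton(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
):
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_sums(t, e, Xs, Xs @ beta, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ReosigError("singular information matrix (collinear or constant covariates)")
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_sums(t, e, Xs, Xs @ new_beta, ties)
        halvings = 0
        while new_ll < ll and halvings < 25:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_sums(t, e, Xs, Xs @ new_beta, ties)
            halvings += 1
        delta = abs(new_ll - ll)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < tol * (abs(ll) + 1.0):
            converged = True
            break
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    # monotone-likelihood separation: the estimate runs away (or the
    # information flattens out) instead of settling at a finite optimum
    if np.any(np.abs(beta) > 15) or np.any(se > 50):
        converged = False
    return beta, se, ll, converged


def _make_fits(beta: np.ndarray, se: np.ndarray, converged: bool, n: int, names) -> list:
    fits = []
    for b, s, name in zip(beta, se, names):
        z = b / s if s > 0 else np.inf * np.sign(b)
        pval = float(2.0 * sps.norm.sf(abs(z)))
        fits.append(
            CoxFit(
                beta=float(b),
                se=float(s),
                hr=float(np.exp(b)),
                ci95=(
                    float(np.exp(min(b - _Z975 * s, 700.0))),
                    float(np.exp(min(b + _Z975 * s, 700.0))),
                ),
                p_value=pval,
                converged=converged,
                n_used=n,
                name=str(name),
            )
        )
    return fits


def cox_univariate(surv: SurvivalData, covariate: Sequence[float], ties: str = "efron") -> CoxFit:
    """Univariate Cox proportional-hazards regression.

    Newton-Raphson on the partial likelihood with Efron tie handling
    (``ties='breslow'`` selectable); returns beta, SE, Wald p, HR and 95% CI.
    Monotone-likelihood separation is flagged via ``converged=False``.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape != (len(surv),):
        raise ReosigError("covariate length must match survival data")
    if np.any(~np.isfinite(x)):
        raise ReosigError("covariate contains non-finite values")
    if len(np.unique(x[surv.event == 1])) < 2 and len(np.unique(x)) < 2:
        raise ConstantInputError("covariate has <2 distinct values")
    beta, se, _, converged = _cox_newton(surv.time, surv.event.astype(float), x[:, None], ties)
    return _make_fits(beta, se, converged, len(surv), ["covariate"])[0]


def cox_multivariate(surv: SurvivalData, covariates, ties: str = "efron"):
    """Jointly fitted Cox model; one :class:`CoxFit` per design column.

    The design must be full rank after dropping incomplete rows; constant or
    collinear columns raise an error naming the offenders.
    """
    import pandas as pd

    df = pd.DataFrame(covariates)
    complete = df.notna().all(axis=1).to_numpy()
    if complete.sum() < df.shape[1] + 2:
        raise ReosigError("too few complete rows for the multivariate design")
    X = df.loc[complete].to_numpy(dtype=float)
    names = list(df.columns)
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        raise ReosigError(f"constant design columns: {const}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        bad = [
            (names[j], names[k])
            for j in range(len(names))
            for k in range(j + 1, len(names))
            if abs(corr[j, k]) > 1 - 1e-10
        ]
        raise ReosigError(f"collinear design columns: {bad or names}")
    keep = np.nonzero(complete)[0]
    sub = SurvivalData(
        [surv.sample_ids[i] for i in keep], surv.time[keep], surv.event[keep]
    )
    beta, se, _, converged = _cox_newton(sub.time, sub.event.astype(float), X, ties)
    return _make_fits(beta, se, converged, len(sub), names)


def c_index(surv: SurvivalData, risk_score: Sequence[float]) -> float:
    """Harrell's concordance index of a risk score against survival.

    A pair (i, j) is permissible iff the member with the shorter time has an
    event; with equal times, one event makes the pair permissible with the
    event as the earlier member, and two events exclude the pair.  Concordant
    pairs score 1, score ties 0.5.
    """
    s = np.asarray(risk_score, dtype=float)
    if s.shape != (len(surv),):
        raise ReosigError("risk score length must match survival data")
    t = surv.time
    e = surv.event.astype(bool)
    # earlier[i, j]: i fails observably before j
    lt = t[:, None] < t[None, :]
    eq = t[:, None] == t[None, :]
    earlier = (lt & e[:, None]) | (eq & e[:, None] & ~e[None, :])
    n_perm = int(earlier.sum())
    if n_perm == 0:
        raise ReosigError("no permissible pairs for the C-index")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    num = (earlier & higher).sum() + 0.5 * (earlier & tied).sum()
    return float(num / n_perm)
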