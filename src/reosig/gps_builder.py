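"""Stage 2: build a gene-pair signature by pair screening + forward selection.

All unordered pairs of the screened genes are tested: the within-sample
indicator I(Ga > Gb) is fed to a univariate Cox model against relapse-free
survival, Benjamini-Hochberg correction is applied over all tested pairs,
and the survivors (Set1) are sorted by their solo concordance index (Set2).
A greedy forward selection then grows the signature from the top of Set2,
keeping a rule only when the majority-vote classification's C-index strictly
increases, and stops at the first rule that fails to increase it (Set3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import stats_core
from .io_model import (
    ExpressionMatrix,
    GenePairRule,
    GenePairSignature,
    PairDirection,
    ReosigError,
    SurvivalData,
    align_expression_survival,
)
from .reo_classifier import classify_cohort
from .stats_core import ConstantInputError

logger = logging.getLogger("reosig")

__all__ = [
    "GenePairRule",
    "GenePairSignature",
    "BuildAudit",
    "enumerate_pairs",
    "screen_pairs",
    "rank_pairs",
    "forward_select",
    "build_gps",
]


def enumerate_pairs(genes: Iterable[str]) -> List[Tuple[str, str]]:
    """All C(n,2) unordered gene pairs, canonically oriented lexicographically."""
    unique = sorted(set(genes))
    if len(unique) < 2:
        raise ReosigError("need at least 2 genes to enumerate pairs")
    return list(combinations(unique, 2))


def _pair_indicator(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Within-sample ordering indicator I(Ga > Gb); ties count as False."""
    return (values_a > values_b).astype(float)


def _vote_scores(indicator: np.ndarray, beta: float) -> np.ndarray:
    """A rule's own binary high-risk vote, used as its solo risk score."""
    return indicator if beta > 0 else 1.0 - indicator


def screen_pairs(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    pairs: Sequence[Tuple[str, str]],
    fdr: float = 0.05,
) -> List[GenePairRule]:
    """Test each pair's REO against survival; keep pairs with FDR < threshold.

    Pairs whose indicator is constant across samples (including always-tied
    expression rows) are excluded with a warning; BH correction runs over
    all pairs actually tested.
    """
    expr, surv = align_expression_survival(expr, surv)
    gene_rows: Dict[str, np.ndarray] = {}
    needed = {g for p in pairs for g in p}
    gene_set = set(expr.gene_ids)
    missing = sorted(needed - gene_set)
    if missing:
        raise ReosigError(f"pair genes absent from expression matrix: {missing[:5]}")
    for g in needed:
        gene_rows[g] = expr.values.loc[g].to_numpy(dtype=float)
    tested: List[Tuple[Tuple[str, str], float, float, np.ndarray]] = []
    n_skipped = 0
    for a, b in pairs:
        ind = _pair_indicator(gene_rows[a], gene_rows[b])
        if ind.min() == ind.max():
            n_skipped += 1
            continue
        try:
            fit = stats_core.cox_univariate(surv, ind)
        except (ConstantInputError, ReosigError):
            n_skipped += 1
            continue
        if not fit.converged:
            n_skipped += 1
            continue
        tested.append(((a, b), fit.beta, fit.p_value, ind))
    if n_skipped:
        logger.warning("pair screen: excluded %d degenerate/non-converged pairs", n_skipped)
    if not tested:
        logger.info("pair screen: 0/%d pairs tested successfully", len(pairs))
        return []
    adjusted = stats_core.bh_adjust([p for _, _, p, _ in tested])
    rules: List[GenePairRule] = []
    for ((a, b), beta, p, ind), q in zip(tested, adjusted):
        if q < fdr:
            solo = stats_core.c_index(surv, _vote_scores(ind, beta))
            rules.append(
                GenePairRule(
                    gene_a=a,
                    gene_b=b,
                    beta=beta,
                    p_value=p,
                    fdr=float(q),
                    c_index_solo=solo,
                    direction=PairDirection.A_GT_B_RISKY
                    if beta > 0
                    else PairDirection.A_GT_B_PROTECTIVE,
                )
            )
    logger.info(
        "pair screen (Set1): %d/%d tested pairs pass FDR < %g",
        len(rules), len(tested), fdr,
    )
    return rules


def rank_pairs(set1: Sequence[GenePairRule]) -> List[GenePairRule]:
    """Sort rules by descending solo C-index (Set2).

    Ties break by smaller p-value, then by lexicographic pair id, so the
    order is a deterministic function of the rule set.
    """
    return sorted(
        set1,
        key=lambda r: (-r.c_index_solo, r.p_value, (r.gene_a, r.gene_b)),
    )


def _composite_c_index(
    rules: List[GenePairRule], expr: ExpressionMatrix, surv: SurvivalData
) -> float:
    sig = GenePairSignature(rules=list(rules))
    calls = classify_cohort(sig, expr)
    by_id = {c.sample_id: c for c in calls}
    scores = np.array(
        [1.0 if by_id[s].label == "high" else 0.0 for s in surv.sample_ids]
    )
    return stats_core.c_index(surv, scores)


def _rule_votes(rule: GenePairRule, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample high-risk vote of one rule (0/1; 0.5 when a gene is missing)."""
    a = expr.values.loc[rule.gene_a].to_numpy(dtype=float)
    b = expr.values.loc[rule.gene_b].to_numpy(dtype=float)
    votes = _vote_scores(_pair_indicator(a, b), rule.beta)
    missing = ~(np.isfinite(a) & np.isfinite(b))
    if missing.any():
        votes = votes.copy()
        votes[missing] = 0.5
    return votes


def forward_select(
    set2: Sequence[GenePairRule],
    expr: ExpressionMatrix,
    surv: SurvivalData,
    policy: str = "stop-at-first-failure",
    score: str = "votes",
) -> GenePairSignature:
    """Greedy forward selection of rules by composite training C-index.

    The top rule of Set2 seeds the signature; each subsequent rule is kept
    only if adding it strictly increases the C-index of the composite risk
    score on the training data.  The default policy stops at the first rule
    that fails; ``policy='skip-and-continue'`` instead skips failures and
    keeps scanning down Set2.

    ``score='votes'`` (default) ranks samples by the number of high-risk
    votes among the candidate rules — the graded quantity underneath the
    majority-vote classifier.  ``score='binary'`` scores the collapsed
    majority-vote label itself; it is provided for comparison but is
    degenerate as a selection criterion: with the at-least-half (tie goes
    high) rule, every even-sized rule set labels ~75% of samples high, a
    partition whose C-index almost never exceeds the preceding odd step, so
    the greedy terminates after a single rule.
    """
    if not set2:
        raise ReosigError("forward_select requires at least one candidate rule")
    if policy not in ("stop-at-first-failure", "skip-and-continue"):
        raise ReosigError(f"unknown selection policy {policy!r}")
    if score not in ("votes", "binary"):
        raise ReosigError(f"unknown score mode {score!r}")
    expr, surv = align_expression_survival(expr, surv)

    if score == "votes":
        vote_sum = _rule_votes(set2[0], expr)
    selected = [set2[0]]
    if score == "votes":
        best = stats_core.c_index(surv, vote_sum)
    else:
        best = _composite_c_index(selected, expr, surv)
    for rule in set2[1:]:
        if score == "votes":
            cand_votes = vote_sum + _rule_votes(rule, expr)
            c_new = stats_core.c_index(surv, cand_votes)
        else:
            c_new = _composite_c_index(selected + [rule], expr, surv)
        if c_new > best:
            selected = selected + [rule]
            best = c_new
            if score == "votes":
                vote_sum = cand_votes
        elif policy == "stop-at-first-failure":
            break
    logger.info(
        "forward selection: %d rules accepted, training C-index %.4f (%s score)",
        len(selected), best, score,
    )
    return GenePairSignature(
        rules=selected,
        provenance=f"forward selection over {len(set2)} candidate pairs; "
        f"training C-index {best:.4f}",
    )


@dataclass
class BuildAudit:
    """Filter-cascade counts of one signature build."""

    n_genes: int = 0
    n_pairs_enumerated: int = 0
    n_pairs_set1: int = 0
    n_rules_signature: int = 0
    training_c_index: float = float("nan")


def build_gps(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    genes: Iterable[str],
    fdr_pairs: float = 0.05,
    policy: str = "stop-at-first-failure",
    score: str = "votes",
    audit: Optional[BuildAudit] = None,
) -> GenePairSignature:
    """Full builder: enumerate pairs -> screen (Set1) -> rank (Set2) -> select (Set3)."""
    genes = sorted(set(genes))
    pairs = enumerate_pairs(genes)
    set1 = screen_pairs(expr, surv, pairs, fdr=fdr_pairs)
    if not set1:
        raise ReosigError("no prognostic pairs at FDR threshold")
    set2 = rank_pairs(set1)
    sig = forward_select(set2, expr, surv, policy=policy, score=score)
    expr_a, surv_a = align_expression_survival(expr, surv)
    training_c = _composite_c_index(list(sig.rules), expr_a, surv_a)
    if audit is not None:
        audit.n_genes = len(genes)
        audit.n_pairs_enumerated = len(pairs)
        audit.n_pairs_set1 = len(set1)
        audit.n_rules_signature = len(sig)
        audit.training_c_index = training_c
    logger.info(
        "build_gps cascade: %d genes -> %d pairs -> %d Set1 -> %d signature rules",
        len(genes), len(pairs), len(set1), len(sig),
    )
    return sig
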