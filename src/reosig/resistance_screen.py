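"""Stage 1: drug-resistance candidate genes and their clinical relevance.

A gene panel is screened against cell-line drug sensitivity (Spearman vs
GI50), the survivors are filtered by univariate Cox association with
relapse-free survival in treated patients, and the sign agreement between
the two screens is summarized by the concordance score s/k with a cumulative
binomial significance at p_e = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np

from . import stats_core
from .io_model import (
    DrugSensitivity,
    ExpressionMatrix,
    GI50Scale,
    ReosigError,
    SurvivalData,
)
from .stats_core import ConstantInputError

logger = logging.getLogger("reosig")


class SignConvention(str, Enum):
    """Which sign agreement counts as concordant.

    ``GI50_EQUALS_RISK`` (default): a gene is concordant when its GI50
    correlation sign equals its Cox hazard sign — genes whose expression
    tracks resistance (higher GI50) also track higher relapse hazard, i.e.
    positively GI50-correlated genes are negatively RFS-correlated.
    ``MIRRORED`` flips the rule.
    """

    GI50_EQUALS_RISK = "gi50_equals_risk"
    MIRRORED = "mirrored"


@dataclass
class GeneScreenRecord:
    """Per-gene screen summary across the cell-line and clinical stages."""

    gene_id: str
    rho_gi50: float = float("nan")
    p_gi50: float = float("nan")
    cox_beta: float = float("nan")
    p_rfs: float = float("nan")
    fdr_rfs: float = float("nan")

    @property
    def sign_gi50(self) -> int:
        return int(np.sign(self.rho_gi50))

    @property
    def sign_risk(self) -> int:
        return int(np.sign(self.cox_beta))


@dataclass
class ConcordanceResult:
    """Sign-agreement summary: s concordant genes of k overlapping."""

    k: int
    s: int
    score: float
    p_binomial: float

    def __post_init__(self) -> None:
        if not (0 <= self.s <= self.k):
            raise ReosigError("require 0 <= s <= k")


def screen_gi50_genes(
    expr: ExpressionMatrix,
    sens: DrugSensitivity,
    alpha: float = 0.05,
) -> List[GeneScreenRecord]:
    """Select genes whose expression correlates with GI50 across cell lines.

    Spearman correlation per gene over the shared cell lines; genes with
    two-sided p < ``alpha`` are retained with rho and its sign.  When the
    sensitivity values are on the -log10 GI50 scale the stored sign is
    flipped so records always carry the GI50-scale sign.  Constant genes are
    skipped with a warning.
    """
    shared = [c for c in expr.sample_ids if c in set(sens.cell_line_ids)]
    if len(shared) < 4:
        raise ReosigError(
            f"need >= 4 shared cell lines between expression and sensitivity, got {len(shared)}"
        )
    logger.info("GI50 screen: %d shared cell lines", len(shared))
    idx = {c: i for i, c in enumerate(sens.cell_line_ids)}
    y = sens.gi50[[idx[c] for c in shared]]
    flip = -1.0 if sens.scale is GI50Scale.NEG_LOG10_GI50 else 1.0
    sub = expr.values[shared]
    records: List[GeneScreenRecord] = []
    n_constant = 0
    for gene in sub.index:
        x = sub.loc[gene].to_numpy(dtype=float)
        mask = np.isfinite(x)
        if mask.sum() < 4:
            n_constant += 1
            continue
        try:
            res = stats_core.spearman(x[mask], y[mask])
        except ConstantInputError:
            n_constant += 1
            continue
        if res.p_value < alpha:
            records.append(
                GeneScreenRecord(
                    gene_id=str(gene),
                    rho_gi50=flip * res.effect,
                    p_gi50=res.p_value,
                )
            )
    if n_constant:
        logger.warning("GI50 screen: skipped %d constant/sparse genes", n_constant)
    logger.info(
        "GI50 screen: %d/%d genes pass p < %g", len(records), expr.shape[0], alpha
    )
    return records


def screen_rfs_genes(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    candidates: Iterable[str],
    fdr: float = 0.20,
    prior: Optional[Mapping[str, GeneScreenRecord]] = None,
) -> List[GeneScreenRecord]:
    """Filter candidate genes by univariate Cox association with RFS.

    One Cox fit per candidate gene on its continuous expression values;
    Benjamini-Hochberg correction within the candidate list only; genes with
    FDR below the threshold are retained with the sign of beta.  ``prior``
    optionally carries the GI50-screen fields forward into the output
    records.  Non-converged fits are excluded and logged.
    """
    candidates = [g for g in candidates]
    gene_set = set(expr.gene_ids)
    missing = [g for g in candidates if g not in gene_set]
    if missing:
        raise ReosigError(f"candidate genes absent from expression matrix: {missing[:5]}")
    if not candidates:
        return []
    sample_idx = {s: i for i, s in enumerate(surv.sample_ids)}
    cols = [s for s in expr.sample_ids if s in sample_idx]
    surv_use = surv.subset(cols)
    sub = expr.values.loc[candidates, cols]
    tested: List[GeneScreenRecord] = []
    pvals: List[float] = []
    n_skipped = 0
    for gene in candidates:
        x = sub.loc[gene].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            n_skipped += 1
            continue
        try:
            fit = stats_core.cox_univariate(surv_use, x)
        except (ConstantInputError, ReosigError):
            n_skipped += 1
            continue
        if not fit.converged:
            n_skipped += 1
            continue
        base = prior.get(gene) if prior else None
        tested.append(
            GeneScreenRecord(
                gene_id=gene,
                rho_gi50=base.rho_gi50 if base else float("nan"),
                p_gi50=base.p_gi50 if base else float("nan"),
                cox_beta=fit.beta,
                p_rfs=fit.p_value,
            )
        )
        pvals.append(fit.p_value)
    if n_skipped:
        logger.warning("RFS screen: excluded %d genes (constant/missing/non-converged)", n_skipped)
    if not tested:
        return []
    adjusted = stats_core.bh_adjust(pvals)
    out = []
    for rec, q in zip(tested, adjusted):
        rec.fdr_rfs = float(q)
        if q < fdr:
            out.append(rec)
    logger.info(
        "RFS screen: %d/%d candidates pass FDR < %g", len(out), len(tested), fdr
    )
    return out


def concordance(
    records_a: Sequence[GeneScreenRecord],
    records_b: Sequence[GeneScreenRecord],
    convention: SignConvention = SignConvention.GI50_EQUALS_RISK,
) -> ConcordanceResult:
    """Sign concordance between the GI50 and survival screens.

    Records are joined by gene id; a gene is concordant iff its GI50 sign
    equals its hazard sign (default convention).  Each record list may carry
    either field; the GI50 sign is taken from whichever record has it, and
    likewise for the hazard sign.
    """
    convention = SignConvention(convention)
    a_by_gene = {r.gene_id: r for r in records_a}
    b_by_gene = {r.gene_id: r for r in records_b}
    overlap = sorted(set(a_by_gene) & set(b_by_gene))
    if not overlap:
        raise ReosigError("no overlapping genes between the two screen lists")
    s = 0
    k = 0
    for gene in overlap:
        ra, rb = a_by_gene[gene], b_by_gene[gene]
        sign_gi50 = ra.sign_gi50 if ra.sign_gi50 != 0 else rb.sign_gi50
        sign_risk = rb.sign_risk if rb.sign_risk != 0 else ra.sign_risk
        if sign_gi50 == 0 or sign_risk == 0:
            continue
        k += 1
        agree = sign_gi50 == sign_risk
        if convention is SignConvention.MIRRORED:
            agree = not agree
        if agree:
            s += 1
    if k == 0:
        raise ReosigError("no genes carrying both screen signs")
    return ConcordanceResult(
        k=k, s=s, score=s / k, p_binomial=stats_core.binom_upper_tail(s, k, 0.5)
    )


def deg_concordance(
    degs_a: Mapping[str, str], degs_b: Mapping[str, str]
) -> ConcordanceResult:
    """Direction concordance of two DEG maps (gene -> 'up'/'down').

    Directions are relative to a fixed group ordering (high-risk vs
    low-risk); a gene is concordant iff both maps give the same direction.
    """
    overlap = sorted(set(degs_a) & set(degs_b))
    if not overlap:
        raise ReosigError("no overlapping genes between the two DEG lists")
    valid = {"up", "down"}
    for g in overlap:
        if degs_a[g] not in valid or degs_b[g] not in valid:
            raise ReosigError(f"direction for gene {g!r} must be 'up' or 'down'")
    k = len(overlap)
    s = sum(1 for g in overlap if degs_a[g] == degs_b[g])
    return ConcordanceResult(
        k=k, s=s, score=s / k, p_binomial=stats_core.binom_upper_tail(s, k, 0.5)
    )
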