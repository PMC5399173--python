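"""Apply a gene-pair signature to expression data one sample at a time.

Each rule compares two genes within a single sample (Ga > Gb) and votes for
high or low risk; the sample is called high risk when at least half of the
non-abstaining rules vote high (ties go to high).  Because every comparison
is internal to the sample, calls are invariant to strictly monotone
per-sample transforms and need no between-sample normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .io_model import (
    ClinicalCovariates,
    DrugSensitivity,
    ExpressionMatrix,
    GenePairRule,
    GenePairSignature,
    PairDirection,
    ReosigError,
    SurvivalData,
)

logger = logging.getLogger("reosig")


class UnclassifiableSampleError(ReosigError):
    """Too many rules abstained to produce a trustworthy risk call."""


@dataclass
class RiskCall:
    """Majority-vote outcome for one sample."""

    sample_id: str
    votes_high: int
    votes_low: int
    votes_abstain: int
    label: Optional[str]  # "high" / "low"; None when unclassifiable

    def __post_init__(self) -> None:
        if self.label not in ("high", "low", None):
            raise ReosigError(f"bad risk label {self.label!r}")


#: The published six-rule signature (11 genes).  All orderings are risk
#: factors (beta > 0): a sample showing >= 3 of these orderings is high risk.
SIX_GPS = GenePairSignature(
    rules=[
        GenePairRule("CHTOP", "CAPN2", beta=1.22, p_value=6.37e-05, fdr=1.89e-03,
                     c_index_solo=0.63, direction=PairDirection.A_GT_B_RISKY),
        GenePairRule("MRPL4", "AXL", beta=0.98, p_value=4.12e-05, fdr=1.70e-03,
                     c_index_solo=0.60, direction=PairDirection.A_GT_B_RISKY),
        GenePairRule("SLC19A1", "NREP", beta=1.09, p_value=2.19e-03, fdr=1.43e-02,
                     c_index_solo=0.59, direction=PairDirection.A_GT_B_RISKY),
        GenePairRule("PUS1", "LTBP2", beta=0.61, p_value=8.74e-03, fdr=3.39e-02,
                     c_index_solo=0.57, direction=PairDirection.A_GT_B_RISKY),
        GenePairRule("MCM2", "IFRD2", beta=0.66, p_value=1.18e-02, fdr=3.89e-02,
                     c_index_solo=0.57, direction=PairDirection.A_GT_B_RISKY),
        GenePairRule("SLC19A1", "WWC2", beta=1.20, p_value=9.92e-05, fdr=2.41e-03,
                     c_index_solo=0.56, direction=PairDirection.A_GT_B_RISKY),
    ],
    provenance="published 6-gene-pair 5-FU prognostic signature",
)


def classify_sample(sig: GenePairSignature, sample: Mapping[str, float],
                    sample_id: str = "") -> RiskCall:
    """Vote all rules of a signature within one sample.

    A rule abstains when either gene is absent or missing; an expression tie
    Ga == Gb counts as "not Ga > Gb".  The call is high risk iff the high
    votes are at least half of the non-abstaining votes.  A sample abstaining
    on more than half of the rules, or on all of them, is unclassifiable.
    """
    votes_high = votes_low = votes_abstain = 0
    for rule in sig.rules:
        ga = sample.get(rule.gene_a)
        gb = sample.get(rule.gene_b)
        if ga is None or gb is None or not np.isfinite(ga) or not np.isfinite(gb):
            votes_abstain += 1
            continue
        indicator = ga > gb  # strict; ties are "not greater"
        risky = indicator if rule.direction is PairDirection.A_GT_B_RISKY else not indicator
        if risky:
            votes_high += 1
        else:
            votes_low += 1
    n_active = votes_high + votes_low
    if n_active == 0 or votes_abstain * 2 > len(sig.rules):
        raise UnclassifiableSampleError(
            f"sample {sample_id or '<unnamed>'}: {votes_abstain}/{len(sig.rules)} rules abstained"
        )
    label = "high" if 2 * votes_high >= n_active else "low"
    return RiskCall(sample_id, votes_high, votes_low, votes_abstain, label)


def classify_cohort(sig: GenePairSignature, expr: ExpressionMatrix) -> List[RiskCall]:
    """Independent per-sample calls over a cohort.

    Unclassifiable samples are returned with ``label=None`` (never silently
    dropped); summary counts are logged.
    """
    calls: List[RiskCall] = []
    gene_rows: Dict[str, np.ndarray] = {}
    for g in sig.genes:
        if g in expr.values.index:
            gene_rows[g] = expr.values.loc[g].to_numpy(dtype=float)
    n_unclassifiable = 0
    for j, sample_id in enumerate(expr.sample_ids):
        profile = {g: row[j] for g, row in gene_rows.items()}
        try:
            calls.append(classify_sample(sig, profile, sample_id))
        except UnclassifiableSampleError:
            n_unclassifiable += 1
            calls.append(RiskCall(sample_id, 0, 0, len(sig.rules), None))
    n_high = sum(1 for c in calls if c.label == "high")
    n_low = sum(1 for c in calls if c.label == "low")
    logger.info(
        "classified %d samples: %d high risk, %d low risk, %d unclassifiable",
        len(calls), n_high, n_low, n_unclassifiable,
    )
    return calls


def calls_to_labels(calls: Sequence[RiskCall]) -> pd.Series:
    """RiskCall list -> sample-indexed label series (NaN for unclassifiable)."""
    return pd.Series(
        {c.sample_id: c.label for c in calls}, dtype="object"
    )


def rank_difference_diagnostic(sig: GenePairSignature, expr: ExpressionMatrix) -> pd.DataFrame:
    """Mean within-sample rank gap per rule.

    For each rule, the mean over samples of \\|rank(Ga) - rank(Gb)\\| where
    ranks are computed within each sample over all genes of the supplied
    matrix (average ranks for ties).  Large gaps indicate orderings that are
    hard to flip by measurement noise; the rank universe size is reported
    alongside because the gap scales with it.
    """
    from scipy.stats import rankdata

    arr = expr.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, arr)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for rule in sig.rules:
        if rule.gene_a not in gene_pos or rule.gene_b not in gene_pos:
            rows.append((rule.gene_a, rule.gene_b, float("nan")))
            continue
        gap = np.abs(ranks[gene_pos[rule.gene_a]] - ranks[gene_pos[rule.gene_b]])
        rows.append((rule.gene_a, rule.gene_b, float(np.nanmean(gap))))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mean_rank_gap"])
    df["rank_universe"] = expr.shape[0]
    logger.info("rank-difference diagnostic over a universe of %d genes", expr.shape[0])
    return df


@dataclass
class StratificationReport:
    """Survival contrast of the two risk groups."""

    n_high: int
    n_low: int
    km_high: stats_core.KMEstimate
    km_low: stats_core.KMEstimate
    logrank: Optional[stats_core.TestResult]
    cox: Optional[stats_core.CoxFit]
    c_index: Optional[float]
    multivariate: Optional[List[stats_core.CoxFit]] = None

    def summary(self) -> Dict[str, float]:
        out = {"n_high": self.n_high, "n_low": self.n_low}
        if self.logrank is not None:
            out["logrank_p"] = self.logrank.p_value
        if self.cox is not None:
            out.update(
                hr=self.cox.hr, hr_ci_low=self.cox.ci95[0], hr_ci_high=self.cox.ci95[1],
                cox_p=self.cox.p_value,
            )
        if self.c_index is not None:
            out["c_index"] = self.c_index
        return out


_COVARIATE_CODING = {
    "stage": {"II": 0.0, "III": 1.0},
    "gender": {"female": 0.0, "male": 1.0},
    "tumor_location": {"proximal": 0.0, "distal": 1.0},
    "mmr_status": {"pMMR": 0.0, "dMMR": 1.0},
    "braf_mut": {"WT": 0.0, "M": 1.0},
    "kras_mut": {"WT": 0.0, "M": 1.0},
}


def stratify_and_report(
    calls: Sequence[RiskCall],
    surv: SurvivalData,
    covariates: Optional[ClinicalCovariates] = None,
    age_cut: float = 70.0,
) -> StratificationReport:
    """KM curves, log-rank, Cox HR of the high-risk label and its C-index.

    When covariates are supplied, a multivariate Cox model adjusts the label
    for stage, gender, dichotomized age, tumor location, MMR status and
    BRAF/KRAS mutation (whichever columns are present).
    """
    labels = calls_to_labels(calls).dropna()
    shared = [s for s in surv.sample_ids if s in labels.index]
    surv_use = surv.subset(shared)
    lab = np.array([1.0 if labels[s] == "high" else 0.0 for s in shared])
    n_high = int(lab.sum())
    n_low = len(lab) - n_high
    km_high = stats_core.km_estimate(surv_use.subset([s for s, l in zip(shared, lab) if l == 1.0])) \
        if n_high else None
    km_low = stats_core.km_estimate(surv_use.subset([s for s, l in zip(shared, lab) if l == 0.0])) \
        if n_low else None
    if n_high == 0 or n_low == 0:
        logger.warning("single-group classification: survival contrast not applicable")
        return StratificationReport(n_high, n_low, km_high, km_low, None, None, None)
    lr = stats_core.logrank(surv_use, lab.astype(int))
    cox = stats_core.cox_univariate(surv_use, lab)
    ci = stats_core.c_index(surv_use, lab)
    multivariate = None
    if covariates is not None:
        design = pd.DataFrame({"risk_high": lab}, index=shared)
        cov = covariates.table.reindex(shared)
        for col, coding in _COVARIATE_CODING.items():
            if col in cov.columns:
                design[col] = cov[col].map(coding)
        if "age" in cov.columns:
            age = pd.to_numeric(cov["age"], errors="coerce")
            design[f"age_gt_{age_cut:g}"] = (age > age_cut).astype(float).where(age.notna())
        multivariate = stats_core.cox_multivariate(surv_use, design)
    return StratificationReport(n_high, n_low, km_high, km_low, lr, cox, ci, multivariate)


@dataclass
class CellLineSplit:
    """Resistant/sensitive split of a cell-line panel with its GI50 contrast."""

    resistant: List[str]
    sensitive: List[str]
    unclassifiable: List[str]
    gi50_test: Optional[stats_core.TestResult]
    mean_gi50_resistant: float
    mean_gi50_sensitive: float


def classify_cell_lines(
    sig: GenePairSignature, expr: ExpressionMatrix, sens: DrugSensitivity
) -> CellLineSplit:
    """Call each cell line resistant (high-risk) or sensitive and compare GI50.

    The comparison is a two-sided Wilcoxon rank-sum test on the stored
    sensitivity values of the two groups; when one group is empty the test is
    skipped with a warning.
    """
    calls = classify_cohort(sig, expr)
    resistant = [c.sample_id for c in calls if c.label == "high"]
    sensitive = [c.sample_id for c in calls if c.label == "low"]
    unclassifiable = [c.sample_id for c in calls if c.label is None]
    idx = {c: i for i, c in enumerate(sens.cell_line_ids)}
    gi_r = np.array([sens.gi50[idx[c]] for c in resistant if c in idx])
    gi_s = np.array([sens.gi50[idx[c]] for c in sensitive if c in idx])
    test = None
    if gi_r.size and gi_s.size:
        test = stats_core.wilcoxon_ranksum(gi_r, gi_s)
    else:
        logger.warning("all cell lines classified one way: GI50 comparison skipped")
    return CellLineSplit(
        resistant=resistant,
        sensitive=sensitive,
        unclassifiable=unclassifiable,
        gi50_test=test,
        mean_gi50_resistant=float(gi_r.mean()) if gi_r.size else float("nan"),
        mean_gi50_sensitive=float(gi_s.mean()) if gi_s.size else float("nan"),
    )
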