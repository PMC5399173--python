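"""Stage 3: transcriptional, genomic and epigenomic contrasts of risk groups.

Given high/low risk labels, this module detects differentially expressed
genes (Wilcoxon rank-sum + BH), tests pathway enrichment (hypergeometric),
contrasts binary alteration frequencies (Fisher), summarizes directional
bias (cumulative binomial), computes per-pathway alteration prevalence,
screens expression-vs-omics correlations (Spearman + BH with a sign filter),
tests direct PPI-link enrichment against anchor genes, and contrasts
MSI-High frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import stats_core
from .io_model import (
    ExpressionMatrix,
    GeneSetCollection,
    PPINetwork,
    ReosigError,
)
from .stats_core import ConstantInputError

logger = logging.getLogger("reosig")


@dataclass
class DEGRecord:
    """One differentially expressed gene between the risk groups."""

    gene_id: str
    p_value: float
    fdr: float
    direction: str  # "up_in_high" / "down_in_high"
    effect: float   # median(high) - median(low)

    def __post_init__(self) -> None:
        if self.direction not in ("up_in_high", "down_in_high"):
            raise ReosigError(f"bad DEG direction {self.direction!r}")
        if self.effect > 0 and self.direction != "up_in_high":
            raise ReosigError("direction inconsistent with median difference")
        if self.effect < 0 and self.direction != "down_in_high":
            raise ReosigError("direction inconsistent with median difference")


@dataclass
class FrequencyContrast:
    """2x2 frequency comparison of one binary feature between groups."""

    feature_id: str
    count_high: int
    n_high: int
    count_low: int
    n_low: int
    p_fisher: float
    fdr: float
    higher_in: str  # "high" / "low"

    def __post_init__(self) -> None:
        if self.count_high > self.n_high or self.count_low > self.n_low:
            raise ReosigError("feature counts exceed group sizes")
        if self.higher_in not in ("high", "low"):
            raise ReosigError(f"bad higher_in {self.higher_in!r}")

    @property
    def freq_high(self) -> float:
        return self.count_high / self.n_high if self.n_high else float("nan")

    @property
    def freq_low(self) -> float:
        return self.count_low / self.n_low if self.n_low else float("nan")


@dataclass
class PathwayPrevalence:
    """Fraction of samples with >= 1 altered gene in a pathway."""

    pathway: str
    n_samples_altered: int
    n_samples: int
    prevalence: float  # NaN when the pathway has no genes in the matrix

    def __post_init__(self) -> None:
        if np.isfinite(self.prevalence) and not (0.0 <= self.prevalence <= 1.0):
            raise ReosigError("prevalence outside [0,1]")


def _split_labels(labels: Mapping[str, str], sample_ids: Sequence[str]):
    high = [s for s in sample_ids if labels.get(s) == "high"]
    low = [s for s in sample_ids if labels.get(s) == "low"]
    return high, low


def detect_degs(
    expr: ExpressionMatrix, labels: Mapping[str, str], fdr: float = 0.05
) -> List[DEGRecord]:
    """Wilcoxon rank-sum DEGs between the high- and low-risk groups.

    BH correction is applied over all genes actually tested; constant genes
    are skipped.  Direction is the sign of the median difference (high minus
    low).
    """
    high, low = _split_labels(labels, expr.sample_ids)
    if len(high) < 2 or len(low) < 2:
        raise ReosigError("detect_degs needs >= 2 samples per group")
    arr_h = expr.values[high].to_numpy(dtype=float)
    arr_l = expr.values[low].to_numpy(dtype=float)
    genes = expr.gene_ids
    tested: List[int] = []
    pvals: List[float] = []
    effects: List[float] = []
    for i in range(len(genes)):
        a = arr_h[i][np.isfinite(arr_h[i])]
        b = arr_l[i][np.isfinite(arr_l[i])]
        if a.size < 2 or b.size < 2 or (np.ptp(np.concatenate([a, b])) == 0):
            continue
        res = stats_core.wilcoxon_ranksum(a, b)
        tested.append(i)
        pvals.append(res.p_value)
        effects.append(float(np.median(a) - np.median(b)))
    if not tested:
        return []
    adjusted = stats_core.bh_adjust(pvals)
    out: List[DEGRecord] = []
    for i, p, q, eff in zip(tested, pvals, adjusted, effects):
        if q < fdr and eff != 0:
            out.append(
                DEGRecord(
                    gene_id=genes[i],
                    p_value=float(p),
                    fdr=float(q),
                    direction="up_in_high" if eff > 0 else "down_in_high",
                    effect=eff,
                )
            )
    logger.info("DEG detection: %d/%d tested genes pass FDR < %g", len(out), len(tested), fdr)
    return out


def degs_to_direction_map(degs: Sequence[DEGRecord]) -> Dict[str, str]:
    """DEG records -> gene -> 'up'/'down' map (for cross-dataset concordance)."""
    return {d.gene_id: ("up" if d.direction == "up_in_high" else "down") for d in degs}


def enrich_pathways(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list across a set collection.

    The universe is the collection's explicit universe when given, else the
    union of its sets; the gene list is restricted to the universe first.
    """
    universe = collection.effective_universe()
    hits = set(gene_list) & universe
    if not hits:
        raise ReosigError("gene list has no overlap with the enrichment universe")
    rows = []
    for name, genes in collection.sets.items():
        genes_in_universe = genes & universe
        overlap = len(hits & genes_in_universe)
        res = stats_core.hypergeom_enrich(
            overlap, len(genes_in_universe), len(hits), len(universe)
        )
        rows.append((name, overlap, len(genes_in_universe), res.p_value))
    df = pd.DataFrame(rows, columns=["pathway", "hits", "set_size", "p_value"])
    df["fdr"] = stats_core.bh_adjust(df["p_value"].to_numpy())
    df["enriched"] = df["fdr"] < fdr
    logger.info(
        "pathway enrichment: %d/%d sets pass FDR < %g (list of %d genes, universe %d)",
        int(df["enriched"].sum()), len(df), fdr, len(hits), len(universe),
    )
    return df.sort_values("p_value").reset_index(drop=True)


def binarize_cna(cna: pd.DataFrame, mode: str = "any") -> pd.DataFrame:
    """GISTIC-style calls -> binary altered/unaltered.

    ``mode='any'`` (default): any gain or loss (|call| >= 1) counts as
    altered; ``mode='strict'``: only high-level events (|call| == 2).
    """
    if mode == "any":
        return (cna.abs() >= 1).astype(int)
    if mode == "strict":
        return (cna.abs() >= 2).astype(int)
    raise ReosigError(f"unknown CNA binarization mode {mode!r}")


def contrast_frequencies(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    threshold: float = 0.05,
    correction: str = "bh",
) -> List[FrequencyContrast]:
    """Per-feature Fisher contrast of binary alteration frequencies.

    ``correction='bh'`` thresholds the BH-adjusted p (used for CNA regions);
    ``correction='none'`` thresholds the raw p (used for mutations).
    Zero-variance features are skipped.
    """
    if correction not in ("bh", "none"):
        raise ReosigError(f"unknown correction {correction!r}")
    vals = features.to_numpy()
    finite = vals[~pd.isna(vals)]
    if not np.isin(finite, [0, 1]).all():
        raise ReosigError("feature matrix must be binary (0/1)")
    high, low = _split_labels(labels, [str(c) for c in features.columns])
    if not high or not low:
        raise ReosigError("both risk groups must be non-empty")
    sub_h = features[high]
    sub_l = features[low]
    tested = []
    for feat in features.index:
        h = sub_h.loc[feat].dropna()
        l = sub_l.loc[feat].dropna()
        ch, nh = int(h.sum()), len(h)
        cl, nl = int(l.sum()), len(l)
        if nh == 0 or nl == 0 or (ch + cl == 0) or (ch + cl == nh + nl):
            continue
        res = stats_core.fisher_exact_2x2([[ch, nh - ch], [cl, nl - cl]])
        tested.append((str(feat), ch, nh, cl, nl, res.p_value))
    if not tested:
        return []
    pvals = [t[5] for t in tested]
    adjusted = stats_core.bh_adjust(pvals)
    out = []
    for (feat, ch, nh, cl, nl, p), q in zip(tested, adjusted):
        crit = q if correction == "bh" else p
        if crit < threshold:
            out.append(
                FrequencyContrast(
                    feature_id=feat,
                    count_high=ch, n_high=nh, count_low=cl, n_low=nl,
                    p_fisher=float(p), fdr=float(q),
                    higher_in="high" if ch / nh >= cl / nl else "low",
                )
            )
    logger.info(
        "frequency contrast: %d/%d features pass %s threshold %g",
        len(out), len(tested), correction, threshold,
    )
    return out


def direction_bias(contrasts: Sequence[FrequencyContrast]):
    """Majority-side bias of significant contrasts.

    s = number of contrasts on the majority side, k = total; upper-tail
    binomial p at p_e = 0.5.
    """
    from .resistance_screen import ConcordanceResult

    if not contrasts:
        raise ReosigError("direction_bias requires at least one contrast")
    k = len(contrasts)
    n_high = sum(1 for c in contrasts if c.higher_in == "high")
    s = max(n_high, k - n_high)
    return ConcordanceResult(
        k=k, s=s, score=s / k, p_binomial=stats_core.binom_upper_tail(s, k, 0.5)
    )


def pathway_prevalence(
    altered: pd.DataFrame, collection: GeneSetCollection
) -> List[PathwayPrevalence]:
    """Per-pathway fraction of samples with >= 1 altered member gene.

    ``altered`` is a binary gene x sample matrix already restricted to the
    group of interest; a pathway with no genes in the matrix is reported
    with NaN prevalence (not assessable).
    """
    vals = altered.to_numpy()
    finite = vals[~pd.isna(vals)]
    if not np.isin(finite, [0, 1]).all():
        raise ReosigError("altered matrix must be binary (0/1)")
    n_samples = altered.shape[1]
    genes_present = set(map(str, altered.index))
    out = []
    for name, genes in collection.sets.items():
        members = sorted(genes & genes_present)
        if not members:
            out.append(PathwayPrevalence(name, 0, n_samples, float("nan")))
            continue
        hit = (altered.loc[members].fillna(0).sum(axis=0) > 0).sum()
        out.append(PathwayPrevalence(name, int(hit), n_samples, int(hit) / n_samples))
    return out


def expr_omics_correlation(
    expr: ExpressionMatrix,
    omics: pd.DataFrame,
    fdr: float = 0.05,
    sign_filter: str = "positive",
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene Spearman screen of expression against an omics layer.

    Correlations run across the shared samples; BH is applied over the genes
    tested, the FDR threshold is applied, and then the requested sign filter
    (``'positive'`` for copy-number dosage, ``'negative'`` for promoter
    methylation).  Returns one row per passing gene.
    """
    if sign_filter not in ("positive", "negative"):
        raise ReosigError(f"sign_filter must be 'positive' or 'negative', got {sign_filter!r}")
    shared_samples = [s for s in expr.sample_ids if s in set(map(str, omics.columns))]
    if samples is not None:
        requested = set(samples)
        shared_samples = [s for s in shared_samples if s in requested]
    if len(shared_samples) < 4:
        raise ReosigError(f"need >= 4 aligned samples, got {len(shared_samples)}")
    shared_genes = [g for g in expr.gene_ids if g in set(map(str, omics.index))]
    logger.info(
        "expression/omics correlation: %d shared genes, %d shared samples",
        len(shared_genes), len(shared_samples),
    )
    e = expr.values.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    o = omics.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(shared_genes):
        mask = np.isfinite(e[i]) & np.isfinite(o[i])
        if mask.sum() < 4:
            continue
        try:
            res = stats_core.spearman(e[i][mask], o[i][mask])
        except ConstantInputError:
            continue
        rows.append((gene, res.effect, res.p_value))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "rho", "p_value", "fdr"])
    df = pd.DataFrame(rows, columns=["gene_id", "rho", "p_value"])
    df["fdr"] = stats_core.bh_adjust(df["p_value"].to_numpy())
    passed = df[df["fdr"] < fdr]
    if sign_filter == "positive":
        passed = passed[passed["rho"] > 0]
    else:
        passed = passed[passed["rho"] < 0]
    logger.info(
        "expression/omics correlation: %d/%d genes pass FDR < %g with %s rho",
        len(passed), len(df), fdr, sign_filter,
    )
    return passed.reset_index(drop=True)


def ppi_link_enrichment(
    set_a: Iterable[str],
    anchors: Iterable[str],
    network: PPINetwork,
    comparison: Iterable[str],
) -> stats_core.TestResult:
    """Fisher test of direct PPI adjacency to anchor genes.

    Compares the fraction of ``set_a`` genes with >= 1 direct edge to an
    anchor against the same fraction in the explicit ``comparison`` set;
    both sets are first restricted to network nodes.
    """
    nodes = network.nodes
    a = sorted(set(set_a) & nodes)
    cmp_set = sorted((set(comparison) & nodes) - set(a))
    anchor_set = set(anchors) & nodes
    if not anchor_set:
        raise ReosigError("no anchor genes present in the network")
    if not a or not cmp_set:
        raise ReosigError("a gene set is empty after restriction to network nodes")

    def n_linked(genes):
        return sum(1 for g in genes if network.neighbors(g) & anchor_set)

    la, lc = n_linked(a), n_linked(cmp_set)
    res = stats_core.fisher_exact_2x2([[la, len(a) - la], [lc, len(cmp_set) - lc]])
    res.metadata.update(
        frac_set=la / len(a), frac_comparison=lc / len(cmp_set),
        n_set=len(a), n_comparison=len(cmp_set),
    )
    return res


def msi_contrast(msi: Mapping[str, str], labels: Mapping[str, str]) -> FrequencyContrast:
    """Fisher contrast of MSI-High frequency between the risk groups.

    MSI categories are binarized as MSI-High vs {MSI-Low, MSS}.
    """
    samples = [s for s in msi if labels.get(s) in ("high", "low")]
    high = [s for s in samples if labels[s] == "high"]
    low = [s for s in samples if labels[s] == "low"]
    if not high or not low:
        raise ReosigError("both risk groups must be represented in the MSI data")
    ch = sum(1 for s in high if msi[s] == "MSI-High")
    cl = sum(1 for s in low if msi[s] == "MSI-High")
    res = stats_core.fisher_exact_2x2(
        [[ch, len(high) - ch], [cl, len(low) - cl]]
    )
    return FrequencyContrast(
        feature_id="MSI-High",
        count_high=ch, n_high=len(high), count_low=cl, n_low=len(low),
        p_fisher=res.p_value, fdr=res.p_value,
        higher_in="high" if ch / len(high) >= cl / len(low) else "low",
    )
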