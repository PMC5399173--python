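"""Synthetic cohorts, cell panels and omics layers with planted structure.

The generator produces every input the pipeline consumes, with known ground
truth, so each stage is testable end to end without downloads:

* tumor cohorts whose relapse hazard follows a proportional-hazards model
  driven by the within-sample orderings of planted gene pairs, with
  independent exponential censoring;
* a cell-line panel in which a subset of genes is monotonically coupled to
  a latent resistance score that also produces the GI50 readout;
* group-differential copy-number region frequencies, mutation frequencies
  and MSI-High frequencies, and promoter methylation beta values negatively
  coupled to expression;
* strictly monotone per-sample distortions (which provably preserve all
  within-sample orderings) and additive gene-wise batch shifts (which may
  not — they are used to measure robustness, not invariance).

Everything is deterministic given ``SimConfig.seed``; per-component
substreams are derived from it with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .io_model import (
    DrugSensitivity,
    ExpressionMatrix,
    GI50Scale,
    OmicsProfileBundle,
    ReosigError,
    SurvivalData,
)

logger = logging.getLogger("reosig")

# printed-style per-region (high, low) alteration frequencies: a strong
# amplification block, a deletion block and null background regions
_DEFAULT_CNA_FREQS = (
    (0.956, 0.435),
    (0.956, 0.435),
    (0.934, 0.435),
    (0.879, 0.391),
    (0.60, 0.30),
    (0.40, 0.40),
    (0.35, 0.35),
    (0.30, 0.30),
)
# mutations enriched in the low-risk group plus null genes
_DEFAULT_MUT_FREQS = tuple([(0.04, 0.28)] * 8 + [(0.10, 0.10)] * 8)


@dataclass
class SimConfig:
    """Study-condition parameters for all simulators.

    Defaults describe the reference scenario used throughout the test
    suite: a 300-sample cohort with six planted reversal gene pairs (each
    risky ordering adds log 3 to the log hazard) among 400 noise genes, a
    58-line cell panel with 30 GI50-coupled genes, and two 90-sample risk
    groups for the omics layers.
    """

    n_genes: int = 412                      # total genes incl. planted pair genes
    n_samples: int = 300
    n_planted_pairs: int = 6
    pair_effect: float = math.log(3.0)      # log-hazard per risky ordering
    baseline_hazard: float = 0.001          # events/month at zero risky orderings
    censor_rate: float = 0.025              # events/month, independent censoring
    n_cell_lines: int = 58
    gi50_coupled_genes: int = 30
    group_sizes: Tuple[int, int] = (90, 90)  # (high, low)
    cna_region_freqs: Tuple[Tuple[float, float], ...] = _DEFAULT_CNA_FREQS
    mutation_freqs: Tuple[Tuple[float, float], ...] = _DEFAULT_MUT_FREQS
    msi_high_freqs: Tuple[float, float] = (0.12, 0.28)  # (high group, low group)
    meth_coupling_strength: float = 1.0
    n_meth_coupled: int = 50
    batch_shift_sd: float = 0.5
    reversal_prevalence: Tuple[float, float] = (0.30, 0.70)  # per-pair firing range
    pair_state_noise: float = 0.8   # sd of the per-pair deviation from latent risk
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            [self.censor_rate >= 0, self.baseline_hazard > 0]
            + [0 <= f <= 1 for pair in self.cna_region_freqs for f in pair]
            + [0 <= f <= 1 for pair in self.mutation_freqs for f in pair]
            + [0 <= f <= 1 for f in self.msi_high_freqs]
        )
        if not all(probs):
            raise ReosigError("rates/frequencies must be valid probabilities")
        if min(self.n_genes, self.n_samples, self.n_cell_lines) <= 0:
            raise ReosigError("sizes must be positive")
        if self.n_planted_pairs * 2 > self.n_genes:
            raise ReosigError("planted pairs need 2 dedicated genes each")
        if self.gi50_coupled_genes > self.n_genes:
            raise ReosigError("more GI50-coupled genes than genes")

    def gene_ids(self) -> List[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def planted_pairs(self) -> List[Tuple[str, str]]:
        """Pair i uses genes (G_{2i-1}, G_{2i}); first > second is risky."""
        g = self.gene_ids()
        return [(g[2 * i], g[2 * i + 1]) for i in range(self.n_planted_pairs)]


def _streams(cfg: SimConfig, n: int, component: int) -> List[np.random.Generator]:
    children = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(component,)).spawn(n)
    return [np.random.default_rng(c) for c in children]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    planted_pairs: List[Tuple[str, str]]
    margins: np.ndarray            # per-pair ordering margin (log2 units)
    risky_state: np.ndarray        # n_pairs x n_samples binary latent states
    n_risky: np.ndarray            # per-sample count of risky orderings
    latent_risk: np.ndarray        # shared per-sample risk factor
    labels: Dict[str, str]         # sample -> "high"/"low" (majority of pairs)
    config: SimConfig = None


def simulate_cohort(cfg: SimConfig) -> Tuple[ExpressionMatrix, SurvivalData, CohortTruth]:
    """Expression + relapse-free survival with planted reversal gene pairs.

    Background expression is i.i.d. Gaussian on the log2 scale.  A shared
    per-sample latent risk factor drives the planted pairs: pair ``p``
    reverses when the risk factor plus a per-pair deviation exceeds a
    pair-specific threshold, with thresholds spread so the risky orderings
    fire in ``reversal_prevalence[0]``..``reversal_prevalence[1]`` of
    samples.  This mirrors real prognostic signatures, whose rules track a
    common biology but trigger at different points of the risk continuum,
    and it is what lets majority voting over several rules out-perform any
    single rule.  Relapse times are exponential with hazard
    ``baseline_hazard * exp(pair_effect * n_risky)`` and are censored by an
    independent exponential clock at ``censor_rate``.
    """
    from scipy.stats import norm

    rng_bg, rng_pair, rng_surv = _streams(cfg, 3, component=0)
    genes = cfg.gene_ids()
    samples = [f"S{j + 1:04d}" for j in range(cfg.n_samples)]
    values = rng_bg.normal(loc=8.0, scale=2.0, size=(cfg.n_genes, cfg.n_samples))

    pairs = cfg.planted_pairs()
    margins = rng_pair.uniform(2.5, 4.0, size=cfg.n_planted_pairs)
    risk = rng_pair.normal(0.0, 1.0, size=cfg.n_samples)
    lo, hi = cfg.reversal_prevalence
    prevalence = np.linspace(lo, hi, cfg.n_planted_pairs)
    # threshold on risk + deviation so each pair fires at its target rate
    tau = norm.ppf(1.0 - prevalence) * np.sqrt(1.0 + cfg.pair_state_noise**2)
    deviation = rng_pair.normal(0.0, cfg.pair_state_noise,
                                size=(cfg.n_planted_pairs, cfg.n_samples))
    z = (risk[None, :] + deviation > tau[:, None]).astype(int)
    for i in range(cfg.n_planted_pairs):
        # the two genes of a pair share a per-sample baseline whose spread is
        # large relative to the ordering margin: it cancels in the pair's own
        # comparison (clean reversal) but dominates comparisons with genes of
        # other pairs, so the planted information lives in the pair ordering
        center = rng_pair.normal(8.0, 3.0, size=cfg.n_samples)
        offset = np.where(z[i] == 1, margins[i] / 2.0, -margins[i] / 2.0)
        noise = rng_pair.normal(0.0, 0.3, size=(2, cfg.n_samples))
        values[2 * i] = center + offset + noise[0]       # gene a
        values[2 * i + 1] = center - offset + noise[1]   # gene b

    n_risky = z.sum(axis=0)
    rate = cfg.baseline_hazard * np.exp(cfg.pair_effect * n_risky)
    t_event = rng_surv.exponential(1.0 / rate)
    t_censor = rng_surv.exponential(1.0 / cfg.censor_rate, size=cfg.n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    labels = {
        s: ("high" if 2 * k >= cfg.n_planted_pairs else "low")
        for s, k in zip(samples, n_risky)
    }
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    surv = SurvivalData(samples, time, event)
    truth = CohortTruth(
        planted_pairs=pairs, margins=margins, risky_state=z,
        n_risky=n_risky, latent_risk=risk, labels=labels, config=cfg,
    )
    logger.info(
        "simulated cohort: %d genes x %d samples, %d planted pairs, %.0f%% events",
        cfg.n_genes, cfg.n_samples, cfg.n_planted_pairs, 100 * event.mean(),
    )
    return expr, surv, truth


@dataclass
class PanelTruth:
    """Ground truth of a simulated cell-line panel."""

    coupled_genes: List[str]
    signs: np.ndarray              # +1: expression rises with GI50 (resistance)
    latent_resistance: np.ndarray
    config: SimConfig = None


def simulate_cell_panel(cfg: SimConfig) -> Tuple[ExpressionMatrix, DrugSensitivity, PanelTruth]:
    """Cell-line expression + GI50 with a latent resistance score.

    ``gi50_coupled_genes`` genes follow ``8 + sign * r`` plus unit noise,
    where ``r`` is the latent per-line resistance score; GI50 is ``r`` plus
    noise, so coupled genes are monotonically associated with GI50 in the
    recorded sign.
    """
    (rng,) = _streams(cfg, 1, component=1)
    genes = cfg.gene_ids()
    lines = [f"CL{j + 1:03d}" for j in range(cfg.n_cell_lines)]
    r = rng.normal(0.0, 1.0, size=cfg.n_cell_lines)
    values = rng.normal(8.0, 1.0, size=(cfg.n_genes, cfg.n_cell_lines))
    signs = rng.choice([-1.0, 1.0], size=cfg.gi50_coupled_genes)
    coupled = genes[: cfg.gi50_coupled_genes]
    for i in range(cfg.gi50_coupled_genes):
        values[i] = 8.0 + signs[i] * r + rng.normal(0.0, 1.0, size=cfg.n_cell_lines)
    gi50 = r + rng.normal(0.0, 0.5, size=cfg.n_cell_lines)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=lines))
    sens = DrugSensitivity(lines, gi50, GI50Scale.GI50)
    return expr, sens, PanelTruth(coupled_genes=list(coupled), signs=signs,
                                  latent_resistance=r, config=cfg)


@dataclass
class OmicsTruth:
    """Ground truth of a simulated omics bundle."""

    cna_signal_regions: List[str]   # regions with unequal group frequencies
    mutation_signal_genes: List[str]
    meth_coupled_genes: List[str]
    config: SimConfig = None


def simulate_omics(
    cfg: SimConfig,
    labels: Dict[str, str],
    expr: Optional[ExpressionMatrix] = None,
) -> Tuple[OmicsProfileBundle, OmicsTruth]:
    """CNA / mutation / MSI / methylation layers conditioned on risk labels.

    Region-level CNA calls and gene-level mutations are Bernoulli draws with
    per-group frequencies from the config (amplified regions coded +2,
    deleted regions -2, alternating); MSI-High is Bernoulli per group.  When
    an expression matrix is supplied, the first ``n_meth_coupled`` of its
    genes receive methylation beta values ``expit(strength * (8 - x) +
    noise)``, planting the negative methylation-expression correlation.
    """
    (rng,) = _streams(cfg, 1, component=2)
    samples = list(labels)
    is_high = np.array([labels[s] == "high" for s in samples])

    regions = [f"R{i + 1:02d}" for i in range(len(cfg.cna_region_freqs))]
    cna = np.zeros((len(regions), len(samples)), dtype=int)
    signal_regions = []
    for i, (fh, fl) in enumerate(cfg.cna_region_freqs):
        p = np.where(is_high, fh, fl)
        altered = rng.random(len(samples)) < p
        cna[i] = np.where(altered, 2 if i % 2 == 0 else -2, 0)
        if fh != fl:
            signal_regions.append(regions[i])

    mut_genes = [f"M{i + 1:03d}" for i in range(len(cfg.mutation_freqs))]
    mutation = np.zeros((len(mut_genes), len(samples)), dtype=int)
    signal_genes = []
    for i, (fh, fl) in enumerate(cfg.mutation_freqs):
        p = np.where(is_high, fh, fl)
        mutation[i] = (rng.random(len(samples)) < p).astype(int)
        if fh != fl:
            signal_genes.append(mut_genes[i])

    p_msi = np.where(is_high, cfg.msi_high_freqs[0], cfg.msi_high_freqs[1])
    msi_high = rng.random(len(samples)) < p_msi
    other = rng.choice(["MSS", "MSI-Low"], size=len(samples))
    msi = pd.Series(np.where(msi_high, "MSI-High", other), index=samples)

    methylation = None
    coupled: List[str] = []
    if expr is not None and cfg.n_meth_coupled > 0:
        shared = [s for s in samples if s in set(expr.sample_ids)]
        coupled = expr.gene_ids[: cfg.n_meth_coupled]
        x = expr.values.loc[coupled, shared].to_numpy(dtype=float)
        noise = rng.normal(0.0, 0.5, size=x.shape)
        beta = expit(cfg.meth_coupling_strength * (8.0 - x) + noise)
        methylation = pd.DataFrame(beta, index=coupled, columns=shared)

    bundle = OmicsProfileBundle(
        samples=samples,
        cna=pd.DataFrame(cna, index=regions, columns=samples),
        mutation=pd.DataFrame(mutation, index=mut_genes, columns=samples),
        methylation=methylation,
        msi=msi,
    )
    truth = OmicsTruth(
        cna_signal_regions=signal_regions,
        mutation_signal_genes=signal_genes,
        meth_coupled_genes=coupled,
        config=cfg,
    )
    return bundle, truth


_MONOTONE_KINDS = ("exp", "affine-positive", "rank", "cube")


def apply_monotone_transform(expr: ExpressionMatrix, kind: str) -> ExpressionMatrix:
    """Apply a strictly monotone per-sample distortion.

    All four kinds preserve every within-sample ordering exactly, so REO
    classification and signature building must be invariant to them.
    """
    arr = expr.values.to_numpy(dtype=float)
    if kind == "exp":
        out = np.exp(arr / 4.0)  # scaled to avoid overflow on log2 data
    elif kind == "affine-positive":
        out = 2.0 * arr + 5.0
    elif kind == "rank":
        out = np.apply_along_axis(rankdata, 0, arr)
    elif kind == "cube":
        out = arr**3
    else:
        raise ReosigError(
            f"unknown/non-monotone transform kind {kind!r}; choose from {_MONOTONE_KINDS}"
        )
    return ExpressionMatrix(pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns))


def apply_batch_shift(expr: ExpressionMatrix, sd: float, seed: int) -> ExpressionMatrix:
    """Additive gene-wise offsets shared across samples (a batch effect).

    Unlike the monotone transforms this can change within-sample orderings
    of genes whose values differ by less than the shift; it is used to
    measure robustness, not invariance.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sd, size=expr.shape[0])
    out = expr.values.to_numpy(dtype=float) + offsets[:, None]
    return ExpressionMatrix(pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns))
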