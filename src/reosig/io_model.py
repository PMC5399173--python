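"""Domain types, file readers/writers and logging shared by every pipeline stage.

All tabular inputs are plain tab-delimited text; gene and sample identifiers
are opaque strings and are never remapped.  Joins across data types are by
string equality, and every alignment step logs the intersection size so that
silent sample loss cannot occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("reosig")

SIGNATURE_MAGIC = "#reosig-signature v1"

MMR_LEVELS = ("pMMR", "dMMR")
STAGE_LEVELS = ("II", "III")
MUT_LEVELS = ("WT", "M")
LOCATION_LEVELS = ("proximal", "distal")
MSI_LEVELS = ("MSI-High", "MSI-Low", "MSS")
CNA_LEVELS = (-2, -1, 0, 1, 2)


class ReosigError(ValueError):
    """Base class for validation and format errors raised by this package."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample continuous abundance matrix (log2 scale, unitless).

    Wraps a pandas DataFrame with genes on the index and samples on the
    columns.  Missing values are NaN; everything else must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
            self.values = df
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ReosigError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique().tolist())
            raise ReosigError(f"duplicate sample ids: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ReosigError(
                f"expression matrix needs >=2 genes and >=1 sample, got {df.shape}"
            )
        arr = df.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ReosigError("expression matrix contains non-finite (inf) values")
        self.values = df.astype(float)

    @property
    def gene_ids(self) -> List[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> List[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def sample_profile(self, sample_id: str) -> pd.Series:
        """Expression of one sample as a gene -> value mapping."""
        return self.values[sample_id]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)])

    def align_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        shared = [s for s in sample_ids if s in self.values.columns]
        logger.info(
            "aligning expression matrix: %d/%d requested samples found",
            len(shared), len(sample_ids),
        )
        return ExpressionMatrix(self.values[shared])


@dataclass
class SurvivalData:
    """Per-sample follow-up: time in months, event 1 = relapse, 0 = censored."""

    sample_ids: List[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ReosigError("duplicate sample ids in survival data")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ReosigError("survival fields must align with sample_ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ReosigError("survival times must be finite and >= 0")
        if not np.isin(self.event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.event).tolist()) - {0, 1})
            raise ReosigError(f"event indicator must be 0/1, found {bad}")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalData":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in sample_ids if s in idx]
        logger.info("survival subset: %d/%d samples retained", len(keep), len(sample_ids))
        return SurvivalData(
            [self.sample_ids[i] for i in keep], self.time[keep], self.event[keep]
        )


class GI50Scale(str, Enum):
    """Orientation of stored drug-sensitivity values."""

    GI50 = "gi50"
    NEG_LOG10_GI50 = "neg_log10_gi50"


@dataclass
class DrugSensitivity:
    """Per-cell-line growth-inhibition readout (GI50 or -log10 GI50)."""

    cell_line_ids: List[str]
    gi50: np.ndarray
    scale: GI50Scale = GI50Scale.GI50

    def __post_init__(self) -> None:
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise ReosigError("duplicate cell line ids")
        self.gi50 = np.asarray(self.gi50, dtype=float)
        if self.gi50.shape != (len(self.cell_line_ids),):
            raise ReosigError("gi50 values must align with cell_line_ids")
        if np.any(~np.isfinite(self.gi50)):
            raise ReosigError("gi50 values must be finite")
        self.scale = GI50Scale(self.scale)


@dataclass
class ClinicalCovariates:
    """Optional per-sample covariates drawn from closed category vocabularies.

    Unknown values are encoded as missing (NaN/None), never as a category.
    """

    table: pd.DataFrame  # index = sample ids

    VOCAB = {
        "stage": STAGE_LEVELS,
        "gender": ("female", "male"),
        "tumor_location": LOCATION_LEVELS,
        "mmr_status": MMR_LEVELS,
        "braf_mut": MUT_LEVELS,
        "kras_mut": MUT_LEVELS,
    }

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ReosigError("duplicate sample ids in clinical covariates")
        for col, levels in self.VOCAB.items():
            if col in self.table.columns:
                vals = self.table[col].dropna()
                bad = sorted(set(vals) - set(levels))
                if bad:
                    raise ReosigError(
                        f"covariate {col!r} contains values outside {levels}: {bad}"
                    )
        if "age" in self.table.columns:
            age = pd.to_numeric(self.table["age"], errors="raise")
            if (age.dropna() < 0).any():
                raise ReosigError("negative age")

    @property
    def sample_ids(self) -> List[str]:
        return [str(s) for s in self.table.index]


@dataclass
class OmicsProfileBundle:
    """Discrete CNA, binary mutation, methylation beta and MSI labels.

    Each matrix is feature x sample; every matrix's samples must be a subset
    of the declared master sample list.
    """

    samples: List[str]
    cna: Optional[pd.DataFrame] = None         # in {-2,-1,0,1,2}
    mutation: Optional[pd.DataFrame] = None    # binary
    methylation: Optional[pd.DataFrame] = None  # beta in [0,1]
    msi: Optional[pd.Series] = None            # sample -> MSI category
    region_map: Optional[Dict[str, Set[str]]] = None

    def __post_init__(self) -> None:
        master = set(self.samples)
        for name in ("cna", "mutation", "methylation"):
            df = getattr(self, name)
            if df is None:
                continue
            extra = set(map(str, df.columns)) - master
            if extra:
                raise ReosigError(f"{name} matrix has samples outside master list: {sorted(extra)[:5]}")
        if self.cna is not None:
            vals = self.cna.to_numpy()
            finite = vals[~pd.isna(vals)]
            if not np.isin(finite.astype(int), CNA_LEVELS).all() or not np.allclose(
                finite, finite.astype(int)
            ):
                raise ReosigError("CNA calls must be integers in {-2,-1,0,1,2}")
        if self.mutation is not None:
            vals = self.mutation.to_numpy()
            finite = vals[~pd.isna(vals)]
            if not np.isin(finite, [0, 1]).all():
                raise ReosigError("mutation matrix must be binary")
        if self.methylation is not None:
            vals = self.methylation.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ReosigError("methylation beta values must lie in [0,1]")
        if self.msi is not None:
            bad = sorted(set(self.msi.dropna()) - set(MSI_LEVELS))
            if bad:
                raise ReosigError(f"MSI labels outside {MSI_LEVELS}: {bad}")
            extra = set(map(str, self.msi.index)) - master
            if extra:
                raise ReosigError(f"MSI labels for samples outside master list: {sorted(extra)[:5]}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) plus an optional explicit background universe."""

    sets: Dict[str, Set[str]]
    universe: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ReosigError(f"gene set {name!r} is empty")

    def effective_universe(self) -> Set[str]:
        if self.universe is not None:
            return set(self.universe)
        out: Set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network (no self-loops)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ReosigError(f"PPI network contains self-loops: {loops[:5]}")

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def neighbors(self, gene: str) -> Set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()


# --- gene-pair signature types (shared by io, builder and classifier) -------


class PairDirection(str, Enum):
    """Risk orientation of the within-sample ordering Ga > Gb."""

    A_GT_B_RISKY = "a_gt_b_risky"
    A_GT_B_PROTECTIVE = "a_gt_b_protective"


@dataclass
class GenePairRule:
    """One REO rule: the ordering Ga > Gb with its Cox statistics.

    ``direction`` must agree with the sign of beta: beta > 0 means the
    ordering Ga > Gb is a risk factor.
    """

    gene_a: str
    gene_b: str
    beta: float
    p_value: float
    fdr: float
    c_index_solo: float
    direction: PairDirection

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ReosigError(f"gene pair with identical genes: {self.gene_a}")
        self.direction = PairDirection(self.direction)
        expected = (
            PairDirection.A_GT_B_RISKY if self.beta > 0 else PairDirection.A_GT_B_PROTECTIVE
        )
        if self.direction is not expected:
            raise ReosigError(
                f"direction {self.direction.value} inconsistent with beta={self.beta}"
            )

    @property
    def pair_key(self) -> FrozenSet[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class GenePairSignature:
    """Ordered REO rule set with the at-least-half majority-vote threshold."""

    rules: List[GenePairRule]
    vote_threshold: str = "at-least-half"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.rules:
            raise ReosigError("a signature must contain at least one rule")
        keys = [r.pair_key for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ReosigError("duplicated unordered gene pair in signature")
        if self.vote_threshold != "at-least-half":
            raise ReosigError(f"unknown vote threshold {self.vote_threshold!r}")

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.rules:
            out |= {r.gene_a, r.gene_b}
        return out

    def __len__(self) -> int:
        return len(self.rules)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path, what: str) -> pd.DataFrame:
    """Tab-delimited table with one id header row and one id column.

    Non-numeric body cells raise with the row/column address; empty cells are
    kept as missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ReosigError(f"{what}: duplicate row ids {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise ReosigError(f"{what}: duplicate column ids {dups}")
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & conv.isna()
            row = df.index[bad][0]
            raise ReosigError(
                f"{what}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def read_expression(path, dialect: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    ``dialect`` declares the file orientation; the returned matrix is always
    genes x samples.
    """
    if dialect not in ("genes-in-rows", "genes-in-columns"):
        raise ReosigError(f"unknown dialect {dialect!r}")
    df = _read_numeric_table(path, "expression matrix")
    if dialect == "genes-in-columns":
        df = df.T
    logger.info("read expression matrix %s: %d genes x %d samples", path, *df.shape)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_clinical(path) -> Tuple[SurvivalData, ClinicalCovariates]:
    """Read a clinical table with ``time`` and ``event`` columns.

    Samples missing time or event are excluded (and counted in the log);
    negative times and events outside {0, 1} are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ReosigError(f"clinical table lacks required column {col!r}")
    complete = df["time"].notna() & df["event"].notna()
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info(
            "clinical table %s: dropped %d/%d samples with missing time/event",
            path, n_drop, len(df),
        )
    kept = df.loc[complete]
    time = pd.to_numeric(kept["time"]).to_numpy(dtype=float)
    if (time < 0).any():
        raise ReosigError("negative survival time in clinical table")
    event = pd.to_numeric(kept["event"]).to_numpy()
    surv = SurvivalData([str(s) for s in kept.index], time, event)
    cov_cols = [c for c in kept.columns if c not in ("time", "event")]
    cov = ClinicalCovariates(kept[cov_cols].copy())
    return surv, cov


def write_clinical(surv: SurvivalData, path, covariates: Optional[ClinicalCovariates] = None) -> None:
    df = pd.DataFrame({"time": surv.time, "event": surv.event}, index=surv.sample_ids)
    if covariates is not None:
        df = df.join(covariates.table, how="left")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gi50(path, scale: GI50Scale = GI50Scale.GI50) -> DrugSensitivity:
    """Two-column TSV: cell line id, sensitivity value."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    return DrugSensitivity(
        [str(c) for c in df.index], pd.to_numeric(df[col]).to_numpy(), scale
    )


def write_gi50(sens: DrugSensitivity, path) -> None:
    pd.DataFrame({"gi50": sens.gi50}, index=sens.cell_line_ids).rename_axis(
        "cell_line"
    ).to_csv(path, sep="\t")


def read_gene_sets(path, universe: Optional[Set[str]] = None) -> GeneSetCollection:
    """GMT reader: name <tab> description <tab> genes... ; <3 fields is an error."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ReosigError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ReosigError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets, universe)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_ppi(path) -> PPINetwork:
    """Edge list (two-column TSV, or three-column SIF) -> undirected network.

    Self-loop edges are dropped with a warning; duplicate pairs in either
    order collapse to a single undirected edge.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            if len(fields) >= 3 and fields[2]:
                a, b = fields[0], fields[2]  # SIF: node relation node
            else:
                a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
    if n_loops:
        logger.warning("read_ppi %s: dropped %d self-loop edges", path, n_loops)
    logger.info("read PPI network %s: %d nodes, %d edges", path, g.number_of_nodes(), g.number_of_edges())
    return PPINetwork(g)


def write_ppi(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_omics(
    samples: Sequence[str],
    cna_path=None,
    mutation_path=None,
    methylation_path=None,
    msi_path=None,
) -> OmicsProfileBundle:
    """Assemble an omics bundle from TSV matrices aligned on a master sample list."""
    cna = _read_numeric_table(cna_path, "CNA matrix") if cna_path else None
    mutation = _read_numeric_table(mutation_path, "mutation matrix") if mutation_path else None
    methylation = (
        _read_numeric_table(methylation_path, "methylation matrix") if methylation_path else None
    )
    msi = None
    if msi_path:
        msi_df = pd.read_csv(msi_path, sep="\t", index_col=0)
        msi = msi_df[msi_df.columns[0]].astype(str)
    return OmicsProfileBundle(
        samples=[str(s) for s in samples],
        cna=cna,
        mutation=mutation,
        methylation=methylation,
        msi=msi,
    )


_SIG_COLUMNS = ["gene_a", "gene_b", "beta", "p_value", "fdr", "c_index", "direction"]


def write_signature(sig: GenePairSignature, path) -> None:
    """Serialize a signature to the self-describing TSV format (version 1)."""
    with open(path, "w") as fh:
        fh.write(SIGNATURE_MAGIC + "\n")
        fh.write(f"#vote_threshold\t{sig.vote_threshold}\n")
        if sig.provenance:
            fh.write(f"#provenance\t{sig.provenance}\n")
        fh.write("\t".join(_SIG_COLUMNS) + "\n")
        for r in sig.rules:
            fh.write(
                "\t".join(
                    [
                        r.gene_a,
                        r.gene_b,
                        repr(float(r.beta)),
                        repr(float(r.p_value)),
                        repr(float(r.fdr)),
                        repr(float(r.c_index_solo)),
                        r.direction.value,
                    ]
                )
                + "\n"
            )


def read_signature(path) -> GenePairSignature:
    """Read a signature TSV written by :func:`write_signature`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != SIGNATURE_MAGIC:
        head = lines[0] if lines else "<empty>"
        raise ReosigError(f"unknown signature schema: {head!r}")
    vote_threshold = "at-least-half"
    provenance = ""
    body_start = 1
    for i, ln in enumerate(lines[1:], start=1):
        if not ln.startswith("#"):
            body_start = i
            break
        key, _, val = ln[1:].partition("\t")
        if key == "vote_threshold":
            vote_threshold = val
        elif key == "provenance":
            provenance = val
    header = lines[body_start].split("\t")
    if header != _SIG_COLUMNS:
        raise ReosigError(f"unexpected signature column header: {header}")
    rules = []
    for ln in lines[body_start + 1 :]:
        f = ln.split("\t")
        if len(f) != len(_SIG_COLUMNS):
            raise ReosigError(f"malformed signature row: {ln!r}")
        try:
            direction = PairDirection(f[6])
        except ValueError:
            raise ReosigError(f"unknown direction token {f[6]!r}") from None
        rules.append(
            GenePairRule(
                gene_a=f[0],
                gene_b=f[1],
                beta=float(f[2]),
                p_value=float(f[3]),
                fdr=float(f[4]),
                c_index_solo=float(f[5]),
                direction=direction,
            )
        )
    return GenePairSignature(rules, vote_threshold=vote_threshold, provenance=provenance)


def align_expression_survival(
    expr: ExpressionMatrix, surv: SurvivalData
) -> Tuple[ExpressionMatrix, SurvivalData]:
    """Restrict both objects to their shared samples, in expression order."""
    shared = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if not shared:
        raise ReosigError("no shared samples between expression and survival data")
    logger.info(
        "expression/survival alignment: %d shared samples (expr %d, surv %d)",
        len(shared), len(expr.sample_ids), len(surv),
    )
    return expr.align_samples(shared), surv.subset(shared)
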