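"""End-to-end orchestration: screen -> build -> classify -> report -> characterize.

``run_full_pipeline`` executes whichever stages its configuration names
inputs for, mirrors the builder's filter cascade in a run manifest
(candidate genes -> clinically relevant genes -> survival-associated pairs
-> signature rules), and writes every artifact as tab-delimited text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import gps_builder, group_characterization, reo_classifier, resistance_screen
from .io_model import (
    ExpressionMatrix,
    GI50Scale,
    ReosigError,
    read_clinical,
    read_expression,
    read_gene_sets,
    read_gi50,
    read_omics,
    read_ppi,
    read_signature,
    write_signature,
)

logger = logging.getLogger("reosig")

DEFAULT_THRESHOLDS = {
    "alpha_gi50": 0.05,   # cell-line Spearman screen
    "fdr_genes": 0.20,    # univariate Cox gene screen
    "fdr_pairs": 0.05,    # REO pair screen
    "fdr_degs": 0.05,     # DEG detection
    "fdr_cna": 0.05,      # CNA region contrasts (BH)
    "alpha_mut": 0.05,    # mutation contrasts (uncorrected)
    "fdr_corr": 0.05,     # expression/omics correlation screens
}


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    command: str
    config: Dict
    input_digests: Dict[str, str] = field(default_factory=dict)
    stage_counts: Dict[str, int] = field(default_factory=dict)
    output_paths: List[str] = field(default_factory=list)
    output_digests: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_screen_report(records, path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "rho_gi50": r.rho_gi50,
            "p_gi50": r.p_gi50,
            "cox_beta": r.cox_beta,
            "p_rfs": r.p_rfs,
            "fdr_rfs": r.fdr_rfs,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_calls(calls, path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "votes_high": c.votes_high,
                "votes_low": c.votes_low,
                "votes_abstain": c.votes_abstain,
                "label": c.label if c.label is not None else "NA",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def run_full_pipeline(config: Dict) -> RunManifest:
    """Run the configured stages in order and write all artifacts.

    Required configuration: ``expression``, ``clinical`` and ``out``.
    Optional inputs switch on the other stages: ``panel_expression`` +
    ``gi50`` (cell-line screen), ``signature`` (skip building and classify
    with an existing signature), ``cna``/``mutation``/``methylation``/
    ``msi``/``gmt``/``ppi`` (characterization).  A stage failure halts the
    run with the stage name; artifacts already written are retained.
    """
    for key in ("expression", "clinical", "out"):
        if key not in config:
            raise ReosigError(f"pipeline config missing required key {key!r}")
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    out_dir = Path(config["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="run", config=dict(config), started=_time.strftime("%Y-%m-%dT%H:%M:%S")
    )
    for key in ("expression", "clinical", "panel_expression", "gi50", "cna",
                "mutation", "methylation", "msi", "gmt", "ppi", "signature"):
        if key in config and config[key]:
            manifest.input_digests[key] = _digest(config[key])

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        manifest.output_paths.append(str(path))
        manifest.output_digests[name] = _digest(path)
        return path

    stage = "load"
    try:
        expr = read_expression(config["expression"])
        surv, covariates = read_clinical(config["clinical"])

        # --- stage 1: resistance screen --------------------------------
        candidates = None
        gi50_records = None
        if config.get("panel_expression") and config.get("gi50"):
            stage = "screen"
            panel = read_expression(config["panel_expression"])
            sens = read_gi50(
                config["gi50"], GI50Scale(config.get("gi50_scale", "gi50"))
            )
            gi50_records = resistance_screen.screen_gi50_genes(
                panel, sens, alpha=thresholds["alpha_gi50"]
            )
            manifest.stage_counts["candidate_genes"] = len(gi50_records)
            prior = {r.gene_id: r for r in gi50_records}
            in_expr = [g for g in prior if g in set(expr.gene_ids)]
            survivors = resistance_screen.screen_rfs_genes(
                expr, surv, in_expr, fdr=thresholds["fdr_genes"], prior=prior
            )
            manifest.stage_counts["clinically_relevant_genes"] = len(survivors)
            if survivors:
                conc = resistance_screen.concordance(gi50_records, survivors)
                manifest.stage_counts["concordant_genes"] = conc.s
            emit("screen_report.tsv", lambda p: _write_screen_report(survivors, p))
            candidates = [r.gene_id for r in survivors]

        # --- stage 2: signature -----------------------------------------
        if config.get("signature"):
            stage = "load-signature"
            sig = read_signature(config["signature"])
        else:
            stage = "build-gps"
            if candidates is None:
                candidates = expr.gene_ids
            audit = gps_builder.BuildAudit()
            sig = gps_builder.build_gps(
                expr, surv, candidates, fdr_pairs=thresholds["fdr_pairs"], audit=audit
            )
            manifest.stage_counts["pairs_enumerated"] = audit.n_pairs_enumerated
            manifest.stage_counts["pairs_set1"] = audit.n_pairs_set1
            manifest.stage_counts["signature_rules"] = audit.n_rules_signature
        emit("signature.tsv", lambda p: write_signature(sig, p))

        # --- stage 3: classify + survival report ------------------------
        stage = "classify"
        calls = reo_classifier.classify_cohort(sig, expr)
        emit("risk_calls.tsv", lambda p: _write_calls(calls, p))
        stage = "report"
        report = reo_classifier.stratify_and_report(
            calls, surv, covariates if covariates.table.shape[1] else None
        )
        emit(
            "stratification.tsv",
            lambda p: pd.DataFrame([report.summary()]).to_csv(p, sep="\t", index=False),
        )

        # --- stage 4: characterization ----------------------------------
        labels = {
            c.sample_id: c.label for c in calls if c.label is not None
        }
        if any(config.get(k) for k in ("cna", "mutation", "methylation", "msi")):
            stage = "characterize"
            bundle = read_omics(
                samples=list(labels),
                cna_path=config.get("cna"),
                mutation_path=config.get("mutation"),
                methylation_path=config.get("methylation"),
                msi_path=config.get("msi"),
            )
            degs = group_characterization.detect_degs(
                expr, labels, fdr=thresholds["fdr_degs"]
            )
            manifest.stage_counts["degs"] = len(degs)
            emit(
                "deg_report.tsv",
                lambda p: pd.DataFrame([dataclasses.asdict(d) for d in degs]).to_csv(
                    p, sep="\t", index=False
                ),
            )
            if bundle.cna is not None:
                contrasts = group_characterization.contrast_frequencies(
                    group_characterization.binarize_cna(bundle.cna),
                    labels, threshold=thresholds["fdr_cna"], correction="bh",
                )
                manifest.stage_counts["cna_regions_significant"] = len(contrasts)
                emit(
                    "cna_contrasts.tsv",
                    lambda p: pd.DataFrame(
                        [dataclasses.asdict(c) for c in contrasts]
                    ).to_csv(p, sep="\t", index=False),
                )
            if bundle.mutation is not None:
                contrasts = group_characterization.contrast_frequencies(
                    bundle.mutation, labels,
                    threshold=thresholds["alpha_mut"], correction="none",
                )
                manifest.stage_counts["mutation_genes_significant"] = len(contrasts)
                emit(
                    "mutation_contrasts.tsv",
                    lambda p: pd.DataFrame(
                        [dataclasses.asdict(c) for c in contrasts]
                    ).to_csv(p, sep="\t", index=False),
                )
            if bundle.msi is not None:
                msi_res = group_characterization.msi_contrast(
                    bundle.msi.to_dict(), labels
                )
                emit(
                    "msi_contrast.tsv",
                    lambda p: pd.DataFrame([dataclasses.asdict(msi_res)]).to_csv(
                        p, sep="\t", index=False
                    ),
                )
            if bundle.methylation is not None:
                meth = group_characterization.expr_omics_correlation(
                    expr, bundle.methylation,
                    fdr=thresholds["fdr_corr"], sign_filter="negative",
                )
                manifest.stage_counts["meth_negative_genes"] = len(meth)
                emit("methylation_correlation.tsv",
                     lambda p: meth.to_csv(p, sep="\t", index=False))
    except Exception as exc:
        raise ReosigError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = _time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    logger.info("pipeline complete; cascade %s", manifest.stage_counts)
    return manifest
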