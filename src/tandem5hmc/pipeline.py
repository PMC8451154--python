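"""End-to-end orchestration: simulate/ingest → deconvolve → select →
enrich → differential → cluster/survival, with a run manifest.

Each stage writes its outputs under the configured directory as TSV/BED and
contributes row counts to the manifest; any stage error aborts the run with
the stage name while earlier outputs remain on disk. The manifest carries
the package version, seed, a parameter hash and per-output row counts, so
reruns with identical configuration are hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import pandas as pd

from . import __version__, io
from .cluster_survival import (
    cluster_tumors,
    cox_fit,
    km_logrank,
    label_clusters,
    top_variable_loci,
)
from .config import RunConfig
from .datatypes import CONTEXTS
from .deconvolution import deconvolve_ml, deconvolve_naive
from .differential import extract_dhmr, fit_locus_models
from .enrichment import (
    cmh_enrichment,
    fisher_context_enrichment,
    gene_high5hmc_score,
    regionset_enrichment,
)
from .exceptions import Tandem5hmcError
from .locus_selection import (
    per_locus_correlation,
    sample_medians,
    select_high_5hmc,
    total_5hmc_index,
    tss_profile,
)
from .simulate import simulate_dataset, simulate_region_sets

logger = logging.getLogger(__name__)


class StageError(Tandem5hmcError):
    """Wraps a failure with the name of the stage it occurred in."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.original = err


def _param_hash(cfg: RunConfig) -> str:
    payload = asdict(cfg)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _enrichment_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    cfg.validate()
    out = cfg.outdir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameter_hash": _param_hash(cfg),
        "row_counts": {},
        "stages_run": [],
    }
    counts = manifest["row_counts"]

    stage = "ingest"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            sim = cfg.simulate
            paired, ann, samples, truth = simulate_dataset(sim)
            io.write_paired(paired, out)
            io.write_annotation(ann, os.path.join(out, "annotation.tsv"))
            io.write_samples(samples, os.path.join(out, "samples.tsv"))
            io.write_truth(truth, os.path.join(out, "truth"))
            collections = simulate_region_sets(sim, ann)
            for coll in collections:
                io.write_bed(coll, os.path.join(out, f"{coll.name}.bed"))
        else:
            paired = io.read_paired(cfg.bs_path, cfg.oxbs_path)
            ann = io.read_annotation(cfg.annotation_path)
            samples = io.read_samples(cfg.samples_path)
            collections = [io.read_bed(p) for p in cfg.region_bed_paths]
        manifest["stages_run"].append(stage)
        counts["loci"] = int(len(paired.locus_ids))
        counts["samples"] = int(len(paired.sample_ids))
        manifest["bookkeeping"] = samples.validate_bookkeeping()

        stage = "deconvolve"
        if cfg.deconvolution_method == "ml":
            props = deconvolve_ml(paired, precision=cfg.ml_precision)
        else:
            props = deconvolve_naive(paired)
        io.write_proportions(props, os.path.join(out, "proportions"))
        manifest["stages_run"].append(stage)

        high_loci = None
        if cfg.stages.get("select", True):
            stage = "select"
            med, tests = sample_medians(props, samples)
            med.to_csv(os.path.join(out, "sample_medians.tsv"), sep="\t")
            summary = select_high_5hmc(props, samples.tumor_ids, cfg.frac_high5hmc)
            summary.to_csv(os.path.join(out, "locus_summary.tsv"), sep="\t")
            high_loci = summary.index[summary["is_high_5hmc"]]
            io.write_bed((high_loci, ann), os.path.join(out, "high_5hmc.bed"))
            rho, ecdf, n_undef = per_locus_correlation(props, samples.tumor_ids)
            ecdf.to_csv(os.path.join(out, "correlation_ecdf.tsv"), sep="\t", index=False)
            prof = tss_profile(props, ann, samples, bin_bp=cfg.tss_bin_bp)
            prof.to_csv(os.path.join(out, "tss_profile.tsv"), sep="\t", index=False)
            idx_labels, idx_threshold = total_5hmc_index(props, samples.tumor_ids)
            idx_labels.to_csv(os.path.join(out, "total_5hmc_index.tsv"), sep="\t")
            counts["high_5hmc_loci"] = int(len(high_loci))
            counts["undefined_correlations"] = int(n_undef)
            manifest["selection_threshold"] = summary.attrs["threshold_median"]
            manifest["total_5hmc_threshold"] = idx_threshold
            manifest["stages_run"].append(stage)

        if cfg.stages.get("enrich", True) and high_loci is not None:
            stage = "enrich"
            universe = props.locus_ids
            rows = [
                fisher_context_enrichment(high_loci, universe, ann, ctx)
                for ctx in CONTEXTS
            ]
            rows += [
                cmh_enrichment(high_loci, universe, ann, flag)
                for flag in ("enhancer", "tfbs", "utr5")
            ]
            rows += regionset_enrichment(high_loci, universe, ann, collections)
            _enrichment_to_frame(rows).to_csv(
                os.path.join(out, "enrichment_high5hmc.tsv"), sep="\t", index=False
            )
            genes = gene_high5hmc_score(high_loci, ann, min_high=cfg.min_high)
            genes.to_csv(os.path.join(out, "gene_scores.tsv"), sep="\t", index=False)
            counts["enrichment_rows"] = len(rows)
            counts["scored_genes"] = int(len(genes))
            manifest["stages_run"].append(stage)

        dhmr = None
        if cfg.stages.get("differential", True) and high_loci is not None:
            stage = "differential"
            diff = fit_locus_models(props, samples, universe=high_loci)
            diff.to_csv(os.path.join(out, "differential.tsv"), sep="\t")
            dhmr = extract_dhmr(diff, fdr=cfg.fdr, direction="hypo")
            io.write_bed((dhmr, ann), os.path.join(out, "dhmr.bed"))
            counts["tested_loci"] = int(len(diff))
            counts["dhmr"] = int(len(dhmr))
            manifest["stages_run"].append(stage)
            if dhmr is not None and len(dhmr) > 0:
                rows = [
                    fisher_context_enrichment(dhmr, pd.Index(high_loci), ann, ctx)
                    for ctx in CONTEXTS
                ]
                _enrichment_to_frame(rows).to_csv(
                    os.path.join(out, "enrichment_dhmr.tsv"), sep="\t", index=False
                )

        if cfg.stages.get("cluster_survival", True):
            stage = "cluster_survival"
            top = top_variable_loci(
                props, samples.tumor_ids, min(cfg.top_n_variable, len(props.locus_ids))
            )
            tree = cluster_tumors(props, samples.tumor_ids, top)
            labels, diagnostics = label_clusters(tree, props, samples)
            labels.to_csv(os.path.join(out, "cluster_labels.tsv"), sep="\t")
            with open(os.path.join(out, "cluster_tree.json"), "w") as fh:
                json.dump(
                    {
                        "leaves": {
                            leaf.node_id: leaf.members for leaf in tree.leaves()
                        },
                        "diagnostics": {
                            k: v
                            for k, v in diagnostics.items()
                            if k != "fisher_cluster_vs_subtype"
                        },
                    },
                    fh,
                    indent=2,
                )
            surv_rows = []
            for outcome in ("death", "recurrence"):
                fit = cox_fit(samples, outcome=outcome, cluster_labels=labels)
                s = fit.summary.copy()
                s.insert(0, "outcome", outcome)
                s.insert(1, "concordance", fit.concordance)
                surv_rows.append(s)
                _, lr_stat, lr_p = km_logrank(samples, labels, outcome=outcome)
                manifest[f"logrank_p_{outcome}"] = lr_p
            pd.concat(surv_rows).to_csv(
                os.path.join(out, "survival.tsv"), sep="\t", index_label="covariate"
            )
            counts["cluster_low"] = int((labels == "low5hmC").sum())
            counts["cluster_high"] = int((labels == "high5hmC").sum())
            manifest["stages_run"].append(stage)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, err) from err

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_report(manifest, os.path.join(out, "report.txt"))
    return manifest


def _write_report(manifest: dict, path: str) -> None:
    lines = [
        f"tandem5hmc v{manifest['version']} run report",
        f"seed: {manifest['seed']}",
        f"parameter hash: {manifest['parameter_hash']}",
        "",
        "stages: " + ", ".join(manifest["stages_run"]),
        "",
    ]
    for key, val in sorted(manifest["row_counts"].items()):
        lines.append(f"{key}: {val}")
    for key in sorted(manifest):
        if key.startswith("logrank_p_") or key.endswith("_threshold"):
            lines.append(f"{key}: {manifest[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
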