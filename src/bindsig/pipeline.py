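"""End-to-end orchestration: simulate → merge → count → classify → assign →
DE → target set → co-binding → clustering.

Each stage is an ordinary function over in-memory objects; :func:`run_all`
chains them from a validated config, writes every declared output as a
plain-text file and records a manifest (config hash, seed, package version,
per-stage row counts). Re-running on identical inputs and config produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import numpy as np
import yaml

from . import __version__
from .clustering import cluster_by_signature, summarize_clusters
from .cobinding import cobind_fraction, three_way_venn
from .config import validate_config
from .coverage import build_coverage_matrix
from .expression import (DEThresholds, call_de, derive_target_set,
                         group_expression_response)
from .genes import assign_regions, distribution_summary, genes_for_group
from .grouping import (GroupThresholds, classify_regions,
                       global_binding_summary, group_sizes,
                       tf_histone_correlation)
from .intervals import PeakSet, merge_two_condition_peaks
from .simulate import (generate_annotation, generate_binding_experiment,
                       generate_expression_matrix, generate_labeled_cohort)

logger = logging.getLogger("bindsig")

__all__ = ["simulate_all", "run_all"]

ASSAY_TF = "PU1"
ASSAY_HIST = "H3K27ac"
ASSAY_CEBPA = "CEBPA"


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_all(config: dict, outdir: str | Path | None = None):
    """Generate the full coherent fixture family from one seed.

    The binding experiment is placed on the generated annotation (Group I/II
    regions intergenic next to private target genes, Group III at promoters)
    and the expression matrix plants its up-regulated genes on the Group I
    target genes plus extra random genes, so the derived signature has a
    known truth.
    """
    seed = int(config["seed"])
    sim = config["simulate"]
    ann = generate_annotation(
        seed=seed,
        promoter_upstream=config["promoter"]["upstream"],
        promoter_downstream=config["promoter"]["downstream"],
        **sim["annotation"],
    )
    bind = generate_binding_experiment(
        seed=seed + 1,
        annotation=ann,
        hist_abs_min=config["thresholds"]["hist_abs_min"],
        **sim["binding"],
    )
    rng = np.random.default_rng(seed + 2)
    planted_up = bind.target_genes("I")
    n_extra = int(sim["expression"].get("n_extra_up", 0))
    pool = sorted(set(ann.annotation["gene_id"]) - set(planted_up))
    extra = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    expr_cfg = {k: v for k, v in sim["expression"].items() if k != "n_extra_up"}
    expr = generate_expression_matrix(
        seed=seed + 2,
        gene_ids=list(ann.annotation["gene_id"]),
        up_genes=sorted(planted_up + extra),
        **expr_cfg,
    )
    if outdir is not None:
        outdir = Path(outdir)
        ann.write(outdir)
        bind.write(outdir)
        expr.write(outdir)
    return ann, bind, expr


def run_all(config: dict, outdir: str | Path) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    counts: dict[str, int] = {}

    # --- simulate ----------------------------------------------------------
    ann, bind, expr = simulate_all(config, outdir=outdir / "fixtures")
    logger.info("simulated %d genes, %d regions, %d probes",
                len(ann.annotation), len(bind.truth), len(expr.expr))
    counts["genes_simulated"] = len(ann.annotation)
    counts["regions_simulated"] = len(bind.truth)

    # --- merge + coverage --------------------------------------------------
    merged = merge_two_condition_peaks(bind.peaks[(ASSAY_TF, "minus")],
                                       bind.peaks[(ASSAY_TF, "plus")])
    merged.to_bed(outdir / "merged_regions.bed")
    counts["merged_regions"] = len(merged)
    cov = build_coverage_matrix(
        merged,
        {
            (ASSAY_TF, "minus"): bind.reads[(ASSAY_TF, "minus")],
            (ASSAY_TF, "plus"): bind.reads[(ASSAY_TF, "plus")],
            (ASSAY_HIST, "minus"): bind.reads[(ASSAY_HIST, "minus")],
            (ASSAY_HIST, "plus"): bind.reads[(ASSAY_HIST, "plus")],
        },
        histone_assays=(ASSAY_HIST,),
        histone_width=int(config["histone"]["width"]),
    )
    cov.write(outdir / "counts.tsv", outdir / "library_sizes.tsv")

    # --- classify ----------------------------------------------------------
    thresholds = GroupThresholds(**config["thresholds"])
    groups = classify_regions(cov, ASSAY_TF, ASSAY_HIST, thresholds)
    groups.to_csv(outdir / "groups.tsv", sep="\t", float_format="%.6g")
    sizes = group_sizes(groups)
    logger.info("group sizes: %s", sizes)
    counts["regions_grouped"] = len(groups)
    summary = global_binding_summary(cov, ASSAY_TF, thresholds)
    summary["group_sizes"] = sizes
    summary["tf_histone_correlation"] = tf_histone_correlation(
        cov, ASSAY_TF, ASSAY_HIST, pseudocount=thresholds.pseudocount
    )
    _json_dump(summary, outdir / "binding_summary.json")

    # --- gene assignment ---------------------------------------------------
    assignments = assign_regions(
        merged, ann.annotation, ann.promoters,
        max_dist=int(config["assignment"]["max_dist"]),
    )
    assignments[["category", "gene_ids", "distances"]].to_csv(
        outdir / "assignments.tsv", sep="\t"
    )
    counts["regions_assigned"] = len(assignments)
    _json_dump(distribution_summary(assignments, groups["group"]),
               outdir / "distribution.json")

    # --- differential expression ------------------------------------------
    de = call_de(expr.expr, expr.design, DEThresholds(**config["de"]))
    de.to_csv(outdir / "de.tsv", sep="\t", float_format="%.6g")
    counts["probes_tested"] = len(de)
    counts["probes_significant"] = int(de["significant"].sum())

    group_gene_sets = {g: genes_for_group(assignments, groups["group"], g)
                       for g in ("I", "II", "III")}
    response = group_expression_response(de, group_gene_sets)
    _json_dump(response, outdir / "group_response.json")

    # --- target set --------------------------------------------------------
    target = derive_target_set(group_gene_sets["I"], de)
    target.write(outdir / "target_genes.txt")
    logger.info("target set: %d genes (%s)", len(target), target.provenance)
    counts["target_genes"] = len(target)

    # --- co-binding --------------------------------------------------------
    cobind = {}
    if (ASSAY_CEBPA, "minus") in bind.peaks:
        cebpa_pre = bind.peaks[(ASSAY_CEBPA, "minus")]
        for grp in ("I", "II", "III"):
            ids = groups.index[groups["group"] == grp]
            sub = merged.df.loc[merged.df["name"].isin(ids)]
            grp_peaks = PeakSet(sub, label=f"{ASSAY_TF}_group_{grp}")
            cobind[f"group_{grp}_at_preexisting_CEBPA"] = cobind_fraction(
                grp_peaks, cebpa_pre
            )
        venn = three_way_venn(bind.peaks[(ASSAY_TF, "minus")],
                              bind.peaks[(ASSAY_TF, "plus")],
                              bind.peaks[(ASSAY_CEBPA, "plus")])
        cobind["venn_atoms"] = {"+".join(sorted(k)): v for k, v in venn.items()}
    _json_dump(cobind, outdir / "cobinding.json")

    # --- cohort clustering -------------------------------------------------
    cohort_cfg = dict(config["simulate"]["cohort"])
    k = int(config["clustering"]["k"])
    cohort = generate_labeled_cohort(
        seed=seed + 3,
        signature_genes=sorted(target.genes) or None,
        **cohort_cfg,
    )
    cohort.write(outdir / "fixtures")
    result = cluster_by_signature(
        cohort.expr, cohort.signature_genes, k=k,
        n_boot=int(config["clustering"]["n_boot"]), seed=seed + 4,
    )
    result.labels.to_csv(outdir / "cluster_labels.tsv", sep="\t",
                         index_label="sample_id")
    with open(outdir / "dendrogram.nwk", "w") as fh:
        fh.write(result.to_newick() + "\n")
    cluster_summary = summarize_clusters(
        result, cohort.expr, cohort.metadata,
        marker_gene=cohort_cfg.get("marker_gene"),
    )
    _json_dump(cluster_summary.to_dict(), outdir / "cluster_summary.json")
    counts["samples_clustered"] = len(result.labels)

    # --- manifest ----------------------------------------------------------
    config_blob = yaml.safe_dump(config, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": seed,
        "version": __version__,
        "row_counts": counts,
    }
    _json_dump(manifest, outdir / "manifest.json")
    return manifest
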