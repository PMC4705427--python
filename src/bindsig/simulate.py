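"""Synthetic fixtures with planted, recorded ground truth.

Every generator is a pure function of (parameters, seed) and returns an
in-memory result object that can also serialize itself to plain-text files
(BED / TSV / YAML manifest). The planted truth is part of the result and is
written alongside the fixtures, so downstream tests never reach into
generator internals.

What is emulated
----------------
* a gene annotation with strand-aware promoter windows (−1000/+200 bp);
* two-condition ChIP peak sets with planted fold-change structure (Group I:
  TF and histone increase; Group II: TF only; Group III: no change), read
  pileups Poisson-sampled around the planted means, and uniform background
  reads filling each library to a fixed depth so both conditions have equal
  library sizes;
* a log2 expression matrix with planted up-regulated genes;
* labeled expression cohorts with planted cluster structure and categorical
  sample metadata (karyotype-style labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genes import _finalize_annotation, promoters_from_annotation
from .intervals import PeakSet

__all__ = [
    "CapacityError",
    "AnnotationResult",
    "BindingResult",
    "ExpressionResult",
    "CohortResult",
    "generate_annotation",
    "generate_binding_experiment",
    "generate_expression_matrix",
    "generate_labeled_cohort",
]


class CapacityError(ValueError):
    """The genome is too small to place the requested features."""


def _write_manifest(outdir: Path, name: str, params: dict) -> None:
    with open(outdir / f"{name}_manifest.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    annotation: pd.DataFrame
    promoters: PeakSet
    chrom_sizes: dict[str, int]
    params: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = ["chrom", "start", "end", "strand", "gene_id"]
        self.annotation[cols].to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        self.promoters.to_bed(outdir / "promoters.bed")
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, size in sorted(self.chrom_sizes.items()):
                fh.write(f"{chrom}\t{size}\n")
        _write_manifest(outdir, "annotation", self.params)


def generate_annotation(
    n_genes: int,
    genome_size: int = 2_000_000,
    seed: int = 0,
    n_chroms: int = 2,
    gene_length: tuple[int, int] = (2_000, 8_000),
    min_gap: int = 6_000,
    promoter_upstream: int = 1_000,
    promoter_downstream: int = 200,
) -> AnnotationResult:
    """Non-overlapping stranded gene bodies plus promoter windows.

    Genes are distributed round-robin over equal-size chromosomes and placed
    left to right with random slack; ``min_gap`` bp always separate adjacent
    features so intergenic fixtures have room for planted peaks.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rng = np.random.default_rng(seed)
    chrom_size = genome_size // n_chroms
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    rows = []
    gid = 0
    for chrom, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        lengths = rng.integers(gene_length[0], gene_length[1] + 1, size=m)
        needed = int(lengths.sum()) + (m + 1) * min_gap
        if needed > chrom_size:
            raise CapacityError(
                f"{chrom}: need {needed} bp for {m} genes, have {chrom_size}"
            )
        slack = chrom_size - needed
        w = rng.random(m + 1)
        extra = np.floor(w / w.sum() * slack).astype(int)
        pos = min_gap + extra[0]
        for j in range(m):
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "strand": strand, "gene_id": f"gene_{gid:05d}"})
            gid += 1
            pos = end + min_gap + extra[j + 1]
    annotation = _finalize_annotation(pd.DataFrame(rows))
    promoters = promoters_from_annotation(
        annotation, upstream=promoter_upstream, downstream=promoter_downstream
    )
    params = dict(
        generator="annotation", n_genes=n_genes, genome_size=genome_size,
        seed=seed, n_chroms=n_chroms, gene_length=list(gene_length),
        min_gap=min_gap, promoter_upstream=promoter_upstream,
        promoter_downstream=promoter_downstream,
    )
    return AnnotationResult(
        annotation=annotation,
        promoters=promoters,
        chrom_sizes={c: chrom_size for c in chroms},
        params=params,
    )


# ---------------------------------------------------------------------------
# binding experiment
# ---------------------------------------------------------------------------

@dataclass
class BindingResult:
    peaks: dict[tuple[str, str], PeakSet]
    reads: dict[tuple[str, str], PeakSet]
    truth: pd.DataFrame
    library_sizes: dict[str, int]
    params: dict
    infeasible: bool = False

    def group_regions(self, group: str) -> PeakSet:
        sub = self.truth[self.truth["group"] == group]
        return PeakSet(sub[["chrom", "start", "end"]].assign(name=sub.index),
                       label=f"group_{group}")

    def target_genes(self, group: str) -> list[str]:
        sub = self.truth[(self.truth["group"] == group)
                         & (self.truth["target_gene"] != "")]
        return sorted(sub["target_gene"].unique())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (assay, cond), ps in sorted(self.peaks.items()):
            ps.to_bed(outdir / f"peaks_{assay}_{cond}.bed")
        for (assay, cond), ps in sorted(self.reads.items()):
            ps.to_bed(outdir / f"reads_{assay}_{cond}.bed")
        self.truth.to_csv(outdir / "truth_regions.tsv", sep="\t",
                          index_label="region_id")
        pd.Series(self.library_sizes, name="library_size").to_csv(
            outdir / "library_sizes.tsv", sep="\t", index_label="assay_condition"
        )
        _write_manifest(outdir, "binding", self.params)


def _truth_group(tf_minus, tf_plus, hist_minus, hist_plus,
                 fc_min=4.0, band=2.0, hist_abs_min=50.0) -> np.ndarray:
    """Noise-free classification of the planted means (no pseudocount)."""
    with np.errstate(divide="ignore"):
        tf_fold = np.where(tf_minus > 0, tf_plus / np.maximum(tf_minus, 1e-12),
                           np.where(tf_plus > 0, np.inf, 1.0))
        hist_fold = np.where(hist_minus > 0,
                             hist_plus / np.maximum(hist_minus, 1e-12),
                             np.where(hist_plus > 0, np.inf, 1.0))
    out = np.full(len(tf_fold), "unclassified", dtype=object)
    tf_up = tf_fold >= fc_min
    gi = tf_up & (hist_fold >= fc_min) & (hist_plus >= hist_abs_min)
    gii = tf_up & ~gi
    giii = ~tf_up & (np.maximum(tf_fold, 1.0 / tf_fold) <= band)
    out[giii] = "III"
    out[gii] = "II"
    out[gi] = "I"
    return out


def _reads_for_condition(rng, truth, mean_col, depth, read_length,
                         chrom_sizes) -> PeakSet:
    """Poisson signal reads per region plus uniform background to depth."""
    means = truth[mean_col].to_numpy(dtype=float)
    counts = rng.poisson(means)
    total_signal = int(counts.sum())
    if total_signal > depth:
        raise CapacityError(
            f"planted signal ({total_signal} reads) exceeds library depth {depth}; "
            f"increase depth"
        )
    frames = []
    if total_signal > 0:
        idx = np.repeat(np.arange(len(truth)), counts)
        r_start = truth["start"].to_numpy()[idx]
        r_end = truth["end"].to_numpy()[idx]
        span = np.maximum(r_end - read_length - r_start, 1)
        starts = r_start + (rng.random(len(idx)) * span).astype(np.int64)
        frames.append(pd.DataFrame({
            "chrom": truth["chrom"].to_numpy()[idx],
            "start": starts, "end": starts + read_length,
        }))
    n_bg = depth - total_signal
    if n_bg > 0:
        chroms = sorted(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        picks = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
        starts = (rng.random(n_bg) * (sizes[picks] - read_length)).astype(np.int64)
        frames.append(pd.DataFrame({
            "chrom": np.array(chroms, dtype=object)[picks],
            "start": starts, "end": starts + read_length,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else None
    return PeakSet(df)


def generate_binding_experiment(
    n_regions_per_group: dict[str, int] | None = None,
    depth: int = 1_000_000,
    fold_pu1: float = 8.0,
    fold_h3k27ac: float = 8.0,
    seed: int = 0,
    genome_size: int = 200_000_000,
    n_chroms: int = 2,
    region_width: int = 400,
    read_length: int = 50,
    tf_base: float = 30.0,
    hist_base: float = 50.0,
    new_binding_frac: float = 0.5,
    include_cebpa: bool = True,
    cebpa_base: float = 30.0,
    cebpa_cobind_frac: dict[str, float] | None = None,
    hist_abs_min: float = 50.0,
    annotation: AnnotationResult | None = None,
    group_placement: dict[str, str] | None = None,
    assay_tf: str = "PU1",
    assay_hist: str = "H3K27ac",
    assay_cebpa: str = "CEBPA",
) -> BindingResult:
    """Two-condition peak sets, read pileups and truth for three region groups.

    Planted means (reads per region): Group I regions get ``fold_pu1``× TF
    and ``fold_h3k27ac``× histone reads after induction; Group II only the TF
    increase; Group III equal means in both conditions. A ``new_binding_frac``
    share of Group I/II regions have no uninduced TF binding at all (de novo
    peaks, absent from the uninduced peak call). Each (assay, condition)
    library is filled to exactly ``depth`` reads with uniform background, so
    the two conditions have equal library sizes as in a real sequencing run.

    With ``annotation`` given, regions are placed relative to genes following
    ``group_placement`` (default: Groups I/II intergenic next to a private
    target gene, Group III inside promoter windows) and the truth records the
    intended target gene of each region. Truth group labels are derived from
    the planted means, so degenerate parameters (e.g. ``fold_pu1=1``)
    label every region III rather than what was requested.
    """
    if n_regions_per_group is None:
        # study group sizes at 1:10 scale
        n_regions_per_group = {"I": 173, "II": 506, "III": 276}
    if cebpa_cobind_frac is None:
        cebpa_cobind_frac = {"I": 0.2, "II": 0.26, "III": 0.55}
    if fold_pu1 <= 0 or fold_h3k27ac <= 0:
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    n_total = sum(n_regions_per_group.values())

    infeasible = False
    if hist_base * fold_h3k27ac < hist_abs_min:
        warnings.warn(
            "expected induced histone count "
            f"{hist_base * fold_h3k27ac:.1f} is below the absolute floor "
            f"{hist_abs_min:g}; planted Group I regions cannot pass criterion (iii)"
        )
        infeasible = True

    requested = np.concatenate([
        np.repeat(g, n) for g, n in sorted(n_regions_per_group.items())
    ])
    rng.shuffle(requested)

    # --- placement ---------------------------------------------------------
    if annotation is None:
        chrom_size = genome_size // n_chroms
        chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
        spacing = (chrom_size - 2 * region_width) // (n_total // n_chroms + 2)
        if spacing <= region_width:
            raise CapacityError("genome too small for the requested regions")
        rows = []
        i = 0
        for chrom in sorted(chrom_sizes):
            m = n_total // n_chroms + (1 if i < n_total % n_chroms else 0)
            jitter = rng.integers(0, max(spacing - region_width, 1), size=m)
            for j in range(m):
                start = region_width + j * spacing + int(jitter[j])
                rows.append({"chrom": chrom, "start": start,
                             "end": start + region_width, "target_gene": ""})
            i += 1
        truth = pd.DataFrame(rows[:n_total])
        truth["group_requested"] = requested[: len(truth)]
    else:
        if group_placement is None:
            group_placement = {"I": "intergenic", "II": "intergenic",
                               "III": "promoter"}
        ann = annotation.annotation
        if n_total > len(ann):
            raise CapacityError(
                f"{n_total} regions requested but only {len(ann)} genes available"
            )
        chrom_sizes = annotation.chrom_sizes
        min_gap = annotation.params.get("min_gap", 6_000)
        gene_pick = rng.permutation(len(ann))[:n_total]
        rows = []
        for idx, group in zip(gene_pick, requested):
            gene = ann.iloc[idx]
            mode = group_placement.get(group, "intergenic")
            if mode == "promoter":
                tss = int(gene["tss"])
                start = max(tss - region_width // 2, 0)
            else:
                lo = 1_200
                hi = max(min_gap - region_width - 1_200, lo + 1)
                start = int(gene["end"]) + int(rng.integers(lo, hi))
            rows.append({"chrom": gene["chrom"], "start": start,
                         "end": start + region_width,
                         "target_gene": gene["gene_id"],
                         "group_requested": group})
        truth = pd.DataFrame(rows)

    truth = truth.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    truth.index = pd.Index([f"region_{i:06d}" for i in range(len(truth))],
                           name="region_id")

    # --- planted means -----------------------------------------------------
    g = truth["group_requested"].to_numpy()
    n = len(truth)
    tf_minus = np.full(n, tf_base)
    tf_plus = np.full(n, tf_base)
    hist_minus = np.full(n, hist_base)
    hist_plus = np.full(n, hist_base)
    up = (g == "I") | (g == "II")
    tf_plus[up] = tf_base * fold_pu1
    hist_plus[g == "I"] = hist_base * fold_h3k27ac
    # de novo peaks only exist when induction actually increases binding
    de_novo = up & (rng.random(n) < new_binding_frac) & (fold_pu1 > 1)
    tf_minus[de_novo] = 0.0

    cebpa = np.zeros(n, dtype=bool)
    for group, frac in cebpa_cobind_frac.items():
        idx = np.flatnonzero(g == group)
        k = int(round(frac * len(idx)))
        if k > 0:
            cebpa[rng.choice(idx, size=k, replace=False)] = True

    truth["tf_mean_minus"] = tf_minus
    truth["tf_mean_plus"] = tf_plus
    truth["hist_mean_minus"] = hist_minus
    truth["hist_mean_plus"] = hist_plus
    truth["cebpa"] = cebpa
    truth["present_minus"] = tf_minus > 0
    truth["present_plus"] = tf_plus > 0
    truth["group"] = _truth_group(tf_minus, tf_plus, hist_minus, hist_plus,
                                  hist_abs_min=hist_abs_min)

    # --- peak calls --------------------------------------------------------
    def _peaks(mask: np.ndarray, label: str) -> PeakSet:
        sub = truth.loc[mask, ["chrom", "start", "end"]].copy()
        sub["name"] = truth.index[mask]
        return PeakSet(sub, label=label)

    peaks = {
        (assay_tf, "minus"): _peaks(truth["present_minus"].to_numpy(),
                                    f"{assay_tf}_minus"),
        (assay_tf, "plus"): _peaks(truth["present_plus"].to_numpy(),
                                   f"{assay_tf}_plus"),
    }
    if include_cebpa:
        peaks[(assay_cebpa, "minus")] = _peaks(cebpa, f"{assay_cebpa}_minus")
        peaks[(assay_cebpa, "plus")] = _peaks(cebpa, f"{assay_cebpa}_plus")

    # --- reads -------------------------------------------------------------
    mean_cols = {
        (assay_tf, "minus"): "tf_mean_minus",
        (assay_tf, "plus"): "tf_mean_plus",
        (assay_hist, "minus"): "hist_mean_minus",
        (assay_hist, "plus"): "hist_mean_plus",
    }
    if include_cebpa:
        truth["cebpa_mean_minus"] = np.where(cebpa, cebpa_base, 0.0)
        truth["cebpa_mean_plus"] = truth["cebpa_mean_minus"]
        mean_cols[(assay_cebpa, "minus")] = "cebpa_mean_minus"
        mean_cols[(assay_cebpa, "plus")] = "cebpa_mean_plus"
    reads = {}
    library_sizes = {}
    for (assay, cond), col in sorted(mean_cols.items()):
        reads[(assay, cond)] = _reads_for_condition(
            rng, truth, col, depth, read_length, chrom_sizes
        )
        library_sizes[f"{assay}_{cond}"] = depth

    params = dict(
        generator="binding", seed=seed, depth=depth,
        n_regions_per_group=dict(sorted(n_regions_per_group.items())),
        fold_pu1=fold_pu1, fold_h3k27ac=fold_h3k27ac,
        genome_size=genome_size, n_chroms=n_chroms,
        region_width=region_width, read_length=read_length,
        tf_base=tf_base, hist_base=hist_base,
        new_binding_frac=new_binding_frac, include_cebpa=include_cebpa,
        cebpa_base=cebpa_base,
        cebpa_cobind_frac=dict(sorted(cebpa_cobind_frac.items())),
        hist_abs_min=hist_abs_min, annotated=annotation is not None,
    )
    return BindingResult(peaks=peaks, reads=reads, truth=truth,
                         library_sizes=library_sizes, params=params,
                         infeasible=infeasible)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionResult:
    expr: pd.DataFrame          # genes × samples, log2 scale
    design: pd.Series           # sample -> uninduced / induced
    up_genes: list[str]
    params: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expr.to_csv(outdir / "expression.tsv", sep="\t",
                         index_label="gene_id", float_format="%.6f")
        self.design.rename("condition").to_csv(outdir / "design.tsv", sep="\t",
                                               index_label="sample_id")
        pd.Series(sorted(self.up_genes), name="gene_id").to_csv(
            outdir / "truth_up_genes.tsv", sep="\t", index=False
        )
        _write_manifest(outdir, "expression", self.params)


def generate_expression_matrix(
    n_genes: int = 5_000,
    n_samples_per_condition: int = 3,
    n_up_genes: int = 100,
    effect_log2fc: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    gene_ids: list[str] | None = None,
    up_genes: list[str] | None = None,
) -> ExpressionResult:
    """Gaussian log2 intensities with planted up-regulated genes.

    Non-planted genes are null (same mean in both conditions); planted genes
    are shifted by ``effect_log2fc`` in the induced samples. Passing
    ``up_genes`` plants the effect on those identifiers (they must be a
    subset of ``gene_ids``); ``effect_log2fc=0`` records an empty truth.
    """
    if n_samples_per_condition < 2:
        raise ValueError("need at least 2 samples per condition")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)
        n_genes = len(gene_ids)
    if up_genes is None:
        if n_up_genes > n_genes:
            raise ValueError("n_up_genes cannot exceed n_genes")
        up_genes = list(np.array(gene_ids)[
            rng.choice(n_genes, size=n_up_genes, replace=False)
        ])
    else:
        unknown = set(up_genes) - set(gene_ids)
        if unknown:
            raise ValueError(f"up_genes not in gene_ids: {sorted(unknown)[:5]}")
        up_genes = list(up_genes)
    samples = ([f"uninduced_{i + 1}" for i in range(n_samples_per_condition)]
               + [f"induced_{i + 1}" for i in range(n_samples_per_condition)])
    design = pd.Series(
        ["uninduced"] * n_samples_per_condition
        + ["induced"] * n_samples_per_condition,
        index=samples, name="condition",
    )
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = base[:, None] + rng.normal(0.0, noise_sd,
                                        size=(n_genes, len(samples)))
    up_mask = pd.Index(gene_ids).isin(up_genes)
    induced_cols = np.array([design[s] == "induced" for s in samples])
    values[np.ix_(up_mask, induced_cols)] += effect_log2fc
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples)
    truth_up = [] if effect_log2fc == 0 else sorted(up_genes)
    params = dict(
        generator="expression", seed=seed, n_genes=n_genes,
        n_samples_per_condition=n_samples_per_condition,
        n_up_genes=len(up_genes), effect_log2fc=effect_log2fc,
        noise_sd=noise_sd, baseline_mean=baseline_mean, baseline_sd=baseline_sd,
    )
    return ExpressionResult(expr=expr, design=design, up_genes=truth_up,
                            params=params)


# ---------------------------------------------------------------------------
# labeled cohort
# ---------------------------------------------------------------------------

_DEFAULT_LABEL_TABLE = {
    "karyotype": [
        {"normal": 0.8, "other": 0.2},
        {"t(8;21)": 0.6, "normal": 0.4},
        {"t(15;17)": 0.9, "normal": 0.1},
    ]
}


@dataclass
class CohortResult:
    expr: pd.DataFrame            # genes × samples
    metadata: pd.DataFrame        # indexed by sample
    cluster_labels: pd.Series     # planted truth: sample -> cluster (1-based)
    signature_genes: list[str]
    params: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expr.to_csv(outdir / "cohort_expression.tsv", sep="\t",
                         index_label="gene_id", float_format="%.6f")
        self.metadata.to_csv(outdir / "cohort_metadata.tsv", sep="\t",
                             index_label="sample_id")
        self.cluster_labels.rename("cluster").to_csv(
            outdir / "truth_cohort_clusters.tsv", sep="\t",
            index_label="sample_id"
        )
        pd.Series(self.signature_genes, name="gene_id").to_csv(
            outdir / "cohort_signature.tsv", sep="\t", index=False
        )
        _write_manifest(outdir, "cohort", self.params)


def generate_labeled_cohort(
    n_samples: int = 60,
    n_clusters: int = 3,
    signature_genes: list[str] | None = None,
    separation: float = 3.0,
    label_table: dict[str, list[dict[str, float]]] | None = None,
    seed: int = 0,
    n_background_genes: int = 200,
    noise_sd: float = 1.0,
    baseline_mean: float = 8.0,
    marker_gene: str | None = None,
    marker_levels: list[float] | None = None,
) -> CohortResult:
    """Expression cohort with planted sample clusters and categorical labels.

    Each planted cluster has its own mean profile over the signature genes,
    drawn N(0, 1) and scaled by ``separation`` (``separation=0`` leaves no
    recoverable structure). Background genes carry no cluster signal.
    Categorical labels are drawn per cluster from ``label_table``
    (column → per-cluster value→probability maps, cycled if shorter than
    ``n_clusters``). An optional ``marker_gene`` row carries cluster-specific
    planted means (default evenly spaced levels).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    if signature_genes is None:
        signature_genes = [f"SIG{i:03d}" for i in range(30)]
    signature_genes = list(signature_genes)
    if label_table is None:
        label_table = _DEFAULT_LABEL_TABLE

    samples = [f"S{i:03d}" for i in range(n_samples)]
    clusters = np.array([i % n_clusters + 1 for i in range(n_samples)])
    centroids = rng.normal(0.0, 1.0, size=(n_clusters, len(signature_genes)))
    centroids *= separation

    sig_values = (baseline_mean + centroids[clusters - 1]
                  + rng.normal(0.0, noise_sd,
                               size=(n_samples, len(signature_genes)))).T
    bg_ids = [f"BG{i:04d}" for i in range(n_background_genes)]
    bg_base = rng.normal(baseline_mean, 1.0, size=n_background_genes)
    bg_values = bg_base[:, None] + rng.normal(
        0.0, noise_sd, size=(n_background_genes, n_samples)
    )
    rows = [pd.DataFrame(sig_values, index=signature_genes, columns=samples),
            pd.DataFrame(bg_values, index=bg_ids, columns=samples)]
    if marker_gene is not None:
        if marker_levels is None:
            marker_levels = list(np.linspace(baseline_mean - 3,
                                             baseline_mean + 3, n_clusters))
        marker_row = (np.asarray(marker_levels)[clusters - 1]
                      + rng.normal(0.0, noise_sd, size=n_samples))
        rows.append(pd.DataFrame(marker_row[None, :], index=[marker_gene],
                                 columns=samples))
    expr = pd.concat(rows)
    expr.index.name = "gene_id"

    meta = {}
    for column, per_cluster in label_table.items():
        values = []
        for c in clusters:
            table = per_cluster[(c - 1) % len(per_cluster)]
            cats = sorted(table)
            probs = np.array([table[v] for v in cats], dtype=float)
            probs = probs / probs.sum()
            values.append(cats[rng.choice(len(cats), p=probs)])
        meta[column] = values
    metadata = pd.DataFrame(meta, index=pd.Index(samples, name="sample_id"))

    params = dict(
        generator="cohort", seed=seed, n_samples=n_samples,
        n_clusters=n_clusters, n_signature_genes=len(signature_genes),
        separation=separation, n_background_genes=n_background_genes,
        noise_sd=noise_sd, baseline_mean=baseline_mean,
        marker_gene=marker_gene,
    )
    return CohortResult(
        expr=expr,
        metadata=metadata,
        cluster_labels=pd.Series(clusters, index=samples, name="cluster"),
        signature_genes=signature_genes,
        params=params,
    )
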