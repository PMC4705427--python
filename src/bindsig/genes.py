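"""Region-to-gene assignment and per-group genomic-distribution summaries.

The assignment cascade, applied per region:

1. overlaps a promoter interval → ``promoter``, linked to the promoter's gene;
2. else overlaps a gene body → ``intragenic``, linked to every overlapped gene;
3. else ``intergenic``: linked to the nearest gene on each genomic side
   (upstream and downstream in chromosome coordinates), each kept iff its
   edge-to-edge distance is within ``max_dist`` (default 50 kb, inclusive);
4. no gene qualifies → ``unassigned``.

Distances are edge-to-edge and 0 for touching features; an equidistant tie
keeps both flanking genes, consistent with the both-flanks rule. Peaks are
strandless, so "5'/3'" means left/right on the chromosome, not transcript
orientation; gene strand enters only through the promoter definition.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = [
    "read_annotation",
    "promoters_from_annotation",
    "assign_regions",
    "distribution_summary",
    "genes_for_group",
]

CATEGORIES = ("promoter", "intragenic", "intergenic", "unassigned")

_ANNOT_COLS = ["chrom", "start", "end", "strand", "gene_id"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with columns chrom, start, end, strand, gene_id.

    Adds a ``tss`` column: ``start`` for '+' genes, ``end`` for '−' genes
    (half-open convention; the last transcribed base of a '−' gene is
    ``end − 1``, its TSS coordinate is taken as ``end``).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    return _finalize_annotation(df)


def _finalize_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def promoters_from_annotation(
    annotation: pd.DataFrame, upstream: int = 1000, downstream: int = 200
) -> PeakSet:
    """Strand-aware fixed window around each TSS (default −1000/+200 bp)."""
    ann = annotation
    plus = ann["strand"] == "+"
    start = np.where(plus, ann["tss"] - upstream, ann["tss"] - downstream)
    end = np.where(plus, ann["tss"] + downstream, ann["tss"] + upstream)
    start = np.maximum(start, 0)
    df = pd.DataFrame(
        {"chrom": ann["chrom"], "start": start, "end": end, "name": ann["gene_id"]}
    )
    return PeakSet(df, label="promoters")


class _ChromIndex:
    """Per-chromosome search structures for overlap and flank queries."""

    def __init__(self, df: pd.DataFrame, id_col: str):
        self.by_chrom = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ids = grp[id_col].to_numpy()
            self.by_chrom[chrom] = {
                "starts": starts,
                "ends": ends,
                "ids": ids,
                "prefmax_end": np.maximum.accumulate(ends),
                # for the nearest-left query: genes sorted by end
                "ends_sorted": np.sort(ends),
                "end_order": np.argsort(ends, kind="stable"),
            }

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        d = self.by_chrom.get(chrom)
        if d is None:
            return []
        idx = np.searchsorted(d["starts"], end, side="left")
        if idx == 0 or d["prefmax_end"][idx - 1] <= start:
            return []
        cand = np.flatnonzero(
            (d["starts"][:idx] < end) & (d["ends"][:idx] > start)
        )
        return list(d["ids"][cand])

    def nearest_flanks(self, chrom: str, start: int, end: int):
        """Nearest features entirely left (end ≤ start) and right (start ≥ end).

        Returns ((left_id, left_dist) | None, (right_id, right_dist) | None).
        """
        d = self.by_chrom.get(chrom)
        if d is None:
            return None, None
        left = None
        k = np.searchsorted(d["ends_sorted"], start, side="right")
        if k > 0:
            j = d["end_order"][k - 1]
            left = (d["ids"][j], int(start - d["ends_sorted"][k - 1]))
        right = None
        k = np.searchsorted(d["starts"], end, side="left")
        if k < len(d["starts"]):
            right = (d["ids"][k], int(d["starts"][k] - end))
        return left, right


def assign_regions(
    regions: PeakSet,
    annotation: pd.DataFrame,
    promoters: PeakSet,
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Apply the promoter → intragenic → intergenic cascade to every region.

    Returns a frame with one row per region: ``region_id``, ``category``,
    ``gene_ids`` (comma-joined, possibly empty) and ``distances``
    (comma-joined bp, 0 for promoter/intragenic links).
    """
    if "name" not in promoters.df.columns:
        raise ValueError("promoter set must carry gene ids in the name column")
    prom_idx = _ChromIndex(promoters.df, "name")
    gene_idx = _ChromIndex(annotation, "gene_id")
    known_chroms = set(annotation["chrom"].unique())

    rdf = regions.df
    ids = (rdf["name"] if "name" in rdf.columns
           else pd.Series([f"region_{i:06d}" for i in range(len(rdf))]))
    records = []
    warned: set[str] = set()
    for rid, chrom, start, end in zip(
        ids, rdf["chrom"], rdf["start"].astype(int), rdf["end"].astype(int)
    ):
        if chrom not in known_chroms:
            if chrom not in warned:
                warnings.warn(f"chromosome {chrom!r} absent from annotation")
                warned.add(chrom)
            records.append((rid, "unassigned", [], []))
            continue
        prom_genes = prom_idx.overlapping(chrom, start, end)
        if prom_genes:
            genes = sorted(set(prom_genes))
            records.append((rid, "promoter", genes, [0] * len(genes)))
            continue
        body_genes = gene_idx.overlapping(chrom, start, end)
        if body_genes:
            genes = sorted(set(body_genes))
            records.append((rid, "intragenic", genes, [0] * len(genes)))
            continue
        left, right = gene_idx.nearest_flanks(chrom, start, end)
        genes, dists = [], []
        for flank in (left, right):
            if flank is not None and flank[1] <= max_dist:
                genes.append(flank[0])
                dists.append(flank[1])
        if genes:
            records.append((rid, "intergenic", genes, dists))
        else:
            records.append((rid, "unassigned", [], []))
    out = pd.DataFrame(records, columns=["region_id", "category", "gene_list", "dist_list"])
    out["gene_ids"] = out["gene_list"].apply(",".join)
    out["distances"] = out["dist_list"].apply(lambda ds: ",".join(map(str, ds)))
    return out.set_index("region_id")


def distribution_summary(
    assignments: pd.DataFrame, groups: pd.Series
) -> dict[str, dict[str, float]]:
    """Per-group fractions of each category plus the intra+intergenic composite.

    ``groups`` maps region_id → group label; every region must appear in
    both tables. Fractions use all regions of the group as denominator.
    """
    joined = assignments.join(groups.rename("group"), how="inner")
    if len(joined) != len(assignments):
        raise ValueError("every assigned region needs a group label")
    summary: dict[str, dict[str, float]] = {}
    for group, grp in joined.groupby("group"):
        n = len(grp)
        frac = {
            cat: float((grp["category"] == cat).sum()) / n for cat in CATEGORIES
        }
        frac["intra_intergenic"] = frac["intragenic"] + frac["intergenic"]
        frac["n_regions"] = n
        summary[str(group)] = frac
    return summary


def genes_for_group(
    assignments: pd.DataFrame, groups: pd.Series, group: str
) -> set[str]:
    """Deduplicated union of gene ids over all regions carrying the label."""
    ids = groups[groups == group].index
    sub = assignments.loc[assignments.index.intersection(ids)]
    out: set[str] = set()
    for genes in sub["gene_list"]:
        out.update(genes)
    return out
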