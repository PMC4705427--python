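"""Per-region read counting and length/depth normalization.

The "coverage score" of a region is the number of reads overlapping it by at
least 1 bp (bedtools-intersect semantics: a read spanning two regions counts
once in each), normalized to reads per kilobase of region per million mapped
reads (RPKM on peak regions). Histone-mark assays are scored over fixed-width
(default 800 bp) windows centred on each region's midpoint, so that length
normalization is a constant factor and scores are comparable across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import PeakSet, resize_peakset

__all__ = [
    "CoverageMatrix",
    "NormalizationError",
    "count_reads",
    "normalize",
    "score_histone_regions",
    "build_coverage_matrix",
]


class NormalizationError(ValueError):
    """Raised when normalization is impossible (zero library size)."""


def _count_overlaps(regions: pd.DataFrame, reads: PeakSet) -> np.ndarray:
    """Reads overlapping each region by ≥1 bp; regions may overlap each other.

    Uses the identity  #{reads : read.start < region.end and read.end >
    region.start} = #{start < region.end} − #{end ≤ region.start}, valid
    per chromosome with independently sorted start and end arrays.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    if len(regions) == 0 or len(reads) == 0:
        return counts
    by_chrom = {}
    for chrom, grp in reads.df.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            np.sort(grp["start"].to_numpy()),
            np.sort(grp["end"].to_numpy()),
        )
    for chrom, grp in regions.groupby("chrom", sort=False):
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        rstarts, rends = arr
        n_start_before = np.searchsorted(rstarts, grp["end"].to_numpy(), side="left")
        n_end_at_or_before = np.searchsorted(rends, grp["start"].to_numpy(), side="right")
        counts[grp.index.to_numpy()] = n_start_before - n_end_at_or_before
    return counts


def count_reads(regions: PeakSet, reads: PeakSet | str | Path) -> tuple[np.ndarray, int]:
    """Raw read count per merged region plus the library size.

    ``regions`` must be merged and sorted (the contract every grouping
    decision relies on); ``reads`` is a read-position BED (single-base reads
    are fine, treated as 1 bp intervals). Library size is the total number of
    reads in the file, mapped anywhere.
    """
    if isinstance(reads, (str, Path)):
        reads = PeakSet.read_bed(reads)
    if not regions.is_merged():
        raise ValueError("region set must be merged and sorted (overlapping regions found)")
    counts = _count_overlaps(regions.df, reads)
    return counts, len(reads)


def normalize(raw: np.ndarray, library_size: int, lengths: np.ndarray) -> np.ndarray:
    """Reads per kb per million mapped reads: raw · 10^6/library · 10^3/length."""
    if library_size <= 0:
        raise NormalizationError(
            f"library size must be positive, got {library_size}"
        )
    raw = np.asarray(raw, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise NormalizationError("region lengths must be positive")
    return raw * (1e6 / library_size) * (1e3 / lengths)


def score_histone_regions(
    regions: PeakSet, reads: PeakSet | str | Path, width: int = 800
) -> tuple[np.ndarray, np.ndarray, int]:
    """Count and normalize a histone assay over fixed-width resized regions.

    Each region is replaced by a ``width`` bp window centred on its midpoint
    before counting; normalization uses the fixed width as the length.
    Returns (raw counts, normalized scores, library size) aligned with the
    input region order.
    """
    if isinstance(reads, (str, Path)):
        reads = PeakSet.read_bed(reads)
    if not regions.is_merged():
        raise ValueError("region set must be merged and sorted (overlapping regions found)")
    df = regions.df.copy()
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    start = mid - width // 2
    end = start + width
    clip = start < 0
    start[clip] = 0
    end[clip] = width
    resized = df[["chrom"]].copy()
    resized["start"] = start
    resized["end"] = end
    raw = _count_overlaps(resized, reads)
    lib = len(reads)
    norm = normalize(raw, lib, np.full(len(raw), width))
    return raw, norm, lib


@dataclass
class CoverageMatrix:
    """Raw and normalized read counts per merged region × (assay, condition).

    ``raw`` and ``norm`` are DataFrames indexed by region id with one column
    per ``assay_condition`` pair; ``library_sizes`` maps the same keys to
    total mapped reads. ``lengths`` records the length used for each assay's
    normalization (region length, or the fixed window for histone assays).
    """

    regions: PeakSet
    raw: pd.DataFrame
    norm: pd.DataFrame
    library_sizes: dict[str, int]
    lengths: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def region_ids(self) -> pd.Index:
        return self.raw.index

    def column(self, assay: str, condition: str) -> str:
        key = f"{assay}_{condition}"
        if key not in self.raw.columns:
            raise KeyError(
                f"assay/condition column {key!r} not in coverage matrix "
                f"(have {list(self.raw.columns)})"
            )
        return key

    def to_frame(self) -> pd.DataFrame:
        """Wide table: region coordinates then raw_* and norm_* columns."""
        base = self.regions.df[[c for c in ("chrom", "start", "end", "sources")
                                if c in self.regions.df.columns]].copy()
        base.index = self.raw.index
        raw = self.raw.add_prefix("raw_")
        norm = self.norm.add_prefix("norm_")
        return pd.concat([base, raw, norm], axis=1)

    def write(self, counts_path: str | Path, libsizes_path: str | Path) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index_label="region_id",
                               float_format="%.6g")
        pd.Series(self.library_sizes, name="library_size").to_csv(
            libsizes_path, sep="\t", index_label="assay_condition"
        )


def build_coverage_matrix(
    regions: PeakSet,
    read_sets: dict[tuple[str, str], PeakSet | str | Path],
    histone_assays: tuple[str, ...] = ("H3K27ac",),
    histone_width: int = 800,
) -> CoverageMatrix:
    """Assemble the full region × (assay, condition) coverage matrix.

    ``read_sets`` maps (assay, condition) to a read-position BED. Assays
    listed in ``histone_assays`` are scored over fixed-width windows; all
    others over the merged region itself.
    """
    if "name" in regions.df.columns:
        ids = pd.Index(regions.df["name"], name="region_id")
    else:
        ids = pd.Index([f"region_{i:06d}" for i in range(len(regions))],
                       name="region_id")
    raw_cols: dict[str, np.ndarray] = {}
    norm_cols: dict[str, np.ndarray] = {}
    libs: dict[str, int] = {}
    lengths: dict[str, np.ndarray] = {}
    region_lengths = regions.lengths()
    for (assay, cond), reads in sorted(read_sets.items()):
        key = f"{assay}_{cond}"
        if assay in histone_assays:
            raw, norm, lib = score_histone_regions(regions, reads, width=histone_width)
            lengths[assay] = np.full(len(regions), histone_width)
        else:
            raw, lib = count_reads(regions, reads)
            norm = normalize(raw, lib, region_lengths)
            lengths[assay] = region_lengths
        raw_cols[key] = raw
        norm_cols[key] = norm
        libs[key] = lib
    return CoverageMatrix(
        regions=regions,
        raw=pd.DataFrame(raw_cols, index=ids),
        norm=pd.DataFrame(norm_cols, index=ids),
        library_sizes=libs,
        lengths=lengths,
    )
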