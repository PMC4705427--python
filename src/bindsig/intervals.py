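"""Genomic interval algebra on 0-based half-open (BED) coordinates.

All peak arithmetic in the pipeline runs through this module: merging peak
calls from two conditions into a single region set (recording which condition
contributed each region), overlap queries, and fixed-width resizing used for
histone-mark scoring. Peaks are strandless; strand only matters for gene
assignment, which lives elsewhere.

Two intervals overlap iff they share at least one base under half-open
arithmetic (``a.start < b.end and b.start < a.end``); bookended intervals
(``a.end == b.start``) do not overlap and are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "IntervalError",
    "BedParseError",
    "merge_peaks",
    "merge_two_condition_peaks",
    "overlaps_any",
    "resize_to_fixed_width",
    "read_chrom_sizes",
]


class IntervalError(ValueError):
    """An interval violates the coordinate contract (start ≥ 0, end > start)."""


class BedParseError(ValueError):
    """A BED record could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strandless half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        """Floor midpoint; fixed so that fixed-width resizing is deterministic."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


#: column layout shared by every PeakSet dataframe
_CORE_COLS = ["chrom", "start", "end"]


class PeakSet:
    """An ordered collection of intervals backed by a pandas DataFrame.

    The frame always carries ``chrom``, ``start``, ``end`` and optionally
    ``name``, ``score`` and ``sources`` (set by the two-condition merge).
    Rows are kept sorted by (chrom, start, end); construction validates the
    interval contract.
    """

    def __init__(self, df: pd.DataFrame | None = None, label: str = ""):
        if df is None:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        df = df.copy()
        for col in _CORE_COLS:
            if col not in df.columns:
                raise ValueError(f"PeakSet frame missing column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = (df["start"] < 0) | (df["end"] <= df["start"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = df.iloc[i]
            raise IntervalError(
                f"malformed interval at row {i}: "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.df = df
        self.label = label

    # -- construction ------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], label: str = "") -> "PeakSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "name": iv.name, "score": iv.score}
            for iv in intervals
        ]
        if not rows:
            return cls(label=label)
        df = pd.DataFrame(rows)
        if df["name"].isna().all():
            df = df.drop(columns=["name"])
        if df["score"].isna().all():
            df = df.drop(columns=["score"])
        return cls(df, label=label)

    @classmethod
    def read_bed(cls, path: str | Path, label: str | None = None) -> "PeakSet":
        """Read BED3/BED6 (tab-separated, no header; extra columns ignored)."""
        path = Path(path)
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                if start < 0 or end <= start:
                    raise BedParseError(
                        f"{path}:{lineno}: malformed interval {parts[0]}:{start}-{end}"
                    )
                rec = {"chrom": parts[0], "start": start, "end": end}
                if len(parts) > 3:
                    rec["name"] = parts[3]
                if len(parts) > 4:
                    try:
                        rec["score"] = float(parts[4])
                    except ValueError:
                        rec["score"] = np.nan
                rows.append(rec)
        df = pd.DataFrame(rows) if rows else None
        return cls(df, label=label if label is not None else path.stem)

    def to_bed(self, path: str | Path) -> None:
        """Write sorted BED; name/score columns included when present."""
        cols = [c for c in ("chrom", "start", "end", "name", "score") if c in self.df.columns]
        out = self.df[cols].copy()
        if "score" in out.columns and "name" not in out.columns:
            out.insert(3, "name", ".")
        out.to_csv(path, sep="\t", header=False, index=False)

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        has_name = "name" in self.df.columns
        has_score = "score" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                name=getattr(row, "name", None) if has_name else None,
                score=getattr(row, "score", None) if has_score else None,
            )

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self.df.iloc[i]
        return GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]),
            name=row.get("name"), score=row.get("score"),
        )

    # -- properties --------------------------------------------------------
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bases(self) -> int:
        """Sum of interval lengths (double counts overlap unless merged)."""
        return int(self.lengths().sum())

    def is_merged(self) -> bool:
        """True when sorted rows are pairwise non-overlapping within chromosomes."""
        df = self.df
        if len(df) < 2:
            return True
        same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        ov = df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]
        return not bool((same & ov).any())


def _sweep_merge(df: pd.DataFrame) -> pd.DataFrame:
    """Connected components of ≥1 bp overlaps; returns envelopes + source union.

    Input must be sorted by (chrom, start, end) and may carry a ``source``
    column; output columns are chrom/start/end/sources.
    """
    if df.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "sources": pd.Series(dtype=str)})
    out = []
    has_src = "source" in df.columns
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # running max of interval ends seen so far (exclusive of current row)
        cmax = np.maximum.accumulate(ends)
        newcomp = np.ones(len(grp), dtype=bool)
        newcomp[1:] = starts[1:] >= cmax[:-1]  # bookended intervals do not merge
        comp = np.cumsum(newcomp) - 1
        g = pd.DataFrame({"start": starts, "end": ends, "comp": comp})
        if has_src:
            g["source"] = grp["source"].to_numpy()
        agg = g.groupby("comp").agg(start=("start", "min"), end=("end", "max"))
        if has_src:
            agg["sources"] = g.groupby("comp")["source"].agg(
                lambda s: ",".join(sorted(set(s)))
            )
        else:
            agg["sources"] = ""
        agg.insert(0, "chrom", chrom)
        out.append(agg.reset_index(drop=True))
    return pd.concat(out, ignore_index=True)


def merge_peaks(ps: PeakSet) -> PeakSet:
    """Merge overlapping intervals within a single set."""
    merged = _sweep_merge(ps.df[_CORE_COLS])
    return PeakSet(merged.drop(columns=["sources"]), label=ps.label)


def merge_two_condition_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union of two peak sets with overlapping (≥1 bp) intervals merged.

    Every connected component of overlapping intervals is replaced by its
    envelope [min start, max end). The result carries a ``sources`` column
    recording which input set(s) contributed to each merged region, and a
    ``name`` column with stable region identifiers.
    """
    la = a.label or "a"
    lb = b.label or "b"
    if la == lb:
        la, lb = la + "_1", lb + "_2"
    frames = []
    for ps, src in ((a, la), (b, lb)):
        d = ps.df[_CORE_COLS].copy()
        d["source"] = src
        frames.append(d)
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort")
    merged = _sweep_merge(allp)
    merged["name"] = [f"region_{i:06d}" for i in range(len(merged))]
    return PeakSet(merged, label=f"merged({la},{lb})")


def overlaps_any(query: PeakSet, reference: PeakSet) -> tuple[np.ndarray, int]:
    """Flag each query interval that shares ≥1 bp with any reference interval.

    Returns (boolean vector aligned with ``query.df`` row order, count of
    flagged queries). An empty reference yields all-False.
    """
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(reference) == 0:
        return flags, 0
    ref_by_chrom = {}
    for chrom, grp in reference.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # starts are sorted; prefix max of ends answers "any end > x among
        # reference intervals starting before y" in O(log n)
        ref_by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    qdf = query.df
    for chrom, grp in qdf.groupby("chrom", sort=False):
        ref = ref_by_chrom.get(chrom)
        if ref is None:
            continue
        starts, prefmax = ref
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        idx = np.searchsorted(starts, qe, side="left")  # refs with start < q.end
        hit = idx > 0
        hit[hit] = prefmax[idx[hit] - 1] > qs[hit]
        flags[grp.index.to_numpy()] = hit
    return flags, int(flags.sum())


def resize_to_fixed_width(
    region: GenomicInterval,
    width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Centre a fixed-width window on the region's floor midpoint.

    If the left edge would fall below 0 the window is shifted right,
    preserving the width; with ``chrom_sizes`` the right edge is clamped
    symmetrically (shift left).
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    mid = region.midpoint()
    start = mid - width // 2
    end = start + width
    if start < 0:
        start, end = 0, width
    if chrom_sizes is not None:
        size = chrom_sizes.get(region.chrom)
        if size is not None and end > size:
            end = size
            start = end - width
            if start < 0:
                raise IntervalError(
                    f"chromosome {region.chrom} ({size} bp) shorter than width {width}"
                )
    return GenomicInterval(region.chrom, start, end, name=region.name)


def resize_peakset(ps: PeakSet, width: int,
                   chrom_sizes: Mapping[str, int] | None = None) -> PeakSet:
    """Vectorised fixed-width resize of every interval in a set.

    Note the result may contain overlapping intervals even if the input was
    merged; callers that need merged output must re-merge.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    df = ps.df.copy()
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    start = mid - width // 2
    end = start + width
    left_clip = start < 0
    start[left_clip] = 0
    end[left_clip] = width
    if chrom_sizes is not None:
        sizes = df["chrom"].map(chrom_sizes).to_numpy()
        over = end > sizes
        if np.any(over & (sizes < width)):
            raise IntervalError(f"chromosome shorter than width {width}")
        end[over] = sizes[over]
        start[over] = end[over] - width
    df["start"] = start
    df["end"] = end
    out = PeakSet(df, label=ps.label)
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, size)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes
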