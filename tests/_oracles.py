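"""Brute-force oracles, independent of the package's sweep/searchsorted paths.

Overlap is decided by dense all-pairs broadcasting; merge components come
from scipy's connected-components on the overlap graph. Quadratic in the
number of intervals, usable up to a few thousand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def overlap_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean len(a) × len(b) matrix of ≥1 bp half-open overlap."""
    same = a["chrom"].to_numpy()[:, None] == b["chrom"].to_numpy()[None, :]
    lt = a["start"].to_numpy()[:, None] < b["end"].to_numpy()[None, :]
    gt = a["end"].to_numpy()[:, None] > b["start"].to_numpy()[None, :]
    return same & lt & gt


def brute_overlaps_any(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    if len(reference) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    return overlap_matrix(query, reference).any(axis=1)


def brute_merge(df: pd.DataFrame) -> pd.DataFrame:
    """Envelopes of connected overlap components, sorted by coordinate.

    Also returns per-component source sets when a ``source`` column exists.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "sources"])
    adj = overlap_matrix(df, df)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    out = []
    for comp in np.unique(labels):
        sub = df.iloc[np.flatnonzero(labels == comp)]
        rec = {
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["start"].min()),
            "end": int(sub["end"].max()),
        }
        if "source" in df.columns:
            rec["sources"] = frozenset(sub["source"])
        out.append(rec)
    return (pd.DataFrame(out)
            .sort_values(["chrom", "start", "end"])
            .reset_index(drop=True))


def brute_count_reads(regions: pd.DataFrame, reads: pd.DataFrame) -> np.ndarray:
    """Reads overlapping each region; a read spanning two regions counts twice."""
    if len(reads) == 0 or len(regions) == 0:
        return np.zeros(len(regions), dtype=int)
    return overlap_matrix(regions, reads).sum(axis=1)


def brute_three_way_venn(frames: dict[str, pd.DataFrame]) -> dict[frozenset, int]:
    """Atom membership counts over the merged union of the named sets."""
    tagged = []
    for label, df in frames.items():
        d = df[["chrom", "start", "end"]].copy()
        d["source"] = label
        tagged.append(d)
    atoms = brute_merge(pd.concat(tagged, ignore_index=True))
    counts: dict[frozenset, int] = {}
    for srcs in atoms["sources"]:
        counts[srcs] = counts.get(srcs, 0) + 1
    return counts


def random_intervals(rng: np.random.Generator, n: int,
                     n_chroms: int = 2, coord_max: int = 10_000,
                     max_len: int = 300) -> pd.DataFrame:
    chroms = rng.integers(1, n_chroms + 1, size=n)
    starts = rng.integers(0, coord_max, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": [f"chr{c}" for c in chroms],
        "start": starts,
        "end": starts + lengths,
    })
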