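"""Co-occupancy between peak sets: pairwise fractions and three-way Venns.

``cobind_fraction`` answers "what fraction of these peaks sit at sites also
bound in that set" (≥1 bp shared); ``three_way_venn`` partitions the merged
union of three peak sets into atoms (connected overlap components) and counts
atoms by which input sets contribute to them. Atom counts, not input peak
counts, are reported — a single wide peak overlapping two peaks of another
set yields one atom.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .intervals import PeakSet, merge_peaks, overlaps_any, _sweep_merge

__all__ = ["cobind_fraction", "three_way_venn"]


def cobind_fraction(query_group: PeakSet, reference_group: PeakSet) -> dict:
    """Count and percentage of query peaks sharing ≥1 bp with the reference.

    ``percent`` is rounded to 1 decimal; ``fraction`` keeps full precision.
    An empty query leaves both undefined (``None``) rather than raising.
    """
    flags, n_overlapping = overlaps_any(query_group, reference_group)
    n_query = len(query_group)
    if n_query == 0:
        return {"n_query": 0, "n_overlapping": 0, "fraction": None, "percent": None}
    fraction = n_overlapping / n_query
    return {
        "n_query": n_query,
        "n_overlapping": n_overlapping,
        "fraction": fraction,
        "percent": round(100.0 * fraction, 1),
    }


def three_way_venn(a: PeakSet, b: PeakSet, c: PeakSet) -> dict[frozenset, int]:
    """Atom counts for the 7 membership classes of three peak sets.

    Atoms are the merged connected components of the union of all three
    sets; each atom is classified by which inputs have ≥1 peak overlapping
    it. Keys are frozensets of set labels (defaults a/b/c when unlabeled).
    """
    labels = []
    for i, ps in enumerate((a, b, c)):
        labels.append(ps.label or "abc"[i])
    if len(set(labels)) != 3:
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    frames = []
    for ps, lab in zip((a, b, c), labels):
        d = ps.df[["chrom", "start", "end"]].copy()
        d["source"] = lab
        frames.append(d)
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort")
    atoms = _sweep_merge(allp)
    counts: dict[frozenset, int] = {}
    for r in range(1, 4):
        for combo in combinations(labels, r):
            counts[frozenset(combo)] = 0
    for srcs in atoms["sources"]:
        key = frozenset(srcs.split(","))
        counts[key] += 1
    return counts
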