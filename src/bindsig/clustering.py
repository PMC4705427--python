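"""Signature-restricted hierarchical clustering of expression datasets.

Samples are clustered on the expression of a target-gene signature only:
distance = 1 − Pearson correlation across the signature genes, average
linkage, cut at a user-chosen k (the method offers no automatic k
selection). Node stability is assessed by an ordinary bootstrap that
resamples signature *genes* with replacement and scores, for each internal
node of the original dendrogram, the fraction of replicate dendrograms
containing a node with the identical sample membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ClusterResult",
    "ClusterSummary",
    "cluster_by_signature",
    "summarize_clusters",
    "label_enrichment_fraction",
]


class SignatureError(ValueError):
    """Too few signature genes are present in the expression matrix."""


def _correlation_condensed(X: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson distance between rows of X (samples × genes)."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    # zero-variance rows yield NaN correlation; treat as maximally distant
    d = np.nan_to_num(d, nan=1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return squareform(d, checks=False)


def _leafsets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Sample-index set under each internal node, in merge order."""
    sets: dict[int, frozenset] = {i: frozenset((i,)) for i in range(n)}
    out = []
    for i, (ia, ib) in enumerate(Z[:, :2].astype(int)):
        s = sets[ia] | sets[ib]
        sets[n + i] = s
        out.append(s)
    return out


@dataclass
class ClusterResult:
    """Dendrogram, k-cut labels and bootstrap node support."""

    linkage: np.ndarray
    samples: list[str]
    k: int
    labels: pd.Series                      # sample -> cluster id (1..k)
    node_leafsets: list[frozenset]         # per internal node, sample indices
    bootstrap_support: list[float]         # aligned with node_leafsets
    n_boot: int
    signature_used: list[str]
    signature_missing: list[str]

    def support_for(self, sample_names: set[str]) -> float | None:
        """Bootstrap support of the node whose leaves are exactly these samples."""
        idx = frozenset(self.samples.index(s) for s in sample_names)
        for node, sup in zip(self.node_leafsets, self.bootstrap_support):
            if node == idx:
                return sup
        return None

    def to_newick(self) -> str:
        """Newick string with bootstrap support as internal-node labels."""
        tree = hierarchy.to_tree(self.linkage)
        support = {frozenset(ls): s for ls, s in
                   zip(self.node_leafsets, self.bootstrap_support)}

        def leaves(node):
            return frozenset(node.pre_order(lambda x: x.id))

        def rec(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:.6g}"
            lab = support.get(leaves(node))
            lab_s = f"{lab:.2f}" if lab is not None else ""
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f"{lab_s}:{length:.6g}")

        return rec(tree, tree.dist) + ";"


def cluster_by_signature(
    expr: pd.DataFrame,
    signature,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Cluster samples on the signature genes present in the matrix.

    ``expr`` is genes × samples; ``signature`` is any iterable of gene ids
    (a TargetGeneSet works). With ``n_boot=0`` the result is fully
    deterministic for a fixed input ordering.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_boot < 0:
        raise ValueError("n_boot must be non-negative")
    sig = sorted(getattr(signature, "genes", signature))
    present = [g for g in sig if g in expr.index]
    missing = [g for g in sig if g not in expr.index]
    if len(present) < 2:
        raise SignatureError(
            f"only {len(present)} signature genes present in matrix; "
            f"missing: {missing}"
        )
    X = expr.loc[present].to_numpy(dtype=float).T  # samples × genes
    samples = list(expr.columns)
    Z = hierarchy.linkage(_correlation_condensed(X), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    nodes = _leafsets(Z, len(samples))

    support = [float("nan")] * len(nodes)
    if n_boot > 0:
        hits = np.zeros(len(nodes))
        rng = np.random.default_rng(seed)
        node_index = {ls: i for i, ls in enumerate(nodes)}
        n_genes = X.shape[1]
        for _ in range(n_boot):
            cols = rng.integers(0, n_genes, size=n_genes)
            Zb = hierarchy.linkage(_correlation_condensed(X[:, cols]),
                                   method="average")
            for ls in _leafsets(Zb, len(samples)):
                i = node_index.get(ls)
                if i is not None:
                    hits[i] += 1
        support = list(hits / n_boot)

    return ClusterResult(
        linkage=Z,
        samples=samples,
        k=k,
        labels=pd.Series(labels, index=samples, name="cluster"),
        node_leafsets=nodes,
        bootstrap_support=support,
        n_boot=n_boot,
        signature_used=present,
        signature_missing=missing,
    )


@dataclass
class ClusterSummary:
    """Per-cluster sizes, marker means and categorical label composition."""

    sizes: dict[int, int]
    marker_gene: str | None
    marker_means: dict[int, float] = field(default_factory=dict)
    marker_argmax: int | None = None
    #: column -> DataFrame of counts (clusters × label values)
    composition: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sizes": {str(c): n for c, n in self.sizes.items()},
            "marker_gene": self.marker_gene,
            "marker_means": {str(c): v for c, v in self.marker_means.items()},
            "marker_argmax": self.marker_argmax,
            "composition": {},
        }
        for col, table in self.composition.items():
            out["composition"][col] = {
                str(cl): {str(v): int(n) for v, n in row.items()}
                for cl, row in table.iterrows()
            }
        return out


def summarize_clusters(
    result: ClusterResult,
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    marker_gene: str | None = None,
    label_columns: list[str] | None = None,
) -> ClusterSummary:
    """Sizes, marker-gene means and label composition for a clustering.

    ``metadata`` is indexed by sample and must cover every clustered sample;
    ``label_columns`` defaults to all non-numeric metadata columns.
    """
    labels = result.labels
    missing = [s for s in labels.index if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata does not cover samples: {missing[:5]}")
    sizes = labels.value_counts().sort_index().to_dict()
    summary = ClusterSummary(sizes={int(c): int(n) for c, n in sizes.items()},
                             marker_gene=marker_gene)
    if marker_gene is not None:
        if marker_gene not in expr.index:
            warnings.warn(f"marker gene {marker_gene!r} absent from matrix")
            summary.marker_gene = None
        else:
            marker = expr.loc[marker_gene, labels.index]
            means = marker.groupby(labels).mean()
            summary.marker_means = {int(c): float(v) for c, v in means.items()}
            summary.marker_argmax = int(means.idxmax())
    if label_columns is None:
        meta = metadata.loc[labels.index]
        label_columns = [c for c in meta.columns
                         if not pd.api.types.is_numeric_dtype(meta[c])]
    for col in label_columns:
        table = pd.crosstab(labels, metadata.loc[labels.index, col])
        summary.composition[col] = table
    return summary


def label_enrichment_fraction(
    summary: ClusterSummary, column: str, label_value: str, cluster_id: int
) -> dict:
    """How much of a label's total falls in one cluster (count and percent)."""
    if column not in summary.composition:
        raise KeyError(f"label column {column!r} not summarized")
    table = summary.composition[column]
    if label_value not in table.columns:
        raise KeyError(f"unknown label value {label_value!r} in column {column!r}")
    total = int(table[label_value].sum())
    count = int(table[label_value].get(cluster_id, 0))
    percent = round(100.0 * count / total, 1) if total else None
    return {"count": count, "total": total, "percent": percent}
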