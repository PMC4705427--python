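"""Differential expression and derivation of the target-gene signature.

The DE contract: quantile-normalize the log2 intensity matrix, test each
probe with an equal-variance two-sample t-statistic whose variance is
shrunk toward a common prior by empirical Bayes (the standard microarray
moderation for triplicate designs; a plain t-test is available with
``moderation=False``), adjust with Benjamini–Hochberg, and call a probe
significant when ``p_adj ≤ alpha`` **and** the linear fold change exceeds
``fc_min`` in either direction (|log2FC| > log2(fc_min)). The
high-confidence target-gene set is the intersection of genes linked to
Group I regions with genes called significantly up-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEThresholds",
    "TargetGeneSet",
    "quantile_normalize",
    "call_de",
    "collapse_probes",
    "group_expression_response",
    "derive_target_set",
]


@dataclass(frozen=True)
class DEThresholds:
    alpha: float = 0.05
    fc_min: float = 1.2
    #: when True, down-regulated probes pass the fold filter at 1/fc_min
    two_sided_fc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be ≥ 1 (linear scale)")


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common distribution of row-wise rank means.

    Ties receive the average of the reference quantiles they span (the usual
    microarray convention); on continuous data all columns end up with
    identical sorted vectors.
    """
    values = expr.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(values.shape[0], dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-8 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Prior degrees of freedom d0 and prior variance s0² from observed s².

    Fits a scaled F distribution to the per-probe sample variances on the
    log scale (method of moments with digamma/trigamma corrections). Probes
    with zero variance are excluded from the fit.
    """
    s2 = s2[s2 > 0]
    if len(s2) < 3:
        return np.inf, float(np.mean(s2)) if len(s2) else 0.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    return d0, s0_2


def _moderated_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance two-sample t with empirical-Bayes variance shrinkage.

    Per-probe pooled variances are shrunk toward the fitted prior
    ``s0²`` with ``d0`` prior degrees of freedom; the t statistic is
    referred to a t distribution with ``df + d0`` degrees of freedom.
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = (((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    s2 = ss / df
    d0, s0_2 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / denom
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # a degenerate all-constant matrix leaves t undefined; no evidence
    p = np.where(np.isnan(p), 1.0, p)
    return t, p


def call_de(
    expr: pd.DataFrame,
    design: pd.Series,
    thresholds: DEThresholds = DEThresholds(),
    gene_map: Mapping[str, str] | None = None,
    detection_p: pd.DataFrame | None = None,
    detection_max: float = 0.01,
    moderation: bool = True,
) -> pd.DataFrame:
    """Per-probe differential-expression table between two conditions.

    ``expr`` is probes × samples on the log2 scale; ``design`` maps each
    sample to ``"uninduced"`` or ``"induced"`` (at least 2 samples each).
    ``gene_map`` optionally maps probe → gene id (defaults to identity).
    ``detection_p`` is an optional probe × sample detection-p matrix; probes
    whose detection p exceeds ``detection_max`` in any sample are dropped
    before testing (absent matrix keeps all probes).

    Returns a frame indexed by probe with columns gene_id, log2fc
    (induced − uninduced mean after normalization), p_raw, p_adj,
    significant, direction.
    """
    design = design.reindex(expr.columns)
    if design.isna().any():
        raise ValueError("design does not cover every sample column")
    levels = set(design.unique())
    if levels != {"uninduced", "induced"}:
        raise ValueError(f"design must label samples uninduced/induced, got {levels}")
    n_un = int((design == "uninduced").sum())
    n_in = int((design == "induced").sum())
    if min(n_un, n_in) < 2:
        raise ValueError("need at least 2 samples per condition")

    if detection_p is not None:
        keep = (detection_p.reindex(index=expr.index, columns=expr.columns)
                .le(detection_max).all(axis=1))
        expr = expr.loc[keep]

    qn = quantile_normalize(expr)
    a = qn.loc[:, design == "induced"].to_numpy()
    b = qn.loc[:, design == "uninduced"].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if moderation:
        _, p = _moderated_ttest(a, b)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        # zero-variance probes with equal means carry no evidence
        p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]

    t = thresholds
    log_fc_min = np.log2(t.fc_min)
    if t.two_sided_fc:
        passes_fc = np.abs(log2fc) > log_fc_min
    else:
        passes_fc = log2fc > log_fc_min
    significant = (p_adj <= t.alpha) & passes_fc
    genes = (pd.Index(expr.index).map(lambda pr: gene_map.get(pr, pr))
             if gene_map is not None else expr.index)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": log2fc,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=pd.Index(expr.index, name="probe_id"),
    )


def collapse_probes(de: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: the probe with the smallest adjusted p represents it."""
    order = de.sort_values(["p_adj", "p_raw"], kind="mergesort")
    return order.loc[~order["gene_id"].duplicated()].set_index("gene_id")


def group_expression_response(
    de: pd.DataFrame,
    group_gene_sets: Mapping[str, Iterable[str]],
    reference_group: str = "I",
) -> dict:
    """Mean linear fold change of array-significant genes mapped to each group.

    For every group, genes that are significant on the array and linked to
    that group contribute ``2**log2fc`` to the group mean (a gene shared by
    two groups contributes to both). Groups other than ``reference_group``
    are compared with it by a two-sided Mann–Whitney test on log2FC. Groups
    with no significant genes are reported as absent (``None``).
    """
    bygene = collapse_probes(de)
    sig = bygene[bygene["significant"]]
    result: dict = {"groups": {}, "tests": {}}
    per_group_fc: dict[str, np.ndarray] = {}
    for group, genes in group_gene_sets.items():
        idx = sig.index.intersection(pd.Index(set(genes)))
        if len(idx) == 0:
            result["groups"][group] = None
            continue
        lfc = sig.loc[idx, "log2fc"].to_numpy()
        per_group_fc[group] = lfc
        result["groups"][group] = {
            "n_genes": int(len(idx)),
            "mean_fold_change": float(np.mean(2.0 ** lfc)),
            "mean_log2fc": float(np.mean(lfc)),
        }
    ref = per_group_fc.get(reference_group)
    for group, lfc in per_group_fc.items():
        if group == reference_group or ref is None:
            continue
        stat, p = stats.mannwhitneyu(ref, lfc, alternative="two-sided")
        result["tests"][f"{reference_group}_vs_{group}"] = {
            "U": float(stat), "p": float(p),
        }
    return result


@dataclass(frozen=True)
class TargetGeneSet:
    """The derived high-confidence target-gene signature with provenance."""

    genes: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes):
                fh.write(g + "\n")

    @classmethod
    def read(cls, path) -> "TargetGeneSet":
        with open(path) as fh:
            genes = frozenset(line.strip() for line in fh if line.strip())
        return cls(genes=genes)


def derive_target_set(group_genes: Iterable[str], de: pd.DataFrame) -> TargetGeneSet:
    """Intersect a group's gene set with significantly up-regulated genes."""
    group_genes = set(group_genes)
    bygene = collapse_probes(de)
    up = set(bygene.index[bygene["significant"] & (bygene["direction"] == "up")])
    genes = frozenset(group_genes & up)
    return TargetGeneSet(
        genes=genes,
        provenance={
            "group_gene_count": len(group_genes),
            "up_gene_count": len(up),
            "intersection_count": len(genes),
        },
    )
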