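"""Classification of merged binding regions into functional groups.

Regions are classified from two-condition fold changes of a transcription
factor (TF) assay and a histone-acetylation assay:

* **Group I** — functional de novo binding: ≥ ``fc_tf_min`` fold increase in
  TF coverage, ≥ ``fc_hist_min`` fold increase in histone coverage, and an
  absolute induced histone read count of at least ``hist_abs_min``.
* **Group II** — TF increase (≥ ``fc_tf_min``) without the Group I histone
  evidence.
* **Group III** — no TF change: fold change within a symmetric
  ``no_change_band`` (default 2-fold either way).

Everything else is left ``unclassified``; the three groups never overlap.
Fold changes are computed on normalized scores with a pseudocount so that
newly bound regions (zero in the uninduced condition) stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageMatrix

__all__ = [
    "GroupThresholds",
    "fold_change",
    "classify_regions",
    "group_sizes",
    "global_binding_summary",
    "tf_histone_correlation",
]

GROUPS = ("I", "II", "III", "unclassified")


@dataclass(frozen=True)
class GroupThresholds:
    """Cutoffs for the three-criterion classification cascade.

    ``pseudocount`` is on the normalized-score scale and is added to both
    conditions before taking ratios.
    """

    fc_tf_min: float = 4.0
    fc_hist_min: float = 4.0
    hist_abs_min: float = 50.0
    no_change_band: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fc_tf_min", "fc_hist_min", "hist_abs_min",
                     "no_change_band", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.no_change_band >= self.fc_tf_min:
            raise ValueError("no_change_band must be below fc_tf_min")


def fold_change(norm_minus, norm_plus, pseudocount: float = 1.0):
    """(plus + pc) / (minus + pc); strictly positive and finite for scores ≥ 0."""
    minus = np.asarray(norm_minus, dtype=float)
    plus = np.asarray(norm_plus, dtype=float)
    if np.any(minus < 0) or np.any(plus < 0):
        raise ValueError("normalized scores must be non-negative")
    out = (plus + pseudocount) / (minus + pseudocount)
    return out if out.ndim else float(out)


def classify_regions(
    cov: CoverageMatrix,
    assay_tf: str,
    assay_hist: str,
    thresholds: GroupThresholds = GroupThresholds(),
    cond_minus: str = "minus",
    cond_plus: str = "plus",
) -> pd.DataFrame:
    """Assign every region a group label with the fold-change evidence.

    Returns a frame indexed by region id with columns ``tf_fc``, ``hist_fc``,
    ``hist_induced_raw`` and ``group``.
    """
    t = thresholds
    tf_m = cov.norm[cov.column(assay_tf, cond_minus)].to_numpy()
    tf_p = cov.norm[cov.column(assay_tf, cond_plus)].to_numpy()
    h_m = cov.norm[cov.column(assay_hist, cond_minus)].to_numpy()
    h_p = cov.norm[cov.column(assay_hist, cond_plus)].to_numpy()
    h_raw = cov.raw[cov.column(assay_hist, cond_plus)].to_numpy()

    tf_fc = fold_change(tf_m, tf_p, t.pseudocount)
    hist_fc = fold_change(h_m, h_p, t.pseudocount)

    tf_up = tf_fc >= t.fc_tf_min
    group_i = tf_up & (hist_fc >= t.fc_hist_min) & (h_raw >= t.hist_abs_min)
    group_ii = tf_up & ~group_i
    no_change = np.maximum(tf_fc, 1.0 / tf_fc) <= t.no_change_band
    group_iii = no_change & ~tf_up

    group = np.full(len(tf_fc), "unclassified", dtype=object)
    group[group_iii] = "III"
    group[group_ii] = "II"
    group[group_i] = "I"
    return pd.DataFrame(
        {
            "tf_fc": tf_fc,
            "hist_fc": hist_fc,
            "hist_induced_raw": h_raw,
            "group": group,
        },
        index=cov.region_ids,
    )


def group_sizes(assignment: pd.DataFrame) -> dict[str, int]:
    counts = assignment["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def global_binding_summary(
    cov: CoverageMatrix,
    assay: str,
    thresholds: GroupThresholds = GroupThresholds(),
    cond_minus: str = "minus",
    cond_plus: str = "plus",
) -> dict:
    """Peak-set comparison between conditions plus the mean coverage fold.

    Requires the coverage matrix to be built on a two-condition merge whose
    regions carry ``sources`` contribution flags. ``mean_fold_increase`` is
    the arithmetic mean over all merged regions of the pseudocounted
    normalized fold change (mean of ratios).
    """
    rdf = cov.regions.df
    if "sources" not in rdf.columns:
        raise ValueError(
            "regions carry no contribution flags; build them with "
            "merge_two_condition_peaks"
        )
    sources = rdf["sources"].astype(str)
    # contribution labels are '<label>' strings joined by ','; the minus/plus
    # condition tag is the suffix of the originating peak-set label
    def _has(cond: str) -> pd.Series:
        return sources.str.split(",").apply(
            lambda toks: any(tok.endswith(cond) for tok in toks)
        )

    in_minus = _has(cond_minus).to_numpy()
    in_plus = _has(cond_plus).to_numpy()
    fc = fold_change(
        cov.norm[cov.column(assay, cond_minus)].to_numpy(),
        cov.norm[cov.column(assay, cond_plus)].to_numpy(),
        thresholds.pseudocount,
    )
    return {
        "n_regions": int(len(rdf)),
        "n_peaks_minus": int(in_minus.sum()),
        "n_peaks_plus": int(in_plus.sum()),
        "n_new": int((in_plus & ~in_minus).sum()),
        "n_lost": int((in_minus & ~in_plus).sum()),
        "n_shared": int((in_minus & in_plus).sum()),
        "mean_fold_increase": float(np.mean(fc)),
    }


def tf_histone_correlation(
    cov: CoverageMatrix,
    assay_tf: str,
    assay_hist: str,
    pseudocount: float = 1.0,
    cond_minus: str = "minus",
    cond_plus: str = "plus",
) -> dict:
    """Pearson r between log2 TF and log2 histone fold changes over regions.

    Returns ``{"r": float | nan, "p": float | nan, "n": int}``; a
    zero-variance vector leaves r undefined (NaN) rather than raising.
    """
    if len(cov.region_ids) < 3:
        raise ValueError("need at least 3 regions for a correlation")
    x = np.log2(fold_change(
        cov.norm[cov.column(assay_tf, cond_minus)].to_numpy(),
        cov.norm[cov.column(assay_tf, cond_plus)].to_numpy(),
        pseudocount,
    ))
    y = np.log2(fold_change(
        cov.norm[cov.column(assay_hist, cond_minus)].to_numpy(),
        cov.norm[cov.column(assay_hist, cond_plus)].to_numpy(),
        pseudocount,
    ))
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": int(len(x))}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}
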