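"""Group I/II/III classification and the global binding summaries."""

import numpy as np
import pandas as pd
import pytest

from bindsig.coverage import CoverageMatrix
from bindsig.grouping import (GroupThresholds, classify_regions, fold_change,
                              global_binding_summary, group_sizes,
                              tf_histone_correlation)
from bindsig.intervals import PeakSet
from conftest import make_peakset


def coverage_from_counts(tf_minus, tf_plus, hist_minus, hist_plus,
                         library_size=1_000_000, length=1000, sources=None):
    """CoverageMatrix with raw counts used directly (no read sampling).

    With library 10^6 and 1 kb regions the normalized score equals the raw
    count, so planted means translate 1:1 into scores.
    """
    n = len(tf_minus)
    rows = [("chr1", 1000 + i * 10_000, 1000 + i * 10_000 + length,
             f"region_{i:06d}") for i in range(n)]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if sources is not None:
        df["sources"] = sources
    regions = PeakSet(df)
    raw = pd.DataFrame(
        {"TF_minus": tf_minus, "TF_plus": tf_plus,
         "H_minus": hist_minus, "H_plus": hist_plus},
        index=pd.Index([r[3] for r in rows], name="region_id"), dtype=float)
    norm = raw * (1e6 / library_size) * (1e3 / length)
    return CoverageMatrix(regions=regions, raw=raw, norm=norm,
                          library_sizes={c: library_size for c in raw.columns})


class TestFoldChange:
    @pytest.mark.parametrize("minus,plus,pc,expected",
                             [(10, 10, 1, 1.0), (0, 0, 1, 1.0), (3, 15, 1, 4.0)])
    def test_pseudocounted_ratio(self, minus, plus, pc, expected):
        assert fold_change(minus, plus, pc) == pytest.approx(expected)

    def test_rejects_negative_scores(self):
        with pytest.raises(ValueError):
            fold_change(-1, 5)


class TestClassify:
    def test_three_criterion_cascade(self):
        cov = coverage_from_counts(
            tf_minus=[10, 10, 50, 10],
            tf_plus=[80, 80, 55, 25],
            hist_minus=[20, 100, 30, 30],
            hist_plus=[160, 110, 30, 30],
        )
        out = classify_regions(cov, "TF", "H")
        assert list(out["group"]) == ["I", "II", "III", "unclassified"]

    def test_histone_floor_is_raw_induced_count(self):
        # strong folds but induced histone raw count below 50 → Group II
        cov = coverage_from_counts([5], [40], [4], [40])
        out = classify_regions(cov, "TF", "H")
        assert list(out["group"]) == ["II"]

    def test_groups_partition_regions(self, rng):
        n = 500
        cov = coverage_from_counts(
            rng.integers(0, 300, n), rng.integers(0, 300, n),
            rng.integers(0, 300, n), rng.integers(0, 300, n))
        out = classify_regions(cov, "TF", "H")
        assert out["group"].isin(["I", "II", "III", "unclassified"]).all()
        assert sum(group_sizes(out).values()) == n

    def test_invariant_to_common_library_rescaling(self):
        # counts away from the decision boundaries: a 4x deeper pair of
        # libraries (both conditions) must not change any group call
        tf_m = [30, 10, 0, 100]
        tf_p = [240, 80, 200, 110]
        h_m = [50, 60, 5, 50]
        h_p = [400, 70, 300, 55]
        a = classify_regions(
            coverage_from_counts(tf_m, tf_p, h_m, h_p, library_size=1_000_000),
            "TF", "H")
        scaled = [4 * np.asarray(v) for v in (tf_m, tf_p, h_m, h_p)]
        b = classify_regions(
            coverage_from_counts(*scaled, library_size=4_000_000),
            "TF", "H")
        assert list(a["group"]) == list(b["group"])

    def test_missing_assay_column_raises(self):
        cov = coverage_from_counts([10], [20], [10], [20])
        with pytest.raises(KeyError, match="CEBPA_minus"):
            classify_regions(cov, "CEBPA", "H")

    def test_noise_free_planted_means_fully_recovered(self):
        cov = coverage_from_counts(
            tf_minus=[30] * 10 + [30] * 10 + [30] * 10,
            tf_plus=[240] * 10 + [240] * 10 + [30] * 10,
            hist_minus=[50] * 30,
            hist_plus=[400] * 10 + [50] * 20,
        )
        out = classify_regions(cov, "TF", "H")
        assert list(out["group"]) == ["I"] * 10 + ["II"] * 10 + ["III"] * 10


class TestGlobalSummary:
    def test_identical_peak_sets_share_everything(self):
        a = make_peakset([("chr1", 0, 100), ("chr1", 500, 600)], "TF_minus")
        b = make_peakset([("chr1", 0, 100), ("chr1", 500, 600)], "TF_plus")
        from bindsig.coverage import build_coverage_matrix
        from bindsig.intervals import merge_two_condition_peaks
        merged = merge_two_condition_peaks(a, b)
        reads = make_peakset([("chr1", 10, 60)])
        cov = build_coverage_matrix(merged, {("TF", "minus"): reads,
                                             ("TF", "plus"): reads},
                                    histone_assays=())
        s = global_binding_summary(cov, "TF")
        assert s["n_new"] == 0 and s["n_lost"] == 0 and s["n_shared"] == 2
        assert s["mean_fold_increase"] == pytest.approx(1.0)

    def test_planted_eightfold_recovered_within_5_percent(self):
        from bindsig.coverage import build_coverage_matrix
        from bindsig.intervals import merge_two_condition_peaks
        from bindsig.simulate import generate_binding_experiment

        bind = generate_binding_experiment(
            n_regions_per_group={"I": 300, "II": 0, "III": 0},
            depth=1_000_000, fold_pu1=8.0, fold_h3k27ac=8.0,
            new_binding_frac=0.0, include_cebpa=False, seed=21)
        merged = merge_two_condition_peaks(bind.peaks[("PU1", "minus")],
                                           bind.peaks[("PU1", "plus")])
        cov = build_coverage_matrix(merged, {k: v for k, v in bind.reads.items()
                                             if k[0] == "PU1"})
        s = global_binding_summary(cov, "PU1")
        assert s["mean_fold_increase"] == pytest.approx(8.0, rel=0.05)


class TestCorrelation:
    def test_identical_vectors_give_r_one(self):
        cov = coverage_from_counts([10, 20, 40, 5], [20, 80, 45, 50],
                                   [10, 20, 40, 5], [20, 80, 45, 50])
        out = tf_histone_correlation(cov, "TF", "H")
        assert out["r"] == pytest.approx(1.0)

    def test_zero_variance_reported_as_undefined(self):
        cov = coverage_from_counts([10, 10, 10], [10, 10, 10],
                                   [5, 20, 80], [7, 40, 10])
        out = tf_histone_correlation(cov, "TF", "H")
        assert np.isnan(out["r"])

    def test_null_and_coupled_simulations(self, rng):
        n = 2000
        # independent Poisson noise in both assays → near-zero correlation
        base = 100
        cov = coverage_from_counts(
            rng.poisson(base, n), rng.poisson(base, n),
            rng.poisson(base, n), rng.poisson(base, n))
        assert abs(tf_histone_correlation(cov, "TF", "H")["r"]) < 0.05
        # histone means track TF means → strong positive correlation
        tf_fold = np.exp(rng.normal(0, 1, n))
        tf_m = rng.poisson(200, n)
        cov = coverage_from_counts(
            tf_m, rng.poisson(200 * tf_fold),
            rng.poisson(200, n), rng.poisson(200 * tf_fold))
        assert tf_histone_correlation(cov, "TF", "H")["r"] >= 0.9
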