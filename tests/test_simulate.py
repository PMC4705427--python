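"""Generator contracts: determinism, planted truth, file round-trips."""

import numpy as np
import pandas as pd
import pytest

from bindsig.intervals import PeakSet, overlaps_any
from bindsig.simulate import (CapacityError, generate_annotation,
                              generate_binding_experiment,
                              generate_expression_matrix,
                              generate_labeled_cohort)


class TestAnnotation:
    def test_rejects_zero_genes_and_tiny_genomes(self):
        with pytest.raises(ValueError):
            generate_annotation(n_genes=0)
        with pytest.raises(CapacityError):
            generate_annotation(n_genes=100, genome_size=50_000)

    def test_same_seed_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            generate_annotation(n_genes=50, seed=11).write(tmp_path / sub)
        for name in ("annotation.tsv", "promoters.bed", "chrom.sizes",
                     "annotation_manifest.yaml"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_gene_bodies_do_not_overlap(self):
        ann = generate_annotation(n_genes=80, seed=3).annotation
        for _, grp in ann.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_every_promoter_covers_its_tss(self):
        res = generate_annotation(n_genes=60, seed=4)
        tss = res.annotation.set_index("gene_id")["tss"]
        chrom = res.annotation.set_index("gene_id")["chrom"]
        prom = res.promoters.df.set_index("name")
        for gene in tss.index:
            row = prom.loc[gene]
            # TSS within ±1 bp of the promoter window
            assert row["chrom"] == chrom[gene]
            assert row["start"] - 1 <= tss[gene] <= row["end"] + 1


@pytest.fixture(scope="module")
def small():
    return generate_binding_experiment(
        n_regions_per_group={"I": 20, "II": 30, "III": 25},
        depth=100_000, seed=42)


class TestBindingExperiment:
    def test_truth_matches_requested_groups_at_planted_folds(self, small):
        counts = small.truth["group"].value_counts().to_dict()
        assert counts == {"II": 30, "III": 25, "I": 20}

    def test_degenerate_fold_plants_only_group_iii(self):
        res = generate_binding_experiment(
            n_regions_per_group={"I": 5, "II": 5, "III": 5},
            depth=50_000, fold_pu1=1.0, fold_h3k27ac=1.0, seed=1)
        assert set(res.truth["group"]) == {"III"}

    def test_same_seed_identical_read_beds(self, tmp_path):
        kw = dict(n_regions_per_group={"I": 5, "II": 5, "III": 5},
                  depth=20_000, seed=9, include_cebpa=False)
        generate_binding_experiment(**kw).write(tmp_path / "a")
        generate_binding_experiment(**kw).write(tmp_path / "b")
        for name in ("reads_PU1_minus.bed", "reads_PU1_plus.bed",
                     "reads_H3K27ac_plus.bed", "truth_regions.tsv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_library_sizes_equal_depth(self, small):
        for key, lib in small.library_sizes.items():
            assert lib == 100_000
            assay, cond = key.rsplit("_", 1)
            assert len(small.reads[(assay, cond)]) == 100_000

    def test_infeasible_histone_floor_warned_and_flagged(self):
        with pytest.warns(UserWarning, match="absolute floor"):
            res = generate_binding_experiment(
                n_regions_per_group={"I": 5, "II": 5, "III": 5},
                depth=20_000, hist_base=4.0, fold_h3k27ac=2.0, seed=2)
        assert res.infeasible

    def test_truth_round_trips_through_tsv(self, small, tmp_path):
        small.write(tmp_path)
        back = pd.read_csv(tmp_path / "truth_regions.tsv", sep="\t",
                           index_col="region_id")
        assert list(back.index) == list(small.truth.index)
        assert list(back["group"]) == list(small.truth["group"])

    def test_annotated_placement_respects_rules(self):
        ann = generate_annotation(n_genes=200, genome_size=6_000_000, seed=5)
        res = generate_binding_experiment(
            n_regions_per_group={"I": 20, "II": 20, "III": 20},
            depth=100_000, seed=5, annotation=ann, include_cebpa=False)
        regions = PeakSet(res.truth.reset_index()[["chrom", "start", "end"]])
        gene_bodies = PeakSet(ann.annotation[["chrom", "start", "end"]])
        overlap_prom, _ = overlaps_any(regions, ann.promoters)
        overlap_body, _ = overlaps_any(regions, gene_bodies)
        truth_sorted = res.truth.sort_values(["chrom", "start", "end"])
        for flag_p, flag_b, (rid, row) in zip(overlap_prom, overlap_body,
                                              truth_sorted.iterrows()):
            if row["group_requested"] == "III":
                assert flag_p  # promoter placement
            else:
                assert not flag_p and not flag_b  # intergenic placement


class TestExpressionMatrix:
    def test_zero_effect_records_no_truth(self):
        res = generate_expression_matrix(n_genes=100, n_up_genes=10,
                                         effect_log2fc=0.0, seed=1)
        assert res.up_genes == []

    def test_planted_mean_shift_close_to_effect(self):
        res = generate_expression_matrix(n_genes=2000, n_up_genes=200,
                                         effect_log2fc=1.0, noise_sd=0.1,
                                         n_samples_per_condition=3, seed=8)
        induced = res.design.index[res.design == "induced"]
        uninduced = res.design.index[res.design == "uninduced"]
        diff = (res.expr.loc[res.up_genes, induced].mean(axis=1)
                - res.expr.loc[res.up_genes, uninduced].mean(axis=1))
        tol = 4 * 0.1 * np.sqrt(2 / 3)  # 4 standard errors of a 3-vs-3 mean diff
        assert (np.abs(diff - 1.0) < tol).all()

    def test_same_seed_identical_matrix(self, tmp_path):
        generate_expression_matrix(n_genes=50, seed=3, n_up_genes=5).write(
            tmp_path / "a")
        generate_expression_matrix(n_genes=50, seed=3, n_up_genes=5).write(
            tmp_path / "b")
        assert ((tmp_path / "a" / "expression.tsv").read_bytes()
                == (tmp_path / "b" / "expression.tsv").read_bytes())

    def test_validates_sample_count(self):
        with pytest.raises(ValueError):
            generate_expression_matrix(n_samples_per_condition=1)


class TestCohort:
    def test_single_category_label_table(self):
        res = generate_labeled_cohort(
            n_samples=12, n_clusters=2, seed=1,
            label_table={"karyotype": [{"normal": 1.0}]})
        assert set(res.metadata["karyotype"]) == {"normal"}

    def test_truth_covers_every_sample_once(self):
        res = generate_labeled_cohort(n_samples=30, n_clusters=3, seed=2)
        assert len(res.cluster_labels) == 30
        assert not res.cluster_labels.index.duplicated().any()
        assert set(res.cluster_labels) == {1, 2, 3}

    def test_zero_separation_leaves_no_structure(self):
        res = generate_labeled_cohort(n_samples=30, n_clusters=2,
                                      separation=0.0, seed=3)
        sig = res.expr.loc[res.signature_genes]
        means_by_cluster = sig.T.groupby(res.cluster_labels).mean()
        spread = (means_by_cluster.max() - means_by_cluster.min()).mean()
        assert spread < 1.0  # noise-level only

    def test_deterministic_files(self, tmp_path):
        generate_labeled_cohort(seed=4).write(tmp_path / "a")
        generate_labeled_cohort(seed=4).write(tmp_path / "b")
        for name in ("cohort_expression.tsv", "cohort_metadata.tsv",
                     "truth_cohort_clusters.tsv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())
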