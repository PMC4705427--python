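"""Differential-expression contract and target-set derivation."""

import numpy as np
import pandas as pd
import pytest

from bindsig.expression import (DEThresholds, call_de, collapse_probes,
                                derive_target_set, group_expression_response,
                                quantile_normalize)
from bindsig.simulate import generate_expression_matrix


class TestQuantileNormalize:
    def test_columns_share_identical_sorted_vectors(self, rng):
        df = pd.DataFrame(rng.normal(8, 2, size=(200, 5)))
        qn = quantile_normalize(df)
        ref = np.sort(qn.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(qn.iloc[:, j].to_numpy()), ref)

    def test_rank_order_preserved_within_column(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)))
        qn = quantile_normalize(df)
        for j in range(3):
            assert np.array_equal(np.argsort(df.iloc[:, j].to_numpy()),
                                  np.argsort(qn.iloc[:, j].to_numpy()))


class TestCallDE:
    def test_identical_columns_yield_no_calls(self):
        col = np.arange(100, dtype=float)
        expr = pd.DataFrame({f"s{i}": col for i in range(6)})
        design = pd.Series(["uninduced"] * 3 + ["induced"] * 3,
                           index=expr.columns)
        de = call_de(expr, design)
        assert not de["significant"].any()

    def test_requires_two_samples_per_condition(self):
        expr = pd.DataFrame(np.ones((10, 3)), columns=["a", "b", "c"])
        design = pd.Series(["uninduced", "induced", "induced"],
                           index=expr.columns)
        with pytest.raises(ValueError, match="2 samples"):
            call_de(expr, design)

    def test_fold_change_filter_blocks_small_effects(self, rng):
        # probe 0: tiny but ultra-consistent shift (significant p, FC < 1.2)
        n = 200
        base = rng.normal(8, 1, size=n)
        expr = pd.DataFrame(
            base[:, None] + rng.normal(0, 0.05, size=(n, 6)),
            columns=[f"s{i}" for i in range(6)])
        expr.iloc[0, 3:] += 0.22  # FC ≈ 1.16 < 1.2
        design = pd.Series(["uninduced"] * 3 + ["induced"] * 3,
                           index=expr.columns)
        de = call_de(expr, design)
        assert de.iloc[0]["p_adj"] <= 0.05
        assert not de.iloc[0]["significant"]

    def test_planted_effects_recovered(self):
        sim = generate_expression_matrix(n_genes=5000, n_up_genes=100,
                                         effect_log2fc=1.0, noise_sd=0.1,
                                         seed=7)
        de = call_de(sim.expr, sim.design)
        called_up = set(de.index[de["significant"] & (de["direction"] == "up")])
        assert len(set(sim.up_genes) & called_up) >= 95

    def test_raw_p_uniform_under_null(self, rng):
        fracs = []
        for seed in range(40):
            sim = generate_expression_matrix(n_genes=800, n_up_genes=0,
                                             effect_log2fc=0.0, noise_sd=0.2,
                                             seed=1000 + seed)
            de = call_de(sim.expr, sim.design)
            fracs.append((de["p_raw"] < 0.05).mean())
        # binomial 3σ band around 0.05 for the mean over seeds
        se = np.sqrt(0.05 * 0.95 / (800 * 40))
        assert abs(np.mean(fracs) - 0.05) < 3 * se + 0.005

    def test_detection_filter_drops_undetected_probes(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, size=(20, 4)),
                            index=[f"p{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(4)])
        design = pd.Series(["uninduced"] * 2 + ["induced"] * 2,
                           index=expr.columns)
        det = pd.DataFrame(0.001, index=expr.index, columns=expr.columns)
        det.iloc[0, 0] = 0.5
        de = call_de(expr, design, detection_p=det)
        assert "p0" not in de.index and len(de) == 19


class TestGroupResponse:
    def test_planted_group_dominates(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(3000)]
        group_i = genes[:100]
        group_ii = genes[100:200]
        sim = generate_expression_matrix(
            gene_ids=genes, up_genes=group_i,
            effect_log2fc=np.log2(1.8), noise_sd=0.05, seed=3)
        # plant a mild significant-but-flat signal on group II genes so they
        # enter the significant set with fold ≈ 1.3
        expr = sim.expr.copy()
        induced = sim.design == "induced"
        expr.loc[group_ii, induced.index[induced]] += np.log2(1.3)
        de = call_de(expr, sim.design)
        out = group_expression_response(de, {"I": group_i, "II": group_ii})
        assert out["groups"]["I"]["mean_fold_change"] > \
            out["groups"]["II"]["mean_fold_change"]
        assert out["tests"]["I_vs_II"]["p"] < 1e-3

    def test_null_groups_similar(self):
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(2000)]
            sim = generate_expression_matrix(
                gene_ids=genes, up_genes=genes[:200],
                effect_log2fc=1.0, noise_sd=0.1, seed=seed)
            de = call_de(sim.expr, sim.design)
            # both groups drawn from the same planted-up population
            a = list(rng.choice(genes[:200], 80, replace=False))
            b = list(rng.choice(genes[:200], 80, replace=False))
            out = group_expression_response(de, {"I": a, "II": b})
            pvals.append(out["tests"]["I_vs_II"]["p"])
        assert np.mean(np.array(pvals) < 0.01) <= 0.05 + 3 * np.sqrt(
            0.01 * 0.99 / 20)

    def test_empty_group_reported_absent(self):
        sim = generate_expression_matrix(n_genes=500, n_up_genes=20, seed=5)
        de = call_de(sim.expr, sim.design)
        out = group_expression_response(de, {"I": sim.up_genes, "II": []})
        assert out["groups"]["II"] is None

    def test_shared_gene_counts_in_both_groups(self):
        sim = generate_expression_matrix(n_genes=500, n_up_genes=20, seed=5)
        de = call_de(sim.expr, sim.design)
        shared = sim.up_genes[0]
        out = group_expression_response(
            de, {"I": [shared], "II": [shared]})
        assert out["groups"]["I"] == out["groups"]["II"]


class TestTargetSet:
    def test_disjoint_sets_give_empty(self):
        sim = generate_expression_matrix(n_genes=300, n_up_genes=10, seed=2)
        de = call_de(sim.expr, sim.design)
        not_up = [g for g in sim.expr.index if g not in sim.up_genes][:30]
        assert len(derive_target_set(not_up, de)) == 0

    def test_intersection_matches_set_oracle(self):
        sim = generate_expression_matrix(n_genes=2000, n_up_genes=80,
                                         noise_sd=0.05, seed=9)
        de = call_de(sim.expr, sim.design)
        bygene = collapse_probes(de)
        up = set(bygene.index[bygene["significant"]
                              & (bygene["direction"] == "up")])
        group_genes = set(list(sim.up_genes)[:40]
                          + [g for g in sim.expr.index if g not in sim.up_genes][:40])
        target = derive_target_set(group_genes, de)
        assert set(target.genes) == group_genes & up
        assert target.provenance["intersection_count"] == len(target)
        assert set(target.genes) <= group_genes
        assert set(target.genes) <= up

    def test_probe_collapse_uses_best_probe(self):
        de = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "log2fc": [1.0, 0.1, 0.5],
                "p_raw": [0.001, 0.5, 0.01],
                "p_adj": [0.003, 0.6, 0.03],
                "significant": [True, False, True],
                "direction": ["up", "up", "up"],
            },
            index=pd.Index(["pA", "pB", "pC"], name="probe_id"),
        )
        bygene = collapse_probes(de)
        assert bygene.loc["g1", "log2fc"] == 1.0
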