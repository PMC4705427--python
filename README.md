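# bindsig

From inducible transcription-factor binding to a target-gene signature.

`bindsig` is a pipeline for a common regulatory-genomics experiment: a
transcription factor (the motivating case is PU.1, with CEBPA as co-binding
partner) is switched on in a cell line, and ChIP-Seq for the factor and the
active-chromatin mark H3K27Ac is collected before and after induction
together with expression arrays. The pipeline answers three questions:

1. **Which binding events are functional?** Peak calls from the two
   conditions are merged (≥1 bp overlap), read coverage is counted per
   merged region and normalized to reads/kb/million, and regions are
   classified:
   - **Group I** — ≥4-fold increase in TF coverage, ≥4-fold increase in
     H3K27Ac coverage, and ≥50 induced H3K27Ac reads in the region
     (functional de novo binding);
   - **Group II** — ≥4-fold TF increase without the histone evidence;
   - **Group III** — TF coverage unchanged (within a symmetric 2-fold band).

   H3K27Ac is scored over fixed 800 bp windows centred on each region's
   midpoint. Fold changes are pseudocounted, `(x₊ + c)/(x₋ + c)`, so newly
   bound regions stay finite.
2. **Which genes do they drive?** Regions are assigned to genes by a
   promoter → intragenic → intergenic cascade; intergenic regions link to
   the nearest gene on *each* side within 50 kb. Differential expression
   between conditions (quantile normalization, moderated t-statistics,
   Benjamini–Hochberg, significant iff adj-p ≤ 0.05 and fold change > 1.2)
   is intersected with the Group I gene set to give the high-confidence
   **target-gene signature**.
3. **Does the signature generalize?** Any expression dataset (a cell-type
   atlas, a patient cohort) can be stratified by hierarchical clustering of
   samples restricted to the signature genes (distance 1 − Pearson r,
   average linkage, gene-resampling bootstrap support), with per-cluster
   marker-gene levels and categorical label composition (e.g. karyotype
   fractions) summarized per cluster.

Because the pipeline's reference datasets are sequencing archives, a
first-class synthetic-data module generates every input — annotation,
two-condition peak sets, read pileups, expression matrices, labeled
cohorts — with planted, recorded ground truth, and the test suite verifies
each stage against brute-force oracles and the planted truth.

## Worked example

The `bindsig` CLI runs the whole pipeline on the synthetic fixture family
(955 regions planted in the three groups at 1:10 study scale, 5000 genes,
3 vs 3 arrays, a 60-sample labeled cohort):

```
$ bindsig --seed 1 --outdir demo run-all
INFO bindsig: simulated 5000 genes, 955 regions, 5000 probes
INFO bindsig: group sizes: {'I': 173, 'II': 506, 'III': 273, 'unclassified': 3}
INFO bindsig: target set: 176 genes ({'group_gene_count': 340, 'up_gene_count': 224, 'intersection_count': 176})
{"genes_simulated": 5000, "regions_simulated": 955, "merged_regions": 955,
 "regions_grouped": 955, "regions_assigned": 955, "probes_tested": 5000,
 "probes_significant": 244, "target_genes": 176, "samples_clustered": 60}
```

Reading the outputs in `demo/`:

- `groups.tsv` / `binding_summary.json` — the classifier recovered the
  planted 173/506/276 group structure (3 Group III regions fall just
  outside the 2-fold band under Poisson noise); TF and histone log2 fold
  changes correlate (r = 0.21) because the coupling is planted only in
  Group I.
- `distribution.json` — Group I/II regions are 100% intra+intergenic and
  Group III 0% (the generator plants Groups I/II next to genes and Group
  III at promoters).
- `target_genes.txt` — 340 Group I-linked genes ∩ 224 up-regulated genes =
  176 signature genes (173 planted targets plus a few up-regulated flank
  neighbours).
- `cobinding.json` — 35/173 (20.2%) of Group I regions sit at pre-existing
  CEBPA peaks, matching the planted 20% co-binding rate.
- `cluster_labels.tsv`, `cluster_summary.json`, `dendrogram.nwk` — the
  signature splits the cohort into the three planted clusters of 20, with
  the marker gene highest in its planted cluster and karyotype fractions
  per cluster.

Individual stages (`simulate`, `merge-count`, `classify`, `assign`, `de`,
`target-set`, `cobind`, `cluster`) re-run from the plain-text intermediates;
`--config` takes a YAML file overriding any default in
`bindsig.config.default_config()`.

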