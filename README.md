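# hscnet

Analysis toolkit for dissecting transcriptional regulatory networks that
maintain hematopoietic stem cells (HSCs), and for asking whether those
networks are re-activated in acute myeloid leukemia (AML).

The package implements, as a tested and reusable pipeline, the
computational stages of a perturbation-to-prognosis study design:

1. **Network discovery** — compare single-cell transcriptomes of
   perturbed versus control HSCs with a two-part *hurdle* likelihood-ratio
   test and call "down"/"up" gene sets at stringent thresholds
   (log2 fold change > 0.05, Bonferroni-adjusted *P* < 1e-20), validated
   by a 100-fold label-permutation null and pseudobulk Spearman
   concordance.
2. **Lineage enrichment** — a permutation z-score
   z = (y_obs − mean(y_perm)) / sd(y_perm) for a gene set's mean
   expression across hematopoietic cell types (1,000 random same-size
   gene sets), locating where in hematopoiesis a program is active.
3. **cisRE–gene linking** — merge accessible-chromatin peaks across
   populations into a cis-regulatory element (cisRE) catalog, link cisREs
   to genes by cross-population accessibility–expression Pearson
   correlation within ±500 kb of the TSS (empirical trans-pair null,
   Benjamini–Hochberg FDR), and select the HSC-specific network by
   accessibility-weighted significant links.
4. **Footprint statistics** — aggregate Tn5 cleavage profiles around TF
   motifs, pairwise footprint co-occurrence in cisREs (two-sided
   hypergeometric), occupancy enrichment of ChIP peaks by 1,000
   genome permutations, footprint spacing, and paired Wilcoxon contrasts
   of footprint signal across lineages.
5. **Chromatin loops** — Knight–Ruiz balancing of 25-kb contact maps,
   aggregate peak analysis (APA) over ±250 kb windows with the
   peak-to-lower-left ratio (P2LL), loop classification by CTCF-footprint
   anchors and network cisREs, and corner-distribution contrasts between
   cell states.
6. **Survival stratification** — per-sample preranked GSEA of a network
   gene set in AML cohorts (classical weighted Kolmogorov–Smirnov running
   sum, NES, permutation *P*), Youden-J optimal thresholds, Kaplan–Meier /
   log-rank / trend tests, Cox proportional-hazards models with marginal
   hazard curves, and expression-cutoff stratification of cell-line
   CRISPR dependencies.

Every input the pipeline consumes can be generated by the
`hscnet.simulate` module with planted ground truth (negative-binomial
scRNA counts with planted DE, stemness-graded lineage profiles, linked
multiome matrices, footprint landscapes with planted co-occurrence,
distance-decay contact maps with planted loops, and survival cohorts
with a planted hazard ratio), so every stage is testable without any
external downloads.

## Worked example

Simulate a two-condition HSC perturbation experiment, discover the
dysregulated network, and locate it in hematopoiesis:

```python
from hscnet.simulate import ScSimConfig, gen_sc_counts, gen_lineage_profiles
from hscnet.network import normalize_log, hurdle_de, call_network
from hscnet.lineage import lineage_zscore

adata, truth = gen_sc_counts(ScSimConfig(n_cells_per_condition=2000, seed=7))
norm = normalize_log(adata)
de = hurdle_de(norm, "condition", group_a="A", group_b="B")
sets = call_network(de, fc_thresh=0.05, p_thresh=1e-20)
print(f"tested genes: {len(de)}")
print(f"down (higher in control): {len(sets.down)} genes")
print(f"up (higher in perturbed): {len(sets.up)} genes")

profiles, stem_set = gen_lineage_profiles(seed=7)
zs = lineage_zscore(profiles, stem_set, n_perm=1000, seed=1)
top = max(zs, key=lambda e: e.z)
print(f"max lineage z: {top.z:.1f} in {top.cell_type}")
```

Output:

```
tested genes: 2000
down (higher in control): 45 genes
up (higher in perturbed): 50 genes
max lineage z: 17.6 in HSC
```

The simulation planted 100 DE genes (5% of 2,000, |log2FC| = 1); the
hurdle test recovers 95 of them at the stringent thresholds with no
false positives, split into the "down" set (lost upon perturbation —
the candidate maintenance network) and the "up" set (de-repressed
differentiation program). The planted stemness-graded gene set scores a
permutation z of 17.6 in the HSC column and lower everywhere else,
mirroring how a maintenance network should track the stem compartment.

## Data formats

All I/O is plain text: MTX + genes/cells TSVs for counts, BED/BED6+1 for
peaks and footprints, BEDPE for loops, 3-column bin triplets for contact
matrices, GMT for gene sets, labelled TSVs for expression matrices and
cohort tables, JASPAR-style text for position frequency matrices. See
`hscnet.io`.

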