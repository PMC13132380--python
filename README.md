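# bivalstate

Chromatin-bivalency analysis at gene promoters, for epigenomics and
regulatory-genomics work on systems — such as drug-resistant prostate
cancer — where poised "bivalent" promoters carrying both the active
H3K4me3 and the repressive H3K27me3 mark control cell-state plasticity.

The package implements, as a tested and reusable pipeline:

1. **Bona fide bivalent-promoter calling.** Promoter windows are TSS ± 1 kb
   (strand-aware, 0-based half-open). A gene is bivalent *by separate ChIP*
   when peaks of both marks overlap its promoter, and *by sequential ChIP*
   (re-ChIP, H3K27me3 → H3K4me3) when a sequential peak does; the
   intersection of the two calls is the bona fide bivalent set. Factor
   co-occupancy (e.g. β-catenin, PRC2 subunits) at bivalent promoters is
   reported as an occupied fraction.
2. **Quantitative differential marking.** Promoter intensities of two
   conditions are put on a common scale by a linear M–A rescaling fitted on
   commonly occupied promoters (M = log₂(x₁/x₂), A = ½·log₂(x₁x₂); fit
   M = a + b·A, rescale x₂′ = x₂·2^(a+bA)). Per-gene significance uses the
   exact conditional count test — conditional on the total t = x₁+x₂, the
   null is x₁ ~ Binomial(t, ½), equivalently P(y|x) = (x+y)!/(x!y!2^(x+y+1))
   — and a change is called at p < 0.05 and |log₂FC| ≥ 0.58.
3. **Chromatin bivalency states (CBS) and transitions.** Bivalent promoters
   are partitioned by their H3K4me3/H3K27me3 ratio with a 1.5-fold rule into
   cluster I (H3K4me3-high), cluster II (H3K27me3-high) and cluster III
   (equal). Transitions between conditions are tabulated (alluvial-ready),
   the fraction of "bivalency resolution" switches (II→I, III→I) with
   increased expression is measured, and mark change versus expression
   change is summarised by a Pearson correlation.
4. **Recurrent-NMF meta-programs.** Per-sample NMF across ranks k = 4–9
   yields programs (top-90 genes per factor); programs that recur across
   ranks and across samples are clustered by Jaccard similarity into
   consensus meta-programs.
5. **Synthetic data with planted truth.** A generator plants bivalency
   states, condition switches, coupled expression and additive gene
   programs, so every stage is benchmarked against known ground truth
   without any external download.

## Worked example

Run the full synthetic pipeline (1,000 genes, 30% planted bivalent, half of
the cluster-II/III genes resolving to cluster I in condition B):

```bash
bivalstate run --seed 1 --outdir demo
```

which prints (abridged):

```json
{
  "n_promoters": 1000,
  "venn": {"n_sequential": 300, "n_separate": 303, "n_overlap": 298},
  "n_bona_fide": 298,
  "cbs_counts": {
    "A": {"cluster_I": 98, "cluster_II": 100, "cluster_III": 100, "nonbivalent": 702},
    "B": {"cluster_I": 198, "cluster_II": 54, "cluster_III": 46, "nonbivalent": 702}
  },
  "transitions": {"cluster_II->cluster_I": 46, "cluster_III->cluster_I": 54, "...": "..."},
  "switch_fraction_up": 0.82,
  "n_switch": 100,
  "correlation": {"r": 0.1267028621, "p_value": 0.0287528, "n": 298}
}
```

Reading: of 1,000 promoters, 300 carry sequential peaks and 303 both
separate marks; 298 intersect as bona fide bivalent (two planted bivalent
genes drop out through log-normal intensity noise at the peak-emission
threshold). Condition B has twice as many H3K4me3-high promoters because
100 planted switch genes moved II→I or III→I; 82% of those switch genes
show increased expression (the planted coupling probability is 0.85), and
H3K4me3 change correlates positively with expression change. Each stage
also writes its own TSV/BED outputs into `demo/`.

The same stages are available as library calls (`call_bivalent_separate`,
`call_differential`, `assign_states`, `transition_table`, …) and as
sklearn-style estimators (`MAnormScaler`, `CBSClassifier`,
`MetaProgramNMF`) for composition with sklearn tooling.

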