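# chromdyn

Chromatin-state dynamics from histone-mark ChIP-seq time courses.

`chromdyn` reimplements, as a tested and reusable Python pipeline, the
regulatory-genomics analyses used to characterize chromatin remodeling
during zebrafish heart regeneration: combinatorial chromatin-state calling
from four histone marks (H3K4me1, H3K4me3, H3K27me3, H3K27ac) across a
time course (0, 1, 4, 14 and 45 days post cryoinjury), assignment of
state-transition groups, H3K4me3 breadth vs. expression analysis with
exact small-n Spearman statistics, temporal k-means clustering of
enrichment profiles, ROSE-style super-enhancer ranking, and discovery of
co-occurring transcription-factor motif ensembles ("TFinZONE"-style:
SNN graph + Louvain + zero-inflated marker test). It is aimed at
computational biologists who want to apply, audit or stress-test this
class of analysis without the original deposited sequencing data: a
first-class synthetic-data module plants known states, transitions,
correlations and motif ensembles, so every stage can be validated against
ground truth.

## The model

**Enrichment.** Merged peak regions are quantified as RPKM and normalized
per (mark, timepoint) column as z = z-score of log2(RPKM + 1).

**Chromatin states.** Per region and time point, one of eight labels from
threshold comparisons: Q1 = 25th percentile of each mark's pooled
normalized values; the H3K4me3 border is fixed at z = 1.

| state | meaning | rule |
|---|---|---|
| Pa | active promoter | H3K4me3 > 1, H3K27me3 < Q1 |
| BiV | bivalent promoter | H3K4me3 > 1, H3K27me3 ≥ Q1 |
| Ea | active enhancer | H3K4me1 ≥ Q1, H3K27ac ≥ Q1, H3K27me3 < Q1 |
| Ep | primed enhancer | H3K4me1 ≥ Q1, others below |
| Er | repressed enhancer | H3K4me1 ≥ Q1, H3K27me3 ≥ Q1, H3K27ac < Q1 |
| Epr | poised enhancer | H3K4me1, H3K27ac and H3K27me3 all ≥ Q1 |
| Ps | silent promoter | H3K4me1 < Q1, H3K27me3 ≥ Q1, H3K27ac < Q1 |
| U | unmarked | everything below threshold |

**Transition groups.** With A = {Ea, Pa}, Ia = {Ep, Er, Epr, BiV, Ps},
states at 0 dpci vs a reference time point map to A_Ia, Ia_A, U_Ea, U_Ia,
U_Pa, or static.

**Breadth and correlation.** H3K4me3 peaks at or above the median width
(Q2) are broad. Mark enrichment is related to expression by Spearman's
rho across the five time points; with n = 5 the permutation null is fully
enumerable, so p-values are exact. Positive/negative calls use
rho ≥ 0.3 / rho ≤ −0.3 with p < 0.35.

**Super-enhancers.** H3K27ac peaks within 12.5 kb are stitched; on the
rank-ordered, [0,1]×[0,1]-scaled signal curve, the cutoff sits where the
slope reaches 1; regions above it are SE, the rest TYE.

**Motif ensembles.** Regions × motif hit matrices are embedded with 10
PCs, connected in a shared-nearest-neighbor graph (k = 30, Jaccard
weights, prune < 1/15) and partitioned by seeded Louvain at resolution
0.5. Marker motifs per cluster pass min.pct ≥ 0.10 and ln fold change
≥ 0.09 with a zero-inflated ("bimod") likelihood-ratio test; hub TFs are
ranked by weighted degree in a protein-interaction edge list.

## Worked example

Generate a synthetic demo dataset (1,000 regions, noise σ = 0.2) and run
the full pipeline:

```bash
chromdyn fixtures --out demo/fx --n-regions 1000 --seed 1
chromdyn run-all --config demo/fx/config.yaml --input-dir demo/fx --out demo/results
```

The run prints the report (abbreviated):

```json
{
  "ensembles": {"n_clusters": 4, "n_regions": 193},
  "group_recovery": 0.996,
  "marked_gene_fraction": 1.0,
  "n_broad": 500,
  "n_positive_correlated": 1000,
  "n_clusters": 6,
  "n_regions": 1000,
  "n_superenhancers": 7,
  "state_recovery": 0.9874
}
```

Reading this: the classifier recovered 98.7% of the 5,000 planted
(region, timepoint) states and 99.6% of the planted transition groups at
the study noise level; exactly half the generated peaks are broad; all
regions were planted with a perfect monotone mark–expression link and all
were called positively correlated; k-means produced the six temporal
clusters; ROSE geometry called 7 of the stitched regions super-enhancers;
and the 193 dynamic regions split into 4 motif communities — the three
planted ensembles plus the background block. Stage outputs
(`states.tsv`, `transitions.tsv`, `breadth.tsv`, `correlations.tsv`,
`clusters.tsv`, `superenhancers.tsv`, `ensemble_markers.tsv`, ...) and a
checksum manifest land in `demo/results/`; rerunning with the same config
and inputs is byte-identical.

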