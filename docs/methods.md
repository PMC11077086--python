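# Methods

This note documents the models, parameter choices and numerical
conventions behind `chromdyn`, what the synthetic generator does and does
not emulate, and the design decisions taken where the procedure was
genuinely open.

## Coordinates, formats and normalization

All coordinates are 0-based half-open (BED convention); 1-based inputs
are converted at the reader boundary. Missing values serialize as `NA`.
Chromosome names compare by exact string match — no `chr` aliasing —
because silent aliasing hides data errors.

RPKM = count / (length in kb × mapped reads in millions). The normalized
layer is the per-column z-score of log2(RPKM + 1), computed with the
sample standard deviation (ddof = 1, the R `scale()` convention); a
`ddof=0` toggle selects the population convention. Replicate RPKM values
are averaged before the log transform, not after. Zero-variance columns
yield an all-zero z column and are flagged rather than raising.

## Region annotation

Priority promoter > genebody > intergenic. A region is a promoter when
its gap distance to the nearest TSS is ≤ 2,000 bp, i.e. when it overlaps
the TSS ± 2 kb window — evaluated on any overlap, matching
annotatePeaks-style behavior; a midpoint rule is available behind a flag.
Genebody requires overlap with the gene span of the assigned
(nearest-TSS) gene; TSS ties break to the lexicographically smallest
gene id so annotation is deterministic.

## Chromatin-state decision table

Thresholds: Q1 is the 25th percentile (linear-interpolation quantile) of
each Q1-mark's normalized values pooled over all regions and time points;
a single threshold per mark, because z-scores are computed on the merged
quantification. The H3K4me3 border is fixed at 1.0 normalized units.
"Marked" means value ≥ Q1 and "unmarked" value < Q1 throughout; using one
inclusive side keeps the 16-corner lattice total and exclusive, which is
pinned by an exhaustive test. The promoter branch (H3K4me3 > 1) takes
precedence regardless of H3K4me1, since H3K4me1 commonly flanks
promoters. Two corners are not fixed by the published taxonomy and are
resolved explicitly in `call_state` (one function, easy to amend):

- H3K4me1 ≥ Q1 with both H3K27ac and H3K27me3 ≥ Q1 → Epr (poised);
  with neither → Ep (primed).
- H3K4me1 < Q1, H3K4me3 ≤ 1, H3K27ac ≥ Q1 → U. Acetylation without
  H3K4me1 or H3K4me3 does not define an element here; Ps additionally
  requires H3K27ac < Q1.

Transition groups treat A = {Ea, Pa} and Ia = {Ep, Er, Epr, BiV, Ps};
Epr counts as inactive. Everything not in the five named transitions is
static.

## Breadth and correlation

The broad/narrow threshold is the median (Q2) of peak widths from the
merged peak list, computed once over all time points (a per-timepoint
mode exists); ties at the median are broad (≥ rule). Spearman's rho uses
midranks; for n ≤ 8 the p-value enumerates all n! permutations of one
margin (at n = 5 the asymptotic p is meaningless), beyond that the
t-approximation. Classification: positive when rho ≥ 0.3 and two-sided
p < 0.35, negative when rho ≤ −0.3 and p < 0.35. The p < 0.35 rule was
chosen over a "bottom quartile of p values" reading because it is an
executable, data-independent rule; a quantile-based alternative can be
layered on the returned raw p values. Group expression differences use
the Mann-Whitney test on log2(mean RPKM + 1).

## k-means

Lloyd's algorithm with k-means++ seeding, 25 restarts (restart count is
recorded in the output), iter_max 500, best run by WSS. Empty clusters
re-seed on the point farthest from its centroid. Cluster ids are
relabeled 1..k by descending size for output stability. The elbow sweep
additionally warm-starts each k from the previous solution's centroids
plus the worst-fit point, which makes reported WSS provably
non-increasing in k. k defaults to 6 but is elbow-guided. Inputs mirror
the published filters: H3K27ac clustering uses only positively correlated
regions; H3K4me3 uses broad peaks with |rho| ≥ 0.3. Tests verify
equivalence with an exhaustive partition search on tiny inputs and with
scikit-learn's Lloyd on well-separated data.

## Super-enhancer ranking

H3K27ac peaks gap ≤ 12,500 bp apart stitch into one region (idempotent);
signal is the constituent sum; no TSS exclusion and no control
subtraction (ROSE default settings), with an exclusion flag available.
Both axes of the ascending rank/signal curve are scaled to [0, 1]; the
slope is estimated by centered finite differences with no smoothing
(bit-reproducibility over aesthetics), and the cutoff is the signal at
the rightmost point with slope ≤ 1. SE means signal strictly above the
cutoff, so constant or exactly linear curves yield zero SE — the
documented degenerate policy — and SE minimum ≥ TYE maximum always holds.

## Motif ensembles

The region × motif matrix is binary presence/absence by default (counts
mode available): co-occurrence, not dosage, is the signal of interest.
Embedding uses the top 10 PCs of the centered matrix via deterministic
full SVD; neighbors are the 30 nearest points (self included); SNN edge
weights are Jaccard indices of neighbor sets, pruned below 1/15 (the
reference pipeline's default). Community detection is seeded Louvain
(greedy modularity with resolution, default 0.5); the implementation
takes the best modularity over 10 seeded node-order shuffles, which on
small graphs reaches the exhaustive-search optimum (tested). A Leiden
refinement is deliberately not applied, for comparability with the
single-level reference.

The "bimod" marker test models each group as a point mass at zero plus a
normal for detected values; the likelihood ratio
2(ll_in + ll_out − ll_pooled) is compared to chi-square with 3 degrees of
freedom (detection proportion, mean, sd). The detected-component sd falls
back to 1 when fewer than two values are detected. Markers require
detection in ≥ 10% of cluster regions and natural-log detection-rate fold
change ≥ 0.09 (pseudocount 0.01), positive direction only by default.
P-values are Bonferroni-adjusted over motifs (mirroring the reference
marker implementation; BH available). Hub TFs rank by weighted degree,
ties by name, top 10% with non-zero degree flagged central.

## Synthetic data: what it emulates and what it does not

The generator plants a state per region per time point: transition
regions switch from their baseline state to the reference state at the
reference time point; static regions keep one state. Ideal normalized
levels sit 1.5 units either side of the operative threshold (0 for the
Q1 marks, 1 for H3K4me3), Gaussian noise of sd `noise_sigma` is added,
and RPKM is emitted through the inverse of the normalization transform so
that the pipeline's own normalization is exercised.

Because Q1 is an adaptive pooled quantile, planted states are only
recoverable when each Q1-mark's background (below-threshold) share of the
pool sits just below 25% — otherwise the threshold lands inside a mode
instead of the gap. The generator therefore solves for a static-region
state mix (palette Epr/U/Ps/Ea/Pa plus a small Er/Ep/BiV flavor, with a
mark-aware trim pass) that places each Q1-mark's low share at ≈ 24.75%
and the H3K4me3-high share at ≈ 15%. This mirrors peak-derived region
sets, where most entries carry signal for at least one mark, and it makes
threshold estimation itself part of the tested path. Default transition
fractions (A_Ia 5%, Ia_A 5%, U_Ea 3%, U_Ia 3%, U_Pa 4%) keep per-column
compositions close enough that the pooled Q1 separates every column's
modes; at the study noise level σ = 0.2 the expected per-entry
misclassification is the pool mass between Q1 and the signal mode,
≈ 1.3%, giving ≥ 98% state recovery.

Expression is coupled to one mark's rank profile through a Gaussian
copula. The Pearson coupling is calibrated so the *expected sample*
Spearman coefficient at the time-course length n equals the requested
target, inverting E[r_s] = 6/(π(n+1))·(arcsin r + (n−2) arcsin(r/2));
at n = 5 the uncalibrated population coupling undershoots visibly.
Targets ±1 copy/reverse ranks exactly. Uncorrelated regions get either
independent noise or flat profiles ("constant" mode) — the latter makes
the uncorrelated class deterministic for noiseless fixed-point checks.
Peak widths are a two-component mixture (uniform 100–480 bp narrow;
520 bp + exponential mean 600 bp broad) with an exact mixing count.
Motif matrices are Bernoulli with p_in inside planted blocks and p_out
elsewhere.

Not emulated: read-level noise, fragment pileups, replicate structure,
realistic sequence composition, many-to-many region–gene assignment
(synthetic data maps one region to one gene to isolate correlation logic
from annotation ambiguity), and inter-mark biological correlations beyond
the planted state patterns. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated noise model, not
performance on real ChIP-seq.

## Problem sizes and determinism

Tests and the acceptance script use 600–1,000 regions × 5 time points,
600-row clustering inputs, 150-region motif matrices and 2,000-iteration
null simulations — sizes chosen so every planted effect is comfortably
detectable while the full suite runs in seconds. Every stochastic
component takes an explicit seed and draws from its own
`numpy.random.default_rng` stream; pipeline reruns with identical inputs
and config are byte-identical (checksummed in the output manifest).

## Known limitations

- The Q1-threshold scheme is inherently relative: on data where fewer
  than ~25% of pooled entries are background for some mark, the threshold
  cuts into the signal mode and "truth" becomes definitionally tied to
  the quantile, as discussed above.
- The exact Spearman enumeration grows factorially; n > 8 silently falls
  back to the t-approximation.
- The bimod chi-square reference is asymptotic; at very small group sizes
  its p-values are conservative near the sd-fallback edge cases.
- ROSE "default settings" drift between versions (TSS exclusion 0 vs
  2,500 bp); the default here is no exclusion, with a flag.
- Louvain restarts make global-optimum recovery highly reliable on small
  graphs but carry no guarantee on large ones.
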