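# Methods

## Study design and data model

The package analyses a two-condition, small-replicate expression study:
untreated diabetic controls (`CK`) against treated animals (`RS`), with
summarized linear-scale intensities per gene and sample (the kind of matrix
an RMA-style summarization produces). All screening statistics treat the
matrix as the unit of analysis; no probe-level modelling is attempted.

Gene symbols are matched case-insensitively after whitespace trimming, and
original spellings are preserved on output. The packaged lipid-metabolism
module carries one alias (`Cptla` → `Cpt1a`): the two spellings appear in
different published tables and are treated as the same measurement when
joining ratios, without asserting identity anywhere else.

## Differential-expression screen

**Fold change** is computed on the linear scale, `FC_i = mean(RS_i) /
mean(CK_i)`, because that is the scale on which screening ratios are
conventionally reported. The **d-statistic** is computed on log2
intensities — the scale on which microarray noise is approximately
additive — as `d_i = (x̄_RS,i − x̄_CK,i) / (s_i + s₀)` with `s_i` the
equal-variance pooled standard error of a two-sample unpaired comparison.
Both conventions are deliberate and documented: the fold-change gate uses
arithmetic means of intensities, the significance gate geometric-mean
differences; their signs can disagree for genes very close to FC = 1,
which never affects calls (such genes fail both gates).

**Fudge factor `s₀`.** Chosen from the percentiles {0, 5, …, 95} of the
per-gene standard-error distribution to minimize the coefficient of
variation of bin-wise median absolute deviations of `d` across
standard-error quantile bins (bins = `min(100, n_genes/10)`, MAD scaled by
1/0.64). Ties resolve to the smallest percentile; a degenerate all-zero SE
distribution yields `s₀ = 0` with a warning.

**Q-values.** Group labels are permuted over distinct assignments of
samples to groups; when the design admits no more assignments than the
permutation budget (e.g. all C(8,4) = 70 of a 4 vs 4 design) enumeration is
exhaustive, otherwise assignments are sampled without replacement. For each
threshold `t` on `|d|` the estimated FDR is `π₀ · median_perms #{|d*| ≥ t}
/ #{|d| ≥ t}`; a gene's Q-value is the minimum estimated FDR over the
rejection regions containing it (thresholds at or below its own `|d|`),
clamped to [0, 1]. This is monotone nonincreasing in `|d|` by construction.
`π₀ = 1` by default — conservative and stable at the 3–4 replicates this
design has; a SAM-style quartile estimator is available behind a flag.

**Calls.** `up` iff `FC ≥ fc_up` and `Q ≤ q_max`; `down` iff `FC ≤ fc_down`
and `Q ≤ q_max`; defaults 2.0 / 0.5 / 0.05, all inclusive. The bounds are
applied with a relative tolerance of 1e-9 — a pure floating-point guard so
that a planted effect of exactly 2× is not dropped by one ulp of rounding;
it is six orders of magnitude below the 4-decimal precision at which
ratios are reported.

**Degenerate inputs.** A zero denominator with a nonzero mean difference
(noiseless data with `s₀ = 0`) maps to a finite signed sentinel (±1e12)
so ordering and sign conventions survive; a zero difference maps to
`d = 0`. With fewer than 2 samples in a group the SAM path refuses and
directs the caller to fold-change-only screening.

## Hierarchical clustering

Average-linkage agglomeration under distance 1 − Pearson correlation of
log2 profiles, over genes or samples. The agglomeration is implemented
directly (Lance–Williams update) so the tie rule is exact and documented:
at equal merge distances the pair with the smallest cluster creation ids
merges first. The distance matrix is symmetrized explicitly because
floating-point correlation matrices are symmetric only to rounding.
Zero-variance profiles correlate 0 with everything (distance 1), with a
warning. Average linkage is monotone, so merge heights never decrease.
Dendrograms export as Newick with branch lengths equal to height drops.
The implementation is O(n²) per merge; it is intended for samples or
post-screen gene sets, not whole-genome clustering.

## Local gene network

A pathway joins the LGN iff it contains at least one disease-associated
differentially expressed gene — the network is anchored on the screened
genes, since that is what a knowledge-based assembly around a screen
means; membership edges attach those genes, and optionally the other
disease-set genes of included pathways attach with `regulation = none`.
Pathway–pathway links are taken from an explicit edge list when supplied
(reconstructing printed sub-structures exactly) and otherwise derived from
shared membership. All edges are undirected; no parallel edges or
self-loops. Components are ordered by decreasing size with ties broken by
the smallest lexicographically-minimal node id; the largest is the "main
network" and pathway nodes outside it are the isolated pathways.

## Topology metrics

Average path length is the mean shortest-path distance (BFS) over
connected unordered pairs of the main component; it is `None` for an
edgeless main component. Clustering uses the Watts–Strogatz convention —
local coefficient `2·triangles / (k(k−1))` for degree ≥ 2, zero otherwise,
all main-component nodes counted in the mean. The scale-free diagnostic is
an ordinary least-squares fit of `log10 count` against `log10 degree`
(degrees ≥ 1, counts > 0), refused below 3 distinct degrees; it is a
descriptive heuristic, not a maximum-likelihood power-law test, matching
how such claims are usually made for small knowledge-based networks.
Because degree anecdotes mix graph views (a gene's degree counts its
pathway memberships; a hub pathway's degree counts its links to other
pathways), reports always carry the full typed graph and both one-mode
projections.

## Synthetic-data generator

Emulates the study conditions: `n_per_group` defaults to 4 (the design
used 3 or more biological replicates), planted fold changes default to the
screen bounds 2× / 0.5× in 5% + 5% of genes, baseline log2 intensities are
Normal(8, 2) and replicate noise Normal(0, 0.25) on the log2 scale —
a moderate post-summarization noise level typical of well-behaved arrays.
Effects multiply the treatment group only, so the expected RS/CK ratio of
a planted gene equals its true fold change. Pathway annotations draw
`n_pathways = 38` sets with sizes uniform on [3, 15], seeded so that every
planted gene belongs to at least one pathway without violating the size
bounds; disease sets sample `⌈frac · n⌉` genes stratified to contain both
planted and null genes when possible. One integer seed governs every
stream (pathway and disease draws use fixed offsets of it), so identical
configurations are byte-reproducible.

What the generator does *not* emulate: probe-level effects, normalization
artifacts, correlated gene blocks, heavy-tailed or intensity-dependent
noise, and realistic pathway overlap structure. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
log-normal model, not robustness to every failure mode of real arrays.

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent oracle at
small scale: exhaustive enumeration of all label assignments for Q-values
(all designs up to 4 vs 4), a brute-force percentile grid for `s₀`,
scipy's average-linkage implementation for dendrogram heights,
Floyd–Warshall and triangle enumeration for path length and clustering
(50 random graphs of ≤ 50 nodes, agreement to 1e-12), union-find for
components, and double loops for projections. Calibration and recovery are
measured by simulation: 200 pure-null runs of 1000 genes at 4 vs 4 for the
Q ≤ 5% false-call rate, and a planted-truth run (1000 genes, 5% + 5% DE at
2.5× / 0.4×, log2 noise 0.25, 4 vs 4) for sensitivity ≥ 0.8 and observed
FDR ≤ 0.15. These sizes keep the full suite under a minute while leaving
the Monte-Carlo standard errors small relative to the margins tested.

## Known limitations

- Genome-wide screen counts from the motivating study (370 of 31,041
  genes; 173 up, 197 down) are not reproducible: the raw arrays were never
  deposited. The packaged fixtures cover only the published
  disease-associated subset.
- Likewise the full 38-pathway network behind the published whole-network
  metrics (average degree ≈ 3, path length 3.68, clustering 0.26, 31 + 7
  component split) was not published as an edge list; those metrics can be
  re-derived on a user-supplied annotation but not verified from the
  packaged data. The demo knowledge base is illustrative.
- The permutation FDR is granular at very small designs (a 3 vs 3 design
  has only 20 assignments), a property of the method rather than the
  implementation.
- `π₀` estimation is off by default; with very high DE fractions the
  default is noticeably conservative.
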