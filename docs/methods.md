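# Methods

## TSSD construction

A TSSD (TSS distribution) is the per-nucleotide histogram of CAGE tag 5′ ends
inside one promoter's tag cluster. Tags on the same strand are chained by
single linkage whenever their intervals overlap by at least `min_overlap`
(default 2 bp; a 1-bp requirement is known to produce "tiling" artefacts in
which marginally overlapping tags stitch unrelated clusters together).
Chains totalling fewer than `min_tags` tags (default 100) are discarded:
shape statistics on shallow histograms are dominated by sampling noise. A
lower threshold is acceptable for small data sets as long as it is held
fixed across a study.

Histograms are stored in the sense direction — index 0 is always the
5′-most covered base, so minus-strand distributions are reversed relative to
genomic coordinates at construction. Width `w` is the inclusive span between
the outermost covered bases.

CTSS input (`chrom pos strand count [tissue]`) yields 1-nt tags; before
chaining, these can be extended 3′-wards to a nominal CAGE tag length
(`extend_to=21`) with 5′ ends preserved, restoring the interval geometry the
overlap rule expects.

**Smoothing order.** Laplace's rule of succession (add one tag to every
position of the trimmed support) is applied after clustering and filtering
and before normalisation, i.e. it affects the distance computation but never
the cluster membership or the width. Peakedness and peak calling operate on
the raw counts; the smoothed pseudo-tags belong to no tissue, so tissue
specificity is also computed on raw counts. The order is a package decision;
smoothing-then-normalising regularises broad histograms toward uniformity
without changing any width.

## GM-distance

The base dissimilarity is MDPA (minimum difference of pair assignments)
between two ordinal histograms of equal length and mass: the minimum total
number of one-bin element moves converting one into the other, which equals
the L1 distance between the cumulative sums (1-D optimal transport with unit
ground distance). Because two TSSDs generally differ in width and share no
coordinate frame, both are normalised to sum to one (making the comparison
shape-only) and one histogram slides over the other: at every integer offset
with at least one overlapping position both are zero-padded to a common
frame and the MDPA evaluated; the GM-distance is the minimum over offsets.

The full offset sweep (rather than, say, anchoring at dominant peaks) is the
package's reading of the sliding construction; it makes the distance
translation-invariant by definition. On shift-equivalence classes of shapes
the result is a pseudometric: non-negative, symmetric, zero on identical
shapes, and satisfying the triangle inequality (verified by property tests
against an exhaustive minimum-cost tag-assignment oracle).

All offsets are evaluated at once on extended CDF arrays via a sliding
window view; the all-pairs matrix costs O(n² w̄²) and is logged as such —
at the reference desk scale (n = 300, w ≤ 200) it takes a few seconds, and
a condensed upper-triangle TSV writer is provided for larger runs.

## Peakedness

For a TSSD with mode mass `m`, total tags `n` and width `w`,

    P = (m / n)^alpha / w^beta ,   alpha = beta = 1 by default.

P ∈ (0, 1] and attains 1 exactly when every tag maps to one nucleotide. The
exponents are exposed in the configuration so alternative weightings of
concentration versus width are one flag away; the default is the simplest
form that is maximal for the single-nucleotide archetype and monotone in
concentration. The intra-cluster peakedness of a cluster is the arithmetic
mean over its members.

## Two-level hybrid clustering

Distance-based clustering alone separates shapes but needs a very deep cut
to isolate the small homogeneous groups; peakedness alone collapses shapes
with equal summary statistics. The two-level procedure combines them:

1. **Level 1:** Ward-linkage agglomeration of the GM-distance matrix, cut
   into `k1` fine clusters (default 500, clamped to n with a warning).
   The Lance–Williams update is applied directly so both Ward dialects are
   available: `classic` operates on the dissimilarities as given (the
   behaviour of R's `hclust(..., "ward.D")`, typical of the era's tooling,
   and the default) and `squared` on their squares with square-root heights
   (`ward.D2`; verified equivalent to scipy's `linkage(..., "ward")` in the
   tests). Merge ties break toward the smallest leaf index, making the tree
   deterministic. Cutting removes the k−1 highest merges; cuts are nested.
2. **Level 2:** the `k1` intra-cluster mean peakedness scores are grouped
   into `k2` tiers (default 3) by an exact 1-D k-means — dynamic programming
   over the sorted scores. The 1-D optimum is attained on contiguous blocks
   of the sorted values, so the DP is globally optimal and removes the only
   seed-dependence from the headline pipeline (a deliberate replacement for
   seeded iterative k-means). Tiers are named in descending mean peakedness:
   ultra-dense, dense, scattered (numeric tiers for k2 ≠ 3). A degenerate
   input with fewer distinct score values than k2 clamps k2 with a warning;
   a data set of identical deltas is therefore labelled ultra-dense.

Explained variance for a partition of a dissimilarity matrix uses the
squared-dissimilarity dispersion decomposition
`EV = 1 − (Σ_k W_k)/T`, `W_k = (1/n_k) Σ_{i<j∈k} d²ᵢⱼ`,
`T = (1/n) Σ_{i<j} d²ᵢⱼ` — 0 for one cluster, 1 for all singletons,
non-decreasing along nested cuts. An EV-vs-k₂ table over the level-2 scores
supports model selection; on the reference simulation k₂ = 3 explains more
than 99% of the peakedness variance.

A PAM-style k-medoids estimator over the same matrix is provided as the
alternative flat clusterer (seeded medoid initialisation, alternating
assignment and medoid update, non-increasing objective).

## Bootstrap cluster stability

The data are resampled with replacement B times (default 100). Each pseudo
data set is clustered into k groups by the same procedure (the precomputed
distance matrix is subset, never recomputed). Clusters are treated as sets
of distinct original identities; bootstrap multiplicity is ignored. For
each original cluster, the replicate contributes the Jaccard coefficient of
the most similar pseudo cluster, with the original cluster restricted to
the items the replicate actually drew — a perfectly reproduced cluster
scores 1 regardless of which items the resample missed, and a cluster with
no item in the resample scores 0. Ties between equally similar pseudo
clusters go to the larger one, then the lowest index. The per-cluster
stability J̄_k is the mean over replicates; the clustering's stability S is
the size-weighted mean of the J̄_k. Replicate b is seeded `seed + b`, so any
subset of replicates is independently reproducible; a replicate with fewer
than k distinct items is re-drawn and logged.

## Peak identification

Within one (raw-normalised) TSSD, candidates are positions carrying at
least `intensity` (default 5%) of the total tags. Candidates are visited in
decreasing mass (ties 5′-first) and accepted unless an accepted peak lies
within `span/2` (default 10 nt) — candidates closer than half a peak width
merge into one peak. A TSSD with no candidate is classified "uniform".
Calling on raw rather than smoothed histograms is the package default
(configurable): add-one smoothing deflates the relative intensity of peaks
in wide TSSDs.

## Tissue specificity

For a TSSD g with tissue fractions p_g and the pooled tissue fractions q of
all tags, specificity is the relative entropy Σ_t p_g(t) log₂(p_g(t)/q(t))
in bits (log base 2 is a package choice; the base rescales but never
reorders scores). It is 0 exactly when the promoter's tissue profile equals
the background, and grows as expression becomes tissue-restricted. Support
of p must lie inside the support of q — automatic whenever q aggregates all
tags.

## Sequence diagnostics

Both operate on user-supplied, equal-width sequence windows aligned at the
dominant peak (genome extraction is out of scope).

* **PWM scan:** the PWM is a 4×L count/frequency table; frequencies get a
  0.01 pseudocount and are scored as log-odds against a uniform background
  (the cited scanning convention fixes neither, so both are package
  choices). A hit at an offset requires the relative score
  `(s − s_min)/(s_max − s_min) ≥ 0.70`; hits are anchored at the match
  start (for a TATA matrix, the first T) and densities are hits per offset
  per sequence. Only the given strand is scanned — TSSDs are already
  sense-oriented.
* **PyPu density:** at each offset relative to an annotated peak, the
  fraction of (sequence, peak) pairs whose −1/+1 dinucleotide is
  pyrimidine-then-purine ({C,T} then {A,G}); pairs with an ambiguous base
  leave the denominator at that offset.

## Synthetic data

The generator plants the three shape archetypes at their observed width
regimes, with 200 tags per TSSD (above the 100-tag threshold, small enough
that the full suite runs in seconds) and 22 tissues:

* **ultra-dense** — all tags at one nucleotide (w = 1);
* **dense** — one discretised bell, sd drawn U(1, 2) nt, samples truncated
  to ±9 so w < 20. The archetype is the canonical sharp (TATA-like)
  promoter whose pre-initiation complex wobbles by a few nucleotides; sds
  much above 2 nt flatten the mode into the scattered peakedness regime and
  would blur the very contrast the classifier measures;
* **scattered** — 1–4 planted peaks over a U(60, 200)-nt span (within the
  20–200 regime; narrower spans genuinely approach dense widths), with peak
  counts drawn at the observed 34/43/20/3% fractions and centres ≥ 20 nt
  apart. A uniform floor of `min(1.2·span, n/3)` tags models dispersed
  background initiation; the remaining tags are split over the peaks by a
  Dirichlet conditioned so every component holds ≥ 15% of the non-floor
  pool (≥ 10% of all tags). Each component places a deterministic spike of
  `min(0.75·component, 0.12·n)` tags (≥ 15) at its centre — so every
  planted peak clears the 5% detection threshold by construction — and
  spreads the rest as a local sd 2–4 bell.

Tissue profiles are class-dependent Dirichlet draws (concentration 0.15 for
dense, 0.8 for ultra-dense, 8 for scattered), reproducing the observed
ordering of tissue specificity: dense most restricted, scattered closest to
background, ultra-dense intermediate.

Two repairs keep histograms consistent with real tag clusters: the span
endpoints always carry ≥ 1 tag, and no internal gap between covered
positions exceeds 19 nt — precisely the constraint that chaining 21-nt tags
with a 2-bp overlap imposes on real TSSDs, and what makes the CTSS
round-trip (`simulate_ctss` → `read_ctss` → `build_tssds(extend_to=21)`)
reconstruct every histogram exactly. Both repairs move single tags off the
current mode, which is orders of magnitude taller.

**What the generator does not emulate.** Real CAGE data carry mapping
artefacts (the 5′ G-addition bias that creates many ultra-dense TSSDs at
ribosomal-protein pseudogenes), cross-mapping, per-library depth variation,
and — most importantly — a far denser population of shape space: thousands
of broad promoters form a near-continuum in which fine clusters are
arbitrary cuts and hence intrinsically unstable under resampling. At desk
scale (100 scattered TSSDs in ~27 fine clusters of 2–8 members) the
scattered clusters are isolated islands that re-form under resampling much
more faithfully (J̄ ≈ 0.78) than their real-data counterparts, and
20-replicate bootstrap noise on such small clusters is large (the
per-replicate Jaccard is quantised to a handful of values, and a cluster
entirely absent from a resample scores 0). Passing tests therefore
demonstrate the machinery — correct metric, deterministic pipeline, exact
arithmetic, recoverable planted structure — but the *strength* of the
stability–peakedness correlation observed on real data is not reproduced at
this scale: the class-level ordering holds (ultra-dense J̄ = 1.0 > dense
≈ 0.89 > scattered ≈ 0.78, Pearson r > 0), while the correlation magnitude
stays near r ≈ 0.33 because the within-class bootstrap noise (≈ 0.11)
exceeds the class-mean spread (≈ 0.08). With noise-free per-cluster
stabilities the same class means would give r ≈ 0.84.

## Numerical choices and degenerate inputs

* Distances in double precision; test comparisons at 1e−9.
* Dominant-peak and peak-calling ties resolve 5′-first everywhere.
* The peak-calling intensity threshold is inclusive (≥), with a 1e−12
  guard against float round-off at the boundary.
* `KMeans1D` clamps k to the number of distinct values (warning);
  `TSSDShapeClassifier` clamps k1 to n (logged warning).
* Ward rejects asymmetric or negative matrices; `cut_dendrogram` validates
  1 ≤ k ≤ n; empty clusters, empty histograms and zero-tag TSSDs raise.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds give byte-identical artifacts.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `min_overlap` | 2 bp | minimum tag-interval overlap for chaining |
| `min_tags` | 100 | minimum tags per TSSD |
| `k1` | 500 | level-1 fine clusters (clamped to n) |
| `k2` | 3 | level-2 shape tiers |
| `B` | 100 | bootstrap replicates |
| `span` | 20 nt | peak width; candidates within span/2 merge |
| `intensity` | 0.05 | minimum per-position tag fraction for a peak |
| `alpha`, `beta` | 1, 1 | peakedness exponents |
| `rel_threshold` | 0.70 | PWM relative-score cutoff |
| pseudocount | 0.01 | PWM frequency pseudocount |
| `n_tags` | 200 | simulated tags per TSSD |
| `n_tissues` | 22 | simulated tissue labels |
| `peak_sep` | 20 nt | minimum planted peak separation |

## Known limitations

* The all-pairs matrix is dense and O(n² w̄²); runs at the original study's
  scale (~7.7k TSSDs) take hours on one CPU and should use the condensed
  writer.
* The peakedness exponent form is one defensible reading of the summary
  statistic; the exponents are exposed rather than asserted.
* Sub-classification of broad promoters by kurtosis/skew is deliberately
  out of scope (reported unfruitful), as are read mapping, liftover,
  epigenetic track aggregation and genome sequence extraction.
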