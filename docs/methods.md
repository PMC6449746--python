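# Methods

`simfuse` fuses disease–disease similarity across heterogeneous data types
("feature spaces") into a single network, the *disease map*. This note
documents the model, its assumptions, the tunable parameters, the numerical
conventions, and what the synthetic data generator does and does not emulate.

## The similarity-fusion model

Each feature space represents every disease as a set of opaque feature
identifiers (ontology terms, phenotypes, co-occurring literature terms,
associated genes, differentially expressed genes, indicated drugs, ...).
Within one space, the similarity of diseases *a* and *b* is the Jaccard
index of their feature sets,

    J(a, b) = |A ∩ B| / |A ∪ B|,

which is symmetric and bounded in [0, 1]. Gene-expression-like spaces are
*signed*: each disease carries disjoint up- and down-regulated sets, and the
score is a weighted mean of the part scores

    J± = w_up · J(A_up, B_up) + w_down · J(A_down, B_down),

with `w_up = (|A_up| + |B_up|) / S` and `S` the total size of all four
sets. This size weighting lets the larger part carry more of the signal and
reduces to the unweighted mean when sizes are balanced; an `unweighted`
rule (plain 0.5/0.5 average) is available and recorded in matrix metadata.
The weighting uses per-pair set sizes; a per-disease variant would differ
only when set sizes vary across diseases and is not implemented.

For *n* diseases each space yields a symmetric n×n matrix. The diagonal is
stored as 1 for display but excluded from everything downstream; the unit
of analysis is the off-diagonal *pair vector* of length n(n−1)/2 in
row-major upper-triangle order over the lexicographically sorted disease
list.

### Why quantile normalization

Similarity distributions differ enormously between spaces: a dense
ontological space where most pairs share terms versus a sparse genetic
space where most pairs share nothing. Averaging raw scores would let
high-scoring spaces dominate, and even sum-normalized scores would let
sparse spaces dominate the upper tail. Quantile normalization forces every
space's pair vector onto one common distribution — the element-wise mean of
the rank-sorted vectors — so each space contributes evenly at every
quantile.

Tied values (exact equality; Jaccard scores are exact rationals, so no
epsilon is used) are adjusted: a run of *k* equal raw values receives the
mean of the *k* reference values spanning their tied ranks. This keeps the
transform well defined (equal raw scores map to equal normalized scores)
and rank-preserving. Tie-group means accumulate strictly left to right so
that the result is bit-reproducible and matches a brute-force
sort/rank/average oracle exactly.

Fusion is the per-pair weighted mean of the normalized vectors; weights are
non-negative, normalized to sum to 1 at construction, and uniform by
default. When a subset of spaces is fused (e.g. the five-space non-drug map
used for hold-out evaluation), the normalization reference is recomputed
over that subset by default, because the reference distribution depends on
the participating spaces; `renormalize=False` reuses the all-space
normalization instead, and the choice is recorded in metadata.

## The randomization null and the link threshold

Whether a fused score is "high" is judged against random fused matrices.
For each space, every disease receives a random feature set of its observed
cardinality drawn from the space's *feature universe* (the union of
observed features) with probability proportional to each feature's observed
frequency, without replacement. Frequency-preserving sampling is essential:
features shared by many diseases would otherwise never produce high random
overlaps, and the threshold would be too permissive. Signed spaces draw the
up set first and the down set from the remaining features, preserving sizes
and disjointness.

Weighted sampling without replacement follows the successive-renormalization
(Plackett–Luce) scheme, realised by the exponential-race construction
(draw `E_i ~ Exp(1)/w_i`, keep the k smallest), which has exactly that
distribution and vectorizes.

Each null iteration randomizes every participating space, reruns the full
normalize-and-fuse pipeline, and pools the fused off-diagonal values. The
threshold is a high percentile of the pooled values — 99.99 by default,
computed by linear interpolation between order statistics (the "type 7"
convention, pinned in metadata). The per-iteration-maximum exceedance
fraction is reported as a diagnostic. Disease pairs whose real fused score
is *strictly* greater than the threshold become edges of the disease map;
ties at the threshold are excluded (with continuous fused scores they are
measure-zero, but the convention must be pinned).

Two properties of this null are worth knowing. First, it is exactly
calibrated against itself: data drawn from the same randomization mechanism
exceeds the threshold at the nominal rate. Second, it is mildly
conservative against independently generated structure-free data at small
scale, because it resamples the *observed* universe weighted by *observed*
counts — a bootstrap-style concentration that slightly inflates null
overlap. At a few thousand pooled values per iteration this effect is
small; it is visible at desk scale (tens of diseases).

## Evaluation procedures

**Novel links.** With per-disease top-level ontology classes (a disease may
hold several or none), an edge is *novel* iff the two diseases' class sets
are disjoint. Edges with an unlabelled endpoint are excluded from the novel
fraction and flagged.

**Comorbidity.** Given an external table of per-pair relative risks (RR),
the evaluator contrasts the median RR of covered linked pairs against
covered non-linked pairs, and at each RR cut-off (default 1.5, 2, 5)
reports the fraction of linked and non-linked pairs above it and their
ratio. Duplicate table pairs keep the maximum RR (sources mapped across
disease vocabularies can yield several records per pair).

**Drug-overlap curves.** Excluding the drug space from fusion, the curve
reports — at each of 100 similarity-quantile levels 0.00–0.99 — the mean
Jaccard overlap of drug sets among pairs whose similarity strictly exceeds
that quantile of the evaluated matrix. Levels with no linked pair are
undefined (NaN), never 0.

**Class prediction.** Membership of one top-level class is predicted from
each disease's *similarity profile*: its row of pairwise similarities with
the self-entry removed. Similarities are computed without label knowledge,
so using the full row (including similarities to test diseases) leaks no
labels; the protocol is transductive. Each Monte-Carlo run draws a
stratified 80–20 train/test split (degenerate splits are redrawn), fits a
random forest with 500 trees, sqrt(p) features per split and unlimited
depth, and scores the held-out diseases. AUROC (trapezoidal) is averaged
over all runs. For display, ROC curves are first reduced to their unique
(FPR, TPR) breakpoints, and only runs whose curve has the modal number of
breakpoints are averaged element-wise — averaging curves of different
lengths element-wise would be meaningless. ("Modal number of points" could
also be read as the modal *averaged* length; the modal-curve-length reading
is implemented.)

## The synthetic data generator

The generator emulates the *shape* of a real multi-space disease dataset so
that every pipeline stage is testable without external data. The default
profile has 84 diseases in four planted classes (proportions roughly 1/3,
1/4, 1/4, 1/6) and six spaces:

| space          | set size      | universe | shared fraction | notes            |
|----------------|---------------|----------|-----------------|------------------|
| ontological    | 100           | 600      | 0.35            | dense            |
| phenotypic     | 21            | 400      | 0.30            | small fixed sets |
| literature     | 100           | 2000     | 0.30            |                  |
| genetic        | 100           | 4000     | 0.03            | sparse, weak     |
| transcriptomic | 100 (60 up / 40 down) | 3000 | 0.03       | signed, weak     |
| drug           | Uniform[2, 15]| 300      | 0.40            | variable sizes   |

Universe sizes differ by an order of magnitude, so raw similarity
distributions are strongly unequal — the condition that motivates quantile
normalization; fusing raw scores on these data is visibly unbalanced.
Per-space class signal is deliberately heterogeneous: the "traditional"
spaces carry strong class-driven sharing while the molecular spaces are
noisy with only a trace of signal, matching the real regime in which
molecular similarities correlate weakly (r < 0.2) with everything else.
The hold-out property of the fused map — higher drug overlap among its top
links than the individual-space average — exists precisely in this
heterogeneous regime; if every space were equally strong their top links
would coincide and fusion would have nothing to denoise.

Each space's universe is partitioned into disjoint per-class shared pools
plus a background pool. A disease of class *c* with set size *s* draws
`m = round(shared_fraction · s)` features uniformly without replacement
from *c*'s pool and `s − m` from the background. Pools are small —
`pool_scale` (default 1.5) times the largest shared draw — so within-class
pairs share most of their pool draw (the frequent features a real disease
cluster shares), while the large background stays sparse. Signed spaces
split the universe and each draw into disjoint up/down parts at
`up_fraction` (default 0.6). Drug-like sharing is coupled to class
membership through the same pools, so hold-out drug evaluation has planted
signal by construction.

Under this model the expected Jaccard index of a pair is an exact
double-hypergeometric sum: the pool overlap X ~ Hypergeom(pool, m_a, m_b)
(zero for between-class pairs) and background overlap Y are independent,
and E[J] = E[(X+Y)/(s_a+s_b−X−Y)] is evaluated by summing over both pmfs
(averaged over the size distribution where sizes vary; for signed spaces
the part weights are deterministic given sizes and factor out).
`expected_jaccard` is the oracle for the generator's parameter-recovery
tests.

**What the generator does not emulate:** real feature-frequency spectra
(heavy-tailed gene and term frequencies), overlapping or hierarchical
disease classes, cross-space feature correlation beyond class membership,
diseases missing from a space, and any actual disease biology. Passing
tests therefore demonstrate that the pipeline recovers planted structure of
realistic shape and scale — not that any particular real-data number is
reproduced.

## Problem sizes and defaults

Desk-scale experiments use reduced sizes chosen to exercise every code
path: null calibration on 20 structure-free diseases with 200 null
iterations at the 99th percentile (the 99.99th percentile is meaningful
only with thousands of pooled values per iteration); planted-structure
recovery on 30 diseases, 3 classes, 4 spaces with 200 cross-validation
runs; hold-out drug overlap on 40 diseases over 20 replicates at the
top-5% level. Production parameters (1000 null iterations, 99.99th
percentile, 1000 CV runs) remain the CLI defaults.

## Known limitations

- Diseases absent from a space are excluded from the common disease list
  (with a logged report), not imputed.
- The null distribution pools values across iterations; per-iteration
  percentiles and per-pair significance are not implemented.
- Alternative set similarities (cosine, overlap coefficient) and fusion
  operators (max, rank aggregation, diffusion) are out of scope; the
  Jaccard/mean pipeline is the method.
- The frequency-preserving null's mild desk-scale conservatism (above)
  means very small maps may under-link rather than over-link.
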