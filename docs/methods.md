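# Methods

This note documents the models and procedures `loopbench` implements, the
parameters that matter, the numerical and design decisions taken where the
underlying definitions left room, and what the synthetic-data tests do and
do not demonstrate.

## Coordinate model

All coordinates are 0-based, half-open `[start, end)` (BED/BEDPE
convention). A loop's anchors are normalised into genome order on
construction, so every intersection test runs in a single orientation. The
inter-anchor distance *d* is midpoint-to-midpoint; "distance between two
anchor regions" admits several readings (gap, midpoint, outer span) and
the midpoint form is the one that is stable under anchor-width changes.

## UV Rate

A PET is Uniquely mapped Valid when both end MAPQs reach `mapq_min`
(default 30), the duplicate flag is unset and the ligation class is
inter-ligation. PET records arrive as a 10-column table exported from an
upstream aligner/duplicate-marker; alignment itself is out of scope.
Self-ligation versus inter-ligation is a genomic-span cutoff, default
8 000 bp and configurable over 5 000–12 000 bp — published pipelines span
exactly that range, and the midpoint is a neutral default. The rate is
undefined (an error) on an empty collection rather than 0: silently
reporting 0 would score a missing input as a worst-case experiment.

## Peak co-occupancy (PC)

Anchors are first merged at 90% *reciprocal* overlap: "overlapped with
each other" is read as symmetric, so the overlap must reach the fraction
of **both** interval lengths; a one-sided mode is available
(`reciprocal=False`). Merging uses an iterated connected-component
closure — build the qualifying-pair graph on the current intervals, union
each component into its span, repeat until no pair qualifies. This makes
the result idempotent and independent of input order, which a greedy
pairwise merge is not.

For each anchor the peak with the longest overlap is selected (ties:
leftmost peak start, then input order — a deterministic rule chosen here,
since any rule must be fixed for reproducibility) and contributes
`max(L(o)/L(peak), L(o)/L(anchor))`. Two report modes exist because the
printed formula `N_A * Σ term / N` exceeds 1 whenever more than one anchor
matches perfectly (every anchor matched exactly gives PC = N_A):
`literal` reproduces that formula; `normalized` (`Σ term / N`, bounded in
[0, 1]) is the default for reporting and is what a co-occupancy fraction
plotted on a 0–1 axis corresponds to.

## Enrichment score (ES)

The ES assumes a true loop is a *local maximum* of PET enrichment: its
anchors should be more enriched than their surroundings. With mean anchor
length `l_m = (l_a + l_b)/2`, the neighbour count

    P_n = min( P[s1-l_m, s1) + P[e1, e1+l_m) ,
               P[s2-l_m, s2) + P[e2, e2+l_m) )

sums the two flanking windows of each anchor and takes the weaker anchor's
flanks; `P[x, y)` counts PET end positions in the window. Windows are
**clipped** at chromosome bounds (not discarded — a telomere-proximal loop
still gets scored, just against a shorter flank). `P_n = 0` is replaced by
a pseudocount of 1 so ES stays finite; the alternative (infinite ES for
isolated loops) would let a single stray PET dominate the global score.
`ES_i = C_i / max(P_n, 1)`, and `ES_i < 1` flags an invalid loop.

The global score corrects for uneven sequencing depth across chromosomes:
with genome-wide PET coverage `C = L*N/G` (PET length L, N PETs, genome
length G) and per-chromosome coverage `C_j`, each chromosome's ratio
`Σ C_i / Σ max(P_n, 1)` is multiplied by `α_j = C / C_j`. Because α is
chromosome-specific the genome aggregate cannot be a single ratio; it is
computed per chromosome and combined with PET-count weights
`w_j = Σ_j C_i / Σ_all C_i`, so chromosomes contribute in proportion to the
loop evidence they carry.

## Accuracy (ACC)

Gold-standard loops are "true"; three sampled false sets of equal size
provide the negative class. A detected loop intersects a reference loop
when both anchor pairs overlap by ≥ 1 bp (a reciprocal-fraction gate is
exposed as `min_overlap_fraction` for stricter matching). TP/FN come from
the truth set; FP/TN are computed against each false replicate and
averaged, and

    ACC = (TP + TN) / (TP + TN + FP + FN).

### Gold-standard construction

Candidate coverage counts the verified contacts whose two regions hit the
two anchors on *distinct* anchors (either orientation; a flag relaxes
this). No parametric form is assumed for "significantly covered": the null
re-places every contact uniformly at random M = 1000 times, preserving its
region lengths and inter-region distance — same-chromosome contacts move
as a rigid block to a position drawn uniformly over all valid genome
positions (chromosomes weighted by the number of valid placements),
inter-chromosomal contacts move each region independently. eQTL variant
loci are pre-expanded by a 5 kb flank on both ends, clipped at chromosome
bounds.

Two p-value estimators are provided. The **conservative** estimator
`(1 + #{perm ≥ obs}) / (M + 1)` is the default for gold-set selection: on
the discrete coverage scale a zero-coverage candidate gets p = 1, so ties
at zero can never enter the gold set and selection is reproducible and
strictly valid. The **randomized** estimator breaks ties with an
independent uniform draw, `(#{perm > obs} + U·(1 + #{perm == obs}))/(M+1)`,
and is exactly uniform under the null; it is the right tool for
calibration analyses (the type-I test uses it) but can, by construction,
admit a few null candidates at any nominal level, which is the wrong
trade-off for building a reference set. Multiple testing uses
Benjamini–Hochberg (via statsmodels); selection requires p < 0.05 **and**
FDR < 0.05.

### False-loop sampling

Each false loop copies the geometry (anchor lengths, midpoint distance) of
a randomly chosen true loop and is placed by rejection sampling on a
length-weighted random chromosome so that neither anchor overlaps the
exclusion mask (TSS and enhancer-like regions) and the loop intersects no
excluded loop set. Matching the truth geometry is deliberate: ACC should
penalise *location* errors, not differences in anchor-width or distance
distributions between the positive and negative class. Replicate k derives
its stream from (seed, k); a rejection budget (default 10⁵ tries per loop)
turns an over-dense mask into an explicit error rather than a hang.

## Significant loops, AR and resolution

The significance pre-filter keeps loops with ≥ 3 PETs (ChIA-PET) or ≥ 8
(HiChIP), and p ≤ 0.05 / FDR ≤ 0.05 *when the caller reports them* —
missing fields pass, since not every method emits significance columns.

For AR, each anchor is labelled E (enhancer-like overlap ≥ 1 bp) or P
(promoter-like); an anchor matching both is labelled P — promoter-like
signatures are the rarer, more specific annotation, and the E-P class
would otherwise be systematically under-counted. Loops with both anchors
labelled form the E-E/E-P/P-P classes; loops with exactly one labelled
anchor are retained for activity classification (counted as "partial");
loops with neither are excluded. Activity compares the total overlap of
both anchors with the **union** of active-mark peak sets against the union
of repressive-mark sets (a per-set summation mode exists behind
`combine="sum"`); strictly larger active overlap means active, strictly
larger repressive means inactive, and ties — including zero overlap with
both — mean "other". AR = active / classified.

Resolution levels bin midpoint distances into d ≤ 10 kb,
10 kb < d ≤ 100 kb and 100 kb < d ≤ 1 Mb (right-inclusive); loops beyond
1 Mb and inter-chromosomal loops fall in no bin, and fractions are over
binned loops.

Min-max rescaling maps per-method scores to [0, 1]; all-equal input maps
to all 1.0 (every method is equally best — mapping to 0 or 0.5 would
invent a ranking where none exists).

## Simulators

**ChIA-PET.** Chromosomes are segmented into 5 000 bp bins and every
intra-chromosomal bin pair with 1 ≤ δ ≤ `max_delta` receives
`n_ij ~ Pois(a / (1 + δ))`. δ is in **bin units**: with base-pair units the
intensity would be ≈ 0 beyond the first bin, contradicting the strong but
gradual distance decay the model is meant to capture. `a` is the intensity
scale — the expected count of a self pair (δ = 0); self pairs are logged
in the companion table on request but never emitted as loops, and
zero-count pairs are never emitted (sparse BEDPE semantics). Each
chromosome draws from a substream keyed on (seed, chromosome name), so
chromosome order cannot change results. The closed-form MLE
`a_hat = Σ n / Σ 1/(1+δ)` validates the generator end-to-end.

**HiChIP.** Hi-C anchor pairs at the same bin size are scored by ChIP-seq
read count over both anchors, and pairs below the `coverage_threshold`
quantile of scores (default 0.5, the median — the "50% coverage" filter
read as a quantile cut, the denominator being the candidate-pair
population) are dropped. An absolute-fraction mode (anchor bases covered)
was considered and rejected as the default because it makes the retained
fraction depend on read depth rather than on ranking. Different antibodies
are emulated solely through the ChIP coverage input.

**Fixture bundles.** `make_fixture` writes a complete, self-consistent
input set with exact planted truths: candidate loops in disjoint genomic
blocks (so a planted contact covers exactly its own loop), PET records
with an exact UV fraction (default 0.4 over 1000 PETs), verified contacts
on 20 of 100 candidates (8 contacts each), enhancer/promoter annotations
on anchor1/anchor2 of every candidate, and histone-mark peaks implementing
a 0.5/0.3/0.2 active/inactive/other split. These defaults are the standard
study conditions used by the tests and the acceptance script.

What the generators emulate: distance decay, Poisson counting noise,
ChIP-enrichment filtering, planted regulatory contacts. What they do not:
restriction-site bias, linker/chimera artefacts, duplicate structure from
PCR, TAD-level correlation between nearby pairs, or anchor-width
heterogeneity within a caller. Passing the planted-truth tests therefore
demonstrates the *correctness of the metric arithmetic and the selection
machinery* on clean geometry, not robustness to the correlated noise of
real libraries.

## Problem sizes and tolerances

The test suite validates each metric against an independent brute-force
oracle on 100 randomised instances of ≤ 10³ intervals; simulator moments
use ≥ 10⁴ draws per (a, δ) cell with a 3-standard-error band on the mean
and a [0.9, 1.1] band on the index of dispersion; intensity recovery uses
5 001 pairs at δ ≤ 2, where the MLE's relative sampling error at a = 1 is
about 2.2%, comfortably inside the 5% check; type-I calibration uses 1000
null candidates × 1000 permutations with the randomized estimator and a
3-sigma binomial band around 0.05. These sizes keep the full suite under
half a minute on one CPU while leaving every statistical check several
standard errors of headroom.

## Known limitations

* The permutation null treats contacts as independent; clustered eQTLs
  violate this and would make the conservative estimator looser still.
* `global_es` scales per-chromosome PET counts from track positions; when
  a track stores both ends of each PET the per-chromosome attribution
  assumes ends are representative of PET location.
* PC's literal mode is reported but not rescaled; cross-method comparison
  should use the normalized mode.
* The comparison matrix averages metrics over datasets with equal weight;
  no variance-based weighting is attempted.
* Running time of callers is logged by users' pipelines, not measured
  here — it is hardware-bound and out of scope.
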