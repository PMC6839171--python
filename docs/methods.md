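# Methods

This note documents the models, parameter choices and numerical
conventions behind `enhancerkit`, and what the synthetic benchmarks do and
do not demonstrate.

## Signal model and normalization

All computation happens on fixed 100-bp bins, 0-based half-open, built
per chromosome (`ceil(length / bin_size)` bins; the last bin may be
shorter). Chromosome names are taken verbatim from the inputs; no
"chr"-prefix harmonization is attempted, and a read set whose chromosomes
are disjoint from the bin grid is an error rather than a silent zero
track.

A read contributes one count to the bin containing its 5′-most aligned
position (reference start on the forward strand, last aligned base on the
reverse strand). This single, documented rule makes `bin_counts` conserve
the number of assigned reads exactly. Paired-end data are counted once
per mate by default; a fragment mode counts each proper pair once at the
template midpoint.

Input normalization is `log2(t+1) − log2(c+1)`, algebraically identical
to `log2((t+1)/(c+1))` but computed as a difference for symmetry around
zero. The H3K4me1/H3K4me3 ratio track first shifts each input-normalized
track by its genome-wide minimum so the minimum becomes 0, then takes
`log2(me1′+1) − log2(me3′+1)`. The shifts are training-time constants
stored in the model; at prediction time values that would fall below a
stored shift are clipped at 0, which can only happen when prediction data
are not quantile-normalized to the training references.

Quantile normalization maps the rank-r input value to the reference
quantile at the same relative rank, with linear interpolation between
stored quantiles and the average-rank convention for ties. References are
stored as 10,000-point sorted quantile summaries of the training
distribution to bound model size; the approximation error of the summary
is below the noise floor of any realistic track. All bins participate in
the reference, including zero bins — excluding them would make the
mapping depend on the (depth-dependent) zero fraction, which is exactly
what normalization is meant to remove; this choice is a candidate for
sensitivity analysis but not exposed as an option.

## Two-tier classifier

Feature vectors concatenate, per mark, the values of the center bin and
N = 5 bins on each side (11 bins = 1100 bp). Classifier 1 (active vs.
inactive genome) uses H3K27ac only (11 features); classifier 2 (enhancer
vs. active promoter) uses H3K27ac, H3K4me1, H3K4me3 and the ratio track
(44 features), in that fixed order. Windows running off a chromosome end
are zero-padded and flagged. Both forests use 100 trees; all other
forest hyperparameters are scikit-learn defaults and are recorded in the
model provenance. N and M are deliberately hard defaults — they are the
tuned operating point of the method — but both are plain arguments for
anyone who wants to re-tune.

The per-bin enhancer probability is the product of the two forest
probabilities (a joint probability of being active and being an enhancer
given activity). The product form is what suppresses promoters: they
score high on classifier 1 but near zero on classifier 2. The test suite
checks this directly against the alternative design — a single forest
trained on the same 1000 regions with enhancers as the only positive
class — by comparing mean predicted probability at planted active
promoter bins.

Training-set composition is fixed (10/5/5/10/70% of 1000; 100:50 of 150)
with largest-remainder rounding when a non-divisible total is requested.
Classifier-1 positives are enhancers and active promoters; classifier-2
positives are enhancers, negatives active promoters. Sampling is without
replacement and seed-reproducible. Predicting on bins with a missing mark
is an error rather than an imputation.

Peak calling is greedy: bins with probability ≥ 0.5 are sorted by
descending probability (ties broken toward the lower coordinate, a
convention this package fixes), each emitting an 1100-bp window
(center ± 5 bins) unless it overlaps an already-emitted window. The
emitted peak carries its summit bin and the summit-bin probability; no
aggregation over the window is attempted. Windows are clipped at
chromosome ends, so a summit within 5 bins of an end yields a shorter
peak. Peaks within 12.5 kb edge-to-edge distance merge into enhancer
clusters by single linkage.

Spatial resolution of a peak set is the median distance from peak centers
to the nearest accessible-region reference point (summit column if
present, else the nearest interval boundary), excluding peaks farther
than 1 kb; an all-excluded set returns NaN with a warning.

## Permutation test for condition differences

For each condition pair, `T_x = (μ_C1 − μ_C2 − w0)/S_Δ` with the pooled
standard deviation
`S_Δ² = [(n1−1)σ²_1 + (n2−1)σ²_2]/(n1+n2−2) · (1/n1 + 1/n2)`
(unbiased group variances). With a single-replicate group, S_Δ is
replaced by ε = 1e−8; any difference beyond w0 then becomes maximally
significant — documented, deliberate behavior in the absence of a
variance estimate. S_Δ is also floored at ε for zero-variance bins.

The statistic is one-sided, so each unordered pair is tested in both
ordered directions. The null distribution comes from one global shuffle
of all matrix entries, with T recomputed for every bin and both
directions (n_null = #bins per round; extra rounds are available).
p-values use the add-one convention `(1 + #{T_null ≥ T_obs})/(1 + n_null)`,
giving the floor 1/(1 + #bins). Each pair shuffles with a sub-seed
derived from the run seed and the pair index, so pairs are independent
but jointly reproducible, and swapping the two condition labels exactly
mirrors the two directions (a tested symmetry).

A bin gets direction code (1,0) for a pair when the p-values of the bin
and its two neighbors on each side are all ≤ P* = 0.05 and the mean
difference at the bin is positive; (0,1) for the mirrored case. The
five-bin window never crosses a chromosome boundary — the first and last
two bins of a chromosome cannot be called. Codes over all pairs form the
activity pattern; for |C| conditions there are `3^C(|C|,2) − 1`
informative patterns.

Same-pattern bins within 2 kb merge into differential regions; the
region's peak is its lowest-p bin, where a bin's p is the minimum over
the ordered tests that fired for it. Regions of different patterns whose
merged spans overlap are combined and labeled by the lower peak p.

Only the raw empirical threshold P* is applied — no FDR correction —
matching the method's definition; users needing family-wise control
should lower P* or post-filter.

## Expression normalization and target linking

Counts are normalized by median-of-ratios size factors (computed over
genes with all-positive counts) followed by `log2(x+1)`. This is a
deliberately simple variance-stabilizing transform: on simulated
negative-binomial counts with means spanning 10–10⁴ and dispersion 0.1
the slope of log(sd) against log(mean) is near zero (tested within
±0.25). A `vst` hook accepts any callable for users who prefer a
model-based transform. All-zero genes stay zero.

A region's per-sample activity is its summit-bin probability (a
mean-over-region alternative is a one-line change at the call site, since
the caller supplies the region × sample matrix). Gene membership in a TAD
is judged by TSS position, region membership by overlap; TADs may overlap
and membership is tested per TAD, so a pair sharing any TAD is tested
once. Pearson correlation requires ≥ 3 samples; zero-variance vectors are
skipped with a warning. Only positive correlations at or above `r_min`
(default 0.9; 0.7 is a reasonable choice for noisier designs and is the
threshold the planted-recovery benchmark uses) are emitted. Topology
labels are assigned post hoc; a unit can be both many:1 and 1:many, in
which case the region-side label (1:many) is primary and both flags are
retained.

## Synthetic genomes

The generator plants elements on a 2 × 1 Mb genome (10,000 bins per
chromosome) with two conditions × two replicates by default — small
enough for the full pipeline to run in seconds, large enough for
~20,000-bin permutation nulls and a few hundred planted elements.
Defaults: 60 shared enhancers, 25 condition-specific enhancers per
condition, 60 active and 60 inactive promoters (the counts keep the
five-class training pool large enough for the fixed 1000/150-region
training composition), background 5 reads/bin, enrichment 8× background,
negative-binomial dispersion 0.1 (var = μ + 0.1 μ²), minimum 5 kb
separation between element centers.

Enhancers add two Gaussian count bumps (sd 150 bp) at ±200 bp around
their center on H3K4me1 and H3K27ac — the flanking-nucleosome anatomy
with a central dip that the 11-bin window is designed to detect. Active
promoters add a central bump on H3K4me3 and H3K27ac. Inactive elements
add nothing. Input tracks are background only. TADs tile the genome at
100 kb. Each planted enhancer gets a target gene with TSS elsewhere in
its TAD whose expected count is `base · (1 + 4 · activity(condition))`;
decoy genes are condition-flat. All draws flow from one seed;
identical configurations give identical outputs.

What the generator does *not* emulate: copy-number and mappability
artifacts, fragment-length effects, correlated noise between marks,
promoter-proximal enhancers, overlapping or nested elements, expression
variance driven by anything but the planted enhancer, and the
CpG-island/H3K4me3 breadth structure of real promoters. Passing the
planted-recovery benchmarks therefore demonstrates that the
implementation is correct and internally consistent — not that the
stated recall/precision transfer to real chromatin.

## Numerical and interface conventions

- Intervals: 0-based half-open everywhere; BED/bedGraph on disk.
- Ties in peak calling and nearest-gene assignment break toward the
  lower genomic coordinate; quantile ties use average ranks.
- Probability floors/ceilings are never clipped post hoc; the forest
  product is exact, and the test suite asserts the product identity
  elementwise.
- Models serialize as a single versioned archive (both forests, quantile
  references, shifts, feature spec, seed); loading a different format
  version is an error, so train-time and predict-time normalization can
  never silently diverge.
- Genes with FPKM in (0, 2] in any replicate are excluded from promoter
  labeling entirely: the active rule is FPKM > 2 in all replicates plus
  accessibility-peak overlap, the inactive rule is FPKM = 0 in all
  replicates, and the band between is deliberately left out of training
  rather than guessed at.
- Background training bins are sampled ≥ 1 kb from any labeled element
  to avoid label leakage into the flanking feature windows.
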