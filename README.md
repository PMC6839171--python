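# enhancerkit

Genome-wide enhancer prediction from histone-modification ChIP-seq,
condition-specific (differential) enhancer calling, and TAD-constrained
linking of enhancers to target genes.

`enhancerkit` is aimed at regulatory-genomics analysts who have, per
sample, aligned ChIP-seq for three core histone marks — H3K4me1, H3K4me3,
H3K27ac — plus an input/control library, and who want (i) per-bin enhancer
probabilities and enhancer peaks, (ii) enhancers that differ between
conditions, and (iii) candidate target genes for those enhancers.

## Method

**Enhancer prediction.** The genome is divided into adjacent 100-bp bins.
Raw counts per bin are input-normalized as `log2(t+1) − log2(c+1)`, and an
H3K4me1/H3K4me3 log-ratio track is added after shifting both distributions
to ≥ 0. Two binary random forests (M = 100 trees each) act on windows of
2N+1 bins (N = 5, i.e. 1100 bp), capturing the nucleosome–accessible
center–nucleosome anatomy of enhancers:

- classifier 1 separates *active* regions (enhancers + active promoters)
  from inactive ones, from H3K27ac alone (11 features);
- classifier 2 separates enhancers from active promoters, from all three
  marks plus the ratio (44 features).

The per-bin enhancer probability is the product

```
P(bin = active enhancer) = P(bin = active) · P(bin = enhancer | active).
```

Training sets emulate genome composition: 10% enhancers, 5% active
promoters, 5% inactive promoters, 10% intragenic, 70% intergenic (1000
regions) for classifier 1; 2/3 enhancers vs 1/3 active promoters (150
regions) for classifier 2. Before predicting on a new sample, its
input-normalized tracks are quantile-normalized to the training
distributions, which makes a trained model portable across samples and
sequencing depths. Bins with probability ≥ 0.5 are greedily expanded into
non-overlapping 1100-bp peaks; peaks within 12.5 kb can be merged into
enhancer clusters.

**Differential enhancers.** Per-bin probabilities from all samples form a
matrix A (bins × samples). For each condition pair the statistic
`T_x = (μ_C1 − μ_C2 − w0) / S_Δ` (pooled SD, default minimum difference
w0 = 0.5) is compared against an empirical null obtained by globally
shuffling A, giving per-bin p-values with floor 1/(1 + #bins). A bin is
called differential when its own p-value and those of two neighbors on
each side are all ≤ P* = 0.05; over all pairs this yields one of
`3^(pairs) − 1` activity patterns (26 for three conditions). Same-pattern
bins within 2 kb merge into regions carrying their lowest-p bin as peak.

**Regulatory units.** Differential regions and genes are gathered per
topologically associated domain (TAD, supplied as BED). For every
(region, gene) pair in a shared TAD, the Pearson correlation across
samples between the region's summit probability and the gene's
variance-stabilized expression is computed; pairs with r ≥ 0.9 (default)
become regulatory units, annotated with their 1:1 / many:1 / 1:many
topology.

A seeded synthetic-genome generator (planted enhancers and promoters with
negative-binomial read noise, condition designs with replicates, TADs and
expression counts coupled to planted enhancer activity) makes the whole
pipeline testable without external data.

## Worked example

Train on one synthetic genome and analyse a second one (2 chromosomes ×
1 Mb, two conditions × two replicates):

```python
import pandas as pd
import enhancerkit as ek
from enhancerkit import classifier, dynamics, synthetic, targets, training
from enhancerkit.signal import input_normalize_marks

sim_tr = synthetic.simulate_expression(synthetic.simulate_tracks(ek.SimConfig(seed=11)))
sim_te = synthetic.simulate_expression(synthetic.simulate_tracks(ek.SimConfig(seed=21)))

pool = synthetic.training_pool_from_truth(sim_tr, seed=11)
set1 = training.assemble_training_set(pool, "classifier1", seed=1)   # 1000 regions
set2 = training.assemble_training_set(pool, "classifier2", seed=2)   # 150 regions
s0 = sim_tr.cfg.samples[0]
marks = input_normalize_marks(sim_tr.raw_tracks[s0], sim_tr.input_tracks[s0])
model = classifier.train(set1, set2, marks, seed=3)

preds = {s: classifier.predict(model, input_normalize_marks(
              sim_te.raw_tracks[s], sim_te.input_tracks[s]))
         for s in sim_te.cfg.samples}
peaks = classifier.call_peaks(preds["cond1_rep1"])
recall, precision = synthetic.match_peaks(peaks, sim_te.truth, condition="cond1")
print(f"{len(peaks)} peaks, recall={recall:.2f}, precision={precision:.2f}")

matrix = dynamics.ProbabilityMatrix.from_tracks(preds, sim_te.cfg.condition_of)
tests = dynamics.all_pair_tests(matrix, w0=0.5, seed=5)
codes = dynamics.assign_patterns(tests, matrix.bins_meta, pstar=0.05)
regions = dynamics.build_regions(tests, matrix.bins_meta, codes)
print(f"{len(regions)} differential regions")

region_probs = pd.DataFrame(
    [[preds[s].p_enhancer[r.chrom][r.peak_bin] for s in sim_te.cfg.samples]
     for r in regions], columns=sim_te.cfg.samples)
expr = targets.normalize_expression(sim_te.counts)
tss = sim_te.genes.rename(columns={"tss": "pos"})[["gene", "chrom", "pos"]]
units = targets.link_targets(regions, region_probs, expr, tss, sim_te.tads, r_min=0.9)
print(f"{len(units)} regulatory units")
```

Output:

```
86 peaks, recall=0.98, precision=0.97
50 differential regions
110 regulatory units
```

All 86 peaks are 1100 bp wide; recall/precision are measured against the
planted enhancer centers (±200 bp). The 50 differential regions recover
the 50 planted condition-specific enhancers, and the regulatory units
include each planted enhancer–gene pair (a region can correlate with
several co-regulated target genes in its TAD, hence > 50 units).

The same pipeline is available from the shell via
`enhancerkit simulate | train | predict | peaks | dynamics | targets`
(see `enhancerkit --help`); every command writes a JSON run manifest.

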