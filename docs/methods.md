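# Methods

This note documents the statistical models behind each `splicescreen` module,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that were genuinely open.

## Screen enrichment

**Model.** Each barcode's abundance is compared between a sorted
(phenotype-positive) pool and its paired unsorted pool. Counts are scaled to
one million reads per sample; the per-replicate statistic is
log2(sorted + pc) − log2(unsorted + pc); replicate values are averaged and
standardised across all barcodes to Z scores; hits are barcodes with Z
strictly above the cutoff (default 3).

**Choices.**
- *Pseudocount* pc = 1 on the reads-per-million scale. One read is the
  smallest observable unit, and zero counts otherwise make the log undefined.
  Exposed as a parameter.
- *SD flavour*: sample standard deviation (ddof = 1), exposed via `ddof`.
- *Replicate combination*: average the replicate log fold-changes, then
  standardise once (`mean_logfc_then_z`). The alternative —
  standardise each replicate and average the Z scores
  (`z_per_replicate_then_mean`) — is provided; its output has SD below 1 by
  construction. Only the default satisfies the exact mean-0/SD-1 invariant.
- Barcodes absent from a sample count as 0 rather than being dropped:
  library representation is part of the Z distribution.
- Several barcodes may tag one ORF; ORF-level scores aggregate by the
  maximum barcode Z (conservative; degenerate under 1:1 mapping).

**Known limitation.** The Z > 3 rule controls the per-barcode false-positive
*rate*, not the false-discovery *proportion* among calls. Over a
10,000-barcode library even a perfectly Gaussian null yields ≈ 13 calls
beyond 3 SD; when only ~20 barcodes are genuinely enriched, half of the
calls can be false even though all true hits are recovered. The skewed
(log-normal) library abundance worsens this: low-abundance barcodes have
noisier fold-changes, making the Z tail heavier than Gaussian. The
`run_all` report and the acceptance script state the realised sensitivity
and false-discovery fraction honestly rather than hiding this property of
the published scoring rule.

## PSI and differential splicing

**Model.** For a skipped-exon event with inclusion count IC, skipping count
SC and effective form lengths lI, lS,

ψ = (IC/lI) / (IC/lI + SC/lS),

undefined (missing, never imputed) when IC + SC = 0. Defaults lI = 2,
lS = 1: a junction-read counter sees two inclusion junctions and one
skipping junction per skipped-exon event. The effective lengths are
configurable per event because junction-counting tools differ by version.

Events are kept only if the summed IC + SC reaches 10 *within each group*
(inclusive boundary). "Within each group" is read as the sum over that
group's replicates; a stricter per-sample scope is available
(`filter_scope="sample"`).

Differential calling pools counts within each group and applies a two-sided
Fisher exact test to [[IC₁, SC₁], [IC₂, SC₂]], BH FDR across tested events,
and requires |Δψ| ≥ 0.05 with Δψ = ψ₂ − ψ₁ from group-pooled counts.
Direction is "exclusion" when Δψ < 0. This pooled-count test is a declared,
simpler substitute for the hierarchical likelihood models of dedicated
junction-count tools: it is exact under the within-group binomial sampling
the generator implements, but will be anticonservative on real data with
between-replicate overdispersion of ψ. Coordinates are 0-based half-open
throughout.

Set-level overlap between two lists of regulated events uses the one-sided
(enrichment) hypergeometric tail on the 2×2 membership table.

## Signature scoring

**Model.** Per sample, genes are ranked by expression descending with ties
broken by stable input gene order. With weights w(position i) = N − i + 1
raised to α (default 0.25),

ES = Σᵢ [P_in(i) − P_out(i)],

where P_in is the weighted cumulative fraction of set genes and P_out the
unweighted cumulative fraction of non-set genes. The ES is reported
un-normalised (no min–max rescaling across samples); depending only on ranks
makes it invariant under any monotone transform of a sample's values. The
combined EMT score is ES(UP) − ES(DOWN); overlapping genes are removed from
both sets with a warning (identical sets are an error). Set members missing
from the matrix are dropped with a warning.

Extreme-quantile classification labels the top floor(fraction·n) samples
mesenchymal and the bottom floor(fraction·n) epithelial (default fraction
0.2; a 1,212-sample cohort yields exactly 242 per tail), remainder
intermediate, ties resolved by stable sample order.

## Information Coefficient

**Model.** For paired vectors (x, y), standardise both axes, place a
product-Gaussian kernel with per-axis Silverman bandwidth
h = 1.06·n^(−1/5)·`bandwidth_mult` on each point, evaluate the joint density
on a 25×25 lattice spanning [min − 3h, max + 3h] per axis, normalise to a
probability mass function, and compute the plug-in mutual information
I = Σ p_ij ln(p_ij / (p_i p_j)). Then

IC = sign(ρ_Pearson) · √(1 − e^(−2I)),

so that for bivariate normal data (I = −½ ln(1 − ρ²)) the IC equals ρ — the
calibration anchor for the estimator.

**Smoothing-bias correction.** Kernel smoothing convolves each standardised
axis with independent N(0, h²) noise, which for Gaussian data attenuates
the effective correlation to ρ/(1 + h²) — at n = 1000 an underestimate of
≈ 0.06 at ρ = 0.9, well outside the intended calibration. The estimator
therefore rescales the dependence magnitude √(1 − e^(−2I)) by (1 + h²)
(capped at 1) before applying the sign. The correction is exact for the
Gaussian reference, conservative in direction for sub-Gaussian dependence,
and strictly monotone at fixed n — permutation p-values are unchanged by
it. It can be disabled (`bias_correction=False`).

**Noise floor.** The plug-in MI of finite samples is positive even under
independence (order 1/(n·h²)), and the square root amplifies it: at
n = 1000 a single null draw gives |IC| ≈ 0.15. The IC's *expectation* under
independence is ~0 only by sign symmetry. Single-draw IC magnitudes below
≈ 0.2 should therefore not be over-read; the permutation test, which
compares |IC| against its own permutation null, is the calibrated
significance statement.

**Permutation test.** y is permuted `n_perm` times (seeded);
p = (1 + #{|IC*| ≥ |IC_obs|}) / (n_perm + 1), two-sided, so the smallest
attainable p is 1/(n_perm + 1). Feature ranking uses pairwise-complete
samples per feature (minimum 8), per-feature child seeds spawned from one
master seed, and BH FDR across tested features. Extremely small published
p-values are matched in spirit only: this implementation reports the
add-one floor.

## Interval statistics

Peaks are 0-based half-open; (a, b) and (b, c) never overlap. The
significance filter keeps p ≤ 1e−5 AND fold ≥ 8, both inclusive. The
overlap statistic is the number of A intervals sharing ≥ 1 bp with any B
interval (each A counted once), computed by merging B per chromosome and
binary-searching each A interval. The permutation test redraws every B
start uniformly within its own chromosome, preserving chromosome and
length, and reports the one-sided add-one p. Shuffling ignores assembly
gaps and mappability — a documented simplification; with no constraints
stated for the published analysis, the uniform model is the neutral choice.
Strand is ignored by default (`stranded=True` available). Region assignment
uses the peak midpoint with priority CDS > 3'UTR > 5'UTR > noncoding exon >
intron > intergenic; the annotation rule behind published pie charts is
rarely stated, so the priority order is explicit and fixed here. Event
annotation searches the contiguous window from the upstream exon's end to
the downstream exon's start (alternative exon plus both flanking introns);
`flank_bp` optionally caps the intronic flanks.

## Synthetic data: what it emulates, what it does not

Each generator reproduces the *sampling structure* a stage assumes, with
planted truth for sensitivity/FDR accounting:

- **Screen**: log-normal (σ = 1) library abundances — pooled libraries are
  skewed — then multinomial counts at fixed depth per sample; sorted pools
  multiply hit abundances by the enrichment fold and renormalise. No
  cell-sorting bottleneck layer, PCR jackpotting, or barcode swapping: this
  is the smallest model that makes the Z-score stage's signal/noise tunable.
- **Junction counts**: per event/sample totals are negative binomial
  parameterised by (mean, dispersion) with variance m + d·m²; inclusion
  reads are binomial given the true ψ and effective lengths. True ψ is
  shared across replicates within a group, so there is no biological
  between-replicate ψ variability — real data would need a beta-binomial
  layer, and the pooled Fisher test would then be anticonservative.
- **Expression**: i.i.d. Gaussian baseline plus ±effect on the planted
  UP/DOWN genes in mesenchymal samples. No gene–gene correlation,
  batch structure, or library-size variation.
- **Bivariate pairs**: exact Gaussian with the requested ρ (constructed as
  y = ρx + √(1−ρ²)z), the reference distribution for IC calibration.
- **Peaks**: uniform placement weighted by chromosome length; a planted
  fraction of B peaks is anchored at A peaks (cycling so planted overlaps
  hit distinct A peaks), with optional jitter. Generated peak statistics
  fall in the significant range so the sets pass the default filter.
- **Bimodal PSI**: a two-component truncated-Gaussian mixture over cell
  lines, the pattern a bistable exon shows across epithelial vs.
  mesenchymal lines.

Consequently, passing tests demonstrate correctness of the statistics under
their stated sampling assumptions — not robustness to overdispersion,
correlation structure, or artefacts of real sequencing data.

## Default study-scale parameters

The test suite and acceptance script exercise the stages at these scales,
chosen to mirror the analysis settings the pipeline is built around while
remaining desk-sized: screen 10,000 barcodes / 20 planted hits / 8× /
depth 2×10⁶ / 2 replicates; splicing 500 events / 50 planted |Δψ| = 0.4 /
coverage mean 100, dispersion 0.3 / 3 replicates per group; classification
cohorts of 1,212 samples (fraction 0.2 → 242 per tail); IC calibration at
n = 1000 with ρ ∈ {0, 0.5, 0.9}; permutation-null calibration with 500
simulated datasets and 99 permutations each (n = 50 samples for the IC
test; 300 + 300 peaks on two 1-Mb chromosomes for the overlap test, sizes
at which the discrete overlap distribution is fine-grained enough for the
add-one p to be approximately uniform under the null).

## Numerical details and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  multi-part analyses spawn child seeds with `SeedSequence` (kept below
  2³¹). Identical seeds give bitwise-identical outputs, including the JSON
  report of `run_all` (sorted keys, no timestamps).
- Zero-coverage events give missing PSI, excluded from group means.
- Constant vectors are rejected wherever a correlation, Z score or IC is
  undefined; all-zero count columns are rejected before normalisation.
- Fisher tests run on integer-pooled counts via `scipy.stats`; BH via
  `statsmodels`. Both are cross-checked in the test suite against exhaustive
  log-factorial hypergeometric enumeration oracles.
- Ties: expression ranking and extreme classification break ties by stable
  input order, making every labelling deterministic.
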