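# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was open.

## Alignment post-processing

Input records are mate-pair alignments (SAM/BAM via pysam, or a
tabular dialect with 0-based coordinates). Post-processing keeps
records with mapping quality ≥ 20 — treated as the operational
definition of "uniquely mapped", with no secondary-alignment tag
inspection — and removes PCR duplicates by keeping one record per
(chromosome, start, insert length), the first in sort order for
determinism. The mapq filter applies per record, not per pair;
unpaired records are retained and contribute read coverage only.
Coordinates are 0-based half-open throughout; SAM/BAM 1-based input
is converted at the boundary.

## Depth-of-coverage caller

**Coverage definition.** A bin's count is (i) the number of reads
whose aligned span overlaps the bin plus (ii) the number of pairs
whose inner span — between the two mates' aligned spans, derived from
the leftmost mate's positive insert — overlaps it. A read counts in
every bin its span overlaps (not only its start bin), consistent with
the "covering" semantics of rule (ii); each pair's inner span is
counted once. With ~2 kb fragments rule (ii) dominates (~80% of each
bin's count), which both boosts depth and low-pass-filters it:
adjacent bins share most of their covering pairs.

**Per-bin test.** Each bin is tested with a two-sided Fisher exact
test on [[count_A, total_A − count_A], [count_B, total_B − count_B]],
the totals being chromosome-wide sums. This normalizes library-size
differences and matches the chromosome-at-a-time processing. The
implementation enumerates the two-sided hypergeometric tail
(probability-mass ≤ observed, the "minlike" convention) vectorized
over the bins of a chromosome with duplicate tables computed once;
it agrees with `scipy.stats.fisher_exact` to ~1e-7 relative and with
an exact rational enumeration oracle to 1e-9 relative (tested).
Benjamini–Hochberg correction is applied per chromosome
(configurable); p = 0 is floored at 1e-300 before taking −log10.

**Segmentation.** On the −log10(q) track, a seed is ≥ `window`
consecutive bins strictly above the seed threshold. Seeds are
extended outward over bins above the extension threshold. Two
robustness rules share one rationale — *a sub-threshold stretch
shorter than the caller's own minimum event (window bins) cannot be
confidently called normal, so it is not evidence of a call boundary*:
extension bridges interior dips shorter than `window` bins (the call
boundary always lands on an above-threshold bin, so trailing
sub-threshold bins are never absorbed), and extended candidates
separated by a sub-window gap are merged. Without these rules,
moderate-coverage data fragments single true events wherever one bin
of a long run dips below threshold (at mean bin coverage 100 a 2×
change yields per-bin z ≈ 5.6, so individual bins fail a
−log10 q > 3 cut a few percent of the time). If the bins of a merged
candidate disagree in the sign of the normalized per-bin ratio, the
candidate is split at the sign changes and sub-window pieces are
dropped, so every emitted call has one direction and is ≥
window × bin_size bp. Calls carry
log2((Σa/total_A)/(Σb/total_B)) over their bins, with a 0.5
pseudocount on the interval sums so homozygous events stay finite;
swapping the samples yields identical intervals with negated fold
changes (tested).

**Threshold profiles.** `deep`: seed −log10 q > 12, window 8,
extension > 10, sized for deeply sequenced mate-pair libraries where
per-bin q-values are enormous; minimum call 1,600 bp. `desk`: seed
> 4, extension > 3, same window, sized for the simulation scale used
throughout the tests (mean bin coverage 100 on 1-Mb chromosomes),
where −log10 q > 12 per bin is out of reach for 2× changes. Under
null simulations (no planted events, 20 seeds) the desk profile
produces ≤ 1 call total (tested): the 8-consecutive-bin seed
requirement makes false seeds astronomically unlikely after BH.

## Intensity HMM and all-pairs orchestration

Per-probe log-ratios between a test and a reference sample are
decoded with a 3-state HMM: state means −μ/0/+μ (default μ = 0.3 on
the log-ratio scale), shared emission SD σ (default: 1.4826 × MAD of
the track, floored at 0.05), stay probability ρ = 0.999 with the
remaining mass split between the other states, uniform initial
distribution, and no transitions across chromosome boundaries. These
are package defaults, not estimates — the upstream array tool this
stage stands in for does not publish its parameters. Viterbi ties
break toward "normal". Maximal non-normal runs become calls spanning
first to last probe + 1. All n(n−1)/2 unordered sample pairs are
decoded (a comparison and its reverse carry the same intervals with
directions swapped — tested; `ordered=True` runs both).

Calls from all comparisons are clustered by the transitive closure of
"reciprocal overlap ≥ 0.5" (configurable); each cluster becomes one
region spanning the members' maximal extent. Because merged extents
can newly reach the threshold, the closure is iterated to a fixpoint,
making unification idempotent (property-tested). Per-sample mean
intensities over the probes inside each region (half-open matching)
feed the association stage; probe-less regions are flagged and
dropped.

## Association stage

**Polygenic residualization.** For trait y and kinship K, the model
y ~ N(μ1, σ²(h²K + (1−h²)I)) is fitted by ML in the eigenbasis of K,
profiling μ and σ² and maximizing over h² on a [0, 0.99] grid (step
0.01) with bounded local refinement; a flat likelihood (K = I)
reports the boundary h² = 0 and centered y. Residuals are
ê = (1−ĥ²)V̂⁻¹(y − μ̂), the environmental component after subtracting
the BLUP of the polygenic effect, rescaled to sample variance
σ̂²(1−ĥ²). This is residualization in the GRAMMAR tradition; exact
equivalence with any specific external implementation's rescaling is
not claimed. Parameter recovery: mean ĥ² within ±0.15 of a true 0.5
over 50 cohorts (n = 200, litter-block kinship) — tested.

**Testing.** Each region's per-sample mean intensity x is tested
against the transformed trait with the Gaussian-GLM likelihood-ratio
statistic n·ln(RSS₀/RSS₁) = −n·ln(1−r²) against χ²(1). Constant x
yields a flagged degenerate result with p = 1; samples missing a
trait value are dropped per trait. Holm correction is applied per
trait across regions. The χ²(1) reference is the standard
large-sample choice and is what a GLM-plus-LRT analysis produces; at
n = 64 it is mildly anticonservative relative to the exact F(1, n−2)
null (analytically ≈ 0.0545 rejection at nominal 0.05). Measured
over 4,000 null region-trait tests the empirical type-I rate is
0.0555 — consistent with that analytic value and within the 95%
binomial band of 0.05 at the 1,000-test scale the acceptance check
uses. Power for a causal region explaining 15% of phenotypic
variance at n = 64 is ~0.85–0.88 at nominal α = 0.05.

## Overlap statistics

The two-proportion Z-test uses the pooled-variance form
z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)); for DE-gene enrichment,
group 1 is genes inside CNV regions and group 2 the remaining tested
genes. The ±1 status encoding emits one row per distinct
(CNV sign, expression sign) combination per gene, so contradictory
evidence duplicates a gene over both signs, and genes lacking either
status are excluded. Weighted kappa over the ordered categories
{−1, +1} uses quadratic disagreement weights by default — with two
categories linear and quadratic weighting coincide (asserted in
tests), so the choice is immaterial here — with the large-sample
null variance of Fleiss–Cohen–Everitt for the p-value, and Holm
correction across brain regions in `kappa_by_region`. The overlap
permutation test draws uniform subsets of the universe (both lists
by default; `fix_a` holds the first fixed) and reports
p = (#{overlap ≥ observed} + 1)/(replicates + 1); in `fix_a` mode it
agrees with the exact hypergeometric tail within Monte-Carlo error
(tested). The universe is a required input: the candidate-gene
analysis's published setup does not determine it, so results are
reported for the configured universe only.

## Synthetic data

**Mate-pair simulator.** Fragments arise from a Poisson process whose
rate is proportional to the local copy ratio *at the fragment
midpoint*; fragment length is Normal(2,000, 100) truncated positive,
reads are 60 bp, and the pair rate is solved from the target mean bin
coverage (default 100) via the expected bin hits per pair. A small
fraction of low-mapq records (2%) and verbatim PCR duplicates (1%)
exercise the post-processing. Midpoint modulation makes the coverage
footprint of an event symmetric: the ±1 kb smearing on each flank is
the genuine resolution loss of 2-kb-fragment insert coverage, not a
modeling bias. Not emulated: GC/mappability bias, sequencing error,
alternative orientations from inversion breakpoints, and
junction-spanning fragments of real structural variants — so passing
recovery tests demonstrate the caller's statistical behavior under
clean coverage physics, not robustness to alignment artifacts.

**Recovery study.** The fixed study design plants eight events
(2, 3, 4, 6, 8, 10, 14, 20 kb), alternating homozygous loss
(ratio 0) and 2× change and alternating the carrying sample, on a
1-Mb chromosome at coverage 100, scored by reciprocal overlap ≥ 0.5
with direction. Pooled over 20 simulated pairs, precision is
≈ 0.97–1.0 and recall ≈ 0.87–0.94 depending on the seed batch. The
2-kb event dominates the misses: with ~1.9 kb inner spans its fully
depleted/duplicated zone is at most a few bins wide, which is the
physical resolution floor, not an algorithmic defect.

**Cohort simulator.** 64 samples (configurable) with integer copy
numbers in {0..3} per region (diploid mode), probe intensity
slope × (copy − 2) + N(0, 0.2) with 12 probes per 50-kb region plus
background probes, litter-style block kinship (families of 4,
coefficient 0.5), and phenotype Σβ·copy + g + e with
g ~ N(0, h²K), e ~ N(0, 1−h²), default h² = 0.4; β for a causal
region is derived from the requested fraction of variance explained.
Not emulated: probe-specific affinities, batch effects, genotyping
artifacts.

**Evaluation conventions.** A planted event is recovered by a call
with matching direction and reciprocal overlap ≥ 0.5; with no calls,
precision is undefined and reported as 1 with a flag.

## Known limitations

- The DOC caller assumes per-bin counts are Fisher-exact comparable;
  insert coverage correlates adjacent bins, so per-chromosome BH
  q-values are approximate FDR statements, and boundary placement
  inherits the ±insert/2 smearing.
- Events shorter than ~the fragment length are detected at reduced
  rates regardless of thresholds (see recovery study).
- HMM emission/transition defaults are package choices; decoding
  accuracy claims (≥ 99% on ±1.0 blocks, σ = 0.2) hold for tracks
  matching those scales.
- The association LRT uses the asymptotic χ²(1) null (see above);
  at small n an exact-F variant would be very slightly more
  conservative.
- The intensity-correlation kinship helper is a coarse stand-in for
  a pedigree- or marker-derived matrix and is flagged as such.
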