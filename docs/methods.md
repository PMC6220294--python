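# Methods

This note documents the models implemented in `methdx`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Bisulfite read-out model

Sodium bisulfite converts unmethylated cytosine to uracil (sequenced as T)
while 5-methylcytosine remains C.  For a cytosine site with true methylation
level `m`, a basecall on a read of the matching conversion strand is C with
probability

    p_C = m + (1 − m)·ε_conv

where `ε_conv` is the per-cytosine non-conversion probability (default
0.004, i.e. a 99.6% conversion rate — typical of a well-run library).
Sequencing error then corrupts every base independently with probability
`ε_seq` (default 0.001), uniformly over the three alternative bases, giving
observed basecall probabilities

    p_obs(C) = (1 − ε_seq)·p_C + (ε_seq/3)·(1 − p_C)
    p_obs(T) = (1 − ε_seq)·(1 − p_C) + (ε_seq/3)·p_C

with the remaining `2ε_seq/3` landing in the "other" class.  The read
simulator applies this model per read; the pileup simulator draws the
marginal per-site counts directly (depth `d` from the configured depth
model, unconverted `x ~ Binomial(d, p_obs(C))`, converted from the
complementary T probability).  The two routes agree in distribution and the
test suite checks this with a two-sample Kolmogorov–Smirnov test on per-site
ratios at matched parameters.

Assumptions worth making explicit: the library is directional (every read
carries an `XG:Z:CT` or `XG:Z:GA` conversion-strand tag and contributes only
to sites on that strand); conversion failures are independent per basecall;
inputs are deduplicated upstream; reads are emitted single-end and stored in
forward-reference orientation with constant Q40 quality strings (no error
profile along the read, no adapter or fragment-size modelling, no
PBAT/amplicon chemistry).  Overlapping proper-pair mates are supported on
the calling side with first-of-pair precedence; the mate span is inferred
assuming equal read lengths.

## Methylation calling

`call_sites` re-implements methratio-style counting: per cytosine site (both
strands; minus-strand cytosines live at forward-reference G positions with
context read on the reverse complement) it tallies unconverted (C),
converted (T) and other basecalls, skipping bases below `min_base_quality`
(default 20) and reads below `min_mapping_quality` (default 20).  The
methylation ratio is `x/(x + t)`; "other" calls are excluded from the
denominator, matching the effective-CT convention of the standard callers.
Cytosines too close to a sequence end for a full two-base context default to
the CHH bucket (they cannot be CpG/CHG).  Internal coordinates are 0-based;
all emitted files are 1-based.  CpG strand merging (summing the two strand
mates of a dinucleotide, reported at the plus-strand C) is available but off
by default; the diagnostics record which mode produced their input and
refuse to intersect tables of mixed mode.

## Conversion diagnostics and the verdict

The central question — genuine methylation or conversion artifact? — is
decided on four quantities computed from two replicate call tables:

1. **Conversion rate**, pooled over basecalls, by default on non-CpG
   cytosines when present (non-CpG methylation is negligible in this
   regime, so the non-CpG rate is immune to contamination by true CpG
   methylation under the alternative).
2. **Replicate-shared partially unconverted CpG sites** and their chance
   expectation under independent artifacts,
   `Σ_sites [1−(1−ε₁)^d₁][1−(1−ε₂)^d₂]`, with `ε_r` estimated from the same
   replicate (sequencing error folded in).  A normal approximation to the
   Poisson-binomial gives a 99% envelope for the observed count.
3. **Placement partition** of the shared sites (placed chromosomes vs
   unplaced scaffolds), reported as a percentage rounded to one decimal.
4. **Coverage–proportion Spearman correlation** at the shared sites.  rho is
   the Pearson correlation of midranks (average ranks on ties); the
   two-sided p-value uses the t approximation for n > 10 and exact
   enumeration of all rank permutations for n ≤ 10 (chunked vectorized
   enumeration keeps n = 10, 3.6 M permutations, feasible).  Raw depth is
   correlated rather than log depth: ranks are invariant to monotone
   transforms, so the choice is cosmetic and log10 is kept only for plot
   output.

The verdict rule, with all thresholds configurable and echoed into the
report: *absent* requires conversion ≥ 0.995 in both replicates, rho ≤ −0.8
with p < 0.01, and a pooled shared-site unconverted fraction within 2× the
global non-conversion rate; *present* requires that fraction to be ≥ 10× the
global rate with the correlation signature not met; anything else is
*inconclusive* (including the degenerate cases of no shared sites or an
undefined correlation, which are noted in the evidence list).  The 2×/10×
defaults separate the pure-artifact signature from a 20% mosaic of 80%
methylated CpGs at six-fold depth with a wide margin; the gap between them
is deliberate, so that ambiguous data land in *inconclusive* rather than
being forced to a call.  p-values are reported to full precision in the
JSON report; "p < 0.001"-style truncation appears only in the human-readable
summary.

The shared-site unconverted fraction is reported both pooled over basecalls
and as a per-site mean.  These differ systematically: at six-fold depth a
per-site mean cannot fall below 1/6th even for pure artifacts, so the two
statistics are labelled and neither is silently preferred.  Depth and
proportions use informative (C+T) basecalls, the same denominator as the
methylation ratio.

## Synthetic study conditions

The preset WGBS experiment (`methdx.presets`) fixes the conditions used by
the end-to-end tests: a 2 Mb assembly (five 400 kb chromosomes, six 22 kb
moderately repetitive unplaced scaffolds, two 2 kb collapsed-satellite
scaffolds) at GC 0.35 and CpG o/e 1.0; Poisson six-fold informative depth on
chromosomes; negative-binomial depth on unplaced scaffolds — mean 60
(size 1.2) for the moderate-repeat stratum and mean 3500 (size 10) for the
satellite stratum; ε_conv = 0.004, ε_seq = 0.001.

The bimodal unplaced coverage structure is the interesting choice.
Assemblies collapse repeat families into far fewer copies than the genome
carries, so unplaced scaffolds attract proportionally more reads: tens-fold
for moderately repetitive sequence, thousands-fold where satellite arrays
megabases long collapse into kilobases of assembly.  Under the
per-basecall artifact model the expected unconverted proportion at sites
selected for `x ≥ 1` in both replicates is `ε/(1 − e^{−dε})` — steeply
falling while `dε ≲ 1` and flat once `dε ≫ 1`.  A coverage mix spanning that
transition smoothly (the moderate stratum) anchored by a very deep stratum
(which pins the pooled fraction near ε and extends the rank range) yields
the full artifact signature: several hundred shared sites, ~90% on unplaced
scaffolds, rho ≈ −0.92, and a pooled fraction ~1.1× the global
non-conversion rate.  Intermediate coverage (`dε` of a few) mainly adds rank
noise, which is why a single unimodal deep stratum reproduces the signature
only weakly.  None of this models real repeat biology — mapping ambiguity,
copy-number variation among repeat units, or per-molecule conversion
failure — so passing these tests demonstrates that the diagnostics recover
a known artifact structure, not that real libraries look exactly like this.

The genome generator draws from a first-order Markov chain whose stationary
base composition equals the requested GC exactly and whose C→G transition is
scaled to hit the requested CpG o/e in expectation (o/e = 1 reduces to iid
bases); compositions requiring P(G|C) > 1 or a negative stationary solution
are rejected.  Methylomes are null, uniform, or mosaic (a seeded fraction of
CpG dinucleotides at `m_high`, assigned symmetrically to both strands).

## CpG depletion and bimodality

Normalized CpG content is the per-sequence estimator `n_CpG·L/(n_C·n_G)`
(N bases excluded from counts and from L; genome-wide application defaults
to 1 kb non-overlapping windows).  The bimodality test fits 1- and
2-component Gaussian mixtures by EM (scikit-learn backend; tolerance 1e-8,
≤ 500 iterations, 10 restarts initialized from quantile pairs — three fixed
pairs plus seeded random pairs — and a variance floor of 1e-6, i.e.
sd ≥ 1e-3, to avoid likelihood singularities).  Significance comes from a
parametric bootstrap under the single-Gaussian fit (default 200 resamples,
4 restarts per refit, p with +1 smoothing), and a *bimodal* call additionally
requires the component means to be separated by more than 2 pooled standard
deviations, because the LRT alone over-rejects for heavy-tailed unimodal
data.  The procedure is deterministic given the seed.

## qPCR relative expression

Crossing points are QC'd per sample × gene: technical replicates are kept
only if their sample standard deviation (n−1 denominator; `|a−b|/√2` for the
usual pair) is strictly below 0.5 cycles; singletons pass with a warning.
Efficiencies come from OLS dilution-series slopes, `E = 10^(−1/slope)`, with
1 < E ≤ 2.2 accepted.  The expression ratio follows the Pfaffl convention
with `ΔCp = control − treatment`, so up-regulation in treatment gives a
ratio > 1; multiple reference genes combine by the geometric mean of their
normalization factors.  All three inferential quantities — the point ratio,
the randomization p and the bootstrap interval — are computed on the same
complete-block sample set (samples missing any involved gene after QC are
dropped), which makes "the interval contains the point estimate" an exact
invariant.

The randomization test permutes group labels jointly across genes per
biological sample (fixed reallocation) and is two-sided on |log ratio|; the
exact tail convention of the legacy tools is undocumented, so this choice is
recorded in the output.  All label assignments are enumerated exactly when
there are at most 20 000 of them, otherwise the p-value is estimated from
`n_iter` random reallocations with +1 smoothing.  The bootstrap interval is
a within-group percentile bootstrap (default 2000 resamples).  Bonferroni
adjustment is `min(1, k·p)` and refuses a family smaller than the number of
p-values.

The Cp simulator draws `Cp = base_cp(gene) − log_E(concentration)` with the
treatment target concentration multiplied by `true_ratio`; Gaussian noise of
`cp_noise_sd` cycles (default 0.15) is added per technical replicate, and an
optional `sample_sd` (default 0) adds biological scatter per sample × gene.
The calibration studies in the test suite use 6–10 samples per group with
`sample_sd` 0.25–0.3: there the exact randomization test rejects at the
nominal 5% level (±2%) and the 95% bootstrap interval covers the true ratio
in ≥ 90% of runs — percentile bootstraps undercover slightly at these group
sizes, which is expected behaviour, not a defect.

## Problem sizes and limitations

The simulation tests run on deliberately compact problems — a 2 Mb study
genome, 30–300 kb genomes for unit checks, ~2.4 M basecalls for
conversion-rate recovery, 200–1000 replicate experiments for the qPCR
calibration studies — sizes at which every statistical assertion has
comfortable Monte-Carlo margin.  Known limitations: no mapper integration
(alignments are taken as given, with trimming, mapping and deduplication
assumed upstream); no per-molecule or position-dependent error structure;
no modelling of mapping ambiguity in repeats; the verdict thresholds are
calibrated for the ~6x, ε_conv ≈ 0.004 regime and should be revisited for
very deep or very dirty libraries; and the bimodality test assumes Gaussian
components on the o/e scale.
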