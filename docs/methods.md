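# Methods

## Model and scope

`selmr` implements two-sample Mendelian randomization entirely at the
summary-statistics level.  For instrument j, the variant–exposure effect γⱼ
and variant–outcome effect Γⱼ are estimated in non-overlapping studies; the
causal model is Γⱼ = θ·γⱼ + αⱼ, where θ is the causal effect of the exposure
on the outcome (log-odds per exposure unit) and αⱼ is a variant-specific
direct (horizontally pleiotropic) effect.  IVW assumes αⱼ = 0 (or balanced
with mean zero); MR-Egger estimates the mean of αⱼ as a regression
intercept and needs the InSIDE condition (αⱼ uncorrelated with γⱼ); the
weighted median tolerates up to half the total weight being invalid.
Genotype-level computation, proxy-variant lookup in reference panels, and
web-service trait queries are out of scope: the confounder screen runs
against a local association table.

## Data preparation

**Reader.** Delimited tables with configurable column names; a record needs
beta+SE or a Z-score.  Rows violating record invariants (allele codes,
frequency or p-value ranges, beta/SE/Z consistency) are rejected with a
logged per-line diagnostic; unparseable numerics and duplicate rsids raise,
since they usually signal a malformed file rather than a bad row.

**Harmonization.** The outcome record is aligned to the exposure's effect
allele: a textual swap negates the outcome beta and complements its
frequency; non-palindromic strand flips are resolved by complementing
alleles before the match/swap test.  Palindromic pairs (A/T, C/G) cannot be
resolved textually; the default policy keeps them only when the allele
frequency is informative (minor-allele frequency ≤ 0.42, the community
convention) and then aligns by frequency.  None of the four packaged
instruments is palindromic, so the policy does not affect the shipped
analysis.

**LD pruning.** Greedy selection in ascending p-value order (ties: larger
|Z| first, then rsid) retaining a variant iff its r² with every retained
variant is below the threshold (default 0.05).  Greedy-by-significance was
chosen because it is the standard clumping heuristic and is deterministic
under the stated tie-breaks, making the output independent of input row
order.  The packaged LD matrix encodes the two published within-locus r²
values (0.04 and 0.03) with zero cross-locus LD.

**Confounder screen.** A variant fails if the local association table links
it to a known outcome risk factor at p < 0.05/k, with k = 7 risk factors by
default (threshold 7.14 × 10⁻³).  The packaged table is empty: no such
association was found for these instruments.

## Z-score conversion and instrument strength

β = Z/√(N·eaf·(1−eaf)) and se = β/Z (equivalently 1/√(N·eaf·(1−eaf)), used
directly so Z = 0 is well-defined).  N defaults to 9,639, the sum of the
circulating (5,477) and toenail (4,162) selenium GWAS sizes; this single
effective N reproduces every published converted effect and F statistic at
the printed precision.  Two conventions exist for the variance term; the
default omits the diploid factor 2 (`variance_form="pq"`) because the
2·eaf·(1−eaf) form does not reproduce the published conversions (it gives
0.21 instead of 0.29 for the strongest instrument).  Both are available.

The F statistic is exposed in two modes because the published
instrument-strength table equals 1/se = √(N·eaf·(1−eaf)), not the
conventional single-variant Wald F = Z²; `mode="paper"` (default) matches
the tabulated values, `mode="conventional"` gives Z².  Per-variant
R² = Z²/(N−2+Z²) — the Wald-F identity r²/(1−r²)·(N−2) = Z² inverted — was
selected over the cruder Z²/N because its sum over the four instruments
lands exactly on the published 2.9%; the two differ only in the fourth
decimal here.

## Estimators

**Wald ratio.** θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE se(Γ̂ⱼ)/|γ̂ⱼ| by default (the
convention that makes IVW identical to the no-intercept weighted
regression); the second-order SE adding the exposure-uncertainty term is
selectable.

**IVW.** Fixed-effect pooling with weights 1/se(θ̂ⱼ)²; `multiplicative_re`
(default) keeps the same point estimate and multiplies the SE by
max(1, √(Q/(L−1))) — mainstream two-sample MR practice; `additive_dl`
re-weights with the DerSimonian–Laird τ².  All three agree on the shipped
fixture at the printed precision.

**MR-Egger.** Instruments are internally oriented so every exposure effect
is positive (never mutating caller data), then outcome effects are
regressed on exposure effects with weights 1/se_out² and a free intercept.
SEs carry a multiplicative overdispersion factor floored at 1; p-values use
a t distribution with L−2 df by default (normal selectable).  Requires ≥ 3
instruments and non-constant exposure effects.

**Weighted median.** Wald ratios sorted; cumulative weight fractions
pⱼ = (Σₖ≤ⱼwₖ − wⱼ/2)/Σw; the estimate interpolates the ratio at p = 0.5.
The SE is a parametric bootstrap: each replicate redraws every ratio from
Normal(θ̂ⱼ, seⱼ) and recomputes the median with the original weights
(n_boot = 1000 by default, mandatory seed).  A lower-level
`weighted_median_estimate` exposes the interpolation alone.

All intervals use the 1.96 normal multiplier so CIs are symmetric and
comparable across methods; the odds-ratio view is exp of the log-odds
fields.

## Diagnostics

Cochran's Q = Σwⱼ(θ̂ⱼ − θ̂)² around the fixed-effect estimate with an exact
chi-square upper-tail p on L−1 df (no continuity correction).  The
directional-pleiotropy flag is raised when the exponentiated Egger
intercept's CI excludes 1.  I²GX = max(0, (Q_GX − (L−1))/Q_GX), where Q_GX
is the weighted dispersion of the (positively oriented) exposure effects;
weighting defaults to the MR-Egger regression weights 1/se_out², which on
the packaged fixture gives ≈ 0.93 versus ≈ 0.89 for 1/se_exp² weighting and
better matches the published 92% (computed upstream from unrounded inputs);
the mode is configurable and recorded in the result.  Negative raw I²GX is
truncated to 0.

A note on reproduction precision: the published Q (7.22), I²GX (92%) and
per-variant Wald ratios were computed from unrounded internal summary
statistics that were never printed.  From the printed 2-dp table the same
code yields Q ≈ 8.2 and I²GX ≈ 0.93, and −0.04/0.16 = −0.25 rather than the
printed −0.22.  The estimator-level odds ratios (0.99 IVW, 0.98 weighted
median) are robust to this rounding; tests therefore assert the headline
ORs exactly at 2 dp and the rounding-limited diagnostics as agreement
bands, never as equalities.

## Synthetic data generator

`simulate_dataset` draws, per variant: eaf ~ U(0.10, 0.90); γⱼ ~ U(0.1,
0.4) — the range the four real instruments span; αⱼ ~ Normal(mean, sd),
optionally correlated with γⱼ (αⱼ += ρ·γⱼ) to break InSIDE; standard errors
1/√(N·eaf·(1−eaf)) with N_exp = 9,639 and N_out = 121,885 mirroring the two
real studies; observed effects are the truths plus Gaussian noise.  Alleles
are drawn from the non-palindromic pairs so harmonization is lossless.  The
default panel is 50 instruments, the size used in the calibration
experiments.  Outcome effects are simulated directly on the linear
summary-statistics scale rather than via individual-level case-control
liability — the estimators consume only summary statistics, so this is the
surface on which their assumptions can be tested.  Consequences: the
generator does not model LD between instruments, winner's-curse selection
of instruments, allele-frequency mismatch between studies, or the
logistic-scale non-collapsibility of real case-control effects; passing
calibration tests demonstrate estimator correctness under the stated model,
not robustness to those real-data features.

`recovery_experiment` runs replicate r at seed `seed + r` (per-replicate
increment, never shared generator state), so experiments are reproducible
and replicates independent.  It reports mean bias, empirical SD, rejection
rate of θ = 0 at α, and 95%-CI coverage per method.  The shipped experiment
sizes (500 replicates, 50 instruments) give a binomial 99% band of
[0.03, 0.08] around a nominal 5% type-I error.

## Pipeline

`run_analysis` executes read → screen → prune → convert → harmonize →
estimate → diagnose from one YAML/dict config (all defaults printable via
`selmr config-schema`); relative file paths resolve against the config
file's directory.  Variants missing from the outcome study are dropped with
a warning (no proxy search, by design); with fewer than three harmonized
instruments MR-Egger and the weighted median are skipped with a warning
while IVW still runs; zero instruments is a hard error.  Reports serialize
losslessly to JSON (display rounding is applied only in the TSV/text
renderings), and the provenance block carries the config echo, seed,
package version, timestamp and all warnings.

## Known limitations

- Single-N Z-score conversion: per-variant sample sizes are supported but
  the shipped analysis uses one effective N for all instruments.
- No correlated-instrument (generalized) IVW; the LD pruner is expected to
  have removed residual correlation.
- No MR-PRESSO, mode-based, multivariable or leave-one-out analyses.
- Bi-allelic SNPs only; indels and multi-allelic records are rejected by
  the reader's allele invariant.
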