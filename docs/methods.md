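# Methods

## Scope and model

`mrmediate` implements the two-sample, two-step mediated MR design: candidate
exposures are screened against an outcome, survivors are checked for reverse
causation, and an exposure/mediator/outcome triple is decomposed by the
product of coefficients. All estimators consume summary statistics only
(per-SNP beta, SE, p, alleles, allele frequency, sample size); binary-outcome
effects are treated as log-odds, and odds ratios are exp(β) with 95% intervals
exp(β ± 1.959964·σ).

## Harmonization conventions

Exposure and outcome panels are intersected on rsid and aligned to the
exposure's effect allele. Swapped alleles negate the outcome beta and
complement its frequency. Palindromic variants (A/T, C/G) are dropped by
default — strand is unknowable from summary data; under `infer_by_eaf` they
are kept only when both panels report frequencies on the same side of 0.5
(then treated as already aligned), otherwise removed. Alleles are compared
case-insensitively; indels pass through as literal strings. These rules are a
declared convention of this package, not a reconstruction of any specific
upstream tool.

## Instrument selection

Strict inequalities on both thresholds: p < 1e−5 and F > 10 (boundary values
excluded). Clumping is greedy by ascending p (ties by chromosome, position):
an index SNP discards candidates only when they are **both** within the
window (default 10,000 kb) **and** above the r² threshold (default 0.001);
SNPs missing from the LD reference are kept and logged as unlinked. The
default F statistic is the Wald form (β/σ)², which needs no allele frequency
or sample size; the R²-based form F = (n−2)r²/(1−r²) with r² = 2·eaf·(1−eaf)·β²
is available when both are present.

## Estimators

- **IVW** defaults to multiplicative random effects: σ<sub>fixed</sub> ·
  √max(Q/(J−1), 1). The floor means random effects can only widen, never
  narrow, the fixed-effect interval. A single SNP degrades to the Wald ratio
  (first-order SE σ_Y/|β_X|; a second-order option adds the exposure term).
- **MR-Egger** pre-orients every SNP to β_X ≥ 0 (the estimator is not
  invariant to joint sign flips; this is the conventional resolution). Slope
  and intercept p-values use t with J−2 df. The slope SE carries the same
  multiplicative floor √max(RSS/(J−2), 1); the intercept SE deliberately uses
  the *unfloored* regression scale so that, under the no-pleiotropy null, the
  intercept test statistic is exactly t-distributed and its p-values uniform —
  a floored intercept SE would make the pleiotropy test conservative and
  miscalibrated.
- **Weighted median** interpolates the weighted empirical quantile function of
  the ratios at 0.5 with cumulative standardized weights (S_j − w_j/2)/S_J.
- **Modes** maximize a normal-kernel density over the ratio support on a
  256-point grid; bandwidth φ·0.9·min(sd, 1.4826·mad)·J^(−1/5) with φ = 1 by
  default. If more than half the ratios tie, the mad is zero and the sd is
  used; if all ratios coincide, that value is returned.
- Median and mode SEs come from a parametric bootstrap (default 1,000
  replicates) perturbing both panels' betas by their SEs; the seed is
  mandatory. IVW/median/mode p-values are two-sided normal.

## Diagnostics

Cochran's Q uses the residual form Σ(β_Yj − β̂·β_Xj)²/σ_Yj², algebraically
equal to the ratio-scale Q and defined even when a β_X is zero; p is the
χ²(J−1) upper tail. MR-PRESSO computes the observed RSS against leave-one-out
IVW predictions, simulates outcome betas from the no-pleiotropy model
(recomputing the leave-one-out predictions within each simulated dataset), and
uses plus-one Monte-Carlo p-values, so the smallest reportable global p is
1/(n_sim+1); per-SNP outlier p-values are Bonferroni-adjusted by J. The
distortion test is intentionally out of scope.

## Screening rules

Forward screening passes a trait when the IVW p is strictly below
alpha_screen (default 0.05); optional Bonferroni or Benjamini-Hochberg
adjustment is applied across traits before the decision (default: none). The
reverse check passes when the reverse-direction IVW p is ≥ alpha_reverse —
the boundary p = 0.05 counts as non-significant and passes. Per-trait
failures (no surviving instruments, empty harmonization) are recorded with a
reason and never abort a batch.

## Mediation

indirect = a·b; direct = total − indirect (exact); proportion mediated =
indirect/total, reported without truncation to [0, 1] and flagged when
indirect and total disagree in sign (inconsistent mediation); it is undefined
(NaN) when the total is zero. The default interval for the product is the
first-order delta method √(b²σ_a² + a²σ_b²); a Monte-Carlo interval (10⁵
seeded draws, percentile 2.5/97.5) is available. Note the first-order
variance omits the σ_a²σ_b² cross term, so it is accurate only when both
stage z-scores are large; the Monte-Carlo option is preferable for weak
stages. The three stage results must come from the same estimator (default
IVW); mixing estimators across stages is rejected.

## Synthetic generator

The generator emulates three non-overlapping GWAS at the summary level: true
marginal effects plus normal noise with σ = 1/√(2·maf·(1−maf)·n), maf ~
U(0.05, 0.5), p-values from the Wald z. Defaults — n = 50,000 per panel, 50
exposure instruments with per-SNP effects γ ~ N(0, 0.08²) — give typical
instrument F of 30–200: selectable at p < 1e−5 yet weak enough that a-scaled
effects on the mediator rarely re-qualify as mediator instruments. The SNP
roles are explicit: exposure instruments (γ), mediator-specific instruments
(δ, same prior), optional outcome-specific instruments (η, used to test
reverse-direction screening via a configurable reverse effect), and null
SNPs. True marginals are x = γ + d·η, m = a·x + δ, y = (c′ + a·b)γ + b·δ + η
+ α, so c_total = c′ + a·b holds exactly in the truth record.

Mediator-specific instruments exist because b is not identifiable from
exposure instruments alone: any SNP acting on the mediator only through the
exposure has Wald ratio b + c′/a for the mediator→outcome stage whenever the
direct effect c′ is nonzero. For the same reason the chain pipeline, by
default, excludes SNPs that qualify as exposure instruments from stage-2
selection (`exclude_exposure_instruments`); disabling it reproduces the
contaminated behaviour.

Directional pleiotropy is planted relative to the exposure-raising allele
(α_j = magnitude · sign(γ_j) in natural coding): a constant shift in an
arbitrary allele coding would cancel after the β_X ≥ 0 orientation and be
indistinguishable from balanced pleiotropy. Balanced pleiotropy draws α ~
N(0, magnitude²) on a random fraction of instruments.

What the generator does **not** model: realistic genome-wide MAF/LD spectra
(LD blocks are constant-r² and affect clumping, not the sampling correlation
of estimates), sample overlap between panels, case-control ascertainment, or
non-normal effect-size distributions. Passing tests therefore demonstrate the
statistical machinery under the stated sampling model, not performance on any
particular real cohort.

## Numerical choices

p-values are floored at 1e−300 to respect the (0, 1] invariant; LD matrices
must be symmetric within 1e−8 and are then symmetrized exactly with unit
diagonal; clump ties on p break by (chromosome, position); the master seed
fans out to per-component seeds via a 4-byte BLAKE2s hash of
"seed:component", so adding a component never shifts another component's
stream, and all derived seeds stay below 2³¹.

## Problem sizes

The default test suite and the acceptance script use simulation sizes chosen
as a compromise between Monte-Carlo error and desk-scale runtime: 100
replicates for the chain signature (60 in the script), 1,000–2,000 for
calibration rates, 200–500 for robustness rates, with bootstrap sizes of
50–500 where only point estimates or rates are compared. Rates reported at
these sizes carry binomial MC error of roughly 1–3 percentage points.

## Known limitations

No multivariable MR, Steiger filtering, correlated-instrument IVW, MR-RAPS or
contamination-mixture estimators; no genotype-level input (LD is always a
matrix input); no liftover; the MR-PRESSO distortion test is omitted. The
reverse-causation testbed uses a one-directional approximation (no feedback
loop). Proportion-mediated uncertainty is not propagated (point estimate
only), matching common reporting practice.
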