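# Methods

`pqtlmr` implements a two-sample Mendelian randomization (MR) workflow for
protein-quantitative-trait-locus (pQTL) instruments and binary disease
outcomes, together with the cross-cohort replication machinery around it.
This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data generator does
and does not emulate.

## Model and assumptions

For each instrument *i*, two GWASs supply the per-allele association with
the exposure, β<sub>X,i</sub> (SE<sub>X,i</sub>), and with the outcome,
β<sub>Y,i</sub> (SE<sub>Y,i</sub>), expressed on a shared effect allele.
Under the instrumental-variable assumptions (relevance, independence from
confounders, no direct outcome path), each Wald ratio
β<sub>Y,i</sub>/β<sub>X,i</sub> estimates the same causal effect β.  The
primary estimator is the fixed-effects inverse-variance-weighted (IVW)
combination of Wald ratios:

    β̂ = Σ w_i β̂_i / Σ w_i ,   SE = (Σ w_i)^(-1/2) ,   w_i = 1/SE_i²

where β̂<sub>i</sub> is the ratio and SE<sub>i</sub> its first-order delta
SE, SE<sub>Y,i</sub>/|β<sub>X,i</sub>|.  This is algebraically identical to
weighted regression of β<sub>Y</sub> on β<sub>X</sub> through the origin
(tested as such).  A second-order delta SE,
√(SE<sub>Y</sub>²/β<sub>X</sub>² + β<sub>Y</sub>²SE<sub>X</sub>²/β<sub>X</sub>⁴),
is available behind a flag; it matters when the exposure GWAS (thousands of
samples) is much noisier than a biobank-scale outcome GWAS, and the
coverage experiment below uses it for that reason.  With one instrument the
IVW reduces exactly to the Wald ratio, and per convention a single-IV
analysis is still reported under the IVW label.

Exposure effects are in phenotypic SD units (rank-inverse-normalised
protein levels), outcome effects are log odds ratios, so β is the log-OR
of the outcome per SD increase in the genetically predicted exposure.

## Instrument selection

Candidates must (i) be present in both exposure GWASs, (ii) have MAF ≥ 0.05
in both, (iii) reach p < 5×10⁻⁸ in both with a concordant effect direction
*after aligning effect alleles between the two tables* — the cross-GWAS
replication requirement.  Judging concordance after alignment is the only
reading that is invariant to each file's arbitrary choice of stored allele.
Greedy LD clumping then ranks candidates by p-value in a caller-chosen
exposure GWAS (an explicit argument, since ranking in the smaller discovery
GWAS is a legitimate design) and retains one index variant per region
(defaults: r² > 0.001 within 10,000 kb — the conventional strict MR
parameter set).  Ties in p are broken lexicographically by variant ID so the
output is independent of input order.  The clumping result carries a full
per-variant disposition log (`kept` / `removed-by-clump(index)` /
`failed-filter(reason)`).

Instruments missing from an outcome GWAS are replaced by the
highest-r² variant present there, if r² ≥ 0.8 (configurable; the floor is a
package default — published proxies are typically r² ≥ 0.97).  The LD
matrix carries a per-pair phase sign saying whether the two variants'
reference effect alleles are positively or negatively correlated; the proxy
mapping first aligns the outcome record onto the LD reference alleles, then
applies the phase, then relabels with the target's alleles, so a
negative-phase proxy flips the outcome beta exactly once.

Harmonization aligns outcome records onto the exposure effect allele:
matching labels copy, swapped labels negate the beta and reflect the EAF,
and complemented labels are treated as strand representation differences
for non-palindromic variants.  Palindromic (A/T, C/G) variants are
orientation-ambiguous; they are kept only when both allele frequencies are
informative (MAF < 0.42, configurable, or the variant is dropped), using
frequency concordance to infer the strand.  An "always drop" policy is
available.

## Estimator battery and diagnostics

* **MR-Egger** — weighted least squares of β<sub>Y</sub> on β<sub>X</sub>
  with intercept, weights 1/SE<sub>Y</sub>², after orienting all
  β<sub>X</sub> > 0.  SEs are multiplied by max(1, residual SD) so
  underdispersed fits are not anti-conservative; inference uses t with k−2
  df.  The intercept estimates directional pleiotropy under the InSIDE
  assumption; the slope is the pleiotropy-adjusted causal estimate.
  Needs k ≥ 3 (the strict two-instrument analysis cannot run it, which is
  exactly why a relaxed suggestive-significance instrument set exists).
* **Weighted median** — the 50th weighted percentile of the ratio estimates
  with linear midpoint interpolation on cumulative standardised weights;
  consistent when ≥ 50% of the weight comes from valid instruments.  SE by
  parametric bootstrap (default 1,000 replicates, explicit seed).
* **Simple/weighted mode** — the mode of a Gaussian kernel density over the
  ratios; bandwidth is φ × the normal-reference rule
  0.9·min(sd, IQR/1.349)·k^(−1/5) with φ = 1 by default, weighted variant
  weights the density by inverse ratio variance; density maximised on a
  2,048-point grid spanning the ratios ± 3 bandwidths.  Degenerate spread
  falls back to the weighted modal value.  SE by parametric bootstrap.
* **RAPS-style profile likelihood** — models β<sub>X,i</sub> ~ N(γ<sub>i</sub>,
  SE<sub>X,i</sub>²), β<sub>Y,i</sub> ~ N(βγ<sub>i</sub>, SE<sub>Y,i</sub>²),
  profiles out γ<sub>i</sub>, and minimises
  ½Σ(β<sub>Y</sub>−ββ<sub>X</sub>)²/(SE<sub>Y</sub>²+β²SE<sub>X</sub>²)
  over β (bounded scalar search, tolerance 1e-10).  No log-variance term
  survives the profiling — that is what removes the weak-instrument
  attenuation that biases the IVW ratio.  The optional overdispersion
  variance τ² ≥ 0 is fitted by moment-matching the standardised residuals,
  alternating with the β step to joint convergence.  SE from the observed
  information (central finite difference at the optimum).  Accepts k ≥ 1
  (k ≥ 3 with overdispersion); in the strong single-instrument limit it
  reduces to the Wald ratio.
* **Cochran's Q** — Σw<sub>i</sub>(β̂<sub>i</sub> − β̂<sub>IVW</sub>)²
  against χ²(k−1), both across instruments and across cohorts.  Q is
  scale-dependent through the weights (only permutation invariance is a
  meaningful invariant).
* **Steiger directionality** — per-trait r² approximated from the observed
  Z statistics as Z²/(Z²+N−2), summed over instruments; the direction is
  correct when the instruments explain more variance in the exposure.  The
  p-value compares Fisher-transformed correlations with a normal reference.
  For binary outcomes this is an observed-scale approximation.
* **Global pleiotropy test** — a simulation-based outlier test: the
  observed residual sum of squares uses leave-one-out IVW predictions of
  each instrument's outcome effect; the null distribution is rebuilt by
  redrawing (β<sub>X</sub>, β<sub>Y</sub>) from the no-pleiotropy model
  (default 1,000 draws, seeded); the empirical upper-tail p has lower bound
  1/n_sim.  Only the global test is provided, no outlier-removal or
  distortion stage.

## Scale conversion for linear-mixed-model outcome GWASs

A biobank GWAS that analyses a 0/1 disease indicator with a linear mixed
model reports effects on the wrong scale for MR against log-OR cohorts.
With genotype variance varG = 2p(1−p) (Hardy-Weinberg) and cohort
prevalence pr = n_cases/n_total, the logistic-scale SE is approximated by
1/√(varG·N·pr·(1−pr)); Z is recovered from the two-sided p-value with the
sign of the linear beta (an exact Z column takes precedence, and p-values
that underflow double precision require one), and β_logit = Z·SE_logit.
The conversion preserves the Z statistic and p-value exactly and, for small
effects (|log OR| ≲ 0.2), recovers the generating log-OR within Monte-Carlo
error in genotype-level simulation (the package ships a small
individual-level generator used for exactly this check).  Note the identity
direction: Z = β/SE definitionally, so the effect is reconstructed as
β = Z·SE from the reported p-value and the SE formula above.

## Meta-analysis, comparison tests, and the replication verdict

Per-cohort estimates are pooled by fixed-effects IVW with a normal-theory
p-value; no random-effects option is provided (the workflow is
fixed-effects throughout).  Two estimates are compared with
z = (β_a−β_b)/√(SE_a²+SE_b²) against a normal reference; no degrees of
freedom are derivable from summary data, so the t-reference variant exists
only with a caller-supplied df and is off by default.  The pre-registered
verdict has four criteria against a prior sign from the discovery study:
(1a) sign of the primary (largest) cohort's estimate, (1b) its p <
1.1×10⁻⁵, (2a) sign of the meta-analysis of the remaining cohorts, (2b)
its p < 0.025 (0.05 Bonferroni-corrected for two traits).  All inequalities
are strict — a p exactly at a threshold fails — and a zero beta raises
rather than guessing a sign.

## Synthetic-data generator

The generator works at the summary level: estimated effects are the truth
plus Gaussian noise at the analytic SE — 1/√(2p(1−p)N) for the
rank-normalised exposure, 1/√(2p(1−p)·N·pr(1−pr)) on the logistic scale for
binary outcomes.  Defaults mirror the replication design: exposure cohorts
of 1,000 and 3,301; one pQTL at 40% variance explained plus a weaker locus
at 5%; outcome cohorts of 452,264 / 128,698 / 48,429 with prevalences
2.7% / 8.6% / 12.0% (the largest emitted on the linear-mixed-model scale,
i.e. β and SE multiplied by pr(1−pr) with the same Z, to exercise the
conversion); true causal log-OR 0.07 per SD.  LD is block-diagonal with a
common within-block correlation; tag variants inherit attenuated marginal
effects (r times the lead effect, with the stored-allele phase sign), block
positions are spaced to exercise the clumping window, and stored alleles
are randomly flipped in all tables except the first exposure (probability
0.2) to exercise harmonization.  Directional pleiotropy adds per-locus
direct outcome effects α ~ N(0.05, 0.02) — a modest shift comparable to
the weaker instruments' outcome effects; the balanced variant centres α at
zero.

Deliberate simplifications: estimation noise is independent across
variants (real summary statistics are correlated within LD blocks), there
is no imputation noise, no haplotype structure beyond compound-symmetric
blocks, and no winner's-curse in the reported exposure effects.  Passing
tests therefore demonstrate the correctness and calibration of the
estimators under the assumed sampling model, not robustness to those
real-data features.  A separate genotype-level generator (binomial
genotypes, logistic disease model, OLS analysis of the 0/1 indicator)
validates the scale conversion where the summary-level shortcut would be
circular.

## Verification experiment sizes

The test suite and `scripts/acceptance.py` use problem sizes chosen to
keep Monte-Carlo error well below the quantities being checked: IVW
CI coverage over 1,000 summary-level replicates at k = 10 with strong
instruments (5–9.5% variance explained each, F ≈ 165–495) and the
second-order delta SE (first-order SEs are anti-conservative here because
the neglected exposure-noise term is ~14% of the ratio variance at
β = 0.2 with a biobank-sized outcome); pleiotropy-test calibration over
100 seeded datasets of 1,000 null simulations each; Egger detection power
over 100 replicates at k = 20 with instrument strengths spanning 0.2–5%
variance explained (the wide spread anchors the intercept); conversion
validation over 40 genotype-level replicates at n = 50,000; end-to-end
pipeline behaviour over 12–60 seeded scenarios.  With the default
two-instrument scenario the pre-registered verdict passes in roughly
70–80% of replicates at true β = 0.07 — the binding constraint is the
primary cohort's 1.1×10⁻⁵ threshold (expected |Z| ≈ 5.1) — and passed in
0/60 null scenarios.

## Known limitations

* The Steiger r² approximation and the conversion formula are
  observed-scale approximations for binary traits; both degrade for large
  effects or extreme prevalence.
* The weighted-median/mode bootstrap resamples summary statistics
  independently per instrument, ignoring any residual LD between retained
  instruments (they are clumped to near-independence by construction).
* The global pleiotropy test simulates its null conditional on
  leave-one-out estimates, so its p-value is approximate for small k; it
  is restricted to k ≥ 4.
* LD phase signs are taken relative to the reference allele convention of
  the panel that produced the LD matrix; proxy mapping is only guaranteed
  correct when reference records from that namespace (e.g. the exposure
  GWAS) are available to anchor the alignment.
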