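# Methods

`mrmediate` implements a two-sample Mendelian randomization (MR) mediation
chain for GWAS summary statistics: an exposure X (e.g. body mass index), one
or more candidate mediators M (e.g. IGF1, smoking), and a binary outcome Y
(e.g. colorectal cancer, on the log-odds scale). This note documents the
models, the defaults and why, the synthetic-data generator, and the design
choices made where the design was genuinely open.

## Estimation model

Each variant j supplies an exposure association estimate b_xj (SE s_xj) and an
outcome estimate b_yj (SE s_yj), aligned to a common effect allele.

**Instrument selection.** Variants with exposure p < 5e-8 are retained and
greedily pruned on LD: visiting variants by ascending p (ties broken by
variant id so results are order-independent), a variant is kept iff its r²
with every kept variant is < 0.001. Both thresholds are exposed; no distance
window is used because LD enters only through the supplied r² matrix.

**Harmonization.** Alleles are aligned to the first exposure by direct match,
swap (outcome beta negated, EAF complemented), or strand complement.
Palindromic variants (A/T, C/G) are resolved by allele frequency and dropped
when any EAF is missing or within ±0.08 of 0.5 — the conservative standard
when the originating strand is unknown. Non-palindromic variants with missing
EAF are retained (EAF is only needed for palindrome resolution). All drops
carry machine-readable reasons.

**Univariable estimators.**

- *IVW* (primary): zero-intercept weighted least squares of b_y on b_x with
  weights 1/s_y², equivalently the precision-weighted average of per-variant
  Wald ratios. "Random effects" is implemented multiplicatively: the
  fixed-effect SE is inflated by max(1, sqrt(Q/(k−1))) with Q the Cochran
  heterogeneity statistic. The additive random-effects variant is not
  offered; the multiplicative form is the usual default in summary-data MR.
- *MR-Egger*: the same regression with a free intercept after orienting all
  (b_x, b_y) pairs so b_x ≥ 0; the intercept estimates directional
  pleiotropy, and its p-value is the standard "Egger intercept" diagnostic
  (gate at p > 0.1 in the pipeline).
- *Weighted median*: the per-variant ratio at which the normalized cumulative
  inverse-variance weight crosses 0.5, linearly interpolated between adjacent
  order statistics; SE by a seeded parametric bootstrap (default 1000 draws)
  resampling both b_x and b_y.
- *Contamination mixture*: a profile likelihood over a grid of candidate
  effects θ. Each variant contributes the larger of a valid log-density
  N(r_j; θ, s_j²) and an invalid log-density N(r_j; θ, s_j² + ψ²); the wider
  invalid component only wins for ratios far from θ, so invalid assignment is
  penalty-bearing near the consensus. ψ defaults to 1.5 × SD of the ratio
  estimates; the grid to 10 001 points over mean ± 6 SD. The 95% set
  {θ : L* − L(θ) < 1.92} can be a union of intervals; the enclosing hull is
  reported with a multimodality flag. A likelihood-ratio p-value against
  θ = 0 is reported when the grid covers zero.

P-values use the normal approximation throughout, matching common
summary-data MR practice; t-based alternatives are not offered.

**Multivariable MR.** Outcome betas are regressed on the matrix of exposure
betas (intercept fixed at zero, weights 1/s_y²) over a combined instrument:
the union of per-exposure genome-wide-significant variants, pruned once by
each variant's minimum p across exposures. Each coefficient is a direct
effect conditional on the co-exposures. MV-Egger frees the intercept after
orienting rows on a chosen exposure. An exposure whose beta column is exactly
zero is reported with direct effect 0 and undefined uncertainty, and the
remaining exposures are refit — this makes the single-informative-exposure
reduction to univariable IVW exact. Rank-deficient (collinear) nonzero
columns raise an error naming the offending exposures.

**Conditional instrument strength.** For a target exposure, its betas are
regressed on the co-exposures' betas by iterated WLS, with per-variant
weights from the delta-method residual variance s_xt² + Σ_c δ_c² s_xc²
(cross-trait estimation covariance assumed zero by default — the common
choice when sample overlap is unknown — with an option to supply it). The
weighted residual sum of squares Q_t gives F_cond = Q_t/(k − p + 1); >10 is
the conventional adequacy gate. Iteration stops when Q changes by < 1e-6 or
after 100 rounds (a non-convergence warning returns the last iterate).
Alternative degrees-of-freedom conventions differ by O(1/k) and are not
offered. When an exposure is conditionally weak, the chain can be rerun with
an alternative instrument set for the other exposure, reporting the change in
F_cond.

**Mediation.** The total effect (univariable IVW on the exposure's own
instruments) minus the direct effect (MVMR adjusting for the mediator) is the
indirect effect; the proportion mediated is indirect/total. The indirect SE
is sqrt(se_T² + se_D² − 2·cov); the proportion's SE is the first-order delta
approximation for a ratio of correlated normals. Proportions outside [0, 1]
are reported unclipped with a flag (negative-adjacent intervals are
meaningful and should not be truncated). The decomposition is on log odds
ratios; odds-ratio non-collapsibility makes it an approximation, accepted as
standard practice for binary outcomes in summary-data MR mediation.

*Covariance of total and direct.* The default is cov = 0. This is
conservative: the two estimates share instruments, so their true covariance
is large and positive, and ignoring it overstates the indirect-effect SE.
The rigorous option (`bootstrap_total_direct_cov`) builds the
indirect-effect variance from three parts and returns the variance-matched
covariance: (i) an exact shared-outcome-noise term (both estimators are
linear in b_y); (ii) a seeded parametric bootstrap over the exposure/mediator
betas only; (iii) a mediator-specific-effect term. Part (iii) reflects a real
phenomenon of finite instrument panels: variants whose mediator effects are
not proportional to their exposure effects act as balanced pleiotropy in the
univariable total (inflating its random-effects variance) but are adjusted
away in the multivariable model, so they decorrelate the two estimates. Its
variance, b_M² · var(δ) · Σ u_j² (u the IVW weights), is estimated from the
precisely measured mediator betas via the measurement-corrected residual
variance of the mediator column on the exposure column. A Q-statistic-based
estimate of the same quantity was rejected: with a few hundred variants its
relative error is ~75%, which destroys interval calibration, whereas the
mediator-beta route achieves ~8%.

*Dual-instrument exclusion.* To separate mediation from horizontal
pleiotropy, a sensitivity rerun drops variants associated (p < 5e-8 from the
harmonized z = b_x/s_x) with both the exposure and a mediator, and reports
unrestricted and restricted results side by side.

**Effect clustering.** Per-variant ratio estimates for a discrepant,
heterogeneous exposure→mediator pair are fitted with mixtures of k
substantive Normal components (free means, variances fixed at the squared
ratio SEs), a null component (mean 0), and a uniform "junk" component over
[min r − 2 max s, max r + 2 max s] that absorbs outliers (a heavy-tailed t
would serve the same role; uniform is simpler and equivalent at this scale).
EM alternates responsibilities and precision-weighted mean updates;
convergence at relative log-likelihood change < 1e-8 or 2000 iterations; 20
restarts per k from jittered quantile starts. Models for k = 0..k_max are
compared by BIC (parameters: k means + k+1 free weights). The k = 0 baseline
(null + junk only) is included deliberately: on null data a substantive
component with mean ≈ 0 duplicates the null component and the weight split
between them is not identified, so without the baseline "all variants null"
is not a selectable model. The log-likelihood is asserted non-decreasing at
every iteration. Posterior probability ≥ 0.8 is a reporting convention for
confident membership, not a fitting rule.

A pair is screened into clustering when Cochran's Q has p < 0.05 and the
marginal signs are discrepant: sign(X→M) · sign(M→Y) ≠ sign(X→Y) (for
example, BMI lowers IGF1, IGF1 raises CRC risk, yet BMI raises CRC risk).

**Pipeline gating.** A mediator enters mediation analysis only when both
marginal directions (X→M and M→Y) are "robust": IVW p < 0.05 and every
computed sensitivity point estimate agrees in sign with IVW. Sign agreement
is a deliberate operationalization of "qualitatively consistent" — requiring
sensitivity significance as well would conflate robustness with power; the
choice is surfaced prominently because other operationalizations are
defensible. No multiple-testing correction is applied across the mediator
panel by default (a Bonferroni option exists), mirroring per-pair gating
practice. Bidirectional runs (M→X) set a confounding-vs-mediation flag when
the reverse IVW is significant.

## Synthetic-data generator

Summary statistics are generated directly at the summary level (no
individual-level genotypes — sufficient for every estimator and fast). Per
variant: γ_j ~ N(0, σ_γ²) is the exposure effect; the mediator effect is
α·γ_j + δ_j with δ_j ~ N(0, σ_δ²) the mediator-specific effect (giving the
mediator independent instruments); the outcome log-odds effect is
τ_direct·γ_j + b_M·(αγ_j + δ_j) + pleio_j, with pleio_j ~ N(μ_p, σ_p²) on an
`invalid_fraction` of variants. Observed betas add noise with
SE = 1/sqrt(2·n·maf·(1−maf)) per trait sample size, maf ~ U(0.05, 0.5). A
controllable fraction of variants is palindromic. Everything is seeded and
byte-reproducible.

Default magnitudes are anchored to the motivating epidemiology: total
exposure→outcome log-OR ln(1.16) per SD, proportion mediated
α·b_M/(τ + α·b_M) ≈ 0.07 (α = −0.13, b_M = −0.08 — a mediator lowered by the
exposure yet raising outcome risk, the discrepant-sign configuration),
400 exposure SNPs, and GWAS-scale samples (n_exp = 700 000, n_med = 400 000,
n_out = 120 000). σ_γ = 0.02 gives selected instruments a mean F around 170,
comparable to (indeed somewhat stronger than) published adiposity instrument
panels. Presets cover directional pleiotropy, 30% contamination with
offsets large relative to the ratio noise, two effect clusters at ±0.3,
a conditionally weak mediator, and a mediator with a built-in reverse effect
on the exposure.

Binary-outcome effects are generated on the log-odds scale directly;
logistic non-collapsibility attenuation is deliberately not simulated.

**What passing tests do and do not show.** The generator draws independent
variants (LD enters only through explicit fixture matrices), homoscedastic
Normal effect distributions, non-overlapping samples, and mediator-specific
effects on *every* variant. Real summary data have LD structure, sample
overlap, sparser and more skewed architectures, and selection artifacts the
generator omits. Two consequences observed in testing are worth stating
plainly:

- *Weak-instrument attenuation.* Selecting instruments in the same exposure
  GWAS that supplies their betas attenuates both the total and the direct
  effect by a factor ≈ 1/(1 + 1/F̄) (about 1% at the default mean F ≈ 170),
  so absolute effect estimates — including the reported odds ratio — are
  mildly shrunk toward the null. Because the two attenuations are closely
  matched, they largely cancel in the proportion mediated, which is unbiased
  to within ±0.1 percentage points in large replication runs at the default
  conditions. The per-stream Monte-Carlo spread of the proportion is wide
  (SD ≈ 0.03 per replicate), so a 500-replicate mean still moves by ±0.3
  percentage points between seed streams.
- *Dense shared architecture and reverse/confounded signals.* Because every
  variant affects the exposure, mediator instruments are never exposure-free;
  bidirectional and mediator→outcome analyses therefore pick up
  exposure-borne signal that sparser real architectures would not produce to
  the same degree. The bidirectional flag should be read accordingly.

## Problem sizes

Replicated checks use 500 replicates for proportion recovery and coverage,
2000 for type-I error calibration, 200 for the contamination comparison, and
100 for cluster recovery; `scripts/acceptance.py` uses 200/500/100/50 for the
corresponding quantities. These sizes give Monte-Carlo SEs comfortably below
the tolerances being checked.

## Numerical choices

- Greedy LD pruning breaks p-value ties by variant id (order invariance).
- Wald ratio requires b_x ≠ 0; ratio-based estimators raise on any zero b_x.
- The contamination-mixture grid must span all ratio estimates (error
  otherwise); degenerate zero-spread ratios fall back to an SE-scaled span.
- EM restarts: restart 0 starts exactly at the ratio quantiles; later
  restarts add seeded N(0, (0.1·range)²) jitter.
- `difference_mediation` refuses |total| < 1e-8 (undefined proportion).
- Harmonization is idempotent, and a full allele flip of any input table is a
  no-op by construction; both are asserted in tests.

## Known limitations

- No additive random-effects IVW, MR-PRESSO, mode-based estimation, Steiger
  filtering, MVMR-median/Lasso, or Q-minimization weak-instrument MVMR.
- The proportion-mediated CI uses the delta method, not Fieller's theorem;
  very weak totals make the delta interval optimistic.
- Odds-ratio non-collapsibility is ignored (documented approximation).
- The EM junk component's uniform range is data-driven and not re-estimated.
- Multiple mediators are adjusted one at a time in the pipeline; no joint
  multi-mediator decomposition is attempted.
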