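# Methods

## Model and estimand

A binary phenotype is modeled as the indicator that a standard-normal latent
liability exceeds a threshold; thresholds are sex-specific and shared across
twins and zygosity groups within sex.  Liability (co)variance follows the
classical twin design: additive-genetic factors correlate κ = 1 across MZ
twins and κ = 0.5 across DZ twins, common-environment factors are shared
within a pair, unique-environment factors are independent.  No dominance
component is modeled and only same-sex pairs are supported.

Structural models are expressed through three liability-scale component
matrices A, C, E (each including its drug-specific diagonal), with
within-twin expectation Σ_W = A + C + E (unit diagonal) and cross-twin
expectation Σ_X = κA + C.  The supported kinds — univariate ACE, bivariate
Cholesky, independent pathway (general factors plus specifics), and
one-factor common pathway — differ only in how free parameters fill A, C, E.

## Two-stage estimation

**Stage 1 (moments).**  Per zygosity-sex group: thresholds from all observed
individuals (both twins pooled, incomplete pairs included); within-person
correlations from all individuals; cross-twin correlations from complete
pairs, pooling both twin orientations so the estimate is exchangeable by
construction.  Each tetrachoric correlation is the ML solution of the
(1,1)-cell orthant equation with thresholds fixed at the margins — a 1-D
root-finding problem solved with a safeguarded Newton iteration on a
bivariate-normal CDF built from Owen's T function (validated in tests
against scipy's Genz integrator; the speed matters because bootstrap and
calibration loops solve millions of tables).  A table containing a zero cell
receives a flat +0.5 continuity correction and is flagged; |r| is clamped at
1 − 1e-8.  Per-moment variances come from the expected information; the
*full* moment covariance, needed by the sandwich estimator and the
mean-adjusted fit statistic, comes from a pair-level nonparametric bootstrap
(default 200 replicates; the calibration suite uses 400 where tail accuracy
of the trace correction matters), fully vectorized across replicates.

**Stage 2 (structure).**  Minimize F(θ) = Σ_g (s_g − σ_g(θ))′ W_g (s_g −
σ_g(θ)) over the p² unique correlations per group — within-person pairs,
cross-twin same-trait, cross-twin cross-trait.  Weight modes: `diagonal`
(inverse information variances; the robust-WLS default), `full` (inverse
bootstrap covariance), `identity`.  Thresholds stay fixed at stage-1 values
in every mode: all packaged specs are saturated in thresholds, so joint
fitting would change no correlation estimate; threshold sampling noise
enters through the bootstrap covariance and the resampling bootstrap.
Optimization is multi-start (default 5 jittered starts, uniform ±0.2)
trust-region least squares with an analytic Jacobian, bounds ±1 on all path
coefficients.  Unit liability variance is enforced exactly by *implying*
each specific-e path, se_j = sqrt(max(0, 1 − explained_j)), with a smooth
quadratic penalty once explained variance exceeds 1; a solution with implied
se² < 1e-6 is boundary-flagged.  Sign indeterminacy is resolved after
fitting: the first free loading of each factor is made nonnegative,
pure-variance paths take absolute values.  Nonconvergence is an ordinary
recorded outcome in ladder runs, never an exception.

## Inference

**Overall fit.**  T = df · F_min / tr(UΓ), with U = W − WΔ(Δ′WΔ)⁻¹Δ′W the
residual-weight operator, Δ the moment Jacobian at the solution, and Γ the
stacked stage-1 covariance (bootstrap blocks per group; groups independent).
This single (mean) scaling gives E[T] ≈ df under a correct model — verified
empirically (mean T within 1% of df in the calibration suite) — and is
deliberately not the mean-and-variance-adjusted variant used by commercial
SEM estimators; the residual variance inflation (~1.2×) leaves empirical
type-I error near 0.07 at nominal 0.05, inside the accepted calibration
band.  Degrees of freedom count distinct fitted correlations minus free
parameters; thresholds are outside the moment vector, so df bookkeeping is
internally consistent but not numerically comparable to software that counts
threshold moments.

**Fit indices.**  RMSEA uses the multi-group convention
sqrt(G · max(T − df, 0)/(df · N)) with N = total individuals — the
convention that reproduces the published first-row value (χ²(399) = 424.58,
N = 7164, G = 4 → 0.006); its 90% interval inverts the noncentral
chi-square.  TLI and CFI are computed against the independence baseline (all
correlations zero, per-group free thresholds), with the max(·,0) guards that
keep CFI in [0,1].  Cutoff flags: RMSEA < 0.05, TLI > 0.95, CFI > 0.95.

**Wald tests.**  W = (Rθ̂ − r)′(R V R′)⁻¹(Rθ̂ − r) on the fuller model, with
V the sandwich (Δ′WΔ)⁻¹Δ′WΓWΔ(Δ′WΔ)⁻¹.  This path-scale statistic is exact
for regular restrictions (empirical type-I error 0.05 on a true-zero general
loading of a retained factor).  Drop-to-zero restrictions on paths that
enter the covariance structure only through squares and products — specific
a/c paths, or an entire general factor — are nonstandard at the boundary:
the information matrix is singular exactly at zero and the path-scale
statistic over-rejects (~4× inflation).  For such restrictions the package
tests the variance components θ² = 0 by the delta method
(`scale='squared'`), which degrades conservatively (empirical type-I ≈
0.025 for one restriction; joint multi-df versions are approximate and can
occasionally exceed nominal when weakly identified loadings absorb noise);
the model-comparison ladder uses this scale for its drop edges, matching
the qualitatively conservative behavior of published ladder comparisons.
A near-singular bread matrix in the sandwich is ridged (relative 1e-10) so
flat directions inflate their variance and shrink W instead of failing.

**Bootstrap.**  Bias-corrected accelerated intervals from pair-level
resampling within zygosity-sex groups; every replicate reruns stage 1 and
stage 2 (replicates are warm-started at the point estimate, single start —
the point fit keeps the multistart default).  Acceleration comes from a
delete-one pair jackknife, switching to a stratified grouped jackknife (40
blocks) above 2000 pairs.  Intervals use converged replicates only; more
than 10% nonconverged attaches a reliability warning.

**Sex analyses.**  The quantitative sex-difference test fits sex-specific
a/c paths (e implied) and Wald-tests their cross-sex equality (2 df).  Sex
as a covariate enters as a per-phenotype liability threshold shift β
(closed-form probit with a binary regressor); variance explained by sex is
β²v_s/(β²v_s + 1) with v_s the indicator variance.  Because groups are
single-sex, a threshold shift leaves within-group correlations untouched,
so the structural stage is unchanged — the adjusted fit differs only in its
reported sex effects.

## Synthetic data

The generator draws factor scores per pair (A with cross-twin correlation κ
per factor, C shared, E independent) and thresholds the resulting unit-
variance liabilities; missingness masks the whole second twin with a fixed
probability, independent of phenotype values (MCAR — the registry gives no
missingness mechanism, and MCAR is the testable default).

The registry-emulation preset encodes: 11 phenotypes with thresholds at the
printed lifetime prevalences (7.79% prescription-opioid misuse down to
1.31% heroin and 1.86% dissociatives); group sizes of 778/1203/662/940
pairs (printed individuals / 2, rounded); per-pair completeness 0.726 so
that 84.12% of *individuals* belong to complete pairs (the published
figure is individual-level); and a reduced independent-pathway structure
(one general a factor, one general e factor, specific a only for the
opioid and sedative phenotypes, specific c for four illicit phenotypes).
Decomposition cells printed in the source prose are used verbatim (POM
14/41/39/0/6; heroin 64/15/0/0/21; prescription-stimulant general-a 80;
sedative specific-a 30, general-e 41, specific-e <1; illicit-stimulant
specific-c 9; solvent specific-c 51); the remaining cells were fixed once
inside the prose-stated ranges (general-e 3–15%, specific-e 6–22%):
stimulants_rx 80/3/0/0/17, sedatives_rx 28.5/41/30/0/0.5, cannabis
50/0/0/28/22, cocaine 75/12/0/0/13, illicit stimulants 65/12/0/9/14,
hallucinogens 70/14/0/0/16, inhalants 55/10/0/20/15, solvents
30/5/0/51/14, dissociatives 70/10/0/0/20.

What a green generator-based test does and does not establish: it verifies
the estimator against the *stated* ACE world — binary thresholds, MCAR
pair-level missingness, sex-invariant structure, no dominance, no
assortative mating, no measurement-model misfit.  Real interview data
violate several of these (item-level missingness patterns, cohort effects,
possible sex-specific structure), so recovery here is a correctness check
on the machinery, not a reproduction of the original estimates — the
registry data are not deposited and real-data point estimates are out of
scope.

## Numerical choices

- Tetrachoric solver: vectorized tables use 24 bisection steps then
  safeguarded Newton (the derivative of the orthant probability in ρ is the
  bivariate density, in closed form); single tables use scalar Brent root
  finding on a float-only CDF.  Accuracy ~1e-12 in ρ.
- The univariate ACE objective is a convex piecewise quadratic in (a², c²);
  with diagonal or identity weights it is solved in closed form by
  enumerating the active-set regions — the exact minimizer of the same
  penalized objective the generic trust-region path optimizes (agreement to
  ~1e-9 verified against it), which makes bootstrap refits cheap.
- The brute-force oracle (tests only) maximizes the multinomial likelihood
  over an iteratively refined ρ grid restricted to |ρ| ≤ 0.999, with
  orthant probabilities from a 2-D Gauss–Legendre product rule (48 nodes,
  switching to 384 when |ρ| > 0.9 to resolve the density ridge).
- Moment variances are floored at 1e-10 before inversion into weights;
  full-weight blocks use an eigenvalue square root clipped at zero.
- Optimizer tolerances: xtol/ftol 1e-14, gtol 1e-12, max 5000 residual
  evaluations; population-moment self-consistency reaches F < 1e-20.
- BCa bias correction uses the tie-aware proportion below the point
  estimate; acceleration from the jackknife skewness with a guard for
  zero dispersion.

## Known limitations

- Wald comparisons that drop many weakly identified parameters at once are
  conservative approximations, not exact tests (see above); a proper
  alternative would be a scaled difference test, which is deliberately out
  of scope for DWLS here.
- Full-weight WLS with 11 phenotypes inverts a 121×121 bootstrap covariance
  per group estimated from a few hundred replicates; it is provided but
  flagged unstable at realistic sample sizes — diagonal weights are the
  default for good reason.
- The stage-1 asymptotic covariance treats distinct moment estimates as
  independent in diagonal mode; cross-moment dependence enters only via the
  bootstrap.  Published χ²/RMSEA values from commercial estimators use
  adjustment conventions that are not all reconstructible, so no numeric
  equivalence on real-data table rows is claimed beyond the RMSEA
  convention check above.
- Only binary phenotypes, same-sex pairs, and ACE (no dominance)
  structures are supported.
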