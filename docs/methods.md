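# Methods

## Sampling model

A study scenario is (q, effect, N_ca, N_co): a control-population
frequency spectrum q over k ≥ 2 categories (all frequencies strictly
positive; renormalized on load, with a warning when the raw sum is off by
more than 1e-6), an effect on one risky category, and the two arm sizes.
Simulated tables draw the control row as Multinomial(N_co, q) and the case
row independently as Multinomial(N_ca, q′). The case spectrum q′ sets the
risky entry to p₁ and scales every other entry by (1−p₁)/(1−p₀), i.e. the
frequency shift is shared proportionally — no non-risky category is
favoured a priori. The effect can be given as a relative deviation δ
(p₁ = p₀(1+δ)), as p₁ itself, or as an odds ratio; the three
parameterizations are interconvertible and round-trip exactly.

Power at level α is the fraction of simulated tables with p < α (strict
inequality), reported with its binomial standard error
√(power·(1−power)/n_sim). Under δ = 0 the same estimator measures the
type-I error. A-posteriori power follows the *prospective* convention:
observed row proportions and row totals define the scenario, which is then
treated exactly as an a-priori design. This is deliberately not the
"observed power" transformation of the achieved p-value, which is
uninformative; only the scenario is taken from the data.

## Test statistic and calibrations

The statistic is the uncorrected Pearson chi-square; no Yates correction
anywhere, including 2×2, because the power analysis needs the same
statistic at every k. All-zero columns (common in small samples with rare
categories) are dropped with a warning and the degrees of freedom
adjusted; a zero row sum is an error.

* **asymptotic**: p from the χ²(k′−1) upper tail. Cochran's adequacy rule
  (no expected count < 1, at most 20% of expected counts < 5) is evaluated
  and reported on every result.
* **permutation**: conditional on both margins, the control row of a 2×k
  table is multivariate hypergeometric in the column totals; B independent
  draws give p = (1 + #{χ²* ≥ χ²_obs}) / (B + 1). This sampler is
  distributionally identical to classical table-permutation algorithms and
  is validated against exhaustive enumeration on small tables. The +1
  estimator keeps p strictly positive and valid; ties are honoured with an
  absolute slack of 1e-9 on the statistic.
* **fisher_mc**: same margin-fixed draws, ranked by null (multivariate
  hypergeometric) probability; p = (1 + #{P* ≤ P_obs}) / (B + 1) — the
  Monte-Carlo analogue of the two-sided Fisher exact test.

Each simulated table gets its own B resampling draws; nothing is pooled
across tables, since margins differ table to table.

## Scaled statistics and the closed form

N_scaled(p₀,p₁,N) = N(p₁−p₀)²/(2p̄(1−p̄)) with p̄ = (p₀+p₁)/2 is the pooled
squared standardized difference for equal arms; its unequal-arm
generalization N_sc replaces N/2 by the harmonic combination
(1/N_ca + 1/N_co)⁻¹ and reduces to N_scaled exactly at equal arms. N_sc is
symmetric in the arms and bounded by (p₁−p₀)²N_ca/(p̄(1−p̄)) as N_co → ∞:
the power ceiling for a fixed case arm is an algebraic fact, not a
simulation artifact. For 2×2 tables the equal-arm statistic evaluated on
the expected table equals the Pearson chi-square of that table, and under
the null the observed-table statistic is asymptotically χ²(1).

For 2×2 equal-arm designs the two-sided arcsine closed form
(φ = 2·arcsin√p, Δ = |φ₁−φ₀|)

    power = Φ(Δ√(N/2) − z_{1−α/2}) + Φ(−Δ√(N/2) − z_{1−α/2})

includes both tails so that δ = 0 returns exactly α. It is cross-checked
in the tests against an independent standard implementation and against
Monte-Carlo power.

## The N_H correction and the N_sc* calibration

Power at matched N_sc decays as more categories are tested. Dividing N_sc
by N_H^0.37 empirically collapses the power-versus-N_sc curves across
table widths onto a single curve; 0.37 is an empirical constant (exposed
as a parameter) and the collapse is good in the useful regime — in our
simulations it becomes tight (spread below 0.05, falling under 0.01) for
power above roughly 0.65–0.70, while an exponent of 0.5 is tighter below
50% power. Near the 50% line neither exponent collapses the curves to
within much better than ~0.08.

The threshold N_sc*(α, β) is calibrated by simulation: a factorial grid of
scenarios (N_H ∈ {4,8,12,16,20}; risky control frequency ∈
{0.30, 0.15, 0.05}; δ ∈ {1.0, 0.5, 0.25}; cases ∈ {100, 250, 500, 750,
1000}; control:case ratio ∈ {1, 2, 3}; the non-risky mass split uniformly
— 675 scenarios, 2,000 simulated tables each, asymptotic p-values, one
batch serving all α simultaneously), then a local-linear Gaussian-kernel
regression of power on N_sc/N_H^0.37 per α, inverted at each β.

Numerical choices in the regression:

* **Window.** The corrected-N_sc axis of the grid extends far past the
  point where power saturates at 1 (to ~160, versus saturation by ~15).
  Isolated saturated tail points make strict leave-one-out CV degenerate
  (their hat-diagonal → 1, so every moderate bandwidth scores +inf) while
  carrying no information about the curve's rise. The regression therefore
  uses only points up to 1.2× the largest x whose power is ≤ 0.995.
* **Bandwidth.** Leave-one-out CV (computed exactly via the linear-smoother
  hat diagonal) over a 25-point log-spaced grid from twice the median
  point spacing to half the window span.
* **Monotonization.** The fitted curve is clipped to [0,1] and projected
  onto non-decreasing functions by isotonic regression (PAVA). A running
  maximum would also monotonize but systematically anticipates high-β
  crossings wherever the raw fit wiggles; the L2 projection does not.
* **Inversion.** Linear interpolation on a 1,500-point evaluation grid; a
  β outside the fitted curve's attainable range raises an error naming
  that range.

The packaged default calibration (`data/default_calibration.csv`, with a
JSON sidecar recording the grid, bandwidths and seed 2013) tabulates α ∈
{0.10, 0.05, 0.01, 0.005, 0.001} × β ∈ {0.50, …, 0.95}. Thresholds in the
saturating elbow (β ≳ 0.95) are intrinsically sensitive to the smoothing
because the curve is nearly flat there; values at β ≤ 0.90 are stable to
within a few percent across seeds and bandwidth choices, and the
calibration is only claimed over the convex support of its scenario grid
(risky frequency 0.05–0.30, δ 0.25–1.0).

## Design inversions

* **Cases at a fixed ratio r**: the smallest integer N with corrected
  N_sc(p₀, p₁, N, ⌊rN⌋) ≥ N_sc*, found by integer search warm-started at
  the closed-form N ≈ N_sc*·N_H^0.37·p̄(1−p̄)(1+1/r)/(p₁−p₀)². Minimality
  (the bound fails at N−1) is the contract; always feasible.
* **One arm fixed**: solving 1/N_free = (p₁−p₀)²/(N_sc*·N_H^0.37·p̄(1−p̄))
  − 1/N_fixed. A non-positive right side means the target power is
  unreachable for any number of controls; that is returned as a result
  state carrying the limiting corrected N_sc (and, when a calibration with
  fitted curves is at hand, the supremum power it maps to), not as an
  error. N_sc's symmetry in the arms makes the two directions one solver.
* **Minimum detectable effect**: the smallest δ with corrected N_sc ≥
  N_sc*, by Brent bisection (relative tolerance 1e-10) on (0, 1/p₀ − 1),
  with p₁ capped below 1; reported as δ, p₁ and OR. Infeasible designs
  report the maximum achievable corrected N_sc instead.

All inversions are validated end-to-end in the tests: minimality at N
versus N−1, Monte-Carlo power at the returned design within 0.03 of β,
and δ_min round-tripping through the sample-size solver to within one
case.

## Synthetic data and what the tests show

The built-in `euro11` spectrum carries the classic European 11-haplogroup
control frequencies verbatim (summing to 110%; renormalized with a warning
on load, so the discrepancy stays visible). Synthetic spectra are
symmetric-Dirichlet draws — realistic in shape (one common, several rare
categories at small concentration) but independent across categories. The
generator emulates multinomial sampling noise only: real studies add
phylogenetic dependence between haplogroups, haplogroup-calling error,
population stratification and case-control frequency mismatches that no
test here exercises. Passing tests therefore demonstrate the statistical
machinery under the stated sampling model, not robustness to those
artefacts.

Problem sizes used by the packaged checks (chosen to keep the full suite
in the minutes range): 10,000 simulated tables with B = 10,000
permutations for the type-I-error cells; 2,000 tables per calibration
scenario; 1,500–4,000 tables for the null-validity and consistency
sweeps; B = 100,000 for comparisons against exact enumeration on 2×2
tables with margins up to 6.

## Known limitations

* The exponent 0.37 is empirical; no analytic derivation is attempted,
  and below ~65% power the 0.5 exponent describes the data better.
* N_sc* values for β above 0.90 depend appreciably on how the saturating
  elbow is smoothed; treat them as indicative.
* The permutation/Fisher loops cost O(n_sim · B) hypergeometric draws; at
  the 10,000 × 10,000 scale a cell takes a minute or two on one core. The
  asymptotic method is the practical choice for large scenario scans.
* No multiple-testing correction across haplogroups beyond the N_H
  scaling, no stratified or matched designs, and no modelling of
  phylogenetic dependence between categories.
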