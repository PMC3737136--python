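# Methods

This note records the statistical model implemented by `bsvm`, the
numerical choices behind it, and what the simulation studies do and do not
demonstrate.

## Model and procedure

**Data.**  n₁ cases and n₂ controls (t ∈ {+1, −1}) genotyped at M
biallelic variants; `g_{ki}` ∈ {0, 1, 2} counts copies of the minor
allele, defined in the pooled sample (ties at frequency 0.5 count the ALT
allele).  Monomorphic variants carry no information and are dropped with a
warning before analysis; their weight would be undefined.

**Risk measure.**  With m_case and m_ctrl the variant's minor-allele
counts in cases and controls and m their sum, per-chromosome Poisson
mutation rates are estimated with add-one smoothing,
λ̂_case = (m_case+1)/(2n₁+2) and λ̂_ctrl = (m_ctrl+1)/(2n₂+2).  A variant
is *risk* iff m_case > m_ctrl (ties → nonrisk).  Its weight is the rate
ratio in the direction of its category times (m+2)/(m+1):

    RM = (λ̂_case/λ̂_ctrl) · (m+2)/(m+1)      (risk)
    RM = (λ̂_ctrl/λ̂_case) · (m+2)/(m+1)      (nonrisk)

On balanced designs this is strictly above 1, grows with the imbalance in
either direction, and is close to 1 for unassociated variants.  For
unbalanced designs the classification rule is unchanged but RM > 1 is no
longer guaranteed; a warning is logged.  The comparison weightings are:
WSt = 1/√(n q̂(1−q̂)) with q̂ the smoothed control frequency;
Fp = 1/√(p̂(1−p̂)) with p̂ the smoothed pooled frequency;
RBt = −log of the one-sided binomial tail probability of the observed
case/control split of the m mutant alleles (success probability n₁/n);
EREC = |β̂ + δ| with β̂ a one-step logistic score estimate (U/I at the
null) and δ = 1 by default, the sign of β̂ + δ overriding the count-based
category.  RBt and EREC are re-implementations from brief published
descriptions, not reproductions of their source implementations; they
exist for comparison and are labelled approximate.  When |β̂ + δ|
degenerates to zero the RM weight and count-based category are the
fallback.

**SVM and R².**  The two collapsed covariates are standardised to zero
mean and unit variance over the sample (configurable) and fed to a
soft-margin SVM with RBF kernel exp(−γ‖x−y‖²), C = 10 and γ = 1/d = 1/2
by default.  The dual QP is solved by a second-order working-set SMO
(below).  Model fit is summarised by R² = 1 − SS_res/SS_tot of the
estimated status t̂ against t.  Three readings of t̂ are implemented:

- `decision` (default): the decision values f(x) after affine
  least-squares calibration onto the labels, making R² the squared
  Pearson correlation corr(t, f)².  This is the only reading with the
  properties the selection needs: it is ≈ 0 for an uninformative model,
  bounded by 1, and monotone in fit quality.
- `raw`: f(x) plugged directly into the residual form.  A decision value
  is a margin, not a least-squares prediction, so raw R² is
  systematically negative (≈ −0.8 for genuine fits at n = 1000) while a
  degenerate constant model scores ≈ 0 — under this reading backward
  elimination maximises R² by *destroying* the model, and the region
  test loses essentially all power.  Kept for diagnostics only.
- `label`: sign(f) in the residual form (equivalently 1 − 4·error/SS_tot).

**Backward elimination.**  Weights and categories are estimated once from
the full data and never refreshed inside the loop; removing variant *i*
only subtracts its fixed contribution from its own burden covariate.
Each round fits the model with every remaining variant left out; the
removal with the highest R^(2(−i)) is accepted if it is ≥ the current R²
(ties broken towards the lowest variant index, making the procedure
deterministic; equality counts as an accepted removal, which also prunes
exact no-ops such as duplicated columns).  A removal that would zero both
covariates is never offered.  The loop performs at most M(M+1)/2 SVM
fits, a bound asserted in the tests.

**Inference.**  The region statistic is the post-selection R².  Each of
the B permutations shuffles the labels and re-runs the entire pipeline —
classification, weighting, collapsing, selection — so the adaptivity of
the procedure is inside the null distribution; the test is then exact
under label exchangeability.  (Permuting labels around the fixed selected
model instead inflates the measured type I error to ~0.5 at n = 1000 and
was rejected.)  P-values use the add-one rule (1+k)/(B+1).  Per-variant
p-values for the retained set use Δᵢ = R²(retained) − R²(retained∖{i})
with the retained set held fixed under permutation and weights
re-estimated from the permuted labels; re-running the selection per
variant per permutation would cost O(B·M³) fits, so the fixed-set null is
an approximation.  Fisher's exact test (two-sided, summing tables no more
probable than the observed) and Pearson's χ² (1 df, no continuity
correction) on the 2×2 allele-count table serve single-variant reporting.

## Simulator

Control minor-allele frequencies follow Wright's stationary density
f(q) ∝ q^(β₁−1)(1−q)^(β₂−1)e^(σ(1−q)) with β₁ = 0.001, β₂ = β₁/3,
σ = 12, truncated to [1/(4·10⁴), q_max] and sampled by inverse CDF on a
4096-point log-spaced grid.  With q_max = 0.5 about 77% of draws fall
below 0.01 — ≈ 141 of 183 variants, the calibration figure the model is
validated against.  Effects are set by per-variant population-attributable
risks: OR = 1 + PAR/(MAF_U(1−PAR)); case frequency
MAF_A = OR·MAF_U/(1 + MAF_U(OR−1)).  Protective variants attach the same
per-variant PAR to the major allele, so the minor allele is depleted in
cases (for rare variants this yields mildly protective ORs, consistent
with attributing a fixed PAR to a rare allele).  Genotypes are
Hardy–Weinberg Binomial(2, MAF) draws, independent across variants —
realistic for rare alleles, a simplification for common ones (no linkage
disequilibrium, no haplotype structure, no covariates).  Equal per-variant
PARs split the total exactly; "uniform" mode renormalises U(0,1) draws to
the total.

**Scenario spectra.**  A pure mixture scenario (M equals the
risk/protective/neutral sum, as in the 20- and 30-variant power and null
conditions) draws its MAFs from the density truncated at q_max = 0.01:
these conditions model a set of *rare* variants with mixed effects, and
only this reading reproduces the published operating characteristics
(drawing the full spectrum, with ~25% common variants absorbing part of
the PAR, roughly halves power).  A larger region (M above the sum, as in
the 183-variant condition) draws the full spectrum to 0.5 and assigns the
causal roles to uniformly chosen variants with MAF_U < 0.01.  Both
defaults are overridable through `WrightParams`.

**Study sizes.**  Power and type-I estimates use 100 and 200 simulation
replicates respectively with B = 199 permutations at n = 1000 — the
package's default desk scale, with exact binomial (Clopper–Pearson)
intervals reported.  `power_study` curtails a replicate's permutations as
soon as the exceedance count makes p > α inevitable; the rejection
decision is identical to the full run, so this is a computation saving,
not an approximation.  `region_test` always runs all B permutations.

## Numerical choices

- **Solver.**  The dual QP is solved by a hand-written SMO with
  first-order selection of the ascent index and second-order (largest
  objective decrease) selection of its partner.  Individuals sharing a
  covariate row and label are merged into one point whose box constraint
  is C times its multiplicity — an exactly equivalent program that shrinks
  n = 1000 fits to the number of distinct genotype patterns (tens).  The
  merged dual coefficient is split evenly over duplicates on output, so
  every reported α ∈ [0, C].  Pair updates keep the equality and box
  constraints satisfied exactly; the KKT stopping tolerance is 1e−3 (the
  conventional SMO default — R² is insensitive at the scale the selection
  compares, and the permutation studies re-run the solver ~10⁵ times).
  The solver is validated in the tests against scikit-learn's SVC decision
  function and a brute-force SLSQP solve of the dual on small instances.
- **Warm starts.**  Within one selection, each candidate fit starts from
  the current model's dual solution (feasible for every candidate since
  the point set and boxes are unchanged).  Results remain deterministic.
- **Degeneracies.**  If both covariates are constant over the sample the
  fit returns the constant label-mean decision (majority class) with
  R² = 0 and a warning.  A covariate with zero variance is dropped from
  standardisation rather than divided by zero.
- **Permutation streams.**  One integer seed drives everything;
  replicates draw independent generators from a spawned `SeedSequence`,
  so studies are reproducible and replicates independent.

## Limitations

- The per-variant permutation null holds the retained set fixed
  (approximation documented above); its p-values are ranking tools rather
  than exact sizes.
- Simulated power under this implementation runs somewhat above the
  published figures for every weighting scheme (e.g. ~0.87 rather than
  0.76 for RM at total PAR 0.03, with the RM/WSt ordering then within one
  rejection at 100 replicates), reflecting the interpretation choices the
  obscured source formulas force (risk-measure smoothing, kernel width,
  R² calibration, rare-spectrum truncation).  Type I error, the PAR-0.05
  and protective-mixture powers, and the rare-variant calibration
  reproduce the published values within their tolerances.
- No covariate adjustment, imputation, phasing, dosages, linkage
  disequilibrium or multiple-testing correction across regions; family
  designs and population stratification are out of scope.
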