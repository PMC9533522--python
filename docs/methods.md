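# Methods

## The composite score and its evaluation

The score counts positive ultrasound signs among tongue thickness > 61 mm,
mandibular condylar mobility ≤ 10 mm, and hyomental distance ≤ 51 mm; the
screening rule is "positive iff score > 1". Three conventional bedside tests
(modified Mallampati grade > 2, thyromental distance < 6.5 cm, mouth
opening < 3 cm) are evaluated with the same machinery for comparison. All
comparators are applied literally — strict `>` for tongue and Mallampati,
inclusive `≤` for condylar mobility and hyomental distance, strict `<` for
thyromental distance and mouth opening — and never after rounding. All
lengths are stored in millimetres internally (thyromental 65 mm, mouth
opening 30 mm); some published tables label these columns in cm while
printing mm-magnitude values, and the mm reading is adopted throughout.

Per-predictor accuracy at the fixed cutoff uses the 2×2 table; sensitivity,
specificity, PPV and NPV carry Clopper–Pearson exact 95% intervals (Wilson
available as an option), the convention of clinical accuracy reporting. AUCs
are computed on the underlying ordinal or continuous values (grade 1–4,
millimetres, score 0–3), with measurements where *smaller* is worse
(mobility, distances, mouth opening) negated first. This distinction matters
for the composite: its 2×2 metrics use the fixed "> 1" rule, while its AUC
uses all four score levels and therefore exceeds the single-threshold bound
(sens + spec)/2.

Ties get half credit in the AUC; ROC curves sweep the rule "score > t" over
the distinct observed values, so the rank (Mann–Whitney) statistic equals
the trapezoidal area exactly. AUC uncertainty and paired comparisons use
DeLong structural components; there is no installed implementation of the
DeLong estimator in the scientific Python stack, so it is implemented here
and validated against a bootstrap SE (within 15% on a fixed n = 300 cohort)
and against `sklearn.roc_auc_score` for the point estimate. Degenerate
(zero-variance) inputs are returned flagged, not raised. Youden's J breaks
ties toward the higher threshold, i.e. the more specific rule, a choice that
matters only on knife-edge data. Group comparisons use Welch's t-test by
default (a flag restores the pooled-variance test), the rank-sum test for
the ordinal Mallampati grade, and the chi-square test (without continuity
correction) for sex.

Rounding is applied only when rendering reports — half away from zero, two
decimals — never inside computations; the JSON "twin" of every rendered
table carries the unrounded values, and re-rounding it reproduces the
rendered table exactly.

## Sample-size design

The design tests one AUC against a null value with κ negatives per positive:
find the smallest integer n₊ with
`z_{α/2}·SE(AUC₀; n₊, κn₊) + z_{power}·SE(AUC₁; n₊, κn₊) ≤ AUC₁ − AUC₀`,
using the Hanley–McNeil SE. The variance formula is not uniquely determined
by the published inputs (AUC 0.9 vs 0.8, α 0.05, power 0.8, κ 19); the
Hanley–McNeil exponential approximation was chosen because it is the
convention of the clinical ROC software family and yields the published
total of exactly 1000 (50 positives + 950 negatives). Normal quantiles are
two-sided for α and one-sided for power. A one-curve-versus-null design is
used, not a paired two-curve design, matching the stated inputs.

## The synthetic cohort generator

The generator emulates the published study conditions: n = 1000 adults (age
clipped to 18–90), DTI prevalence 26/1000 or DL prevalence 51/1000,
indicator positivity equal to the published sensitivities among cases and
1 − specificity among controls, and demographics drawn from the published
per-group means and SDs. Case counts are binomial by default; an
`exact_counts` switch fixes them at `round(n·prevalence)` to reproduce the
26/974 and 51/949 denominators that the tests need.

Dependence between the three indicators is a single exchangeable Gaussian
copula correlation ρ: latent `Z_i = √ρ·W + √(1−ρ)·ε_i`, indicator positive
when `Z_i ≤ Φ⁻¹(rate_i)`. Marginals are exact in expectation at any ρ; ρ
only moves co-occurrence. The default ρ = 0.3 was chosen because real
airway measurements are anatomically correlated and independence (ρ = 0)
would make the composite slightly *better* than observed: the analytic
composite AUC under the DTI calibration is 0.903 at ρ = 0 versus 0.871 at
ρ = 0.3, bracketing the published 0.89. The analytic score distribution at
any ρ is available by Gauss–Hermite integration over the shared factor
(`score_pmf_correlated`, 80 nodes) and serves as the oracle the simulated
AUCs are tested against.

Continuous values are back-filled per indicator from truncated normals on
the side of the cutoff implied by the binary state: the three ultrasound
variables use location = cutoff with scales 3/6/5 mm (condylar / hyomental /
tongue) — plausible clinical spreads; since only the dichotomized states
feed the downstream analysis, these choices are cosmetic. Thyromental
distance and mouth opening are back-filled from each group's published
moments truncated to the indicated side, so group means stay near the
published values while rates stay exact. Mallampati grades are drawn within
the positive side as {3, 4} with probabilities (0.75, 0.25) and within the
negative side as {1, 2} with (0.30, 0.70). Re-dichotomizing any generated
cohort reproduces its generating indicators exactly (boundary draws are
nudged one ulp onto the correct side).

The two outcomes' joint distribution is unreported, so the generator is
calibrated for one outcome at a time; the other label comes from a
nested-severity rule (every DTI case is DL; in DL mode a DL case is DTI
with probability p_DTI/p_DL) and is approximate — analyses of the
non-selected outcome on a generated cohort inherit no calibration
guarantee. A single seeded generator drives each cohort; identical
(config, seed) pairs give byte-identical CSVs.

### What passing tests do and do not show

The generator reproduces the *marginal* structure of the study — rates,
prevalences, group moments — under an assumed copula. It does not model
measurement error, operator variability, within-patient correlation between
ultrasound and conventional tests beyond the shared ρ, or the real joint
DL/DTI structure. Agreement of simulated accuracy with the published point
estimates therefore validates the analysis machinery and the calibration
arithmetic, not the clinical claim; the published headline AUCs (0.89 DTI,
0.84 DL) are recoverable only approximately, and the package's tests check
the machinery against analytic oracles instead of asserting those AUCs.

## Numerical choices and degenerate inputs

- Clopper–Pearson bounds are beta quantiles via `statsmodels`; coverage at
  n = 26 is verified by exact binomial enumeration rather than simulation.
- Single-class label vectors are rejected with a named error everywhere;
  empty tables and zero denominators yield flagged `nan`s, not crashes.
- The sample-size search rejects AUC gaps below 1e-9 (unbounded n) and is
  verified minimal: power holds at n₊ and fails at n₊ − 1.
- Simulation-based tests use fixed seeds with tolerances set from binomial /
  Monte-Carlo standard errors (3 SE bands, 99% binomial intervals). Problem
  sizes: 100 000 draws for marginal and pmf checks, 150 replicate cohorts of
  n = 1000 for the paired-test power check, 60 for the AUC-calibration
  check, 2000 bootstrap replicates at n = 300 for the DeLong SE check.

## Known limitations

- The published logistic-regression analysis is not implemented: no
  coefficients were printed, leaving nothing to reproduce or verify.
- One published NPV cell (condylar mobility against DL) is internally
  inconsistent with its own row's sensitivity/specificity and prevalence;
  the package asserts the Bayes-consistent value (0.98, not the printed
  0.99).
- One published group-means row for the DL outcome prints its columns in
  the direction opposite to every other row; the generator follows the
  direction implied by the accuracy tables.
- Binormal ROC smoothing, partial AUC, covariate-adjusted ROC regression,
  and multiplicity corrections (beyond an optional Bonferroni flag kept off
  by default, matching per-comparison reporting) are out of scope.
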