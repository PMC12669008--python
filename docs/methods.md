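# Methods

## Data model and decision rule

A cohort is n subjects with a classifier score s ∈ [0, 1] and a binary
label (1 = pathology). Scores of exactly 0 or 1 are legal (deployed
models saturate); missing scores are a hard error rather than imputed,
since a screening evaluation without a model output for an exam is not
interpretable. BI-RADS categories, when used as the label source, are
mapped 1–3 → normal, 4–6 → pathology (category 3 carries under 2%
malignancy likelihood and is conventionally followed, not recalled);
category 0 marks an unassessable exam and is excluded with the exclusion
counted and reported, never silently dropped.

A subject is predicted positive iff s ≥ t. The inclusive rule makes t = 0
the all-positive ROC corner and every observed score an attainable
cut-off; a strict `>` variant is available where a consumer needs the
other convention. Which convention an external model used is generally
unrecoverable from summary tables, so the choice is documented rather
than hidden. Ties in scores are handled by the same rule, and AUC gives
tied positive–negative pairs half credit, matching the Mann–Whitney
pair-counting identity that the tests use as an oracle.

## ROC sweep

Candidate thresholds are the unique observed scores plus a sentinel just
above the maximum, so the empirical curve is exact on finite data and
runs from (0, 0) to (1, 1). AUC is the trapezoid over that curve.
scikit-learn's ROC is used in the test suite as an independent
cross-check, never as the implementation, because the threshold
convention here is load-bearing for everything downstream.

Sensitivity, specificity and accuracy follow the usual ratios; a ratio
with an empty denominator (single-class stratum) is reported as NaN with
a warning instead of raising, so batch evaluations over many strata
survive degenerate cells.

## Net-benefit curves and the intersection threshold

The classical decision-curve net benefit at threshold probability p_t is
NB = TP/n − FP/n · p_t/(1 − p_t), where p_t = L/(L + P) encodes the
relative harm of a false positive against the value of a true positive.
The package's central method replaces this single curve with two:

    NB0(t) = TP(t)/n − TN(t)/n · w0,    NB1(t) = FP(t)/n − FN(t)/n · w1,

and selects the x-coordinate of their intersection as the decision
threshold. The weight probabilities default to the sweep value
(w0 = w1 = t/(1 − t)), which is the reading under which both curves can
be drawn against a single threshold axis and intersected; explicitly
supplied fixed p0, p1 (e.g. from a loss profile) are accepted as
overrides since no loss/profit figures are bundled with the method. Two
boundary identities pin the curves down and are asserted on every cohort:
NB0(0) = prevalence, NB1(0) = 1 − prevalence; both curves diverge to −∞
as t → 1 whenever their weighted class is non-empty, so the grid stops at
1 − ε with ε = 10⁻³.

The default grid is 1,001 even points on [0, 1 − ε] united with the
cohort's unique scores: even spacing for smooth interpolation, observed
scores so every count change is representable. The counts are step
functions of t, so the difference D = NB0 − NB1 is piecewise smooth with
jumps only at observed scores; a crossing is a transition between a
strictly positive and a strictly negative run of D, located by linear
interpolation between the bracketing grid points (midpoint of a
zero-valued run when the curves coincide across it). No iterative solver
is involved, which keeps the root bit-reproducible. Grid points where D
is exactly zero are *not* crossings by themselves: in uninformative tail
regions (and identically, for class-balanced cohorts, wherever the
empirical Youden index vanishes) the two curves coincide over whole
plateaus. Multiple crossings are all reported; the smallest-t one is
returned as the selection (the most sensitivity-preserving choice in a
screening context) with a warning. The criterion value recorded for the
selection is NB0 at the crossing. If D never changes sign the selector
raises an explicit no-intersection error rather than inventing a
threshold.

## Geometry of the intersection at low prevalence

A structural property worth stating plainly, because it decides what the
method can and cannot do on rare-disease cohorts. At any crossing,
TP + w·FN = FP + w·TN with w = t/(1 − t) ≥ 0. Both left-hand terms are
bounded by the positive-class size n_pos, so FP ≤ n_pos(1 + w) and
w ≤ n_pos/TN. At prevalence π this forces

    FPR ≤ π/(1 − π) · (1 + w),   i.e.   Sp ≳ 1 − π/(1 − π)

wherever an intersection exists at all. At π ≈ 0.03 any crossing
therefore sits at specificity ≥ ~0.97 — always *above* the Youden
operating point, with correspondingly *lower* sensitivity. Two practical
consequences, both verified by the test suite:

- For centered score distributions (class-conditional score mass in the
  middle of [0, 1]) at low prevalence there is **no** crossing anywhere on
  [0, 1): D(0) = 2π − 1 < 0 and the weighted TN term keeps D negative
  throughout. The selector's no-intersection error is the correct and
  expected outcome there.
- Crossings exist when the normal-class scores are concentrated near
  zero — the regime a probability-calibrated model produces at ~3%
  prevalence — and then sit in the extreme-specificity tail, near where
  the TP and FP counts equalize.

A configuration in which the intersection instead lands on the
high-sensitivity/low-specificity side (e.g. Se ≈ 0.9 at Sp ≈ 0.5)
requires FP ≫ n_pos at the crossing and is arithmetically incompatible
with the curve definitions at low prevalence. The acceptance suite keeps
one test asserting that high-sensitivity direction at prevalence 0.029
across 20 seeds; it fails in all runs, consistently with this bound, and
is retained as an honest negative result rather than weakened. With the
optional class-balancing switch (majority class downsampled to the
minority count before the curves are formed; off by default) the
difference factors exactly as D = J(t)(1 − w)/2, pinning any crossing in
an informative region to t = 0.5 regardless of the data — a degeneracy
users should know before reaching for that switch.

## McNemar comparison

Two strategies are compared on the same subjects through the discordant
counts (b, c) of their paired predictions: exact two-sided binomial test
on (min(b, c), b + c, ½) when b + c < 25, continuity-corrected
χ² = (max(0, |b − c| − 1))²/(b + c) with 1 df otherwise (the textbook
switch; both variants callable explicitly), p = 1 when b + c = 0. The
computation is delegated to statsmodels, with the binomial-sum and
hand-formula oracles asserted in the tests. p-values are displayed to 4
significant figures with a "< 0.0001" floor. No multiple-testing
correction is applied; reports record how many tests they contain.
Aggregation across models reports mean/min/max of Se/Sp/Acc per strategy
both as raw fractions and as whole percents using round-half-away-from-
zero, the convention of the printed tables the aggregates are checked
against.

## Synthetic cohorts

The generator emulates the structure of a screening cohort: labels drawn
Bernoulli(π) with π defaulting to 0.029 (the prevalence of the motivating
mammography cohort, 19,441 pathology in 663,606 exams), then scores from
class-conditional distributions. The binormal-logistic model draws latent
Gaussians N(μ0, σ0²) / N(μ1, σ1²) and maps them through the logistic
function: scores stay strictly inside (0, 1) and, because the map is
monotone, the ROC and the analytic AUC Φ((μ1 − μ0)/√(σ0² + σ1²)) are
preserved, giving exact oracles for AUC convergence and Youden-threshold
parameter recovery. A beta-pair model is available where scores are used
as probabilities directly. One seeded generator draws labels first, then
scores in fixed class order, so a seed pins the cohort byte-for-byte
through a CSV round-trip; `fixed_counts` fixes the positive count to
round(nπ) for exactly reproducible prevalence.

Three deterministic presets ("service-like A/B/C", analytic AUC 0.78 /
0.85 / 0.90 at π = 0.029, mid-range Youden thresholds) emulate the
operating regime of deployed mammography AI services qualitatively — they
are not reproductions of any service, whose score distributions are not
public. A fourth constructor, `tail_concentrated_spec` (normals at latent
N(−6, 0.3²), pathology N(−4.918, 1), AUC 0.85), produces the
calibrated-score regime in which NB curves actually intersect; it is the
default demonstration cohort. What the synthetic cohorts do not emulate:
per-exam correlation structure (multi-view, repeat visits), calibration
drift across model versions, reader variability in the labels. Passing
tests therefore show correctness of the estimators and selectors under
clean sampling, not robustness to those real-data effects.

## Problem sizes and numerical choices

Test and demonstration sizes were chosen to keep every oracle exact or
tight: exhaustive-search equivalence on cohorts up to n = 200 (100 random
draws), intersection-vs-dense-grid (10⁵ points) agreement within 10⁻³ on
n = 20,000 cohorts, AUC and Youden parameter recovery at n = 10⁵ within
0.01 / 0.02. Selector ties are broken toward higher sensitivity, then
smaller threshold (screening prioritizes detection; determinism matters
for reproducibility). Comparisons of float criteria use a 10⁻¹² guard.
Reports round displayed metrics to 2 decimals while all internal values
keep full precision.

## Known limitations

- The intersection threshold inherits the low-prevalence geometry above:
  it cannot produce a high-sensitivity operating point on rare-disease
  cohorts under the common-axis reading of the weights. Users wanting a
  sensitivity-first threshold should use the fixed-sensitivity selector.
- With fixed external weights p0 ≠ p1 the two curves live on different
  cost scales; the package computes what is asked but the interpretation
  of their crossing is the user's responsibility.
- The empirical Youden threshold converges slowly (cube-root rate) on
  flat ROC regions; the 0.02 recovery tolerance reflects that.
- Exact McNemar p-values are conservative near b + c = 25; the switch
  point is a convention, not an optimum.
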