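# Methods

This note documents the statistical procedures implemented in `armtrial`,
the assumptions behind them, the synthetic-cohort model, and the numerical
and design choices made where the underlying trial methodology left room for
interpretation.

## Trial model

Five scheduled visits (enrollment, two monthly visits of rehabilitation
alone, two monthly visits of add-on therapy) define the `Timepoint`
enumeration; all analyses operate on long-format assessment tables
(participant × visit × outcome). The outcome registry records each
instrument's measurement bounds, improvement direction, and — for the six
responder outcomes — its minimally important difference (MID): UEMS 2,
GRASSP-Strength 4, pinch force 2.4 N, grasp force 6 N (strength domain);
GRASSP-Prehension 2, CUE-T 4 (functional domain). The modified
intention-to-treat (mITT) rule retains participants with ≥ 24 sessions in
*each* period (default; configurable).

Handling of incomplete data is deliberately conservative and
imputation-free: an outcome missing either window endpoint counts as not
met (logged); a participant with no MID outcome observed at both endpoints
is excluded from classification with a warning. This mirrors a
completers-only analysis.

The MID boundary is inclusive (change ≥ MID), with a 1e-9 absolute guard so
that a change exactly equal to a non-dyadic MID (e.g. 22.4 − 20.0 against
2.4 N) is not lost to floating-point representation.

## Confirmatory tests

*Primary*: upper-tail exact binomial p-value by tail summation; no
approximation at any n.

*Conversion*: exact McNemar on the discordant pairs. The exact variant is
the one consistent with the reference analysis: for discordants (4, 16) it
gives 0.0118 → 0.012, where the chi-square variants give 0.0073/0.0139.

*Secondary endpoints*: each endpoint's paired differences are the
difference of the two enrollment-anchored changes, which telescopes per
participant to the change over the therapy period; a unit test asserts the
algebraic identity holds on noise-free data. The normality gate is
Shapiro–Wilk at α = 0.05 on the differences (the reference analysis states
only "as appropriate"); users can override per endpoint via
`normality_alpha`. The Wilcoxon branch drops zero differences, uses the
exact null distribution for n ≤ 25 and the continuity-corrected normal
approximation beyond; a zero-variance vector short-circuits to the
closed-form signed-rank tail (0.5ⁿ when all differences are positive).
Lower-is-better endpoints test a decrease. Alongside either branch a
two-sided t-based 90% CI is reported, consistent with a two-sided 10%
type-I error while the tests themselves are one-sided at 5%.

*Gatekeeping*: endpoints are tested in the pre-specified order
(pinch force, GRASSP-Prehension, GRASSP-Strength, UEMS, total sensory
score, EQ-5D-5L, SCIM III, then the four WHOQOL domain scores) at full
alpha; the first failure halts the sequence; an endpoint with fewer than 3
paired differences is treated as a failure (with a warning) rather than
silently skipped. Untested endpoints keep their descriptive summaries but
no p-value; the report renders them with a dash.

## Time-course analysis

The repeated-measures ANOVA is the classical one-way within-subject
decomposition with subject as a blocking factor and no sphericity
correction. Tukey HSD compares visit means using the within-subject error
mean square: qᵢⱼ = |m̄ᵢ − m̄ⱼ| / √(MSE/n) referred to the studentized range
with (k, (k−1)(n−1)) degrees of freedom. Whether the reference analysis
applied any sphericity correction is unknown; the uncorrected form matches
a plain "one-way repeated-measures ANOVA" reading, and the F statistic is
verified against a brute-force sums-of-squares oracle to 1e-10 relative
error.

The plateau contrast applies the paired one-sided machinery to the month-1 →
month-2 rehabilitation changes.

## Baseline cutoff scan

For each candidate threshold t (descending), participants are binarized at
baseline ≥ t and the odds ratio of responding is the 2×2 cross-product,
with the Haldane–Anscombe 0.5 correction applied to all cells whenever one
is empty. The scan halts at the first OR ≤ 1; the cutoff is the last
threshold with OR > 1.

Two grid/stopping choices deserve note. First, thresholds at or below the
observed minimum are excluded from the default grid: they binarize nobody,
and their noise-dominated OR (≈ the overall responder odds) would trigger
spurious halts. Second, when response probability increases monotonically
with baseline, the population OR exceeds 1 at *every* threshold, so the
scan never crosses 1; in that case the cutoff is reported as the threshold
of peak enrichment (maximal OR, ties to the lowest threshold). Under
perfect separation at a value c the corrected OR is maximal exactly at c,
so the rule recovers the separating value, and with steep logistic response
it recovers the true cutoff within one grid step in ≳ 95% of simulated
cohorts. Grid steps default to 1 point for scored outcomes and 5 N for
forces. OR confidence intervals are not part of the halt rule (only point
ORs are used).

## Design calculations

The default sample-size rule is the one-sample normal-approximation formula
with full-precision normal quantiles and *multiplicative* dropout inflation
round(n·(1+d)). With (power 0.80, two-sided α 0.10, p₀ 0.50, p₁ 0.67,
d 0.25) it yields 52 evaluable → 65 enrolled. The conventions matter:
dividing by (1 − d) would give 70, and exact-power sizing needs 53
evaluable (the exact test's power at 52 is 0.758) — both alternatives are
exposed but are not the default because only the multiplicative
normal-approximation convention reproduces the published enrollment.
`exact_power` returns the smallest critical value whose size is ≤ α along
with the exact power, by tail summation; its size is verified never to
exceed α for all n ≤ 200.

The safety tabulation counts *participants* with ≥ 1 qualifying event per
category and period (any / serious / device-related / serious
device-related / procedure-related / leading to discontinuation) plus total
event counts — the participant-vs-event distinction is load-bearing and
tested.

## Synthetic cohort model

Each outcome follows

value(i, visit) = baseline_i + G(visit)·m_i + ε,  truncated to scale bounds,

with baseline_i from a truncated normal inside the instrument bounds,
G(visit) the cumulative configured gain (rehabilitation months 1–2, therapy
months 1–2), m_i = max(0, 1 + subject_sd·z_i) a responsiveness multiplier
built from a standard-normal factor z_i *shared across outcomes*, and ε
visit-level Gaussian noise (enrollment included). The shared factor induces
the cross-outcome correlation that makes composite responders cluster;
truncation at the bounds acts as a floor/ceiling measurement model.

Defaults (versioned in `data/default_cohort.yaml`): 60 participants, AIS
mix 15/46.7/38.3% (B/C/D), sessions uniform on [24, 40] per period,
rehabilitation gains confined to the functional domain and to month 1 (the
plateau), therapy-period gains on strength, function and sensory outcomes
equal to the published mean differences (pinch 4.8 N, GRASSP-Prehension
1.6, GRASSP-Strength 2.8, UEMS 2.2, TSS 9.6; CUE-T and grasp force, for
which no mean difference is published, are set to 5 and 8 points). The
noise and subject spreads were calibrated once, by Monte Carlo, so that the
mean composite responder rate over seeds matches the observed 71.7% with a
function-domain rate near 75%; the implied strength-domain rate runs near
93% (observed: 86.7%) — a known compromise of the single-multiplier
heterogeneity model, which cannot hit all three marginals at once with the
means fixed. Baseline means/SDs are plausibility choices (e.g. UEMS
centered at 25) since the source reports no baseline distributions for most
outcomes.

What the generator does *not* emulate: item-level instrument structure,
per-hand laterality (a single value per outcome per visit; an aggregation
option covers bilateral inputs), floor/ceiling-induced skewness beyond
truncation, informative dropout (truncation visits are uniform), or any
mechanistic recovery dynamics. Passing tests therefore demonstrate the
correctness and calibration of the *statistical machinery* under a
plausible data-generating process, not clinical realism of trajectories.

`null_calibrated` constructs an exact null: zero gains, zero shared factor,
and per-outcome noise solved analytically so the per-participant composite
probability equals a target (default 0.5): with independent per-outcome hit
probability q, the composite probability is (1−(1−q)⁴)(1−(1−q)²); q is
solved by root-finding and noise_sd back-computed as MID/(√2·z₁₋q).
Baselines sit mid-scale so truncation does not disturb the identity. This
makes the responder count exactly Binomial(n, 0.5), so the primary test's
empirical rejection rate can be compared against its nominal size (4.62% at
n = 60, by discreteness).

Adverse events are per-participant Poisson counts per period with
independent per-event flag probabilities, calibrated so a 64-participant
safety population averages the published 5/105/128 events per period
(238 total).

## Problem sizes in the validation suite

The simulation-based checks use 2,000 seeds for type-I-error calibration,
500 seeds for gain recovery (asserted within 3 SE — a 1-SE band would
reject an unbiased estimator a third of the time), 300 seeds for cutoff
recovery, and exhaustive enumeration for the binomial and signed-rank
oracles at n ≤ 12. The residual recovery bias from multiplier clipping
(E[max(0, 1+0.5z)] ≈ 1.0085) stays within the 3-SE band at these sizes.

## Known limitations

- The strength-domain responder marginal of the default generator overshoots
  the observed rate (see above).
- The EQ-5D-5L reference row (p = 0.028 with a 90% CI spanning zero) is
  internally consistent only for a one-sided or nonparametric test; the
  package reports both pieces and leaves interpretation to the analyst.
- The cutoff-scan stopping rule is inherently heuristic; the full OR profile
  over the grid is always returned so users need not rely on the scalar
  cutoff.
- No figure rendering; results are tables, JSON and Markdown.
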