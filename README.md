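# armtrial

Statistical analysis of single-arm, sequential-treatment clinical trials with
a composite responder primary endpoint — the design used to evaluate an
upper-limb therapy in people with chronic cervical spinal cord injury, where
each participant completes a rehabilitation-alone period followed by an
equally long add-on therapy period, with monthly assessments throughout.

The package is written for trial statisticians and methods researchers who
want the complete analysis chain as reusable, tested code: from long-format
assessment tables to the final effectiveness and safety report, plus a
calibrated synthetic-cohort generator so every stage can be exercised and
validated without access to patient data.

## The statistics

**Composite responder endpoint.** A participant is a responder over a change
window if they improve by at least the minimally important difference (MID)
on ≥1 strength outcome *and* ≥1 functional outcome. The six MID-bearing
outcomes are: upper-extremity motor score (UEMS, MID = 2 points),
GRASSP-Strength (4 points), pinch force (2.4 N), grasp force (6 N) in the
strength domain; GRASSP-Prehension (2 points) and CUE-T (4 points) in the
functional domain. The primary window runs from the end of the
rehabilitation-alone period to the end of therapy.

**Primary test.** With n evaluable participants and x responders, the
one-sided exact binomial test evaluates H₀: p ≤ p₀ against p > p₀ for a
performance goal p₀ = 0.5, with p-value P(X ≥ x | n, p₀) by exact tail
summation.

**Conversion superiority.** Responder status in the two enrollment-anchored
windows forms a 2×2 table; the exact McNemar test on the discordant pairs
(b, c) uses p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½).

**Fixed-sequence gatekeeping.** Ordered secondary endpoints are tested at
full α = 0.05 (one-sided), each on the per-participant difference of changes
(enrollment→end-of-therapy minus enrollment→end-of-rehabilitation, which
telescopes to the therapy-period change). A Shapiro–Wilk gate chooses paired
t vs Wilcoxon signed-rank; the first p ≥ α halts the sequence and downstream
endpoints are reported untested.

**Time course and post hoc.** One-way repeated-measures ANOVA (subject as
blocking factor) with Tukey HSD on the within-subject error; a plateau
contrast between rehabilitation months 1 and 2; and a sequential odds-ratio
scan over baseline thresholds that reports the lowest enrollment value still
enriched for responders.

**Design.** n = ⌈(z₁₋ₐ√(p₀q₀) + z₁₋ᵦ√(p₁q₁))² / (p₁−p₀)²⌉ evaluable
participants, inflated multiplicatively for dropout; exact-binomial critical
values and power are also provided.

## Worked example

```python
from armtrial import (default_config, default_registry, generate_cohort,
                      responder_rate, exact_binomial_test, conversion_table,
                      mcnemar_exact, PRIMARY_WINDOW)

registry = default_registry()
profiles, assessments = generate_cohort(default_config(seed=1), registry)

rate = responder_rate(assessments, PRIMARY_WINDOW, registry)
test = exact_binomial_test(rate.count, rate.n, p0=0.5)
conv = conversion_table(assessments, registry)
print(rate.count, rate.n, round(test.p_value, 4))
print(conv.discordants, round(mcnemar_exact(*conv.discordants), 6))
```

prints

```
40 60 0.0067
(2, 22) 3.6e-05
```

40 of 60 synthetic participants meet the composite responder definition
(p = 0.0067 against the 50% performance goal), and the 22-vs-2 discordant
split shows conversion concentrated in the therapy period. The scripts in
`examples/` walk through each capability — simulation, primary/conversion
testing, the gatekeeping hierarchy, time-course analysis with baseline
cutoffs, and design calculations — and print annotated output.

A thin CLI wraps the same pipeline:

```
armtrial simulate --seed 1 --out-dir cohort
armtrial analyze --assessments cohort/assessments.csv \
    --profiles cohort/profiles.csv --events cohort/adverse_events.csv
armtrial power
```

`analyze` writes `results.json` and a Markdown report shaped like a trial
effectiveness/safety table, with the dash convention for hierarchy endpoints
left untested.

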