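"""Fixed-sequence (gatekeeping) testing of the secondary endpoints.

Each endpoint supplies per-participant paired differences — the change from
enrollment to end of therapy minus the change from enrollment to end of
rehabilitation alone.  Endpoints are tested in the pre-specified order at
full alpha; the first failure halts the sequence and downstream endpoints
are reported with a dash.
"""

from armtrial import default_config, default_registry, generate_cohort, run_hierarchy
from armtrial.pipeline import DEFAULT_HIERARCHY, hierarchy_differences

registry = default_registry()
_, assessments = generate_cohort(default_config(seed=1), registry)

diffs = hierarchy_differences(assessments, DEFAULT_HIERARCHY)
directions = {name: registry[name].direction for name in DEFAULT_HIERARCHY}
report = run_hierarchy(DEFAULT_HIERARCHY, diffs, alpha=0.05, directions=directions)

for row in report.as_rows():
    p = f"{row['p_value']:.3f}" if row["tested"] else "-"
    print(f"{row['endpoint']:>22}: mean diff {row['mean_diff']:+6.2f} "
          f"± {row['sd_diff']:.2f}  p = {p}")
if report.halt_index is not None:
    print(f"hierarchy halted at position {report.halt_index + 1} "
          f"({report.ordered_endpoints[report.halt_index]})")

# Endpoints after the halt carry no p-value by design: the fixed-sequence rule
# spends the full alpha on each endpoint but forfeits everything downstream of
# the first failure, controlling the family-wise error rate.
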