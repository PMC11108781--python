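"""Markdown report rendering.

The effectiveness table mirrors the trial-report layout: responder counts with
the primary p-value, the conversion 2x2 with McNemar's p, then the ordered
secondary endpoints as mean +- SD with one-sided p-values.  Untested hierarchy
endpoints (after the gatekeeper halts) are shown with a dash in place of a
p-value; parametric (paired-t) branches are starred.
"""

from __future__ import annotations

import math


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "-"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def _fmt_mean_sd(mean, sd) -> str:
    if mean is None:
        return "-"
    return f"{mean:.1f} ± {sd:.1f}"


def render_effectiveness(results: dict) -> str:
    lines = ["## Effectiveness endpoints (mITT population)", ""]
    lines.append("| Endpoint | Value | P value |")
    lines.append("| --- | --- | --- |")

    resp = results.get("responders", {}).get("primary")
    primary = results.get("primary_test")
    if resp and primary:
        n = resp["n"]

        def row(label, count, p=""):
            lines.append(f"| {label} | {count} ({100 * count / n:.1f}%) | {p} |")

        row("Strength responder, n (%)", resp["strength"])
        row("Function responder, n (%)", resp["function"])
        row("Responder, n (%)", resp["composite"], _fmt_p(primary["p_value"]))

    conv = results.get("conversion")
    if conv:
        n = conv["n"]
        lines.append("| **Conversion analysis** | | |")
        lines.append(
            f"| Therapy non-responder / rehabilitation responder | {conv['rn']} "
            f"({100 * conv['rn'] / n:.1f}%) | |"
        )
        lines.append(
            f"| Therapy non-responder / rehabilitation non-responder | {conv['nn']} "
            f"({100 * conv['nn'] / n:.1f}%) | |"
        )
        lines.append(
            f"| Therapy responder / rehabilitation responder | {conv['rr']} "
            f"({100 * conv['rr'] / n:.1f}%) | |"
        )
        lines.append(
            f"| Therapy responder / rehabilitation non-responder | {conv['nr']} "
            f"({100 * conv['nr'] / n:.1f}%) | {_fmt_p(conv['mcnemar_p'])} |"
        )

    hier = results.get("hierarchy")
    if hier:
        lines.append("| **Secondary hierarchical endpoints** | | |")
        for r in hier["rows"]:
            star = "*" if r.get("method") == "paired_t" else ""
            p = _fmt_p(r["p_value"]) + star if r["tested"] else "-"
            lines.append(
                f"| {r['endpoint']} | {_fmt_mean_sd(r['mean_diff'], r['sd_diff'])} | {p} |"
            )
        if hier["halt_index"] is not None:
            failed = hier["rows"][hier["halt_index"]]["endpoint"]
            lines.append("")
            lines.append(
                f"The hierarchy failed at endpoint {hier['halt_index'] + 1} "
                f"({failed}); dashes indicate endpoints not tested under the "
                "fixed-sequence rule. * indicates a parametric test."
            )
    lines.append("")
    return "\n".join(lines)


_SAFETY_LABELS = {
    "any": "Any adverse event",
    "serious": "Any serious adverse event",
    "device_related": "Adverse event related to device",
    "serious_device_related": "Serious adverse event related to device",
    "procedure_related": "Adverse event related to study procedures",
    "led_to_discontinuation": "Adverse event leading to discontinuation",
}
_PERIOD_LABELS = {
    "before_rehab": "Before rehabilitation",
    "rehab_alone": "Rehabilitation alone",
    "therapy": "Therapy",
    "any_time": "Any time",
}


def render_safety(results: dict) -> str:
    safety = results.get("safety")
    if not safety:
        return ""
    periods = list(_PERIOD_LABELS)
    lines = ["## Overview of adverse events (safety population)", ""]
    lines.append("| Event | " + " | ".join(_PERIOD_LABELS[p] for p in periods) + " |")
    lines.append("|" + " --- |" * (len(periods) + 1))
    for cat, label in _SAFETY_LABELS.items():
        cells = []
        for p in periods:
            count = safety["participants"][p][cat]
            pct = safety["percentages"][p][cat]
            cells.append(f"{count} ({pct:.1f})")
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    totals = [str(safety["total_events"][p]) for p in periods]
    lines.append("| Total number of adverse events | " + " | ".join(totals) + " |")
    lines.append("")
    lines.append(f"Counts are participants (percent of n={safety['n_safety']}).")
    lines.append("")
    return "\n".join(lines)


def render_cutoffs(results: dict) -> str:
    scans = results.get("threshold_scans")
    if not scans:
        return ""
    lines = ["## Baseline responder cutoffs (post hoc)", ""]
    lines.append("| Outcome | Cutoff |")
    lines.append("| --- | --- |")
    for name, scan in scans.items():
        cutoff = scan["cutoff"]
        lines.append(f"| {name} | {'-' if cutoff is None else f'{cutoff:g}'} |")
    lines.append("")
    return "\n".join(lines)


def render_report(results: dict) -> str:
    mitt = results.get("mitt", {})
    header = [
        "# Trial analysis report",
        "",
        f"Enrolled: {mitt.get('n_enrolled', '?')}; "
        f"mITT population: {mitt.get('n_mitt', '?')}.",
        "",
    ]
    parts = [
        "\n".join(header),
        render_effectiveness(results),
        render_safety(results),
        render_cutoffs(results),
    ]
    errors = results.get("errors")
    if errors:
        parts.append(
            "## Stage errors\n\n"
            + "\n".join(f"- {k}: {v}" for k, v in errors.items())
            + "\n"
        )
    return "\n".join(p for p in parts if p)
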