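"""End-to-end analysis pipeline.

``analyze`` chains every stage of the trial analysis: mITT filter, responder
classification in all three change windows, the primary exact-binomial test,
the conversion table with McNemar's test, the fixed-sequence secondary
hierarchy, per-outcome repeated-measures ANOVA, plateau contrasts, baseline
threshold scans, and the safety tabulation.  Stage failures are recorded and
independent later stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .design import tabulate_adverse_events
from .longitudinal import make_grid, plateau_contrast, rm_anova_tukey, visit_matrix
from .model import OutcomeRegistry, Timepoint, default_registry, filter_mitt
from .responders import (
    PRIMARY_WINDOW,
    REHAB_WINDOW,
    THERAPY_WINDOW,
    change_matrix,
    classify_cohort,
    conversion_table,
    results_to_frame,
)
from .stats import exact_binomial_test, mcnemar_exact, run_hierarchy

logger = logging.getLogger(__name__)

#: Pre-specified fixed-sequence order of the secondary endpoints; the four
#: quality-of-life domain scores close the sequence.
DEFAULT_HIERARCHY = [
    "pinch_force",
    "grassp_prehension",
    "grassp_strength",
    "uems",
    "tss",
    "eq5d5l",
    "scim3",
    "whoqol_physical",
    "whoqol_psychological",
    "whoqol_social",
    "whoqol_environment",
]

#: Grid step for the baseline threshold scans: 5 N for forces, 1 point
#: otherwise.
SCAN_STEPS = {"pinch_force": 5.0, "grasp_force": 5.0}


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    p0: float = 0.50
    normality_alpha: float = 0.05
    min_sessions_per_period: int = 24
    hierarchy: list[str] = field(default_factory=lambda: list(DEFAULT_HIERARCHY))
    n_safety: int | None = None
    scan_outcomes: list[str] | None = None  # default: MID outcomes + sensory

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown analysis-config keys: {sorted(unknown)}")
        return cls(**data)


def hierarchy_differences(
    assessments: pd.DataFrame, endpoints: list[str]
) -> dict[str, np.ndarray]:
    """Per-endpoint paired differences for the fixed-sequence tests.

    Each participant contributes (change enrollment -> end of therapy) minus
    (change enrollment -> end of rehabilitation alone); the enrollment value
    telescopes away, leaving the change over the therapy period.
    """
    therapy = change_matrix(assessments, THERAPY_WINDOW, endpoints)
    rehab = change_matrix(assessments, REHAB_WINDOW, endpoints)
    out: dict[str, np.ndarray] = {}
    for name in endpoints:
        if name in therapy.columns and name in rehab.columns:
            d = (therapy[name] - rehab[name]).dropna()
            out[name] = d.to_numpy()
    return out


def analyze(
    assessments: pd.DataFrame,
    profiles: pd.DataFrame,
    events: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    registry: OutcomeRegistry | None = None,
) -> dict:
    """Run the full pipeline; returns a JSON-serializable results dictionary."""
    config = config or AnalysisConfig()
    registry = registry or default_registry()
    results: dict = {"schema_version": 1, "package_version": _version,
                     "config": dataclasses.asdict(config), "errors": {}}

    # -- mITT ---------------------------------------------------------------
    mitt_ids = filter_mitt(profiles, config.min_sessions_per_period)
    n_enrolled = len(profiles)
    assessments = assessments[assessments["participant_id"].isin(mitt_ids)]
    results["mitt"] = {"n_enrolled": n_enrolled, "n_mitt": len(mitt_ids)}
    logger.info("mITT filter: %d of %d participants retained", len(mitt_ids), n_enrolled)

    # -- responder classification + primary test ----------------------------
    windows = {"primary": PRIMARY_WINDOW, "rehab": REHAB_WINDOW, "therapy": THERAPY_WINDOW}
    results["responders"] = {}
    primary_flags: dict[str, bool] = {}
    for label, window in windows.items():
        try:
            cls = classify_cohort(assessments, window, registry)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            results["errors"][f"responders.{label}"] = str(exc)
            continue
        frame = results_to_frame(cls)
        n = len(cls)
        summary = {
            "n": n,
            "composite": int(frame["composite"].sum()),
            "strength": int(frame["strength_met"].sum()),
            "function": int(frame["function_met"].sum()),
            "any_domain": int(frame["any_domain"].sum()),
            "per_participant": frame.to_dict(orient="records"),
        }
        results["responders"][label] = summary
        if label == "primary":
            primary_flags = dict(zip(frame["participant_id"], frame["composite"]))
            test = exact_binomial_test(summary["composite"], n, config.p0)
            results["primary_test"] = {
                "successes": test.successes, "n": test.n, "p0": test.p0,
                "proportion": test.successes / test.n, "p_value": test.p_value,
                "alternative": test.alternative,
            }
            logger.info("primary endpoint: %d/%d responders, p=%.4g",
                        test.successes, test.n, test.p_value)

    # -- conversion + McNemar ------------------------------------------------
    try:
        conv = conversion_table(assessments, registry)
        b, c = conv.discordants
        results["conversion"] = {
            "rr": conv.rr, "rn": conv.rn, "nr": conv.nr, "nn": conv.nn,
            "n": conv.n, "mcnemar_p": mcnemar_exact(b, c),
        }
    except Exception as exc:  # noqa: BLE001
        results["errors"]["conversion"] = str(exc)

    # -- fixed-sequence hierarchy -------------------------------------------
    try:
        diffs = hierarchy_differences(assessments, config.hierarchy)
        directions = {
            name: registry[name].direction for name in config.hierarchy
            if name in registry
        }
        report = run_hierarchy(
            config.hierarchy, diffs, alpha=config.alpha,
            directions=directions, normality_alpha=config.normality_alpha,
        )
        results["hierarchy"] = {
            "alpha": config.alpha,
            "halt_index": report.halt_index,
            "rows": report.as_rows(),
        }
    except Exception as exc:  # noqa: BLE001
        results["errors"]["hierarchy"] = str(exc)

    # -- time course: RM-ANOVA + plateau ------------------------------------
    results["rm_anova"] = {}
    results["plateau"] = {}
    for name in registry.names:
        if name not in set(assessments["outcome"]):
            continue
        try:
            wide = visit_matrix(assessments, name)
            if wide.shape[1] == len(Timepoint) and len(wide) >= 3:
                res = rm_anova_tukey(wide, outcome=name)
                results["rm_anova"][name] = {
                    "f_stat": res.f_stat, "df_time": res.df_time,
                    "df_error": res.df_error, "p_value": res.p_value,
                    "tukey": [
                        {"pair": [t.level_a, t.level_b], "mean_diff": t.mean_diff,
                         "p_adj": t.p_adj}
                        for t in res.tukey_pairs
                    ],
                }
        except Exception as exc:  # noqa: BLE001
            results["errors"][f"rm_anova.{name}"] = str(exc)
        try:
            pt = plateau_contrast(assessments, name, registry)
            results["plateau"][name] = {
                "n": pt.n, "mean_diff": pt.mean_diff, "p_value": pt.p_value,
                "method": pt.method,
            }
        except Exception as exc:  # noqa: BLE001
            results["errors"][f"plateau.{name}"] = str(exc)

    # -- baseline threshold scans -------------------------------------------
    results["threshold_scans"] = {}
    scan_outcomes = config.scan_outcomes
    if scan_outcomes is None:
        scan_outcomes = [o.name for o in registry.mid_outcomes()] + [
            o.name for o in registry if o.domain.value == "sensory"
        ]
    if primary_flags:
        from .longitudinal import sequential_or_scan

        baselines = assessments[
            assessments["timepoint"] == Timepoint.ENROLLMENT.name
        ].pivot_table(index="participant_id", columns="outcome", values="value",
                      aggfunc="first")
        for name in scan_outcomes:
            if name not in baselines.columns:
                continue
            try:
                sub = baselines[name].dropna()
                sub = sub[sub.index.isin(primary_flags)]
                flags = np.array([primary_flags[p] for p in sub.index])
                grid = make_grid(sub.to_numpy(), SCAN_STEPS.get(name, 1.0))
                scan = sequential_or_scan(sub.to_numpy(), flags, grid, outcome=name)
                results["threshold_scans"][name] = {
                    "cutoff": scan.cutoff,
                    "halted_at": scan.halted_at,
                    "grid": scan.grid.tolist(),
                    "odds_ratios": scan.odds_ratios.tolist(),
                }
            except Exception as exc:  # noqa: BLE001
                results["errors"][f"threshold_scan.{name}"] = str(exc)

    # -- safety --------------------------------------------------------------
    if events is not None:
        try:
            n_safety = config.n_safety if config.n_safety is not None else n_enrolled
            ae = tabulate_adverse_events(events, n_safety)
            results["safety"] = {
                "n_safety": ae.n_safety,
                "participants": ae.participants.to_dict(),
                "percentages": ae.percentages.round(1).to_dict(),
                "total_events": ae.total_events.to_dict(),
            }
        except Exception as exc:  # noqa: BLE001
            results["errors"]["safety"] = str(exc)

    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def save_results(results: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2)
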