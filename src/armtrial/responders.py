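"""Composite MID responder classification and period-conversion analysis.

A participant is a *responder* over a change window when they meet or exceed
the minimally important difference (MID) on at least one strength-domain
outcome AND at least one functional-performance outcome.  The primary window
runs from the end of the rehabilitation-alone period to the end of the therapy
period; the conversion analysis compares the two enrollment-anchored windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Direction, Domain, OutcomeDefinition, OutcomeRegistry, Timepoint

logger = logging.getLogger(__name__)

#: Absolute guard for the inclusive MID boundary: a change equal to the MID
#: counts as met even when binary representation leaves it a few ulps short
#: (e.g. 22.4 - 20.0 < 2.4 in double precision).
_MID_EPS = 1e-9


class ClassificationError(ValueError):
    """Raised when a participant cannot be classified at all."""


@dataclass(frozen=True)
class ChangeWindow:
    start: Timepoint
    end: Timepoint

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")


#: enrollment -> end of rehabilitation alone (conversion analysis)
REHAB_WINDOW = ChangeWindow(Timepoint.ENROLLMENT, Timepoint.REHAB_END)
#: enrollment -> end of therapy (conversion analysis)
THERAPY_WINDOW = ChangeWindow(Timepoint.ENROLLMENT, Timepoint.THERAPY_END)
#: end of rehabilitation alone -> end of therapy (primary endpoint)
PRIMARY_WINDOW = ChangeWindow(Timepoint.REHAB_END, Timepoint.THERAPY_END)

WINDOWS = {"rehab": REHAB_WINDOW, "therapy": THERAPY_WINDOW, "primary": PRIMARY_WINDOW}


@dataclass(frozen=True)
class ResponderResult:
    participant_id: str
    window: ChangeWindow
    met_outcomes: frozenset[str]
    strength_met: bool
    function_met: bool

    @property
    def composite(self) -> bool:
        return self.strength_met and self.function_met

    @property
    def any_domain(self) -> bool:
        return self.strength_met or self.function_met


@dataclass(frozen=True)
class RateResult:
    count: int
    proportion: float
    n: int


@dataclass(frozen=True)
class ConversionTable:
    """2x2 responder-conversion counts; first index is the rehab-alone window."""

    rr: int  # rehab responder,     therapy responder
    rn: int  # rehab responder,     therapy non-responder
    nr: int  # rehab non-responder, therapy responder
    nn: int  # rehab non-responder, therapy non-responder

    @property
    def n(self) -> int:
        return self.rr + self.rn + self.nr + self.nn

    @property
    def discordants(self) -> tuple[int, int]:
        """(b, c) = (rehab-only responders, therapy-only responders)."""
        return self.rn, self.nr

    def as_array(self) -> np.ndarray:
        return np.array([[self.rr, self.rn], [self.nr, self.nn]])


def outcome_met_mid(
    outcome: OutcomeDefinition, start_value: float, end_value: float
) -> bool:
    """Whether the change over the window meets the outcome's MID.

    Improvement is an increase for higher-is-better outcomes and a decrease
    otherwise; the boundary is inclusive (a change exactly equal to the MID
    counts as met).
    """
    if outcome.mid is None:
        raise ValueError(f"outcome {outcome.name!r} has no MID responder role")
    change = end_value - start_value
    if outcome.direction is Direction.LOWER_IS_BETTER:
        change = -change
    return change >= outcome.mid - _MID_EPS


def change_matrix(
    assessments: pd.DataFrame, window: ChangeWindow, outcomes: list[str] | None = None
) -> pd.DataFrame:
    """Per-participant change (end minus start) for each outcome over a window.

    Returns a participants x outcomes frame; NaN where either endpoint visit is
    missing for that participant/outcome.
    """
    sub = assessments[assessments["timepoint"].isin([window.start.name, window.end.name])]
    if outcomes is not None:
        sub = sub[sub["outcome"].isin(outcomes)]
    wide = sub.pivot_table(
        index="participant_id", columns=["outcome", "timepoint"], values="value",
        aggfunc="first",
    )
    changes = {}
    for outcome in wide.columns.get_level_values(0).unique():
        block = wide[outcome]
        if window.start.name in block and window.end.name in block:
            changes[outcome] = block[window.end.name] - block[window.start.name]
        else:
            changes[outcome] = pd.Series(np.nan, index=wide.index)
    return pd.DataFrame(changes)


def _met_frame(
    changes: pd.DataFrame, registry: OutcomeRegistry, domain: Domain
) -> pd.DataFrame:
    """Boolean met-MID frame for one domain; missing changes count as not met."""
    cols = {}
    for o in registry.mid_outcomes(domain):
        if o.name in changes.columns:
            delta = changes[o.name]
            if o.direction is Direction.LOWER_IS_BETTER:
                delta = -delta
            cols[o.name] = (delta >= o.mid - _MID_EPS).fillna(False)
    return pd.DataFrame(cols, index=changes.index, dtype=bool)


def classify_cohort(
    assessments: pd.DataFrame,
    window: ChangeWindow,
    registry: OutcomeRegistry,
) -> dict[str, ResponderResult]:
    """Classify every classifiable participant; returns id -> ResponderResult.

    A participant is classifiable when at least one MID outcome has values at
    both window endpoints; outcomes missing an endpoint are conservatively
    treated as not met (and logged).  Unclassifiable participants are dropped
    with a warning.
    """
    mid_names = [o.name for o in registry.mid_outcomes()]
    changes = change_matrix(assessments, window, mid_names)
    strength = _met_frame(changes, registry, Domain.STRENGTH)
    function = _met_frame(changes, registry, Domain.FUNCTION)

    results: dict[str, ResponderResult] = {}
    for pid in changes.index:
        observed = changes.loc[pid].notna()
        if not observed.any():
            logger.warning(
                "participant %s: no MID outcome observed at both window endpoints; "
                "excluded from responder classification", pid,
            )
            continue
        if not observed.all():
            missing = [c for c in changes.columns if not observed[c]]
            logger.info(
                "participant %s: outcomes %s missing a window endpoint; treated as not met",
                pid, missing,
            )
        met = set()
        if len(strength.columns):
            met |= {c for c in strength.columns if strength.loc[pid, c]}
        if len(function.columns):
            met |= {c for c in function.columns if function.loc[pid, c]}
        results[pid] = ResponderResult(
            participant_id=str(pid),
            window=window,
            met_outcomes=frozenset(met),
            strength_met=bool(strength.loc[pid].any()) if len(strength.columns) else False,
            function_met=bool(function.loc[pid].any()) if len(function.columns) else False,
        )
    if not results:
        raise ClassificationError(
            "no participant has a MID outcome observed at both window endpoints"
        )
    return results


def classify_participant(
    assessments: pd.DataFrame, window: ChangeWindow, registry: OutcomeRegistry
) -> ResponderResult:
    """Classify a single participant's assessment frame."""
    pids = assessments["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("classify_participant expects assessments for one participant")
    return classify_cohort(assessments, window, registry)[str(pids[0])]


def responder_rate(
    assessments: pd.DataFrame,
    window: ChangeWindow,
    registry: OutcomeRegistry,
    which: str = "composite",
) -> RateResult:
    """Responder count and proportion over the classifiable participants.

    ``which`` selects the flag: composite (default), strength, function or
    any_domain.
    """
    results = classify_cohort(assessments, window, registry)
    n = len(results)
    if n == 0:
        raise ClassificationError("no classifiable participants")
    attr = {"composite": "composite", "strength": "strength_met",
            "function": "function_met", "any_domain": "any_domain"}[which]
    count = sum(bool(getattr(r, attr)) for r in results.values())
    return RateResult(count=count, proportion=count / n, n=n)


def conversion_table(
    assessments: pd.DataFrame, registry: OutcomeRegistry
) -> ConversionTable:
    """Cross-classification of composite responder status in the two
    enrollment-anchored windows (rehabilitation alone vs therapy)."""
    rehab = classify_cohort(assessments, REHAB_WINDOW, registry)
    therapy = classify_cohort(assessments, THERAPY_WINDOW, registry)
    common = sorted(set(rehab) & set(therapy))
    if not common:
        raise ClassificationError("no participant classifiable in both windows")
    cells = {"rr": 0, "rn": 0, "nr": 0, "nn": 0}
    for pid in common:
        key = ("r" if rehab[pid].composite else "n") + (
            "r" if therapy[pid].composite else "n"
        )
        cells[key] += 1
    return ConversionTable(**cells)


def results_to_frame(results: dict[str, ResponderResult]) -> pd.DataFrame:
    """Per-participant responder flags as a tidy frame (for JSON/CSV export)."""
    rows = [
        {
            "participant_id": r.participant_id,
            "window_start": r.window.start.name,
            "window_end": r.window.end.name,
            "met_outcomes": ",".join(sorted(r.met_outcomes)),
            "strength_met": r.strength_met,
            "function_met": r.function_met,
            "composite": r.composite,
            "any_domain": r.any_domain,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
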