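"""Long-format table I/O.

All tables travel as UTF-8 CSV with a header row:

* assessments: ``participant_id,timepoint,outcome,value`` (long format, one row
  per participant x visit x outcome; timepoint as label or ordinal 0-4)
* profiles: ``participant_id,age,sex,ais_grade,neuro_level,years_since_injury,
  sessions_rehab,sessions_therapy``
* adverse events: ``participant_id,period,serious,device_related,
  procedure_related,led_to_discontinuation,description`` with 0/1 booleans

In memory, each table is a validated :class:`pandas.DataFrame`; the assessment
frame always stores the canonical timepoint labels.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .model import (
    OutcomeRegistry,
    ParticipantProfile,
    Period,
    Timepoint,
    ValidationError,
)

ASSESSMENT_COLUMNS = ["participant_id", "timepoint", "outcome", "value"]
PROFILE_COLUMNS = [
    "participant_id", "age", "sex", "ais_grade", "neuro_level",
    "years_since_injury", "sessions_rehab", "sessions_therapy",
]
AE_COLUMNS = [
    "participant_id", "period", "serious", "device_related",
    "procedure_related", "led_to_discontinuation", "description",
]
_AE_FLAGS = ["serious", "device_related", "procedure_related", "led_to_discontinuation"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns: {missing}")


def validate_assessments(
    df: pd.DataFrame,
    registry: OutcomeRegistry,
    force_aggregation: str = "max_hand",
) -> pd.DataFrame:
    """Validate and canonicalize an assessment frame.

    Checks outcome names against the registry, values against scale bounds, and
    uniqueness of (participant, timepoint, outcome).  Returns a copy with the
    timepoint column normalized to enumeration labels and values as floats.

    Bilateral inputs: when a ``side`` column is present (e.g. per-hand force
    measurements), the sides are collapsed to one value per key according to
    ``force_aggregation`` — ``"max_hand"`` (default) or ``"sum"``.
    """
    _require_columns(df, ASSESSMENT_COLUMNS, "assessments")
    if "side" in df.columns:
        if force_aggregation not in ("max_hand", "sum"):
            raise ValueError("force_aggregation must be 'max_hand' or 'sum'")
        agg = "max" if force_aggregation == "max_hand" else "sum"
        df = (
            df.groupby(["participant_id", "timepoint", "outcome"], sort=False)
            ["value"].agg(agg).reset_index()
        )
    df = df.loc[:, ASSESSMENT_COLUMNS].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["outcome"] = df["outcome"].astype(str)

    try:
        df["timepoint"] = [Timepoint.parse(t).name for t in df["timepoint"]]
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc

    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)

    unknown = set(df["outcome"]) - set(registry.names)
    if unknown:
        rows = df.index[df["outcome"].isin(unknown)].tolist()[:5]
        raise ValidationError(
            f"unknown outcome(s) {sorted(unknown)} (first offending rows: {rows})"
        )

    for name, sub in df.groupby("outcome", sort=False):
        o = registry[name]
        bad = ~sub["value"].map(o.in_bounds)
        if bad.any():
            row = sub.index[bad][0]
            raise ValidationError(
                f"row {row}: value {sub.loc[row, 'value']} outside bounds "
                f"[{o.scale_min}, {o.scale_max}] for outcome {name!r}"
            )

    dup = df.duplicated(subset=["participant_id", "timepoint", "outcome"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValidationError(
            "duplicate (participant, timepoint, outcome) key: "
            f"({first.participant_id}, {first.timepoint}, {first.outcome})"
        )
    return df.reset_index(drop=True)


def load_assessments(
    path, registry: OutcomeRegistry, force_aggregation: str = "max_hand"
) -> pd.DataFrame:
    """Read and validate a long-format assessment CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str, "outcome": str})
    return validate_assessments(df, registry, force_aggregation=force_aggregation)


def write_assessments(df: pd.DataFrame, path) -> None:
    df.loc[:, ASSESSMENT_COLUMNS].to_csv(path, index=False)


def load_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, PROFILE_COLUMNS, "profiles")
    df = df.loc[:, PROFILE_COLUMNS].copy()
    bad = ~df["ais_grade"].isin(["B", "C", "D"])
    if bad.any():
        raise ValidationError(
            f"AIS grade must be B, C or D (rows {df.index[bad].tolist()[:5]})"
        )
    for col in ("sessions_rehab", "sessions_therapy"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 0).any():
            raise ValidationError(f"negative session counts in column {col}")
    return df


def write_profiles(df: pd.DataFrame, path) -> None:
    df.loc[:, PROFILE_COLUMNS].to_csv(path, index=False)


def profiles_to_objects(df: pd.DataFrame) -> list[ParticipantProfile]:
    return [
        ParticipantProfile(
            id=str(r.participant_id),
            age=float(r.age),
            sex=str(r.sex),
            ais_grade=str(r.ais_grade),
            neuro_level=str(r.neuro_level),
            years_since_injury=float(r.years_since_injury),
            sessions_rehab=int(r.sessions_rehab),
            sessions_therapy=int(r.sessions_therapy),
        )
        for r in df.itertuples(index=False)
    ]


def load_adverse_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    _require_columns(df, AE_COLUMNS, "adverse events")
    df = df.loc[:, AE_COLUMNS].copy()
    valid = {p.value for p in Period}
    bad = ~df["period"].isin(valid)
    if bad.any():
        raise ValidationError(
            f"period must be one of {sorted(valid)} (rows {df.index[bad].tolist()[:5]})"
        )
    for col in _AE_FLAGS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int).astype(bool)
    return df


def write_adverse_events(df: pd.DataFrame, path) -> None:
    out = df.loc[:, AE_COLUMNS].copy()
    for col in _AE_FLAGS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
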