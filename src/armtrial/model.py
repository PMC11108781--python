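"""Domain model for a single-arm, two-period (rehabilitation then therapy) trial.

The trial schedule is five monthly visits: enrollment, two months of structured
rehabilitation alone, then two months of rehabilitation combined with the
investigational therapy.  Outcomes are registered with their measurement scale,
improvement direction and — for the six outcomes that define responder status —
a minimally important difference (MID).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping


class Timepoint(enum.IntEnum):
    """Scheduled assessment visits; the integer value is months since enrollment."""

    ENROLLMENT = 0
    REHAB_M1 = 1
    REHAB_END = 2
    THERAPY_M1 = 3
    THERAPY_END = 4

    @classmethod
    def parse(cls, value) -> "Timepoint":
        """Accept an enum member, its label, or the ordinal 0-4."""
        if isinstance(value, Timepoint):
            return value
        if isinstance(value, str):
            v = value.strip().upper()
            if v in cls.__members__:
                return cls[v]
            if v.lstrip("-").isdigit():
                value = int(v)
            else:
                raise ValueError(f"unknown timepoint label {value!r}")
        try:
            return cls(int(value))
        except ValueError as exc:
            raise ValueError(f"timepoint ordinal out of range: {value!r}") from exc


class Domain(str, enum.Enum):
    STRENGTH = "strength"
    FUNCTION = "function"
    SENSORY = "sensory"
    QOL = "qol"
    INDEPENDENCE = "independence"
    OTHER = "other"


class Direction(str, enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class Period(str, enum.Enum):
    """Trial phases used for adverse-event attribution."""

    BEFORE_REHAB = "before_rehab"
    REHAB_ALONE = "rehab_alone"
    THERAPY = "therapy"


class ValidationError(ValueError):
    """Raised when an input table violates the model's invariants."""


@dataclass(frozen=True)
class OutcomeDefinition:
    """Registry entry for one outcome measure.

    ``mid`` is the responder threshold in outcome units; it is present only for
    the six outcomes with a responder role.  ``scale_min``/``scale_max`` are the
    instrument bounds (``None`` for unbounded force measures).
    """

    name: str
    domain: Domain
    direction: Direction = Direction.HIGHER_IS_BETTER
    mid: float | None = None
    units: str = ""
    scale_min: float | None = None
    scale_max: float | None = None

    def __post_init__(self):
        if self.mid is not None and self.mid < 0:
            raise ValueError(f"{self.name}: MID must be non-negative")
        if (
            self.scale_min is not None
            and self.scale_max is not None
            and self.scale_min >= self.scale_max
        ):
            raise ValueError(f"{self.name}: scale_min must be below scale_max")

    def in_bounds(self, value: float) -> bool:
        if self.scale_min is not None and value < self.scale_min:
            return False
        if self.scale_max is not None and value > self.scale_max:
            return False
        return True


class OutcomeRegistry:
    """Ordered collection of :class:`OutcomeDefinition`, keyed by name."""

    def __init__(self, outcomes: Iterable[OutcomeDefinition] = ()):
        self._outcomes: dict[str, OutcomeDefinition] = {}
        for o in outcomes:
            self.add(o)

    def add(self, outcome: OutcomeDefinition) -> None:
        if outcome.name in self._outcomes:
            raise ValueError(f"duplicate outcome {outcome.name!r}")
        self._outcomes[outcome.name] = outcome

    def __contains__(self, name: str) -> bool:
        return name in self._outcomes

    def __getitem__(self, name: str) -> OutcomeDefinition:
        try:
            return self._outcomes[name]
        except KeyError:
            raise KeyError(f"outcome {name!r} not registered") from None

    def __iter__(self):
        return iter(self._outcomes.values())

    def __len__(self) -> int:
        return len(self._outcomes)

    @property
    def names(self) -> list[str]:
        return list(self._outcomes)

    def mid_outcomes(self, domain: Domain | None = None) -> list[OutcomeDefinition]:
        """Outcomes carrying a responder MID, optionally restricted to a domain."""
        out = [o for o in self if o.mid is not None]
        if domain is not None:
            out = [o for o in out if o.domain is domain]
        return out

    # -- JSON round trip -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = []
        for o in self:
            d = asdict(o)
            d["domain"] = o.domain.value
            d["direction"] = o.direction.value
            payload.append(d)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "OutcomeRegistry":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("["):
                payload = json.loads(text)
            else:
                with open(text, encoding="utf-8") as fh:
                    payload = json.load(fh)
        outcomes = []
        for d in payload:
            outcomes.append(
                OutcomeDefinition(
                    name=d["name"],
                    domain=Domain(d["domain"]),
                    direction=Direction(d["direction"]),
                    mid=d.get("mid"),
                    units=d.get("units", ""),
                    scale_min=d.get("scale_min"),
                    scale_max=d.get("scale_max"),
                )
            )
        return cls(outcomes)


def default_registry() -> OutcomeRegistry:
    """The trial's outcome set.

    Six outcomes carry MIDs and define responder status: four in the strength
    domain (upper-extremity motor score, GRASSP strength, pinch and grasp
    force) and two in the functional-performance domain (GRASSP prehension
    performance and CUE-T).  The remaining outcomes feed the secondary
    hierarchy, the sensory analyses and quality-of-life reporting.
    """
    H, L = Direction.HIGHER_IS_BETTER, Direction.LOWER_IS_BETTER
    return OutcomeRegistry(
        [
            OutcomeDefinition("uems", Domain.STRENGTH, H, mid=2, units="points",
                              scale_min=0, scale_max=50),
            OutcomeDefinition("grassp_strength", Domain.STRENGTH, H, mid=4,
                              units="points", scale_min=0, scale_max=100),
            OutcomeDefinition("pinch_force", Domain.STRENGTH, H, mid=2.4,
                              units="N", scale_min=0),
            OutcomeDefinition("grasp_force", Domain.STRENGTH, H, mid=6,
                              units="N", scale_min=0),
            OutcomeDefinition("grassp_prehension", Domain.FUNCTION, H, mid=2,
                              units="points", scale_min=0, scale_max=60),
            OutcomeDefinition("cue_t", Domain.FUNCTION, H, mid=4,
                              units="points", scale_min=0, scale_max=136),
            OutcomeDefinition("tss", Domain.SENSORY, H, units="points",
                              scale_min=0, scale_max=224),
            OutcomeDefinition("grassp_sensibility", Domain.SENSORY, H,
                              units="points", scale_min=0, scale_max=24),
            OutcomeDefinition("eq5d5l", Domain.QOL, H, units="points",
                              scale_min=0, scale_max=100),
            OutcomeDefinition("scim3", Domain.INDEPENDENCE, H, units="points",
                              scale_min=0, scale_max=100),
            OutcomeDefinition("whoqol_physical", Domain.QOL, H, units="points",
                              scale_min=0, scale_max=100),
            OutcomeDefinition("whoqol_psychological", Domain.QOL, H,
                              units="points", scale_min=0, scale_max=100),
            OutcomeDefinition("whoqol_social", Domain.QOL, H, units="points",
                              scale_min=0, scale_max=100),
            OutcomeDefinition("whoqol_environment", Domain.QOL, H,
                              units="points", scale_min=0, scale_max=100),
            OutcomeDefinition("psfs", Domain.OTHER, L, units="points",
                              scale_min=0, scale_max=4),
            OutcomeDefinition("mos_sleep", Domain.OTHER, L, units="points",
                              scale_min=0, scale_max=100),
            OutcomeDefinition("nrs_pain", Domain.OTHER, L, units="points",
                              scale_min=0, scale_max=10),
        ]
    )


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    age: float
    sex: str
    ais_grade: str
    neuro_level: str
    years_since_injury: float
    sessions_rehab: int
    sessions_therapy: int

    def __post_init__(self):
        if self.ais_grade not in {"B", "C", "D"}:
            raise ValidationError(
                f"participant {self.id}: AIS grade must be B, C or D, got {self.ais_grade!r}"
            )
        if self.sessions_rehab < 0 or self.sessions_therapy < 0:
            raise ValidationError(f"participant {self.id}: negative session count")


@dataclass(frozen=True)
class AssessmentRecord:
    """One outcome value for one participant at one scheduled visit."""

    participant_id: str
    timepoint: Timepoint
    outcome: str
    value: float


@dataclass(frozen=True)
class AdverseEvent:
    participant_id: str
    period: Period
    serious: bool = False
    device_related: bool = False
    procedure_related: bool = False
    led_to_discontinuation: bool = False
    description: str = ""


def filter_mitt(
    profiles: Iterable[ParticipantProfile] | "pandas.DataFrame",
    min_sessions_per_period: int = 24,
) -> list[str]:
    """Modified intention-to-treat filter.

    A participant is analyzable only with at least ``min_sessions_per_period``
    rehabilitation sessions in each of the two study periods (the trial used 24,
    an average of 12 sessions per month).  Accepts either profile objects or a
    profiles DataFrame.
    """
    ids: list[str] = []
    if hasattr(profiles, "itertuples") and hasattr(profiles, "columns"):
        rows = profiles.itertuples(index=False)
        for row in rows:
            if (
                row.sessions_rehab >= min_sessions_per_period
                and row.sessions_therapy >= min_sessions_per_period
            ):
                ids.append(str(row.participant_id))
        return ids
    for p in profiles:
        if (
            p.sessions_rehab >= min_sessions_per_period
            and p.sessions_therapy >= min_sessions_per_period
        ):
            ids.append(p.id)
    return ids
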