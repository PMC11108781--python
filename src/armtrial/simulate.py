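"""Synthetic trial cohorts with the longitudinal structure the analysis assumes.

The generator emulates a 60-participant single-arm trial assessed at
enrollment and monthly for four months: two months of rehabilitation alone,
then two months of combined therapy.  Its default parameters encode the
trial-like effect structure: functional gains that appear in the first month
of rehabilitation and then plateau, and broad strength/function/sensory gains
without plateau during the therapy period.  Between-participant responsiveness
is a shared latent factor, which induces the cross-outcome correlation that
makes composite responders cluster.

Values are drawn as

    value(participant, visit) = baseline + cumulative_gain(visit) * m + noise

with ``baseline`` from a truncated normal within the instrument bounds,
``m = max(0, 1 + subject_sd * z)`` a per-participant responsiveness multiplier
(z shared across outcomes), visit-level Gaussian noise, and the result clipped
to the instrument bounds (a ceiling/floor measurement model).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.optimize import brentq

from .model import (
    Direction,
    OutcomeRegistry,
    Period,
    Timepoint,
    default_registry,
)

_TIMEPOINTS = [tp.name for tp in Timepoint]

#: AIS-grade mix of the analyzed population (B/C/D).
DEFAULT_AIS_MIX = {"B": 0.15, "C": 0.467, "D": 0.383}

_NEURO_LEVELS = ["C2", "C3", "C4", "C5", "C6", "C7", "C8"]
_NEURO_PROBS = [0.15, 0.05, 0.267, 0.217, 0.217, 0.09, 0.009]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeParams:
    """Per-outcome simulation parameters, all in outcome units.

    ``rehab_gain_m1/m2`` are mean improvements over the two months of
    rehabilitation alone (m2 defaults to 0: the plateau); ``therapy_gain_m1/m2``
    the mean improvements over the two therapy months.  ``subject_sd`` scales
    the shared responsiveness factor for this outcome (relative units).
    Lower-is-better outcomes take negative gains for improvement.
    """

    baseline_mean: float
    baseline_sd: float
    rehab_gain_m1: float = 0.0
    rehab_gain_m2: float = 0.0
    therapy_gain_m1: float = 0.0
    therapy_gain_m2: float = 0.0
    noise_sd: float = 0.0
    subject_sd: float = 0.0

    def __post_init__(self):
        if self.baseline_sd < 0 or self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")

    @property
    def cumulative_gains(self) -> np.ndarray:
        return np.cumsum(
            [0.0, self.rehab_gain_m1, self.rehab_gain_m2,
             self.therapy_gain_m1, self.therapy_gain_m2]
        )

    @property
    def therapy_gain_total(self) -> float:
        return self.therapy_gain_m1 + self.therapy_gain_m2


@dataclass(frozen=True)
class AEPeriodParams:
    """Per-period adverse-event generation: a per-participant Poisson event
    rate plus independent flag probabilities per event."""

    rate: float
    serious_p: float = 0.0
    device_related_p: float = 0.0
    procedure_related_p: float = 0.0
    discontinuation_p: float = 0.0

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError("event rate must be non-negative")
        for p in (self.serious_p, self.device_related_p,
                  self.procedure_related_p, self.discontinuation_p):
            if not (0 <= p <= 1):
                raise ConfigurationError("flag probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EffectConfig:
    outcomes: dict[str, OutcomeParams]
    n_participants: int = 60
    ais_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AIS_MIX))
    dropout_rate: float = 0.0
    sessions_range: tuple[int, int] = (24, 40)
    ae_params: dict[str, AEPeriodParams] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be non-negative")
        if not (0 <= self.dropout_rate <= 1):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        total = sum(self.ais_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"ais_mix must sum to 1 (got {total})")
        if self.sessions_range[0] > self.sessions_range[1]:
            raise ConfigurationError("sessions_range must be (low, high)")

    def replace(self, **kwargs) -> "EffectConfig":
        return dataclasses.replace(self, **kwargs)

    def replace_outcome(self, name: str, **kwargs) -> "EffectConfig":
        outcomes = dict(self.outcomes)
        outcomes[name] = dataclasses.replace(outcomes[name], **kwargs)
        return self.replace(outcomes=outcomes)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "ais_mix": dict(self.ais_mix),
            "dropout_rate": self.dropout_rate,
            "sessions_range": list(self.sessions_range),
            "seed": self.seed,
            "outcomes": {k: dataclasses.asdict(v) for k, v in self.outcomes.items()},
            "ae_params": {k: dataclasses.asdict(v) for k, v in self.ae_params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        return cls(
            outcomes={k: OutcomeParams(**v) for k, v in d.get("outcomes", {}).items()},
            n_participants=d.get("n_participants", 60),
            ais_mix=d.get("ais_mix", dict(DEFAULT_AIS_MIX)),
            dropout_rate=d.get("dropout_rate", 0.0),
            sessions_range=tuple(d.get("sessions_range", (24, 40))),
            ae_params={k: AEPeriodParams(**v) for k, v in d.get("ae_params", {}).items()},
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_file(cls, path) -> "EffectConfig":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(seed: int = 0) -> EffectConfig:
    """The calibrated trial-like configuration shipped with the package."""
    ref = importlib.resources.files("armtrial").joinpath("data/default_cohort.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    cfg = EffectConfig.from_dict(data)
    return cfg.replace(seed=seed)


def null_calibrated(
    target_rate: float = 0.5,
    n_participants: int = 60,
    seed: int = 0,
    registry: OutcomeRegistry | None = None,
) -> EffectConfig:
    """A no-effect configuration whose composite responder rate is exactly
    ``target_rate`` per participant, by construction.

    All gains and the shared responsiveness factor are zero, so per-outcome
    window changes are independent N(0, 2 * noise_sd^2).  With a common
    per-outcome hit probability q, the composite probability over 4 strength
    and 2 function outcomes is (1-(1-q)^4)(1-(1-q)^2); q is solved for the
    target and each noise_sd is back-calculated from the outcome's MID.
    Baselines sit mid-scale so bound truncation is negligible.
    """
    registry = registry or default_registry()
    ns = len([o for o in registry.mid_outcomes() if o.domain.value == "strength"])
    nf = len([o for o in registry.mid_outcomes() if o.domain.value == "function"])

    def composite(q):
        return (1 - (1 - q) ** ns) * (1 - (1 - q) ** nf) - target_rate

    q = brentq(composite, 1e-9, 1 - 1e-9)
    z = sps.norm.ppf(1 - q)
    if z <= 0:
        raise ConfigurationError("target rate too high for a pure-noise null")

    mids = {"uems": (25.0, 5.0), "grassp_strength": (50.0, 8.0),
            "pinch_force": (30.0, 5.0), "grasp_force": (80.0, 10.0),
            "grassp_prehension": (30.0, 5.0), "cue_t": (70.0, 10.0)}
    outcomes = {}
    for o in registry.mid_outcomes():
        mean, bsd = mids.get(o.name, (o.scale_max / 2 if o.scale_max else 50.0, 5.0))
        outcomes[o.name] = OutcomeParams(
            baseline_mean=mean, baseline_sd=bsd,
            noise_sd=float(o.mid / (np.sqrt(2.0) * z)), subject_sd=0.0,
        )
    return EffectConfig(outcomes=outcomes, n_participants=n_participants, seed=seed)


# -- generation ---------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: EffectConfig, registry: OutcomeRegistry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic trial; returns (profiles, assessments) frames.

    Deterministic for a fixed ``config.seed``.  Only outcomes present in
    ``config.outcomes`` are generated; bounds are looked up in the registry.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    width = max(2, len(str(max(n, 1))))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    grades = list(config.ais_mix)
    probs = np.array([config.ais_mix[g] for g in grades], dtype=float)
    profiles = pd.DataFrame(
        {
            "participant_id": ids,
            "age": np.round(np.clip(rng.normal(47.2, 15.5, n), 22, 75), 1),
            "sex": rng.choice(["F", "M"], size=n, p=[0.17, 0.83]),
            "ais_grade": rng.choice(grades, size=n, p=probs / probs.sum()),
            "neuro_level": rng.choice(_NEURO_LEVELS, size=n, p=_NEURO_PROBS),
            "years_since_injury": np.round(
                np.clip(rng.lognormal(1.4, 0.8, n), 1.0, 34.0), 1
            ),
            "sessions_rehab": rng.integers(
                config.sessions_range[0], config.sessions_range[1] + 1, n
            ),
            "sessions_therapy": rng.integers(
                config.sessions_range[0], config.sessions_range[1] + 1, n
            ),
        }
    )

    z = rng.standard_normal(n)  # shared responsiveness factor

    frames = []
    for name, params in config.outcomes.items():
        if name not in registry:
            raise ConfigurationError(f"outcome {name!r} not in registry")
        o = registry[name]
        baseline = _truncnorm(
            rng, params.baseline_mean, params.baseline_sd, o.scale_min, o.scale_max, n
        )
        mult = np.maximum(0.0, 1.0 + params.subject_sd * z)
        noise = (
            rng.normal(0.0, params.noise_sd, size=(n, 5))
            if params.noise_sd > 0
            else np.zeros((n, 5))
        )
        values = baseline[:, None] + params.cumulative_gains[None, :] * mult[:, None] + noise
        if o.scale_min is not None or o.scale_max is not None:
            values = np.clip(
                values,
                o.scale_min if o.scale_min is not None else -np.inf,
                o.scale_max if o.scale_max is not None else np.inf,
            )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids, 5),
                    "timepoint": np.tile(_TIMEPOINTS, n),
                    "outcome": name,
                    "value": values.ravel(),
                }
            )
        )

    if frames:
        assessments = pd.concat(frames, ignore_index=True)
    else:
        assessments = pd.DataFrame(
            columns=["participant_id", "timepoint", "outcome", "value"]
        )
    return profiles, assessments


def apply_dropout(
    profiles: pd.DataFrame,
    assessments: pd.DataFrame,
    rate: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independently drop participants with the given probability.

    A dropped participant keeps visits only up to a uniformly chosen
    truncation visit (enrollment through the penultimate visit); their profile
    is retained (they were enrolled).  Deterministic for a fixed seed.
    """
    if not (0 <= rate <= 1):
        raise ValueError("dropout rate must lie in [0, 1]")
    ids = profiles["participant_id"].tolist()
    rng = np.random.default_rng(seed)
    dropped = rng.random(len(ids)) < rate
    truncation = rng.integers(0, len(_TIMEPOINTS) - 1, size=len(ids))
    keep_until = {
        pid: (int(t) if d else len(_TIMEPOINTS) - 1)
        for pid, d, t in zip(ids, dropped, truncation)
    }
    ordinal = assessments["timepoint"].map(lambda s: Timepoint[s].value)
    limit = assessments["participant_id"].map(keep_until)
    kept = assessments[ordinal <= limit].reset_index(drop=True)
    return profiles.copy(), kept


def generate_adverse_events(
    profiles: pd.DataFrame,
    ae_params: dict[str, AEPeriodParams],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant Poisson event counts per trial period with flagged
    attributes; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    rows = []
    ids = profiles["participant_id"].tolist()
    for period in [p.value for p in Period]:
        params = ae_params.get(period)
        if params is None or params.rate == 0:
            continue
        counts = rng.poisson(params.rate, size=len(ids))
        for pid, k in zip(ids, counts):
            for _ in range(int(k)):
                rows.append(
                    {
                        "participant_id": pid,
                        "period": period,
                        "serious": bool(rng.random() < params.serious_p),
                        "device_related": bool(rng.random() < params.device_related_p),
                        "procedure_related": bool(
                            rng.random() < params.procedure_related_p
                        ),
                        "led_to_discontinuation": bool(
                            rng.random() < params.discontinuation_p
                        ),
                        "description": "synthetic adverse event",
                    }
                )
    columns = [
        "participant_id", "period", "serious", "device_related",
        "procedure_related", "led_to_discontinuation", "description",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
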