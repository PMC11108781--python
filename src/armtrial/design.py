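"""Design calculations for the single-arm responder trial, plus the safety
tabulation.

The design tests the responder proportion against a fixed performance goal
p0 with a one-sided exact binomial test.  Sample size follows the one-sample
normal-approximation formula

    n = ceil( (z_{1-a} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1))^2 / (p1 - p0)^2 )

with a = alpha_two_sided / 2, inflated multiplicatively for dropout:
n_enrolled = round(n * (1 + dropout)).  The exact alternative searches for the
smallest n whose exact-binomial power meets the target.  Note the
multiplicative inflation convention (not division by 1 - dropout): with the
default parameters it yields 52 evaluable and 65 enrolled participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Period

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignParams:
    power_target: float = 0.80
    alpha_two_sided: float = 0.10
    p0: float = 0.50  # performance goal
    p1: float = 0.67  # assumed responder rate
    dropout: float = 0.25

    def __post_init__(self):
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1):
            raise ValueError("p0 and p1 must lie in (0, 1)")
        if self.p1 <= self.p0:
            raise ValueError("design undefined unless p1 > p0")
        if not (0 < self.alpha_two_sided < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")


def sample_size(params: DesignParams, method: str = "normal_approx") -> tuple[int, int]:
    """(n_evaluable, n_enrolled) for the one-sample responder design."""
    if method == "normal_approx":
        alpha = params.alpha_two_sided / 2.0
        z_a = sps.norm.ppf(1 - alpha)
        z_b = sps.norm.ppf(params.power_target)
        p0, p1 = params.p0, params.p1
        num = (z_a * math.sqrt(p0 * (1 - p0)) + z_b * math.sqrt(p1 * (1 - p1))) ** 2
        n_eval = math.ceil(num / (p1 - p0) ** 2)
    elif method == "exact":
        alpha = params.alpha_two_sided / 2.0
        n_eval = None
        for n in range(2, 10_000):
            _, power = exact_power(n, params.p0, params.p1, alpha, warn=False)
            if power >= params.power_target:
                n_eval = n
                break
        if n_eval is None:
            raise RuntimeError("no n <= 10000 reaches the target power")
    else:
        raise ValueError(f"unknown method {method!r}")
    n_enrolled = round(n_eval * (1 + params.dropout))
    return n_eval, n_enrolled


def exact_power(n: int, p0: float, p1: float,
                alpha_one_sided: float, warn: bool = True) -> tuple[int, float]:
    """Critical value and power of the one-sided exact binomial test.

    critical_k is the smallest k with P(X >= k | n, p0) <= alpha; power is
    P(X >= critical_k | n, p1), both by exact tail summation.  When no k
    satisfies the size constraint (tiny n), critical_k = n + 1 and power 0.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    k_values = np.arange(n + 2)
    # sf(k-1) = P(X >= k)
    tail0 = sps.binom.sf(k_values - 1, n, p0)
    ok = np.nonzero(tail0 <= alpha_one_sided)[0]
    if len(ok) == 0 or ok[0] > n:
        if warn:
            logger.warning("n=%d too small for size %.3g; power is 0",
                           n, alpha_one_sided)
        return n + 1, 0.0
    critical_k = int(ok[0])
    power = float(sps.binom.sf(critical_k - 1, n, p1))
    return critical_k, power


AE_CATEGORIES = [
    ("any", lambda df: pd.Series(True, index=df.index)),
    ("serious", lambda df: df["serious"]),
    ("device_related", lambda df: df["device_related"]),
    ("serious_device_related", lambda df: df["serious"] & df["device_related"]),
    ("procedure_related", lambda df: df["procedure_related"]),
    ("led_to_discontinuation", lambda df: df["led_to_discontinuation"]),
]

_PERIOD_ORDER = [Period.BEFORE_REHAB.value, Period.REHAB_ALONE.value, Period.THERAPY.value]


@dataclass(frozen=True)
class AdverseEventTable:
    """Safety tabulation: participants with >= 1 event per category and period
    (with percentages of the safety population) plus total event counts."""

    participants: pd.DataFrame  # categories x (periods + any_time)
    percentages: pd.DataFrame
    total_events: pd.Series  # per period + any_time
    n_safety: int


def tabulate_adverse_events(events: pd.DataFrame, n_safety: int) -> AdverseEventTable:
    """Build the safety overview from a long adverse-event table.

    Counts are participants with at least one qualifying event (never event
    counts), tallied per period and over any time; the final row of the
    rendered safety table is the total number of events.
    """
    cols = _PERIOD_ORDER + ["any_time"]
    counts = pd.DataFrame(0, index=[c for c, _ in AE_CATEGORIES], columns=cols)
    totals = pd.Series(0, index=cols)
    if len(events):
        bad = set(events["period"]) - set(_PERIOD_ORDER)
        if bad:
            raise ValueError(f"unknown adverse-event period(s): {sorted(bad)}")
        for cat, selector in AE_CATEGORIES:
            mask = selector(events)
            sub = events[mask]
            for period in _PERIOD_ORDER:
                counts.loc[cat, period] = sub.loc[
                    sub["period"] == period, "participant_id"
                ].nunique()
            counts.loc[cat, "any_time"] = sub["participant_id"].nunique()
        for period in _PERIOD_ORDER:
            totals[period] = int((events["period"] == period).sum())
        totals["any_time"] = int(len(events))
    pct = counts / n_safety * 100.0 if n_safety else counts * np.nan
    return AdverseEventTable(
        participants=counts, percentages=pct, total_events=totals, n_safety=n_safety
    )
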