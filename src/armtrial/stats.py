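"""Confirmatory statistics for the responder design.

* one-sided exact binomial test of the responder rate against a performance
  goal (the primary endpoint)
* exact McNemar test on the conversion table's discordant pairs
* paired one-sided secondary tests with a Shapiro-Wilk normality gate choosing
  between the paired t-test and the Wilcoxon signed-rank test
* fixed-sequence (gatekeeping) testing of the ordered secondary endpoints:
  each endpoint is tested at full alpha, and the first failure halts the
  sequence so downstream endpoints are never tested
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .model import Direction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinomialTestResult:
    successes: int
    n: int
    p0: float
    p_value: float
    alternative: str = "greater"


@dataclass(frozen=True)
class PairedTestResult:
    endpoint: str
    n: int
    mean_diff: float
    sd_diff: float
    ci90: tuple[float, float]
    method: str  # "paired_t" | "wilcoxon_signed_rank"
    p_value: float
    normality_p: float


@dataclass(frozen=True)
class HierarchyReport:
    ordered_endpoints: list[str]
    results: list[PairedTestResult | None]
    tested: list[bool]
    passed: list[bool]
    halt_index: int | None

    def as_rows(self) -> list[dict]:
        rows = []
        for name, res, t, p in zip(
            self.ordered_endpoints, self.results, self.tested, self.passed
        ):
            rows.append(
                {
                    "endpoint": name,
                    "tested": t,
                    "passed": p,
                    "p_value": res.p_value if (t and res is not None) else None,
                    "mean_diff": res.mean_diff if res is not None else None,
                    "sd_diff": res.sd_diff if res is not None else None,
                    "ci90": res.ci90 if res is not None else None,
                    "method": res.method if (t and res is not None) else None,
                }
            )
        return rows


def exact_binomial_test(successes: int, n: int, p0: float) -> BinomialTestResult:
    """Upper-tail exact binomial test of H0: p <= p0 vs H1: p > p0.

    The p-value is the exact tail sum P(X >= successes | n, p0); no normal
    approximation is involved.
    """
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    if not (0 < p0 < 1):
        raise ValueError("performance goal p0 must lie strictly in (0, 1)")
    p_value = float(sps.binom.sf(successes - 1, n, p0))
    return BinomialTestResult(successes=successes, n=n, p0=p0, p_value=p_value)


def mcnemar_exact(discordant_b: int, discordant_c: int) -> float:
    """Two-sided exact McNemar p-value from the discordant-pair counts.

    Conditional on b + c discordant pairs, the smaller count is Binomial(b+c,
    1/2) under marginal homogeneity; p = min(1, 2 P(X <= min(b, c))).  The
    concordant cells are irrelevant.  Returns 1.0 when there are no discordant
    pairs.
    """
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = discordant_b + discordant_c
    if m == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(discordant_b, discordant_c), m, 0.5)))


def summarize_change(differences) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD and two-sided t-based 90% CI of a change vector."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(d.size)
    tq = float(sps.t.ppf(0.95, d.size - 1))
    return mean, sd, (mean - tq * se, mean + tq * se)


def paired_one_sided(
    differences,
    direction: Direction | str = Direction.HIGHER_IS_BETTER,
    normality_alpha: float = 0.05,
    endpoint: str = "",
) -> PairedTestResult:
    """One-sided paired test of improvement, with a normality gate.

    Shapiro-Wilk on the differences decides the branch: paired t-test when
    normality is not rejected at ``normality_alpha``, Wilcoxon signed-rank
    otherwise.  The alternative is "mean difference > 0" for higher-is-better
    endpoints and "< 0" for lower-is-better ones.  A two-sided t-based 90% CI
    on the mean difference is reported alongside either branch.

    Wilcoxon branch: zero differences are dropped; the exact null distribution
    is used for n <= 25 and the normal approximation with continuity
    correction beyond that.  A zero-variance vector is degenerate for both
    Shapiro-Wilk and the t-test and falls through to the exact signed-rank
    branch (all signs identical).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 paired differences")
    direction = Direction(direction)
    if direction is Direction.LOWER_IS_BETTER:
        d = -d  # improvement is now always "greater than zero"

    mean, sd, ci = summarize_change(d)
    if direction is Direction.LOWER_IS_BETTER:
        mean, sd, ci = -mean, sd, (-ci[1], -ci[0])

    if np.ptp(d) == 0.0:
        # all differences identical: no normality decision possible
        normality_p = float("nan")
        method = "wilcoxon_signed_rank"
        p_value = _wilcoxon_greater(d)
    else:
        normality_p = float(sps.shapiro(d).pvalue)
        if normality_p >= normality_alpha:
            method = "paired_t"
            p_value = float(sps.ttest_1samp(d, 0.0, alternative="greater").pvalue)
        else:
            method = "wilcoxon_signed_rank"
            p_value = _wilcoxon_greater(d)

    return PairedTestResult(
        endpoint=endpoint, n=int(d.size), mean_diff=mean, sd_diff=sd, ci90=ci,
        method=method, p_value=p_value, normality_p=normality_p,
    )


def _wilcoxon_greater(d: np.ndarray) -> float:
    nz = d[d != 0.0]
    if nz.size == 0:
        return 1.0
    if np.ptp(nz) == 0.0:
        # identical nonzero differences: exact signed-rank tail in closed form
        p_all_same_sign = 0.5 ** nz.size
        return float(p_all_same_sign if nz[0] > 0 else 1.0)
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(
        nz, alternative="greater", method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


def run_hierarchy(
    endpoint_order: list[str],
    differences_by_endpoint: dict,
    alpha: float = 0.05,
    directions: dict | None = None,
    normality_alpha: float = 0.05,
) -> HierarchyReport:
    """Fixed-sequence testing of the ordered secondary endpoints.

    Each endpoint supplies the per-participant paired differences (the change
    from enrollment to end of therapy minus the change from enrollment to end
    of rehabilitation alone, which telescopes to the change over the therapy
    period).  Endpoints are tested in order at full ``alpha``; testing halts at
    the first p >= alpha.  Endpoints after the halt are reported untested with
    no p-value.  An endpoint with insufficient data counts as a failure and
    halts the sequence.
    """
    if not endpoint_order:
        raise ValueError("endpoint order must be non-empty")
    directions = directions or {}
    results: list[PairedTestResult | None] = []
    tested: list[bool] = []
    passed: list[bool] = []
    halt_index: int | None = None

    for i, name in enumerate(endpoint_order):
        if halt_index is not None:
            # untested, but descriptive summary still useful for reporting
            results.append(_describe_only(name, differences_by_endpoint.get(name)))
            tested.append(False)
            passed.append(False)
            continue
        diffs = differences_by_endpoint.get(name)
        if diffs is None or len(np.atleast_1d(np.asarray(diffs, float))) < 3:
            logger.warning(
                "hierarchy endpoint %s has insufficient data; treated as failed", name
            )
            results.append(_describe_only(name, diffs))
            tested.append(True)
            passed.append(False)
            halt_index = i
            continue
        res = paired_one_sided(
            diffs,
            direction=directions.get(name, Direction.HIGHER_IS_BETTER),
            normality_alpha=normality_alpha,
            endpoint=name,
        )
        results.append(res)
        tested.append(True)
        ok = res.p_value < alpha
        passed.append(ok)
        if not ok:
            halt_index = i

    return HierarchyReport(
        ordered_endpoints=list(endpoint_order),
        results=results,
        tested=tested,
        passed=passed,
        halt_index=halt_index,
    )


def _describe_only(name: str, diffs) -> PairedTestResult | None:
    if diffs is None:
        return None
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        return None
    mean, sd, ci = summarize_change(d)
    return PairedTestResult(
        endpoint=name, n=int(d.size), mean_diff=mean, sd_diff=sd, ci90=ci,
        method="", p_value=float("nan"), normality_p=float("nan"),
    )
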