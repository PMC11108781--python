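"""Monthly time-course analysis and baseline-cutoff discovery.

* one-way repeated-measures ANOVA (subject as blocking factor, uncorrected)
  with Tukey HSD pairwise comparisons of visit means on the within-subject
  error term
* the plateau contrast: a paired one-sided test of change between the first
  and second month of rehabilitation alone
* the sequential odds-ratio threshold scan identifying the lowest baseline
  value still enriched for responders
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

from .model import OutcomeRegistry, Timepoint
from .responders import ChangeWindow
from .stats import PairedTestResult, paired_one_sided

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TukeyPair:
    level_a: str
    level_b: str
    mean_diff: float
    q_stat: float
    p_adj: float


@dataclass(frozen=True)
class RmAnovaResult:
    outcome: str
    f_stat: float
    df_time: int
    df_error: int
    p_value: float
    ss_time: float
    ss_error: float
    tukey_pairs: list[TukeyPair]


@dataclass(frozen=True)
class ThresholdScanResult:
    outcome: str
    grid: np.ndarray  # strictly increasing candidate thresholds
    odds_ratios: np.ndarray  # aligned with grid
    cutoff: float | None
    halted_at: float | None  # grid value where the scan crossed OR <= 1


def greenhouse_geisser_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance of
    the timepoint columns; ranges from 1/(k-1) (maximal violation) to 1."""
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    mean_all = s.mean()
    mean_diag = np.trace(s) / k
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def rm_anova_tukey(values, timepoint_labels: list[str] | None = None,
                   outcome: str = "",
                   sphericity_correction: bool = False) -> RmAnovaResult:
    """One-way within-subject ANOVA with Tukey HSD on the visit means.

    ``values`` is a complete participants x timepoints matrix (DataFrame or
    ndarray); every participant must have all visits.  The ANOVA blocks on
    subject and by default applies no sphericity correction; with
    ``sphericity_correction`` the p-value uses Greenhouse-Geisser adjusted
    degrees of freedom (the F statistic is unchanged).  Tukey HSD uses the
    within-subject error mean square and studentized-range quantiles with
    (k, df_error) degrees of freedom.
    """
    if isinstance(values, pd.DataFrame):
        if values.isna().any().any():
            bad = values.index[values.isna().any(axis=1)].tolist()
            raise ValueError(f"incomplete matrix; participants with missing visits: {bad}")
        labels = [str(c) for c in values.columns]
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if np.isnan(x).any():
            bad = np.where(np.isnan(x).any(axis=1))[0].tolist()
            raise ValueError(f"incomplete matrix; rows with missing visits: {bad}")
        labels = timepoint_labels or [f"t{j}" for j in range(x.shape[1])]
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 timepoints and 3 participants")

    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_time = n * float(((col_means - grand) ** 2).sum())
    ss_subj = k * float(((row_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_time - ss_subj, 0.0)
    df_time, df_err = k - 1, (k - 1) * (n - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err

    if ss_time == 0.0:
        f_stat, p_value = 0.0, 1.0
    elif ms_err == 0.0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = ms_time / ms_err
        if sphericity_correction:
            eps = greenhouse_geisser_epsilon(x)
            p_value = float(sps.f.sf(f_stat, eps * df_time, eps * df_err))
        else:
            p_value = float(sps.f.sf(f_stat, df_time, df_err))

    pairs = []
    se = np.sqrt(ms_err / n)
    for i, j in combinations(range(k), 2):
        diff = float(col_means[j] - col_means[i])
        if se == 0.0:
            q = float("inf") if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p_adj = float(studentized_range.sf(q, k, df_err))
        pairs.append(TukeyPair(labels[i], labels[j], diff, q, min(p_adj, 1.0)))

    return RmAnovaResult(
        outcome=outcome, f_stat=float(f_stat), df_time=df_time, df_error=df_err,
        p_value=float(p_value), ss_time=ss_time, ss_error=ss_err, tukey_pairs=pairs,
    )


def visit_matrix(assessments: pd.DataFrame, outcome: str,
                 completers_only: bool = True) -> pd.DataFrame:
    """Participants x timepoints value matrix for one outcome, visit-ordered."""
    sub = assessments[assessments["outcome"] == outcome]
    wide = sub.pivot_table(index="participant_id", columns="timepoint",
                           values="value", aggfunc="first")
    order = [tp.name for tp in Timepoint if tp.name in wide.columns]
    wide = wide[order]
    if completers_only:
        wide = wide.dropna()
    return wide


def plateau_contrast(assessments: pd.DataFrame, outcome: str,
                     registry: OutcomeRegistry | None = None) -> PairedTestResult:
    """Paired one-sided test of change between months 1 and 2 of
    rehabilitation alone (the plateau check)."""
    window = ChangeWindow(Timepoint.REHAB_M1, Timepoint.REHAB_END)
    wide = visit_matrix(assessments, outcome, completers_only=False)
    for tp in (window.start.name, window.end.name):
        if tp not in wide.columns:
            raise ValueError(f"outcome {outcome!r} has no {tp} visit")
    diffs = (wide[window.end.name] - wide[window.start.name]).dropna().to_numpy()
    direction = registry[outcome].direction if registry is not None else "higher_is_better"
    return paired_one_sided(diffs, direction=direction, endpoint=outcome)


def make_grid(values, step: float = 1.0) -> np.ndarray:
    """Candidate thresholds at the given step within the observed range.

    Thresholds at or below the observed minimum are excluded: ``baseline >= t``
    would place every participant in one group, so such a threshold defines no
    binarization.
    """
    v = np.asarray(values, dtype=float)
    lo = np.ceil(v.min() / step) * step
    if lo <= v.min():
        lo += step
    hi = np.floor(v.max() / step) * step
    if hi < lo:
        return np.array([lo])
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def sequential_or_scan(
    baseline_values,
    responder_flags,
    grid,
    outcome: str = "",
) -> ThresholdScanResult:
    """Sequential odds-ratio scan for a baseline responder cutoff.

    For each threshold t (scanned in descending order) participants are
    binarized into baseline >= t versus < t and the odds ratio of responding
    given >= t is computed from the 2x2 table, with the Haldane-Anscombe 0.5
    correction whenever a cell is empty.  The scan halts at the first
    threshold where the odds ratio crosses 1 (OR <= 1); the cutoff is the last
    threshold scanned with OR > 1.  If the odds ratio never crosses 1 over the
    grid — the generic outcome when response increases monotonically with
    baseline — the cutoff is the threshold of peak enrichment (maximal OR,
    ties resolved to the lowest threshold).

    Returns the full OR profile over the grid for reporting, the cutoff, and
    the grid value at which the scan halted (if it did).
    """
    x = np.asarray(baseline_values, dtype=float)
    flags = np.asarray(responder_flags, dtype=bool)
    if x.shape != flags.shape:
        raise ValueError("baseline values and responder flags must align")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing vector")

    if flags.all() or (~flags).all():
        logger.warning(
            "outcome %s: all participants share one responder status; no scan possible",
            outcome,
        )
        return ThresholdScanResult(
            outcome=outcome, grid=grid,
            odds_ratios=np.full(len(grid), np.nan), cutoff=None, halted_at=None,
        )

    ors = np.empty(len(grid))
    for idx, t in enumerate(grid):
        above = x >= t
        a = float(np.sum(above & flags))
        b = float(np.sum(above & ~flags))
        c = float(np.sum(~above & flags))
        d = float(np.sum(~above & ~flags))
        if min(a, b, c, d) == 0.0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        ors[idx] = (a * d) / (b * c)

    cutoff: float | None = None
    halted_at: float | None = None
    for idx in range(len(grid) - 1, -1, -1):  # descending scan
        if ors[idx] <= 1.0:
            halted_at = float(grid[idx])
            break
        cutoff = float(grid[idx])
    else:
        # never crossed 1: report the threshold of peak enrichment
        peak = int(np.argmax(ors))  # argmax returns the first (lowest) on ties
        cutoff = float(grid[peak])

    return ThresholdScanResult(
        outcome=outcome, grid=grid, odds_ratios=ors, cutoff=cutoff, halted_at=halted_at,
    )
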