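"""Reaction-time pipeline: block medians, paired tests, equivalence, sub-blocks.

Per participant and block the median RT of correct, responded trials is
computed; subtracting the pre-stimulation baseline block gives a practice-
corrected ΔRT per block.  ΔRT is compared between conditions with
one-tailed paired t-tests (directional hypothesis: anodal stimulation
speeds responses) reported with Cohen's dz = mean(diff)/sd(diff).
Baseline equivalence between sessions is assessed with the two one-sided
tests (TOST) procedure on dz bounds, using the closed forms
t_lower = (dz + bound)·sqrt(n) and t_upper = (dz - bound)·sqrt(n) on
n - 1 degrees of freedom.  An exploratory time course bootstraps the
median RT per 10-trial sub-block, reusing the bootstrap-band and
window-detection machinery of :mod:`shamblind.blinding`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blinding import DistinctWindows, compute_bands, find_distinct_windows
from .protocol import TASK_DESIGN, TaskDesign

__all__ = [
    "BlockSummaries",
    "block_medians",
    "PairedTestResult",
    "paired_t_one_tailed",
    "TOSTResult",
    "tost_paired",
    "AccuracySummary",
    "accuracy_summary",
    "SubblockTimecourse",
    "subblock_timecourse",
]


@dataclass(frozen=True)
class BlockSummaries:
    """Per participant x condition x block median RT and baseline-corrected ΔRT."""

    table: pd.DataFrame  # columns: participant_id, condition, block, median_rt_ms, delta_rt_ms
    flagged: list[tuple[str, str, int]]  # (participant, condition, block) with no usable trials


def block_medians(trials: pd.DataFrame) -> BlockSummaries:
    """Median RT of correct, responded trials per participant, condition, block.

    ΔRT for blocks >= 2 subtracts the same session's block-1 median; blocks
    without any usable trial are flagged and carry NaN.
    """
    usable = trials[trials["correct"].astype(bool) & trials["rt_ms"].notna()]
    med = (usable.groupby(["participant_id", "condition", "block"], sort=True)["rt_ms"]
           .median().rename("median_rt_ms"))
    full_index = pd.MultiIndex.from_product(
        [trials["participant_id"].unique(), trials["condition"].unique(), [1, 2, 3, 4]],
        names=["participant_id", "condition", "block"])
    # keep only participant x condition cells actually present in the data
    present = pd.MultiIndex.from_frame(
        trials[["participant_id", "condition"]].drop_duplicates())
    full_index = full_index[full_index.droplevel("block").isin(present)]
    med = med.reindex(full_index)
    table = med.reset_index()
    baseline = table[table["block"] == 1].set_index(["participant_id", "condition"])["median_rt_ms"]
    base = pd.MultiIndex.from_frame(table[["participant_id", "condition"]]).map(baseline)
    delta = table["median_rt_ms"] - np.asarray(base, dtype=float)
    delta[table["block"] == 1] = np.nan
    table["delta_rt_ms"] = delta
    flagged = [tuple(r) for r in table.loc[table["median_rt_ms"].isna(),
                                           ["participant_id", "condition", "block"]].itertuples(index=False)]
    return BlockSummaries(table=table, flagged=flagged)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    dz: float
    tail: str


def _paired_diff(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    return d, sd


def paired_t_one_tailed(delta_active, delta_sham,
                        alternative: str = "active_faster") -> PairedTestResult:
    """One-tailed paired t-test of ΔRT between conditions.

    The test statistic is computed on d = sham - active, so anodal
    facilitation (active faster, hence smaller ΔRT) yields a positive t and
    ``p = P(T >= t)`` under ``alternative="active_faster"``.
    ``alternative="two_sided"`` gives the conventional two-tailed test.
    """
    d, sd = _paired_diff(delta_sham, delta_active)
    n = d.size
    dz = float(d.mean() / sd)
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    if alternative == "active_faster":
        p = float(stats.t.sf(t, df))
        tail = "one_tailed"
    elif alternative == "two_sided":
        p = float(2.0 * stats.t.sf(abs(t), df))
        tail = "two_tailed"
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PairedTestResult(t=t, df=df, p=p, dz=dz, tail=tail)


@dataclass(frozen=True)
class TOSTResult:
    dz_observed: float
    bound_dz: float
    t_lower: float
    t_upper: float
    df: int
    p_lower: float
    p_upper: float
    p: float
    alpha: float
    equivalent: bool


def tost_paired(x, y, bound_dz: float, alpha: float = 0.05) -> TOSTResult:
    """Two one-sided paired equivalence tests on Cohen's dz bounds.

    Tests H0: |dz| >= bound_dz against equivalence, with
    t_lower = (dz + bound)·sqrt(n) and t_upper = (dz - bound)·sqrt(n) on
    n - 1 df.  The TOST p-value is the larger of the two one-sided
    p-values; equivalence is declared when it falls below ``alpha``.
    """
    if bound_dz <= 0:
        raise ValueError("bound_dz must be positive")
    d, sd = _paired_diff(x, y)
    n = d.size
    dz = float(d.mean() / sd)
    rt_n = np.sqrt(n)
    t_lower = float((dz + bound_dz) * rt_n)
    t_upper = float((dz - bound_dz) * rt_n)
    df = n - 1
    p_lower = float(stats.t.sf(t_lower, df))   # H0: dz <= -bound
    p_upper = float(stats.t.cdf(t_upper, df))  # H0: dz >= +bound
    p = max(p_lower, p_upper)
    return TOSTResult(dz_observed=dz, bound_dz=float(bound_dz), t_lower=t_lower,
                      t_upper=t_upper, df=df, p_lower=p_lower, p_upper=p_upper,
                      p=p, alpha=alpha, equivalent=bool(p < alpha))


@dataclass(frozen=True)
class AccuracySummary:
    percent: float
    ci_lo: float
    ci_hi: float
    n_participants: int


def accuracy_summary(trials: pd.DataFrame, n_boot: int = 5000, level: float = 0.95,
                     seed: int = 0) -> AccuracySummary:
    """Group mean of per-participant accuracy (%) with a percentile-bootstrap CI.

    Non-responses count as errors (the task is forced-choice with a
    deadline).  Participants are the resampling unit.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    acc = trials.groupby("participant_id", sort=True)["correct"].mean().to_numpy(float) * 100.0
    n = acc.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = acc[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return AccuracySummary(percent=float(acc.mean()), ci_lo=float(lo), ci_hi=float(hi),
                           n_participants=n)


@dataclass(frozen=True)
class SubblockTimecourse:
    bands: pd.DataFrame
    windows: DistinctWindows


def subblock_timecourse(trials: pd.DataFrame, n_boot: int = 5000, level: float = 0.95,
                        seed: int = 0, design: TaskDesign = TASK_DESIGN) -> SubblockTimecourse:
    """Bootstrap median-RT bands per 10-trial sub-block and their non-overlap windows.

    Sub-blocks are indexed on the probe grid (sub-block k at k x 30 s), so
    the distinct-window machinery of the blinding analysis applies verbatim.
    """
    task = trials[(trials["subblock"] >= 1) & trials["correct"].astype(bool)
                  & trials["rt_ms"].notna()]
    per = (task.groupby(["participant_id", "condition", "subblock"], sort=True)["rt_ms"]
           .median().rename("median_rt_ms").reset_index())
    per["time_s"] = per["subblock"] * design.probe_interval_s
    bands = compute_bands(per, value_col="median_rt_ms", time_col="time_s",
                          n_boot=n_boot, level=level, seed=seed)
    conditions = sorted(bands["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conditions}")
    windows = find_distinct_windows(bands[bands["condition"] == conditions[0]],
                                    bands[bands["condition"] == conditions[1]])
    return SubblockTimecourse(bands=bands, windows=windows)
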