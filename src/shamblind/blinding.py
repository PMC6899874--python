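"""Sham-blinding time-course analysis.

Each in-task probe pair ("Is the stimulation on?" x "How sure are you?")
is collapsed into a signed *weighted score*: +1 for "yes" and -1 for "no",
multiplied by the 0-10 confidence, so +10 means certain-on and -10
certain-off.  Per condition and probe time, the group median score is
summarised with a percentile-bootstrap confidence interval over
participants (default 5,000 resamples, 95% level).  Probes at which the
active and sham intervals do not overlap are merged into *distinct
windows*; their summed span, expressed as a fraction of the difference in
total current-on time between protocols, quantifies how much of the
nominally hidden stimulation-time difference was in fact perceptible.

The module also provides the per-individual binomial logistic fit of
answer on time with an explicit failure taxonomy (non-convergence,
slope indistinguishable from zero, crossover outside the task window,
single-valued responses), formalising why a per-participant 50/50
crossover-time estimate may be unavailable for noisy switchers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .protocol import StimulationProtocol

__all__ = [
    "weighted_score",
    "add_weighted_scores",
    "BootstrapCI",
    "bootstrap_band",
    "compute_bands",
    "DistinctWindows",
    "find_distinct_windows",
    "merge_flag_runs",
    "percent_of_stim_difference",
    "CrossoverFit",
    "fit_logistic_crossover",
    "fit_all_crossovers",
]


def weighted_score(answer, confidence):
    """Signed detection score: +confidence for "yes", -confidence for "no".

    A missing answer propagates to a missing (NaN) score rather than zero:
    zero is a meaningful value (a maximally unsure response), absence is not.
    """
    if answer is None or (isinstance(answer, float) and np.isnan(answer)) or pd.isna(answer):
        return np.nan
    if answer not in ("yes", "no"):
        raise ValueError(f"answer must be 'yes' or 'no', got {answer!r}")
    confidence = float(confidence)
    if not 0.0 <= confidence <= 10.0:
        raise ValueError(f"confidence {confidence} outside [0, 10]")
    return confidence if answer == "yes" else -confidence


def add_weighted_scores(probes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`weighted_score` over a probes table; adds a ``score`` column."""
    conf = pd.to_numeric(probes["confidence"], errors="coerce")
    if ((conf < 0) | (conf > 10)).any():
        raise ValueError("confidence outside [0, 10]")
    answer = probes["answer"]
    bad = answer.notna() & ~answer.isin(["yes", "no"])
    if bad.any():
        raise ValueError(f"invalid answers: {sorted(answer[bad].unique())}")
    sign = answer.map({"yes": 1.0, "no": -1.0}).astype(float)
    out = probes.copy()
    out["score"] = sign.to_numpy() * conf.to_numpy()
    return out


class BootstrapCI(NamedTuple):
    median: float
    ci_lo: float
    ci_hi: float


def bootstrap_band(scores: Sequence[float], n_boot: int = 5000, level: float = 0.95,
                   rng: np.random.Generator | None = None,
                   method: str = "sample") -> BootstrapCI:
    """Percentile-bootstrap CI for the group median of one probe's scores.

    Participants are resampled with replacement ``n_boot`` times; the CI is
    the percentile interval of the bootstrap median distribution.  With
    ``method="exhaustive"`` all n**n equally likely resamples are enumerated
    instead (feasible only for very small n), which the sampled interval
    converges to.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 non-missing scores, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if method == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        idx = np.array(list(itertools.product(range(n), repeat=n)))
        meds = np.median(x[idx], axis=1)
    elif method == "sample":
        if rng is None:
            rng = np.random.default_rng()
        idx = rng.integers(0, n, size=(n_boot, n))
        meds = np.median(x[idx], axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return BootstrapCI(float(np.median(x)), float(lo), float(hi))


def compute_bands(scores: pd.DataFrame, value_col: str = "score", time_col: str = "time_s",
                  n_boot: int = 5000, level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Bootstrap bands per condition over the probe grid.

    One seeded RNG stream is spawned per condition (in sorted label order)
    and probes are processed in time order, so results are reproducible
    bit-for-bit for a given seed.  Probes with fewer than two non-missing
    scores are flagged and carry NaN bands.
    """
    conditions = sorted(scores["condition"].unique())
    streams = dict(zip(conditions, np.random.SeedSequence(seed).spawn(len(conditions))))
    rows = []
    for condition in conditions:
        rng = np.random.default_rng(streams[condition])
        sub = scores[scores["condition"] == condition]
        for t, grp in sub.groupby(time_col, sort=True):
            vals = grp[value_col].to_numpy(dtype=float)
            n_obs = int(np.sum(~np.isnan(vals)))
            row = {"condition": condition, time_col: float(t), "n": n_obs}
            if n_obs < 2:
                row.update(median=np.nan, ci_lo=np.nan, ci_hi=np.nan, flagged=True)
            else:
                band = bootstrap_band(vals, n_boot=n_boot, level=level, rng=rng)
                row.update(median=band.median, ci_lo=band.ci_lo, ci_hi=band.ci_hi,
                           flagged=False)
            rows.append(row)
    return pd.DataFrame(rows)


def merge_flag_runs(times: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Merge consecutive flagged probes into (start, end) windows on the probe grid.

    A run spans from its first to its last probe time, so an isolated
    flagged probe yields a zero-span window.
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if times.shape != flags.shape:
        raise ValueError("times and flags must have equal length")
    windows: list[tuple[float, float]] = []
    i = 0
    while i < flags.size:
        if flags[i]:
            j = i
            while j + 1 < flags.size and flags[j + 1]:
                j += 1
            windows.append((float(times[i]), float(times[j])))
            i = j + 1
        else:
            i += 1
    return windows


@dataclass(frozen=True)
class DistinctWindows:
    """Non-overlap summary: per-probe flags and merged windows on the probe grid."""

    times: np.ndarray
    distinct_flags: np.ndarray
    windows: list[tuple[float, float]]

    @property
    def total_distinct_s(self) -> float:
        return float(sum(end - start for start, end in self.windows))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "distinct": self.distinct_flags})


def find_distinct_windows(band_a: pd.DataFrame, band_b: pd.DataFrame) -> DistinctWindows:
    """Identify probes where the two conditions' CIs are disjoint, merged into windows.

    Probe k is distinct iff [lo_a, hi_a] and [lo_b, hi_b] have empty
    intersection (intervals merely touching at an endpoint overlap).  Probes
    flagged unusable in either band are never distinct.  The two bands must
    share the same probe grid; the operation is symmetric in its arguments.
    """
    a = band_a.sort_values("time_s").reset_index(drop=True)
    b = band_b.sort_values("time_s").reset_index(drop=True)
    ta, tb = a["time_s"].to_numpy(float), b["time_s"].to_numpy(float)
    if ta.shape != tb.shape or not np.allclose(ta, tb):
        raise ValueError("bands must share the same probe grid")
    lo_a, hi_a = a["ci_lo"].to_numpy(float), a["ci_hi"].to_numpy(float)
    lo_b, hi_b = b["ci_lo"].to_numpy(float), b["ci_hi"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        flags = (lo_a > hi_b) | (lo_b > hi_a)
    flags &= ~(np.isnan(lo_a) | np.isnan(lo_b))
    windows = merge_flag_runs(ta, flags)
    return DistinctWindows(times=ta, distinct_flags=flags, windows=windows)


def percent_of_stim_difference(total_distinct_s: float, active: StimulationProtocol,
                               sham: StimulationProtocol) -> float:
    """Distinct time as % of the difference in total current-on time (ramps included).

    With the default protocols the denominator is 660 - 80 = 580 s.
    """
    if total_distinct_s < 0:
        raise ValueError("total_distinct_s must be non-negative")
    denom = active.total_on_s - sham.total_on_s
    if denom <= 0:
        raise ValueError(
            "stimulation-time difference is non-positive "
            f"({active.total_on_s} s active vs {sham.total_on_s} s sham); "
            "the percentage is undefined")
    return 100.0 * total_distinct_s / denom


@dataclass(frozen=True)
class CrossoverFit:
    """Per participant-session logistic fit of P(answer = yes) on probe time."""

    participant_id: str
    condition: str
    intercept: float
    slope_per_s: float
    crossover_s: float | None
    converged: bool
    failure_reason: str  # ok | nonconvergent | non_monotone | crossover_out_of_range | degenerate_responses


_TIME_SCALE = 960.0  # seconds; logistic fits use t / _TIME_SCALE for conditioning


def _penalized_logistic(ts: np.ndarray, y: np.ndarray, lam: float = 1e-3):
    """Ridge-penalised Bernoulli logistic MLE; finite even under complete separation."""
    X = np.column_stack([np.ones_like(ts), ts])

    def nll(beta):
        eta = X @ beta
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * lam * beta @ beta)

    def grad(beta):
        p = expit(X @ beta)
        return X.T @ (p - y) + lam * beta

    res = minimize(nll, np.zeros(2), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    # BFGS may report precision loss at an already-stationary point
    ok = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    return res.x, ok


def fit_logistic_crossover(times: Sequence[float], answers: Sequence, participant_id: str = "",
                           condition: str = "", task_window_s: tuple[float, float] = (0.0, 960.0),
                           alpha: float = 0.05) -> CrossoverFit:
    """Fit answer ~ time by binomial logistic regression; estimate the 50/50 crossover.

    The crossover time is -intercept/slope, defined only when the fit
    converged, the slope is distinguishable from zero, and the crossover
    falls inside the task window.  Responses perfectly separated by a time
    threshold are fitted with a light ridge penalty, which places the
    crossover inside the separating gap; single-valued (all-yes/all-no)
    responses are classified ``degenerate_responses``.
    """
    t = np.asarray(times, dtype=float)
    ans = pd.Series(list(answers))
    keep = ans.isin(["yes", "no"]).to_numpy()
    t, ans = t[keep], ans[keep]
    if t.size < 2:
        raise ValueError("need at least 2 probes with non-missing answers")
    y = (ans == "yes").to_numpy(dtype=float)

    def result(b0, b1, crossover, converged, reason):
        return CrossoverFit(participant_id, condition, float(b0), float(b1),
                            crossover, converged, reason)

    if y.min() == y.max():
        return result(np.nan, np.nan, None, False, "degenerate_responses")

    ts = t / _TIME_SCALE
    t_yes_max, t_no_min = t[y == 1].max(), t[y == 0].min()
    t_no_max, t_yes_min = t[y == 0].max(), t[y == 1].min()
    separated = (t_yes_max < t_no_min) or (t_no_max < t_yes_min)
    if separated:
        # MLE diverges; the threshold itself is well identified within the gap.
        beta, ok = _penalized_logistic(ts, y)
        b0, b1 = beta
        crossover = -b0 / b1 * _TIME_SCALE
        if not ok:
            return result(b0, b1 / _TIME_SCALE, None, False, "nonconvergent")
        if not task_window_s[0] <= crossover <= task_window_s[1]:
            return result(b0, b1 / _TIME_SCALE, None, True, "crossover_out_of_range")
        return result(b0, b1 / _TIME_SCALE, float(crossover), True, "ok")

    import statsmodels.api as sm

    exog = sm.add_constant(ts)
    try:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200, warn_convergence=False)
        converged = bool(fit.mle_retvals.get("converged", False))
        b0, b1 = fit.params
        slope_lo, slope_hi = fit.conf_int(alpha)[1]
    except (np.linalg.LinAlgError, ValueError):
        return result(np.nan, np.nan, None, False, "nonconvergent")
    if not converged or not np.all(np.isfinite([b0, b1, slope_lo, slope_hi])):
        return result(b0, b1 / _TIME_SCALE, None, False, "nonconvergent")
    if slope_lo <= 0.0 <= slope_hi:
        return result(b0, b1 / _TIME_SCALE, None, True, "non_monotone")
    crossover = -b0 / b1 * _TIME_SCALE
    if not task_window_s[0] <= crossover <= task_window_s[1]:
        return result(b0, b1 / _TIME_SCALE, None, True, "crossover_out_of_range")
    return result(b0, b1 / _TIME_SCALE, float(crossover), True, "ok")


def fit_all_crossovers(probes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`fit_logistic_crossover` for every participant x condition."""
    rows = []
    for (pid, condition), grp in probes.groupby(["participant_id", "condition"], sort=True):
        fit = fit_logistic_crossover(grp["time_s"], grp["answer"], str(pid), condition,
                                     alpha=alpha)
        rows.append({
            "participant_id": fit.participant_id,
            "condition": fit.condition,
            "intercept": fit.intercept,
            "slope_per_s": fit.slope_per_s,
            "crossover_s": np.nan if fit.crossover_s is None else fit.crossover_s,
            "converged": fit.converged,
            "failure_reason": fit.failure_reason,
        })
    return pd.DataFrame(rows)
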