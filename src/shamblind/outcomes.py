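"""Retrospective questionnaire statistics and the a-priori power calculation.

Side-effect ratings (1-5 ordinal, five scales) are compared between
conditions with Wilcoxon signed-rank tests using the classical
normal approximation: zero differences are discarded, absolute
differences receive midranks, and the tie-corrected variance
sum(ranks^2)/4 standardises the positive-rank sum.  End-of-study sham
guesses are summarised as a proportion with an exact one-sided binomial
test against chance.  The sample-size routine inverts the noncentral-t
power function of the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RATING_SCALES

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "side_effect_tests",
    "GuessTestResult",
    "guess_accuracy_test",
    "paired_t_power",
    "required_sample_size",
]


@dataclass(frozen=True)
class WilcoxonResult:
    scale: str
    z: float
    p: float
    n_effective: int
    undefined: bool = False


def wilcoxon_signed_rank(active, sham, scale: str = "") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (normal approximation, midrank ties).

    ``z`` is signed so that positive values indicate higher ranks in the
    active condition.  Zero differences are discarded before ranking; when
    every difference is zero the test is undefined and flagged rather than
    raised, so a battery over several scales can proceed.
    """
    a = np.asarray(active, dtype=float)
    s = np.asarray(sham, dtype=float)
    if a.shape != s.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    d = a - s
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(scale=scale, z=np.nan, p=np.nan, n_effective=0, undefined=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = float(np.sum(ranks ** 2)) / 4.0  # tie-corrected under midranks
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(scale=scale, z=float(z), p=p, n_effective=n)


def side_effect_tests(ratings: pd.DataFrame) -> dict[str, WilcoxonResult]:
    """Wilcoxon tests for all five side-effect scales, pairing by participant.

    No multiplicity correction is applied across the five scales; report
    consumers should treat the battery as descriptive.
    """
    wide = ratings.pivot(index="participant_id", columns="condition",
                         values=list(RATING_SCALES))
    out = {}
    for scale in RATING_SCALES:
        sub = wide[scale].dropna()
        out[scale] = wilcoxon_signed_rank(sub["active"], sub["sham"], scale=scale)
    return out


@dataclass(frozen=True)
class GuessTestResult:
    n_correct: int
    n_total: int
    percent: float
    p_binomial: float  # exact one-sided vs 0.5 ("above chance" is directional)


def guess_accuracy_test(guesses: pd.DataFrame) -> GuessTestResult:
    """Proportion of correct end-of-study sham guesses with an exact binomial test."""
    if len(guesses) == 0:
        raise ValueError("no guesses")
    k = int(guesses["correct"].astype(bool).sum())
    n = int(len(guesses))
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return GuessTestResult(n_correct=k, n_total=n, percent=100.0 * k / n,
                           p_binomial=float(p))


def paired_t_power(n: int, d: float, alpha: float = 0.05, tails: str = "one") -> float:
    """Power of the paired t-test at effect size dz = d with n pairs (noncentral t)."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == "one":
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    if tails == "two":
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.8,
                         tails: str = "one", n_max: int = 1_000_000) -> int:
    """Smallest n whose paired-t noncentral power at effect dz = d reaches ``power``."""
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d, alpha, tails) >= power:
            return n
    raise ValueError(f"target power not reachable with n <= {n_max}")
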