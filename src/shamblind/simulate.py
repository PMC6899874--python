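"""Synthetic crossover cohorts for the sham-blinding and reaction-time pipeline.

The generator emulates a two-session, counterbalanced within-subject
crossover in which every participant receives one active tDCS session
(30 s ramp-up, 600 s plateau at 1 mA, 30 s ramp-down) and one sham session
(30 s ramp-up, 20 s plateau, 30 s ramp-down).  Each session contributes a
100-trial baseline block, 320 in-task forced-choice trials in 32 ten-trial
sub-blocks, 32 detection probes on a 30 s grid, and a post-session
side-effect questionnaire; each participant additionally contributes one
end-of-study sham guess.

The perceptual model behind the probe answers is deliberately minimal: the
probability of answering "yes, the stimulation is on" interpolates between
a floor ``p_off`` and a ceiling ``p_on`` via a salience function s(t) that
is 1 during current ramps, decays exponentially during a sustained plateau
(scalp desensitisation), and decays linearly to 0 over a short persistence
window after ramp-down (lingering skin sensation).  Confidence ratings are
truncated-normal on the 0-10 visual-analogue scale.

Reaction times are log-normal with a participant-level intercept, a small
per-block practice effect, and an optional anodal facilitation expressed as
a standardized paired effect size (Cohen's dz) on the baseline-corrected
block-median difference between conditions, which is the unit the paired
analyses operate in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .protocol import ACTIVE_PROTOCOL, SHAM_PROTOCOL, TASK_DESIGN, StimulationProtocol, TaskDesign, probe_schedule

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "detection_probability",
    "sample_probe_responses",
    "sample_trials",
    "sample_ratings_and_guesses",
    "generate_cohort",
    "write_cohort",
]

# Ordinal base distributions (ratings 1..5) for the five side-effect scales.
# Tingling/itching are common mild sensations under tDCS; pain is rare.
RATING_BASE_P = {
    "headache": (0.60, 0.25, 0.10, 0.04, 0.01),
    "tingling": (0.20, 0.30, 0.30, 0.15, 0.05),
    "itching": (0.30, 0.30, 0.25, 0.10, 0.05),
    "burning": (0.45, 0.30, 0.15, 0.07, 0.03),
    "pain": (0.70, 0.20, 0.07, 0.02, 0.01),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Detection parameters (``p_on``, ``p_off``, ``desensitization_halflife_s``,
    ``persistence_s``) shape the yes-probability time course; confidence
    parameters shape the 0-10 sureness ratings; RT parameters define the
    log-normal trial model; ``anodal_dz`` injects a true standardized RT
    facilitation during the active stimulation blocks (0 = null effect).
    """

    n_participants: int = 32
    active: StimulationProtocol = ACTIVE_PROTOCOL
    sham: StimulationProtocol = SHAM_PROTOCOL
    design: TaskDesign = TASK_DESIGN
    # --- detection model ---
    p_on: float = 0.95          # P(answer "yes") while current is on and salient
    p_off: float = 0.05         # P(answer "yes") with no current and no after-sensation
    desensitization_halflife_s: float = 600.0  # exponential salience decay on the plateau
    persistence_s: float = 45.0  # lingering-sensation window after ramp-down
    lapse_p: float = 0.02        # probe response window lapses -> missing answer
    # --- confidence model (0-10 visual analogue scale) ---
    confidence_on_mean: float = 7.5
    confidence_off_mean: float = 7.0
    confidence_sd: float = 2.0           # within-participant probe-to-probe spread
    confidence_participant_sd: float = 1.5  # between-participant scale-use offset
    # --- reaction-time model ---
    rt_median_ms: float = 430.0      # group-level baseline median RT
    rt_sigma_log: float = 0.2        # log-normal shape (within-participant trial noise)
    rt_participant_sd_ms: float = 55.0  # between-participant spread of median RT
    practice_slope_ms_per_block: float = -2.0
    anodal_dz: float = 0.0           # true dz of active-vs-sham baseline-corrected block medians
    accuracy_p: float = 0.956
    # --- questionnaire model ---
    ratings_shift_itching: int = 1   # ordinal upward shift of itching in the active session
    guess_informed_p: float = 25.0 / 32.0  # P(end-of-study sham guess is correct)
    guess_confidence_mean: float = 7.0
    guess_confidence_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_off < self.p_on <= 1.0:
            raise ValueError("require 0 <= p_off < p_on <= 1")
        for name in ("confidence_on_mean", "confidence_off_mean"):
            if not 0.0 <= getattr(self, name) <= 10.0:
                raise ValueError(f"{name} must lie in [0, 10]")
        if not 0.0 <= self.lapse_p < 1.0:
            raise ValueError("lapse_p must lie in [0, 1)")
        if not 0.0 < self.accuracy_p <= 1.0:
            raise ValueError("accuracy_p must lie in (0, 1]")
        if not 0.5 <= self.guess_informed_p <= 1.0:
            raise ValueError("guess_informed_p must lie in [0.5, 1]")
        if self.ratings_shift_itching < 0:
            raise ValueError("ratings_shift_itching must be >= 0")

    def anodal_shift_ms(self) -> float:
        """Millisecond reduction of in-stimulation block medians realising ``anodal_dz``.

        The paired analyses standardise by the SD of the difference of
        baseline-corrected block medians between conditions.  Under the trial
        model that SD is driven by sampling noise of four independent block
        medians; the asymptotic variance of the median of n log-normal trials
        is (median * sigma_log)^2 * pi / (2 n), with n deflated by the
        accuracy rate because only correct trials enter the medians.  The
        multiplicative trial model makes that variance scale with the
        participant's own median, so the participant random intercept
        inflates the pooled variance by 1 + (participant_sd / median)^2.
        """
        d = self.design

        def sd_median(n_trials: int) -> float:
            n_eff = n_trials * self.accuracy_p
            return self.rt_median_ms * self.rt_sigma_log * math.sqrt(math.pi / (2.0 * n_eff))

        sd_diff = math.sqrt(2.0 * sd_median(d.trials_in_block(3)) ** 2
                            + 2.0 * sd_median(d.trials_in_block(1)) ** 2)
        sd_diff *= math.sqrt(1.0 + (self.rt_participant_sd_ms / self.rt_median_ms) ** 2)
        return self.anodal_dz * sd_diff

    def protocol(self, condition: str) -> StimulationProtocol:
        if condition == "active":
            return self.active
        if condition == "sham":
            return self.sham
        raise ValueError(f"unknown condition {condition!r}")


def _salience(t, protocol: StimulationProtocol, cfg: GeneratorConfig):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    ru, pl = protocol.ramp_up_s, protocol.plateau_s
    total = protocol.total_on_s
    s = np.zeros_like(t)
    on_ramp = (t <= ru) | ((t > ru + pl) & (t <= total))
    s[on_ramp] = 1.0
    plateau = (t > ru) & (t <= ru + pl)
    if plateau.any():
        s[plateau] = np.exp2(-(t[plateau] - ru) / cfg.desensitization_halflife_s)
    if cfg.persistence_s > 0:
        after = (t > total) & (t < total + cfg.persistence_s)
        s[after] = 1.0 - (t[after] - total) / cfg.persistence_s
    return s


def detection_probability(t, protocol: StimulationProtocol, cfg: GeneratorConfig):
    """P(answer "yes, the stimulation is on") at time ``t`` under ``protocol``.

    Equals ``p_off + (p_on - p_off) * s(t)`` where the salience s(t) is 1
    during ramps, halves every ``desensitization_halflife_s`` seconds on the
    plateau, and decays linearly to 0 over ``persistence_s`` after ramp-down.
    """
    p = cfg.p_off + (cfg.p_on - cfg.p_off) * _salience(t, protocol, cfg)
    return float(p) if np.isscalar(t) else p


def _truncnorm_01(mean, sd, lo, hi, rng):
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return mean.copy()
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return np.atleast_1d(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_probe_responses(participant_id: str, condition: str, cfg: GeneratorConfig,
                           rng: np.random.Generator, session: int = 1,
                           confidence_offset: float = 0.0) -> pd.DataFrame:
    """Draw one session's 32 probe responses (yes/no answer + confidence).

    ``confidence_offset`` is the participant's idiosyncratic shift of the
    0-10 scale and must be held fixed across that participant's sessions.
    """
    protocol = cfg.protocol(condition)
    times = probe_schedule(cfg.design.total_task_s, cfg.design.probe_interval_s)
    p = detection_probability(times, protocol, cfg)
    yes = rng.random(times.size) < p
    lapsed = rng.random(times.size) < cfg.lapse_p
    conf_mean = np.clip(np.where(yes, cfg.confidence_on_mean, cfg.confidence_off_mean)
                        + confidence_offset, 0.0, 10.0)
    conf = _truncnorm_01(conf_mean, cfg.confidence_sd, 0.0, 10.0, rng)
    answer = np.where(yes, "yes", "no").astype(object)
    answer[lapsed] = None
    conf = conf.astype(float)
    conf[lapsed] = np.nan
    return pd.DataFrame({
        "participant_id": participant_id,
        "condition": condition,
        "session": session,
        "probe_index": np.arange(1, times.size + 1),
        "time_s": times,
        "answer": pd.array(answer, dtype="string"),
        "confidence": conf,
    })


def sample_trials(participant_id: str, condition: str, cfg: GeneratorConfig,
                  rng: np.random.Generator, participant_offset_ms: float = 0.0,
                  session: int = 1) -> pd.DataFrame:
    """Draw one session's baseline + in-task forced-choice trials.

    ``participant_offset_ms`` is the participant's random intercept and must
    be held fixed across that participant's two sessions.
    """
    d = cfg.design
    n_total = d.n_baseline_trials + d.n_task_trials
    subblock = np.concatenate([
        np.zeros(d.n_baseline_trials, dtype=int),
        np.repeat(np.arange(1, d.n_subblocks + 1), d.trials_per_subblock),
    ])
    block = d.block_of_subblock(subblock)
    stim_sq = rng.random(n_total) < 0.5
    correct = rng.random(n_total) < cfg.accuracy_p
    median_ms = (cfg.rt_median_ms + participant_offset_ms
                 + cfg.practice_slope_ms_per_block * (block - 1)).astype(float)
    if condition == "active" and cfg.anodal_dz != 0.0:
        median_ms[(block == 2) | (block == 3)] -= cfg.anodal_shift_ms()
    if np.any(median_ms <= 0):
        raise ValueError("RT model produced a non-positive median; check config")
    rt = np.exp(rng.normal(np.log(median_ms), cfg.rt_sigma_log))
    stimulus = np.where(stim_sq, "square", "diamond")
    correct_resp = np.where(stim_sq, "right", "left")
    wrong_resp = np.where(stim_sq, "left", "right")
    response = np.where(correct, correct_resp, wrong_resp)
    return pd.DataFrame({
        "participant_id": participant_id,
        "condition": condition,
        "session": session,
        "block": block,
        "subblock": subblock,
        "stimulus": stimulus,
        "response": response,
        "correct": correct,
        "rt_ms": rt,
    })


def sample_ratings_and_guesses(participant_id: str, cfg: GeneratorConfig,
                               rng: np.random.Generator, sham_session: int = 2):
    """Draw both sessions' side-effect ratings and the end-of-study sham guess."""
    rows = []
    for condition in ("active", "sham"):
        row = {"participant_id": participant_id, "condition": condition}
        for scale, probs in RATING_BASE_P.items():
            r = int(rng.choice(5, p=probs)) + 1
            if scale == "itching" and condition == "active":
                r = min(5, r + cfg.ratings_shift_itching)
            row[scale] = r
        rows.append(row)
    correct = bool(rng.random() < cfg.guess_informed_p)
    guessed = sham_session if correct else 3 - sham_session
    conf = float(_truncnorm_01(np.array([cfg.guess_confidence_mean]),
                               cfg.guess_confidence_sd, 1.0, 10.0, rng)[0])
    guess = {"participant_id": participant_id,
             "guessed_sham_session": f"session{guessed}",
             "correct": correct, "confidence": conf}
    return rows, guess


@dataclass
class SyntheticCohort:
    """The four tidy tables of one synthetic crossover cohort plus the config used."""

    probes: pd.DataFrame
    trials: pd.DataFrame
    ratings: pd.DataFrame
    guesses: pd.DataFrame
    config: GeneratorConfig = field(repr=False)


def generate_cohort(cfg: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete cohort; counterbalancing alternates by participant index.

    Even-indexed participants receive active in session 1, odd-indexed
    participants sham in session 1.  With a fixed seed the output is
    bit-reproducible.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    probe_frames, trial_frames, rating_rows, guess_rows = [], [], [], []
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:02d}"
        offset = rng.normal(0.0, cfg.rt_participant_sd_ms)
        conf_offset = rng.normal(0.0, cfg.confidence_participant_sd)
        order = ("active", "sham") if i % 2 == 0 else ("sham", "active")
        sham_session = order.index("sham") + 1
        for session, condition in enumerate(order, start=1):
            probe_frames.append(sample_probe_responses(pid, condition, cfg, rng, session,
                                                       confidence_offset=conf_offset))
            trial_frames.append(sample_trials(pid, condition, cfg, rng, offset, session))
        rows, guess = sample_ratings_and_guesses(pid, cfg, rng, sham_session)
        rating_rows.extend(rows)
        guess_rows.append(guess)
    return SyntheticCohort(
        probes=pd.concat(probe_frames, ignore_index=True),
        trials=pd.concat(trial_frames, ignore_index=True),
        ratings=pd.DataFrame(rating_rows),
        guesses=pd.DataFrame(guess_rows),
        config=cfg if seed is None else replace(cfg, seed=seed),
    )


def write_cohort(cohort: SyntheticCohort, out_dir, header_comment: str | None = None) -> dict:
    """Write the cohort's four CSVs into ``out_dir``; returns the path map."""
    from pathlib import Path

    from .io import write_table

    out = Path(out_dir)
    paths = {}
    for name in ("probes", "trials", "ratings", "guesses"):
        path = out / f"{name}.csv"
        write_table(getattr(cohort, name), path, header_comment)
        paths[name] = path
    return paths
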