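"""Stimulation protocol timing and task-design arithmetic.

A transcranial direct current stimulation (tDCS) session delivers a weak
current through scalp electrodes following a trapezoidal envelope: a linear
ramp-up, a constant plateau, and a linear ramp-down.  An *active* protocol
holds the plateau for minutes; a *sham* (placebo) protocol holds it only for
seconds, so that the initial cutaneous sensations are matched while the
neuromodulatory dose is not.  Everything downstream (probe scheduling,
window summaries) is driven by the timing arithmetic defined here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulationProtocol",
    "ACTIVE_PROTOCOL",
    "SHAM_PROTOCOL",
    "TaskDesign",
    "TASK_DESIGN",
    "current_at",
    "probe_schedule",
]


@dataclass(frozen=True)
class StimulationProtocol:
    """Trapezoidal current envelope: ramp-up, plateau, ramp-down.

    Parameters
    ----------
    label
        Condition name, conventionally ``"active"`` or ``"sham"``.
    ramp_up_s, plateau_s, ramp_down_s
        Phase durations in seconds; all must be non-negative.
    intensity_mA
        Plateau current in milliamperes.
    """

    label: str
    ramp_up_s: float
    plateau_s: float
    ramp_down_s: float
    intensity_mA: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ramp_up_s", "plateau_s", "ramp_down_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.intensity_mA < 0:
            raise ValueError("intensity_mA must be non-negative")

    @property
    def total_on_s(self) -> float:
        """Total time with non-zero current, ramps included."""
        return self.ramp_up_s + self.plateau_s + self.ramp_down_s


#: 1 mA for 10 min with 30 s ramps (600 s plateau, 660 s total current-on).
ACTIVE_PROTOCOL = StimulationProtocol("active", 30.0, 600.0, 30.0, 1.0)
#: 1 mA for 20 s with 30 s ramps (80 s total current-on).
SHAM_PROTOCOL = StimulationProtocol("sham", 30.0, 20.0, 30.0, 1.0)


def current_at(protocol: StimulationProtocol, t):
    """Current (mA) delivered by ``protocol`` at time ``t`` seconds after ramp-up onset.

    Ramps are linear; the plateau is constant; the current is zero once the
    ramp-down has completed.  ``t`` may be a scalar or array; negative times
    raise ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative (seconds since ramp-up onset)")
    ru, pl, rd = protocol.ramp_up_s, protocol.plateau_s, protocol.ramp_down_s
    total = protocol.total_on_s
    out = np.zeros_like(t_arr)
    if ru > 0:
        rising = t_arr <= ru
        out[rising] = protocol.intensity_mA * t_arr[rising] / ru
    plateau = (t_arr > ru) & (t_arr <= ru + pl)
    out[plateau] = protocol.intensity_mA
    if rd > 0:
        falling = (t_arr > ru + pl) & (t_arr < total)
        out[falling] = protocol.intensity_mA * (total - t_arr[falling]) / rd
    if np.isscalar(t):
        return float(out)
    return out


def probe_schedule(total_task_s: float = 960.0, interval_s: float = 30.0) -> np.ndarray:
    """Probe-question times: every ``interval_s`` seconds from the first interval.

    The in-task detection probes ("Is the stimulation on?" / "How sure are
    you?") are asked on a fixed grid starting one interval after stimulation
    onset.  The default 16-minute task with a 30 s interval yields 32 probes
    at 30, 60, ..., 960 s.
    """
    if total_task_s <= 0 or interval_s <= 0:
        raise ValueError("total_task_s and interval_s must be positive")
    n = int(np.floor(total_task_s / interval_s))
    return interval_s * np.arange(1, n + 1)


@dataclass(frozen=True)
class TaskDesign:
    """Forced-choice reaction-time task layout around the stimulation period.

    Block 1 is a pre-stimulation baseline.  Blocks 2-4 run continuously for
    16 min from ramp-up onset, with a probe pair inserted after every
    ``trials_per_subblock`` trials (i.e. every ``probe_interval_s`` seconds).
    Blocks 2 and 3 span the stimulation period of the active protocol and
    block 4 the post-stimulation period.
    """

    n_baseline_trials: int = 100
    n_task_trials: int = 320
    trials_per_subblock: int = 10
    probe_interval_s: float = 30.0
    total_task_s: float = 960.0
    stimulus_ms: float = 100.0
    fixation_ms: tuple[float, float] = (1700.0, 2100.0)
    # sub-block index (1-based) at which blocks 3 and 4 begin
    block3_first_subblock: int = 12
    block4_first_subblock: int = 23

    @property
    def n_subblocks(self) -> int:
        return self.n_task_trials // self.trials_per_subblock

    @property
    def n_probes(self) -> int:
        return len(probe_schedule(self.total_task_s, self.probe_interval_s))

    @property
    def mean_trial_ms(self) -> float:
        return self.stimulus_ms + 0.5 * (self.fixation_ms[0] + self.fixation_ms[1])

    @property
    def baseline_duration_s(self) -> float:
        """Expected duration of the baseline block (trials x mean trial length)."""
        return self.n_baseline_trials * self.mean_trial_ms / 1000.0

    def block_of_subblock(self, subblock) -> np.ndarray:
        """Map 1-based task sub-block indices to block labels 2-4 (0 -> baseline block 1)."""
        sb = np.asarray(subblock)
        out = np.full(sb.shape, 2)
        out[sb >= self.block3_first_subblock] = 3
        out[sb >= self.block4_first_subblock] = 4
        out[sb == 0] = 1
        return out

    def trials_in_block(self, block: int) -> int:
        if block == 1:
            return self.n_baseline_trials
        per = self.trials_per_subblock
        if block == 2:
            return (self.block3_first_subblock - 1) * per
        if block == 3:
            return (self.block4_first_subblock - self.block3_first_subblock) * per
        if block == 4:
            return (self.n_subblocks - self.block4_first_subblock + 1) * per
        raise ValueError(f"unknown block {block}")

    @property
    def n_stimulation_trials(self) -> int:
        """Trials presented while the active protocol delivers current (blocks 2-3)."""
        return self.trials_in_block(2) + self.trials_in_block(3)

    def subblock_times(self) -> np.ndarray:
        """Probe-grid time (s) associated with each task sub-block."""
        return self.probe_interval_s * np.arange(1, self.n_subblocks + 1)


TASK_DESIGN = TaskDesign()
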