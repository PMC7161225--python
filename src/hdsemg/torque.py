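"""Torque protocol arithmetic: peak torque, MVC targets, best-trial selection.

The protocol records maximal voluntary contractions (MVC) at a fixed knee
angle; the highest MVC peak defines the 25/50/75% submaximal target
torques, and for every repeated contraction the trial with the highest
peak is carried into analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ContractionTrial",
    "TrialSelection",
    "peak_torque",
    "mvc_targets",
    "select_best_trial",
]

ISOKINETIC_VELOCITY_RAD_S = 1.05  # protocol's constant angular velocity

_ISOMETRIC_LEVELS = {25, 50, 75, 100}


@dataclass
class ContractionTrial:
    """One recorded contraction's torque trace (Nm)."""

    torque: np.ndarray
    fs: float
    mode: str = "isometric"  # isometric | isokinetic
    level: int | str = 100  # %MVC, or "isokinetic"
    angular_velocity: float = 0.0  # rad/s

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float)
        if self.torque.size == 0:
            raise ValueError("empty torque trace")
        if self.mode not in {"isometric", "isokinetic"}:
            raise ValueError(f"unknown contraction mode {self.mode!r}")
        if self.mode == "isometric" and self.level not in _ISOMETRIC_LEVELS:
            raise ValueError(f"isometric level must be one of {sorted(_ISOMETRIC_LEVELS)}")
        if self.mode == "isokinetic":
            self.level = "isokinetic"
            if self.angular_velocity == 0.0:
                self.angular_velocity = ISOKINETIC_VELOCITY_RAD_S


@dataclass(frozen=True)
class TrialSelection:
    """Best trial plus provenance of the choice."""

    trial: ContractionTrial
    index: int
    peak: float
    tied: bool


def peak_torque(trial: ContractionTrial) -> float:
    """Maximum of the torque trace, Nm (full trace; no phase windowing)."""
    return float(np.max(trial.torque))


def mvc_targets(mvc_peak: float) -> dict[int, float]:
    """Submaximal target torques at 25/50/75% of the MVC peak."""
    if mvc_peak <= 0:
        raise ValueError("MVC peak torque must be positive")
    return {25: 0.25 * mvc_peak, 50: 0.50 * mvc_peak, 75: 0.75 * mvc_peak}


def select_best_trial(trials: Sequence[ContractionTrial]) -> TrialSelection:
    """The trial with the highest peak torque; ties go to the earliest trial.

    All trials must share mode and level (they are repetitions of one
    condition); the tie-break and the chosen index are recorded in the
    returned selection.
    """
    if not trials:
        raise ValueError("no trials supplied")
    modes = {t.mode for t in trials}
    levels = {t.level for t in trials}
    if len(modes) > 1 or len(levels) > 1:
        raise ValueError(f"trials mix conditions: modes={sorted(modes)}, levels={sorted(map(str, levels))}")
    peaks = [peak_torque(t) for t in trials]
    best = int(np.argmax(peaks))  # argmax takes the first maximum: earliest trial wins ties
    tied = peaks.count(peaks[best]) > 1
    return TrialSelection(trial=trials[best], index=best, peak=peaks[best], tied=tied)
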