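"""Signal conditioning, single-differential derivation and epoch extraction.

The single-differential (bipolar) montage subtracts vertically adjacent
electrodes within each column — the muscle-fiber direction on the default
grid — suppressing common-mode signal. On the 13x5 / 64-electrode grid this
yields the canonical 59 bipolar channels. Analysis windows are 1-s epochs
centered at the contraction midpoint (isometric) or at fixed fractions of
the contraction cycle (isokinetic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_grid import GridGeometry, MonopolarRecording

__all__ = [
    "BipolarSet",
    "Epoch",
    "bandpass",
    "single_differential",
    "bipolar_pairs",
    "midpoint_epoch",
    "isokinetic_cycle_epochs",
    "detect_contraction",
]

Pair = tuple[tuple[int, int], tuple[int, int]]


@dataclass
class BipolarSet:
    """Single-differential channels with (row-pair, column) provenance."""

    signals: np.ndarray  # [n_bipolar, n_samples], mV
    pairs: tuple[Pair, ...]  # ((row, col), (row+1, col)) per channel
    fs: float
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[0] != len(self.pairs):
            raise ValueError("one provenance pair is required per bipolar channel")

    @property
    def n_bipolar(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class Epoch:
    """A fixed-duration analysis window of bipolar signals."""

    signals: np.ndarray  # [n_bipolar, n_epoch_samples]
    fs: float
    center_time: float  # s
    duration: float  # s
    label: str
    pairs: tuple[Pair, ...]
    geometry: GridGeometry

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def bandpass(
    recording: MonopolarRecording,
    low_hz: float = 10.0,
    high_hz: float = 500.0,
    order: int = 4,
) -> MonopolarRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Defaults replicate the 10–500 Hz acquisition band of the recording
    chain so that synthetic inputs see an equivalent transfer function.
    Zero-phase filtering (forward-backward) preserves epoch timing.
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist frequency {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return MonopolarRecording(
        samples=filtered,
        fs=recording.fs,
        geometry=recording.geometry,
        channel_map=recording.channel_map,
        torque=recording.torque,
    )


def bipolar_pairs(geometry: GridGeometry) -> tuple[Pair, ...]:
    """Vertically adjacent populated pairs, column-major then by row."""
    miss = set(geometry.missing)
    pairs = []
    for c in range(geometry.n_cols):
        for r in range(geometry.n_rows - 1):
            if (r, c) not in miss and (r + 1, c) not in miss:
                pairs.append(((r, c), (r + 1, c)))
    return tuple(pairs)


def single_differential(recording: MonopolarRecording) -> BipolarSet:
    """Derive single-differential channels: upper minus lower electrode.

    Each vertically adjacent populated pair (i, j), (i+1, j) within a
    column yields sEMG_{i,j} − sEMG_{i+1,j}. Pairs broken by a missing
    electrode are dropped, so the default 64-electrode grid gives 59
    channels and a full 13x5 grid gives 60.
    """
    pairs = bipolar_pairs(recording.geometry)
    idx = recording.position_index()
    upper = [idx[p[0]] for p in pairs]
    lower = [idx[p[1]] for p in pairs]
    signals = recording.samples[upper] - recording.samples[lower]
    return BipolarSet(signals=signals, pairs=pairs, fs=recording.fs, geometry=recording.geometry)


def _extract(bipolar: BipolarSet, center_s: float, duration: float, label: str) -> Epoch:
    n = _round_half_away(duration * bipolar.fs)
    if n < 1:
        raise ValueError("epoch duration shorter than one sample")
    start = _round_half_away(center_s * bipolar.fs) - n // 2
    if start < 0 or start + n > bipolar.n_samples:
        raise ValueError(
            f"epoch [{start}, {start + n}) samples exceeds recording bounds "
            f"[0, {bipolar.n_samples})"
        )
    return Epoch(
        signals=bipolar.signals[:, start : start + n],
        fs=bipolar.fs,
        center_time=center_s,
        duration=duration,
        label=label,
        pairs=bipolar.pairs,
        geometry=bipolar.geometry,
    )


def midpoint_epoch(
    bipolar: BipolarSet,
    contraction_start: float,
    contraction_end: float,
    duration: float = 1.0,
    label: str = "midpoint",
) -> Epoch:
    """Epoch centered at the midpoint of the contraction interval."""
    if contraction_end - contraction_start < duration:
        raise ValueError(
            f"contraction interval {contraction_end - contraction_start:.3f} s "
            f"is shorter than the {duration:.3f} s epoch"
        )
    center = 0.5 * (contraction_start + contraction_end)
    return _extract(bipolar, center, duration, label)


def isokinetic_cycle_epochs(
    bipolar: BipolarSet,
    cycle: tuple[float, float] | None = None,
    torque: np.ndarray | None = None,
    duration: float = 1.0,
) -> list[Epoch]:
    """Epochs at 25/50/75/100% of the contraction cycle.

    The cycle bounds are supplied directly or detected from the torque
    trace. Epochs are centered at onset + f·(cycle length) for
    f ∈ {0.25, 0.5, 0.75, 1.0}; an epoch that would overrun the cycle end
    (always the 100% one) is right-aligned to it.
    """
    if cycle is None:
        if torque is None:
            raise ValueError("supply either explicit cycle bounds or a torque trace")
        cycle = detect_contraction(torque, bipolar.fs)
    start, end = cycle
    length = end - start
    if length < duration:
        raise ValueError(f"cycle of {length:.3f} s is shorter than the {duration:.3f} s epoch")
    if length == duration:
        warnings.warn("cycle length equals epoch duration; the four epochs fully overlap")
    n = _round_half_away(duration * bipolar.fs)
    start_sample = _round_half_away(start * bipolar.fs)
    end_sample = _round_half_away(end * bipolar.fs)
    epochs = []
    for frac in (0.25, 0.50, 0.75, 1.00):
        center = start + frac * length
        first = _round_half_away(center * bipolar.fs) - n // 2
        # keep the window inside the cycle; the 100% epoch right-aligns
        first = min(max(first, start_sample), end_sample - n)
        center = (first + n // 2) / bipolar.fs
        epochs.append(_extract(bipolar, center, duration, label=f"{int(frac * 100)}%"))
    return epochs


def detect_contraction(
    torque: np.ndarray,
    fs: float,
    threshold_frac: float = 0.05,
    hysteresis: float = 0.01,
) -> tuple[float, float]:
    """Contraction bounds from a torque trace by thresholding at a fraction
    of the trial peak, with hysteresis on the release side.

    Returns (onset_s, offset_s). Onset is the first sample above
    ``threshold_frac * peak``; offset the last sample above
    ``(threshold_frac − hysteresis) * peak``.
    """
    torque = np.asarray(torque, dtype=float)
    peak = float(np.max(torque))
    if peak <= 0:
        raise ValueError("torque trace has no positive excursion")
    above = np.nonzero(torque >= threshold_frac * peak)[0]
    if above.size == 0:
        raise ValueError("no samples exceed the onset threshold")
    onset = int(above[0])
    release = np.nonzero(torque >= (threshold_frac - hysteresis) * peak)[0]
    offset = int(release[-1])
    return onset / fs, (offset + 1) / fs
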