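"""Convenience front-end tying the processing stages together."""

from __future__ import annotations

from .io_grid import MonopolarRecording
from .preprocess import bandpass, midpoint_epoch, single_differential
from .spatial_features import SpatialFeatures, features

__all__ = ["features_from_recording"]


def features_from_recording(
    rec: MonopolarRecording,
    interval: tuple[float, float] | None = None,
    epoch_duration: float = 1.0,
    apply_bandpass: bool = True,
    low_hz: float = 10.0,
    high_hz: float = 500.0,
) -> SpatialFeatures:
    """Band-pass, derive single differentials, epoch at the contraction
    midpoint and compute the spatial feature bundle.

    ``interval`` gives the contraction bounds in seconds; by default the
    whole recording is treated as the contraction.
    """
    if apply_bandpass:
        rec = bandpass(rec, low_hz, high_hz)
    bipolar = single_differential(rec)
    start, end = interval if interval is not None else (0.0, rec.duration)
    epoch = midpoint_epoch(bipolar, start, end, duration=epoch_duration)
    return features(epoch)
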