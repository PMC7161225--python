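"""Activation maps and scalar spatial features of grid EMG.

The per-channel RMS of the bipolar signals over an analysis epoch forms a
2-D activation map; four scalars summarize it:

* intensity ``I = log10(mean(HM))`` — log amplitude of the map;
* differential intensity ``DI = log10(RMS(single differential))``, averaged
  over channels — log amplitude of the spatially differentiated signal;
* modified entropy ``E = −Σ q_i log2 q_i`` with ``q_i`` the channel power
  normalized to unit sum — maximal (log2 N) for a uniform map, 0 when all
  power sits in one channel;
* coefficient of variation ``CV = 100·SD/mean`` of the channel RMS values.

E and CV quantify the spatial heterogeneity of muscle activation: tight
clustering of active motor-unit territories lowers E and raises CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_grid import GridGeometry
from .preprocess import Epoch, Pair

__all__ = [
    "ActivationMap",
    "SpatialFeatures",
    "rms",
    "activation_map",
    "intensity",
    "differential_intensity",
    "modified_entropy",
    "coefficient_of_variation",
    "features",
    "map_to_grid",
    "heatmap_export",
]


@dataclass
class ActivationMap:
    """Per-bipolar-channel RMS values (mV) with grid provenance."""

    values: np.ndarray  # [n_bipolar], mV, >= 0
    pairs: tuple[Pair, ...]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != len(self.pairs):
            raise ValueError("one RMS value per bipolar channel is required")
        if np.any(self.values < 0):
            raise ValueError("RMS values cannot be negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SpatialFeatures:
    """Scalar bundle summarizing one activation map."""

    mean_rms_mv: float
    intensity: float  # log10(mV)
    mean_differential_intensity: float  # log10(mV)
    modified_entropy_bits: float
    cv_percent: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rms_mv": self.mean_rms_mv,
            "intensity": self.intensity,
            "mean_di": self.mean_differential_intensity,
            "entropy_bits": self.modified_entropy_bits,
            "cv_pct": self.cv_percent,
        }


def rms(x: np.ndarray, axis: int | None = -1) -> np.ndarray | float:
    """Root mean square along ``axis``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot take the RMS of an empty signal")
    return np.sqrt(np.mean(np.square(x), axis=axis))


def activation_map(epoch: Epoch) -> ActivationMap:
    """Per-channel RMS of the epoch, in channel order."""
    if epoch.n_samples == 0:
        raise ValueError("empty epoch")
    return ActivationMap(values=rms(epoch.signals, axis=1), pairs=epoch.pairs, geometry=epoch.geometry)


def intensity(amap: ActivationMap) -> float:
    """Common logarithm of the map mean, ``log10(mean(HM))``."""
    m = float(np.mean(amap.values))
    if m <= 0:
        raise ValueError("intensity is undefined for an all-zero map")
    return float(np.log10(m))


def differential_intensity(
    epoch: Epoch, double_difference: bool = False
) -> tuple[np.ndarray, float, int]:
    """Per-channel ``log10(RMS)`` of the spatial differentials and its mean.

    The epoch's channels are already single differentials of the monopolar
    montage, so by default each channel's RMS is logged directly. With
    ``double_difference=True`` the differentials are re-formed from
    consecutive within-column bipolar channels (a double-differential
    reading for inputs that were recorded bipolar).

    Channels with zero RMS are excluded (log of zero) and counted; returns
    ``(per_channel, mean, n_excluded)``.
    """
    if double_difference:
        sigs, pairs = [], []
        for k in range(len(epoch.pairs) - 1):
            (r0, c0), _ = epoch.pairs[k]
            (r1, c1), _ = epoch.pairs[k + 1]
            if c0 == c1 and r1 == r0 + 1:
                sigs.append(epoch.signals[k] - epoch.signals[k + 1])
        if not sigs:
            raise ValueError("no consecutive within-column channel pairs")
        values = rms(np.asarray(sigs), axis=1)
    else:
        values = rms(epoch.signals, axis=1)
    nonzero = values > 0
    n_excluded = int(np.sum(~nonzero))
    if not np.any(nonzero):
        raise ValueError("all differential channels have zero RMS")
    per_channel = np.full(values.shape, np.nan)
    per_channel[nonzero] = np.log10(values[nonzero])
    return per_channel, float(np.nanmean(per_channel)), n_excluded


def modified_entropy(amap: ActivationMap) -> float:
    """Entropy (bits) of the normalized channel power distribution.

    With ``q_i = RMS_i² / Σ_j RMS_j²``, returns ``−Σ q_i log2 q_i`` using
    the 0·log 0 = 0 convention. Ranges from 0 (one-hot) to log2 N
    (uniform; 5.884 bits for the 59-channel map).
    """
    power = np.square(amap.values)
    total = power.sum()
    if total <= 0:
        raise ValueError("modified entropy is undefined for an all-zero map")
    q = power / total
    nz = q > 0
    return float(-np.sum(q[nz] * np.log2(q[nz])))


def coefficient_of_variation(amap: ActivationMap) -> float:
    """100 · SD / mean of the channel RMS values (sample SD, n−1)."""
    m = float(np.mean(amap.values))
    if m <= 0:
        raise ValueError("CV is undefined for an all-zero map")
    return float(100.0 * np.std(amap.values, ddof=1) / m)


def features(epoch: Epoch, double_difference: bool = False) -> SpatialFeatures:
    """Compute the full scalar feature bundle for one epoch."""
    amap = activation_map(epoch)
    _, mean_di, _ = differential_intensity(epoch, double_difference=double_difference)
    return SpatialFeatures(
        mean_rms_mv=float(np.mean(amap.values)),
        intensity=intensity(amap),
        mean_differential_intensity=mean_di,
        modified_entropy_bits=modified_entropy(amap),
        cv_percent=coefficient_of_variation(amap),
    )


def map_to_grid(amap: ActivationMap) -> np.ndarray:
    """Arrange channel values on the (n_rows−1) x n_cols bipolar grid.

    Each bipolar channel is placed at the grid site of its upper electrode;
    sites whose pair is broken by a missing electrode are NaN.
    """
    grid = np.full((amap.geometry.n_rows - 1, amap.geometry.n_cols), np.nan)
    for value, ((r, c), _) in zip(amap.values, amap.pairs):
        grid[r, c] = value
    return grid


def heatmap_export(
    amap: ActivationMap,
    path,
    normalization: str = "per-trial",
    reference: ActivationMap | None = None,
):
    """Export the activation map as a blue-to-red heatmap image.

    ``normalization='per-trial'`` scales colors to the map's own range;
    ``'per-subject-mvc'`` scales to the maximum of ``reference`` (the
    subject's MVC map) so maps are comparable across contraction levels.
    Missing/broken grid sites are rendered blank.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = map_to_grid(amap)
    if normalization == "per-subject-mvc":
        if reference is None:
            raise ValueError("per-subject-mvc normalization requires a reference MVC map")
        vmax = float(np.max(reference.values))
        if vmax <= 0:
            raise ValueError("reference MVC map has no positive values")
        grid = grid / vmax
        vmin, vmax = 0.0, 1.0
    elif normalization == "per-trial":
        vmin, vmax = None, None
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    fig, ax = plt.subplots(figsize=(2.5, 5))
    im = ax.imshow(grid, cmap="jet", vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("column")
    ax.set_ylabel("row (fiber direction)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
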