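"""Synthetic motor-unit grid EMG with controllable territory clustering.

Each motor unit (MU) fires a renewal spike train convolved with a Ricker
(Mexican-hat) action-potential kernel; the resulting source is projected
onto the electrode grid with Gaussian amplitude decay from the MU's
territory center. Channels sum the active MUs plus white noise. Torque is
a low-pass-filtered sum of MU activations times a gain.

Two knobs matter for the spatial features:

* ``clustering`` κ ∈ [0, 1]: with probability κ an MU's territory center
  is drawn tightly around one of a few cluster foci, otherwise uniformly
  over the grid. κ = 0 gives spatially uniform activation (high entropy,
  low CV); κ = 1 concentrates power near the foci (low entropy, high CV).
* ``recruitment_curve``: fraction of the MU pool active at each %MVC
  level. MUs are ordered by amplitude (size principle) so active sets are
  nested across increasing levels.

Everything derives deterministically from the root seed via independent
substreams (placement, firing, noise), so two simulations that differ only
in κ share their firing and noise realizations exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_grid import GridGeometry, MonopolarRecording, make_default_geometry

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "ricker_kernel",
    "simulate",
    "sweep_clustering",
    "simulate_cohort",
]

LEVELS = (25, 50, 75, 100)  # isometric contraction levels, %MVC


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the grid-EMG generator.

    Defaults emulate the study conditions: a 13x5/64-electrode grid sampled
    at 1024 Hz, 3-s contractions analyzed over the 1-s midpoint epoch, an
    80-MU pool with nested recruitment of 40/60/80/100% of the pool at
    25/50/75/100 %MVC, 20 ± 4 Hz firing, a 10x amplitude range across the
    pool, and territories elongated along the fiber (column) axis.
    """

    seed: int = 0
    n_mus: int = 80
    grid: GridGeometry = field(default_factory=make_default_geometry)
    territory_sigma_rows: float = 3.0  # spread along fibers, electrode pitches
    territory_sigma_cols: float = 1.2  # spread across fibers
    clustering: float = 0.0  # κ
    fixed_centers: tuple[tuple[float, float], ...] | None = None  # override random placement
    n_foci: int = 2
    focus_sigma_rows: float = 1.0  # territory-center scatter around a focus
    focus_sigma_cols: float = 0.6
    recruitment_curve: tuple[tuple[int, float], ...] = (
        (25, 0.40),
        (50, 0.60),
        (75, 0.80),
        (100, 1.00),
    )
    level: int = 100  # %MVC simulated
    firing_rate_hz: tuple[float, float] = (20.0, 4.0)  # mean, sd across MUs
    isi_cv: float = 0.15
    muap_amplitude_mv: float = 0.10  # geometric-mean MU gain at the territory center
    amplitude_range: float = 10.0  # largest/smallest MU gain (size principle)
    muap_width_ms: float = 2.0  # Ricker kernel scale (spectral peak ~110 Hz)
    noise_rms_mv: float = 0.005  # additive white noise per channel
    duration_s: float = 3.0
    fs: float = 1024.0
    torque_gain: float = 1.0  # Nm per mV·spike/s of smoothed activation drive
    torque_noise_nm: float = 0.3

    def validate(self) -> None:
        problems = []
        if self.n_mus < 0:
            problems.append("n_mus must be >= 0")
        if not (0.0 <= self.clustering <= 1.0):
            problems.append("clustering must lie in [0, 1]")
        if self.fs <= 0:
            problems.append("fs must be positive")
        if self.duration_s <= 0:
            problems.append("duration_s must be positive")
        if self.firing_rate_hz[0] <= 0:
            problems.append("mean firing rate must be positive")
        if self.noise_rms_mv < 0:
            problems.append("noise_rms_mv must be >= 0")
        if self.amplitude_range < 1:
            problems.append("amplitude_range must be >= 1")
        curve = dict(self.recruitment_curve)
        fracs = [curve[lvl] for lvl in sorted(curve)]
        if any(f <= 0 or f > 1 for f in fracs):
            problems.append("recruitment fractions must lie in (0, 1]")
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            problems.append("recruitment_curve must be non-decreasing in level")
        if self.level not in curve:
            problems.append(f"level {self.level} missing from recruitment_curve")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    def active_count(self, level: int) -> int:
        frac = dict(self.recruitment_curve)[level]
        return max(1, math.ceil(frac * self.n_mus)) if self.n_mus else 0


@dataclass
class SyntheticGroundTruth:
    """What the generator actually injected, for oracle-style tests."""

    mu_centers: np.ndarray  # [n_mus, 2] (row, col), grid coordinates
    mu_amplitudes: np.ndarray  # [n_mus], mV, ascending (recruitment order)
    active_sets: dict[int, np.ndarray]  # level -> MU indices (nested)
    expected_channel_power: np.ndarray  # [n_electrodes], relative units
    torque_peak_nm: float


def ricker_kernel(width_ms: float, fs: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet: (1 − t²/a²)·exp(−t²/2a²), unit peak.

    Band-limited with spectral peak at √2/(2πa); a = 2 ms puts it near
    110 Hz, in the typical surface-EMG band.
    """
    a = width_ms / 1000.0
    half = round(4 * a * fs)
    t = np.arange(-half, half + 1) / fs  # symmetric grid including t = 0
    return (1.0 - (t / a) ** 2) * np.exp(-0.5 * (t / a) ** 2)


def _spike_trains(cfg: SyntheticConfig, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Binned renewal spike trains, one row per MU."""
    n_samples = round(cfg.duration_s * cfg.fs)
    trains = np.zeros((len(rates), n_samples))
    for k, rate in enumerate(rates):
        mean_isi = 1.0 / rate
        max_spikes = int(cfg.duration_s * rate * 2) + 8
        isis = rng.normal(mean_isi, cfg.isi_cv * mean_isi, size=max_spikes)
        isis = np.clip(isis, 0.2 * mean_isi, None)
        times = rng.uniform(0, mean_isi) + np.cumsum(isis)
        times = times[times < cfg.duration_s]
        idx = (times * cfg.fs).astype(int)
        np.add.at(trains[k], idx, 1.0)
    return trains


def _territory_centers(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """MU centers: κ-mixture of uniform placement and 2-focus clusters.

    Draws a fixed number of variates per MU regardless of the branch taken,
    so simulations that differ only in κ consume identical random streams.
    """
    g = cfg.grid
    foci = np.column_stack(
        [
            rng.uniform(0.15 * (g.n_rows - 1), 0.85 * (g.n_rows - 1), size=cfg.n_foci),
            rng.uniform(0.15 * (g.n_cols - 1), 0.85 * (g.n_cols - 1), size=cfg.n_foci),
        ]
    )
    uniform = np.column_stack(
        [
            rng.uniform(0, g.n_rows - 1, size=cfg.n_mus),
            rng.uniform(0, g.n_cols - 1, size=cfg.n_mus),
        ]
    )
    which_focus = rng.integers(0, cfg.n_foci, size=cfg.n_mus)
    scatter = rng.normal(size=(cfg.n_mus, 2)) * np.array(
        [cfg.focus_sigma_rows, cfg.focus_sigma_cols]
    )
    clustered = foci[which_focus] + scatter
    use_cluster = rng.random(cfg.n_mus) < cfg.clustering
    centers = np.where(use_cluster[:, None], clustered, uniform)
    centers[:, 0] = np.clip(centers[:, 0], 0, g.n_rows - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, g.n_cols - 1)
    return centers


def simulate(
    config: SyntheticConfig, envelope: np.ndarray | None = None
) -> tuple[MonopolarRecording, SyntheticGroundTruth]:
    """Generate one grid recording plus its ground truth.

    ``envelope`` optionally modulates both the EMG and the activation drive
    over time (e.g. a raised-sine profile for an isokinetic cycle); by
    default the contraction is held constant.
    """
    config.validate()
    cfg = config
    n_samples = round(cfg.duration_s * cfg.fs)
    root = np.random.default_rng(cfg.seed)
    placement_rng, firing_rng, noise_rng = root.spawn(3)

    positions = np.asarray(cfg.grid.positions(), dtype=float)  # column-major, matches default map

    if cfg.n_mus > 0:
        if cfg.fixed_centers is not None:
            centers = np.asarray(cfg.fixed_centers, dtype=float)
            if centers.shape != (cfg.n_mus, 2):
                raise ValueError("fixed_centers must supply one (row, col) per MU")
        else:
            centers = _territory_centers(cfg, placement_rng)
        # Size principle: gains ascend geometrically; recruitment order = index order.
        span = np.linspace(-0.5, 0.5, cfg.n_mus) if cfg.n_mus > 1 else np.zeros(1)
        amplitudes = cfg.muap_amplitude_mv * cfg.amplitude_range**span
        rates = np.clip(
            firing_rng.normal(cfg.firing_rate_hz[0], cfg.firing_rate_hz[1], size=cfg.n_mus),
            8.0,
            40.0,
        )
        active_sets = {lvl: np.arange(cfg.active_count(lvl)) for lvl, _ in cfg.recruitment_curve}
        active = active_sets[cfg.level]

        trains = _spike_trains(cfg, rates[active], firing_rng)
        kernel = ricker_kernel(cfg.muap_width_ms, cfg.fs)
        sources = sps.fftconvolve(trains, kernel[None, :], mode="same", axes=1)

        d2 = (
            (positions[:, None, 0] - centers[None, active, 0]) ** 2
            / cfg.territory_sigma_rows**2
            + (positions[:, None, 1] - centers[None, active, 1]) ** 2
            / cfg.territory_sigma_cols**2
        )
        gains = amplitudes[active][None, :] * np.exp(-0.5 * d2)  # [n_elec, n_active]
        emg = gains @ sources
        # Amplitude-weighted firing drive in mV·spikes/s; its 2 Hz-smoothed
        # mean sets the torque scale (~160 Nm at MVC with unit gain).
        drive = (amplitudes[active] @ trains) * cfg.fs
        kernel_energy = float(np.sum(kernel**2))
        expected_power = (gains**2) @ (rates[active] * kernel_energy)
    else:
        centers = np.zeros((0, 2))
        amplitudes = np.zeros(0)
        active_sets = {lvl: np.arange(0) for lvl, _ in cfg.recruitment_curve}
        emg = np.zeros((cfg.grid.n_electrodes, n_samples))
        drive = np.zeros(n_samples)
        expected_power = np.zeros(cfg.grid.n_electrodes)

    if cfg.noise_rms_mv > 0:
        emg = emg + cfg.noise_rms_mv * noise_rng.standard_normal(emg.shape)

    if envelope is not None:
        envelope = np.asarray(envelope, dtype=float)
        if envelope.shape != (n_samples,):
            raise ValueError("envelope must have one value per sample")
        emg = emg * envelope[None, :]
        drive = drive * envelope

    # Torque: smoothed total activation x gain (+ measurement noise).
    sos = sps.butter(2, 2.0, btype="lowpass", fs=cfg.fs, output="sos")
    smoothed = np.clip(sps.sosfiltfilt(sos, drive), 0.0, None)
    torque = cfg.torque_gain * smoothed
    if cfg.torque_noise_nm > 0:
        torque = torque + cfg.torque_noise_nm * noise_rng.standard_normal(n_samples)

    rec = MonopolarRecording(samples=emg, fs=cfg.fs, geometry=cfg.grid, torque=torque)
    gt = SyntheticGroundTruth(
        mu_centers=centers,
        mu_amplitudes=amplitudes,
        active_sets=active_sets,
        expected_channel_power=expected_power,
        torque_peak_nm=float(np.max(torque)),
    )
    return rec, gt


def _pipeline_entropy_cv(rec: MonopolarRecording) -> tuple[float, float]:
    """Run the full analysis pipeline on one recording; return (E, CV)."""
    from .preprocess import bandpass, midpoint_epoch, single_differential
    from .spatial_features import activation_map, coefficient_of_variation, modified_entropy

    filtered = bandpass(rec)
    bipolar = single_differential(filtered)
    epoch = midpoint_epoch(bipolar, 0.0, rec.duration)
    amap = activation_map(epoch)
    return modified_entropy(amap), coefficient_of_variation(amap)


def sweep_clustering(
    kappas, config: SyntheticConfig | None = None, n_reps: int = 20
) -> pd.DataFrame:
    """Entropy and CV versus the clustering parameter κ.

    Runs the full pipeline (band-pass, single differential, midpoint
    epoch, activation map) per replicate, with replicate seeds paired
    across κ values so differences are attributable to clustering alone.
    Returns one row per κ with mean ± sd of entropy and CV.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = config or SyntheticConfig()
    rows = []
    for kappa in kappas:
        ent, cv = [], []
        for rep in range(n_reps):
            rep_cfg = replace(cfg, clustering=float(kappa), seed=cfg.seed + rep)
            rec, _ = simulate(rep_cfg)
            e, c = _pipeline_entropy_cv(rec)
            ent.append(e)
            cv.append(c)
        rows.append(
            {
                "kappa": float(kappa),
                "entropy_mean": float(np.mean(ent)),
                "entropy_sd": float(np.std(ent, ddof=1)) if n_reps > 1 else 0.0,
                "cv_mean": float(np.mean(cv)),
                "cv_sd": float(np.std(cv, ddof=1)) if n_reps > 1 else 0.0,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_GROUPS = (("young", "male"), ("young", "female"), ("older", "male"), ("older", "female"))


def iter_cohort(
    group_specs: dict[tuple[str, str], dict] | None = None,
    n_per_group: int = 10,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
    include_isokinetic: bool = True,
):
    """Yield (meta, recording, ground_truth) for every subject x condition.

    ``group_specs`` maps (age_group, sex) to SyntheticConfig field
    overrides (e.g. a lower ``torque_gain`` for older groups or a
    ``clustering`` offset between sexes); omitted groups use the base
    config. Conditions are the four isometric levels plus, optionally, an
    isokinetic cycle whose activation envelope peaks at the cycle midpoint.
    """
    base = base_config or SyntheticConfig()
    specs = group_specs or {}
    subject = 0
    for g_idx, group in enumerate(DEFAULT_GROUPS):
        overrides = specs.get(group, {})
        for s_idx in range(n_per_group):
            subject += 1
            # One substream per subject, stable under reordering of groups.
            subj_seed = (seed * 100003 + g_idx * 1009 + s_idx * 7 + 1) % (2**31 - 1)
            subj_cfg = replace(base, **overrides, seed=subj_seed)
            meta_base = {
                "subject": f"S{subject:03d}",
                "age_group": group[0],
                "sex": group[1],
            }
            for level in LEVELS:
                cfg = replace(subj_cfg, level=level, seed=subj_seed + level)
                rec, gt = simulate(cfg)
                yield {**meta_base, "contraction": "isometric", "level": level}, rec, gt
            if include_isokinetic:
                cfg = replace(subj_cfg, level=100, seed=subj_seed + 999)
                n = round(cfg.duration_s * cfg.fs)
                env = np.sin(np.pi * np.arange(n) / n) ** 2  # peak at the cycle midpoint
                rec, gt = simulate(cfg, envelope=env)
                yield {**meta_base, "contraction": "isokinetic", "level": "isokinetic"}, rec, gt


def simulate_cohort(
    group_specs: dict[tuple[str, str], dict] | None = None,
    n_per_group: int = 10,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
    include_isokinetic: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full 2 age x 2 sex cohort and run the feature pipeline.

    Returns ``(features, ground_truth)``: a long feature table with one row
    per (subject, contraction, level, feature) ready for the stats module,
    and a per-recording ground-truth table (injected torque peak, κ).
    Recordings are processed streamingly; use :func:`iter_cohort` to access
    the raw signals.
    """
    from .pipeline import features_from_recording

    feat_rows, gt_rows = [], []
    for meta, rec, gt in iter_cohort(
        group_specs, n_per_group, seed, base_config, include_isokinetic
    ):
        feats = features_from_recording(rec)
        for name, value in feats.as_dict().items():
            feat_rows.append({**meta, "feature": name, "value": value})
        gt_rows.append({**meta, "torque_peak_nm": gt.torque_peak_nm})
    return pd.DataFrame(feat_rows), pd.DataFrame(gt_rows)
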