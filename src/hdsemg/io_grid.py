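"""Grid geometry, recording I/O and feature-table serialization.

The native on-disk dialect is a plain delimited matrix (CSV/TSV) with a
sidecar metadata file (JSON or YAML) carrying ``fs_hz``, ``orientation``,
``units``, ``missing_positions`` and optionally an explicit channel map,
plus an HDF5 container with datasets ``emg``/``torque`` and an ``fs_hz``
attribute. Vendor binary formats are out of scope; `load_recording` is the
single entry point so other readers can be plugged in front of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GridGeometry",
    "MonopolarRecording",
    "make_default_geometry",
    "default_channel_map",
    "validate_channel_map",
    "load_recording",
    "save_recording",
    "load_sidecar",
    "write_features_table",
    "read_features_table",
]

#: Columns written by :func:`write_features_table`, in order.
FEATURE_COLUMNS = (
    "mean_rms_mv",
    "intensity",
    "mean_di",
    "entropy_bits",
    "cv_pct",
)
KEY_COLUMNS = ("subject", "age_group", "sex", "contraction", "level")


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid layout: rows x columns with optional unpopulated sites.

    The default research grid has 13 rows and 5 columns (65 sites) but only
    64 physical electrodes; the absent site is configurable and defaults to
    the (0, 0) corner. Columns run along the muscle-fiber direction.
    """

    n_rows: int = 13
    n_cols: int = 5
    missing: tuple[tuple[int, int], ...] = ((0, 0),)
    column_axis_is_fiber_direction: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 1:
            raise ValueError("grid must have at least 2 rows and 1 column")
        seen = set()
        for r, c in self.missing:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"missing position {(r, c)} outside {self.n_rows}x{self.n_cols} grid")
            if (r, c) in seen:
                raise ValueError(f"duplicate missing position {(r, c)}")
            seen.add((r, c))

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols - len(self.missing)

    def positions(self) -> list[tuple[int, int]]:
        """Populated (row, col) positions in column-major order."""
        miss = set(self.missing)
        return [
            (r, c)
            for c in range(self.n_cols)
            for r in range(self.n_rows)
            if (r, c) not in miss
        ]

    def is_populated(self, row: int, col: int) -> bool:
        return (row, col) not in set(self.missing) and 0 <= row < self.n_rows and 0 <= col < self.n_cols


def make_default_geometry(missing: Sequence[tuple[int, int]] = ((0, 0),)) -> GridGeometry:
    """The 13x5 grid with one unpopulated corner site (64 electrodes).

    Any single missing end-of-column site yields the canonical 59
    single-differential channels; the corner is the conventional choice.
    """
    return GridGeometry(n_rows=13, n_cols=5, missing=tuple(tuple(p) for p in missing))


def default_channel_map(geometry: GridGeometry) -> tuple[tuple[int, int], ...]:
    """Electrode index -> (row, col), column-major over populated sites."""
    return tuple(geometry.positions())


def validate_channel_map(
    geometry: GridGeometry, channel_map: Sequence[tuple[int, int]]
) -> None:
    """Check that the map is a bijection onto the populated grid sites."""
    positions = [tuple(p) for p in channel_map]
    miss = set(geometry.missing)
    for pos in positions:
        r, c = pos
        if not (0 <= r < geometry.n_rows and 0 <= c < geometry.n_cols):
            raise ValueError(f"channel maps to out-of-bounds position {pos}")
        if pos in miss:
            raise ValueError(f"channel maps to missing grid position {pos}")
    if len(set(positions)) != len(positions):
        raise ValueError("channel map assigns two electrodes to one grid position")
    if len(positions) != geometry.n_electrodes:
        raise ValueError(
            f"channel map covers {len(positions)} electrodes; geometry has {geometry.n_electrodes}"
        )


@dataclass
class MonopolarRecording:
    """Multichannel monopolar EMG (mV) with optional synchronized torque (Nm)."""

    samples: np.ndarray  # [n_electrodes, n_samples], mV
    fs: float  # Hz
    geometry: GridGeometry
    channel_map: tuple[tuple[int, int], ...] | None = None
    torque: np.ndarray | None = None  # [n_samples], Nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [channels x samples] array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_map is None:
            self.channel_map = default_channel_map(self.geometry)
        else:
            self.channel_map = tuple(tuple(p) for p in self.channel_map)
        validate_channel_map(self.geometry, self.channel_map)
        if self.samples.shape[0] != self.geometry.n_electrodes:
            raise ValueError(
                f"expected {self.geometry.n_electrodes} channels for this geometry, "
                f"found {self.samples.shape[0]}"
            )
        if self.torque is not None:
            self.torque = np.asarray(self.torque, dtype=float)
            if self.torque.shape != (self.samples.shape[1],):
                raise ValueError("torque and EMG must share the sample count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def position_index(self) -> dict[tuple[int, int], int]:
        """(row, col) -> electrode index."""
        return {pos: i for i, pos in enumerate(self.channel_map)}


# ---------------------------------------------------------------------------
# Recording I/O


def load_sidecar(path: str | Path) -> dict:
    """Read a JSON or YAML metadata sidecar."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def _geometry_from_meta(meta: Mapping) -> GridGeometry:
    missing = tuple(tuple(p) for p in meta.get("missing_positions", [(0, 0)]))
    return GridGeometry(
        n_rows=int(meta.get("n_rows", 13)),
        n_cols=int(meta.get("n_cols", 5)),
        missing=missing,
    )


def load_recording(
    path: str | Path,
    geometry: GridGeometry | None = None,
    meta: Mapping | str | Path | None = None,
) -> MonopolarRecording:
    """Load a monopolar grid recording from CSV/TSV (+ sidecar) or HDF5.

    ``meta`` may be a mapping or a path to a JSON/YAML sidecar; for text
    matrices it must declare ``fs_hz`` and may declare ``orientation``
    (``channels_x_samples``, the normalized layout, or ``samples_x_channels``),
    ``channel_map`` and ``missing_positions``. HDF5 containers carry
    ``fs_hz`` as an attribute on the ``emg`` dataset or the file.
    """
    path = Path(path)
    if isinstance(meta, (str, Path)):
        meta = load_sidecar(meta)
    meta = dict(meta or {})

    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            emg = np.asarray(f["emg"], dtype=float)
            fs = float(f["emg"].attrs.get("fs_hz", f.attrs.get("fs_hz", meta.get("fs_hz", 0))))
            torque = np.asarray(f["torque"], dtype=float) if "torque" in f else None
    else:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        try:
            emg = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse numeric matrix from {path}: {exc}") from exc
        fs = float(meta.get("fs_hz", 0))
        torque = None
        if meta.get("torque_path"):
            torque = np.loadtxt(Path(meta["torque_path"]), delimiter=delimiter)
    if fs <= 0:
        raise ValueError("sampling rate fs_hz must be supplied and positive")

    if meta.get("orientation", "channels_x_samples") == "samples_x_channels":
        emg = emg.T

    if geometry is None:
        geometry = _geometry_from_meta(meta)
    if emg.shape[0] != geometry.n_electrodes:
        raise ValueError(
            f"channel count mismatch: geometry expects {geometry.n_electrodes} "
            f"electrodes, file has {emg.shape[0]} channels"
        )
    channel_map = meta.get("channel_map")
    if channel_map is not None:
        channel_map = tuple(tuple(p) for p in channel_map)
    return MonopolarRecording(
        samples=emg, fs=fs, geometry=geometry, channel_map=channel_map, torque=torque
    )


def save_recording(rec: MonopolarRecording, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a recording in the native dialect (suffix selects the format).

    ``.h5``/``.hdf5`` writes an HDF5 container; anything else writes a
    delimited text matrix plus a JSON sidecar (default ``<path>.meta.json``).
    Returns the data path.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("emg", data=rec.samples)
            d.attrs["fs_hz"] = rec.fs
            d.attrs["units"] = "mV"
            if rec.torque is not None:
                t = f.create_dataset("torque", data=rec.torque)
                t.attrs["units"] = "Nm"
        return path
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    np.savetxt(path, rec.samples, delimiter=delimiter)
    meta = {
        "fs_hz": rec.fs,
        "orientation": "channels_x_samples",
        "units": {"emg": "mV", "torque": "Nm"},
        "n_rows": rec.geometry.n_rows,
        "n_cols": rec.geometry.n_cols,
        "missing_positions": [list(p) for p in rec.geometry.missing],
        "channel_map": [list(p) for p in rec.channel_map],
    }
    if rec.torque is not None:
        torque_path = path.with_suffix(".torque" + path.suffix)
        np.savetxt(torque_path, rec.torque, delimiter=delimiter)
        meta["torque_path"] = str(torque_path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# Feature tables


def write_features_table(records: Sequence[tuple[Mapping, "object"]], path: str | Path) -> Path:
    """Write one row per (subject, contraction, level) of scalar features.

    ``records`` is a sequence of ``(labels, features)`` pairs where
    ``labels`` supplies the key columns (at least ``subject``,
    ``contraction``, ``level``) and ``features`` is a
    :class:`~hdsemg.spatial_features.SpatialFeatures` (or any object with
    an ``as_dict`` method producing the feature columns).
    """
    if not records:
        raise ValueError("no feature records to write")
    rows = []
    for labels, feats in records:
        row = {k: labels.get(k) for k in KEY_COLUMNS}
        row.update(feats.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_COLUMNS))
    keys = df[["subject", "contraction", "level"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, contraction, level) keys: {dupes}")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
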