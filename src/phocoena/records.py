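"""Sensor and kinematic series containers with CSV / NetCDF round-trips.

Conventions: depth in metres positive down, acceleration in m s^-2 in the
tag frame (x forward, y left, z up), time in seconds from deployment start.
Uniform sampling at ``fs``; a trimmed record keeps its original time base
(``t_start`` > 0 after first-hour removal), times are never re-zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorRecord", "KinematicSeries"]


def _meta_header(meta: dict) -> str:
    return "".join(f"# {k}={json.dumps(v)}\n" for k, v in meta.items())


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].strip().partition("=")
            meta[key.strip()] = json.loads(raw)
    return meta


@dataclass
class SensorRecord:
    """Calibrated depth + triaxial acceleration series for one deployment."""

    fs: float
    depth: np.ndarray
    acc: np.ndarray  # (n, 3)
    animal_id: str = "synthetic"
    body_length_m: float = 1.31
    t_start: float = 0.0

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.acc.shape[0] != self.depth.shape[0]:
            raise ValueError("depth and acc lengths differ")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return self.depth.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t_start + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "depth_m": self.depth,
                "acc_x": self.acc[:, 0],
                "acc_y": self.acc[:, 1],
                "acc_z": self.acc[:, 2],
            }
        )

    def _meta(self) -> dict:
        return {
            "fs": self.fs,
            "animal_id": self.animal_id,
            "body_length_m": self.body_length_m,
            "t_start": self.t_start,
        }

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_meta_header(self._meta()))
            self.to_frame().drop(columns="time_s").to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorRecord":
        meta = _read_meta(path)
        df = pd.read_csv(path, comment="#")
        return cls(
            fs=meta["fs"],
            depth=df["depth_m"].to_numpy(),
            acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
            animal_id=meta.get("animal_id", "unknown"),
            body_length_m=meta.get("body_length_m", 1.31),
            t_start=meta.get("t_start", 0.0),
        )

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {
                "depth": ("time", self.depth),
                "acc_x": ("time", self.acc[:, 0]),
                "acc_y": ("time", self.acc[:, 1]),
                "acc_z": ("time", self.acc[:, 2]),
            },
            coords={"time": self.time},
            attrs={
                "fs": self.fs,
                "animal_id": self.animal_id,
                "body_length_m": self.body_length_m,
                "t0": self.t_start,
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "SensorRecord":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            acc = np.column_stack(
                [ds["acc_x"].values, ds["acc_y"].values, ds["acc_z"].values]
            )
            return cls(
                fs=float(ds.attrs["fs"]),
                depth=ds["depth"].values.copy(),
                acc=acc,
                animal_id=str(ds.attrs.get("animal_id", "unknown")),
                body_length_m=float(ds.attrs.get("body_length_m", 1.31)),
                t_start=float(ds.attrs.get("t0", 0.0)),
            )


@dataclass
class KinematicSeries:
    """Derived kinematics: depth, MSA, pitch, roll on a shared time base."""

    fs: float
    depth: np.ndarray
    msa: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    t_start: float = 0.0
    animal_id: str = "synthetic"
    body_length_m: float = 1.31
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.depth)
        for name in ("msa", "pitch", "roll"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from depth")

    @property
    def n(self) -> int:
        return len(self.depth)

    @property
    def time(self) -> np.ndarray:
        return self.t_start + np.arange(self.n) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "depth_m": self.depth,
                "msa": self.msa,
                "pitch_rad": self.pitch,
                "roll_rad": self.roll,
            }
        )

    def to_csv(self, path) -> None:
        meta = {
            "fs": self.fs,
            "animal_id": self.animal_id,
            "body_length_m": self.body_length_m,
            "t_start": self.t_start,
        }
        with open(path, "w") as fh:
            fh.write(_meta_header(meta))
            self.to_frame().drop(columns="time_s").to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "KinematicSeries":
        meta = _read_meta(path)
        df = pd.read_csv(path, comment="#")
        return cls(
            fs=meta["fs"],
            depth=df["depth_m"].to_numpy(),
            msa=df["msa"].to_numpy(),
            pitch=df["pitch_rad"].to_numpy(),
            roll=df["roll_rad"].to_numpy(),
            t_start=meta.get("t_start", 0.0),
            animal_id=meta.get("animal_id", "unknown"),
            body_length_m=meta.get("body_length_m", 1.31),
        )

    def slice_time(self, start: float, end: float) -> tuple[int, int]:
        """Index range [i0, i1) of samples with start <= t < end."""
        i0 = int(np.searchsorted(self.time, start, side="left"))
        i1 = int(np.searchsorted(self.time, end, side="left"))
        return i0, i1
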