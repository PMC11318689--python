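"""Sensor preparation: decimation, MSA, pitch/roll, winsorizing, trimming.

MSA (minimum specific acceleration) is ``| ||a|| - g |``: the absolute
difference between the norm of measured acceleration and gravity. It is a
lower bound on the magnitude of the specific (non-gravitational)
acceleration and serves as the activity proxy throughout the pipeline.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.signal
import scipy.stats

from .records import KinematicSeries, SensorRecord

G_STANDARD = 9.81

__all__ = [
    "decimate_series",
    "compute_msa",
    "trim_upper_percentile",
    "estimate_pitch_roll",
    "circular_variance",
    "trim_deployment_start",
    "prepare_kinematics",
]


def decimate_series(x: np.ndarray, fs_in: float, fs_out: float = 25.0) -> np.ndarray:
    """Anti-alias filter and resample from fs_in to fs_out (fs_in >= fs_out).

    Works along the first axis; output length is ceil(n * fs_out / fs_in).
    """
    if fs_in < fs_out:
        raise ValueError(f"fs_in ({fs_in}) must be >= fs_out ({fs_out})")
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    return scipy.signal.resample_poly(
        np.asarray(x, dtype=float), up, down, axis=0, padtype="line"
    )


def compute_msa(acc: np.ndarray, g: float = G_STANDARD) -> np.ndarray:
    """MSA(t) = | ||a(t)||_2 - g |, rotation invariant and >= 0."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:
        acc = acc[None, :]
    return np.abs(np.linalg.norm(acc, axis=-1) - g)


def trim_upper_percentile(x: np.ndarray, p: float = 95.0) -> np.ndarray:
    """Winsorize: replace values above the p-th percentile with that value.

    The percentile uses linear interpolation between order statistics and is
    computed over the whole series (transient spikes are a record-level
    artifact). Length-preserving and idempotent.
    """
    if not 0 < p < 100:
        raise ValueError("percentile must lie in (0, 100)")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    cap = np.nanpercentile(x, p)
    return np.minimum(x, cap)


def estimate_pitch_roll(
    acc: np.ndarray, fs: float, smooth_s: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation angles from the gravity-dominated (low-passed) acceleration.

    pitch = -asin(a_x / ||a||) in [-pi/2, pi/2]; roll = atan2(a_y, a_z) in
    (-pi, pi]. Tag frame x forward, y left, z up. The low-pass is a moving
    average of ``smooth_s`` seconds separating orientation from stroking.
    Samples with zero norm are flagged NaN.
    """
    acc = np.asarray(acc, dtype=float)
    win = max(int(round(smooth_s * fs)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        sm = np.column_stack(
            [np.convolve(acc[:, i], kernel, mode="same") for i in range(3)]
        )
    else:
        sm = acc
    norm = np.linalg.norm(sm, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = -np.arcsin(np.clip(sm[:, 0] / norm, -1.0, 1.0))
        roll = np.arctan2(sm[:, 1], sm[:, 2])
    bad = norm == 0
    pitch[bad] = np.nan
    roll[bad] = np.nan
    return pitch, roll


def circular_variance(angles) -> float:
    """1 - mean resultant length of the unit vectors (cos, sin); in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("circular_variance of an empty angle list")
    return float(scipy.stats.circvar(angles))


def trim_deployment_start(record: SensorRecord, cut: float = 3600.0) -> SensorRecord:
    """Drop all samples with t < cut (handling artifacts); times keep their base."""
    t = record.time
    if t[-1] <= cut:
        raise ValueError(
            f"record ends at {t[-1]:.1f} s, shorter than the {cut:.0f} s cut; "
            "nothing would remain after trimming"
        )
    i0 = int(np.searchsorted(t, cut, side="left"))
    return SensorRecord(
        fs=record.fs,
        depth=record.depth[i0:].copy(),
        acc=record.acc[i0:].copy(),
        animal_id=record.animal_id,
        body_length_m=record.body_length_m,
        t_start=float(t[i0]),
    )


def prepare_kinematics(
    record: SensorRecord,
    cut: float = 3600.0,
    fs_out: float = 25.0,
    winsor_p: float = 95.0,
    pitch_smooth_s: float = 5.0,
) -> KinematicSeries:
    """Full preparation stage: trim start, decimate, MSA (winsorized), angles."""
    rec = trim_deployment_start(record, cut=cut) if cut > 0 else record
    if rec.fs != fs_out:
        depth = decimate_series(rec.depth, rec.fs, fs_out)
        acc = decimate_series(rec.acc, rec.fs, fs_out)
        rec = SensorRecord(
            fs=fs_out,
            depth=depth,
            acc=acc,
            animal_id=rec.animal_id,
            body_length_m=rec.body_length_m,
            t_start=rec.t_start,
        )
    msa = trim_upper_percentile(compute_msa(rec.acc), winsor_p)
    pitch, roll = estimate_pitch_roll(rec.acc, rec.fs, pitch_smooth_s)
    return KinematicSeries(
        fs=rec.fs,
        depth=rec.depth,
        msa=msa,
        pitch=pitch,
        roll=roll,
        t_start=rec.t_start,
        animal_id=rec.animal_id,
        body_length_m=rec.body_length_m,
    )
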