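"""Per-dive HMM input metrics, dive cycles, and unit-interval squeezing.

Eight metrics summarize each dive for the behavioral-state model:
log mean MSA (Gaussian), median buzz depth relative to maximum dive depth
(beta; missing when the dive has no buzz), circular variance of pitch and
of roll (beta), proportions of time at the bottom and near the surface
(beta; depth bands of one and two body lengths), circular variance of
pitch during the bottom phase (beta; missing when there is none), and
presence/absence of a buzz (Bernoulli).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import KinematicSeries
from .sensor import circular_variance

__all__ = [
    "METRIC_COLUMNS",
    "BETA_METRICS",
    "compute_metrics",
    "compute_all_metrics",
    "build_dive_cycles",
    "squeeze_unit_interval",
    "squeeze_metrics",
]

METRIC_COLUMNS = [
    "log_mean_msa",
    "rel_buzz_depth",
    "circ_var_pitch",
    "circ_var_roll",
    "prop_bottom",
    "prop_surface",
    "circ_var_pitch_bottom",
    "buzz_present",
]
BETA_METRICS = METRIC_COLUMNS[1:7]

_EPS = 1e-9


def squeeze_unit_interval(x, n: int):
    """Map [0, 1] onto the open interval via (x*(n-1) + 0.5)/n.

    Standard compression for beta-distributed responses observed at the
    support boundary; 0.5 is a fixed point for every n.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (x < -_EPS) | (x > 1 + _EPS)
    if np.any(bad[np.isfinite(x)]):
        raise ValueError("squeeze_unit_interval requires values in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = (np.clip(x, 0.0, 1.0) * (n - 1) + 0.5) / n
    return out if out.ndim else float(out)


def compute_metrics(
    dive_start: float,
    dive_end: float,
    buzzes: pd.DataFrame,
    kin: KinematicSeries,
    body_length: float,
) -> dict:
    """Metric vector for one dive (half-open [start, end) interval).

    ``buzzes`` must carry median_depth_m and are attributed by midpoint.
    Missing values (no buzz / no bottom phase) are NaN.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    i0, i1 = kin.slice_time(dive_start, dive_end)
    if i1 <= i0:
        raise ValueError("dive contains no samples")
    depth = kin.depth[i0:i1]
    msa = kin.msa[i0:i1]
    pitch = kin.pitch[i0:i1]
    roll = kin.roll[i0:i1]
    max_depth = float(depth.max())
    bottom = depth >= max_depth - body_length
    surface = depth <= 2.0 * body_length

    mids = (buzzes["start_s"].to_numpy() + buzzes["end_s"].to_numpy()) / 2.0 if len(buzzes) else np.empty(0)
    in_dive = (mids >= dive_start) & (mids < dive_end)
    n_buzz = int(in_dive.sum())
    if n_buzz:
        rel = buzzes["median_depth_m"].to_numpy()[in_dive] / max_depth
        rel_buzz_depth = float(np.clip(np.median(rel), _EPS, 1.0 - _EPS))
    else:
        rel_buzz_depth = np.nan

    mean_msa = float(np.nanmean(msa))
    return {
        "log_mean_msa": np.log(max(mean_msa, _EPS)),
        "rel_buzz_depth": rel_buzz_depth,
        "circ_var_pitch": circular_variance(pitch),
        "circ_var_roll": circular_variance(roll),
        "prop_bottom": float(bottom.mean()),
        "prop_surface": float(surface.mean()),
        "circ_var_pitch_bottom": (
            circular_variance(pitch[bottom]) if np.isfinite(pitch[bottom]).any() else np.nan
        ),
        "buzz_present": float(n_buzz > 0),
    }


def compute_all_metrics(
    dives: pd.DataFrame,
    buzzes: pd.DataFrame,
    kin: KinematicSeries,
    body_length: float | None = None,
) -> pd.DataFrame:
    """Metric table for every row of ``dives`` (columns start_s / end_s)."""
    body_length = body_length if body_length is not None else kin.body_length_m
    rows = [
        compute_metrics(r.start_s, r.end_s, buzzes, kin, body_length)
        for r in dives.itertuples()
    ]
    out = pd.DataFrame(rows, columns=METRIC_COLUMNS, index=dives.index)
    return out


def squeeze_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Apply the unit-interval squeeze to every beta-bound metric column.

    n is the pooled non-missing count per metric so that shared emissions
    see one consistent support compression.
    """
    out = metrics.copy()
    for col in BETA_METRICS:
        vals = out[col].to_numpy(dtype=float)
        n = int(np.isfinite(vals).sum())
        if n >= 1:
            mask = np.isfinite(vals)
            vals[mask] = squeeze_unit_interval(vals[mask], n)
            out[col] = vals
    return out


def build_dive_cycles(
    dives: pd.DataFrame,
    resp_times: np.ndarray,
    buzzes: pd.DataFrame,
) -> pd.DataFrame:
    """Dive-cycle table: each dive plus its surface time to the next dive.

    One cycle per dive except the last. Respirations are counted in the
    half-open [dive_start, next_dive_start); buzzes by midpoint in the same
    window. Rates are per minute: respiration rate over cycle duration,
    buzz rate over dive duration (the denominators the field uses).
    """
    dv = dives.sort_values("start_s")
    starts = dv["start_s"].to_numpy(dtype=float)
    ends = dv["end_s"].to_numpy(dtype=float)
    if np.any(ends[:-1] > starts[1:]):
        raise ValueError("overlapping dives")
    resp_times = np.asarray(resp_times, dtype=float)
    mids = (
        (buzzes["start_s"].to_numpy() + buzzes["end_s"].to_numpy()) / 2.0
        if len(buzzes)
        else np.empty(0)
    )
    rows = []
    for k in range(len(dv) - 1):
        c0, c1 = starts[k], starts[k + 1]
        dive_dur = ends[k] - starts[k]
        n_resp = int(np.sum((resp_times >= c0) & (resp_times < c1)))
        n_buzz = int(np.sum((mids >= c0) & (mids < c1)))
        rows.append(
            (
                dv.index[k],
                c0,
                c1,
                c1 - c0,
                dive_dur,
                n_resp,
                n_resp / ((c1 - c0) / 60.0),
                n_buzz,
                n_buzz / (dive_dur / 60.0) if dive_dur > 0 else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dive_id",
            "dive_start_s",
            "next_dive_start_s",
            "cycle_duration_s",
            "dive_duration_s",
            "n_respirations",
            "resp_rate_per_min",
            "n_buzzes",
            "buzz_rate_per_min",
        ],
    )
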