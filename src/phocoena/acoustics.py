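"""Echolocation click detection and buzz assembly.

A buzz — the terminal phase of a prey-capture attempt — is a click series
with inter-click intervals (ICIs) below 10 ms for at least five consecutive
clicks, lasting at least 0.2 s and containing more than 100 clicks.
Validated buzzes closer than 1 s are merged to avoid double-counting
prolonged chases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

log = logging.getLogger(__name__)

__all__ = ["detect_clicks", "assemble_buzzes", "assign_buzzes_to_dives", "attach_buzz_depth"]

BUZZ_COLUMNS = ["start_s", "end_s", "n_clicks"]


def detect_clicks(
    envelope: np.ndarray,
    fs: float,
    noise_window: float = 0.5,
    threshold_margin: float = 15.0,
    floor_db: float = -60.0,
    blanking: float = 0.001,
) -> pd.DataFrame:
    """Peak-pick clicks from a linear signal envelope (units of clip level).

    A sample is a click iff it is a local maximum, its level in dB re clip
    exceeds max(noise + margin, floor), and it falls at least ``blanking``
    seconds after the previously accepted click (dismisses surface
    reflections). The noise estimate is a running median of the envelope
    over ``noise_window`` seconds, robust to click contamination.

    Returns a DataFrame with columns ``time_s`` and ``amp_db``.
    """
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if fs * blanking < 2:
        raise ValueError(f"fs={fs} too low: blanking window must span >= 2 samples")
    win = int(round(noise_window * fs))
    win += 1 - win % 2  # odd
    noise = scipy.ndimage.median_filter(env, size=max(win, 3), mode="nearest")
    with np.errstate(divide="ignore"):
        env_db = 20.0 * np.log10(env)
        noise_db = 20.0 * np.log10(noise)
    thresh = np.maximum(noise_db + threshold_margin, floor_db)
    peaks, _ = scipy.signal.find_peaks(env)
    peaks = peaks[env_db[peaks] > thresh[peaks]]
    times, amps = [], []
    last = -np.inf
    for p in peaks:
        t = p / fs
        if t - last >= blanking:
            times.append(t)
            amps.append(env_db[p])
            last = t
    return pd.DataFrame({"time_s": times, "amp_db": amps})


def band_envelope(
    audio: np.ndarray,
    fs: float,
    band: tuple[float, float] = (100e3, 240e3),
    order: int = 4,
) -> np.ndarray:
    """Band-pass (4-pole Butterworth) then Hilbert-magnitude envelope."""
    sos = scipy.signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, np.asarray(audio, dtype=float))
    return np.abs(scipy.signal.hilbert(filtered))


def assemble_buzzes(
    click_times: np.ndarray,
    max_ici: float = 0.010,
    min_run: int = 5,
    min_dur: float = 0.2,
    min_clicks: int = 101,
    merge_gap: float = 1.0,
) -> pd.DataFrame:
    """Assemble clicks into validated buzzes.

    Rules, applied in order: (i) partition into maximal runs whose internal
    ICIs are all < ``max_ici``; (ii) discard runs with fewer than
    ``min_run`` clicks; (iii) retain runs with duration >= ``min_dur`` and
    at least ``min_clicks`` clicks; (iv) merge retained runs separated by
    less than ``merge_gap`` (spans unioned, counts summed). Thresholding
    precedes merging.
    """
    t = np.asarray(click_times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("click times must be strictly increasing")
    if t.size == 0:
        return pd.DataFrame(columns=BUZZ_COLUMNS).astype(
            {"start_s": float, "end_s": float, "n_clicks": int}
        )
    # (i) split where ICI >= max_ici
    breaks = np.nonzero(np.diff(t) >= max_ici)[0] + 1
    runs = np.split(t, breaks)
    # (ii) + (iii)
    kept = [
        r
        for r in runs
        if r.size >= min_run and (r[-1] - r[0]) >= min_dur and r.size >= min_clicks
    ]
    # (iv) merge close runs
    buzzes: list[list[float]] = []
    for r in kept:
        if buzzes and (r[0] - buzzes[-1][1]) < merge_gap:
            buzzes[-1][1] = r[-1]
            buzzes[-1][2] += r.size
        else:
            buzzes.append([r[0], r[-1], r.size])
    return pd.DataFrame(buzzes, columns=BUZZ_COLUMNS).astype(
        {"start_s": float, "end_s": float, "n_clicks": int}
    )


def attach_buzz_depth(buzzes: pd.DataFrame, depth: np.ndarray, time: np.ndarray, fs: float) -> pd.DataFrame:
    """Add ``median_depth_m``: depth at the buzz temporal midpoint (nearest sample).

    Buzzes outside the depth record are dropped with a log message.
    """
    out = buzzes.copy()
    mids = (out["start_s"].to_numpy() + out["end_s"].to_numpy()) / 2.0
    t0, t1 = time[0], time[-1]
    inside = (mids >= t0) & (mids <= t1)
    if not inside.all():
        log.warning("dropping %d buzzes outside the depth record", int((~inside).sum()))
    out = out.loc[inside].copy()
    idx = np.clip(np.round((out["start_s"] + out["end_s"]).to_numpy() / 2.0 * fs - t0 * fs), 0, len(depth) - 1).astype(int)
    out["median_depth_m"] = depth[idx]
    return out


def assign_buzzes_to_dives(buzzes: pd.DataFrame, dives: pd.DataFrame) -> pd.DataFrame:
    """Attribute each buzz to the dive (half-open [start, end)) holding its midpoint.

    ``dives`` needs columns start_s/end_s; adds a ``dive_id`` column (the
    dive row index, or -1 for buzzes outside any dive).
    """
    out = buzzes.copy()
    mids = (out["start_s"].to_numpy() + out["end_s"].to_numpy()) / 2.0
    starts = dives["start_s"].to_numpy()
    ends = dives["end_s"].to_numpy()
    ids = np.full(len(out), -1, dtype=int)
    pos = np.searchsorted(starts, mids, side="right") - 1
    ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, len(ends) - 1)])
    ids[ok] = dives.index.to_numpy()[pos[ok]]
    out["dive_id"] = ids
    return out
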