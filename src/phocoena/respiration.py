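"""Respiration detection, interbreath intervals, and dive/apnea separation.

Respirations are detectable from the depth trace alone: each maximal
surfacing (depth < 0.5 m) yields one candidate breath at its minimum-depth
sample. The record between consecutive respirations tiles into interbreath
intervals (IBIs); a Gaussian multivariate mixture on log duration, log
maximum depth and log mean MSA separates true dives from shallow apneas.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .records import KinematicSeries

log = logging.getLogger(__name__)

__all__ = ["detect_respirations", "build_ibis", "classify_dives"]

IBI_COLUMNS = ["start_s", "end_s", "duration_s", "max_depth_m", "mean_msa"]


def detect_respirations(
    depth: np.ndarray,
    fs: float,
    t_start: float = 0.0,
    surface_threshold: float = 0.5,
    min_iri: float = 0.4,
) -> np.ndarray:
    """Respiration times (s) from a uniformly sampled depth trace.

    One candidate per maximal segment with depth < ``surface_threshold``,
    placed at the minimum-depth sample (earliest on ties); candidates
    closer than ``min_iri`` to the previously accepted one are dropped.
    """
    depth = np.asarray(depth, dtype=float)
    at_surface = depth < surface_threshold
    if not at_surface.any():
        warnings.warn("no samples above the surface threshold; no respirations")
        return np.empty(0)
    edges = np.diff(at_surface.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if at_surface[0]:
        starts = np.r_[0, starts]
    if at_surface[-1]:
        ends = np.r_[ends, len(depth)]
    times = []
    last = -np.inf
    for s, e in zip(starts, ends):
        idx = s + int(np.argmin(depth[s:e]))  # argmin returns the first minimum
        t = t_start + idx / fs
        if t - last >= min_iri:
            times.append(t)
            last = t
    return np.asarray(times)


def build_ibis(resp_times: np.ndarray, kin: KinematicSeries) -> pd.DataFrame:
    """One IBI per consecutive respiration pair, half-open [start, end).

    max_depth and mean (winsorized) MSA are computed over the samples in
    each interval. With fewer than two respirations the table is empty.
    """
    resp_times = np.asarray(resp_times, dtype=float)
    if resp_times.size < 2:
        return pd.DataFrame(columns=IBI_COLUMNS)
    time = kin.time
    idx = np.searchsorted(time, resp_times, side="left")
    rows = []
    for k in range(resp_times.size - 1):
        i0, i1 = idx[k], idx[k + 1]
        seg_depth = kin.depth[i0:i1]
        seg_msa = kin.msa[i0:i1]
        rows.append(
            (
                resp_times[k],
                resp_times[k + 1],
                resp_times[k + 1] - resp_times[k],
                float(seg_depth.max()) if seg_depth.size else 0.0,
                float(np.nanmean(seg_msa)) if seg_msa.size else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=IBI_COLUMNS)


def _log_features(ibis: pd.DataFrame) -> np.ndarray:
    feats = ibis[["duration_s", "max_depth_m", "mean_msa"]].to_numpy(dtype=float)
    out = np.empty_like(feats)
    for j in range(3):
        col = feats[:, j].copy()
        if np.all(col == col[0]):
            raise ValueError(
                f"degenerate feature {j}: zero variance, mixture cannot be fitted"
            )
        pos = col[col > 0]
        if pos.size == 0:
            raise ValueError(f"feature {j} has no positive values")
        col[col <= 0] = pos.min() / 2.0  # offset zeros below the support
        out[:, j] = np.log(col)
    return out


def classify_dives(
    ibis: pd.DataFrame,
    n_components_range=range(2, 6),
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Label each IBI ``dive`` or ``apnea`` via a full-covariance Gaussian mixture.

    Mixtures over ``n_components_range`` are fitted on (log duration, log
    max depth, log mean MSA) and the component count chosen by BIC. The
    dive class is the component whose mean is maximal in all three features
    (dominance rule); if no component dominates, the component with the
    deepest mean log depth is used. Deterministic given ``seed``.

    Returns a copy of ``ibis`` with ``label`` and ``posterior`` columns.
    """
    if len(ibis) < 10:
        raise ValueError("need at least 10 IBIs to fit the mixture")
    X = _log_features(ibis)
    best = None
    for k in n_components_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    means = gm.means_  # (k, 3)
    top = means.argmax(axis=0)
    if top[0] == top[1] == top[2]:
        dive_comp = int(top[0])
    else:
        dive_comp = int(means[:, 1].argmax())  # depth is the cleanest separator
        log.info("no component dominates all features; falling back to deepest")
    post = gm.predict_proba(X)
    assign = post.argmax(axis=1)
    out = ibis.copy()
    out["label"] = np.where(assign == dive_comp, "dive", "apnea")
    out["posterior"] = post[:, dive_comp]
    return out
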