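"""Synthetic tag-data generator with full ground truth.

Simulation is dive-level: a Markov chain over behavioral states (optionally
drawn from one of several context transition matrices) assigns a state to
each dive cycle, then sensor traces are rendered around the schedule —
descent/bottom/ascent depth profiles, surfacings with one V-notch per
respiration (neighbouring breaths are separated by brief >0.5 m
submersions, the near-surface "apneas" real records show), click trains
inside scheduled buzz intervals, and a triaxial acceleration series whose
MSA tracks each state's activity level and whose orientation follows the
dive profile. A day/night effect multiplies buzz rates and, optionally,
the entry probability of the pelagic state at night.

Default state parameters follow the observed day-time regime of wild
harbor porpoises: short shallow dives, near-continuous diving, buzz rates
of roughly 0.1 / 2.6 / 1.6 per diving minute for nonfeeding / pelagic /
bottom states. The single default context TPM is a free parameter
(diagonal-dominant persistence) — no fitted TPM is available to mirror.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .records import SensorRecord

__all__ = [
    "StateParams",
    "GenConfig",
    "GroundTruth",
    "default_config",
    "generate_deployment",
    "render_dive_profile",
    "render_click_train",
    "render_envelope",
    "simulate_states",
    "simulate_metric_sequences",
    "true_states_for_intervals",
]

G = 9.81
_HALF_NORMAL = float(np.sqrt(np.pi / 2.0))  # sigma scale so E|N(0,sigma)| = level


@dataclass
class StateParams:
    """Per-state dive, breathing, foraging, and activity parameters."""

    name: str
    duration_mean_s: float
    duration_sd_s: float
    depth_mean_m: float
    depth_sd_m: float
    surface_mean_s: float
    surface_sd_s: float
    buzz_rate_per_min: float  # buzzes per minute of dive time
    resp_rate_per_min: float  # respirations per minute of cycle time
    activity_msa: float  # mean MSA, m s^-2
    bottom_fraction: float = 0.15
    buzz_placement: str = "uniform"  # or "bottom"
    roll_sd_rad: float = 0.15
    activity_cv: float = 0.20  # log-sd of the per-dive activity multiplier


@dataclass
class GenConfig:
    states: list
    context_tpms: list
    context_weights: list
    night_buzz_multiplier: float = 2.5
    night_pelagic_multiplier: float = 2.4
    pelagic_state: int | None = 1
    buzz_ici_mean_s: float = 0.003
    buzz_dur_range: tuple = (0.4, 0.8)
    duration_h: float = 24.0
    fs: float = 25.0
    start_hour: float = 12.0
    sunset_hour: float = 18.0
    sunrise_hour: float = 6.0
    seed: int = 0
    animal_id: str = "synthetic"
    body_length_m: float = 1.31
    surface_activity_msa: float = 0.4
    swim_speed_ms: float = 1.8
    min_dive_duration_s: float = 6.0
    min_depth_m: float = 2.0

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("deployment duration must be positive")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        K = self.n_states
        if K == 0:
            raise ValueError("need at least one state")
        for s in self.states:
            if s.duration_mean_s <= 0 or s.depth_mean_m <= 0:
                raise ValueError(f"state {s.name}: duration/depth means must be positive")
            if min(s.buzz_rate_per_min, s.resp_rate_per_min, s.activity_msa) < 0:
                raise ValueError(f"state {s.name}: rates must be nonnegative")
            if not 0 <= s.bottom_fraction < 1:
                raise ValueError(f"state {s.name}: bottom_fraction must lie in [0, 1)")
        tpms = np.asarray(self.context_tpms, dtype=float)
        if tpms.ndim != 3 or tpms.shape[1:] != (K, K):
            raise ValueError("context_tpms must be a list of KxK matrices")
        if np.any(tpms < 0) or not np.allclose(tpms.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("non-stochastic TPM row")
        w = np.asarray(self.context_weights, dtype=float)
        if w.shape != (tpms.shape[0],) or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("context weights must be nonnegative and sum to 1")

    def is_night(self, t_s: float) -> bool:
        hour = (self.start_hour + t_s / 3600.0) % 24.0
        if self.sunset_hour <= self.sunrise_hour:
            return self.sunset_hour <= hour < self.sunrise_hour
        return hour >= self.sunset_hour or hour < self.sunrise_hour


def default_config(duration_h: float = 24.0, seed: int = 0, **overrides) -> GenConfig:
    """Three-state day-regime defaults (nonfeeding / pelagic / bottom)."""
    states = [
        StateParams(
            "nonfeeding", 50.7, 15.0, 4.4, 1.5, 25.1, 8.0,
            0.1, 2.4, 1.8, bottom_fraction=0.10, buzz_placement="uniform",
            roll_sd_rad=0.10,
        ),
        StateParams(
            "pelagic", 44.4, 14.0, 8.2, 2.5, 35.7, 10.0,
            2.6, 3.0, 2.3, bottom_fraction=0.15, buzz_placement="uniform",
            roll_sd_rad=0.20,
        ),
        StateParams(
            "bottom", 77.5, 20.0, 11.6, 3.5, 34.4, 10.0,
            1.6, 2.7, 1.9, bottom_fraction=0.50, buzz_placement="bottom",
            roll_sd_rad=0.30,
        ),
    ]
    tpm = [
        [0.85, 0.10, 0.05],
        [0.10, 0.80, 0.10],
        [0.10, 0.15, 0.75],
    ]
    cfg = GenConfig(
        states=states,
        context_tpms=[tpm],
        context_weights=[1.0],
        duration_h=duration_h,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """True events and states underlying a synthetic deployment."""

    dives: pd.DataFrame  # start_s, end_s, duration_s, max_depth_m, state, state_name, night
    cycles: pd.DataFrame
    resp_times: np.ndarray
    click_times: np.ndarray
    buzzes: pd.DataFrame  # start_s, end_s, dive_idx, state
    context: int = 0

    def events_frame(self) -> pd.DataFrame:
        """Long-format event table (type, start_s, end_s, state)."""
        rows = [("respiration", t, t, -1) for t in self.resp_times]
        rows += [
            ("dive", r.start_s, r.end_s, r.state) for r in self.dives.itertuples()
        ]
        rows += [
            ("buzz", r.start_s, r.end_s, r.state) for r in self.buzzes.itertuples()
        ]
        rows += [("click", t, t, -1) for t in self.click_times]
        return pd.DataFrame(rows, columns=["type", "start_s", "end_s", "state"]).sort_values(
            "start_s", ignore_index=True
        )


# ---------------------------------------------------------------------------
# elementary renderers


def render_dive_profile(
    duration: float,
    max_depth: float,
    bottom_fraction: float,
    fs: float,
    surface_depth: float = 0.2,
) -> np.ndarray:
    """Piecewise descent-bottom-ascent depth profile sampled at fs.

    Descent and ascent share the non-bottom time equally; phase boundaries
    are snapped to the sample grid so the maximum depth is attained exactly
    (a single sample for a V-shaped dive). First and last samples sit at
    ``surface_depth`` (< 0.5 m).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration <= 0 or max_depth <= 0:
        raise ValueError("duration and max_depth must be positive")
    if not 0 <= bottom_fraction < 1:
        raise ValueError("bottom_fraction must lie in [0, 1)")
    n = int(round(duration * fs))
    if n < 3:
        raise ValueError("dive too short for the sample rate")
    desc_i = int(round((1.0 - bottom_fraction) / 2.0 * duration * fs))
    asc_i = int(round(((1.0 - bottom_fraction) / 2.0 + bottom_fraction) * duration * fs))
    desc_i = min(max(desc_i, 1), n - 2)
    asc_i = min(max(asc_i, desc_i), n - 2)
    idx = np.arange(n)
    xp = [0, desc_i, asc_i, n - 1]
    fp = [surface_depth, max_depth, max_depth, surface_depth]
    return np.interp(idx, xp, fp)


def render_click_train(
    interval: tuple,
    ici_mean: float,
    seed: int | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Deterministically spaced click times filling a buzz interval.

    Clicks sit at start + k * ici_mean, giving floor(len/ici) + 1 clicks,
    all ICIs below 10 ms; an interval of at least 101 * ici_mean is
    therefore buzz-detectable by construction. Optional multiplicative
    jitter (< 0.5) perturbs interior clicks while preserving ordering.
    Intervals shorter than 5 ICIs emit a sub-threshold train with a
    warning (useful as a negative control).
    """
    if ici_mean >= 0.010:
        raise ValueError(f"ici_mean {ici_mean} s is not a buzz ICI (< 10 ms required)")
    start, end = float(interval[0]), float(interval[1])
    length = end - start
    if length < 0:
        raise ValueError("interval end precedes start")
    if length < 5 * ici_mean:
        warnings.warn("buzz interval shorter than 5 ICIs: sub-threshold click train")
    k = int(np.floor(length / ici_mean)) + 1
    times = start + np.arange(k) * ici_mean
    if jitter > 0:
        if jitter >= 0.5:
            raise ValueError("jitter must be < 0.5 to preserve ordering")
        rng = np.random.default_rng(seed)
        times[1:-1] = times[1:-1] + rng.uniform(-jitter, jitter, max(k - 2, 0)) * ici_mean
    return times


def render_envelope(
    click_times: np.ndarray,
    duration: float,
    fs: float = 20000.0,
    noise_floor_db: float = -80.0,
    click_db: float = -40.0,
    decay_s: float = 0.0003,
    seed: int = 0,
) -> np.ndarray:
    """Clicks as decaying peaks on a noise floor (linear clip units).

    A lightweight stand-in for a demodulated acoustic envelope, meant to
    exercise the click detector; no propagation or waveform modelling.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    env = 10 ** (noise_floor_db / 20.0) * rng.uniform(0.5, 1.5, n)
    kernel_n = max(int(round(5 * decay_s * fs)), 2)
    kernel = 10 ** (click_db / 20.0) * np.exp(-np.arange(kernel_n) / (decay_s * fs))
    for t in np.asarray(click_times, dtype=float):
        i = int(round(t * fs))
        if 0 <= i < n:
            j = min(i + kernel_n, n)
            env[i:j] = np.maximum(env[i:j], kernel[: j - i])
    return env


def simulate_states(
    tpm: np.ndarray,
    n: int,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a state chain of length n (init defaults to the stationary law)."""
    from .hmm import stationary_distribution

    tpm = np.asarray(tpm, dtype=float)
    if init is None:
        init = stationary_distribution(tpm)
    K = tpm.shape[0]
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(K, p=np.asarray(init) / np.sum(init))
    for t in range(1, n):
        states[t] = rng.choice(K, p=tpm[states[t - 1]])
    return states


# ---------------------------------------------------------------------------
# deployment generation


def _truncated_lognormal(rng, mean, sd, minimum, size=None):
    """Lognormal matched to (mean, sd) by moments, resampled above minimum."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    draw = rng.lognormal(mu, np.sqrt(sigma2), size)
    for _ in range(100):
        bad = draw < minimum
        if not np.any(bad):
            break
        draw = np.where(bad, rng.lognormal(mu, np.sqrt(sigma2), size), draw)
    return np.maximum(draw, minimum)


def _schedule_respirations(rng, t0, dur, n, min_gap=2.0, edge=0.6):
    n = max(1, min(n, int((dur - 2 * edge) // min_gap) + 1))
    slots = t0 + edge + (dur - 2 * edge) * (np.arange(n) + 0.5) / n
    jit = rng.uniform(-0.3, 0.3, n)
    times = np.sort(slots + jit)
    # enforce the minimum gap after jitter
    for i in range(1, n):
        times[i] = max(times[i], times[i - 1] + min_gap)
    return times[times < t0 + dur - edge / 2]


def _schedule_buzzes(rng, window, n, dur_range, min_gap=1.2):
    """Non-overlapping buzz intervals inside window with >= min_gap spacing."""
    w0, w1 = window
    placed = []
    for _ in range(n):
        bdur = rng.uniform(*dur_range)
        if w1 - w0 <= bdur:
            continue
        for _attempt in range(50):
            s = rng.uniform(w0, w1 - bdur)
            if all(s > e + min_gap or s + bdur < b - min_gap for b, e in placed):
                placed.append((s, s + bdur))
                break
    placed.sort()
    return placed


def generate_deployment(config: GenConfig) -> tuple[SensorRecord, GroundTruth]:
    """Render a deployment and its ground truth; bit-identical per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    total_s = config.duration_h * 3600.0
    tpms = np.asarray(config.context_tpms, dtype=float)
    tpms = tpms / tpms.sum(axis=2, keepdims=True)
    ctx = int(rng.choice(len(tpms), p=np.asarray(config.context_weights, dtype=float)))
    tpm = tpms[ctx]
    from .hmm import stationary_distribution

    snap = lambda t: np.round(np.asarray(t) * fs) / fs

    cps_t: list[float] = [0.0]
    cps_d: list[float] = [0.3]
    dive_rows = []
    cycle_rows = []
    resp_times: list[float] = []
    buzz_rows = []
    click_times: list[float] = []

    def add_surface(t0, dur, n_resp):
        times = snap(_schedule_respirations(rng, t0, dur, n_resp))
        for i, r in enumerate(np.atleast_1d(times)):
            if i > 0:
                mid = (np.atleast_1d(times)[i - 1] + r) / 2.0
                cps_t.append(mid)
                cps_d.append(rng.uniform(0.75, 1.2))
            cps_t.extend([r - 0.3, r, r + 0.3])
            cps_d.extend([0.35, rng.uniform(0.06, 0.16), 0.35])
            resp_times.append(float(r))
        return len(np.atleast_1d(times))

    # lead-in surfacing with one breath
    lead = 8.0
    add_surface(0.0, lead, 1)
    t = lead

    state = int(rng.choice(config.n_states, p=stationary_distribution(tpm)))
    while True:
        sp = config.states[state]
        night = config.is_night(t)
        dur = float(
            _truncated_lognormal(rng, sp.duration_mean_s, sp.duration_sd_s, config.min_dive_duration_s)
        )
        depth = float(_truncated_lognormal(rng, sp.depth_mean_m, sp.depth_sd_m, config.min_depth_m))
        surf = float(_truncated_lognormal(rng, sp.surface_mean_s, sp.surface_sd_s, 4.0))
        # mean-preserving per-dive activity variability around the state level
        act = sp.activity_msa * rng.lognormal(-0.5 * sp.activity_cv**2, sp.activity_cv)
        if t + dur + surf > total_s:
            break
        # dive control points (phase boundaries snapped to the grid)
        d0 = t
        desc_end = float(snap(d0 + (1 - sp.bottom_fraction) / 2.0 * dur))
        asc_start = float(snap(desc_end + sp.bottom_fraction * dur))
        asc_start = min(max(asc_start, desc_end), d0 + dur - 0.2)
        cps_t.extend([d0, desc_end, asc_start, d0 + dur])
        cps_d.extend([0.2, depth, depth, 0.2])

        # buzzes
        rate = sp.buzz_rate_per_min * (config.night_buzz_multiplier if night else 1.0)
        n_buzz_target = rng.poisson(rate * dur / 60.0)
        if sp.buzz_placement == "bottom" and asc_start - desc_end > config.buzz_dur_range[1] + 0.2:
            window = (desc_end, asc_start)
        else:
            window = (d0 + 0.1 * dur, d0 + 0.9 * dur)
        placed = _schedule_buzzes(rng, window, n_buzz_target, config.buzz_dur_range)
        for b0, b1 in placed:
            buzz_rows.append((b0, b1, len(dive_rows), state))
            click_times.extend(render_click_train((b0, b1), config.buzz_ici_mean_s))

        # surfacing + respirations
        cycle = dur + surf
        lam = sp.resp_rate_per_min * cycle / 60.0
        n_resp = 1 + rng.poisson(lam - 1.0) if lam > 1.0 else max(1, rng.poisson(lam))
        n_resp_actual = add_surface(d0 + dur, surf, n_resp)

        dive_rows.append((d0, d0 + dur, dur, depth, act, state, sp.name, night))
        cycle_rows.append((d0, dur, surf, cycle, state, sp.name, night, n_resp_actual, len(placed)))
        t += cycle

        row = tpm[state].copy()
        if night and config.pelagic_state is not None and config.night_pelagic_multiplier != 1.0:
            row[config.pelagic_state] *= config.night_pelagic_multiplier
            row /= row.sum()
        state = int(rng.choice(config.n_states, p=row))

    # short breath-free tail so the record ends at the surface
    tail = min(4.0, total_s - t) if total_s > t else 2.0
    t += max(tail, 1.0)
    cps_t.append(t)
    cps_d.append(0.3)

    order = np.argsort(cps_t, kind="mergesort")
    cp_t = np.asarray(cps_t)[order]
    cp_d = np.asarray(cps_d)[order]
    n_samples = int(round(t * fs)) + 1
    tgrid = np.arange(n_samples) / fs
    depth_series = np.interp(tgrid, cp_t, cp_d)

    dives = pd.DataFrame(
        dive_rows,
        columns=[
            "start_s", "end_s", "duration_s", "max_depth_m", "activity_msa",
            "state", "state_name", "night",
        ],
    )
    cycles = pd.DataFrame(
        cycle_rows,
        columns=[
            "dive_start_s", "dive_duration_s", "surface_duration_s", "cycle_duration_s",
            "state", "state_name", "night", "n_respirations", "n_buzzes",
        ],
    )
    buzzes = pd.DataFrame(buzz_rows, columns=["start_s", "end_s", "dive_idx", "state"])

    # per-sample state and activity
    state_at = np.full(n_samples, -1, dtype=int)
    activity = np.full(n_samples, config.surface_activity_msa)
    for r in dives.itertuples():
        i0 = int(np.round(r.start_s * fs))
        i1 = int(np.round(r.end_s * fs))
        state_at[i0:i1] = r.state
        activity[i0:i1] = r.activity_msa
    roll_sd = np.where(
        state_at >= 0,
        np.asarray([s.roll_sd_rad for s in config.states])[np.clip(state_at, 0, None)],
        0.08,
    )
    spec = np.abs(rng.standard_normal(n_samples)) * activity * _HALF_NORMAL
    w_vert = np.gradient(depth_series) * fs
    pitch = -np.arcsin(np.clip(w_vert / config.swim_speed_ms, -0.95, 0.95))
    phi = 0.98
    noise = rng.standard_normal(n_samples) * roll_sd * np.sqrt(1 - phi**2)
    roll = scipy.signal.lfilter([1.0], [1.0, -phi], noise)
    norm = G + spec
    acc = np.column_stack(
        [
            -norm * np.sin(pitch),
            norm * np.cos(pitch) * np.sin(roll),
            norm * np.cos(pitch) * np.cos(roll),
        ]
    )

    record = SensorRecord(
        fs=fs,
        depth=depth_series,
        acc=acc,
        animal_id=config.animal_id,
        body_length_m=config.body_length_m,
    )
    truth = GroundTruth(
        dives=dives,
        cycles=cycles,
        resp_times=np.asarray(resp_times),
        click_times=np.asarray(sorted(click_times)),
        buzzes=buzzes,
        context=ctx,
    )
    return record, truth


def true_states_for_intervals(truth: GroundTruth, intervals: pd.DataFrame) -> np.ndarray:
    """True state for each half-open [start_s, end_s) interval.

    An interval inherits the state of the true dive whose midpoint it
    contains (detected dive IBIs bracket exactly one rendered dive); -1
    marks intervals containing no true dive.
    """
    mids = (truth.dives["start_s"].to_numpy() + truth.dives["end_s"].to_numpy()) / 2.0
    states = truth.dives["state"].to_numpy()
    out = np.full(len(intervals), -1, dtype=int)
    for i, r in enumerate(intervals.itertuples()):
        hit = np.nonzero((mids >= r.start_s) & (mids < r.end_s))[0]
        if hit.size:
            out[i] = states[hit[0]]
    return out


def simulate_metric_sequences(model, lengths, seed: int = 0):
    """Draw per-dive metric sequences directly from a fitted-model structure.

    For each animal a context is sampled from the model weights, a state
    chain from that context's TPM (stationary start), and the eight metrics
    from the state's emission distributions. ``rel_buzz_depth`` is missing
    exactly when the Bernoulli buzz indicator is 0.

    Returns (sequences as DataFrames, true state arrays, context indices).
    """
    from .divemetrics import METRIC_COLUMNS
    from .hmm import stationary_distribution

    rng = np.random.default_rng(seed)
    seqs, paths, ctxs = [], [], []
    eps = 1e-6
    for T in lengths:
        c = int(rng.choice(model.C, p=model.weights))
        states = simulate_states(
            model.tpms[c], T, rng, init=stationary_distribution(model.tpms[c])
        )
        X = np.empty((T, 8))
        for t, k in enumerate(states):
            X[t, 0] = rng.normal(model.mu[k], model.sd[k])
            for j in range(6):
                X[t, 1 + j] = np.clip(
                    rng.beta(model.beta_a[k, j], model.beta_b[k, j]), eps, 1 - eps
                )
            X[t, 7] = float(rng.random() < model.bern_p[k])
            if X[t, 7] == 0.0:
                X[t, 1] = np.nan
        seqs.append(pd.DataFrame(X, columns=METRIC_COLUMNS))
        paths.append(states)
        ctxs.append(c)
    return seqs, paths, ctxs
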