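"""Time-energy budgets: interval summaries, activity-specific FMR,
foraging efficiency, energy balance, metabolic scope, SDA scenario.

The bioenergetic arithmetic works from a daily field metabolic rate (FMR,
MJ day^-1) supplied as an input parameter, per-state respiration-rate
elevations relative to nonfeeding, and per-state time fractions. Energy
intake is attributed to buzzes (prey-capture attempts) with a configurable
assimilation efficiency and prey energy density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EnergyParams",
    "summarize_intervals",
    "normalize_by_nonfeeding",
    "activity_specific_fmr",
    "foraging_efficiency",
    "energy_balance",
    "metabolic_scope",
    "sda_scenario",
]


@dataclass
class EnergyParams:
    """Bioenergetic constants for a representative adult animal."""

    daily_fmr_mj: float = 15.0
    assimilation: float = 0.90
    prey_energy_density_kj_g: float = 4.2
    sda_fraction: float = 0.125
    body_mass_kg: float = 40.0

    def __post_init__(self):
        vals = (
            self.daily_fmr_mj,
            self.assimilation,
            self.prey_energy_density_kj_g,
            self.sda_fraction,
            self.body_mass_kg,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all energy parameters must be positive")
        if self.assimilation > 1:
            raise ValueError("assimilation must lie in (0, 1]")


def summarize_intervals(
    cycles: pd.DataFrame,
    width: float = 1200.0,
    purity_min: float = 0.75,
    resp_times: np.ndarray | None = None,
    buzz_mids: np.ndarray | None = None,
    msa: np.ndarray | None = None,
    msa_time: np.ndarray | None = None,
) -> pd.DataFrame:
    """Contiguous fixed-width windows with a majority behavioral state.

    ``cycles`` needs dive_start_s / next_dive_start_s / state columns. The
    state time in a window is the overlap of each dive cycle with it; the
    window is retained iff the majority state occupies more than
    ``purity_min`` of the window (controls cost spillover between mixed
    behaviors). Event counts use raw timestamps, not proration.
    """
    if len(cycles) == 0:
        return pd.DataFrame(
            columns=[
                "start_s", "width_s", "majority_state", "purity",
                "n_buzzes", "n_respirations", "total_msa", "retained",
            ]
        )
    t0 = float(cycles["dive_start_s"].min())
    t_end = float(cycles["next_dive_start_s"].max())
    states = cycles["state"].to_numpy()
    c_start = cycles["dive_start_s"].to_numpy(dtype=float)
    c_end = cycles["next_dive_start_s"].to_numpy(dtype=float)
    uniq = pd.unique(states)
    rows = []
    n_win = int(math.floor((t_end - t0) / width))
    for w in range(n_win):
        w0 = t0 + w * width
        w1 = w0 + width
        occ = {}
        for s in uniq:
            sel = states == s
            overlap = np.clip(np.minimum(c_end[sel], w1) - np.maximum(c_start[sel], w0), 0.0, None)
            occ[s] = float(overlap.sum())
        major = max(occ, key=occ.get)
        purity = occ[major] / width
        n_buzz = (
            int(np.sum((buzz_mids >= w0) & (buzz_mids < w1))) if buzz_mids is not None else 0
        )
        n_resp = (
            int(np.sum((resp_times >= w0) & (resp_times < w1))) if resp_times is not None else 0
        )
        if msa is not None and msa_time is not None:
            i0 = int(np.searchsorted(msa_time, w0, side="left"))
            i1 = int(np.searchsorted(msa_time, w1, side="left"))
            total_msa = float(np.nansum(msa[i0:i1]))
        else:
            total_msa = np.nan
        rows.append((w0, width, major, purity, n_buzz, n_resp, total_msa, purity > purity_min))
    return pd.DataFrame(
        rows,
        columns=[
            "start_s", "width_s", "majority_state", "purity",
            "n_buzzes", "n_respirations", "total_msa", "retained",
        ],
    )


def normalize_by_nonfeeding(values, reference_values):
    """Divide by the median of the nonfeeding reference cohort.

    The reference median maps to exactly 1. Raises when the reference is
    empty or has a zero median (caller should exclude that animal).
    """
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("no nonfeeding reference values for this animal")
    med = float(np.median(ref))
    if med == 0:
        raise ValueError("nonfeeding reference median is zero")
    return np.asarray(values, dtype=float) / med


def activity_specific_fmr(
    daily_fmr_mj: float,
    time_fractions: dict,
    multipliers: dict,
) -> dict:
    """Split a daily FMR into per-state hourly rates (kJ h^-1).

    Solves base * sum_s f_s * m_s = daily_fmr / 24 for the base rate, where
    f_s are fractions of total time (summing to 1) and m_s relative
    respiration-rate elevations with the reference (nonfeeding) state at 1;
    returns base * m_s per state. Conserves energy exactly.
    """
    states = list(time_fractions)
    f = np.array([time_fractions[s] for s in states], dtype=float)
    m = np.array([multipliers[s] for s in states], dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError(f"time fractions sum to {f.sum()}, expected 1")
    if np.any(m <= 0):
        raise ValueError("multipliers must be positive")
    hourly = daily_fmr_mj * 1000.0 / 24.0
    base = hourly / float(f @ m)
    return {s: base * mi for s, mi in zip(states, m)}


def foraging_efficiency(
    intake_mj_day: float,
    assimilation: float,
    state_fmrs_kj_h: dict,
    time_fractions: dict,
    nonfeeding_state: str = "nonfeeding",
    gross_intake: bool = True,
) -> float:
    """Energy acquired while foraging over the marginal cost of foraging.

    The marginal cost is the difference between the time-weighted foraging
    FMR and the nonfeeding FMR, accumulated over the day's foraging hours.
    ``gross_intake`` keeps ingested energy as-is; otherwise intake is
    discounted by the assimilation efficiency before the ratio.
    """
    if intake_mj_day < 0:
        raise ValueError("intake must be nonnegative")
    forage_states = [s for s in time_fractions if s != nonfeeding_state]
    f_forage = sum(time_fractions[s] for s in forage_states)
    if f_forage <= 0:
        raise ValueError("no foraging time; efficiency undefined")
    weighted = (
        sum(time_fractions[s] * state_fmrs_kj_h[s] for s in forage_states) / f_forage
    )
    marginal_kj = (weighted - state_fmrs_kj_h[nonfeeding_state]) * (f_forage * 24.0)
    if marginal_kj <= 0:
        raise ValueError("marginal cost of foraging is zero or negative")
    acquired_kj = intake_mj_day * 1000.0 * (1.0 if gross_intake else assimilation)
    return acquired_kj / marginal_kj


def energy_balance(
    resp_times: np.ndarray,
    buzz_times: np.ndarray,
    params: EnergyParams,
    deployment_s: float,
) -> pd.DataFrame:
    """Cumulative energy balance (MJ): buzz gains minus respiration costs.

    Total FMR over the deployment is split evenly per respiration on the
    expenditure side and, after assimilation, evenly per buzz on the intake
    side, so the final balance closes at zero by construction. The implied
    gross prey mass per buzz (g) is attached as ``DataFrame.attrs``.
    """
    resp_times = np.sort(np.asarray(resp_times, dtype=float))
    buzz_times = np.sort(np.asarray(buzz_times, dtype=float))
    if resp_times.size == 0:
        raise ValueError("need at least one respiration")
    if buzz_times.size == 0:
        raise ValueError("no buzzes: per-buzz energy is undefined")
    total_mj = params.daily_fmr_mj * deployment_s / 86400.0
    per_resp = total_mj / resp_times.size
    per_buzz = total_mj / buzz_times.size  # assimilated
    events = pd.DataFrame(
        {
            "time_s": np.concatenate([resp_times, buzz_times]),
            "delta_mj": np.concatenate(
                [np.full(resp_times.size, -per_resp), np.full(buzz_times.size, per_buzz)]
            ),
        }
    ).sort_values("time_s", kind="mergesort", ignore_index=True)
    events["balance_mj"] = events["delta_mj"].cumsum()
    gross_per_buzz_kj = per_buzz * 1000.0 / params.assimilation
    events.attrs["per_resp_mj"] = per_resp
    events.attrs["per_buzz_assimilated_mj"] = per_buzz
    events.attrs["prey_g_per_buzz"] = gross_per_buzz_kj / params.prey_energy_density_kj_g
    return events


def metabolic_scope(vo2max: float, fmr: float) -> float:
    """VO2max / FMR, rounded half-away-from-zero to one decimal."""
    if vo2max <= 0 or fmr <= 0:
        raise ValueError("rates must be positive")
    ratio = vo2max / fmr
    return math.floor(ratio * 10.0 + 0.5) / 10.0


def sda_scenario(sda_fraction: float, foraging_time_fraction: float) -> float:
    """Relative FMR increase during foraging if all digestion happens then.

    The daily specific-dynamic-action energy (a fraction of FMR) is
    concentrated into the foraging hours and expressed relative to the
    average FMR: sda_fraction / foraging_time_fraction.
    """
    if not 0 < sda_fraction <= 1 or not 0 < foraging_time_fraction <= 1:
        raise ValueError("fractions must lie in (0, 1]")
    return sda_fraction / foraging_time_fraction
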