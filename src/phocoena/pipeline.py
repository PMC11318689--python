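"""End-to-end orchestration: prep -> events -> dives -> metrics -> HMM -> energy.

Every stage parameter defaults to the field-standard constant (0.5 m
surfacing threshold, 0.4 s breath separation, 10 ms buzz ICI, 5-click
runs, 0.2 s / >100 clicks, 1 s merge, 1 ms blanking, -60 dB floor, 25 Hz,
95th-percentile winsorizing, one/two body-length depth bands, 20-min
intervals with >75% purity, 50 HMM restarts, first-hour removal). Runs
are reproducible: a single seed drives every stochastic stage and outputs
carry the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, divemetrics, energy, hmm, respiration, sensor
from .records import KinematicSeries, SensorRecord

log = logging.getLogger("phocoena.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "diel_split", "night_intervals"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # preparation
    cut_s: float = 3600.0
    fs_out: float = 25.0
    winsor_percentile: float = 95.0
    pitch_smooth_s: float = 5.0
    # respiration detection
    surface_threshold_m: float = 0.5
    min_iri_s: float = 0.4
    # click / buzz detection
    max_ici_s: float = 0.010
    min_run: int = 5
    min_buzz_dur_s: float = 0.2
    min_buzz_clicks: int = 101
    merge_gap_s: float = 1.0
    blanking_s: float = 0.001
    click_floor_db: float = -60.0
    click_margin_db: float = 15.0
    noise_window_s: float = 0.5
    # dive/apnea mixture
    mixture_components: tuple = (2, 3, 4, 5)
    mixture_n_init: int = 10
    # behavioral-state HMM
    k_range: tuple = (2, 3, 4)
    c_range: tuple = (1,)
    n_restarts: int = 50
    hmm_max_iter: int = 500
    decode: str = "viterbi"
    # energy budget
    interval_width_s: float = 1200.0
    purity_min: float = 0.75
    energy_params: energy.EnergyParams = field(default_factory=energy.EnergyParams)
    # diel clock (sunrise/sunset are inputs, not computed)
    start_hour: float = 12.0
    sunset_hour: float = 18.0
    sunrise_hour: float = 6.0
    body_length_m: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "energy_params" in d and isinstance(d["energy_params"], dict):
            d["energy_params"] = energy.EnergyParams(**d["energy_params"])
        for key in ("mixture_components", "k_range", "c_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def night_intervals(
    t0: float, t1: float, start_hour: float, sunset_hour: float, sunrise_hour: float
) -> list[tuple[float, float]]:
    """Night spans [sunset, next sunrise) in record seconds covering [t0, t1]."""
    out = []
    day0 = int(np.floor((t0 / 3600.0 + start_hour) / 24.0)) - 1
    day1 = int(np.ceil((t1 / 3600.0 + start_hour) / 24.0)) + 1
    for day in range(day0, day1 + 1):
        sunset = (day * 24.0 + sunset_hour - start_hour) * 3600.0
        rise_hour = sunrise_hour + (24.0 if sunrise_hour <= sunset_hour else 0.0)
        sunrise = (day * 24.0 + rise_hour - start_hour) * 3600.0
        if sunrise > t0 and sunset < t1:
            out.append((max(sunset, t0 - 1e-9), min(sunrise, t1 + 1e-9)))
    return out


def diel_split(times, nights: list[tuple[float, float]]) -> np.ndarray:
    """Boolean night label per timestamp; night iff t in [sunset, sunrise)."""
    times = np.asarray(times, dtype=float)
    is_night = np.zeros(times.shape, dtype=bool)
    for s, r in nights:
        is_night |= (times >= s) & (times < r)
    return is_night


@dataclass
class PipelineResult:
    config: PipelineConfig
    kin: KinematicSeries
    resp_times: np.ndarray
    buzzes: pd.DataFrame
    ibis: pd.DataFrame
    dives: pd.DataFrame
    metrics: pd.DataFrame
    fit: hmm.FitResult
    state_names: list
    cycles: pd.DataFrame
    intervals: pd.DataFrame
    balance: pd.DataFrame
    report: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_s": self.resp_times}).to_csv(out / "respirations.csv", index=False)
        self.buzzes.to_csv(out / "buzzes.csv", index=False)
        self.ibis.to_csv(out / "ibis.csv", index=False)
        self.dives.to_csv(out / "dives.csv", index=False)
        self.metrics.to_csv(out / "dive_metrics.csv", index=False)
        self.cycles.to_csv(out / "dive_cycles.csv", index=False)
        self.intervals.to_csv(out / "intervals.csv", index=False)
        self.balance.to_csv(out / "energy_balance.csv", index=False)
        with open(out / "model.json", "w") as fh:
            json.dump(self.fit.to_dict(), fh, indent=1)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=1, default=float)


def run_pipeline(
    record: SensorRecord,
    config: PipelineConfig | None = None,
    click_times: np.ndarray | None = None,
    envelope: np.ndarray | None = None,
    envelope_fs: float | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run every stage on one deployment and assemble the energy report.

    Acoustic input is either a pre-detected click-time list (canonical) or
    a demodulated envelope to run the click detector on.
    """
    cfg = config or PipelineConfig()
    log.info("pipeline start: %d samples at %g Hz (config %s, seed %d)",
             record.n, record.fs, cfg.config_hash(), cfg.seed)

    kin = sensor.prepare_kinematics(
        record, cut=cfg.cut_s, fs_out=cfg.fs_out,
        winsor_p=cfg.winsor_percentile, pitch_smooth_s=cfg.pitch_smooth_s,
    )

    resp = respiration.detect_respirations(
        kin.depth, kin.fs, t_start=kin.t_start,
        surface_threshold=cfg.surface_threshold_m, min_iri=cfg.min_iri_s,
    )
    log.info("stage events: %d respirations", resp.size)

    if click_times is None and envelope is not None:
        clicks = acoustics.detect_clicks(
            envelope, envelope_fs, noise_window=cfg.noise_window_s,
            threshold_margin=cfg.click_margin_db, floor_db=cfg.click_floor_db,
            blanking=cfg.blanking_s,
        )
        click_times = clicks["time_s"].to_numpy()
    if click_times is None:
        click_times = np.empty(0)
    click_times = np.asarray(click_times, dtype=float)
    click_times = click_times[click_times >= kin.t_start]
    buzzes = acoustics.assemble_buzzes(
        click_times, max_ici=cfg.max_ici_s, min_run=cfg.min_run,
        min_dur=cfg.min_buzz_dur_s, min_clicks=cfg.min_buzz_clicks,
        merge_gap=cfg.merge_gap_s,
    )
    buzzes = acoustics.attach_buzz_depth(buzzes, kin.depth, kin.time, kin.fs)
    log.info("stage events: %d clicks -> %d buzzes", click_times.size, len(buzzes))

    ibis = respiration.build_ibis(resp, kin)
    labeled = respiration.classify_dives(
        ibis, n_components_range=cfg.mixture_components, seed=cfg.seed,
        n_init=cfg.mixture_n_init,
    )
    dives = labeled[labeled["label"] == "dive"].copy()
    log.info("stage dives: %d IBIs, %d dives", len(labeled), len(dives))

    buzzes = acoustics.assign_buzzes_to_dives(buzzes, dives)
    body_length = cfg.body_length_m or kin.body_length_m
    metrics = divemetrics.compute_all_metrics(dives, buzzes, kin, body_length)
    squeezed = divemetrics.squeeze_metrics(metrics)

    fits = [
        hmm.fit_mixed_hmm(
            [squeezed], K=k, C=c, n_restarts=cfg.n_restarts, seed=cfg.seed,
            max_iter=cfg.hmm_max_iter,
        )
        for k in cfg.k_range
        for c in cfg.c_range
    ]
    best = hmm.select_model(fits)
    paths, ctx_post = hmm.decode_states(best.model, [squeezed], method=cfg.decode)
    names = hmm.name_states(best.model)
    best.model.state_names = names
    dives["state"] = [names[s] for s in paths[0]]
    log.info("stage hmm: selected K=%d C=%d (AIC %.1f)", best.model.K, best.model.C, best.aic)

    cycles = divemetrics.build_dive_cycles(dives, resp, buzzes)
    state_by_dive = dives["state"]
    cycles["state"] = state_by_dive.loc[cycles["dive_id"]].to_numpy()

    buzz_mids = (buzzes["start_s"].to_numpy() + buzzes["end_s"].to_numpy()) / 2.0
    intervals = energy.summarize_intervals(
        cycles, width=cfg.interval_width_s, purity_min=cfg.purity_min,
        resp_times=resp, buzz_mids=buzz_mids, msa=kin.msa, msa_time=kin.time,
    )

    report = _energy_report(
        cfg, kin, resp, buzzes, buzz_mids, dives, cycles, intervals, best, n_ibis=len(labeled)
    )
    deployment_s = kin.time[-1] - kin.t_start
    balance = energy.energy_balance(resp, buzz_mids, cfg.energy_params, deployment_s) \
        if buzz_mids.size else pd.DataFrame(columns=["time_s", "delta_mj", "balance_mj"])
    report["energy_balance_final_mj"] = (
        float(balance["balance_mj"].iloc[-1]) if len(balance) else np.nan
    )

    result = PipelineResult(
        config=cfg, kin=kin, resp_times=resp, buzzes=buzzes, ibis=labeled,
        dives=dives, metrics=metrics, fit=best, state_names=names,
        cycles=cycles, intervals=intervals, balance=balance, report=report,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def _energy_report(cfg, kin, resp, buzzes, buzz_mids, dives, cycles, intervals, best, n_ibis=0) -> dict:
    t0, t1 = float(kin.t_start), float(kin.time[-1])
    nights = night_intervals(t0, t1, cfg.start_hour, cfg.sunset_hour, cfg.sunrise_hour)
    night_s = sum(min(r, t1) - max(s, t0) for s, r in nights if r > t0 and s < t1)
    day_s = (t1 - t0) - night_s
    buzz_night = int(diel_split(buzz_mids, nights).sum()) if buzz_mids.size else 0
    buzz_day = int(buzz_mids.size) - buzz_night
    rate_night = buzz_night / (night_s / 3600.0) if night_s > 0 else np.nan
    rate_day = buzz_day / (day_s / 3600.0) if day_s > 0 else np.nan

    frac = cycles.groupby("state")["cycle_duration_s"].sum()
    frac = (frac / frac.sum()).to_dict()
    med_resp = cycles.groupby("state")["resp_rate_per_min"].median().to_dict()
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "animal_id": kin.animal_id,
        "n_respirations": int(resp.size),
        "n_buzzes": int(len(buzzes)),
        "n_ibis": int(n_ibis),
        "n_dives": int(len(dives)),
        "n_intervals_retained": int(intervals["retained"].sum()) if len(intervals) else 0,
        "n_intervals_total": int(len(intervals)),
        "hmm_K": best.model.K,
        "hmm_C": best.model.C,
        "hmm_aic": best.aic,
        "hmm_loglik": best.loglik,
        "time_fraction_by_state": frac,
        "night_hours": night_s / 3600.0,
        "day_hours": day_s / 3600.0,
        "buzzes_night": buzz_night,
        "buzzes_day": buzz_day,
        "buzz_rate_night_per_h": rate_night,
        "buzz_rate_day_per_h": rate_day,
        "night_day_buzz_ratio": (
            rate_night / rate_day if rate_day and np.isfinite(rate_day) and rate_day > 0 else np.nan
        ),
    }
    if "nonfeeding" in med_resp and med_resp["nonfeeding"] > 0 and len(frac) == len(med_resp):
        multipliers = {s: med_resp[s] / med_resp["nonfeeding"] for s in med_resp}
        try:
            fmrs = energy.activity_specific_fmr(
                cfg.energy_params.daily_fmr_mj, frac, multipliers
            )
            report["resp_rate_multipliers"] = multipliers
            report["activity_specific_fmr_kj_h"] = fmrs
            intake = cfg.energy_params.daily_fmr_mj / cfg.energy_params.assimilation
            report["foraging_efficiency_gross"] = energy.foraging_efficiency(
                intake, cfg.energy_params.assimilation, fmrs, frac
            )
        except ValueError as exc:
            report["energy_note"] = str(exc)
    return report
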