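"""Energy budget arithmetic, interval summaries, and balance closure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phocoena.energy import (
    EnergyParams,
    activity_specific_fmr,
    energy_balance,
    foraging_efficiency,
    metabolic_scope,
    normalize_by_nonfeeding,
    sda_scenario,
    summarize_intervals,
)


class TestActivitySpecificFMR:
    def test_uniform_multipliers_give_hourly_fmr(self):
        out = activity_specific_fmr(
            15.0, {"a": 0.38, "b": 0.37, "c": 0.25}, {"a": 1.0, "b": 1.0, "c": 1.0}
        )
        for v in out.values():
            assert v == pytest.approx(625.0)

    def test_field_worked_example(self):
        out = activity_specific_fmr(
            15.0,
            {"nonfeeding": 0.38, "pelagic": 0.37, "bottom": 0.25},
            {"nonfeeding": 1.0, "pelagic": 1.22, "bottom": 1.09},
        )
        assert out["nonfeeding"] == pytest.approx(566.5, abs=1.0)
        assert out["pelagic"] == pytest.approx(691.0, abs=1.0)
        # the bottom state evaluates near 617 from these rounded inputs
        assert out["bottom"] == pytest.approx(617.1, abs=1.0)

    def test_single_state_exact(self):
        out = activity_specific_fmr(12.0, {"x": 1.0}, {"x": 1.0})
        assert out["x"] == pytest.approx(500.0)

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=2, max_size=4),
        st.lists(st.floats(0.5, 3.0), min_size=4, max_size=4),
    )
    def test_energy_conservation(self, raw_f, raw_m):
        f = np.array(raw_f)
        f = f / f.sum()
        m = np.array(raw_m[: len(f)])
        fractions = {str(i): v for i, v in enumerate(f)}
        mult = {str(i): v for i, v in enumerate(m)}
        out = activity_specific_fmr(15.0, fractions, mult)
        daily = sum(fractions[s] * out[s] * 24.0 for s in fractions)
        assert daily == pytest.approx(15_000.0, rel=1e-9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            activity_specific_fmr(15.0, {"a": 0.5, "b": 0.6}, {"a": 1, "b": 1})


class TestForagingEfficiency:
    FMRS = {"nonfeeding": 567.0, "pelagic": 692.0, "bottom": 613.0}
    FRACS = {"nonfeeding": 0.38, "pelagic": 0.37, "bottom": 0.25}

    def test_zero_intake_zero_efficiency(self):
        assert foraging_efficiency(0.0, 0.9, self.FMRS, self.FRACS) == 0.0

    def test_equal_rates_rejected(self):
        flat = {k: 600.0 for k in self.FMRS}
        with pytest.raises(ValueError, match="marginal"):
            foraging_efficiency(17.0, 0.9, flat, self.FRACS)

    def test_hand_computed_gross_example(self):
        # weighted foraging FMR (0.37*692 + 0.25*613)/0.62 = 660.1 kJ/h;
        # marginal = (660.1 - 567) * 14.88 h; 17000 / that = 12.27
        out = foraging_efficiency(17.0, 0.9, self.FMRS, self.FRACS, gross_intake=True)
        assert out == pytest.approx(12.27, abs=0.05)

    def test_assimilated_convention_scales_down(self):
        gross = foraging_efficiency(17.0, 0.9, self.FMRS, self.FRACS, gross_intake=True)
        net = foraging_efficiency(17.0, 0.9, self.FMRS, self.FRACS, gross_intake=False)
        assert net == pytest.approx(0.9 * gross)


class TestEnergyBalance:
    def test_final_balance_closes_at_zero(self, rng):
        for _ in range(10):
            resp = np.sort(rng.uniform(0, 86400, rng.integers(10, 3000)))
            buzz = np.sort(rng.uniform(0, 86400, rng.integers(1, 2000)))
            out = energy_balance(resp, buzz, EnergyParams(), 86400.0)
            assert out["balance_mj"].iloc[-1] == pytest.approx(0.0, abs=1e-9 * 15)

    def test_late_buzzes_mean_negative_first_half(self):
        resp = np.linspace(0, 86400, 1000)
        buzz = np.linspace(50000, 86400, 500)
        out = energy_balance(resp, buzz, EnergyParams(), 86400.0)
        first_half = out[out["time_s"] < 43200]
        assert (first_half["balance_mj"] < 0).all()

    def test_zero_buzzes_rejected(self):
        with pytest.raises(ValueError, match="buzz"):
            energy_balance(np.array([1.0]), np.array([]), EnergyParams(), 1000.0)

    def test_implied_prey_mass_per_buzz(self):
        # 15 MJ/day over a day, 2396 buzzes, 90% assimilation, 4.2 kJ/g
        resp = np.linspace(0, 86400, 100)
        buzz = np.linspace(0, 86400, 2396)
        out = energy_balance(resp, buzz, EnergyParams(), 86400.0)
        assert out.attrs["prey_g_per_buzz"] == pytest.approx(
            (15000 / 0.9 / 2396) / 4.2, rel=1e-9
        )
        assert out.attrs["prey_g_per_buzz"] == pytest.approx(1.66, abs=0.01)


class TestMetabolicScope:
    @pytest.mark.parametrize(
        "vo2max, fmr, expected",
        [
            (11.0, 0.9, 12.2),  # coyote
            (10.9, 0.7, 15.6),  # red fox
            (2.1, 0.7, 3.0),  # mountain lion
            (3.6, 0.4, 9.0),  # African lion
            (1.8, 1.1, 1.6),  # bottlenose dolphin
            (2.0, 1.1, 1.8),  # harbor seal
            (9.4, 1.0, 9.4),  # grey wolf
        ],
    )
    def test_reference_table(self, vo2max, fmr, expected):
        assert metabolic_scope(vo2max, fmr) == expected

    def test_identity_ratio(self):
        assert metabolic_scope(3.3, 3.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            metabolic_scope(0.0, 1.0)


class TestSDA:
    @pytest.mark.parametrize(
        "frac, expected", [(1.0, 0.125), (0.62, 0.2016), (0.52, 0.2404)]
    )
    def test_scenarios(self, frac, expected):
        assert sda_scenario(0.125, frac) == pytest.approx(expected, abs=1e-4)

    def test_zero_foraging_rejected(self):
        with pytest.raises(ValueError):
            sda_scenario(0.125, 0.0)


class TestNormalize:
    def test_all_equal_maps_to_one(self):
        out = normalize_by_nonfeeding([3.0, 3.0, 3.0], [3.0, 3.0])
        assert np.allclose(out, 1.0)

    def test_hand_example(self):
        out = normalize_by_nonfeeding([1.0, 2.0, 3.0], [1.5, 2.0, 2.5])
        assert np.allclose(out, [0.5, 1.0, 1.5])

    def test_reference_median_maps_to_one(self, rng):
        ref = rng.lognormal(1, 0.5, 101)
        out = normalize_by_nonfeeding(ref, ref)
        assert np.median(out) == pytest.approx(1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_nonfeeding([1.0], [])

    def test_generator_contrast_recovered(self, small_deployment):
        """Configured pelagic/nonfeeding respiration-rate contrast (3.0 vs
        2.4 = 1.25x) shows up in the normalized per-cycle rates."""
        _, _, truth = small_deployment
        cyc = truth.cycles
        rates = cyc["n_respirations"] / (cyc["cycle_duration_s"] / 60.0)
        ref = rates[cyc["state_name"] == "nonfeeding"]
        pel = rates[cyc["state_name"] == "pelagic"]
        normalized = normalize_by_nonfeeding(pel, ref)
        se = normalized.std(ddof=1) / np.sqrt(len(normalized))
        assert np.median(normalized) == pytest.approx(1.25, abs=max(3 * se, 0.12))


def _cycles_from_truth(truth):
    cyc = truth.cycles.copy()
    cyc["dive_start_s"] = cyc["dive_start_s"].astype(float)
    cyc["next_dive_start_s"] = cyc["dive_start_s"] + cyc["cycle_duration_s"]
    cyc["state"] = cyc["state_name"]
    return cyc


class TestSummarizeIntervals:
    def _toy_cycles(self, states):
        rows = []
        t = 0.0
        for s in states:
            rows.append((t, t + 100.0, s))
            t += 100.0
        return pd.DataFrame(rows, columns=["dive_start_s", "next_dive_start_s", "state"])

    def test_pure_window_retained(self):
        out = summarize_intervals(self._toy_cycles(["a"] * 12), width=1200)
        assert len(out) == 1 and bool(out.loc[0, "retained"])
        assert out.loc[0, "purity"] == pytest.approx(1.0)

    def test_60_40_window_dropped(self):
        cycles = self._toy_cycles(["a"] * 7 + ["b"] * 5)
        out = summarize_intervals(cycles, width=1200)
        assert not bool(out.loc[0, "retained"])  # 0.583 <= 0.75

    def test_counts_by_timestamp(self):
        cycles = self._toy_cycles(["a"] * 12)
        resp = np.array([10.0, 500.0, 1199.9, 1200.0])
        buzz = np.array([100.0, 1100.0])
        out = summarize_intervals(cycles, width=1200, resp_times=resp, buzz_mids=buzz)
        assert out.loc[0, "n_respirations"] == 3
        assert out.loc[0, "n_buzzes"] == 2

    def test_retention_falls_with_faster_mixing(self):
        """Lower state persistence means more mixed 20-min windows."""
        import phocoena.synthetic as syn

        retained = []
        for diag in (0.95, 0.80, 0.50):
            off = (1.0 - diag) / 2.0
            tpm = [
                [diag, off, off],
                [off, diag, off],
                [off, off, diag],
            ]
            cfg = syn.default_config(duration_h=6.0, seed=21)
            cfg = dataclasses.replace(
                cfg, context_tpms=[tpm], night_buzz_multiplier=1.0,
                night_pelagic_multiplier=1.0,
            )
            _, truth = syn.generate_deployment(cfg)
            out = summarize_intervals(_cycles_from_truth(truth))
            retained.append(out["retained"].mean())
        assert retained[0] > retained[1] > retained[2]

    def test_window_accounting(self, small_deployment):
        _, _, truth = small_deployment
        out = summarize_intervals(_cycles_from_truth(truth))
        assert len(out) == int(out["retained"].sum()) + int((~out["retained"]).sum())
        assert (out["purity"] <= 1.0 + 1e-9).all()
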