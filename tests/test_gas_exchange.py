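import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyflux import (
    CarbonConversion,
    SamplingSchedule,
    carbon_use_efficiency,
    daily_carbon_gain,
    daily_period_means,
    demultiplex_stream,
    flux_series,
    gross_photosynthesis,
    net_flux,
    predict_harvest_mass,
)

CONV = CarbonConversion()


def constant_stream(n_chambers, sample_s, purge_s, seconds, value=5.0, flow=0.02):
    """Raw stream with constant per-chamber signal and marked purge rows."""
    sched = SamplingSchedule(n_chambers, sample_s, purge_s)
    t = np.arange(seconds, dtype=float)
    chamber = sched.chamber_at(t)
    in_sample = sched.in_sample_window(t)
    delta = np.where(in_sample, value, 1e6)  # purge rows poisoned
    return (
        pd.DataFrame(
            {
                "timestamp_s": t,
                "chamber_id": chamber,
                "flow_mol_s": flow,
                "delta_co2_umol_mol": delta,
                "light_on": True,
            }
        ),
        sched,
    )


class TestDemultiplex:
    def test_revisit_period_four_chambers(self):
        sched = SamplingSchedule(4, 30, 40)
        assert sched.cycle_s == 280.0  # each chamber sampled every 4 min 40 s

    def test_single_chamber_no_purge_is_identity_passthrough(self):
        stream, sched = constant_stream(1, 30, 0, 300, value=3.0)
        out = demultiplex_stream(stream, sched, window_discard_s=0.0)
        assert (out["chamber_id"] == 0).all()
        assert out["delta_co2_umol_mol"].to_numpy() == pytest.approx(3.0)
        # every second retained, grouped into 10 windows of 30 s
        assert len(out) == 10

    def test_two_full_cycles_retain_sixty_seconds_per_chamber(self):
        # Oracle: enumerate the schedule — 2 cycles x 30 sample-seconds.
        stream, sched = constant_stream(4, 30, 40, 560)
        retained = stream[sched.in_sample_window(stream["timestamp_s"].to_numpy())]
        counts = retained.groupby("chamber_id").size()
        assert (counts == 60).all()
        out = demultiplex_stream(stream, sched, window_discard_s=0.0)
        assert len(out) == 8  # 2 visits x 4 chambers

    def test_purge_rows_are_discarded(self):
        stream, sched = constant_stream(4, 30, 40, 2800, value=7.0)
        out = demultiplex_stream(stream, sched, window_discard_s=10.0)
        assert out["delta_co2_umol_mol"].to_numpy() == pytest.approx(7.0)

    def test_discard_longer_than_window_raises(self):
        stream, sched = constant_stream(2, 30, 40, 280)
        with pytest.raises(ValueError, match="window_discard_s"):
            demultiplex_stream(stream, sched, window_discard_s=30.0)

    def test_chamber_ids_inconsistent_with_schedule_raise(self):
        stream, _ = constant_stream(4, 30, 40, 560)
        with pytest.raises(ValueError, match="inconsistent"):
            demultiplex_stream(stream, SamplingSchedule(2, 30, 40))


class TestNetFlux:
    def test_worked_value(self):
        assert net_flux(0.034, 25.0, 0.17) == pytest.approx(5.0)

    def test_zero_delta_gives_zero(self):
        assert net_flux(0.02, 0.0, 0.17) == 0.0

    def test_dark_period_sign_convention(self):
        assert net_flux(0.02, -4.0, 0.17) < 0

    @pytest.mark.parametrize("flow,area", [(0, 0.17), (-1, 0.17), (0.02, 0)])
    def test_nonpositive_inputs_raise(self, flow, area):
        with pytest.raises(ValueError):
            net_flux(flow, 5.0, area)

    @given(
        st.floats(1e-3, 0.1),
        st.floats(-50, 50),
        st.floats(1.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_flow_and_delta(self, flow, delta, scale):
        base = net_flux(flow, delta, 0.17)
        assert net_flux(flow * scale, delta, 0.17) == pytest.approx(base * scale)
        assert net_flux(flow, delta * scale, 0.17) == pytest.approx(base * scale)


def day_flux_frame(light_value, dark_value, n_days=1, step_s=280.0):
    """Per-visit flux records for one chamber over whole days."""
    t = np.arange(0, n_days * 86400.0, step_s)
    light = (t % 86400.0) < 14 * 3600.0
    return pd.DataFrame(
        {
            "timestamp_s": t,
            "chamber_id": 0,
            "pnet_umol_m2_s": np.where(light, light_value, dark_value),
            "light_on": light,
        }
    )


class TestDailyPeriodMeans:
    def test_constant_fluxes_convert_to_mol_per_hour(self):
        means = daily_period_means(day_flux_frame(5.0, -1.0))
        assert means["pnet_light_mol_m2_h"].iloc[0] == pytest.approx(0.018)
        assert means["rdark_mol_m2_h"].iloc[0] == pytest.approx(-0.0036)

    def test_all_zero_series(self):
        means = daily_period_means(day_flux_frame(0.0, 0.0))
        assert means["pnet_light_mol_m2_h"].iloc[0] == 0.0
        assert means["rdark_mol_m2_h"].iloc[0] == 0.0

    def test_transition_spikes_are_excluded(self):
        clean = day_flux_frame(5.0, -1.0)
        spiked = clean.copy()
        t_in = spiked["timestamp_s"] % 86400.0
        spike_zone = (t_in < 600) | (
            (t_in >= 14 * 3600.0) & (t_in < 14 * 3600.0 + 600)
        )
        spiked.loc[spike_zone, "pnet_umol_m2_s"] = 500.0
        a = daily_period_means(clean)
        b = daily_period_means(spiked)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_dark_period_raises(self):
        frame = day_flux_frame(5.0, -1.0)
        frame = frame[frame["light_on"]]
        with pytest.raises(ValueError, match="missing light or dark|incomplete"):
            daily_period_means(frame)


class TestDailyCarbonEquations:
    def test_gross_photosynthesis_worked_value(self):
        # (0.018 + 0.004) x 14 x 0.17 x 30
        assert gross_photosynthesis(0.018, -0.004, CONV) == pytest.approx(1.5708)

    def test_zero_respiration_reduces_to_light_term(self):
        assert gross_photosynthesis(0.018, 0.0, CONV) == pytest.approx(
            0.018 * 14 * 0.17 * 30
        )
        assert gross_photosynthesis(0.0, 0.0, CONV) == 0.0

    def test_daily_carbon_gain_worked_value(self):
        # (0.018 x 14 - 0.004 x 10) x 0.17 x 30
        assert daily_carbon_gain(0.018, -0.004, CONV) == pytest.approx(1.0812)

    def test_dcg_equals_pgross_without_respiration(self):
        assert daily_carbon_gain(0.02, 0.0, CONV) == pytest.approx(
            gross_photosynthesis(0.02, 0.0, CONV)
        )

    def test_pure_respiration_gives_negative_dcg(self):
        assert daily_carbon_gain(0.0, -0.004, CONV) < 0

    def test_cue_worked_value(self):
        assert carbon_use_efficiency(1.0812, 1.5708) == pytest.approx(
            0.6883, abs=5e-5
        )

    @pytest.mark.parametrize("dcg,pg,expected", [(1.2, 1.2, 1.0), (0.0, 1.5, 0.0)])
    def test_cue_limits(self, dcg, pg, expected):
        assert carbon_use_efficiency(dcg, pg) == expected

    def test_cue_undefined_for_zero_pgross(self):
        with pytest.raises(ValueError, match="undefined"):
            carbon_use_efficiency(0.5, 0.0)

    @given(st.floats(0, 0.05), st.floats(-0.02, 0))
    @settings(max_examples=100, deadline=None)
    def test_pgross_minus_dcg_identity(self, pnl, rd):
        # Algebraic identity: P_gross - DCG = |R_dark| x 24 h x area x g/mol
        pg = gross_photosynthesis(pnl, rd, CONV)
        dcg = daily_carbon_gain(pnl, rd, CONV)
        assert pg - dcg == pytest.approx(abs(rd) * 24 * 0.17 * 30, abs=1e-9)

    @given(st.floats(1e-4, 0.05), st.floats(-0.02, 0))
    @settings(max_examples=50, deadline=None)
    def test_cue_bounded_for_physiological_signs(self, pnl, rd):
        pg = gross_photosynthesis(pnl, rd, CONV)
        cue = carbon_use_efficiency(daily_carbon_gain(pnl, rd, CONV), pg)
        assert cue <= 1.0 + 1e-12


class TestPredictHarvestMass:
    def test_constant_dcg_summation(self):
        assert predict_harvest_mass(np.ones(10), 0.5) == pytest.approx(10.5)

    def test_empty_series_returns_initial(self):
        assert predict_harvest_mass([], 0.3) == pytest.approx(0.3)

    def test_ratio_to_measured(self):
        pred, pct = predict_harvest_mass(np.ones(10), 0.5, measured_dry_mass_g=10.5)
        assert pct == pytest.approx(100.0)

    def test_nonpositive_measured_mass_raises(self):
        with pytest.raises(ValueError):
            predict_harvest_mass(np.ones(3), 0.0, measured_dry_mass_g=0.0)


def test_flux_series_attaches_net_flux():
    records = pd.DataFrame(
        {
            "timestamp_s": [0.0, 70.0],
            "chamber_id": [0, 1],
            "flow_mol_s": [0.034, 0.017],
            "delta_co2_umol_mol": [25.0, -10.0],
            "light_on": [True, False],
        }
    )
    out = flux_series(records, 0.17)
    assert out["pnet_umol_m2_s"].to_numpy() == pytest.approx([5.0, -1.0])
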