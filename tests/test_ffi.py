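import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from barrel4.ffi import (
    FFICellConfig,
    all_scenarios,
    condition_spike_stats,
    ffi_cell_config,
    ffi_threshold,
    scenario_config,
    simulate_ffi_trial,
    sweep_ga_frequency,
    train_times,
)
from barrel4.stp import amplitudes_at
from barrel4.synapses import conductance_train
from barrel4.units import MOHM_NS

from conftest import scenario_row


class TestSingleTrial:
    def test_no_stimuli_rests_at_leak(self, wt):
        cfg = ffi_cell_config(wt)
        t, v, spikes = simulate_ffi_trial(cfg, [])
        assert np.allclose(v, cfg.cell.v_rest)
        assert spikes.size == 0

    def test_dt_guard(self, wt):
        with pytest.raises(ValueError):
            simulate_ffi_trial(ffi_cell_config(wt), [20.0], dt=0.5)

    def test_peak_tc_conductance_is_one_ns(self, wt):
        # the measured TC peak conductance: 1 nS, ~60 pA inward from -60 mV
        cfg = ffi_cell_config(wt)
        t_grid = np.arange(0.0, 60.0, 0.01)
        amps = amplitudes_at(cfg.tc_syn.stp, np.array([20.0]))
        g = cfg.tc_syn.g_max * conductance_train(t_grid, [20.0], amps, cfg.tc_syn)
        assert g.max() == pytest.approx(1.0, abs=1e-6)
        assert g.max() * 60.0 == pytest.approx(60.0, abs=1e-4)  # pA at rest

    def test_subthreshold_epsp_matches_ode_oracle(self, wt):
        """Exponential-Euler trace equals an independent adaptive-step ODE
        solution of the conductance-driven membrane equation within 1%."""
        cfg = ffi_cell_config(wt, ga_ratio=0.0)
        weak = replace(cfg, tc_syn=replace(cfg.tc_syn, g_max=0.2, stp=None))
        t, v, spikes = simulate_ffi_trial(weak, [10.0], dt=0.025, t_stop=120.0)
        assert spikes.size == 0

        cell = weak.cell
        spec = weak.tc_syn

        def rhs(tt, y):
            g = spec.g_max * conductance_train(np.array([tt]), [10.0], [1.0], spec)[0]
            i_syn = g * (y[0] - spec.e_rev)
            return [(-(y[0] - cell.v_rest) - cell.r_in * MOHM_NS * i_syn) / cell.tau_m]

        sol = solve_ivp(
            rhs, (0.0, 120.0), [cell.v_rest], t_eval=t, rtol=1e-8, atol=1e-10, max_step=0.5
        )
        peak_sim = v.max() - cell.v_rest
        peak_ode = sol.y[0].max() - cell.v_rest
        assert peak_sim == pytest.approx(peak_ode, rel=0.01)

    def test_late_inhibition_equals_no_inhibition(self, wt):
        """With the E-I lag beyond the simulated window, strong FFI is inert."""
        cfg = ffi_cell_config(wt, ga_ratio=8.0)
        late = replace(cfg, ei_lag=1e6)
        none = replace(cfg, ga_ratio=0.0)
        stim = train_times(20.0)
        _, v_late, s_late = simulate_ffi_trial(late, stim)
        _, v_none, s_none = simulate_ffi_trial(none, stim)
        assert np.array_equal(s_late, s_none)
        assert np.allclose(v_late, v_none)

    def test_threshold_scales_with_rheobase_depolarization(self, wt, ko):
        assert ffi_threshold(412.0, 72.0) > ffi_threshold(609.0, 44.0)
        cfg_wt, cfg_ko = ffi_cell_config(wt), ffi_cell_config(ko)
        assert cfg_wt.cell.v_thresh > cfg_ko.cell.v_thresh > cfg_ko.cell.v_reset


class TestSweep:
    def test_grids_must_be_nonempty(self, wt):
        with pytest.raises(ValueError):
            sweep_ga_frequency(wt, ga_grid=[], frequencies=[20.0])

    def test_shape_and_labels(self, default_sweeps):
        sw = default_sweeps["WT"]
        assert sw.spike_count.shape == (21, 10)
        assert sw.label == "WT"
        df = sw.to_frame()
        assert len(df) == 210
        assert set(df.columns) >= {"ga_ratio", "frequency_hz", "n_spikes"}

    def test_inhibition_never_adds_firing_conditions(self, default_sweeps):
        """At fixed frequency, raising G/A can only silence, not recruit."""
        for sw in default_sweeps.values():
            fires = sw.spike_count >= 1
            recruited = fires[1:] & ~fires[:-1]
            assert not recruited.any()

    def test_latency_defined_only_where_spiking(self, default_sweeps):
        sw = default_sweeps["KO"]
        assert np.all(np.isnan(sw.first_latency[sw.spike_count == 0]))
        assert np.all(np.isfinite(sw.first_latency[sw.spike_count >= 1]))

    def test_deterministic_without_trial_jitter(self, wt):
        a = sweep_ga_frequency(wt, ga_grid=[0.0, 2.0], frequencies=[10.0, 50.0])
        b = sweep_ga_frequency(wt, ga_grid=[0.0, 2.0], frequencies=[10.0, 50.0])
        assert np.array_equal(a.spike_count, b.spike_count)

    def test_trial_jitter_produces_finite_jitter(self, wt):
        sw = sweep_ga_frequency(
            wt, ga_grid=[0.0], frequencies=[20.0], n_trials=5, g_jitter_cv=0.2, seed=3
        )
        assert np.isfinite(sw.jitter[0, 0])

    def test_dt_convergence_of_firing_conditions(self, wt):
        """Halving the step flips under 1% of grid conditions."""
        coarse = sweep_ga_frequency(wt, dt=0.05)
        fine = sweep_ga_frequency(wt, dt=0.025)
        flips = np.sum((coarse.spike_count >= 1) != (fine.spike_count >= 1))
        assert flips <= 2  # 1% of 210


class TestRescueMatrix:
    def test_sixteen_distinct_scenarios(self):
        scenarios = all_scenarios()
        assert len(scenarios) == len(set(scenarios)) == 16

    def test_summary_has_all_scenarios(self, rescue):
        assert len(rescue["summary"]) == 16

    def test_all_wt_scenario_equals_baseline(self, rescue, default_sweeps, all_wt_scenario):
        res = rescue["results"][all_wt_scenario]
        assert np.array_equal(res.spike_count, default_sweeps["WT"].spike_count)

    def test_all_ko_scenario_equals_baseline(self, rescue, default_sweeps, all_ko_scenario):
        res = rescue["results"][all_ko_scenario]
        assert np.array_equal(res.spike_count, default_sweeps["KO"].spike_count)

    def test_scenario_config_mixes_groups(self, wt, ko):
        from barrel4.ffi import RescueScenario

        sc = RescueScenario(stp=True, delay=False, intrinsic=True, kinetics=False)
        cfg = scenario_config(wt, ko, sc)
        assert cfg.cell.r_in == wt.ex_cell.r_in  # intrinsic from WT
        assert cfg.ei_lag == ko.ei_lag  # delay from KO
        assert cfg.tc_syn.stp == wt.synapses["tc_ex"].stp  # plasticity from WT
        assert cfg.ffi_syn.tau_decay == ko.synapses["ffi"].tau_decay  # kinetics KO

    def test_reference_percentages_are_zero_for_wt(self, rescue):
        row = scenario_row(rescue["summary"], True, True, True, True)
        assert row["spikes_pct_vs_wt"] == 0.0
        assert row["conditions_pct_vs_wt"] == 0.0


class TestConditionStats:
    def test_only_spiking_conditions_reported(self, default_sweeps):
        df = condition_spike_stats(default_sweeps["WT"])
        assert (df["n_spikes"] >= 1).all()
        assert len(df) == default_sweeps["WT"].firing_conditions

    def test_zero_jitter_for_deterministic_trials(self, default_sweeps):
        df = condition_spike_stats(default_sweeps["WT"])
        assert np.allclose(df["jitter_ms"], 0.0)

    def test_empty_spiking_set_is_empty_frame(self, wt):
        # overwhelming inhibition: nothing fires, no failure
        cfg = ffi_cell_config(wt, ga_ratio=0.0)
        strong = FFICellConfig(
            cell=cfg.cell,
            tc_syn=replace(cfg.tc_syn, g_max=0.0),
            ffi_syn=cfg.ffi_syn,
            ei_lag=cfg.ei_lag,
        )
        sw = sweep_ga_frequency(strong, ga_grid=[0.0, 5.0], frequencies=[20.0])
        df = condition_spike_stats(sw)
        assert len(df) == 0
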