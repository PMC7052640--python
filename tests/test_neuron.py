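"""Conductance-based model: fixed points, linear responses, spiking, populations."""

from dataclasses import replace

import numpy as np
import pytest

from dgephys import (
    APTemplate,
    MembraneParams,
    SpikeParams,
    analytic_impedance,
    default_granule_cell,
    fast_resonant_cell,
    hold_at_voltage,
    make_chirp,
    make_pulse,
    rheobase_estimate,
    simulate_spiking,
    simulate_subthreshold,
)
from dgephys.errors import IntegrationError, InvalidArgumentError, InvalidSpecError
from dgephys.population import (
    Moments,
    SectorPopulationSpec,
    default_population_specs,
    sample_sector_population,
)
from dgephys.suprathreshold import classify_excitability, fi_curve

FREQS = np.linspace(1.0 / 15.0, 15.0, 800)


class TestSubthresholdDynamics:
    def test_zero_stimulus_stays_at_resting_fixed_point(self, hcn_cell):
        tr = simulate_subthreshold(hcn_cell, make_pulse(0.0, duration=2000.0))
        v_rest = hcn_cell.resting_potential()
        assert np.max(np.abs(tr.samples - v_rest)) < 0.01

    def test_passive_step_matches_rc_closed_form(self, passive_cell):
        amp = 100.0
        stim = make_pulse(amp, duration=700.0)
        tr = simulate_subthreshold(passive_cell, stim)
        sl = stim.epoch_slice("pulse")
        t = tr.time()[sl] - stim.epochs["pulse"][0]
        tau = passive_cell.C / passive_cell.g_L
        r_mv_per_pa = 1.0 / passive_cell.g_L  # 170 MΩ -> 0.17 mV/pA
        expected = passive_cell.E_L + amp * r_mv_per_pa * (1 - np.exp(-t / tau))
        assert np.max(np.abs(tr.samples[sl] - expected)) < 1e-3 * amp * r_mv_per_pa

    def test_resting_potential_solves_current_balance(self, hcn_cell):
        # independent check: the reported rest is a root of the steady-state I-V
        v = hcn_cell.resting_potential()
        assert hcn_cell.steady_current(v) == pytest.approx(0.0, abs=1e-8)
        grid = np.linspace(-95.0, -50.0, 2000)
        residual = np.array([hcn_cell.steady_current(x) for x in grid])
        v_grid = grid[np.argmin(np.abs(residual))]
        assert v == pytest.approx(v_grid, abs=0.05)

    def test_passive_rest_is_e_leak_and_r_is_inverse_leak(self):
        p = MembraneParams(g_h=0.0, E_L=-71.0)
        assert p.resting_potential() == pytest.approx(-71.0, abs=1e-9)
        z = analytic_impedance(p, [1e-4], -71.0)
        assert z.magnitude[0] == pytest.approx(1000.0 / p.g_L, rel=1e-6)

    def test_noise_is_seeded_and_deterministic(self, hcn_cell):
        stim = make_pulse(0.0, duration=300.0)
        a = simulate_subthreshold(hcn_cell, stim, noise_sd=5.0, seed=11)
        b = simulate_subthreshold(hcn_cell, stim, noise_sd=5.0, seed=11)
        c = simulate_subthreshold(hcn_cell, stim, noise_sd=5.0, seed=12)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_divergent_drive_raises_integration_error(self, passive_cell):
        with pytest.raises(IntegrationError):
            simulate_subthreshold(passive_cell, make_pulse(-50000.0, duration=700.0))


class TestHolding:
    def test_bias_at_rest_is_zero(self, hcn_cell):
        assert hold_at_voltage(hcn_cell, hcn_cell.resting_potential()) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("target", [-80.0, -75.0, -70.0, -65.0, -60.0])
    def test_voltage_sweep_settles_at_target(self, hcn_cell, target):
        bias = hold_at_voltage(hcn_cell, target)
        tr = simulate_subthreshold(hcn_cell, make_pulse(0.0, duration=1000.0), bias=bias)
        assert np.abs(np.mean(tr.samples[-2000:]) - target) < 0.1

    def test_hyperpolarized_holding_needs_negative_bias(self, hcn_cell):
        assert hold_at_voltage(hcn_cell, -85.0) < 0 < hold_at_voltage(hcn_cell, -65.0)


class TestAnalyticImpedance:
    def test_passive_closed_form_magnitude_and_phase(self, passive_cell):
        z = analytic_impedance(passive_cell, FREQS, -75.0)
        tau_s = passive_cell.C / passive_cell.g_L / 1000.0
        r = 1000.0 / passive_cell.g_L
        expected_mag = r / np.sqrt(1 + (2 * np.pi * FREQS * tau_s) ** 2)
        expected_ph = -np.arctan(2 * np.pi * FREQS * tau_s)
        assert np.allclose(z.magnitude, expected_mag, rtol=1e-9)
        assert np.allclose(z.phase, expected_ph, atol=1e-9)

    def test_default_slow_hcn_cell_is_low_pass(self, hcn_cell):
        v = hcn_cell.resting_potential()
        z = analytic_impedance(hcn_cell, FREQS, v)
        i_max = np.argmax(z.magnitude)
        assert FREQS[i_max] < 1.0
        q = z.magnitude[i_max] / np.interp(0.5, FREQS, z.magnitude)
        assert q < 1.05
        above_1hz = FREQS >= 1.0
        assert np.all(np.diff(z.magnitude[above_1hz]) < 0)
        assert np.max(z.phase) < 0.002

    def test_fast_strong_hcn_turns_band_pass(self):
        p = fast_resonant_cell()
        z = analytic_impedance(p, FREQS, p.resting_potential())
        i_max = np.argmax(z.magnitude)
        assert FREQS[i_max] > 1.0
        assert z.magnitude[i_max] / np.interp(0.5, FREQS, z.magnitude) > 1.1

    def test_rejects_nonpositive_frequencies(self, hcn_cell):
        with pytest.raises(InvalidArgumentError):
            analytic_impedance(hcn_cell, [0.0, 1.0], -75.0)


class TestSpiking:
    def test_below_rheobase_no_spikes(self, spiking_cell):
        rheo = rheobase_estimate(spiking_cell)
        tr = simulate_spiking(spiking_cell, make_pulse(rheo - 15.0, duration=700.0))
        assert len(tr.metadata["true_spike_times"]) == 0

    def test_default_rheobase_in_granule_cell_range(self, spiking_cell):
        assert 50.0 <= rheobase_estimate(spiking_cell) <= 150.0

    def test_class_one_excitability_low_rate_at_threshold(self, spiking_cell):
        amps = [0.0, 50.0, 100.0, 150.0, 200.0, 250.0]
        steps = [(a, simulate_spiking(spiking_cell, make_pulse(a))) for a in amps]
        profile = fi_curve(steps)
        assert classify_excitability(profile, cell=spiking_cell) == "I"

    def test_fi_rates_nondecreasing_and_broadly_linear(self, spiking_cell):
        amps = np.arange(0.0, 251.0, 50.0)
        steps = [(a, simulate_spiking(spiking_cell, make_pulse(a))) for a in amps]
        profile = fi_curve(steps)
        assert np.all(np.diff(profile.rates) >= 0)
        above = profile.amplitudes >= profile.rheobase
        r = np.corrcoef(profile.amplitudes[above], profile.rates[above])[0, 1]
        assert r > 0.97

    @pytest.mark.parametrize("amp", [150.0, 250.0])
    def test_spike_count_stable_under_step_refinement(self, spiking_cell, amp):
        n2 = len(simulate_spiking(spiking_cell, make_pulse(amp), substeps=2).metadata["true_spike_times"])
        n8 = len(simulate_spiking(spiking_cell, make_pulse(amp), substeps=8).metadata["true_spike_times"])
        assert abs(n2 - n8) <= 1

    def test_spiking_requires_spike_params(self, hcn_cell):
        with pytest.raises(InvalidArgumentError):
            simulate_spiking(hcn_cell, make_pulse(250.0))

    def test_ground_truth_spike_times_sit_on_template_peaks(self, spiking_cell):
        tr = simulate_spiking(spiking_cell, make_pulse(250.0))
        dt = tr.sample_interval
        for t_peak in tr.metadata["true_spike_times"]:
            i = int(round(t_peak / dt))
            win = tr.samples[i - 4: i + 5]
            assert np.max(win) == pytest.approx(spiking_cell.spike.template.V_peak, abs=0.2)


class TestAPTemplate:
    def test_threshold_crossing_at_designed_voltage(self):
        tpl = APTemplate()
        dt = 0.05
        v = tpl.sample(dt)
        dv = np.gradient(v, dt)
        ups = np.flatnonzero((dv[:-1] < 20.0) & (dv[1:] >= 20.0))
        j = ups[-1]
        frac = (20.0 - dv[j]) / (dv[j + 1] - dv[j])
        v_cross = v[j] + frac * (v[j + 1] - v[j])
        assert v_cross == pytest.approx(tpl.V_th, abs=0.1)

    def test_shape_extrema_match_parameters(self):
        tpl = APTemplate()
        v = tpl.sample(0.005)
        dv = np.gradient(v, 0.005)
        assert np.max(v) == pytest.approx(tpl.V_peak, abs=0.05)
        assert np.max(dv) == pytest.approx(tpl.dvdt_max, rel=0.02)
        assert np.min(dv) == pytest.approx(tpl.dvdt_min, rel=0.02)

    def test_template_shorter_than_refractory(self):
        sp = SpikeParams()
        assert sp.template.duration < sp.refractory

    def test_invalid_geometries_rejected(self):
        with pytest.raises(InvalidArgumentError):
            APTemplate(V_start=-30.0, V_th=-38.5)
        with pytest.raises(InvalidArgumentError):
            APTemplate(V_peak=-5.0)
        with pytest.raises(InvalidArgumentError):
            APTemplate(d0=25.0)


class TestPopulationSampling:
    def test_n_zero_gives_empty_population(self):
        spec = replace(default_population_specs(5)[0], n=0)
        assert sample_sector_population(spec, seed=1) == []

    def test_sampling_is_deterministic_per_seed(self):
        spec = default_population_specs(3)[1]
        a = sample_sector_population(spec, seed=9)
        b = sample_sector_population(spec, seed=9)
        assert [p for p, _ in a] == [p for p, _ in b]

    def test_sampled_parameters_satisfy_model_invariants(self):
        for spec in default_population_specs(6):
            for params, sector in sample_sector_population(spec, seed=4):
                assert sector == spec.name
                assert params.C > 0 and params.g_L > 0 and params.g_h >= 0
                assert params.tau_h > 0 and params.k_slope > 0
                sp = params.spike
                assert sp.template.duration < sp.refractory
                assert sp.V_T < sp.template.V_start < sp.template.V_th < 0

    def test_resting_potentials_track_sector_target(self):
        spec = default_population_specs(40)[1]  # crest: V_RMP -76.09 +/- 4.22
        cells = sample_sector_population(spec, seed=2)
        rests = np.array([p.resting_potential() for p, _ in cells])
        se = spec.V_RMP.sd / np.sqrt(len(rests))
        assert abs(np.mean(rests) - spec.V_RMP.mean) < 3 * se

    def test_infeasible_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            Moments(100.0, -5.0)
        with pytest.raises(InvalidSpecError):
            replace(default_population_specs(5)[0], n=-1)
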