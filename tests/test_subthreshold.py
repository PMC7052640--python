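"""Subthreshold measurements: formula oracles, closed-form checks, HCN behavior."""

import numpy as np
import pytest

from dgephys import (
    ImpedanceProfile,
    StimulusWaveform,
    VoltageTrace,
    hold_at_voltage,
    impedance_profile,
    input_resistance_fit,
    make_alpha_train,
    make_chirp,
    make_pulse,
    pulse_input_resistance,
    resonance_measures,
    sag_percentage,
    simulate_subthreshold,
    summation_ratio,
    total_inductive_phase,
)
from dgephys.errors import (
    ContaminatedProtocolError,
    InsufficientDataError,
    InvalidArgumentError,
    ProtocolError,
)
from dgephys.stimuli import alpha_kernel

DT = 0.05


def step_trace(amplitude, deflection, v_rmp=-75.0, tau=0.0):
    """Trace responding to a 700-ms pulse with a known steady deflection."""
    stim = make_pulse(amplitude, duration=700.0, sample_interval=DT)
    t = stim.time()
    t0 = stim.epochs["pulse"][0]
    v = np.full_like(t, v_rmp)
    inside = (t >= t0) & (t < stim.epochs["pulse"][1])
    if tau > 0:
        v[inside] += deflection * (1 - np.exp(-(t[inside] - t0) / tau))
    else:
        v[inside] += deflection
    return VoltageTrace(samples=v, sample_interval=DT, stimulus=stim)


class TestInputResistanceFit:
    def test_exact_linear_deflections_recover_slope(self):
        steps = [(a, step_trace(a, 0.15 * a)) for a in np.arange(-50.0, 51.0, 10.0)]
        fit = input_resistance_fit(steps)
        assert fit.value == pytest.approx(150.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_high_rin_small_amplitude_family_accepted(self):
        steps = [(a, step_trace(a, 0.3 * a)) for a in np.arange(-25.0, 26.0, 5.0)]
        assert input_resistance_fit(steps).value == pytest.approx(300.0, rel=1e-9)

    def test_recovers_leak_resistance_of_noiseless_passive_cell(self, passive_cell):
        steps = []
        for a in np.arange(-50.0, 51.0, 10.0):
            steps.append((a, simulate_subthreshold(passive_cell, make_pulse(a, duration=700.0))))
        assert input_resistance_fit(steps).value == pytest.approx(170.0, rel=0.01)

    def test_too_few_amplitudes_rejected(self):
        steps = [(a, step_trace(a, 0.15 * a)) for a in (-50.0, 50.0)]
        with pytest.raises(InsufficientDataError):
            input_resistance_fit(steps)

    def test_spiking_trace_flagged_with_amplitude(self):
        bad = step_trace(50.0, 7.5)
        sl = bad.epoch_slice("pulse")
        i0 = sl.start + 1000
        bad.samples[i0: i0 + 20] = np.linspace(-60.0, 40.0, 20)  # fake AP upstroke
        steps = [(a, step_trace(a, 0.15 * a)) for a in np.arange(-50.0, 41.0, 10.0)]
        steps.append((50.0, bad))
        with pytest.raises(ContaminatedProtocolError) as exc:
            input_resistance_fit(steps)
        assert exc.value.amplitude == 50.0


class TestPulseInputResistance:
    def test_ohms_law_on_constructed_deflection(self):
        stim = make_chirp()
        t = stim.time()
        v = np.full_like(t, -75.0)
        sl = stim.epoch_slice("prepulse")
        v[sl] = -87.0  # -12 mV deflection for -100 pA
        tr = VoltageTrace(samples=v, sample_interval=stim.sample_interval, stimulus=stim)
        assert pulse_input_resistance(tr).value == pytest.approx(120.0, rel=1e-9)

    def test_hcn_shunts_below_leak_resistance(self, hcn_cell, hcn_chirp_trace):
        rbar = pulse_input_resistance(hcn_chirp_trace).value
        assert rbar < 1000.0 / hcn_cell.g_L

    def test_decreases_with_hyperpolarized_holding(self, hcn_cell, chirp_stim):
        rbars = []
        for target in (-80.0, -70.0, -60.0):
            bias = hold_at_voltage(hcn_cell, target)
            tr = simulate_subthreshold(hcn_cell, chirp_stim, bias=bias)
            rbars.append(pulse_input_resistance(tr).value)
        assert rbars[0] < rbars[1] < rbars[2]

    def test_missing_pulse_epoch_rejected(self):
        stim = make_chirp(prepulse_duration=0.0)
        tr = VoltageTrace(np.zeros(stim.n_samples), stim.sample_interval, stim)
        with pytest.raises(ProtocolError):
            pulse_input_resistance(tr)


class TestSag:
    def test_formula_arithmetic_on_constructed_pulse(self):
        stim = make_chirp()
        t = stim.time()
        v = np.full_like(t, -75.0)
        sl = stim.epoch_slice("prepulse")
        n = sl.stop - sl.start
        # dips to -87 then relaxes to a -86.6 plateau: sag = 100*(1 - 11.6/12)
        v[sl.start: sl.start + 200] = np.linspace(-75.0, -87.0, 200)
        v[sl.start + 200: sl.start + 400] = np.linspace(-87.0, -86.6, 200)
        v[sl.start + 400: sl.stop] = -86.6
        tr = VoltageTrace(samples=v, sample_interval=stim.sample_interval, stimulus=stim)
        assert sag_percentage(tr).value == pytest.approx(100.0 * (1 - 11.6 / 12.0), abs=1e-6)

    def test_passive_rc_has_no_sag(self, passive_cell, plain_chirp):
        tr = simulate_subthreshold(passive_cell, make_chirp())
        assert abs(sag_percentage(tr).value) < 0.2

    def test_slow_hcn_cell_produces_small_positive_sag(self, hcn_chirp_trace):
        sag = sag_percentage(hcn_chirp_trace).value
        assert 0.0 < sag < 10.0

    def test_sub_noise_floor_deflection_flagged(self):
        stim = make_chirp()
        v = np.full(stim.n_samples, -75.0)
        sl = stim.epoch_slice("prepulse")
        v[sl] = -75.2
        tr = VoltageTrace(samples=v, sample_interval=stim.sample_interval, stimulus=stim)
        assert "UNRELIABLE" in sag_percentage(tr).flags


class TestSummationRatio:
    def test_interval_much_longer_than_tau_gives_unity(self, passive_cell):
        stim = make_alpha_train(interval=1000.0, post=1500.0)
        tr = simulate_subthreshold(passive_cell, stim)
        assert summation_ratio(tr).value == pytest.approx(1.0, abs=0.01)

    def test_matches_linear_superposition_convolution_oracle(self):
        from dgephys import MembraneParams
        cell = MembraneParams(C=180.0, g_L=6.0, E_L=-75.0, g_h=0.0)  # tau = 30 ms
        stim = make_alpha_train(interval=50.0)
        tr = simulate_subthreshold(cell, stim)
        measured = summation_ratio(tr).value
        # oracle: convolve the stimulus with the RC impulse response
        dt = stim.sample_interval
        t = np.arange(0.0, 4000.0, dt)
        h = np.exp(-t * cell.g_L / cell.C) / cell.C * dt  # mV per (pA*ms)
        v = np.convolve(stim.samples, h)[: stim.n_samples]
        onsets = stim.params["onsets"]
        i0, i1 = int(onsets[0] / dt), int(onsets[-1] / dt)
        iw = int(50.0 / dt)
        expected = np.max(v[i1: i1 + iw]) / np.max(v[i0: i0 + iw])
        assert measured == pytest.approx(expected, rel=0.01)

    def test_invariant_to_uniform_amplitude_scaling(self, passive_cell):
        r = []
        for i_max in (10.0, 40.0):
            tr = simulate_subthreshold(passive_cell, make_alpha_train(i_max=i_max))
            r.append(summation_ratio(tr).value)
        assert r[0] == pytest.approx(r[1], rel=1e-6)

    def test_spike_during_train_rejected(self, passive_cell):
        stim = make_alpha_train()
        tr = simulate_subthreshold(passive_cell, stim)
        i0 = stim.epoch_slice("train").start + 500
        tr.samples[i0: i0 + 20] = np.linspace(-60.0, 40.0, 20)
        with pytest.raises(ContaminatedProtocolError):
            summation_ratio(tr)


class TestImpedanceProfile:
    def test_pure_resistor_flat_magnitude_zero_phase(self):
        stim = make_chirp(prepulse_duration=0.0)
        r_gohm = 0.15  # 150 MΩ in mV/pA
        v = -75.0 + r_gohm * stim.samples
        tr = VoltageTrace(samples=v, sample_interval=stim.sample_interval, stimulus=stim)
        prof = impedance_profile(tr)
        band = prof.band_mask()
        assert np.allclose(prof.magnitude[band], 150.0, rtol=1e-6)
        assert np.max(np.abs(prof.phase[band])) < 1e-6

    def test_passive_rc_matches_closed_form(self, passive_cell, passive_chirp_trace):
        prof = impedance_profile(passive_chirp_trace)
        band = prof.band_mask()
        f = prof.freqs[band]
        tau_s = passive_cell.C / passive_cell.g_L / 1000.0
        mag = (1000.0 / passive_cell.g_L) / np.sqrt(1 + (2 * np.pi * f * tau_s) ** 2)
        ph = -np.arctan(2 * np.pi * f * tau_s)
        assert np.max(np.abs(prof.magnitude[band] - mag) / mag) < 0.02
        assert np.max(np.abs(prof.phase[band] - ph)) < 0.02

    def test_hyperpolarization_suppresses_low_frequency_gain(self, hcn_cell, chirp_stim):
        profs = {}
        for target in (-80.0, -65.0):
            bias = hold_at_voltage(hcn_cell, target)
            tr = simulate_subthreshold(hcn_cell, chirp_stim, bias=bias)
            profs[target] = impedance_profile(tr)
        low = profs[-80.0].freqs < 2.0
        assert np.all(profs[-80.0].magnitude[low] < profs[-65.0].magnitude[low])

    def test_spike_in_chirp_epoch_rejected(self, passive_chirp_trace):
        tr = VoltageTrace(
            samples=passive_chirp_trace.samples.copy(),
            sample_interval=passive_chirp_trace.sample_interval,
            stimulus=passive_chirp_trace.stimulus,
        )
        i0 = tr.epoch_slice("chirp").start + 5000
        tr.samples[i0: i0 + 20] = np.linspace(-60.0, 40.0, 20)
        with pytest.raises(ContaminatedProtocolError):
            impedance_profile(tr)


class TestResonanceMeasures:
    def test_strictly_decreasing_profile_pins_fr_at_band_edge(self):
        f = np.linspace(0.5, 15.0, 200)
        prof = ImpedanceProfile(freqs=f, magnitude=200.0 / (1 + f), phase=np.zeros_like(f))
        res = resonance_measures(prof)
        assert res.f_R == 0.5
        assert res.Q == pytest.approx(1.0)

    def test_constructed_band_pass_peak_recovered(self):
        f = np.linspace(1.0 / 15.0, 15.0, 500)
        mag = 100.0 + 40.0 * np.exp(-((f - 4.0) ** 2) / 2.0)
        prof = ImpedanceProfile(freqs=f, magnitude=mag, phase=np.zeros_like(f))
        res = resonance_measures(prof)
        assert res.f_R == pytest.approx(4.0, abs=f[1] - f[0])
        expected_q = np.max(mag) / np.interp(0.5, f, mag)
        assert res.Q == pytest.approx(expected_q, rel=1e-9)
        assert res.Z_max == pytest.approx(np.max(mag))

    def test_ties_resolve_to_lowest_frequency(self):
        f = np.linspace(0.5, 15.0, 100)
        prof = ImpedanceProfile(freqs=f, magnitude=np.full_like(f, 120.0), phase=np.zeros_like(f))
        assert resonance_measures(prof).f_R == 0.5

    def test_q_at_least_one_when_band_contains_reference(self):
        rng = np.random.default_rng(5)
        f = np.linspace(1.0 / 15.0, 15.0, 300)
        for _ in range(50):
            mag = np.abs(rng.normal(150.0, 30.0, size=f.size)) + 1.0
            prof = ImpedanceProfile(freqs=f, magnitude=mag, phase=np.zeros_like(f))
            assert resonance_measures(prof).Q >= 1.0 - 1e-12

    def test_empty_profile_rejected(self):
        prof = ImpedanceProfile(freqs=np.array([20.0]), magnitude=np.array([1.0]),
                                phase=np.array([0.0]))
        with pytest.raises(InvalidArgumentError):
            resonance_measures(prof)


class TestTotalInductivePhase:
    def test_nonpositive_phase_gives_zero(self):
        f = np.linspace(0.5, 15.0, 200)
        prof = ImpedanceProfile(freqs=f, magnitude=np.ones_like(f),
                                phase=-np.abs(np.sin(f)))
        assert total_inductive_phase(prof) == 0.0

    def test_triangular_lobe_area_matches_trapezoid_oracle(self):
        f = np.linspace(0.5, 15.0, 2000)
        phase = np.zeros_like(f)
        lobe = (f >= 2.0) & (f <= 6.0)
        phase[lobe] = 0.02 * (1 - np.abs(f[lobe] - 4.0) / 2.0)  # triangle, peak 0.02
        prof = ImpedanceProfile(freqs=f, magnitude=np.ones_like(f), phase=phase)
        assert total_inductive_phase(prof) == pytest.approx(0.04, rel=1e-3)

    def test_sub_tolerance_excursions_are_zeroed(self):
        f = np.linspace(0.5, 15.0, 500)
        phase = np.zeros_like(f)
        phase[(f > 2) & (f < 3)] = 0.003   # below tolerance
        phase[(f > 8) & (f < 9)] = 0.02    # genuine lobe
        prof = ImpedanceProfile(freqs=f, magnitude=np.ones_like(f), phase=phase)
        full = total_inductive_phase(prof, phase_tol=0.0)
        cleaned = total_inductive_phase(prof, phase_tol=0.005)
        assert cleaned < full
        assert cleaned == pytest.approx(0.02 * 1.0, rel=0.05)

    def test_slow_hcn_cell_has_zero_inductive_phase_at_all_holdings(self, hcn_cell, chirp_stim):
        for target in (-80.0, -75.0, -70.0, -65.0, -60.0):
            bias = hold_at_voltage(hcn_cell, target)
            tr = simulate_subthreshold(hcn_cell, chirp_stim, bias=bias)
            prof = impedance_profile(tr)
            assert total_inductive_phase(prof, phase_tol=0.005) == 0.0


class TestCrossEstimatorConsistency:
    def test_three_dc_gain_estimators_agree_for_passive_cell(self, passive_cell, passive_chirp_trace):
        steps = [(a, simulate_subthreshold(passive_cell, make_pulse(a))) for a in
                 np.arange(-50.0, 51.0, 25.0)]
        r_in = input_resistance_fit(steps).value
        tr = simulate_subthreshold(passive_cell, make_chirp())
        r_bar = pulse_input_resistance(tr).value
        z_max = resonance_measures(impedance_profile(passive_chirp_trace)).Z_max
        assert r_bar == pytest.approx(r_in, rel=0.1)
        assert z_max == pytest.approx(r_in, rel=0.1)

    def test_measurements_stable_under_step_halving(self, hcn_cell, chirp_stim):
        vals = []
        for sub in (2, 4):
            steps = [(a, simulate_subthreshold(hcn_cell, make_pulse(a), substeps=sub))
                     for a in (-50.0, 0.0, 50.0)]
            r_in = input_resistance_fit(steps).value
            tr = simulate_subthreshold(hcn_cell, chirp_stim, substeps=sub)
            f_r = resonance_measures(impedance_profile(tr)).f_R
            vals.append((r_in, f_r))
        assert vals[0][0] == pytest.approx(vals[1][0], rel=0.005)
        assert vals[0][1] == pytest.approx(vals[1][1], rel=0.005)
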