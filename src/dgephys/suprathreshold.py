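"""Spike detection, f–I characterization, and AP waveform metrics.

Firing rates are computed from 700-ms pulse responses and extrapolated to
1 s (rate = count × 1000/700). AP waveform features are taken on the first
action potential of the 250-pA response: threshold by the 20 V/s dV/dt
criterion, peak voltage, amplitude relative to V_RMP, half-width at the
half-maximal level referenced to V_RMP, dV/dt extrema, latency to first
spike, and first interspike interval. Excitability class follows the Hodgkin
scheme: class I cells sustain arbitrarily low rates just above rheobase,
class II cells jump discontinuously to a finite rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, ProtocolError
from .traces import VoltageTrace

#: dV/dt threshold-crossing criterion, V/s.
THRESHOLD_DVDT = 20.0
#: A spike peak must exceed this voltage (granule-cell AP peaks are ≈ +47 mV).
PEAK_V_MIN = 0.0
#: The 20 V/s crossing must precede the peak within this window, ms.
CROSSING_WINDOW = 5.0
#: Peaks closer than this are merged (keep the larger), ms.
MERGE_WINDOW = 2.0

#: Class-boundary constants (Hz) for the Hodgkin classification: a class I
#: cell can fire below ``CLASS_I_MAX_RATE`` just above rheobase; a class II
#: cell jumps discontinuously to above ``CLASS_II_MIN_RATE``.
CLASS_I_MAX_RATE = 5.0
CLASS_II_MIN_RATE = 20.0


@dataclass
class FiringProfile:
    """f–I curve of one cell: extrapolated rates (Hz) per pulse amplitude (pA)."""

    amplitudes: np.ndarray
    rates: np.ndarray
    counts: np.ndarray
    rheobase: float = np.nan          # NaN when no tested amplitude fired
    class_label: str = "undetermined"
    flags: list = field(default_factory=list)


@dataclass
class APMeasurements:
    """Waveform-level measurements of the first AP; NaN marks absent values."""

    V_th: float = np.nan
    V_AP_peak: float = np.nan
    V_AP: float = np.nan
    T_APHW: float = np.nan
    dVdt_max: float = np.nan
    dVdt_min: float = np.nan
    T_1AP: float = np.nan
    T_1ISI: float = np.nan
    n_spikes: int = 0


def detect_spikes(trace: VoltageTrace) -> np.ndarray:
    """Spike (peak) times in ms.

    A spike is a local voltage maximum above ``PEAK_V_MIN`` preceded within
    ``CROSSING_WINDOW`` ms by an upward dV/dt crossing of ``THRESHOLD_DVDT``;
    peaks closer than ``MERGE_WINDOW`` ms are merged keeping the larger one.
    An empty array is a valid result for a subthreshold trace.
    """
    v = trace.samples
    dt = trace.sample_interval
    dv = trace.dvdt()
    cand = np.flatnonzero((v[1:-1] > PEAK_V_MIN) & (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])) + 1
    if len(cand) == 0:
        return np.empty(0)
    up = np.flatnonzero((dv[:-1] < THRESHOLD_DVDT) & (dv[1:] >= THRESHOLD_DVDT))
    w = int(round(CROSSING_WINDOW / dt))
    peaks = [i for i in cand if np.any((up >= i - w) & (up < i))]
    merged: list[int] = []
    for i in peaks:
        if merged and (i - merged[-1]) * dt < MERGE_WINDOW:
            if v[i] > v[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return np.asarray(merged, dtype=float) * dt


def firing_rate(trace: VoltageTrace) -> float:
    """Firing rate (Hz) extrapolated to 1 s from the pulse epoch spike count."""
    if "pulse" not in trace.stimulus.epochs:
        raise ProtocolError("firing_rate requires an annotated pulse epoch")
    t0, t1 = trace.stimulus.epochs["pulse"]
    spikes = detect_spikes(trace)
    count = int(np.sum((spikes >= t0) & (spikes < t1)))
    return count * 1000.0 / (t1 - t0)


def fi_curve(steps: Sequence[tuple[float, VoltageTrace]]) -> FiringProfile:
    """Firing profile over a family of pulse amplitudes (default 0–250 pA, step 50).

    Rheobase is the smallest tested amplitude eliciting at least one spike
    (NaN, flagged, when none does). The class label is assigned from the
    profile alone; see :func:`classify_excitability` for the refined,
    simulation-based call.
    """
    if len(steps) < 2:
        raise InvalidArgumentError("fi_curve needs >= 2 amplitudes")
    order = np.argsort([a for a, _ in steps])
    amps, rates, counts = [], [], []
    for k in order:
        amp, trace = steps[k]
        t0, t1 = trace.stimulus.epochs["pulse"]
        spikes = detect_spikes(trace)
        n = int(np.sum((spikes >= t0) & (spikes < t1)))
        amps.append(amp)
        counts.append(n)
        rates.append(n * 1000.0 / (t1 - t0))
    amps = np.asarray(amps, dtype=float)
    rates = np.asarray(rates)
    counts = np.asarray(counts)
    fired = np.flatnonzero(counts > 0)
    profile = FiringProfile(amplitudes=amps, rates=rates, counts=counts)
    if len(fired) == 0:
        profile.flags.append("RHEOBASE_UNDEFINED")
        return profile
    profile.rheobase = float(amps[fired[0]])
    profile.class_label = _label_from_rate(rates[fired[0]])
    return profile


def _label_from_rate(rate_at_threshold: float) -> str:
    if rate_at_threshold < CLASS_I_MAX_RATE:
        return "I"
    if rate_at_threshold > CLASS_II_MIN_RATE:
        return "II"
    return "undetermined"


def classify_excitability(
    profile: FiringProfile,
    cell=None,
    resolution: float = 5.0,
    test_duration: float = 2000.0,
) -> str:
    """Hodgkin excitability class ("I" | "II" | "undetermined") of a firing profile.

    Without a cell, the label comes from the rate at the tested rheobase
    amplitude. Given the generating :class:`~dgephys.neuron.MembraneParams`,
    the rheobase is refined by bisection (``resolution`` pA) with long
    ``test_duration`` pulses and the label uses the minimum sustained rate
    just above threshold — class I if it is below ``CLASS_I_MAX_RATE``,
    class II if the rate jumps above ``CLASS_II_MIN_RATE``.
    """
    if np.isnan(profile.rheobase):
        return "undetermined"
    if cell is None:
        return _label_from_rate(profile.rates[profile.amplitudes == profile.rheobase][0])
    from .neuron import simulate_spiking
    from .stimuli import make_pulse

    def count_at(amp: float) -> int:
        stim = make_pulse(amp, duration=test_duration)
        tr = simulate_spiking(cell, stim)
        t0, t1 = stim.epochs["pulse"]
        s = tr.metadata["true_spike_times"]
        return int(np.sum((s >= t0) & (s < t1)))

    lo = profile.rheobase - 50.0
    hi = profile.rheobase
    if count_at(lo) > 0:
        lo, hi = lo - 100.0, lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if count_at(mid) > 0:
            hi = mid
        else:
            lo = mid
    rate = count_at(hi) * 1000.0 / test_duration
    return _label_from_rate(rate)


def ap_features(trace: VoltageTrace, v_rmp: float | None = None) -> APMeasurements:
    """Waveform measurements on the first AP of a suprathreshold pulse response.

    Returns an :class:`APMeasurements` with NaN entries when no spike exists
    (and NaN ``T_1ISI`` with a single spike); features are computed only from
    samples around the first AP, so the result is independent of later
    activity. ``v_rmp`` defaults to the trace's own pre-stimulus baseline.
    """
    dt = trace.sample_interval
    v = trace.samples
    dv = trace.dvdt()
    if v_rmp is None:
        v_rmp = trace.v_rmp
    t0 = trace.stimulus.epochs["pulse"][0] if "pulse" in trace.stimulus.epochs else 0.0
    spikes = detect_spikes(trace)
    out = APMeasurements(n_spikes=len(spikes))
    if len(spikes) == 0:
        return out
    ip = int(round(spikes[0] / dt))
    # refine to the exact sample-level maximum near the detected peak
    lo = max(ip - 3, 0)
    ip = lo + int(np.argmax(v[lo:ip + 4]))
    out.V_AP_peak = float(v[ip])
    out.V_AP = out.V_AP_peak - v_rmp

    w = int(round(CROSSING_WINDOW / dt))
    seg = slice(max(ip - w, 0), ip)
    up = np.flatnonzero((dv[seg][:-1] < THRESHOLD_DVDT) & (dv[seg][1:] >= THRESHOLD_DVDT))
    if len(up):
        j = seg.start + up[-1]
        frac = (THRESHOLD_DVDT - dv[j]) / (dv[j + 1] - dv[j])
        out.V_th = float(v[j] + frac * (v[j + 1] - v[j]))
        t_threshold = (j + frac) * dt
        out.T_1AP = t_threshold - t0
    # dV/dt extrema over the first AP (stop before the next spike)
    stop = ip + w
    if len(spikes) > 1:
        stop = min(stop, int(round(spikes[1] / dt)) - w)
    ap = slice(max(ip - w, 0), min(stop, len(v)))
    out.dVdt_max = float(np.max(dv[ap]))
    out.dVdt_min = float(np.min(dv[ap]))
    # full width at half of V_AP above V_RMP, crossings linearly interpolated
    half = v_rmp + out.V_AP / 2.0
    i = ip
    while i > ap.start and v[i - 1] > half:
        i -= 1
    left = (i - 1 + (half - v[i - 1]) / (v[i] - v[i - 1])) * dt if i > ap.start else np.nan
    k = ip
    while k < ap.stop - 1 and v[k + 1] > half:
        k += 1
    right = (k + (half - v[k]) / (v[k + 1] - v[k])) * dt if k < ap.stop - 1 else np.nan
    out.T_APHW = right - left
    if len(spikes) > 1:
        out.T_1ISI = float(spikes[1] - spikes[0])
    return out
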