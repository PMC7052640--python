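"""Subthreshold measurements: R_in, S_alpha, sag, and chirp impedance metrics.

The eight measurements characterize steady-state and frequency-dependent
subthreshold excitability of a cell at one holding voltage:

* ``input_resistance_fit`` — R_in as the slope of the steady-state V–I plot
  over a family of pulse amplitudes;
* ``pulse_input_resistance`` — R̄_in from the single −100 pA pulse preceding
  the chirp;
* ``sag_percentage`` — 100·(1 − V_ss/V_peak) from the same pulse;
* ``summation_ratio`` — S_alpha = E_last/E_first over the 5-event α-EPSP train;
* ``impedance_profile`` — Z(f) as the FFT ratio of voltage response to chirp
  current (ZAP magnitude, ZPP phase);
* ``resonance_measures`` — f_R, |Z|_max, and Q = |Z|_max / |Z|(0.5 Hz);
* ``total_inductive_phase`` — Φ_L, the area under the positive part of the ZPP.

A low-pass cell has f_R at the bottom of the band, Q ≈ 1, and Φ_L = 0;
a resonating cell has an interior impedance peak (Q > 1) and may show an
inductive (positive) phase lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ContaminatedProtocolError, InsufficientDataError, InvalidArgumentError, ProtocolError
from .traces import VoltageTrace

#: Steady-state window: last part of a pulse over which the deflection is averaged (ms).
STEADY_STATE_WINDOW = 200.0
#: Analysis band for impedance-derived measures (Hz).
DEFAULT_BAND = (0.5, 15.0)
#: Deflections smaller than this (mV) set the ``unreliable`` flag.
NOISE_FLOOR_MV = 0.5
#: Spike-contamination criterion: dV/dt above this (V/s) at V above ``SPIKE_V_MIN``.
SPIKE_DVDT = 20.0
SPIKE_V_MIN = -20.0


@dataclass
class ImpedanceProfile:
    """Impedance magnitude (MΩ) and phase (rad) on a strictly increasing frequency grid."""

    freqs: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray
    f_band: tuple = DEFAULT_BAND

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if not (len(self.freqs) == len(self.magnitude) == len(self.phase)):
            raise InvalidArgumentError("freqs, magnitude, phase must have equal length")
        if len(self.freqs) and np.any(np.diff(self.freqs) <= 0):
            raise InvalidArgumentError("freqs must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise InvalidArgumentError("impedance magnitude must be non-negative")

    def band_mask(self) -> np.ndarray:
        lo, hi = self.f_band
        return (self.freqs >= lo) & (self.freqs <= hi)


class FitResult(NamedTuple):
    value: float
    r_squared: float
    flags: tuple = ()


class ResonanceResult(NamedTuple):
    f_R: float
    Q: float
    Z_max: float


@dataclass
class SubthresholdMeasurements:
    """The eight subthreshold measurements of one cell at one holding voltage."""

    V_RMP: float = np.nan
    R_in: float = np.nan
    S_alpha: float = np.nan
    R_in_bar: float = np.nan
    sag: float = np.nan
    f_R: float = np.nan
    Z_max: float = np.nan
    Q: float = np.nan
    Phi_L: float = np.nan
    V_hold: float = np.nan
    r_squared: float = np.nan
    flags: list = field(default_factory=list)


def _check_not_contaminated(trace: VoltageTrace, sl: slice, amplitude=None):
    v = trace.samples[sl]
    dv = np.gradient(v, trace.sample_interval)
    if np.any((dv > SPIKE_DVDT) & (v > SPIKE_V_MIN)):
        where = f" at amplitude {amplitude} pA" if amplitude is not None else ""
        raise ContaminatedProtocolError(
            f"spike detected within a nominally subthreshold epoch{where}", amplitude
        )


def _steady_deflection(trace: VoltageTrace, epoch: str, window: float = STEADY_STATE_WINDOW) -> float:
    """Mean deflection from V_RMP over the last ``window`` ms of the epoch (mV)."""
    t0, t1 = trace.stimulus.epochs[epoch]
    dt = trace.sample_interval
    sl = slice(int(round(max(t0, t1 - window) / dt)), int(round(t1 / dt)))
    return float(np.mean(trace.samples[sl])) - trace.v_rmp


def input_resistance_fit(steps: Sequence[tuple[float, VoltageTrace]]) -> FitResult:
    """Input resistance (MΩ) as the least-squares slope of the steady-state V–I plot.

    ``steps`` pairs each pulse amplitude (pA) with its voltage response; at
    least three distinct amplitudes are required and every trace must be
    spike-free. The deflection for each amplitude is the mean over the
    steady-state window minus that trace's own V_RMP.
    """
    if len({amp for amp, _ in steps}) < 3:
        raise InsufficientDataError("input_resistance_fit needs >= 3 distinct amplitudes")
    amps, dvs = [], []
    for amp, trace in steps:
        _check_not_contaminated(trace, trace.epoch_slice("pulse"), amplitude=amp)
        amps.append(amp)
        dvs.append(_steady_deflection(trace, "pulse"))
    amps = np.asarray(amps)
    dvs = np.asarray(dvs)
    slope, intercept = np.polyfit(amps, dvs, 1)
    pred = slope * amps + intercept
    ss_res = float(np.sum((dvs - pred) ** 2))
    ss_tot = float(np.sum((dvs - np.mean(dvs)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(value=slope * 1000.0, r_squared=r2)  # mV/pA -> MΩ


def pulse_input_resistance(trace: VoltageTrace, amplitude: float | None = None) -> FitResult:
    """R̄_in (MΩ) from the single pulse preceding the chirp: |ΔV_ss| / |I|.

    With a 500-ms pulse and a slow HCN conductance the steady window samples a
    partially settled response, so R̄_in is expected to sit below the 700-ms
    slope-fit R_in — as in recorded granule cells.
    """
    epoch = "prepulse" if "prepulse" in trace.stimulus.epochs else "pulse"
    if epoch not in trace.stimulus.epochs:
        raise ProtocolError("trace has no annotated pulse epoch for R̄_in")
    if amplitude is None:
        amplitude = trace.stimulus.params.get(
            "prepulse_amplitude", trace.stimulus.params.get("amplitude")
        )
    if not amplitude:
        raise InvalidArgumentError("pulse amplitude must be non-zero")
    dv = _steady_deflection(trace, epoch, window=100.0)
    flags = ("LOW_DEFLECTION",) if abs(dv) < NOISE_FLOOR_MV else ()
    return FitResult(value=abs(dv) / abs(amplitude) * 1000.0, r_squared=np.nan, flags=flags)


def sag_percentage(trace: VoltageTrace) -> FitResult:
    """Percentage sag, 100·(1 − V_ss/V_peak), from the hyperpolarizing pulse.

    ``V_peak`` is the extremal deflection from V_RMP within the pulse and
    ``V_ss`` the steady-state deflection. A pure RC response approaches its
    steady state monotonically and has 0% sag; an activating hyperpolarization-
    gated conductance produces a rebound (positive sag). Negative values
    (creep) are reported as computed. Deflections below the noise floor set
    the ``UNRELIABLE`` flag but the value is still returned.
    """
    epoch = "prepulse" if "prepulse" in trace.stimulus.epochs else "pulse"
    if epoch not in trace.stimulus.epochs:
        raise ProtocolError("trace has no annotated hyperpolarizing pulse epoch")
    sl = trace.epoch_slice(epoch)
    defl = trace.samples[sl] - trace.v_rmp
    v_ss = _steady_deflection(trace, epoch, window=100.0)
    i_ext = np.argmax(np.abs(defl))
    v_peak = float(defl[i_ext])
    flags = ("UNRELIABLE",) if abs(v_peak) < NOISE_FLOOR_MV else ()
    if v_peak == 0.0:
        return FitResult(value=np.nan, r_squared=np.nan, flags=("UNRELIABLE",))
    return FitResult(value=100.0 * (1.0 - v_ss / v_peak), r_squared=np.nan, flags=flags)


def summation_ratio(trace: VoltageTrace, onsets: Sequence[float] | None = None) -> FitResult:
    """Temporal summation ratio S_alpha = E_last / E_first over the α-EPSP train.

    Both amplitudes are peak deflections from the common pre-train baseline:
    E_first within the first inter-onset window, E_last within one interval
    after the last onset. With an inter-event interval much longer than the
    membrane time constant S_alpha → 1; shorter intervals leave residual
    depolarization and S_alpha > 1.
    """
    if onsets is None:
        onsets = trace.stimulus.params.get("onsets")
    if onsets is None or len(onsets) < 2:
        raise ProtocolError("summation_ratio needs >= 2 annotated event onsets")
    dt = trace.sample_interval
    interval = onsets[1] - onsets[0]
    sl_train = slice(int(round(onsets[0] / dt)), int(round((onsets[-1] + interval) / dt)))
    _check_not_contaminated(trace, sl_train)
    # baseline over 50 ms immediately before the first onset
    sl_base = slice(int(round((onsets[0] - 50.0) / dt)), int(round(onsets[0] / dt)))
    base = float(np.mean(trace.samples[sl_base]))

    def peak(t0):
        sl = slice(int(round(t0 / dt)), min(int(round((t0 + interval) / dt)), len(trace.samples)))
        return float(np.max(trace.samples[sl])) - base

    e_first = peak(onsets[0])
    e_last = peak(onsets[-1])
    flags = ("UNRELIABLE",) if abs(e_first) < NOISE_FLOOR_MV else ()
    return FitResult(value=e_last / e_first, r_squared=np.nan, flags=flags)


def impedance_profile(
    response: VoltageTrace,
    chirp=None,
    f_band: tuple = DEFAULT_BAND,
    smooth_bins: int = 0,
    tail_ms: float = 200.0,
) -> ImpedanceProfile:
    """Impedance profile Z(f) = F[V − mean(V)] / F[I − mean(I)] on the chirp epoch.

    The raw FFT ratio is used (no taper, no smoothing by default); frequency
    resolution is ~1/T for a T-second sweep, so the grid starts near 1/15 Hz
    for Chirp15. Up to ``tail_ms`` of post-chirp samples (zero current) are
    appended to the window so the membrane's response to the final cycles is
    fully contained — without the tail, truncation leaks a percent-level bias
    into the high-frequency end of the profile. The returned grid covers
    (0, f_band[1]]; the profile's ``f_band`` marks the analysis band used by
    the derived measures. ``smooth_bins`` optionally applies a centered moving
    average for noisy recordings.
    """
    if chirp is None:
        chirp = response.stimulus
    if "chirp" not in chirp.epochs:
        raise ProtocolError("stimulus has no annotated chirp epoch")
    sl = chirp.epoch_slice("chirp")
    stop = min(sl.stop + int(round(tail_ms / response.sample_interval)), len(response.samples))
    sl = slice(sl.start, stop)
    _check_not_contaminated(response, sl)
    v = response.samples[sl]
    i = chirp.samples[sl]
    v = v - np.mean(v)
    i = i - np.mean(i)
    dt_s = response.sample_interval / 1000.0
    Z = np.fft.rfft(v) / np.fft.rfft(i)
    freqs = np.fft.rfftfreq(len(v), dt_s)
    keep = (freqs > 0) & (freqs <= f_band[1] + 1e-12)
    mag = np.abs(Z[keep]) * 1000.0  # mV/pA == GΩ -> MΩ
    phase = np.unwrap(np.angle(Z)[keep])
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        mag = np.convolve(mag, kern, mode="same")
        phase = np.convolve(phase, kern, mode="same")
    return ImpedanceProfile(freqs=freqs[keep], magnitude=mag, phase=phase, f_band=f_band)


def resonance_measures(profile: ImpedanceProfile) -> ResonanceResult:
    """Resonance frequency f_R, strength Q, and |Z|_max from an impedance profile.

    |Z|_max is the maximum magnitude over the searchable band (the full
    positive-frequency grid up to the band top; the DC bin is never present),
    f_R its frequency (lowest on ties), and Q = |Z|_max divided by the
    magnitude linearly interpolated at 0.5 Hz. A strictly decreasing (low-pass)
    profile has f_R at the bottom of the grid and Q ≈ 1.
    """
    if len(profile.freqs) == 0:
        raise InvalidArgumentError("empty impedance profile")
    hi = profile.f_band[1]
    mask = profile.freqs <= hi + 1e-12
    if not np.any(mask):
        raise InvalidArgumentError("analysis band contains no frequency bins")
    f = profile.freqs[mask]
    m = profile.magnitude[mask]
    i_max = int(np.argmax(m))  # np.argmax returns the first (lowest-f) maximum
    z_max = float(m[i_max])
    z_ref = float(np.interp(0.5, f, m))
    return ResonanceResult(f_R=float(f[i_max]), Q=z_max / z_ref, Z_max=z_max)


def total_inductive_phase(profile: ImpedanceProfile, phase_tol: float = 0.0) -> float:
    """Total inductive phase Φ_L (rad·Hz): area under the positive part of the ZPP.

    The trapezoidal integral of max(phase, 0) is taken over the analysis band.
    Contiguous positive excursions whose peak stays below ``phase_tol`` (rad)
    are treated as estimation noise and zeroed first; the default of 0 keeps
    every positive sample, appropriate for noiseless synthetic data.
    """
    mask = profile.band_mask()
    f = profile.freqs[mask]
    ph = profile.phase[mask].copy()
    if len(f) < 2:
        return 0.0
    pos = ph > 0
    if phase_tol > 0 and np.any(pos):
        # zero sub-tolerance excursions, one contiguous run at a time
        idx = np.flatnonzero(np.diff(np.concatenate(([False], pos, [False])).astype(int)))
        for start, stop in zip(idx[::2], idx[1::2]):
            if np.max(ph[start:stop]) < phase_tol:
                ph[start:stop] = 0.0
    return float(np.trapezoid(np.maximum(ph, 0.0), f))
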