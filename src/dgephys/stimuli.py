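"""Current-injection protocols used to characterize granule cells.

Three stimulus families cover the whole characterization battery:

* rectangular **pulses** (V–I input resistance, sag, f–I curves),
* trains of **alpha-current** events mimicking EPSCs (temporal summation),
* the **Chirp15** stimulus — a constant-amplitude sinusoid whose frequency
  sweeps linearly 0→15 Hz over 15 s — for impedance (ZAP/ZPP) profiling,
  preceded by a −100 pA pulse used as a single-pulse input-resistance check.

All generators are deterministic and return :class:`StimulusWaveform` objects
whose ``epochs`` dictionary annotates the analysis windows in milliseconds.
Currents are in pA, times in ms unless a parameter is explicitly in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Default digitization step, ms (20 kHz).
DEFAULT_SAMPLE_INTERVAL = 0.05

#: Default chirp amplitude, pA (constant-amplitude sinusoid below threshold).
DEFAULT_CHIRP_AMPLITUDE = 30.0


@dataclass
class StimulusWaveform:
    """A sampled current-command waveform.

    Parameters
    ----------
    samples : ndarray
        Injected current, pA.
    sample_interval : float
        Digitization step, ms.
    kind : str
        ``"pulse"``, ``"alpha_train"`` or ``"chirp"``.
    params : dict
        The generating parameter set (protocol metadata).
    epochs : dict
        Named analysis windows ``{name: (start_ms, end_ms)}``.
    """

    samples: np.ndarray
    sample_interval: float
    kind: str
    params: dict = field(default_factory=dict)
    epochs: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Total duration, ms."""
        return self.n_samples * self.sample_interval

    @property
    def t_start_of_interest(self) -> float:
        """Onset of the primary analysis epoch, ms."""
        name = {"pulse": "pulse", "alpha_train": "train", "chirp": "chirp"}[self.kind]
        return self.epochs[name][0]

    def time(self) -> np.ndarray:
        """Sample times, ms (sample k sits at k*dt)."""
        return np.arange(self.n_samples) * self.sample_interval

    def epoch_slice(self, name: str) -> slice:
        """Index slice covering the named epoch."""
        t0, t1 = self.epochs[name]
        dt = self.sample_interval
        return slice(int(round(t0 / dt)), int(round(t1 / dt)))


def _n(duration_ms: float, dt: float) -> int:
    return int(round(duration_ms / dt))


def make_pulse(
    amplitude: float,
    duration: float = 700.0,
    pre: float = 200.0,
    post: float = 300.0,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> StimulusWaveform:
    """Rectangular current pulse: zero outside ``[pre, pre+duration)``.

    The 700-ms default matches the V–I and f–I protocols (pulse amplitudes
    −50…+50 pA in 10-pA steps for input resistance; 0…250 pA in 50-pA steps
    for firing profiles).
    """
    if duration <= 0 or sample_interval <= 0:
        raise InvalidArgumentError("duration and sample_interval must be > 0")
    if pre < 0 or post < 0:
        raise InvalidArgumentError("pre/post padding must be >= 0")
    dt = sample_interval
    n = _n(pre + duration + post, dt)
    samples = np.zeros(n)
    samples[_n(pre, dt):_n(pre + duration, dt)] = amplitude
    return StimulusWaveform(
        samples=samples,
        sample_interval=dt,
        kind="pulse",
        params={"amplitude": amplitude, "duration": duration, "pre": pre, "post": post},
        epochs={"baseline": (0.0, pre), "pulse": (pre, pre + duration)},
    )


def alpha_kernel(t_ms: np.ndarray, i_max: float, alpha: float) -> np.ndarray:
    """EPSC-like alpha current ``I_max * t * exp(-alpha*t)`` for t >= 0 (pA).

    Peak value is ``I_max / (alpha * e)`` at ``t = 1/alpha``.
    """
    t = np.asarray(t_ms, dtype=float)
    out = i_max * t * np.exp(-alpha * t)
    return np.where(t >= 0.0, out, 0.0)


def make_alpha_train(
    i_max: float = 25.0,
    alpha: float = 0.1,
    n_events: int = 5,
    interval: float = 50.0,
    pre: float = 200.0,
    post: float = 300.0,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> StimulusWaveform:
    """Superposed train of alpha-current events (temporal-summation protocol).

    Defaults give the five α-EPSC events at 50-ms intervals (20 Hz) with
    ``alpha = 0.1 ms⁻¹``. Event onsets are spaced ``interval`` apart; kernels
    from successive events sum where they overlap.
    """
    if i_max <= 0 or alpha <= 0 or interval <= 0:
        raise InvalidArgumentError("i_max, alpha, and interval must be > 0")
    if n_events < 1:
        raise InvalidArgumentError("n_events must be >= 1")
    if sample_interval <= 0:
        raise InvalidArgumentError("sample_interval must be > 0")
    dt = sample_interval
    total = pre + (n_events - 1) * interval + post
    t = np.arange(_n(total, dt)) * dt
    onsets = [pre + k * interval for k in range(n_events)]
    samples = np.zeros_like(t)
    for t_k in onsets:
        samples += alpha_kernel(t - t_k, i_max, alpha)
    return StimulusWaveform(
        samples=samples,
        sample_interval=dt,
        kind="alpha_train",
        params={
            "i_max": i_max,
            "alpha": alpha,
            "n_events": n_events,
            "interval": interval,
            "onsets": onsets,
        },
        epochs={"baseline": (0.0, pre), "train": (pre, total)},
    )


def make_chirp(
    amplitude: float = DEFAULT_CHIRP_AMPLITUDE,
    f_start: float = 0.0,
    f_end: float = 15.0,
    duration: float = 15.0,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    prepulse_amplitude: float = -100.0,
    prepulse_duration: float = 500.0,
    prepulse_gap: float = 500.0,
    baseline: float = 200.0,
    post: float = 300.0,
) -> StimulusWaveform:
    """Chirp15 protocol: −100 pA pulse, recovery gap, then a linear chirp.

    The chirp phase is analytic, ``phi(t) = 2*pi*(f_start*t +
    (f_end-f_start)*t^2/(2*T))`` with ``t`` and ``T = duration`` in seconds,
    so the instantaneous frequency rises linearly from ``f_start`` to
    ``f_end``. The hyperpolarizing pre-pulse provides the single-pulse input
    resistance (R̄_in) and sag measurements. Set ``prepulse_duration=0`` to
    omit the pulse epoch.

    Parameters ``f_start``/``f_end`` are in Hz and ``duration`` in seconds;
    all other times are in ms.
    """
    if duration <= 0 or sample_interval <= 0:
        raise InvalidArgumentError("duration and sample_interval must be > 0")
    if f_end <= f_start or f_start < 0:
        raise InvalidArgumentError("need f_end > f_start >= 0")
    dt = sample_interval
    chirp_ms = duration * 1000.0
    if prepulse_duration > 0:
        t_pulse0, t_pulse1 = baseline, baseline + prepulse_duration
        t_chirp0 = t_pulse1 + prepulse_gap
    else:
        t_pulse0 = t_pulse1 = baseline
        t_chirp0 = baseline
    t_chirp1 = t_chirp0 + chirp_ms
    total = t_chirp1 + post
    t = np.arange(_n(total, dt)) * dt
    samples = np.zeros_like(t)
    if prepulse_duration > 0:
        samples[_n(t_pulse0, dt):_n(t_pulse1, dt)] = prepulse_amplitude
    sl = slice(_n(t_chirp0, dt), _n(t_chirp1, dt))
    ts = (t[sl] - t_chirp0) / 1000.0  # s from chirp onset
    phase = 2.0 * np.pi * (f_start * ts + (f_end - f_start) * ts**2 / (2.0 * duration))
    samples[sl] = amplitude * np.sin(phase)
    epochs = {"baseline": (0.0, baseline), "chirp": (t_chirp0, t_chirp1)}
    if prepulse_duration > 0:
        epochs["prepulse"] = (t_pulse0, t_pulse1)
        epochs["gap"] = (t_pulse1, t_chirp0)
    if post > 0:
        epochs["post"] = (t_chirp1, total)
    return StimulusWaveform(
        samples=samples,
        sample_interval=dt,
        kind="chirp",
        params={
            "amplitude": amplitude,
            "f_start": f_start,
            "f_end": f_end,
            "duration": duration,
            "prepulse_amplitude": prepulse_amplitude,
            "prepulse_duration": prepulse_duration,
        },
        epochs=epochs,
    )


def instantaneous_frequency(chirp: StimulusWaveform, t: float) -> float:
    """Analytic instantaneous frequency of a chirp at time ``t`` (s from sweep onset).

    For a linear sweep this is ``f_start + (f_end - f_start) * t / T`` — e.g.
    exactly 15 Hz at the end of the default 15-s sweep.
    """
    if chirp.kind != "chirp":
        raise InvalidArgumentError("instantaneous_frequency requires a chirp waveform")
    T = chirp.params["duration"]
    if not (0.0 <= t <= T):
        raise InvalidArgumentError(f"t={t} s outside the sweep [0, {T}] s")
    f0, f1 = chirp.params["f_start"], chirp.params["f_end"]
    return f0 + (f1 - f0) * t / T
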