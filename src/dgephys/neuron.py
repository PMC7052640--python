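"""Conductance-based single-compartment granule-cell model.

The membrane carries a leak conductance and a slow HCN-like (h) conductance:

    C dV/dt = −g_L (V − E_L) − g_h s (V − E_h) + I_inj(t) + ξ(t)
    ds/dt   = (s_∞(V) − s) / τ_h,   s_∞(V) = 1 / (1 + exp((V − V_half)/k))

with activation increasing under hyperpolarization (k > 0). Granule-cell HCN
kinetics are very slow (τ_h ≈ 500 ms), which is why these cells show no
membrane resonance: the resonant admittance term rolls off below the
frequency at which the membrane capacitance takes over, leaving a low-pass
impedance profile with Q ≈ 1 and no inductive phase lead. Speeding the same
conductance up (τ_h ≈ 50 ms, steeper activation) converts the profile to the
band-pass shape familiar from CA1 pyramidal and entorhinal stellate cells.

Spiking uses an exponential spike-initiation term plus a stereotyped AP
waveform template pasted at each spike (for waveform-level feature
extraction), and a spike-triggered adaptation current (increment ``adapt_b``,
decay ``adapt_tau``) that slows repetitive firing to the observed granule-cell
f–I scale while preserving class I excitability: without it, an
exponential-integrate-and-fire cell with R_in ≈ 170 MΩ and rheobase ≈ 90 pA
would fire several-fold faster at 250 pA than granule cells do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import _core
from .errors import IntegrationError, InvalidArgumentError
from .stimuli import StimulusWaveform
from .subthreshold import ImpedanceProfile
from .traces import VoltageTrace

#: integration substeps per 0.05-ms output sample (fine step 0.025 ms)
DEFAULT_SUBSTEPS = 2


@dataclass(frozen=True)
class APTemplate:
    """Stereotyped action-potential waveform pasted at each spike.

    Piecewise-analytic in time, three segments joined C¹-smoothly:

    * an *upstroke foot* on which the slope grows exponentially with voltage,
      dV/dt = d0·exp((V − V_start)/κ), with κ chosen so that the slope passes
      20 V/s exactly at the designed threshold ``V_th`` — the 20 V/s AP
      threshold criterion therefore recovers ``V_th`` by construction, and
      the crossing sits strictly inside a smooth monotone-slope segment
      (robust to the digitization rate). The foot ends where the slope
      reaches ``dvdt_max``;
    * a quarter-sine *shoulder* decelerating from ``dvdt_max`` to the peak
      ``V_peak``;
    * a raised-cosine *downstroke* from ``V_peak`` to the fast
      afterhyperpolarization ``V_ahp`` with minimum slope ``dvdt_min`` (V/s).
    """

    V_start: float = -50.0
    V_th: float = -38.5
    V_peak: float = 47.0
    V_ahp: float = -62.0
    d0: float = 8.0          # V/s, slope at the paste point
    dvdt_max: float = 450.0  # V/s
    dvdt_min: float = -120.0  # V/s

    def __post_init__(self):
        if not (self.V_start < self.V_th < 0.0 < self.V_peak):
            raise InvalidArgumentError("need V_start < V_th < 0 < V_peak")
        if self.V_ahp >= self.V_th:
            raise InvalidArgumentError("V_ahp must sit below V_th")
        if not (0.0 < self.d0 < 20.0) or self.dvdt_max <= 20.0 or self.dvdt_min >= 0.0:
            raise InvalidArgumentError("need 0 < d0 < 20 V/s, dvdt_max > 20, dvdt_min < 0")
        if self.v_foot_end >= self.V_peak:
            raise InvalidArgumentError("dvdt_max reached above V_peak; lower kappa/dvdt_max")

    @property
    def kappa(self) -> float:
        """e-fold scale (mV) of the foot slope; fixes the 20 V/s crossing at V_th."""
        return (self.V_th - self.V_start) / math.log(20.0 / self.d0)

    @property
    def v_foot_end(self) -> float:
        """Voltage at which the slope reaches dvdt_max (end of the foot)."""
        return self.V_start + self.kappa * math.log(self.dvdt_max / self.d0)

    @property
    def t_foot(self) -> float:
        return (self.kappa / self.d0) * (1.0 - self.d0 / self.dvdt_max)

    @property
    def t_shoulder(self) -> float:
        return (self.V_peak - self.v_foot_end) * math.pi / (2.0 * self.dvdt_max)

    @property
    def t_fall(self) -> float:
        return (self.V_peak - self.V_ahp) * math.pi / (2.0 * abs(self.dvdt_min))

    @property
    def duration(self) -> float:
        """Total template duration, ms."""
        return self.t_foot + self.t_shoulder + self.t_fall

    @property
    def peak_offset(self) -> float:
        """Paste point to waveform peak, ms."""
        return self.t_foot + self.t_shoulder

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template voltage at times ``t`` (ms from paste)."""
        t = np.asarray(t, dtype=float)
        kap, tf, ts, tfall = self.kappa, self.t_foot, self.t_shoulder, self.t_fall
        v = np.empty_like(t)
        a = t < tf
        # du/dt = -d0/kappa for u = exp(-(V-V_start)/kappa)
        v[a] = self.V_start - kap * np.log(1.0 - self.d0 * t[a] / kap)
        b = (t >= tf) & (t < tf + ts)
        v1 = self.v_foot_end
        v[b] = v1 + (self.V_peak - v1) * np.sin(math.pi * (t[b] - tf) / (2.0 * ts))
        c = t >= tf + ts
        tc = np.minimum(t[c] - tf - ts, tfall)
        v[c] = self.V_peak - (self.V_peak - self.V_ahp) * (1.0 - np.cos(math.pi * tc / tfall)) / 2.0
        return v

    def sample(self, dt: float) -> np.ndarray:
        return self(np.arange(int(round(self.duration / dt))) * dt)


@dataclass(frozen=True)
class SpikeParams:
    """Class-I spike generator: exponential initiation, template paste, adaptation."""

    V_T: float = -59.0       # mV, exponential-initiation threshold voltage
    delta_T: float = 2.0     # mV, initiation sharpness
    refractory: float = 5.0  # ms, no re-initiation from the paste trigger
    adapt_b: float = 80.0    # pA, spike-triggered adaptation increment
    adapt_tau: float = 150.0  # ms, adaptation decay
    template: APTemplate = field(default_factory=APTemplate)

    def __post_init__(self):
        if self.refractory <= 0:
            raise InvalidArgumentError("refractory must be > 0")
        if self.template.duration >= self.refractory:
            raise InvalidArgumentError("AP template must be shorter than the refractory period")
        if self.delta_T <= 0:
            raise InvalidArgumentError("delta_T must be > 0")


@dataclass(frozen=True)
class MembraneParams:
    """Ground-truth biophysical parameters of one synthetic granule cell.

    Defaults give R_in ≈ 165 MΩ, V_RMP ≈ −77 mV, τ_m ≈ 25 ms, and a weak,
    very slow h-conductance — a low-pass, non-resonant cell. With ``g_h = 0``
    the resting potential is ``E_L`` and the input resistance ``1/g_L``.
    """

    C: float = 147.0          # pF
    g_L: float = 1000.0 / 170.0  # nS  (leak resistance 170 MΩ)
    E_L: float = -78.0        # mV
    g_h: float = 0.25         # nS, maximal HCN conductance
    E_h: float = -30.0        # mV
    V_half: float = -82.0     # mV, HCN half-activation
    k_slope: float = 8.0      # mV (activation increases with hyperpolarization)
    tau_h: float = 500.0      # ms, HCN activation time constant
    spike: SpikeParams | None = None

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0 or self.g_h < 0 or self.tau_h <= 0 or self.k_slope <= 0:
            raise InvalidArgumentError("require C>0, g_L>0, g_h>=0, tau_h>0, k_slope>0")

    def s_inf(self, v: float) -> float:
        return 1.0 / (1.0 + np.exp((v - self.V_half) / self.k_slope))

    def ds_inf_dv(self, v: float) -> float:
        s = self.s_inf(v)
        return -s * (1.0 - s) / self.k_slope

    def steady_current(self, v: float) -> float:
        """Injected DC (pA) balancing the ionic currents at voltage ``v``."""
        return self.g_L * (v - self.E_L) + self.g_h * self.s_inf(v) * (v - self.E_h)

    def resting_potential(self, bias: float = 0.0) -> float:
        """Numerically solved resting steady state under a DC bias (mV)."""
        f = lambda v: bias - self.steady_current(v)
        return float(brentq(f, -150.0, 20.0, xtol=1e-10))


def default_granule_cell(spiking: bool = True) -> MembraneParams:
    """The default slow-HCN granule cell (optionally with the spike mechanism)."""
    return MembraneParams(spike=SpikeParams() if spiking else None)


def fast_resonant_cell() -> MembraneParams:
    """Contrast cell: same architecture with fast, strong HCN activation.

    τ_h = 50 ms with a steeper activation curve and a larger g_h — the
    CA1-pyramidal/stellate-like regime, producing a band-pass impedance
    profile (Q > 1.1, interior f_R).
    """
    return MembraneParams(g_h=4.0, k_slope=4.0, tau_h=50.0)


def hold_at_voltage(params: MembraneParams, target_v: float) -> float:
    """DC bias (pA) whose steady state is ``target_v``; 0 at the resting potential."""
    return float(params.steady_current(target_v))


def _run(params, stimulus, noise_sd, seed, bias, has_spike, substeps):
    rng = np.random.default_rng(seed)
    n = stimulus.n_samples
    noise = (
        rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    )
    v0 = params.resting_potential(bias)
    s0 = params.s_inf(v0)
    sp = params.spike
    dtf = stimulus.sample_interval / substeps
    if has_spike:
        tpl = sp.template.sample(dtf)
        v_t, d_t, v_cut = sp.V_T, sp.delta_T, sp.template.V_start
        refr, peak_off = sp.refractory, sp.template.peak_offset
        b, tau_w = sp.adapt_b, sp.adapt_tau
    else:
        tpl = np.zeros(0)
        v_t, d_t, v_cut, refr, peak_off, b, tau_w = 0.0, 1.0, 1e9, 1.0, 0.0, 0.0, 1.0
    v_out, spike_times, nsp = _core.integrate(
        np.ascontiguousarray(stimulus.samples, dtype=np.float64),
        stimulus.sample_interval, substeps,
        params.C, params.g_L, params.E_L,
        params.g_h, params.E_h, params.V_half, params.k_slope, params.tau_h,
        noise, bias,
        has_spike, v_t, d_t, v_cut, refr, tpl, peak_off, b, tau_w,
        v0, s0,
    )
    if nsp == _core.DIVERGED:
        raise IntegrationError("membrane potential diverged (|V| > 200 mV)")
    return v_out, spike_times


def simulate_subthreshold(
    params: MembraneParams,
    stimulus: StimulusWaveform,
    noise_sd: float = 0.0,
    seed: int = 0,
    bias: float = 0.0,
    substeps: int = DEFAULT_SUBSTEPS,
) -> VoltageTrace:
    """Integrate the passive + HCN membrane (no spike mechanism) from its resting state.

    ``noise_sd`` is the SD (pA) of white current noise held constant over each
    output sample; the result is deterministic given ``seed``. ``bias`` is a
    DC holding current added throughout (see :func:`hold_at_voltage`).
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    v, _ = _run(params, stimulus, noise_sd, seed, bias, False, substeps)
    return VoltageTrace(
        samples=v,
        sample_interval=stimulus.sample_interval,
        stimulus=stimulus,
        metadata={"bias_pA": bias, "seed": seed, "noise_sd": noise_sd},
    )


def simulate_spiking(
    params: MembraneParams,
    stimulus: StimulusWaveform,
    seed: int = 0,
    noise_sd: float = 0.0,
    bias: float = 0.0,
    substeps: int = DEFAULT_SUBSTEPS,
) -> VoltageTrace:
    """Integrate with the spike mechanism; ground-truth spike (peak) times go to metadata."""
    if params.spike is None:
        raise InvalidArgumentError("simulate_spiking requires params.spike")
    v, spikes = _run(params, stimulus, noise_sd, seed, bias, True, substeps)
    return VoltageTrace(
        samples=v,
        sample_interval=stimulus.sample_interval,
        stimulus=stimulus,
        metadata={
            "bias_pA": bias,
            "seed": seed,
            "noise_sd": noise_sd,
            "true_spike_times": np.asarray(spikes),
        },
    )


def analytic_impedance(params: MembraneParams, freqs, v_op: float) -> ImpedanceProfile:
    """Closed-form impedance of the model linearized about ``v_op``.

    Small-signal admittance (nS, with f in Hz, C in nF-equivalents):

        Y(ω) = g_L + g_h s_∞ + g_h (V_op − E_h) s_∞'(V_op) / (1 + iωτ_h) + iωC

    For an HCN-like gate (s_∞' < 0, V_op < E_h) the gating term is positive —
    a resonating admittance that suppresses low frequencies and rolls off
    above 1/(2πτ_h). Magnitude is returned in MΩ, phase in rad.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise InvalidArgumentError("freqs must be > 0")
    s = params.s_inf(v_op)
    sp = params.ds_inf_dv(v_op)
    w = 2.0 * np.pi * freqs
    tau_s = params.tau_h / 1000.0
    y = (
        params.g_L
        + params.g_h * s
        + params.g_h * (v_op - params.E_h) * sp / (1.0 + 1j * w * tau_s)
        + 1j * w * (params.C * 1e-3)
    )
    z = 1.0 / y  # 1/nS = GΩ
    return ImpedanceProfile(freqs=freqs, magnitude=np.abs(z) * 1000.0, phase=np.angle(z))


def rheobase_estimate(params: MembraneParams, v_max: float | None = None) -> float:
    """Quasi-static rheobase (pA): the current at which the subthreshold fixed point vanishes.

    Uses the steady-state I–V curve including the exponential initiation term
    with s = s_∞(V) (the slow gate tracks quasi-statically near rheobase);
    the curve is searched up to ``v_max`` (the template paste voltage by
    default), where the initiation takes over.
    """
    sp = params.spike
    if sp is None:
        raise InvalidArgumentError("rheobase requires a spike mechanism")
    if v_max is None:
        v_max = sp.template.V_start
    v = np.linspace(-100.0, v_max, 4000)
    s = 1.0 / (1.0 + np.exp((v - params.V_half) / params.k_slope))
    i_need = (
        params.g_L * (v - params.E_L)
        + params.g_h * s * (v - params.E_h)
        - params.g_L * sp.delta_T * np.exp((v - sp.V_T) / sp.delta_T)
    )
    return float(np.max(i_need))


def threshold_for_rheobase(
    params: MembraneParams, rheobase: float, delta_T: float = 2.0, v_max: float = -45.0
) -> float:
    """Solve the initiation threshold V_T that yields the requested quasi-static rheobase."""
    base = replace(params, spike=None)

    def f(v_t):
        p = replace(base, spike=SpikeParams(V_T=v_t, delta_T=delta_T))
        return rheobase_estimate(p, v_max=v_max) - rheobase

    return float(brentq(f, -90.0, -16.0, xtol=1e-6))
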