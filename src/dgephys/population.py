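"""Heterogeneous per-sector populations of synthetic granule cells.

Each dentate-gyrus sector (suprapyramidal blade, crest, infrapyramidal blade)
is described by target means and SDs of the *measured* quantities — input
resistance, resting potential, firing rate at 250 pA, and the AP waveform
features. Sampling draws per-cell targets from those distributions
(log-normal for resistances/conductance-like quantities, normal for
voltages, truncated by resampling) and then inverts the model: the leak
conductance and reversal are solved so the measured R_in and V_RMP land on
the drawn targets, the spike-initiation threshold is solved for the drawn
rheobase, and the adaptation increment is solved — against the actual
simulator — so the 250-pA firing rate lands on the drawn target.

A latent per-cell excitability factor couples R_in and f_250 draws, giving
the positive correlation between excitability measures seen across real
granule cells; all other targets are drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidSpecError
from .neuron import (
    APTemplate,
    MembraneParams,
    SpikeParams,
    rheobase_estimate,
    simulate_spiking,
    threshold_for_rheobase,
)
from .stimuli import make_pulse

SECTOR_NAMES = ("suprapyramidal", "crest", "infrapyramidal")

#: fraction of the slow HCN admittance settled within the 700-ms steady-state
#: window, used when converting a target R_in into a leak conductance
HCN_SETTLING = 0.75


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidSpecError("target SD must be >= 0")


@dataclass(frozen=True)
class SectorPopulationSpec:
    """Target measurement statistics and sampling settings for one sector."""

    name: str
    n: int
    R_in: Moments            # MΩ (log-normal)
    V_RMP: Moments           # mV (normal)
    f_250: Moments           # Hz (normal, truncated at 0; <1 Hz -> non-spiker)
    rheobase: Moments        # pA (normal, truncated to the feasible range)
    V_th: Moments            # mV (normal)
    V_AP_peak: Moments       # mV (normal)
    dvdt_max: Moments        # V/s (normal)
    dvdt_min: Moments        # V/s (normal)
    rho_excitability: float = 0.5   # latent correlation between R_in and f_250
    tau_m: Moments = Moments(25.0, 3.0)   # ms, membrane time constant
    g_h: Moments = Moments(0.25, 0.075)   # nS (log-normal)
    noise_sd: float = 5.0    # pA, current noise used when simulating this population

    def __post_init__(self):
        if self.n < 0:
            raise InvalidSpecError("n per sector must be >= 0")
        if not -1.0 < self.rho_excitability < 1.0:
            raise InvalidSpecError("rho_excitability must lie in (-1, 1)")
        if self.R_in.mean <= 0 or self.tau_m.mean <= 0:
            raise InvalidSpecError("R_in and tau_m means must be > 0")


def default_population_specs(n: int = 70) -> list[SectorPopulationSpec]:
    """The three sector specs calibrated to the recorded-population statistics."""
    return [
        SectorPopulationSpec(
            name="suprapyramidal", n=n,
            R_in=Moments(174.44, 94.29), V_RMP=Moments(-74.69, 4.35),
            f_250=Moments(15.89, 10.56), rheobase=Moments(105.0, 25.0),
            V_th=Moments(-37.20, 4.35), V_AP_peak=Moments(47.44, 5.25),
            dvdt_max=Moments(439.13, 77.35), dvdt_min=Moments(-121.25, 15.03),
        ),
        SectorPopulationSpec(
            name="crest", n=n,
            R_in=Moments(157.22, 56.02), V_RMP=Moments(-76.09, 4.22),
            f_250=Moments(13.30, 8.13), rheobase=Moments(115.0, 25.0),
            V_th=Moments(-38.58, 3.97), V_AP_peak=Moments(48.14, 7.04),
            dvdt_max=Moments(476.83, 95.42), dvdt_min=Moments(-123.94, 15.89),
        ),
        SectorPopulationSpec(
            name="infrapyramidal", n=n,
            R_in=Moments(179.44, 72.25), V_RMP=Moments(-75.26, 3.52),
            f_250=Moments(16.57, 9.57), rheobase=Moments(100.0, 25.0),
            V_th=Moments(-37.18, 5.55), V_AP_peak=Moments(46.67, 6.01),
            dvdt_max=Moments(438.11, 83.13), dvdt_min=Moments(-119.05, 16.54),
        ),
    ]


def _lognormal(rng, m: Moments, z=None) -> float:
    sigma2 = np.log1p((m.sd / m.mean) ** 2)
    mu = np.log(m.mean) - sigma2 / 2.0
    if z is None:
        z = rng.standard_normal()
    return float(np.exp(mu + np.sqrt(sigma2) * z))


def _truncnorm(rng, m: Moments, lo: float, hi: float, z=None) -> float:
    for _ in range(1000):
        zz = rng.standard_normal() if z is None else z
        x = m.mean + m.sd * zz
        if lo <= x <= hi:
            return float(x)
        z = None  # correlated draw violated the bounds; fall back to resampling
    raise InvalidSpecError(f"could not draw a value in [{lo}, {hi}] from {m}")


def _solve_adaptation(params: MembraneParams, f_target: float, stim) -> float:
    """Bisect the adaptation increment b so the 250-pA rate hits ``f_target``."""
    t0, t1 = stim.epochs["pulse"]
    dur_s = (t1 - t0) / 1000.0

    def rate(b):
        p = replace(params, spike=replace(params.spike, adapt_b=b))
        try:
            s = simulate_spiking(p, stim).metadata["true_spike_times"]
        except IntegrationError:
            # over-adapted high-R_in cell hyperpolarized past the guard:
            # treat as silenced so the bisection backs off
            return 0.0
        return np.sum((s >= t0) & (s < t1)) / dur_s

    # rate is monotone decreasing in b; cap b so that a burst-accumulated
    # adaptation current cannot hyperpolarize a high-R_in cell past the
    # integration guard
    lo, hi = 2.0, min(600.0, 60.0 * (params.g_L + params.g_h))
    if rate(lo) <= f_target:
        return lo
    if rate(hi) >= f_target:
        b = hi
    else:
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if rate(mid) > f_target:
                lo = mid
            else:
                hi = mid
        b = 0.5 * (lo + hi)
    while b > lo:
        try:
            simulate_spiking(replace(params, spike=replace(params.spike, adapt_b=b)), stim)
            break
        except IntegrationError:
            b *= 0.8
    return b


def _sample_cell(spec: SectorPopulationSpec, rng) -> MembraneParams:
    for _ in range(50):
        z_exc = rng.standard_normal()
        r_z = spec.rho_excitability
        r_in = _lognormal(rng, spec.R_in, z=z_exc)
        if not 60.0 <= r_in <= 450.0:
            continue
        v_rmp = _truncnorm(rng, spec.V_RMP, -88.0, -62.0)
        g_h = _lognormal(rng, spec.g_h)
        tau_m = _truncnorm(rng, spec.tau_m, 15.0, 40.0)

        base = MembraneParams(g_h=g_h)  # carries the fixed HCN kinetics
        s = base.s_inf(v_rmp)
        dsdv = abs(base.ds_inf_dv(v_rmp))
        g_dc = 1000.0 / r_in
        # measured DC conductance = leak + open HCN + (partially settled) gating term
        g_l = g_dc - g_h * (s + HCN_SETTLING * (base.E_h - v_rmp) * dsdv)
        if g_l <= 1.5:
            continue
        e_l = v_rmp + g_h * s * (v_rmp - base.E_h) / g_l
        c = tau_m * (g_l + g_h * s)

        # --- spike machinery ---
        f_250 = spec.f_250.mean + spec.f_250.sd * (
            r_z * z_exc + np.sqrt(1 - r_z**2) * rng.standard_normal()
        )
        v_th = _truncnorm(rng, spec.V_th, -50.0, -26.0)
        v_peak = _truncnorm(rng, spec.V_AP_peak, 30.0, 65.0)
        dmax = _truncnorm(rng, spec.dvdt_max, 250.0, 750.0)
        dmin = _truncnorm(rng, spec.dvdt_min, -180.0, -80.0)
        v_ahp = _truncnorm(rng, Moments(-62.0, 2.0), -70.0, v_th - 10.0)
        passive = MembraneParams(C=c, g_L=g_l, E_L=e_l, g_h=g_h)
        # highest rheobase this membrane can express while leaving room for
        # the template foot: V_T <= V_th - 8 (exact, from the solver's I-V curve)
        probe = replace(passive, spike=SpikeParams(V_T=v_th - 8.0, delta_T=2.0))
        rheo_cap = rheobase_estimate(probe, v_max=v_th - 4.0) - 1.0
        if rheo_cap < 25.0:
            continue  # pathologically depolarized/high-R draw; resample
        if f_250 < 1.0 and rheo_cap < 260.0:
            # only a low-R_in membrane can push rheobase beyond the tested
            # 250 pA; an excitable membrane drawn as a non-spiker becomes a
            # weak spiker instead (avoids selecting against high R_in)
            f_250 = 1.0 + abs(f_250)
        if f_250 < 1.0:
            # non-spiker: initiation threshold out of reach of a 250-pA pulse
            rheo = float(rng.uniform(260.0, min(420.0, rheo_cap)))
        else:
            # depolarized/high-R_in membranes cannot express high rheobases
            # with a fixed threshold; clip into the feasible range (low
            # rheobase for excitable cells, as observed)
            draw = spec.rheobase.mean + spec.rheobase.sd * rng.standard_normal()
            rheo = float(np.clip(draw, min(50.0, rheo_cap), min(245.0, rheo_cap)))
        v_t = threshold_for_rheobase(passive, rheo, v_max=v_th - 4.0)
        v_start = max(v_th - 11.5, v_t + 6.0)
        v_start = min(v_start, v_th - 4.0)
        if not v_t + 4.0 <= v_start < v_th:
            continue
        tpl = APTemplate(
            V_start=v_start, V_th=v_th, V_peak=v_peak,
            V_ahp=v_ahp, dvdt_max=dmax, dvdt_min=dmin,
        )
        spike = SpikeParams(
            V_T=v_t, refractory=max(5.0, tpl.duration + 0.5), template=tpl,
        )
        params = replace(passive, spike=spike)
        if f_250 >= 1.0:
            b = _solve_adaptation(params, f_250, make_pulse(250.0))
            params = replace(params, spike=replace(spike, adapt_b=b))
        return params
    raise InvalidSpecError(f"could not sample a feasible cell for sector {spec.name}")


def sample_sector_population(
    spec: SectorPopulationSpec, seed: int
) -> list[tuple[MembraneParams, str]]:
    """Draw ``spec.n`` ground-truth parameter sets for one sector (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    return [(_sample_cell(spec, rng), spec.name) for _ in range(spec.n)]


def sample_populations(
    specs: list[SectorPopulationSpec] | None = None, seed: int = 0, n: int | None = None
) -> list[tuple[MembraneParams, str]]:
    """Sample all sectors; per-sector seeds are derived from ``seed``."""
    if specs is None:
        specs = default_population_specs(n) if n else default_population_specs()
    cells = []
    for k, spec in enumerate(specs):
        cells.extend(sample_sector_population(spec, seed=(seed * 7919 + k) % (2**31 - 1)))
    return cells
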