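"""Compiled inner loop of the single-compartment integrator.

The membrane equation is integrated at a fine step ``dt/substeps`` with a
forward-Euler update for V and an exponential-Euler update for the HCN gating
variable (stable for stiff gating). The injected current and the noise are
held constant over each output sample (zero-order hold). When the spiking
mechanism is enabled, an exponential spike-initiation term is added and, on
reaching the paste trigger voltage, a stereotyped AP template (pre-sampled at
the fine step) is written into the trajectory, after which V resumes from the
template's final value; spike initiation stays disabled for the refractory
period measured from the trigger.
"""

import numpy as np
from numba import njit

#: sentinel spike count signalling |V| > 200 mV divergence
DIVERGED = -1


@njit(cache=True)
def integrate(
    I,            # injected current per output sample, pA
    dt,           # output sample interval, ms
    substeps,     # integration substeps per output sample
    C,            # pF
    g_L, E_L,     # nS, mV
    g_h, E_h, V_half, k_slope, tau_h,   # nS, mV, mV, mV, ms
    noise,        # per-output-sample current noise, pA (same length as I)
    bias,         # DC holding current, pA
    has_spike,    # bool
    V_T, delta_T, V_cut,                # mV
    refrac_ms,    # ms
    template,     # AP template sampled at the fine step, mV
    peak_offset_ms,                     # trigger -> template peak, ms
    adapt_b, adapt_tau,                 # pA, ms
    V0, s0,       # initial state
):
    n = I.shape[0]
    dtf = dt / substeps
    V_out = np.empty(n)
    V_out[0] = V0
    exp_h = 1.0 - np.exp(-dtf / tau_h)
    decay_w = np.exp(-dtf / adapt_tau) if adapt_tau > 0 else 1.0
    refrac_steps = int(round(refrac_ms / dtf))
    tpl_len = template.shape[0]

    V = V0
    s = s0
    w = 0.0
    paste_pos = tpl_len  # >= tpl_len means "not pasting"
    refrac_left = 0
    spike_times = np.empty(100000)
    nsp = 0

    for i in range(1, n):
        Ii = I[i - 1] + bias + noise[i - 1]
        for j in range(substeps):
            if paste_pos < tpl_len:
                V = template[paste_pos]
                paste_pos += 1
                # gating keeps tracking the (template) voltage
                sinf = 1.0 / (1.0 + np.exp((V - V_half) / k_slope))
                s += (sinf - s) * exp_h
                w *= decay_w
            else:
                sinf = 1.0 / (1.0 + np.exp((V - V_half) / k_slope))
                s += (sinf - s) * exp_h
                I_ion = -g_L * (V - E_L) - g_h * s * (V - E_h)
                if has_spike and refrac_left == 0:
                    I_ion += g_L * delta_T * np.exp((V - V_T) / delta_T)
                V += (I_ion + Ii - w) * dtf / C
                w *= decay_w
                if has_spike and refrac_left == 0 and V >= V_cut:
                    # the template takes over from this step: a single Euler
                    # overshoot of the stiff initiation term never escapes
                    t_fine = ((i - 1) * substeps + j + 1) * dtf
                    spike_times[nsp] = t_fine + peak_offset_ms
                    nsp += 1
                    w += adapt_b
                    V = template[0]
                    paste_pos = 1
                    refrac_left = refrac_steps
                elif V > 200.0 or V < -200.0:
                    return V_out, spike_times[:nsp], DIVERGED
            if refrac_left > 0:
                refrac_left -= 1
        V_out[i] = V
    return V_out, spike_times[:nsp], nsp
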