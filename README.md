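# dgephys

Intrinsic-electrophysiology characterization of dentate gyrus (DG) granule
cells: the complete current-clamp measurement battery — steady-state,
frequency-dependent, and spiking — implemented as a tested Python library,
together with a conductance-based synthetic-neuron module that generates
realistic per-sector populations (suprapyramidal blade, crest,
infrapyramidal blade) for end-to-end validation.

The package is for cellular neurophysiologists and modelers who need
reproducible, scriptable implementations of the standard granule-cell
protocol suite: multi-amplitude V–I pulses, α-EPSP trains, the Chirp15
impedance sweep, and f–I families, plus the population statistics used to
quantify cell-to-cell heterogeneity.

## Measurements

**Subthreshold** (from pulse, α-train, and chirp protocols):

- input resistance `R_in` — slope of the steady-state V–I plot over pulse
  amplitudes (−50…+50 pA in 10-pA steps, or ±25 pA in 5-pA steps for
  high-R_in cells);
- single-pulse estimate `R̄_in` and percentage sag `100·(1 − V_ss/V_peak)`
  from the −100 pA pulse preceding the chirp;
- temporal summation ratio `S_α = E_last/E_first` over five α-current
  EPSCs, `I_α = I_max · t · exp(−αt)` with `α = 0.1 ms⁻¹`, at 20 Hz;
- the impedance amplitude (ZAP) and phase (ZPP) profiles
  `Z(f) = F[V]/F[I]` under Chirp15 (constant-amplitude sinusoid sweeping
  0→15 Hz in 15 s), and from them the resonance frequency `f_R`, resonance
  strength `Q = |Z|_max / |Z|(0.5 Hz)`, `|Z|_max`, and the total inductive
  phase `Φ_L` (area under the positive part of the ZPP, rad·Hz).

**Suprathreshold** (700-ms pulses, 0–250 pA in 50-pA steps; rates
extrapolated to 1 s): spike detection, f–I curves and rheobase, Hodgkin
excitability class, and first-AP waveform features — threshold `V_th` at
the 20 V/s dV/dt crossing, peak voltage, amplitude `V_AP` relative to
`V_RMP`, half-width `T_APHW`, dV/dt extrema, latency `T_1AP`, first ISI
`T_1ISI`.

**Population statistics**: SD / IQR / signed CV variability metrics,
parametric (ANOVA + Tukey HSD) and nonparametric (Kruskal–Wallis, Wilcoxon
rank-sum) sector comparisons, pairwise-complete Pearson correlation
matrices with the weak band |R| < 0.4, and PCA on the standardized
18-measurement table.

## The synthetic neuron

A single-compartment membrane with leak and a slow HCN-like conductance,

    C dV/dt = −g_L (V − E_L) − g_h s (V − E_h) + I(t) + ξ(t)
    ds/dt   = (s_∞(V) − s)/τ_h,   s_∞(V) = 1/(1 + exp((V − V_half)/k))

with τ_h = 500 ms: slow enough that the resonant admittance rolls off
before membrane capacitance takes over, leaving a **low-pass** impedance
profile (f_R < 1 Hz, Q ≈ 1, Φ_L = 0) even though the cell expresses a
resonating conductance — speeding the same gate up (τ_h = 50 ms) restores
the band-pass profile familiar from CA1 pyramidal and stellate cells.
Spiking adds an exponential initiation term, a stereotyped AP waveform
template (for waveform-level feature extraction with known ground truth),
and spike-triggered adaptation, yielding class I excitability with
granule-cell firing rates. See `docs/methods.md` for the full model
account and every default.

## Worked example

`python examples/chirp_impedance.py` prints:

```
slow HCN (granule cell): resting at -77.28 mV
  R_in_bar =  160.8 MOhm   sag =  2.43 %
  f_R  =  0.33 Hz   Q = 1.005   |Z|_max =  169.2 MOhm
  Phi_L = 0.0000 rad*Hz

fast strong HCN (contrast): resting at -74.23 mV
  R_in_bar =   64.2 MOhm   sag = 33.96 %
  f_R  =  5.46 Hz   Q = 1.375   |Z|_max =  126.6 MOhm
  Phi_L = 0.0633 rad*Hz
```

The granule cell is low-pass: maximum impedance at the bottom of the
0.5–15 Hz band, resonance strength indistinguishable from 1, no inductive
phase lead, and only ~2% sag. The contrast cell — same conductance, fast
kinetics — resonates at 5.5 Hz with Q ≈ 1.4 and a positive phase area.
`examples/fi_and_ap_features.py` (f–I curve 0→14.3 Hz, rheobase 100 pA,
class I, V_th −38.5 mV, V_AP 124 mV), `examples/voltage_dependence.py`
(five-holding sweep), and `examples/population_heterogeneity.py`
(sector summary tables, 82% weak correlations) cover the other
capabilities.

A thin CLI wraps the same pipeline:

```bash
dgephys run --seed 1 --out out/            # simulate -> measure -> stats -> figures
dgephys simulate --seed 1 --out traces.h5  # stages can be run separately
dgephys measure traces.h5 --out out/
```

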