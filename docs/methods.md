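# Methods

## The membrane model

Each synthetic granule cell is a single compartment with a leak conductance
and a slow hyperpolarization-activated (HCN-like) conductance:

    C dV/dt = −g_L (V − E_L) − g_h s (V − E_h) + I_inj(t) + ξ(t)
    ds/dt   = (s_∞(V) − s)/τ_h,     s_∞(V) = 1/(1 + exp((V − V_half)/k))

with k > 0, so activation grows under hyperpolarization. Defaults
(`MembraneParams`):

| parameter | default | unit | rationale |
|---|---|---|---|
| C | 147 | pF | τ_m = C/g_L = 25 ms at R = 170 MΩ |
| g_L | 5.882 (= 1/170 MΩ) | nS | granule-cell R_in scale |
| E_L | −78 | mV | rest ≈ −77 mV after the HCN shift |
| g_h | 0.25 | nS | see "Sizing the HCN conductance" |
| E_h | −30 | mV | mixed-cation reversal |
| V_half, k | −82, 8 | mV | HCN activation curve |
| τ_h | 500 | ms | very slow granule-cell HCN kinetics |

ξ(t) is white current noise (SD `noise_sd`, default 5 pA for population
runs, 0 for oracle tests), held constant over each output sample and fully
determined by the seed. Recorded granule cells carry synaptic background
whose statistics are not available; this noise model is a free choice and
is surfaced in the run config.

### Sizing the HCN conductance

The linearized admittance about an operating point V₀ is

    Y(ω) = g_L + g_h s_∞ + g_h (V₀ − E_h) s_∞′(V₀)/(1 + iωτ_h) + iωC.

For an HCN gate (s_∞′ < 0, V₀ < E_h) the gating term is positive — a
resonating admittance that suppresses low frequencies. Whether the cell
actually resonates is a race between this term's roll-off (corner
1/2πτ_h ≈ 0.32 Hz at τ_h = 500 ms) and the capacitive roll-off
(≈ 6–7 Hz here). Scanning g_h with the default kinetics shows that the
measured phenotype — f_R < 1 Hz, Q < 1.05, no positive phase lead at any
holding from −80 to −60 mV — requires g_h ≲ 0.3 nS; stronger g_h pushes a
shallow impedance peak above 1 Hz and opens a small inductive phase lobe.
The default g_h = 0.25 nS therefore shifts the resting potential by less
than 1 mV, and the voltage dependence of R̄_in and |Z|_max across holdings
is correspondingly weak (a few percent) — much weaker than in real granule
cells, where other subthreshold conductances contribute. The contrast cell
(`fast_resonant_cell`: τ_h = 50 ms, k = 4, g_h = 4 nS) shows that the same
architecture resonates (Q ≈ 1.4 at ≈ 5 Hz) once the kinetics are fast —
the kinetics–resonance relationship the low-pass phenotype rests on.

### Spiking mechanism

Subthreshold dynamics are augmented by an exponential spike-initiation term
g_L·Δ_T·exp((V−V_T)/Δ_T) (Δ_T = 2 mV). When V reaches the paste trigger, a
stereotyped AP waveform template is written into the trajectory and the
cell resumes from the template's afterhyperpolarization; initiation is
disabled for a refractory period (5 ms) from the trigger. A
spike-triggered adaptation current (w += b at each spike, decay
τ_w = 150 ms) slows repetitive firing: without it, a fast-initiation cell
with R_in ≈ 170 MΩ and rheobase ≈ 100 pA would fire ≈ 70–100 Hz at 250 pA,
several-fold above granule-cell rates; b = 80 pA brings the 700-ms f–I
curve to [0, 0, 1.4, 5.7, 10.0, 14.3] Hz at 0–250 pA. Adaptation preserves
class I excitability (arbitrarily low sustained rates just above
rheobase); it is the one mechanism added beyond the minimal
"initiation + template" design because the firing-rate scale cannot be
reached without it.

The AP template is piecewise-analytic with C¹ joins: an upstroke foot
whose slope grows exponentially with voltage (dV/dt = d0·e^((V−V_start)/κ),
κ fixed so the slope crosses 20 V/s exactly at the designed threshold
V_th), a quarter-sine shoulder reaching the peak with maximum slope
`dvdt_max`, and a raised-cosine downstroke with minimum slope `dvdt_min`.
Because the 20 V/s crossing sits strictly inside a smooth, monotone-slope
segment, the dV/dt threshold criterion recovers V_th to < 0.1 mV and is
invariant to the digitization rate. Defaults: V_start −50, V_th −38.5,
V_peak +47, V_ahp −62 mV, dvdt_max 450, dvdt_min −120 V/s. Note that the
centered-difference derivative at 20 kHz undersamples the brief slope
extremum of the pasted waveform, so measured dV/dt maxima run ~10–15%
below the template parameter; this is a property of the estimator at this
sampling rate, shared with any sharp waveform.

### Integration

Forward Euler for V, exponential Euler for the gating variable (stable for
stiff gating), fine step 0.025 ms (two substeps per 0.05-ms output sample,
a 20 kHz digitization). The stiff initiation term can overshoot in the
final step before a spike; the template takes over at the trigger step, so
the overshoot never enters the trace. |V| > 200 mV raises an
integration-failure error. Halving the step changes measured R_in and f_R
by < 0.5% (tested), and spike counts by at most one (tested at 4× refinement).
The inner loop is compiled with numba.

## Measurement conventions

- **Steady-state window**: last 200 ms of the 700-ms pulse; **baseline**:
  last 100 ms before stimulus onset (also defines V_RMP).
- **R̄_in / sag** use the last 100 ms of the 500-ms prepulse; with
  τ_h = 500 ms the HCN response is only partly settled there, which is why
  R̄_in sits below the 700-ms slope-fit R_in, as in recorded cells.
- **Impedance**: raw FFT ratio with mean removal, no taper or smoothing
  (optional moving-average smoothing behind a flag). Up to 200 ms of
  post-chirp samples are appended to the window so the response to the
  final cycles is contained; without the tail, truncation leaks a ~2% bias
  into the profile. Frequency resolution ≈ 1/15 Hz; |Z|(0.5 Hz) for Q is
  linearly interpolated between bins.
- **f_R search band**: all positive-frequency bins up to 15 Hz (DC
  excluded); reported f_R floors at the resolution, so strongly low-pass
  cells report f_R ≈ 0.07–0.33 Hz.
- **Φ_L**: trapezoidal area of max(phase, 0) over 0.5–15 Hz; contiguous
  positive excursions whose peak stays below `phase_tol` are zeroed first.
  The default tolerance is 0 (appropriate for noiseless synthetic data);
  0.005 rad is the documented choice for noisy recordings, where tiny
  positive excursions are estimation noise.
- **Spike contamination**: any sample with dV/dt > 20 V/s and V > −20 mV
  inside a nominally subthreshold epoch fails that measurement with an
  explicit error; the pipeline logs the flag and records NaN.
- **Spike detection**: local maximum above 0 mV preceded within 5 ms by an
  upward 20 V/s crossing; peaks closer than 2 ms merge. The 0 mV criterion
  reflects granule-cell AP peaks near +47 mV.
- **T_1AP** is referenced to the threshold crossing of the first AP (the
  fiducial is configurable; peak-referenced latency differs by < 1 ms).
- **Excitability class**: with the generating cell available, rheobase is
  refined by bisection (5-pA resolution, 2-s pulses); class I if the
  sustained rate just above threshold is below 5 Hz, class II if it jumps
  above 20 Hz. The numeric boundaries are module constants chosen from the
  Hodgkin-classification literature; the profile-only call uses the rate
  at the tested rheobase amplitude and is correspondingly coarser on a
  50-pA grid.

## Population generator

Each sector (suprapyramidal blade, crest, infrapyramidal blade) is
specified by target means and SDs of *measured* quantities: R_in
(log-normal, e.g. crest 157.22 ± SD 56.02 MΩ), V_RMP (normal), firing rate
at 250 pA (normal, truncated at 0; sub-1 Hz draws on low-R_in membranes
become genuine non-spikers), rheobase (normal, clipped to the membrane's
feasible range), and the AP template parameters. Conductance-like
quantities are log-normal (positivity); voltages normal; bounds enforced
by resampling, with care that no resampling path selects on R_in (an early
version discarded infeasible high-R_in draws and biased the measured mean
by ~7%; the current feasibility caps are computed per membrane and clamp
instead of discarding).

The generator inverts the measurement model per cell: g_L from the target
R_in via the DC admittance with a 0.75 settling factor for the slow gating
term (measured/target ratio 1.008 ± 0.006), E_L from the target V_RMP via
the exact steady-state balance, V_T solved from the drawn rheobase on the
quasi-static I–V curve, and the adaptation increment b solved by bisection
against the actual simulator at 250 pA. A latent per-cell excitability
factor correlates the R_in and f_250 draws (ρ = 0.5), reproducing the
strong positive correlations among excitability measures; the repolarizing
pair (T_APHW, dVdt_min) is coupled through the template geometry.

**What the generator emulates**: the measurement-level means, SDs and
heterogeneity structure of the three sector populations at rest; the
low-pass/zero-Φ_L frequency response; class I firing at granule-cell
rates; partially settled R̄_in below R_in. **What it does not emulate**:
synaptic background (noise is white), the full strength of the voltage
dependence of excitability (limited here by the weak g_h needed for the
low-pass phenotype), sag at the recorded ~3% scale for every cell,
AP-feature correlations beyond the built-in couplings, and any
within-sector spatial gradients. Passing population tests therefore
validate the measurement pipeline and the calibration machinery, not
claims about real tissue beyond the statistics explicitly targeted. In
PCA, the first three components explain ~55–65% of the variance — less
than in real granule cells, whose measurements share more common channel
substrates than this model's partly independent draws.

## Numerical and design choices

- Sample interval 0.05 ms (20 kHz) by default; the acquisition rate of the
  protocols this mirrors is not published.
- Chirp amplitude 30 pA (subthreshold for every sampled cell); the
  oracle-equivalence tests use a prepulse-free chirp because the −100 pA
  prepulse leaves a slow HCN relaxation (τ_h up to 800 ms in the random
  sweep) that contaminates the lowest-frequency bins additively.
- Pulse padding 200 ms before / 300 ms after; prepulse and recovery gap
  500 ms each.
- Wilcoxon rank-sum p-values come from the Mann–Whitney U statistic
  (identical test), exact for small samples — matching an explicit
  permutation oracle at n ≤ 8.
- IQR uses linear-interpolation (type-7) quantiles; CV carries the sign of
  the mean.
- Correlations use pairwise deletion; PCA complete cases, z-scored, via
  eigendecomposition of the correlation matrix with the largest-|loading|
  sign convention; constant columns (e.g. Φ_L ≡ 0 in noiseless runs) are
  dropped from the embedding. No multiple-testing correction is applied to
  the per-pair correlation p-values by default (a Benjamini–Hochberg
  option exists).
- Determinism: every stochastic step derives from the master seed; reruns
  with the same config produce byte-identical measurement CSVs.

## Known limitations

Single compartment only (no dendritic impedance transfer), one gating
variable with voltage-independent τ_h, templated APs (no conductance-based
spike shape), no spike-frequency-adaptation *measurements* (the mechanism
exists; indices of it are not part of the battery), and no readers for
proprietary acquisition formats — the HDF5 trace bundle is the interchange
container.
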