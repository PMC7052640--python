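"""Voltage-trace container pairing a membrane-potential recording with its stimulus."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import StimulusWaveform

#: Length of the window (ms) at the end of the pre-stimulus baseline epoch
#: over which the resting membrane potential is averaged.
V_RMP_WINDOW = 100.0


@dataclass
class VoltageTrace:
    """A sampled membrane-potential response paired with its stimulus.

    ``samples`` are in mV and share length and ``sample_interval`` (ms) with
    the stimulus. ``metadata`` carries cell id, sector label, holding bias
    (pA), seed, and — for synthetic traces — the ground-truth spike times.
    """

    samples: np.ndarray
    sample_interval: float
    stimulus: StimulusWaveform
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.samples) != self.stimulus.n_samples:
            raise ValueError("voltage and stimulus must have the same length")
        if self.sample_interval != self.stimulus.sample_interval:
            raise ValueError("voltage and stimulus must share sample_interval")

    @property
    def v_rmp(self) -> float:
        """Resting membrane potential: mean over the tail of the pre-stimulus baseline (mV)."""
        t0, t1 = self.stimulus.epochs.get("baseline", (0.0, self.stimulus.t_start_of_interest))
        t0 = max(t0, t1 - V_RMP_WINDOW)
        dt = self.sample_interval
        sl = slice(int(round(t0 / dt)), int(round(t1 / dt)))
        return float(np.mean(self.samples[sl]))

    def time(self) -> np.ndarray:
        return self.stimulus.time()

    def epoch_slice(self, name: str) -> slice:
        return self.stimulus.epoch_slice(name)

    def dvdt(self) -> np.ndarray:
        """Centered-difference temporal derivative, V/s (== mV/ms); one-sided at the ends."""
        return np.gradient(self.samples, self.sample_interval)
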