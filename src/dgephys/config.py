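"""Run configuration: every tunable default surfaces as a named YAML key."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import InvalidArgumentError

DEFAULTS: dict = {
    "seed": 0,
    "stimuli": {
        "sample_interval": 0.05,      # ms (20 kHz digitization)
        "chirp_amplitude": 30.0,      # pA, constant-amplitude sweep
        "chirp_f_end": 15.0,          # Hz
        "chirp_duration": 15.0,       # s
        "prepulse_amplitude": -100.0,  # pA, R̄_in / sag pulse before the chirp
        "prepulse_duration": 500.0,   # ms
        "prepulse_gap": 500.0,        # ms
        "pulse_pre": 200.0,           # ms padding before pulses
        "pulse_post": 300.0,          # ms padding after pulses
        "vi_amplitudes": [-50, -40, -30, -20, -10, 0, 10, 20, 30, 40, 50],
        "vi_amplitudes_high_rin": [-25, -20, -15, -10, -5, 0, 5, 10, 15, 20, 25],
        "fi_amplitudes": [0, 50, 100, 150, 200, 250],
        "alpha_i_max": 25.0,          # pA/ms
        "alpha_rate_ms": 0.1,         # ms^-1
        "alpha_n_events": 5,
        "alpha_interval": 50.0,       # ms
    },
    "simulation": {
        "noise_sd": 5.0,              # pA white current noise
        "substeps": 2,                # integration substeps per sample (0.025 ms)
    },
    "population": {
        "n_per_sector": 50,
        "high_rin_threshold": 250.0,  # MΩ: use the ±25 pA V–I family above this
    },
    "measurement": {
        "f_band": [0.5, 15.0],        # Hz, impedance analysis band
        "phase_tol": 0.0,             # rad, Φ_L noise tolerance
        "impedance_tail_ms": 200.0,   # post-chirp tail included in the FFT window
        "steady_state_window": 200.0,  # ms
    },
    "output": {
        "dir": "dgephys_out",
        "write_bundle": False,
        "figures": True,
    },
}


def _merge(base: dict, override: dict, path="") -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k not in base:
            raise InvalidArgumentError(f"unknown config key {path + k!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise InvalidArgumentError(f"config key {path + k!r} must be a mapping")
            out[k] = _merge(base[k], v, path=f"{path}{k}.")
        else:
            out[k] = v
    return out


class RunConfig:
    """Validated configuration for the simulate→measure→stats pipeline."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge(DEFAULTS, overrides or {})

    def __getitem__(self, key):
        return self.data[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path):
        with open(path, "w") as f:
            yaml.safe_dump(self.data, f, sort_keys=True)

    def hash(self) -> str:
        """Stable digest stamped onto every output of a run."""
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
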