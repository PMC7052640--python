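"""Hierarchical trace container: per-cell groups of stimulus/response pairs.

On-disk layout (HDF5)::

    /cells/<cell_id>/                 attrs: sector, seed
        <protocol>/                   attrs: kind, sample_interval, bias_pA,
                                      params (JSON), epochs (JSON), units
            stimulus   float64[n]     pA
            voltage    float64[n]     mV
            true_spike_times          (optional ground truth, ms)
    /ground_truth/<cell_id>           attrs: params (JSON) — synthetic cells

Round trips are lossless: write∘read is the identity on samples and
metadata. Schema violations (e.g. a voltage dataset without its stimulus)
raise :class:`~dgephys.errors.FormatError` naming the offending cell and
protocol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError
from .stimuli import StimulusWaveform
from .traces import VoltageTrace


@dataclass
class CellRecord:
    """All protocol responses of one cell plus its metadata."""

    cell_id: str
    sector: str
    seed: int = 0
    traces: dict = field(default_factory=dict)      # protocol -> VoltageTrace
    ground_truth: dict = field(default_factory=dict)


@dataclass
class TraceBundle:
    cells: dict = field(default_factory=dict)       # cell_id -> CellRecord

    def add(self, record: CellRecord):
        self.cells[record.cell_id] = record

    def __len__(self):
        return len(self.cells)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_bundle(bundle: TraceBundle, path: str | Path):
    """Write a bundle to ``path`` (HDF5), overwriting any existing file."""
    with h5py.File(path, "w") as f:
        cells = f.create_group("cells")
        gt_root = f.create_group("ground_truth")
        for cid, rec in bundle.cells.items():
            g = cells.create_group(cid)
            g.attrs["sector"] = rec.sector
            g.attrs["seed"] = rec.seed
            for proto, trace in rec.traces.items():
                pg = g.create_group(proto)
                pg.create_dataset("stimulus", data=trace.stimulus.samples)
                pg.create_dataset("voltage", data=trace.samples)
                pg.attrs["kind"] = trace.stimulus.kind
                pg.attrs["sample_interval"] = trace.sample_interval
                pg.attrs["bias_pA"] = float(trace.metadata.get("bias_pA", 0.0))
                pg.attrs["params"] = json.dumps(trace.stimulus.params, default=_json_default)
                pg.attrs["epochs"] = json.dumps(trace.stimulus.epochs, default=_json_default)
                pg.attrs["units"] = json.dumps({"voltage": "mV", "stimulus": "pA", "time": "ms"})
                st = trace.metadata.get("true_spike_times")
                if st is not None:
                    pg.create_dataset("true_spike_times", data=np.asarray(st, dtype=float))
            if rec.ground_truth:
                gt = gt_root.create_group(cid)
                gt.attrs["params"] = json.dumps(rec.ground_truth, default=_json_default)


def read_bundle(path: str | Path) -> TraceBundle:
    """Read a bundle written by :func:`write_bundle`, validating the schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bundle = TraceBundle()
    with h5py.File(path, "r") as f:
        if "cells" not in f:
            raise FormatError("bundle has no /cells group")
        for cid, g in f["cells"].items():
            rec = CellRecord(
                cell_id=cid,
                sector=str(g.attrs.get("sector", "")),
                seed=int(g.attrs.get("seed", 0)),
            )
            for proto, pg in g.items():
                for needed in ("stimulus", "voltage"):
                    if needed not in pg:
                        raise FormatError(
                            f"cell {cid!r} protocol {proto!r}: missing {needed!r} dataset"
                        )
                for needed in ("kind", "sample_interval", "epochs"):
                    if needed not in pg.attrs:
                        raise FormatError(
                            f"cell {cid!r} protocol {proto!r}: missing {needed!r} attribute"
                        )
                stim_samples = pg["stimulus"][()]
                v = pg["voltage"][()]
                if len(stim_samples) != len(v):
                    raise FormatError(
                        f"cell {cid!r} protocol {proto!r}: stimulus/voltage length mismatch"
                    )
                epochs = {k: tuple(v_) for k, v_ in json.loads(pg.attrs["epochs"]).items()}
                stim = StimulusWaveform(
                    samples=stim_samples,
                    sample_interval=float(pg.attrs["sample_interval"]),
                    kind=str(pg.attrs["kind"]),
                    params=json.loads(pg.attrs["params"]) if "params" in pg.attrs else {},
                    epochs=epochs,
                )
                metadata = {"bias_pA": float(pg.attrs.get("bias_pA", 0.0)), "cell_id": cid}
                if "true_spike_times" in pg:
                    metadata["true_spike_times"] = pg["true_spike_times"][()]
                rec.traces[proto] = VoltageTrace(
                    samples=v,
                    sample_interval=stim.sample_interval,
                    stimulus=stim,
                    metadata=metadata,
                )
            if "ground_truth" in f and cid in f["ground_truth"]:
                rec.ground_truth = json.loads(f["ground_truth"][cid].attrs["params"])
            bundle.add(rec)
    return bundle
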