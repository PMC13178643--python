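"""Plain-text readers/writers shared by the generators and the CLI.

Traces travel as CSV (time_s, value, unit) with a JSON sidecar carrying
the protocol and condition metadata; count matrices as an MTX triplet
plus a metadata TSV; event logs as TSV.  Everything is deterministic
byte-for-byte for fixed inputs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio, sparse

from .behavior import TrialEvent
from .fscv import StimulusProtocol, VoltammetryTrace
from .transcriptomics import CountMatrix

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_event_log",
    "write_json",
]


def write_trace_csv(trace: VoltammetryTrace, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value", "unit"])
        for t, v in zip(trace.time, trace.signal):
            writer.writerow([f"{t:.6f}", f"{v:.9g}", trace.unit])
    sidecar = {
        "protocol": dataclasses.asdict(trace.protocol),
        "stim_onset": trace.stim_onset,
        "condition": dict(trace.condition),
    }
    write_json(sidecar, path.with_suffix(".json"))


def read_trace_csv(path) -> VoltammetryTrace:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time_s", "value", "unit"]:
            raise ValueError(f"{path}: expected header time_s,value,unit")
        rows = [row for row in reader if row]
    time = np.array([float(r[0]) for r in rows])
    signal = np.array([float(r[1]) for r in rows])
    units = {r[2] for r in rows}
    if len(units) != 1:
        raise ValueError(f"{path}: mixed units {units}")
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        protocol = StimulusProtocol(**meta["protocol"])
        stim_onset = float(meta["stim_onset"])
        condition = meta.get("condition", {})
    else:
        protocol = StimulusProtocol()
        stim_onset = float(time[0])
        condition = {}
    return VoltammetryTrace(
        time=time, signal=signal, unit=units.pop(), protocol=protocol,
        stim_onset=stim_onset, condition=condition,
    )


def write_counts_mtx(cm: CountMatrix, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "matrix.mtx", sparse.coo_matrix(cm.counts), field="integer")
    (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
    (out_dir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in cm.nucleus_meta["nucleus_id"])
    )
    cm.nucleus_meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)


def read_counts_mtx(in_dir) -> CountMatrix:
    in_dir = Path(in_dir)
    counts = sparse.csr_matrix(spio.mmread(in_dir / "matrix.mtx"))
    gene_ids = (in_dir / "genes.tsv").read_text().splitlines()
    meta = pd.read_csv(in_dir / "metadata.tsv", sep="\t")
    return CountMatrix(counts=counts, gene_ids=gene_ids, nucleus_meta=meta)


def write_event_log(events: Sequence[TrialEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("t_s\tevent\tport\n")
        for ev in events:
            fh.write(f"{ev.t:.3f}\t{ev.event}\t{ev.port}\n")


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
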