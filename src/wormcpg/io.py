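"""Serialization: trace export (HDF5/CSV), run manifests, checksums."""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import sys
from pathlib import Path

import h5py
import pandas as pd

from . import __version__
from .circuit import CLASSES, N_CLASSES
from .simulation import SimConfig, SimulationTrace


def trace_to_hdf5(trace: SimulationTrace, path: str | Path) -> None:
    """Dense trace storage: neural outputs, muscle activations, midlines."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_units"] = trace.n_units
        fh.create_dataset("times", data=trace.times)
        fh.create_dataset("outputs", data=trace.outputs, compression="gzip")
        if trace.muscle_activation is not None:
            fh.create_dataset("muscle_activation", data=trace.muscle_activation,
                              compression="gzip")
        if trace.midline is not None:
            fh.create_dataset("midline", data=trace.midline, compression="gzip")
        if trace.potentials is not None:
            fh.create_dataset("potentials", data=trace.potentials, compression="gzip")
        if trace.config is not None:
            fh.attrs["config"] = json.dumps(dataclasses.asdict(trace.config))


def trace_from_hdf5(path: str | Path) -> SimulationTrace:
    with h5py.File(path, "r") as fh:
        cfg = None
        if "config" in fh.attrs:
            cfg = SimConfig(**json.loads(fh.attrs["config"]))
        return SimulationTrace(
            times=fh["times"][:],
            outputs=fh["outputs"][:],
            n_units=int(fh.attrs["n_units"]),
            muscle_activation=fh["muscle_activation"][:] if "muscle_activation" in fh else None,
            midline=fh["midline"][:] if "midline" in fh else None,
            potentials=fh["potentials"][:] if "potentials" in fh else None,
            config=cfg,
        )


def neural_trace_frame(trace: SimulationTrace) -> pd.DataFrame:
    """Long-format (time, unit, class[, V], S) table of neural activity."""
    rows = []
    for u in range(trace.n_units):
        for ci, c in enumerate(CLASSES):
            cols = {
                "time": trace.times,
                "unit": u,
                "class": c,
                "S": trace.outputs[:, u * N_CLASSES + ci],
            }
            if trace.potentials is not None:
                cols["V"] = trace.potentials[:, u * N_CLASSES + ci]
            rows.append(pd.DataFrame(cols))
    return pd.concat(rows, ignore_index=True)


def midlines_to_csv(trace: SimulationTrace, path: str | Path) -> None:
    """Per-frame midline coordinates: columns t, x0, y0, x1, y1, ..."""
    if trace.midline is None:
        raise ValueError("trace has no midline recording")
    n_rod = trace.midline.shape[1]
    flat = trace.midline.reshape(len(trace.times), 2 * n_rod)
    cols = [f"{ax}{i}" for i in range(n_rod) for ax in ("x", "y")]
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "t", trace.times)
    df.to_csv(path, index=False)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: list[str] | None = None,
    config: dict | None = None,
    seeds: dict | None = None,
) -> Path:
    """Run manifest: enough metadata to re-derive the directory bit-identically."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    files = {
        p.name: file_checksum(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    doc = {
        "package": "wormcpg",
        "version": __version__,
        "command": command if command is not None else sys.argv,
        "config": config or {},
        "seeds": seeds or {},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "files": files,
    }
    manifest_path.write_text(json.dumps(doc, indent=1))
    return manifest_path
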