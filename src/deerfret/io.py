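"""Plain-text I/O for DEER traces and smFRET intensity tables.

DEER traces are two-column CSV files (``t_us,amplitude``); a manifest CSV
maps filenames to conditions (ligand, transducer group).  FRET traces are
tabular files with columns ``frame,I_D,I_A`` (one file per trace) or a
multi-trace table with an extra ``trace_id`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .deer.forward import DipolarSignal, TimeAxis
from .fret.traces import CY3_CY5, CY3_CY7, DyePairConstants, FretTrace

__all__ = [
    "write_deer_trace",
    "read_deer_trace",
    "write_deer_dataset",
    "read_deer_manifest",
    "write_fret_traces",
    "read_fret_traces",
]

_PAIRS = {"Cy3/Cy5": CY3_CY5, "Cy3/Cy7": CY3_CY7}


def write_deer_trace(signal: DipolarSignal, path: str | Path) -> None:
    df = pd.DataFrame({"t_us": signal.time.t, "amplitude": signal.amplitude})
    df.to_csv(path, index=False)


def read_deer_trace(path: str | Path, condition: str = "",
                    group: str = "none") -> DipolarSignal:
    df = pd.read_csv(path)
    if not {"t_us", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns t_us,amplitude")
    return DipolarSignal(time=TimeAxis(df["t_us"].to_numpy(float)),
                         amplitude=df["amplitude"].to_numpy(float),
                         condition=condition or Path(path).stem, group=group)


def write_deer_dataset(signals: list[DipolarSignal], out_dir: str | Path,
                       ) -> Path:
    """Write one trace file per condition plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in signals:
        fname = f"{s.condition.replace('/', '_').replace('+', '_')}.csv"
        write_deer_trace(s, out / fname)
        rows.append(dict(filename=fname, condition=s.condition, group=s.group))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_deer_manifest(manifest: str | Path) -> list[DipolarSignal]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    need = {"filename", "condition", "group"}
    if not need <= set(table.columns):
        raise ValueError(f"{manifest}: manifest needs columns {sorted(need)}")
    return [read_deer_trace(manifest.parent / row.filename,
                            condition=row.condition, group=row.group)
            for row in table.itertuples()]


def write_fret_traces(traces: list[FretTrace], path: str | Path) -> None:
    """Multi-trace table: trace_id, frame, I_D, I_A (pair and dt in a header comment)."""
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "trace_id": t.trace_id, "frame": np.arange(t.n_frames),
            "I_D": t.donor, "I_A": t.acceptor}))
    df = pd.concat(frames, ignore_index=True)
    pair = traces[0].pair.name
    dt = traces[0].frame_interval
    with open(path, "w") as fh:
        fh.write(f"# pair={pair} frame_interval_s={dt}\n")
        df.to_csv(fh, index=False)


def read_fret_traces(path: str | Path,
                     pair: DyePairConstants | None = None,
                     frame_interval: float | None = None) -> list[FretTrace]:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    pair = pair or _PAIRS.get(meta.get("pair", ""), CY3_CY5)
    dt = frame_interval or float(meta.get("frame_interval_s", 0.1))
    out = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(FretTrace(donor=grp["I_D"].to_numpy(float),
                             acceptor=grp["I_A"].to_numpy(float),
                             pair=pair, frame_interval=dt, trace_id=str(tid)))
    return out
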