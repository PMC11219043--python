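"""Trace file I/O and dataset round-trip.

One plain-text file per test: two tab-separated columns (time_s,
position_deg) with a one-line header, plus a YAML sidecar
(``<stem>.meta.yaml``) holding the test metadata (animal, group, protocol,
block/test indices, stimulus frequency and peak velocity, and — for
synthetic data — the ground-truth gain).  Values are written with full
double precision so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EyeTrace, FormatError
from .synthetic import CohortDataset

__all__ = [
    "sidecar_path",
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_traces",
]

#: relative timestep jitter tolerated before a file is declared non-uniform
UNIFORMITY_TOL = 1e-6


def sidecar_path(trace_path: str | Path) -> Path:
    return Path(trace_path).with_suffix("").with_suffix(".meta.yaml")


def write_trace(trace: EyeTrace, path: str | Path) -> None:
    """Write a trace and its metadata sidecar."""
    path = Path(path)
    data = np.column_stack((trace.time, trace.position))
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header="time_s\tposition_deg")
    meta = {k: _plain(v) for k, v in trace.metadata.items()}
    meta["rate_hz"] = float(trace.rate)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def read_trace(path: str | Path, sidecar: str | Path | None = None) -> EyeTrace:
    """Read a two-column trace file and its sidecar.

    The sampling rate is inferred from the median timestep; timestamps
    deviating from uniformity by more than 1 ppm of the timestep raise a
    :class:`FormatError`, as does a missing sidecar.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t")
    except ValueError as exc:
        raise FormatError(f"{path}: not a two-column numeric file ({exc})") from exc
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 3:
        raise FormatError(f"{path}: expected >=3 rows of (time_s, position_deg)")
    t, pos = data[:, 0], data[:, 1]
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > UNIFORMITY_TOL * step + 1e-12):
        raise FormatError(f"{path}: non-uniform or non-monotone sampling")
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    rate = float(meta.pop("rate_hz", 1.0 / step))
    return EyeTrace(pos, rate, t0=float(t[0]), metadata=meta)


def _trace_filename(row: pd.Series) -> str:
    return (
        f"{row['animal']}_b{int(row['block_index']):03d}_t{int(row['test_index'])}.tsv"
    )


def write_dataset(dataset: CohortDataset, outdir: str | Path) -> pd.DataFrame:
    """Write every trace of a simulated cohort plus the cohort table.

    Returns the cohort table with a ``file`` column.  Traces land in
    ``<outdir>/traces/``; the table in ``<outdir>/cohort.csv``.
    """
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    tracedir.mkdir(parents=True, exist_ok=True)
    table = dataset.table.copy()
    files = []
    for _, row in table.iterrows():
        fname = _trace_filename(row)
        write_trace(dataset.traces[int(row["trace"])], tracedir / fname)
        files.append(f"traces/{fname}")
    table["file"] = files
    table = table.drop(columns=["trace"])
    table.to_csv(outdir / "cohort.csv", index=False)
    return table


def read_traces(indir: str | Path) -> list[EyeTrace]:
    """Read every ``*.tsv`` trace under ``indir`` (recursively), sorted by
    path for deterministic downstream ordering."""
    indir = Path(indir)
    paths = sorted(indir.rglob("*.tsv"))
    return [read_trace(p) for p in paths]
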