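"""CSV series interchange and run manifests.

Runs travel as plain CSV, one file per run with channels as columns (a
layout that fits all three testbeds as well as typical physiological
exports), plus a ``manifest.csv`` mapping each file to its ground truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .systems import LabeledRun, MultivariateSeries, Truth

__all__ = ["read_series", "write_series", "write_runs", "read_runs"]


def read_series(path, dt: float = 1.0) -> MultivariateSeries:
    """Read a numeric CSV (channels as columns, optional header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty, not a series")
    with open(path) as fh:
        first = fh.readline()
    header = 0
    for tok in first.strip().split(","):
        try:
            float(tok)
            header = None
            break
        except ValueError:
            continue
    df = pd.read_csv(path, header=header, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"{path} contains no data rows")
    return MultivariateSeries(values=values, dt=dt)


def write_series(series: MultivariateSeries, path) -> None:
    """Write a series as CSV with ``ch0..ch{q-1}`` headers, full precision."""
    cols = [f"ch{i}" for i in range(series.q)]
    # pandas' default float formatting is the shortest roundtripping repr
    pd.DataFrame(series.values, columns=cols).to_csv(path, index=False)


def write_runs(runs, out_dir, seed: int | None = None) -> Path:
    """Write one CSV per run plus a manifest with the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, run in enumerate(runs):
        name = f"run_{i:04d}.csv"
        write_series(run.series, out / name)
        truth = run.series.truth
        rows.append({
            "file": name,
            "t_p": "" if run.t_p is None else run.t_p,
            "delta_h": run.delta_h,
            "params_before": "" if truth is None else _fmt_param(truth.before),
            "params_after": "" if truth is None else _fmt_param(truth.after),
            "seed": "" if seed is None else seed,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _fmt_param(p) -> str:
    if p is None:
        return ""
    if isinstance(p, np.ndarray):
        return ";".join(str(int(v)) for v in p.ravel())
    return str(p)


def read_runs(run_dir) -> list[LabeledRun]:
    """Load runs back from a directory written by :func:`write_runs`."""
    run_dir = Path(run_dir)
    manifest = pd.read_csv(run_dir / "manifest.csv")
    runs = []
    for _, row in manifest.iterrows():
        series = read_series(run_dir / row["file"])
        t_p = None if pd.isna(row["t_p"]) or row["t_p"] == "" else int(row["t_p"])
        delta_h = float(row["delta_h"]) if not pd.isna(row["delta_h"]) else 0.0
        series = MultivariateSeries(
            values=series.values, dt=series.dt,
            truth=Truth(t_p=t_p, delta_h=delta_h))
        runs.append(LabeledRun(series=series, t_p=t_p, delta_h=delta_h))
    return runs
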