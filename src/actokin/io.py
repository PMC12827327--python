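"""File-format plumbing: trace CSVs, filament-field CSVs, manifests.

Trace CSV convention (written by the simulators): long format with
columns ``time_s, signal, condition_id``.  Generic plate-reader
exports (wide format: one time column, one signal column per well) are
read through a configurable column map.  Every stochastic artifact is
written next to a JSON manifest recording parameters and seed.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import FluorescenceTrace
from .tirf import Filament, FilamentField

__all__ = [
    "TraceFormatError",
    "read_trace_csv",
    "write_trace_csv",
    "write_field_csv",
    "read_field_csv",
    "write_manifest",
    "load_config",
    "spawn_seeds",
]

FLOAT_FMT = "%.9g"  # 9 significant digits for reproducible text output


class TraceFormatError(ValueError):
    """A delimited trace file violates the expected layout."""


def _check_time(t: np.ndarray, label: str) -> None:
    if not np.all(np.isfinite(t)):
        raise TraceFormatError(f"{label}: non-finite time values")
    if not np.all(np.diff(t) > 0):
        raise TraceFormatError(f"{label}: time column is not strictly increasing")


def read_trace_csv(
    path: str | Path,
    column_map: Optional[dict] = None,
    time_unit: str = "s",
) -> dict[str, FluorescenceTrace]:
    """Read traces from CSV, one trace per condition.

    Long format (``time_s, signal, condition_id``) is detected
    automatically; otherwise the file is treated as wide format whose
    first column (or ``column_map['time']``) is time and every other
    numeric column one trace.  ``time_unit`` may be ``'s'`` or
    ``'min'`` (converted to seconds).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    if time_unit not in ("s", "min"):
        raise ValueError("time_unit must be 's' or 'min'")
    factor = 60.0 if time_unit == "min" else 1.0
    column_map = column_map or {}

    long_cols = {"time_s", "signal", "condition_id"}
    if long_cols.issubset(df.columns):
        traces: dict[str, FluorescenceTrace] = {}
        for cond, grp in df.groupby("condition_id", sort=False):
            cond = str(cond)
            if cond in traces:
                raise TraceFormatError(f"duplicate condition label {cond!r}")
            t = _numeric(grp["time_s"], path, "time_s") * factor
            f = _numeric(grp["signal"], path, "signal")
            _check_time(t, f"{path} [{cond}]")
            traces[cond] = FluorescenceTrace(t, f, condition=cond)
        return traces

    time_col = column_map.get("time", df.columns[0])
    if time_col not in df.columns:
        raise TraceFormatError(f"{path}: no time column {time_col!r}")
    t = _numeric(df[time_col], path, time_col) * factor
    _check_time(t, str(path))
    signal_cols = column_map.get(
        "signals", [c for c in df.columns if c != time_col]
    )
    if not signal_cols:
        raise TraceFormatError(f"{path}: no signal columns")
    if len(set(signal_cols)) != len(signal_cols):
        raise TraceFormatError(f"{path}: duplicate condition labels")
    traces = {}
    for col in signal_cols:
        f = _numeric(df[col], path, col)
        traces[str(col)] = FluorescenceTrace(t.copy(), f, condition=str(col))
    return traces


def _numeric(series: pd.Series, path: Path, col: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = np.nonzero(values.isna().to_numpy() & series.notna().to_numpy())[0]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise TraceFormatError(f"{path}: non-numeric cells in {col!r} at rows {rows}")
    if values.isna().any():
        rows = ", ".join(str(i + 2) for i in np.nonzero(values.isna().to_numpy())[0][:5])
        raise TraceFormatError(f"{path}: missing cells in {col!r} at rows {rows}")
    return values.to_numpy(dtype=float)


def write_trace_csv(
    traces: dict[str, FluorescenceTrace] | Sequence[tuple[str, FluorescenceTrace]],
    path: str | Path,
) -> None:
    """Write traces in the long format ``time_s, signal, condition_id``."""
    items = traces.items() if isinstance(traces, dict) else traces
    frames = [
        pd.DataFrame(
            {"time_s": tr.t, "signal": tr.f, "condition_id": str(cond)}
        )
        for cond, tr in items
    ]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_field_csv(field: FilamentField, path: str | Path) -> None:
    """Filament-field round-trip: one row per filament-frame, plus a
    JSON header (same stem, ``.json``) with area/threshold metadata."""
    rows = []
    for fid, fil in enumerate(field.filaments):
        times = field.frame_times[fil.first_frame:fil.first_frame + len(fil.lengths)]
        for tt, ll in zip(times, fil.lengths):
            rows.append((fid, tt, ll))
    df = pd.DataFrame(rows, columns=["filament_id", "t_s", "length_um"])
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    header = {
        "area_um2": field.area,
        "detect_min_length_um": field.detect_min_length,
        "frame_times_s": [float(x) for x in field.frame_times],
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_field_csv(path: str | Path) -> FilamentField:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    frame_times = np.asarray(header["frame_times_s"], dtype=float)
    df = pd.read_csv(path)
    filaments = []
    for _, grp in df.groupby("filament_id", sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        first = int(np.searchsorted(frame_times, t[0] - 1e-9))
        filaments.append(
            Filament(
                birth_time=float(t[0]), first_frame=first,
                lengths=grp["length_um"].to_numpy(dtype=float),
            )
        )
    return FilamentField(
        area=float(header["area_um2"]), frame_times=frame_times,
        filaments=filaments,
        detect_min_length=float(header["detect_min_length_um"]),
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON manifest (parameters, seed, package version)."""
    from . import __version__

    payload = {"actokin_version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into independent per-stage seeds.

    Uses NumPy's SeedSequence spawning, so adding a later stage never
    perturbs the streams of earlier stages.  Returned seeds are < 2^31.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
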