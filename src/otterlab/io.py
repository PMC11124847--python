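"""Delimited-text formats for signals, datasets and reports.

Signals travel as two-column CSV (time_s, signal) with optional ``#``
comment lines carrying metadata (``# key: value``).  Datasets are a
directory: ``signals.csv`` (one row per signal, columns are the shared
time grid), ``manifest.csv`` (row index, labels, truth parameters) and
``provenance.yaml`` (generation spec, seed, package version).  Floats are
written with 12 significant digits so a write/read round-trip is lossless
at that precision.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import Dataset

__all__ = ["Signal", "SignalFormatError", "read_signal", "write_signal", "save_dataset", "load_dataset"]

_FLOAT_FMT = "%.12g"


class SignalFormatError(ValueError):
    """Raised when a signal file violates the two-column contract."""


@dataclass
class Signal:
    """One transient record: time (s), signal (detector units), metadata."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")


def read_signal(path) -> Signal:
    """Parse a two-column delimited signal file, enforcing a finite,
    strictly increasing time column (errors carry the offending line)."""
    path = Path(path)
    meta: dict = {}
    times, vals = [], []
    seen_data = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if not seen_data and any(not _is_number(p) for p in parts):
                continue  # header row
            seen_data = True
            if len(parts) < 2 or not all(_is_number(p) for p in parts[:2]):
                raise SignalFormatError(f"{path}:{lineno}: expected two numeric columns, got {line!r}")
            times.append(float(parts[0]))
            vals.append(float(parts[1]))
    if not times:
        raise SignalFormatError(f"{path}: no data rows")
    t = np.asarray(times)
    y = np.asarray(vals)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise SignalFormatError(f"{path}: non-finite values")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SignalFormatError(f"{path}: time column not strictly increasing near data row {bad[0] + 2}")
    return Signal(t=t, y=y, meta=meta)


def write_signal(sig: Signal, path) -> None:
    """Write a signal as CSV with metadata comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in sig.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s,signal\n")
        for ti, yi in zip(sig.t, sig.y):
            fh.write(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % yi}\n")


def save_dataset(ds: Dataset, out_dir) -> Path:
    """Write a dataset directory: bundled signal matrix, label/truth
    manifest, and provenance (spec + seed + package version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = ",".join(_FLOAT_FMT % t for t in ds.grid)
    with (out / "signals.csv").open("w") as fh:
        fh.write("# columns: signal values on the shared time grid (seconds)\n")
        fh.write(header + "\n")
        np.savetxt(fh, ds.signals, delimiter=",", fmt=_FLOAT_FMT)
    manifest = pd.concat(
        [ds.labels.add_prefix("label_"), ds.truth.add_prefix("truth_")], axis=1
    )
    manifest.insert(0, "row", np.arange(len(manifest)))
    manifest.to_csv(out / "manifest.csv", index=False, float_format=_FLOAT_FMT)
    prov = dict(ds.provenance)
    prov["package_version"] = __version__
    with (out / "provenance.yaml").open("w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    return out


def load_dataset(in_dir) -> Dataset:
    """Read back a dataset directory written by :func:`save_dataset`."""
    src = Path(in_dir)
    with (src / "signals.csv").open() as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    grid = np.asarray([float(x) for x in lines[0].split(",")])
    signals = np.loadtxt(_io.StringIO("".join(lines[1:])), delimiter=",", ndmin=2)
    manifest = pd.read_csv(src / "manifest.csv")
    labels = manifest[[c for c in manifest.columns if c.startswith("label_")]].rename(
        columns=lambda c: c[len("label_") :]
    )
    truth = manifest[[c for c in manifest.columns if c.startswith("truth_")]].rename(
        columns=lambda c: c[len("truth_") :]
    )
    prov_path = src / "provenance.yaml"
    prov = yaml.safe_load(prov_path.read_text()) if prov_path.exists() else {}
    return Dataset(signals=signals, grid=grid, labels=labels, truth=truth, provenance=prov or {})


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
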