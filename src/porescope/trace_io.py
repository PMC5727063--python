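"""Reading and writing of current traces, pulse tables and derived artifacts.

All quantities are stored in SI units: currents in amperes, times in
seconds.  Picoamperes and milliseconds appear only at the presentation
layer.  Two trace formats are supported:

* ``raw`` — little-endian 32-bit floats (amperes) plus a JSON sidecar
  ``<file>.json`` holding at least ``sampling_rate_hz``; arbitrary
  provenance keys are preserved in :attr:`CurrentTrace.meta`.
* ``tsv`` — two columns ``time_s``/``current_a`` with a header line.

All writers are deterministic given identical inputs and all readers
reject non-finite samples loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "Histogram2D",
    "read_trace",
    "write_trace",
    "read_pulse_table",
    "write_pulse_table",
    "write_histogram2d",
    "read_histogram2d",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_manifest",
    "read_manifest",
    "write_json_report",
]

PULSE_TABLE_COLUMNS = ["pulse_id", "t_s", "t_e", "peak_time", "I_p", "t_d", "source"]


@dataclass
class CurrentTrace:
    """Sampled ionic current with sampling-rate metadata.

    Parameters
    ----------
    samples : ndarray
        Ionic current in amperes.
    sampling_rate : float
        Sampling rate in Hz (1 MHz for the reference recordings).
    meta : dict
        Free-form provenance (geometry, seed, bias voltage, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class Histogram2D:
    """2-D event-overlay histogram (time x current), as plotted from
    stacked pulse windows.

    ``counts[i, j]`` is the number of samples in time bin ``i`` and
    current bin ``j``; edges are in seconds and amperes.
    """

    counts: np.ndarray
    t_edges: np.ndarray
    i_edges: np.ndarray

    @property
    def time_bin(self) -> float:
        return float(self.t_edges[1] - self.t_edges[0]) if len(self.t_edges) > 1 else 0.0

    @property
    def current_bin(self) -> float:
        return float(self.i_edges[1] - self.i_edges[0]) if len(self.i_edges) > 1 else 0.0


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_trace(trace: CurrentTrace, path, format: str = "raw") -> Path:
    """Write a trace; returns the path written.

    ``raw`` stores samples as float32 little-endian amperes with a JSON
    sidecar; ``tsv`` stores two columns with a header.
    """
    path = Path(path)
    if format == "raw":
        trace.samples.astype("<f4").tofile(path)
        sidecar = {"sampling_rate_hz": trace.sampling_rate}
        sidecar.update(trace.meta)
        _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, default=str))
    elif format == "tsv":
        t = trace.times
        with open(path, "w") as fh:
            fh.write("time_s\tcurrent_a\n")
            for ti, ii in zip(t, trace.samples):
                fh.write(f"{ti:.9e}\t{ii:.9e}\n")
    else:
        raise ValueError(f"unknown trace format: {format!r}")
    return path


def read_trace(path, format: str | None = None) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    The format is inferred from the file name when not given
    (``.tsv``/``.txt`` -> tsv, otherwise raw).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tsv" if path.suffix in {".tsv", ".txt"} else "raw"
    if format == "raw":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"raw trace {path} requires its JSON sidecar {sidecar}, which is missing"
            )
        meta = json.loads(sidecar.read_text())
        try:
            rate = float(meta.pop("sampling_rate_hz"))
        except KeyError as exc:
            raise ValueError(f"sidecar {sidecar} lacks 'sampling_rate_hz'") from exc
        samples = np.fromfile(path, dtype="<f4").astype(float)
        return CurrentTrace(samples, rate, meta)
    if format == "tsv":
        data = pd.read_csv(path, sep="\t")
        t = data.iloc[:, 0].to_numpy(dtype=float)
        i = data.iloc[:, 1].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"tsv trace {path} has fewer than two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"tsv trace {path} is not uniformly sampled")
        return CurrentTrace(i, 1.0 / float(dt[0]), {"source": str(path)})
    raise ValueError(f"unknown trace format: {format!r}")


def write_pulse_table(table: pd.DataFrame, path) -> Path:
    """Write a pulse table (one row per detected pulse) as TSV."""
    missing = [c for c in PULSE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pulse table lacks columns: {missing}")
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_pulse_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    num = table[["t_s", "t_e", "peak_time", "I_p", "t_d"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise ValueError(f"pulse table {path} contains non-finite values")
    bad = (table["t_s"] >= table["peak_time"]) | (table["peak_time"] >= table["t_e"])
    if bad.any():
        raise ValueError(f"pulse table {path} violates t_s < peak_time < t_e")
    if (table["I_p"] <= 0).any():
        raise ValueError(f"pulse table {path} has non-positive I_p")
    return table


def write_histogram2d(hist: Histogram2D, path) -> Path:
    """Write a 2-D histogram as a TSV matrix with bin-edge header rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# time_bin_s\t{hist.time_bin:.9e}\n")
        fh.write(f"# current_bin_a\t{hist.current_bin:.9e}\n")
        fh.write("# t_edges_s\t" + "\t".join(f"{e:.9e}" for e in hist.t_edges) + "\n")
        fh.write("# i_edges_a\t" + "\t".join(f"{e:.9e}" for e in hist.i_edges) + "\n")
        for row in hist.counts:
            fh.write("\t".join(str(int(c)) for c in row) + "\n")
    return path


def read_histogram2d(path) -> Histogram2D:
    t_edges = i_edges = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# t_edges_s"):
                t_edges = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("# i_edges_a"):
                i_edges = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("#"):
                continue
            else:
                rows.append([int(x) for x in line.split()])
    if t_edges is None or i_edges is None:
        raise ValueError(f"histogram file {path} lacks edge header rows")
    return Histogram2D(np.array(rows), t_edges, i_edges)


def write_feature_matrix(matrix: pd.DataFrame, path) -> Path:
    """Write a feature matrix (one row per pulse) as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_feature_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t")
    numeric = matrix.select_dtypes(include=[np.number]).to_numpy()
    if not np.all(np.isfinite(numeric)):
        raise ValueError(f"feature matrix {path} contains non-finite values")
    return matrix


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    """Write a dataset manifest (label, pulse_id, file, t0) as TSV."""
    for col in ("label", "pulse_id", "file", "t0"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks column {col!r}")
    manifest.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(report: dict, path) -> Path:
    """Write a JSON report deterministically (sorted keys, stable floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return path
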