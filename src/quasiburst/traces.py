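"""Uniformly sampled time series with provenance.

A :class:`Trace` is the exchange format between the simulators, the signal
tools and the burst extractor: a 1-D float array, its sampling interval in
milliseconds, a semantic label and the seed / parameter hash that produced
it. Traces round-trip through HDF5 (one group per label) and two-column
CSV text.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np

__all__ = ["Trace", "params_hash", "save_traces", "load_traces"]


def params_hash(params: Mapping[str, Any] | None) -> str:
    """Short stable hash of a parameter mapping, for provenance stamps."""
    if params is None:
        return ""
    blob = json.dumps({k: params[k] for k in sorted(params)}, sort_keys=True, default=float)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class Trace:
    values: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""
    seed: int | None = None
    params_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a Trace holds a single 1-D series")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        return self.dt * len(self.values)

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz (dt is in ms)."""
        return 1000.0 / self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    def crop(self, t_start: float | None = None, t_end: float | None = None) -> "Trace":
        """Slice by time (ms); boundaries snap to the sample grid."""
        i0 = 0 if t_start is None else max(0, int(np.ceil((t_start - self.t0) / self.dt)))
        i1 = len(self) if t_end is None else min(len(self), int((t_end - self.t0) / self.dt) + 1)
        return replace(self, values=self.values[i0:i1], t0=self.t0 + i0 * self.dt)

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header=f"time_ms,{self.label or 'value'}",
            comments="",
        )

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "Trace":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, v = data[:, 0], data[:, 1]
        dts = np.diff(t)
        if len(dts) and (dts.max() - dts.min()) > 1e-6 * dts.mean():
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return cls(values=v, dt=float(dts.mean()) if len(dts) else 1.0,
                   t0=float(t[0]), label=label)


def save_traces(path: str | Path, traces: Mapping[str, Trace],
                attrs: Mapping[str, Any] | None = None) -> None:
    """Write traces to HDF5, one group per label."""
    with h5py.File(path, "w") as f:
        for name, tr in traces.items():
            g = f.create_group(name)
            g.create_dataset("values", data=tr.values)
            g.attrs["dt"] = tr.dt
            g.attrs["t0"] = tr.t0
            g.attrs["label"] = tr.label or name
            if tr.seed is not None:
                g.attrs["seed"] = tr.seed
            g.attrs["params_hash"] = tr.params_hash
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_traces(path: str | Path) -> dict[str, Trace]:
    out: dict[str, Trace] = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            out[name] = Trace(
                values=g["values"][...],
                dt=float(g.attrs["dt"]),
                t0=float(g.attrs.get("t0", 0.0)),
                label=str(g.attrs.get("label", name)),
                seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
                params_hash=str(g.attrs.get("params_hash", "")),
            )
    return out
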