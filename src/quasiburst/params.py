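"""Network parameter sets for the stochastic E-I (PING) model.

The model is a fully connected network of two-state (quiescent/active)
excitatory and inhibitory neurons whose population activities obey a
stochastic Wilson-Cowan system. Twelve biophysical parameters define it:
per-population decay rates ``alpha``, maximal activation rates ``beta``,
external inputs ``h``, four synaptic gains ``W_**`` and the two population
sizes. Rates are per millisecond throughout, so e.g. ``alpha_E = 0.1``
means a 10 ms mean active (refractory) period for an excitatory cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["NetworkParams", "DEFAULT_PARAMS", "WORKING_POINTS", "load_params"]


@dataclass(frozen=True)
class NetworkParams:
    """Biophysical parameters of the two-population spiking network.

    Synaptic gains are total population-to-population weights (each single
    synapse carries ``W/N`` of it); all four are stored as non-negative
    magnitudes, the inhibitory sign is applied in the input formulas.
    """

    alpha_E: float = 0.1
    alpha_I: float = 0.2
    beta_E: float = 1.0
    beta_I: float = 2.0
    h_E: float = -3.8
    h_I: float = -8.0
    W_ee: float = 27.4
    W_ii: float = 1.3
    W_ei: float = 26.3
    W_ie: float = 32.0
    N_E: int = 800
    N_I: int = 200

    def __post_init__(self) -> None:
        for name in ("alpha_E", "alpha_I", "beta_E", "beta_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.alpha_E <= 0 or self.alpha_I <= 0:
            raise ValueError("decay rates alpha_E, alpha_I must be positive")
        for name in ("W_ee", "W_ii", "W_ei", "W_ie"):
            if getattr(self, name) < 0:
                raise ValueError(f"synaptic strength {name} must be >= 0")
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be at least 1")

    # -- derived inputs ----------------------------------------------------
    def input_E(self, E: float, I: float) -> float:
        """Total input to an excitatory cell at population activities (E, I)."""
        return self.W_ee * E - self.W_ei * I + self.h_E

    def input_I(self, E: float, I: float) -> float:
        """Total input to an inhibitory cell at population activities (E, I)."""
        return self.W_ie * E - self.W_ii * I + self.h_I

    @property
    def c_EI(self) -> float:
        """Population-size ratio sqrt(N_E / N_I)."""
        return float((self.N_E / self.N_I) ** 0.5)

    def with_overrides(self, **kwargs: Any) -> "NetworkParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float | int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NetworkParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


#: Canonical parameter set used throughout (gamma-range transient synchrony).
DEFAULT_PARAMS = NetworkParams()

#: Four standard working points along the recurrent-excitation axis, ordered
#: from far below the oscillatory transition (a) to just below it (d).
WORKING_POINTS: dict[str, NetworkParams] = {
    "point_a": DEFAULT_PARAMS.with_overrides(W_ee=20.4),
    "point_b": DEFAULT_PARAMS.with_overrides(W_ee=27.4),
    "point_c": DEFAULT_PARAMS.with_overrides(W_ee=28.4),
    "point_d": DEFAULT_PARAMS.with_overrides(W_ee=29.4),
}


def load_params(path: str | Path, **overrides: Any) -> NetworkParams:
    """Read a flat key:value parameter file (YAML or JSON).

    Keys must match :class:`NetworkParams` field names; unknown keys are
    rejected. ``overrides`` are applied after the file is read.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter names to values")
    data.update(overrides)
    return NetworkParams.from_dict(data)
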