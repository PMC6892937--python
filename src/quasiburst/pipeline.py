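"""Configuration-driven experiments tying the modules together.

An experiment = parameter set -> simulator level -> LFP/envelope -> burst
extraction -> summary, with every random element seeded and a manifest
recording the configuration hash for reproducibility. Microscopic and
rate-level activities are rescaled by sqrt(N_E) (resp. sqrt(N_I)) before
analysis so their LFP fluctuations are in the same units as the linear
theory and the envelope thresholds derived from R apply unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .bursts import (Burst, BurstSummary, bursts_to_frame, extract_bursts,
                     summarize, threshold_from_envelope, threshold_from_mode)
from .fpt import EnvelopeLaw, closed_form_spec, empirical_spec, mean_burst_duration
from .model import ReducedParams, lna_coefficients, reduce_params, solve_fixed_point
from .params import WORKING_POINTS, NetworkParams, load_params
from .signals import analytic_signal, make_lfp
from .simulate import (SimResult, simulate_gillespie, simulate_lna,
                       simulate_rate_sde, simulate_sam)
from .traces import Trace, save_traces

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_fixture"]

_LEVELS = ("gillespie", "rate_sde", "lna", "sam")
_DEFAULT_DT = {"gillespie": 0.5, "rate_sde": 0.01, "lna": 0.1, "sam": 0.05}


@dataclass(frozen=True)
class ExperimentConfig:
    level: str = "sam"
    preset: str | None = None
    params_file: str | None = None
    params: dict[str, Any] = field(default_factory=dict)
    duration: float = 100_000.0  # ms
    dt: float | None = None
    dt_out: float = 0.5
    seed: int = 0
    band: tuple[float, float] = (20.0, 100.0)
    burst_convention: str = "closed_form"  # or "empirical"
    d_convention: str = "sam"
    burn_in: float = 500.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"level must be one of {_LEVELS}, got {self.level!r}")
        if self.preset is not None and self.preset not in WORKING_POINTS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(WORKING_POINTS)}")
        if self.burst_convention not in ("closed_form", "empirical"):
            raise ValueError(f"unknown burst convention {self.burst_convention!r}")
        if self.d_convention not in ("sam", "swapped"):
            raise ValueError(f"unknown D convention {self.d_convention!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        return cls.from_dict(data)

    def network_params(self) -> NetworkParams:
        if self.params_file:
            return load_params(self.params_file, **self.params)
        base = WORKING_POINTS[self.preset] if self.preset else NetworkParams()
        return base.with_overrides(**self.params) if self.params else base

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    reduced: ReducedParams
    traces: dict[str, Trace]
    envelope: Trace
    lfp: Trace
    bursts: list[Burst]
    summary: BurstSummary
    theory_duration: float
    manifest: dict[str, Any]


def _simulate(config: ExperimentConfig, params: NetworkParams,
              reduced: ReducedParams) -> SimResult:
    dt = config.dt if config.dt is not None else _DEFAULT_DT[config.level]
    if config.level == "gillespie":
        return simulate_gillespie(params, config.duration, seed=config.seed,
                                  dt_out=dt, burn_in=config.burn_in)
    if config.level == "rate_sde":
        return simulate_rate_sde(params, config.duration, dt=dt, seed=config.seed,
                                 dt_out=config.dt_out, burn_in=config.burn_in)
    if config.level == "lna":
        coeffs = lna_coefficients(params)
        return simulate_lna(coeffs, config.duration, dt=dt, seed=config.seed,
                            burn_in=config.burn_in)
    return simulate_sam(reduced, config.duration, dt=dt, seed=config.seed,
                        burn_in=config.burn_in)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run one seeded experiment end to end.

    Reruns with the same configuration are bit-identical. When
    ``config.out_dir`` is set, traces (HDF5), the burst table (CSV), the
    summary and a provenance manifest (JSON) are written there.
    """
    params = config.network_params()
    reduced = reduce_params(params, d_convention=config.d_convention)
    sim = _simulate(config, params, reduced)

    if config.level == "sam":
        lfp = sim["lfp_E"]
        env = sim["envelope"]
    else:
        if config.level in ("gillespie", "rate_sde"):
            act = sim["activity_E"]
            scaled = act.with_values(
                (act.values - act.values.mean()) * math.sqrt(params.N_E),
                label="lfp_E",
            )
            lfp = make_lfp(scaled, band=config.band)
        else:
            lfp = sim["lfp_E"]
        env = analytic_signal(lfp).envelope

    if config.burst_convention == "closed_form" and reduced.R is not None:
        b = threshold_from_mode(reduced.R)
    else:
        b = threshold_from_envelope(env.values)
    omega0 = reduced.omega0
    bursts = extract_bursts(env, lfp, threshold=b, omega0=omega0, band=config.band)
    window = 2.0 * (2.0 * math.pi / omega0) if omega0 else math.nan
    summary = summarize(bursts, total_time=env.duration,
                        threshold_b=b, criterion_window=window)

    theory = math.nan
    if reduced.regime == "transient_synchrony" and reduced.D is not None:
        law = EnvelopeLaw(nu=reduced.nu, D=reduced.D)
        spec = (closed_form_spec(law) if config.burst_convention == "closed_form"
                else empirical_spec(env.values))
        theory = mean_burst_duration(law, spec)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "params": params.to_dict(),
        "reduced": {
            "nu": reduced.nu, "omega0": reduced.omega0, "D": reduced.D,
            "R": reduced.R, "regime": reduced.regime,
            "d_convention": reduced.d_convention,
        },
        "n_bursts": summary.n_bursts,
        "mean_duration_ms": summary.mean_duration,
        "freq_dev_sd_hz": summary.freq_dev_sd,
        "theory_duration_ms": theory,
    }

    result = ExperimentResult(
        config=config, reduced=reduced, traces=dict(sim.traces), envelope=env,
        lfp=lfp, bursts=bursts, summary=summary, theory_duration=theory,
        manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_traces(out / "traces.h5", sim.traces, attrs={"config_hash": config.config_hash()})
        bursts_to_frame(bursts).to_csv(out / "bursts.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return result


# ---------------------------------------------------------------------------
# Synthetic fixtures with analytically known properties
# ---------------------------------------------------------------------------

def make_fixture(kind: str, spec: Mapping[str, Any] | None = None) -> dict[str, Trace]:
    """Deterministic synthetic traces with known ground truth.

    Kinds: ``crossing_envelope`` (piecewise envelope with designed burst
    boundaries), ``pure_tone``, ``chirp``, ``ou_pair`` (seeded envelope
    process with known (nu, D)).
    """
    spec = dict(spec or {})
    if kind == "crossing_envelope":
        return _crossing_envelope(**spec)
    if kind == "pure_tone":
        return _pure_tone(**spec)
    if kind == "chirp":
        return _chirp(**spec)
    if kind == "ou_pair":
        return _ou_pair(**spec)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _crossing_envelope(
    n_bursts: int = 3,
    threshold: float = 1.0,
    baseline: float = 0.2,
    peak: float = 2.0,
    burst_ms: float = 60.0,
    gap_ms: float = 80.0,
    ramp_ms: float = 10.0,
    dt: float = 0.5,
) -> dict[str, Trace]:
    """Trapezoidal bursts over a low baseline; each plateau sits well above
    the trace mean for its full length, so every designed burst passes any
    super-mean criterion shorter than the plateau. The b-crossings of ramp
    k are at gap + k (burst + gap) +/- known ramp offsets."""
    total = gap_ms + n_bursts * (burst_ms + gap_ms)
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, baseline)
    for k in range(n_bursts):
        t0 = gap_ms + k * (burst_ms + gap_ms)
        rise = (t >= t0) & (t < t0 + ramp_ms)
        top = (t >= t0 + ramp_ms) & (t < t0 + burst_ms - ramp_ms)
        fall = (t >= t0 + burst_ms - ramp_ms) & (t < t0 + burst_ms)
        v[rise] = baseline + (peak - baseline) * (t[rise] - t0) / ramp_ms
        v[top] = peak
        v[fall] = baseline + (peak - baseline) * (t0 + burst_ms - t[fall]) / ramp_ms
    return {"envelope": Trace(v, dt=dt, label="envelope")}


def _pure_tone(freq_hz: float = 85.0, duration: float = 1000.0,
               amplitude: float = 1.0, dt: float = 0.5) -> dict[str, Trace]:
    t = np.arange(0.0, duration, dt)
    v = amplitude * np.cos(2.0 * math.pi * freq_hz * t / 1000.0)
    return {"lfp": Trace(v, dt=dt, label="pure_tone")}


def _chirp(f0_hz: float = 60.0, f1_hz: float = 90.0, duration: float = 1000.0,
           dt: float = 0.5) -> dict[str, Trace]:
    from scipy.signal import chirp as _scipy_chirp

    t = np.arange(0.0, duration, dt)
    v = _scipy_chirp(t / 1000.0, f0=f0_hz, t1=duration / 1000.0, f1=f1_hz)
    return {"lfp": Trace(v, dt=dt, label="chirp")}


def _ou_pair(nu: float = 0.0182, D: float = 0.0705, omega0: float = 0.5,
             duration: float = 20_000.0, dt: float = 0.5,
             seed: int = 0) -> dict[str, Trace]:
    red = ReducedParams(nu=nu, omega0=omega0, D=D, R=math.sqrt(D / (2 * nu)),
                        alpha_ratio=1.0, delta=0.0, regime="transient_synchrony")
    sim = simulate_sam(red, duration=duration, dt=dt, seed=seed, burn_in=0.0)
    return dict(sim.traces)
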