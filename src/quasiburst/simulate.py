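"""Simulators for the same rhythm at three levels of description.

* :func:`simulate_gillespie` — exact stochastic simulation of the
  microscopic two-state network, run on the aggregate Markov chain over
  the active counts (k, l) with four reaction channels. For the
  homogeneous all-to-all network this is statistically exact and orders of
  magnitude faster than a per-neuron event queue; a per-neuron raster is
  recovered afterwards by exchangeability (uniform assignment of each
  aggregate event to an eligible neuron).
* :func:`simulate_rate_sde` — Euler-Maruyama integration of the nonlinear
  population rate SDEs with the system-size-scaled multiplicative noise.
* :func:`simulate_lna` — the linear fluctuation SDEs around the fixed
  point. Being linear, they are sampled with the exact Gaussian
  transition (matrix-exponential propagator and exact one-step noise
  covariance), so the stationary covariance is unbiased at any step size.
* :func:`simulate_sam` — the reduced envelope-phase process, realised
  through the pair of independent Ornstein-Uhlenbeck processes whose
  modulus and angle are the envelope and phase (this avoids the negative
  envelope excursions a direct discretisation would produce). OU updates
  are exact.

All simulators are pure functions of (parameters, duration, dt, seed).
The response function inside the microscopic and rate-level kernels is the
logistic sigmoid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit
from scipy.linalg import expm, solve_lyapunov
from scipy.signal import lfilter

from .model import LNACoefficients, ReducedParams, solve_fixed_point
from .params import NetworkParams
from .traces import Trace, params_hash

__all__ = [
    "SimResult",
    "simulate_gillespie",
    "simulate_rate_sde",
    "simulate_lna",
    "simulate_sam",
    "stationary_covariance",
]

DEFAULT_BURN_IN = 500.0  # ms discarded from every simulator output


@dataclass
class SimResult:
    """Bundle of labelled traces plus run metadata (clip counts, rasters...)."""

    traces: dict[str, Trace]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> Trace:
        return self.traces[key]

    def keys(self):
        return self.traces.keys()


def _derive_seed(seed: int) -> int:
    # numba kernels use the numpy legacy generator, seeded with 32 bits
    return int(np.random.default_rng(seed).integers(1, 2**31 - 1))


def _trim(tr: Trace, burn_in: float) -> Trace:
    return tr.crop(t_start=burn_in) if burn_in > 0 else tr


# ---------------------------------------------------------------------------
# Microscopic network (exact SSA on the aggregate chain)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _ssa_kernel(k0, l0, NE, NI, aE, aI, bE, bI, hE, hI,
                Wee, Wii, Wei, Wie, dt_out, n_out, seed,
                ev_t, ev_c, record):
    """Aggregate-chain SSA; fills zero-order-hold samples of (k, l).

    Returns (n_events, absorbed). When ``record`` the event stream
    (times, channels) is written into ev_t / ev_c (sized by a prior
    counting pass with the same seed)."""
    np.random.seed(seed)
    outE = np.empty(n_out)
    outI = np.empty(n_out)
    k = k0
    l = l0
    t = 0.0
    idx = 0
    n_ev = 0
    absorbed = False
    while idx < n_out:
        sE = Wee * k / NE - Wei * l / NI + hE
        sI = Wie * k / NE - Wii * l / NI + hI
        fE = 1.0 / (1.0 + math.exp(-sE))
        fI = 1.0 / (1.0 + math.exp(-sI))
        r0 = k * aE                  # E active -> quiescent
        r1 = (NE - k) * bE * fE      # E quiescent -> active
        r2 = l * aI                  # I active -> quiescent
        r3 = (NI - l) * bI * fI      # I quiescent -> active
        rtot = r0 + r1 + r2 + r3
        if rtot <= 0.0:
            absorbed = True
            while idx < n_out:
                outE[idx] = k / NE
                outI[idx] = l / NI
                idx += 1
            break
        t_new = t + (-math.log(np.random.random()) / rtot)
        while idx < n_out and idx * dt_out < t_new:
            outE[idx] = k / NE
            outI[idx] = l / NI
            idx += 1
        u = np.random.random() * rtot
        if u < r0:
            k -= 1
            c = 0
        elif u < r0 + r1:
            k += 1
            c = 1
        elif u < r0 + r1 + r2:
            l -= 1
            c = 2
        else:
            l += 1
            c = 3
        if record:
            ev_t[n_ev] = t_new
            ev_c[n_ev] = c
        n_ev += 1
        t = t_new
    return outE, outI, n_ev, absorbed


@njit(cache=False)
def _assign_neurons(channels, NE, NI, k0, l0, seed):
    """Uniformly assign each aggregate event to an eligible neuron.

    Exchangeability of the homogeneous network makes this distributionally
    identical to a per-neuron simulation. Excitatory ids are 0..NE-1,
    inhibitory ids NE..NE+NI-1."""
    np.random.seed(seed)
    permE = np.arange(NE)
    permI = np.arange(NI)
    kk = k0
    ll = l0
    ids = np.empty(len(channels), dtype=np.int64)
    for i in range(len(channels)):
        c = channels[i]
        if c == 0:  # deactivate a random active E cell
            j = np.random.randint(kk)
            n = permE[j]
            permE[j] = permE[kk - 1]
            permE[kk - 1] = n
            kk -= 1
            ids[i] = n
        elif c == 1:  # activate a random quiescent E cell
            j = kk + np.random.randint(NE - kk)
            n = permE[j]
            permE[j] = permE[kk]
            permE[kk] = n
            kk += 1
            ids[i] = n
        elif c == 2:
            j = np.random.randint(ll)
            n = permI[j]
            permI[j] = permI[ll - 1]
            permI[ll - 1] = n
            ll -= 1
            ids[i] = NE + n
        else:
            j = ll + np.random.randint(NI - ll)
            n = permI[j]
            permI[j] = permI[ll]
            permI[ll] = n
            ll += 1
            ids[i] = NE + n
    return ids


def simulate_gillespie(
    params: NetworkParams,
    duration: float,
    seed: int,
    dt_out: float = 0.5,
    record: str = "population",
    initial: tuple[int, int] | None = None,
    burn_in: float = DEFAULT_BURN_IN,
) -> SimResult:
    """Exact SSA of the two-state network; activities on a uniform grid.

    ``record="raster"`` additionally returns the per-neuron activation
    raster in ``meta["raster"]`` as (times_ms, neuron_ids) arrays.
    By default the chain starts at the rounded mean-field fixed point.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if record not in ("population", "raster"):
        raise ValueError(f"unknown record mode {record!r}")
    if initial is None:
        fp = solve_fixed_point(params)
        k0 = int(round(params.N_E * fp.E0))
        l0 = int(round(params.N_I * fp.I0))
    else:
        k0, l0 = initial
    if not (0 <= k0 <= params.N_E and 0 <= l0 <= params.N_I):
        raise ValueError("initial counts outside population bounds")

    n_out = int(round(duration / dt_out))
    s1 = _derive_seed(seed)
    p = params
    args = (k0, l0, p.N_E, p.N_I, p.alpha_E, p.alpha_I, p.beta_E, p.beta_I,
            p.h_E, p.h_I, p.W_ee, p.W_ii, p.W_ei, p.W_ie, dt_out, n_out, s1)
    empty_t = np.empty(0)
    empty_c = np.empty(0, dtype=np.int64)
    meta: dict = {}
    if record == "raster":
        # counting pass, then an identically seeded recording pass
        _, _, n_ev, _ = _ssa_kernel(*args, empty_t, empty_c, False)
        ev_t = np.empty(n_ev)
        ev_c = np.empty(n_ev, dtype=np.int64)
        outE, outI, n_ev, absorbed = _ssa_kernel(*args, ev_t, ev_c, True)
        ids = _assign_neurons(ev_c, p.N_E, p.N_I, k0, l0, _derive_seed(seed + 1))
        act = (ev_c == 1) | (ev_c == 3)
        keep = act & (ev_t >= burn_in)
        meta["raster"] = (ev_t[keep], ids[keep])
    else:
        outE, outI, n_ev, absorbed = _ssa_kernel(*args, empty_t, empty_c, False)
    if absorbed:
        warnings.warn("total reaction rate hit zero; chain absorbed before the horizon")
    meta.update(n_events=int(n_ev), absorbed=bool(absorbed))
    h = params_hash(params.to_dict())
    traces = {
        "activity_E": Trace(outE, dt=dt_out, label="activity_E", seed=seed, params_hash=h),
        "activity_I": Trace(outI, dt=dt_out, label="activity_I", seed=seed, params_hash=h),
    }
    return SimResult({k: _trim(t, burn_in) for k, t in traces.items()}, meta)


# ---------------------------------------------------------------------------
# Nonlinear rate SDEs (Euler-Maruyama)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _rate_sde_kernel(E0, I0, NE, NI, aE, aI, bE, bI, hE, hI,
                     Wee, Wii, Wei, Wie, dt, n_steps, stride, seed, outE, outI):
    np.random.seed(seed)
    E = E0
    I = I0
    sqdt = math.sqrt(dt)
    clips = 0
    oi = 0
    for i in range(n_steps):
        if i % stride == 0 and oi < len(outE):
            outE[oi] = E
            outI[oi] = I
            oi += 1
        sE = Wee * E - Wei * I + hE
        sI = Wie * E - Wii * I + hI
        fE = 1.0 / (1.0 + math.exp(-sE))
        fI = 1.0 / (1.0 + math.exp(-sI))
        gE = (1.0 - E) * bE * fE
        gI = (1.0 - I) * bI * fI
        E = E + (-aE * E + gE) * dt + math.sqrt((gE + aE * E) / NE) * sqdt * np.random.normal()
        I = I + (-aI * I + gI) * dt + math.sqrt((gI + aI * I) / NI) * sqdt * np.random.normal()
        if E < 0.0:
            E = 0.0
            clips += 1
        elif E > 1.0:
            E = 1.0
            clips += 1
        if I < 0.0:
            I = 0.0
            clips += 1
        elif I > 1.0:
            I = 1.0
            clips += 1
    return clips


def simulate_rate_sde(
    params: NetworkParams,
    duration: float,
    dt: float = 0.01,
    seed: int = 0,
    dt_out: float | None = None,
    burn_in: float = DEFAULT_BURN_IN,
    initial: tuple[float, float] | None = None,
) -> SimResult:
    """Euler-Maruyama integration of the nonlinear rate SDEs.

    Trajectories are clipped to [0, 1]; the clip count is reported in
    ``meta["clips"]`` and a warning is raised if more than 0.1% of steps
    clipped. Output is subsampled onto ``dt_out`` (defaults to dt).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if initial is None:
        fp = solve_fixed_point(params)
        initial = (fp.E0, fp.I0)
    dt_out = dt if dt_out is None else dt_out
    stride = max(1, int(round(dt_out / dt)))
    dt_out = dt * stride
    n_steps = int(round(duration / dt))
    n_out = (n_steps + stride - 1) // stride
    outE = np.empty(n_out)
    outI = np.empty(n_out)
    p = params
    clips = _rate_sde_kernel(
        initial[0], initial[1], p.N_E, p.N_I, p.alpha_E, p.alpha_I, p.beta_E,
        p.beta_I, p.h_E, p.h_I, p.W_ee, p.W_ii, p.W_ei, p.W_ie,
        dt, n_steps, stride, _derive_seed(seed), outE, outI,
    )
    if clips > 0.001 * 2 * n_steps:
        warnings.warn(f"{clips} boundary clips in {n_steps} steps (> 0.1%)")
    h = params_hash(params.to_dict())
    traces = {
        "activity_E": Trace(outE, dt=dt_out, label="activity_E", seed=seed, params_hash=h),
        "activity_I": Trace(outI, dt=dt_out, label="activity_I", seed=seed, params_hash=h),
    }
    return SimResult({k: _trim(t, burn_in) for k, t in traces.items()},
                     {"clips": int(clips), "n_steps": n_steps})


# ---------------------------------------------------------------------------
# Linear fluctuation SDEs (exact Gaussian transition)
# ---------------------------------------------------------------------------

def stationary_covariance(coeffs: LNACoefficients) -> np.ndarray:
    """Stationary covariance of the linear fluctuations: solution of
    A S + S A' + Q = 0 with Q = diag(sigma_E^2, sigma_I^2)."""
    Q = np.diag([coeffs.sigma_E**2, coeffs.sigma_I**2])
    return solve_lyapunov(coeffs.A, -Q)


def _exact_propagator(A: np.ndarray, Q: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-step transition matrix and noise covariance via the Van Loan
    block-exponential (valid for stable and unstable A alike)."""
    n = A.shape[0]
    H = np.zeros((2 * n, 2 * n))
    H[:n, :n] = A
    H[:n, n:] = Q
    H[n:, n:] = -A.T
    G = expm(H * dt)
    M = G[:n, :n]
    Qd = G[:n, n:] @ M.T
    return M, (Qd + Qd.T) / 2.0


@njit(cache=False)
def _ar_kernel(M, L, n, seed, v0, v1, out):
    np.random.seed(seed)
    for i in range(n):
        z0 = np.random.normal()
        z1 = np.random.normal()
        w0 = M[0, 0] * v0 + M[0, 1] * v1 + L[0, 0] * z0 + L[0, 1] * z1
        w1 = M[1, 0] * v0 + M[1, 1] * v1 + L[1, 0] * z0 + L[1, 1] * z1
        v0 = w0
        v1 = w1
        out[i, 0] = v0
        out[i, 1] = v1


def simulate_lna(
    coeffs: LNACoefficients,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    burn_in: float = DEFAULT_BURN_IN,
    initial: tuple[float, float] = (0.0, 0.0),
) -> SimResult:
    """Sample the linear fluctuation SDEs with the exact Gaussian transition.

    The recursion v[n+1] = M v[n] + L xi[n] uses M = expm(A dt) and the
    exact integrated noise covariance, so stationary moments carry no
    step-size bias. Starts at the fixed point (v = 0) by default; burn-in
    discarded.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    nu = -(coeffs.A11 + coeffs.A22) / 2.0
    if nu <= 0 and duration > 10.0 / max(abs(nu), 1e-12):
        warnings.warn("drift matrix is unstable (nu <= 0); trajectories will diverge")
    Q = np.diag([coeffs.sigma_E**2, coeffs.sigma_I**2])
    M, Qd = _exact_propagator(coeffs.A, Q, dt)
    w, U = np.linalg.eigh(Qd)
    L = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n = int(round(duration / dt))
    out = np.empty((n, 2))
    _ar_kernel(M, L, n, _derive_seed(seed), float(initial[0]), float(initial[1]), out)
    traces = {
        "lfp_E": Trace(out[:, 0], dt=dt, label="lfp_E", seed=seed),
        "lfp_I": Trace(out[:, 1], dt=dt, label="lfp_I", seed=seed),
    }
    return SimResult({k: _trim(t, burn_in) for k, t in traces.items()},
                     {"propagator": M, "step_cov": Qd})


# ---------------------------------------------------------------------------
# Reduced envelope-phase process (OU pair, exact updates)
# ---------------------------------------------------------------------------

def simulate_sam(
    reduced: ReducedParams,
    duration: float,
    dt: float = 0.5,
    seed: int = 0,
    burn_in: float = DEFAULT_BURN_IN,
    unwrap_phase: bool = False,
) -> SimResult:
    """Envelope and phase via the two-OU representation.

    Two independent OU processes with rate nu and noise sqrt(D) are sampled
    exactly (AR(1) with the exact OU transition); the envelope is their
    modulus and the phase their angle, which keeps the envelope positive by
    construction. The fast LFPs are reconstructed as
    V_E = Z cos(omega0 t + phi) and V_I = alpha Z cos(omega0 t + phi - delta).
    Valid only in transient synchrony (nu > 0, D > 0).
    """
    if reduced.regime != "transient_synchrony":
        raise ValueError(
            f"envelope-phase reduction requires transient synchrony (nu > 0), "
            f"got regime {reduced.regime!r}"
        )
    nu, D = reduced.nu, reduced.D
    if D is None or D <= 0:
        raise ValueError("envelope noise D must be positive")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    omega0 = reduced.omega0
    n = int(round(duration / dt))
    a = math.exp(-nu * dt)
    s = math.sqrt(D * (1.0 - a * a) / (2.0 * nu))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((2, n))
    # exact OU sampling: E[k+1] = a E[k] + s xi
    E1 = lfilter([s], [1.0, -a], noise[0])
    E2 = lfilter([s], [1.0, -a], noise[1])
    t = dt * np.arange(n)
    Z = np.hypot(E1, E2)
    phi = np.arctan2(E2, E1)
    wt = omega0 * t
    V_E = E1 * np.cos(wt) - E2 * np.sin(wt)
    alpha, delta = reduced.alpha_ratio, reduced.delta
    V_I = alpha * (E1 * np.cos(wt - delta) - E2 * np.sin(wt - delta))
    phase = np.unwrap(phi) if unwrap_phase else phi
    traces = {
        "envelope": Trace(Z, dt=dt, label="envelope", seed=seed),
        "phase": Trace(phase, dt=dt, label="phase", seed=seed),
        "lfp_E": Trace(V_E, dt=dt, label="lfp_E", seed=seed),
        "lfp_I": Trace(V_I, dt=dt, label="lfp_I", seed=seed),
    }
    return SimResult({k: _trim(tr, burn_in) for k, tr in traces.items()},
                     {"nu": nu, "D": D, "omega0": omega0})
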