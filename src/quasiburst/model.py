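"""Fixed point, linear-noise coefficients and envelope-phase reduction.

The deterministic rate equations for the population activities are

    dE/dt = -alpha_E E + (1 - E) beta_E f(s_E),   s_E = W_ee E - W_ei I + h_E
    dI/dt = -alpha_I I + (1 - I) beta_I f(s_I),   s_I = W_ie E - W_ii I + h_I

with f the single-neuron response function. Linearising the stochastic
system around the stable fixed point (E0*, I0*) gives coupled linear SDEs
for the scaled fluctuations (the model LFPs) with drift matrix A and
additive noise intensities sigma_E = sqrt(2 alpha_E E0*), sigma_I =
sqrt(2 alpha_I I0*). The eigenvalues of A are written -nu +/- i omega0;
in the transient-synchrony (quasi-cycle) regime nu > 0 and the rhythm at
angular frequency omega0 is sustained purely by noise. Stochastic
averaging reduces the fluctuations to a slow envelope/phase pair governed
by the two master parameters (nu, D); the stationary envelope density is
Rayleigh with mode R = sqrt(D / (2 nu)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .params import NetworkParams

__all__ = [
    "response_function",
    "response_derivative",
    "FixedPoint",
    "solve_fixed_point",
    "find_fixed_points",
    "LNACoefficients",
    "lna_coefficients",
    "coefficient_forms",
    "ReducedParams",
    "reduce_to_envelope",
    "regime_map",
    "nu_zero_crossing",
]

ResponseKind = Literal["logistic", "erf"]

_SQRT_PI = math.sqrt(math.pi)


def response_function(s, kind: ResponseKind = "logistic"):
    """Single-neuron input-output response f(s), a sigmoid mapping to [0, 1].

    The logistic default ``1 / (1 + exp(-s))`` is not arbitrary: the
    substituted (fixed-point) algebraic forms of the linearised drift
    coefficients are exact identities only when f' = f (1 - f), which holds
    for the logistic alone.
    """
    s = np.asarray(s, dtype=float)
    if kind == "logistic":
        out = np.empty_like(s)
        pos = s >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
        es = np.exp(s[~pos])
        out[~pos] = es / (1.0 + es)
    elif kind == "erf":
        from scipy.special import erf

        out = 0.5 * (1.0 + erf(s / math.sqrt(2.0)))
    else:
        raise ValueError(f"unknown response kind {kind!r}")
    return out if out.ndim else float(out)


def response_derivative(s, kind: ResponseKind = "logistic"):
    """Derivative f'(s) of the response function."""
    s = np.asarray(s, dtype=float)
    if kind == "logistic":
        fs = np.asarray(response_function(s, "logistic"))
        out = fs * (1.0 - fs)
    elif kind == "erf":
        out = np.exp(-0.5 * s * s) / math.sqrt(2.0 * math.pi)
    else:
        raise ValueError(f"unknown response kind {kind!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fixed point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    """Stationary population activities (E0*, I0*), each in (0, 1)."""

    E0: float
    I0: float
    residual: float


def _rate_rhs(params: NetworkParams, kind: ResponseKind) -> Callable:
    def rhs(t, y):
        E, I = y
        fE = response_function(params.input_E(E, I), kind)
        fI = response_function(params.input_I(E, I), kind)
        return (
            -params.alpha_E * E + (1.0 - E) * params.beta_E * fE,
            -params.alpha_I * I + (1.0 - I) * params.beta_I * fI,
        )

    return rhs


def _residual(params: NetworkParams, y: Sequence[float], kind: ResponseKind) -> float:
    dE, dI = _rate_rhs(params, kind)(0.0, y)
    return max(abs(dE), abs(dI))


def solve_fixed_point(
    params: NetworkParams,
    kind: ResponseKind = "logistic",
    start: tuple[float, float] = (0.1, 0.1),
    tol: float = 1e-12,
) -> FixedPoint:
    """Fixed point of the deterministic rate equations.

    Deterministic procedure: forward-integrate the rate equations from
    ``start`` until the flow has settled, then polish with a root solver.
    Under multistability this selects the attractor reached from ``start``
    (use :func:`find_fixed_points` to enumerate all roots).
    """
    rhs = _rate_rhs(params, kind)
    horizon = 50.0 / min(params.alpha_E, params.alpha_I)
    sol = solve_ivp(rhs, (0.0, horizon), start, rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    root, info, flag, msg = fsolve(lambda v: rhs(0.0, v), y, xtol=1e-13, full_output=True)
    res = _residual(params, root, kind)
    # fsolve may report slow progress even at a machine-precision root; the
    # residual is the binding criterion
    if res > 1e-10:
        raise RuntimeError(
            f"fixed-point solver did not converge: {msg} (last residual {res:.3e})"
        )
    E0, I0 = float(root[0]), float(root[1])
    if not (0.0 <= E0 < 1.0 and 0.0 <= I0 < 1.0):
        raise RuntimeError(f"fixed point ({E0}, {I0}) outside the unit square")
    return FixedPoint(E0=E0, I0=I0, residual=res)


def find_fixed_points(
    params: NetworkParams,
    kind: ResponseKind = "logistic",
    grid: int = 12,
) -> list[FixedPoint]:
    """All distinct roots of the rate equations found by a multi-start search."""
    rhs = _rate_rhs(params, kind)
    seen: list[FixedPoint] = []
    for e0 in np.linspace(0.02, 0.98, grid):
        for i0 in np.linspace(0.02, 0.98, grid):
            root, _, flag, _ = fsolve(
                lambda v: rhs(0.0, v), (e0, i0), xtol=1e-13, full_output=True
            )
            if flag != 1:
                continue
            res = _residual(params, root, kind)
            if res > 1e-10:
                continue
            E0, I0 = float(root[0]), float(root[1])
            if not (0.0 <= E0 < 1.0 and 0.0 <= I0 < 1.0):
                continue
            if any(abs(E0 - p.E0) < 1e-7 and abs(I0 - p.I0) < 1e-7 for p in seen):
                continue
            seen.append(FixedPoint(E0=E0, I0=I0, residual=res))
    return sorted(seen, key=lambda p: (p.E0, p.I0))


# ---------------------------------------------------------------------------
# Linear noise approximation coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LNACoefficients:
    """Drift matrix entries and noise intensities of the linearised system.

    ``A12 < 0`` (inhibition onto E) and ``A21 > 0`` (excitation onto I)
    always hold in this model. ``c_EI = sqrt(N_E / N_I)`` carries the
    population-size asymmetry of the fluctuation scaling.
    """

    A11: float
    A12: float
    A21: float
    A22: float
    sigma_E: float
    sigma_I: float
    c_EI: float
    fixed_point: FixedPoint

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.A11, self.A12], [self.A21, self.A22]])


def coefficient_forms(
    params: NetworkParams, fp: FixedPoint, kind: ResponseKind = "logistic"
) -> tuple[dict[str, float], dict[str, float]]:
    """Both algebraic forms of the drift entries: the f'-based form and the
    fixed-point-substituted form. They agree (to rounding) only for the
    logistic response, for which f' = f (1 - f)."""
    E0, I0 = fp.E0, fp.I0
    sE = params.input_E(E0, I0)
    sI = params.input_I(E0, I0)
    fE, fI = response_function(sE, kind), response_function(sI, kind)
    dfE, dfI = response_derivative(sE, kind), response_derivative(sI, kind)
    c = params.c_EI

    prime = {
        "A11": -params.alpha_E - params.beta_E * fE
        + (1.0 - E0) * params.W_ee * params.beta_E * dfE,
        "A12": -(1.0 - E0) * params.W_ei * params.beta_E * dfE * c,
        "A21": (1.0 - I0) * params.W_ie * params.beta_I * dfI / c,
        "A22": -params.alpha_I - params.beta_I * fI
        - (1.0 - I0) * params.W_ii * params.beta_I * dfI,
    }
    gE = params.alpha_E * E0 * (1.0 - params.alpha_E * E0 / ((1.0 - E0) * params.beta_E))
    gI = params.alpha_I * I0 * (1.0 - params.alpha_I * I0 / ((1.0 - I0) * params.beta_I))
    substituted = {
        "A11": -params.alpha_E / (1.0 - E0) + gE * params.W_ee,
        "A12": -c * gE * params.W_ei,
        "A21": gI * params.W_ie / c,
        "A22": -params.alpha_I / (1.0 - I0) - gI * params.W_ii,
    }
    return prime, substituted


def lna_coefficients(
    params: NetworkParams,
    fp: FixedPoint | None = None,
    kind: ResponseKind = "logistic",
) -> LNACoefficients:
    """Linear-noise coefficients at the fixed point.

    Raises if ``fp`` does not solve the stationarity equations to 1e-8.
    """
    if fp is None:
        fp = solve_fixed_point(params, kind)
    res = _residual(params, (fp.E0, fp.I0), kind)
    if res > 1e-8:
        raise ValueError(f"supplied point is not a fixed point (residual {res:.3e})")
    prime, _ = coefficient_forms(params, fp, kind)
    return LNACoefficients(
        A11=prime["A11"],
        A12=prime["A12"],
        A21=prime["A21"],
        A22=prime["A22"],
        sigma_E=math.sqrt(2.0 * params.alpha_E * fp.E0),
        sigma_I=math.sqrt(2.0 * params.alpha_I * fp.I0),
        c_EI=params.c_EI,
        fixed_point=fp,
    )


# ---------------------------------------------------------------------------
# Envelope-phase reduction
# ---------------------------------------------------------------------------

DConvention = Literal["sam", "swapped"]


@dataclass(frozen=True)
class ReducedParams:
    """Master parameters of the envelope-phase reduction.

    nu          damping of the underlying focus (per ms); > 0 below the
                oscillatory transition (transient synchrony).
    omega0      angular rhythm frequency (rad/ms); None when the
                eigenvalues are real.
    D           effective envelope noise intensity (None outside the
                oscillatory regimes).
    R           mode of the stationary Rayleigh envelope density,
                sqrt(D / (2 nu)); defined only for nu > 0.
    alpha_ratio mean inhibitory/excitatory envelope ratio sqrt(-A21/A12).
    delta       mean E-I phase difference (rad), in (-pi, pi].
    regime      one of transient_synchrony, high_synchrony, asynchronous,
                unstable_non_oscillatory.
    """

    nu: float
    omega0: float | None
    D: float | None
    R: float | None
    alpha_ratio: float | None
    delta: float | None
    regime: str
    d_convention: DConvention = "sam"

    @property
    def frequency_hz(self) -> float | None:
        """Rhythm peak frequency omega0 / (2 pi), in Hz."""
        return None if self.omega0 is None else self.omega0 / (2.0 * math.pi) * 1000.0


def _envelope_noise(coeffs: LNACoefficients, omega0: float, convention: DConvention) -> float:
    sE2, sI2 = coeffs.sigma_E**2, coeffs.sigma_I**2
    if convention == "swapped":
        sE2, sI2 = sI2, sE2
    return -(coeffs.A12 / (2.0 * omega0**2)) * (-coeffs.A12 * sI2 + coeffs.A21 * sE2)


def reduce_to_envelope(
    coeffs: LNACoefficients, d_convention: DConvention = "sam"
) -> ReducedParams:
    """Reduce the linear fluctuation dynamics to the (nu, D) master parameters.

    ``d_convention`` selects how the two noise intensities are paired inside
    the envelope diffusion constant D. The default ``"sam"`` is the
    stochastic-averaging result, D = -(A12 / 2 omega0^2)(-A12 sigma_I^2 +
    A21 sigma_E^2); it agrees with the exact Lyapunov stationary variance of
    the linear system to O(nu/omega0). The ``"swapped"`` variant
    interchanges sigma_E^2 and sigma_I^2; it reproduces the (D, R) values of
    the reference working-point tables shipped with this package and is
    retained for comparison with them. nu, omega0, the envelope ratio and
    the phase lag are identical under both conventions.
    """
    A11, A12, A21, A22 = coeffs.A11, coeffs.A12, coeffs.A21, coeffs.A22
    nu = -(A11 + A22) / 2.0
    disc = -((A11 - A22) ** 2) - 4.0 * A12 * A21
    if disc <= 0.0:
        # Real eigenvalues: no rhythm. A stable node (nu > 0) is the
        # asynchronous regime; an unstable node is flagged separately.
        regime = "asynchronous" if nu > 0 else "unstable_non_oscillatory"
        return ReducedParams(
            nu=nu, omega0=None, D=None, R=None, alpha_ratio=None, delta=None,
            regime=regime, d_convention=d_convention,
        )
    omega0 = 0.5 * math.sqrt(disc)
    D = _envelope_noise(coeffs, omega0, d_convention)
    R = math.sqrt(D / (2.0 * nu)) if nu > 0 else None
    alpha_ratio = math.sqrt(-A21 / A12)
    # two-branch arctan rule: arctan(2 omega0 / (A11 - A22)), plus pi when
    # A11 - A22 <= 0; with omega0 > 0 this is exactly atan2, already in (0, pi)
    delta = math.atan2(2.0 * omega0, A11 - A22)
    regime = "transient_synchrony" if nu > 0 else "high_synchrony"
    return ReducedParams(
        nu=nu, omega0=omega0, D=D, R=R, alpha_ratio=alpha_ratio, delta=delta,
        regime=regime, d_convention=d_convention,
    )


def reduce_params(
    params: NetworkParams,
    kind: ResponseKind = "logistic",
    d_convention: DConvention = "sam",
) -> ReducedParams:
    """Full pipeline params -> fixed point -> LNA coefficients -> reduction."""
    return reduce_to_envelope(lna_coefficients(params, kind=kind), d_convention)


__all__.append("reduce_params")


# ---------------------------------------------------------------------------
# Regime maps and bifurcation curves
# ---------------------------------------------------------------------------

_SWEEPABLE = {"W_ee", "W_ii", "W_ei", "W_ie", "h_E", "h_I"}


def regime_map(
    params: NetworkParams,
    axis1: tuple[str, Iterable[float]],
    axis2: tuple[str, Iterable[float]],
    kind: ResponseKind = "logistic",
    d_convention: DConvention = "sam",
) -> pd.DataFrame:
    """Classify the dynamical regime over a 2-D parameter grid.

    Returns a tidy frame with columns (axis1, axis2, regime, nu, omega0_Hz,
    D, R). Grid cells where the fixed-point solve fails are labelled
    ``invalid`` rather than aborting the scan.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _SWEEPABLE:
            raise ValueError(f"axis {name!r} not sweepable; choose from {sorted(_SWEEPABLE)}")
    rows = []
    for v1 in grid1:
        for v2 in grid2:
            p = params.with_overrides(**{name1: float(v1), name2: float(v2)})
            try:
                red = reduce_params(p, kind=kind, d_convention=d_convention)
                rows.append(
                    {
                        name1: float(v1),
                        name2: float(v2),
                        "regime": red.regime,
                        "nu": red.nu,
                        "omega0_Hz": np.nan if red.frequency_hz is None else red.frequency_hz,
                        "D": np.nan if red.D is None else red.D,
                        "R": np.nan if red.R is None else red.R,
                    }
                )
            except RuntimeError:
                rows.append(
                    {
                        name1: float(v1), name2: float(v2), "regime": "invalid",
                        "nu": np.nan, "omega0_Hz": np.nan, "D": np.nan, "R": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def nu_zero_crossing(
    params: NetworkParams,
    axis: str,
    lo: float,
    hi: float,
    kind: ResponseKind = "logistic",
) -> float:
    """Locate the oscillatory transition (nu = 0) along one parameter axis
    by bisection. Raises if nu does not change sign on [lo, hi]."""
    if axis not in _SWEEPABLE:
        raise ValueError(f"axis {axis!r} not sweepable")

    def nu_of(v: float) -> float:
        red = reduce_params(params.with_overrides(**{axis: v}), kind=kind)
        return red.nu

    return brentq(nu_of, lo, hi, xtol=1e-10)
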