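"""Closed-form envelope statistics and first-passage burst-duration theory.

In transient synchrony the rhythm's envelope z(t) is a Rayleigh process

    dz = (-nu z + D / (2 z)) dt + sqrt(D) dW,

whose stationary density P(z) = (2 nu / D) z exp(-nu z^2 / D) has mode
R = sqrt(D / (2 nu)), mean sqrt(pi/2) R and SD sqrt((4 - pi)/2) R. A
burst is modelled as an up-passage from the extraction threshold b to a
typical excursion maximum c (reflecting at b, absorbing at c) followed by
the return passage (reflecting at c, absorbing at b); both mean
first-passage times are exponential-integral closed forms and their sum
is the theoretical mean burst duration

    T = (1 / 2 nu) [e^{-nu b^2 / D} - e^{-nu c^2 / D}]
                   [Ei(nu c^2 / D) - Ei(nu b^2 / D)],

with *positive* arguments inside Ei. (A variant with negated Ei
arguments circulates in print; it disagrees with direct Monte-Carlo
passage times and is provided only as
:func:`mean_burst_duration_negated_ei` for documentation of that
discrepancy.) With the closed-form convention b = R sqrt(ln 2 / 2),
c = R (sqrt(pi/2) + sqrt((4 - pi)/2)), both ratios b/R and c/R are fixed
constants, so T is exactly proportional to 1 / (2 nu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expi

__all__ = [
    "EnvelopeLaw",
    "FPTSpec",
    "closed_form_spec",
    "empirical_spec",
    "stationary_density",
    "mfpt_up",
    "mfpt_down",
    "mean_burst_duration",
    "mean_burst_duration_negated_ei",
    "mc_mfpt",
]

#: c / R under the closed-form convention: Rayleigh mean + one SD, over R.
C_RATIO = math.sqrt(math.pi / 2.0) + math.sqrt((4.0 - math.pi) / 2.0)
#: b / R under the closed-form convention: half the Rayleigh median, over R.
B_RATIO = math.sqrt(math.log(2.0) / 2.0)


@dataclass(frozen=True)
class EnvelopeLaw:
    """Stationary envelope law, parameterised by the master pair (nu, D)."""

    nu: float
    D: float

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("no stationary envelope law for nu <= 0")
        if self.D <= 0:
            raise ValueError("envelope noise D must be positive")

    @property
    def R(self) -> float:
        """Mode of the stationary density (most probable envelope)."""
        return math.sqrt(self.D / (2.0 * self.nu))

    @property
    def mean_env(self) -> float:
        return math.sqrt(math.pi / 2.0) * self.R

    @property
    def sd_env(self) -> float:
        return math.sqrt((4.0 - math.pi) / 2.0) * self.R

    @property
    def median_env(self) -> float:
        return self.R * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FPTSpec:
    """Threshold pair for the passage-time decomposition of a burst.

    ``b`` is the burst extraction threshold; ``c`` the typical excursion
    maximum. The closed-form convention fixes both as multiples of R; the
    empirical convention estimates them from a simulated envelope (b =
    half its median, c = its mean + SD).
    """

    b: float
    c: float
    convention: Literal["closed_form", "empirical"] = "closed_form"

    def __post_init__(self) -> None:
        if not 0.0 < self.b < self.c:
            raise ValueError(f"need 0 < b < c, got b={self.b}, c={self.c}")


def closed_form_spec(law: EnvelopeLaw) -> FPTSpec:
    return FPTSpec(b=B_RATIO * law.R, c=C_RATIO * law.R, convention="closed_form")


def empirical_spec(env_values: np.ndarray) -> FPTSpec:
    env_values = np.asarray(env_values, dtype=float)
    return FPTSpec(
        b=0.5 * float(np.median(env_values)),
        c=float(env_values.mean() + env_values.std()),
        convention="empirical",
    )


def stationary_density(law: EnvelopeLaw, z) -> np.ndarray | float:
    """Rayleigh stationary density P(z) = (2 nu / D) z exp(-nu z^2 / D)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("envelope values must be non-negative")
    out = (2.0 * law.nu / law.D) * z * np.exp(-law.nu * z * z / law.D)
    return out if out.ndim else float(out)


def _check_interval(law: EnvelopeLaw, b: float, c: float) -> None:
    if not 0.0 < b < c:
        raise ValueError(f"need 0 < b < c, got b={b}, c={c}")


def mfpt_up(law: EnvelopeLaw, b: float, c: float, z0: float | None = None) -> float:
    """Mean time to first reach c starting from z0 in (b, c], with a
    reflecting boundary at b and absorption at c. Defaults to z0 = b."""
    _check_interval(law, b, c)
    z0 = b if z0 is None else z0
    if not b <= z0 <= c:
        raise ValueError(f"need b <= z0 <= c, got z0={z0}")
    k = law.nu / law.D
    return float(
        math.exp(-k * b * b) / (2.0 * law.nu) * (expi(k * c * c) - expi(k * z0 * z0))
        - math.log(c / z0) / law.nu
    )


def mfpt_down(law: EnvelopeLaw, b: float, c: float, z0: float | None = None) -> float:
    """Mean time to first reach b starting from z0 in [b, c), with a
    reflecting boundary at c and absorption at b. Defaults to z0 = c."""
    _check_interval(law, b, c)
    z0 = c if z0 is None else z0
    if not b <= z0 <= c:
        raise ValueError(f"need b <= z0 <= c, got z0={z0}")
    k = law.nu / law.D
    return float(
        math.exp(-k * c * c) / (2.0 * law.nu) * (expi(k * b * b) - expi(k * z0 * z0))
        + math.log(z0 / b) / law.nu
    )


def mean_burst_duration(law: EnvelopeLaw, spec: FPTSpec) -> float:
    """Theoretical mean burst duration T = T_up(b -> c) + T_down(c -> b).

    The logarithmic terms of the two passage times cancel exactly, leaving
    the product form with positive exponential-integral arguments.
    """
    return mfpt_up(law, spec.b, spec.c) + mfpt_down(law, spec.b, spec.c)


def mean_burst_duration_negated_ei(law: EnvelopeLaw, spec: FPTSpec) -> float:
    """The negated-Ei-argument variant of the duration formula.

    Kept only to document that this reading disagrees with Monte-Carlo
    passage times of the envelope process (see the discrepancy test); it
    is NOT the sum of the two passage times.
    """
    R = law.R
    xb = 0.5 * (spec.b / R) ** 2
    xc = 0.5 * (spec.c / R) ** 2
    return float(
        (math.exp(-xb) - math.exp(-xc)) * (expi(-xc) - expi(-xb)) / (2.0 * law.nu)
    )


def mc_mfpt(
    law: EnvelopeLaw,
    b: float,
    c: float,
    direction: Literal["up", "down"],
    n: int = 10_000,
    dt: float = 0.01,
    seed: int = 0,
    max_time: float = 1e6,
) -> tuple[float, float]:
    """Monte-Carlo mean first-passage time of the envelope SDE (oracle).

    Euler-Maruyama at step ``dt`` (ms) with the reflecting boundary
    implemented by sign-mirroring about it; returns (mean, standard error)
    over ``n`` replicates. ``direction="up"`` starts at b, reflects at b,
    absorbs at c; ``"down"`` is the reverse. Discrete monitoring
    systematically misses barrier crossings between steps, so the
    absorbing barrier carries the standard continuity correction (shifted
    into the interior by 0.5826 sqrt(D dt)); without it the estimate is
    biased upward by O(sqrt(dt)).
    """
    _check_interval(law, b, c)
    rng = np.random.default_rng(seed)
    nu, D = law.nu, law.D
    sq = math.sqrt(D * dt)
    shift = 0.5826 * sq  # Broadie-Glasserman-Kou barrier correction
    if direction == "up":
        z = np.full(n, float(b))
        c_eff = c - shift
    elif direction == "down":
        z = np.full(n, float(c))
        b_eff = b + shift
    else:
        raise ValueError("direction must be 'up' or 'down'")
    alive = np.arange(n)
    times = np.zeros(n)
    t = 0.0
    while alive.size and t < max_time:
        t += dt
        za = z[alive]
        za = za + (-nu * za + D / (2.0 * za)) * dt + sq * rng.standard_normal(alive.size)
        if direction == "up":
            za = np.where(za < b, 2.0 * b - za, za)  # mirror at the reflecting wall
            hit = za >= c_eff
        else:
            za = np.where(za > c, 2.0 * c - za, za)
            hit = za <= b_eff
        z[alive] = za
        if hit.any():
            times[alive[hit]] = t
            alive = alive[~hit]
    if alive.size:
        raise RuntimeError(f"{alive.size} replicates not absorbed by t={max_time} ms")
    return float(times.mean()), float(times.std(ddof=1) / math.sqrt(n))
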