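"""Proximity-ligation kinetics: one-step vs two-step ligation models.

Two mass-action ODE systems describe how chromatin fragment ends turn into
ligation products. ``omega`` is the pool of fragments held in proximity by
protein complexes (2N at t=0), ``beta`` the abundance of isolated fragments,
``y`` the accumulated *signal* products (protein-mediated pairs) and ``z`` the
accumulated *noise* products (random collisions).

One-step ligation (fragment ends join directly)::

    d omega/dt = -(p1 + p2) * omega        omega(0) = 2N
    d y/dt     =  p1 * omega**2            y(0) = 0
    d z/dt     =  p2 * beta * omega        z(0) = 0

Two-step ligation (a bridge linker first caps fragment ends at rate p0,
producing intermediates ``x``, which then join partners)::

    d omega/dt = -2 p0 * omega                     omega(0) = 2N
    d x/dt     =  2 p0 * omega - (p1 + p2) * x     x(0) = 0
    d y/dt     =  p1 * x * omega                   y(0) = 0
    d z/dt     =  p2 * x * beta                    z(0) = 0

Both systems have closed-form solutions (see :func:`one_step_closed_form` and
:func:`two_step_closed_form`); the two-step solution involves the coefficient
``alpha = 2 p0 / (2 p0 - (p1 + p2))``, which is singular at 2 p0 = p1 + p2 —
there the analytic limit is used instead. A fixed-step RK4 integrator
(:func:`integrate`) provides an independent numerical route; the two agree to
1e-6 relative error away from the singular line.

Time and rates are dimensionless model units; there is no unit conversion
layer. Default rates p0=0.05, p1=1, p2=0.025 reflect that random (noise)
ligation is intrinsically much faster than the protein-mediated (signal)
channel per collision partner, while the linker-capping step is slow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

Model = Literal["one-step", "two-step"]

#: Relative half-width of the singular band |2*p0 - (p1+p2)| around zero in
#: which the analytic limit of the two-step solution is evaluated.
SINGULAR_RTOL = 1e-9


@dataclass(frozen=True)
class KineticsParams:
    """Rate parameters of the ligation models (dimensionless units).

    N is the initial chromatin-fragment *pair* count (total fragments 2N),
    beta the isolated-fragment abundance, p0 the linker-ligation rate
    (two-step only), p1/p2 the signal/noise ligation rates.
    """

    N: float = 1.0
    beta: float = 1.0
    p0: float = 0.05
    p1: float = 1.0
    p2: float = 0.025

    def __post_init__(self) -> None:
        vals = (self.N, self.beta, self.p0, self.p1, self.p2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("kinetics parameters must be finite")
        if self.N <= 0:
            raise ValueError("N must be > 0")
        if min(self.beta, self.p0, self.p1, self.p2) < 0:
            raise ValueError("beta, p0, p1, p2 must be >= 0")

    @property
    def singular(self) -> bool:
        """True on the singular line 2*p0 = p1 + p2 of the two-step solution."""
        scale = 2 * self.p0 + self.p1 + self.p2
        return abs(2 * self.p0 - (self.p1 + self.p2)) < SINGULAR_RTOL * scale

    @property
    def alpha(self) -> float:
        """Two-step coefficient alpha = 2*p0 / (2*p0 - (p1 + p2))."""
        d = 2 * self.p0 - (self.p1 + self.p2)
        if d == 0:
            raise ZeroDivisionError("alpha undefined at 2*p0 == p1 + p2")
        return 2 * self.p0 / d


@dataclass(frozen=True)
class KineticsState:
    """Model state at time ``t`` (x is identically 0 for the one-step model)."""

    t: float
    omega: float
    x: float
    y: float
    z: float
    singular_branch: bool = False


@dataclass
class Trajectory:
    """A solution sampled on a time grid."""

    params: KineticsParams
    model: Model
    times: np.ndarray
    omega: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    singular_branch: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def states(self) -> Iterator[KineticsState]:
        for i, t in enumerate(self.times):
            yield KineticsState(
                float(t), float(self.omega[i]), float(self.x[i]),
                float(self.y[i]), float(self.z[i]), self.singular_branch,
            )


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def _one_step_arrays(params: KineticsParams, t: np.ndarray):
    n2 = 2 * params.N
    s = params.p1 + params.p2
    if s == 0:  # no ligation at all: nothing ever reacts
        zeros = np.zeros_like(t)
        return np.full_like(t, n2), zeros, zeros
    omega = n2 * np.exp(-s * t)
    y = params.p1 * n2**2 * (1 - np.exp(-2 * s * t)) / (2 * s)
    z = params.p2 * params.beta * n2 * (1 - np.exp(-s * t)) / s
    return omega, y, z


def _two_step_arrays(params: KineticsParams, t: np.ndarray):
    """Closed-form two-step solution; returns (omega, x, y, z, singular_used)."""
    n2 = 2 * params.N
    p0, p1, p2, beta = params.p0, params.p1, params.p2, params.beta
    s = p1 + p2
    omega = n2 * np.exp(-2 * p0 * t)
    if p0 == 0:  # ends are never capped: no intermediates, no products
        zeros = np.zeros_like(t)
        return omega, zeros, zeros, zeros, False
    if s == 0:  # intermediates accumulate but never resolve
        x = n2 * (1 - np.exp(-2 * p0 * t))
        zeros = np.zeros_like(t)
        return omega, x, zeros, zeros, False
    if params.singular:
        # analytic limit of the closed form as 2*p0 -> p1 + p2 =: q
        q = s
        e_q = np.exp(-q * t)
        x = n2 * q * t * e_q
        y = p1 * n2**2 * (1 - (1 + 2 * q * t) * np.exp(-2 * q * t)) / (4 * q)
        z = p2 * beta * n2 * (1 - (1 + q * t) * e_q) / q
        return omega, x, y, z, True
    a = params.alpha
    x = a * n2 * (np.exp(-s * t) - np.exp(-2 * p0 * t))
    y = a * p1 * n2**2 * (
        (1 - np.exp(-(s + 2 * p0) * t)) / (s + 2 * p0)
        - (1 - np.exp(-4 * p0 * t)) / (4 * p0)
    )
    z = a * beta * p2 * n2 * (
        (1 - np.exp(-s * t)) / s - (1 - np.exp(-2 * p0 * t)) / (2 * p0)
    )
    return omega, x, y, z, False


def one_step_closed_form(params: KineticsParams, t: float) -> KineticsState:
    """Closed-form one-step state at time ``t`` (t >= 0)."""
    ta = _check_time(t)
    omega, y, z = _one_step_arrays(params, ta)
    return KineticsState(float(ta), float(omega), 0.0, float(y), float(z))


def two_step_closed_form(params: KineticsParams, t: float) -> KineticsState:
    """Closed-form two-step state at time ``t``.

    On the singular line 2*p0 = p1 + p2 (where alpha diverges) the analytic
    limit is evaluated and the returned state carries ``singular_branch=True``.
    """
    ta = _check_time(t)
    omega, x, y, z, sing = _two_step_arrays(params, ta)
    return KineticsState(float(ta), float(omega), float(x), float(y), float(z), sing)


def closed_form_trajectory(
    params: KineticsParams, model: Model, times: np.ndarray
) -> Trajectory:
    """Evaluate the closed-form solution on a time grid."""
    times = _check_time(np.asarray(times, dtype=float))
    if model == "one-step":
        omega, y, z = _one_step_arrays(params, times)
        x = np.zeros_like(times)
        sing = False
    elif model == "two-step":
        omega, x, y, z, sing = _two_step_arrays(params, times)
    else:
        raise ValueError(f"unknown model {model!r}")
    return Trajectory(params, model, times, omega, x, y, z, sing)


def rhs(params: KineticsParams, model: Model, state: tuple) -> tuple:
    """Right-hand side of the chosen ODE system at (omega, x, y, z)."""
    omega, x, _, _ = state
    p0, p1, p2, beta = params.p0, params.p1, params.p2, params.beta
    if model == "one-step":
        return (-(p1 + p2) * omega, 0.0, p1 * omega * omega, p2 * beta * omega)
    if model == "two-step":
        return (
            -2 * p0 * omega,
            2 * p0 * omega - (p1 + p2) * x,
            p1 * x * omega,
            p2 * x * beta,
        )
    raise ValueError(f"unknown model {model!r}")


def integrate(
    params: KineticsParams, model: Model, t_end: float, n_steps: int
) -> Trajectory:
    """Fixed-step classical RK4 solution of the chosen model on [0, t_end].

    Deterministic and dependency-light; agrees with the closed forms to 1e-6
    relative error at every grid point for non-singular parameters when the
    step is small against the fastest rate (see docs/methods.md).
    """
    if not (math.isfinite(t_end) and t_end > 0):
        raise ValueError("t_end must be finite and > 0")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if model not in ("one-step", "two-step"):
        raise ValueError(f"unknown model {model!r}")
    h = t_end / n_steps
    omega = [0.0] * (n_steps + 1)
    xs = [0.0] * (n_steps + 1)
    ys = [0.0] * (n_steps + 1)
    zs = [0.0] * (n_steps + 1)
    state = (2.0 * params.N, 0.0, 0.0, 0.0)
    omega[0] = state[0]
    for i in range(n_steps):
        k1 = rhs(params, model, state)
        k2 = rhs(params, model, tuple(s + 0.5 * h * k for s, k in zip(state, k1)))
        k3 = rhs(params, model, tuple(s + 0.5 * h * k for s, k in zip(state, k2)))
        k4 = rhs(params, model, tuple(s + h * k for s, k in zip(state, k3)))
        state = tuple(
            s + (h / 6.0) * (a + 2 * b + 2 * c + d)
            for s, a, b, c, d in zip(state, k1, k2, k3, k4)
        )
        omega[i + 1], xs[i + 1], ys[i + 1], zs[i + 1] = state
    times = np.linspace(0.0, t_end, n_steps + 1)
    return Trajectory(
        params, model, times,
        np.asarray(omega), np.asarray(xs), np.asarray(ys), np.asarray(zs),
    )


def signal_noise_curve(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-time signal-to-noise ratio y/z, restricted to points with z > 0.

    As t -> 0+ the ratio tends to (p1/p2) * (2N/beta) for both models.
    Returns (times, ratios); empty arrays (with a warning) if z is never
    positive.
    """
    mask = traj.z > 0
    if not np.any(mask):
        warnings.warn("z is zero everywhere; signal/noise ratio undefined")
        return np.empty(0), np.empty(0)
    return traj.times[mask], traj.y[mask] / traj.z[mask]


def z_infinity(params: KineticsParams) -> float:
    """Asymptotic noise product, identical for both models.

    z(inf) = p2 * beta * 2N / (p1 + p2) — algebraic consequence of both
    printed solutions (the two-step alpha cancels exactly).
    """
    s = params.p1 + params.p2
    if s == 0:
        return 0.0
    return params.p2 * params.beta * 2 * params.N / s


def one_step_y_infinity(params: KineticsParams) -> float:
    """Asymptotic one-step signal product p1 (2N)^2 / (2 (p1 + p2))."""
    s = params.p1 + params.p2
    if s == 0:
        return 0.0
    return params.p1 * (2 * params.N) ** 2 / (2 * s)
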