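"""Forward simulation of the three transcription-kinetics models.

Three models of increasing complexity describe a target's mRNA level x(t):

* ``constant``     dx/dt = k1 - k2*x
* ``direct``       dx/dt = k1 * sigmoid(w*y(t) + b) - k2*x,
                   where y is the regulator concentration
* ``cooperative``  same as direct, but y is the concentration of the
                   regulator-cofactor equilibrium complex

The complex concentration comes from mass action on free species with the
two profile inputs treated as totals: given totals yA, yB and equilibrium
constant q (q = [A][B]/[AB]), the complex level is the smaller root of
y^2 - (yA + yB + q) y + yA*yB = 0, which interpolates between
min(yA, yB) at q -> 0 and 0 at q -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .expression_data import SmoothedProfile

__all__ = [
    "MODEL_KINDS",
    "KineticParams",
    "ComplexProfile",
    "complex_concentration",
    "simulate",
    "linear_ode_response",
]

MODEL_KINDS = ("constant", "direct", "cooperative")


@dataclass(frozen=True)
class KineticParams:
    """ODE parameter vector; fields irrelevant to ``model_kind`` stay None.

    k1: maximum synthesis rate (expression units / h, >= 0)
    k2: decay rate constant (1/h, >= 0)
    w:  regulatory weight (per regulator unit; direct/cooperative)
    b:  bias (dimensionless; direct/cooperative)
    q:  equilibrium constant (regulator units, >= 0; cooperative)
    x0: initial target level at the first sample time
    """

    model_kind: str
    k1: float
    k2: float
    x0: float
    w: float | None = None
    b: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        needs = {"constant": (), "direct": ("w", "b"),
                 "cooperative": ("w", "b", "q")}[self.model_kind]
        for name in ("w", "b", "q"):
            val = getattr(self, name)
            if name in needs and val is None:
                raise ValueError(f"{self.model_kind} model requires {name}")
            if name not in needs and val is not None:
                raise ValueError(f"{self.model_kind} model does not take {name}")
        if self.q is not None and self.q < 0:
            raise ValueError("q must be non-negative")

    @property
    def n_regulators(self) -> int:
        return {"constant": 0, "direct": 1, "cooperative": 2}[self.model_kind]


def complex_concentration(y_a, y_b, q):
    """Equilibrium complex concentration from totals ``y_a``, ``y_b`` and ``q``.

    Returns the smaller root of y^2 - (yA+yB+q) y + yA*yB = 0 evaluated in
    the cancellation-free form 2*yA*yB / (S + sqrt(S^2 - 4*yA*yB)) with
    S = yA + yB + q, which stays accurate when q >> yA, yB.  Accepts scalars
    or arrays (broadcast).
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(y_a)) and np.all(np.isfinite(y_b))
            and np.all(np.isfinite(q))):
        raise ValueError("inputs must be finite")
    if np.any(y_a < 0) or np.any(y_b < 0) or np.any(q < 0):
        raise ValueError("concentrations and q must be non-negative")
    s = y_a + y_b + q
    prod = y_a * y_b
    # discriminant in additive form: every term is non-negative, so there is
    # no cancellation either at large q or at q ~ 0 with yA ~ yB
    diff = y_a - y_b
    disc = np.sqrt(diff * diff + 2.0 * q * (y_a + y_b) + q * q)
    denom = s + disc
    scalar = np.ndim(denom) == 0
    denom = np.atleast_1d(denom)
    prod = np.atleast_1d(np.broadcast_to(prod, denom.shape)).astype(float)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = 2.0 * prod[nz] / denom[nz]
    return float(out[0]) if scalar else out


class ComplexProfile:
    """Time-dependent complex concentration built from two profiles and q.

    Satisfies 0 <= y_AB(t) <= min(y_A(t), y_B(t)) on the common domain.
    """

    def __init__(self, profile_a: SmoothedProfile, profile_b: SmoothedProfile,
                 q: float):
        if q < 0:
            raise ValueError("q must be non-negative")
        self.profile_a = profile_a
        self.profile_b = profile_b
        self.q = float(q)
        self.t_min = max(profile_a.t_min, profile_b.t_min)
        self.t_max = min(profile_a.t_max, profile_b.t_max)
        if self.t_min >= self.t_max:
            raise ValueError("profiles share no time domain")

    def __call__(self, t, clip_negative: bool = True):
        ya = self.profile_a(t, clip_negative=True)
        yb = self.profile_b(t, clip_negative=True)
        return complex_concentration(ya, yb, self.q)


def _sigmoid(z):
    # numerically safe logistic
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return float(out[0]) if scalar else out


def _synthesis_fn(params: KineticParams, regulators: Sequence[SmoothedProfile]):
    """Return s(t), the (possibly time-dependent) synthesis rate."""
    if params.model_kind == "constant":
        return lambda t: params.k1 * np.ones_like(np.asarray(t, dtype=float))
    if params.model_kind == "direct":
        (reg,) = regulators
        return lambda t: params.k1 * _sigmoid(
            params.w * reg(t, clip_negative=True) + params.b)
    comp = ComplexProfile(regulators[0], regulators[1], params.q)
    return lambda t: params.k1 * _sigmoid(params.w * comp(t) + params.b)


def simulate(params: KineticParams, regulators: Sequence[SmoothedProfile],
             times, rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Solve the model ODE from x(times[0]) = params.x0 and sample at ``times``.

    The constant model uses its closed form
    x(t) = k1/k2 + (x0 - k1/k2) e^{-k2 (t - t0)}; the regulated models use an
    adaptive Runge-Kutta solver with dense output.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and non-empty")
    if len(regulators) != params.n_regulators:
        raise ValueError(
            f"{params.model_kind} model needs {params.n_regulators} "
            f"regulator(s), got {len(regulators)}"
        )
    for reg in regulators:
        if times[0] < reg.t_min - 1e-9 or times[-1] > reg.t_max + 1e-9:
            raise ValueError("times extend outside the regulator domain")

    t0 = times[0]
    if params.model_kind == "constant":
        if params.k2 == 0:
            return params.x0 + params.k1 * (times - t0)
        ss = params.k1 / params.k2
        return ss + (params.x0 - ss) * np.exp(-params.k2 * (times - t0))

    synth = _synthesis_fn(params, regulators)

    def rhs(t, x):
        return synth(np.array([t])) - params.k2 * x

    sol = solve_ivp(rhs, (t0, times[-1]), [params.x0], t_eval=times,
                    method="RK45", rtol=rtol, atol=atol, dense_output=False,
                    max_step=(times[-1] - t0) / 16 if times.size > 1 else np.inf)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def linear_ode_response(synthesis: np.ndarray, k2: float, x0: float,
                        h: float) -> np.ndarray:
    """Solve dx/dt = s(t) - k2*x on a uniform grid given s at the grid nodes.

    Uses the exact integrating-factor solution with per-step trapezoidal
    quadrature of the damped convolution, vectorized as a discrete
    convolution with powers of exp(-k2*h).  This is the fast inner loop of
    parameter fitting; global error is O(h^2) in the grid spacing.
    """
    synthesis = np.asarray(synthesis, dtype=float)
    n = synthesis.size
    if k2 < 0:
        raise ValueError("k2 must be non-negative")
    if k2 == 0:
        incr = np.concatenate(
            ([0.0], np.cumsum(0.5 * h * (synthesis[1:] + synthesis[:-1]))))
        return x0 + incr
    decay = np.exp(-k2 * h)
    powers = decay ** np.arange(n)
    conv = np.convolve(synthesis, powers)[:n]
    # trapezoid end-corrections: half weight at both ends of each step chain
    x = x0 * powers + h * (conv - 0.5 * synthesis[0] * powers - 0.5 * synthesis)
    x[0] = x0
    return x
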