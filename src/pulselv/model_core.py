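"""Deterministic core of the time-delayed predator-prey model.

The model is a Lotka-Volterra predator-prey system in which the predator
responds to a *distributed* delayed average of the prey population and the
prey is subject to weak self-competition.  For small mean delay ``gamma`` the
integro-differential model reduces (first-order Taylor expansion of the
delayed prey population) to a planar ODE whose conservative part

    dx1/dt = x1 (a - b x2)
    dx2/dt = x2 (-c + f x1) (1 + eps^4 s gamma x1)

possesses a first integral ``r(x1, x2)`` generalizing the classical
Lotka-Volterra invariant.  The closed level curves ``r = K`` and their
quasi-periods ``T(K)`` are the geometric backbone of the stochastic
averaging performed in :mod:`pulselv.averaging`.

Scaling convention: the self-competition ``s``, the mean delay ``gamma`` and
the noise amplitude variances are bookkeeping-scaled by the small parameter
``eps`` — the physically quoted quantities are ``eps^2 s``, ``eps^2 gamma``
and ``lambda_i eps^2 E[Y_i^2]``.  Configuration files quote the scaled
values; :class:`ModelParams` stores the raw values and exposes both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "ModelParams",
    "Point",
    "Orbit",
    "derive_reduced_growth",
    "equilibrium",
    "first_integral",
    "conservative_drift",
    "reduced_drift",
    "find_orbit",
    "period",
    "period_integrals",
    "harmonic_period",
    "orbit_average",
    "exponential_delay_kernel",
]


class Point(NamedTuple):
    """A point in the positive population quadrant (prey, predator)."""

    x1: float
    x2: float


def derive_reduced_growth(a1: float, s: float, c: float, f: float) -> float:
    """Effective prey growth rate ``a = a1 - s c / f``.

    ``s`` here is the *physical* self-competition coefficient (the quoted
    ``eps^2 s``).  A positive interior equilibrium requires ``a > 0``.
    """
    for name, v in (("a1", a1), ("c", c), ("f", f)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if s < 0:
        raise ValueError(f"s must be non-negative, got {s}")
    a = a1 - s * c / f
    if a <= 0:
        raise ValueError(
            f"a = a1 - s*c/f = {a:g} <= 0: no positive interior equilibrium "
            "(self-competition too strong for this parameterization)"
        )
    return a


@dataclass(frozen=True)
class ModelParams:
    """Ecological rates with the eps-scaling bookkeeping.

    Parameters
    ----------
    a : float
        Effective prey growth rate ``a = a1 - (eps^2 s) c / f`` (1/time).
    b : float
        Predation rate.
    c : float
        Predator death rate (1/time).
    f : float
        Prey-to-predator conversion rate.
    eps : float
        Small perturbation bookkeeping parameter; the method assumes
        ``eps`` small and a warning is emitted above 0.5.
    s : float
        Raw self-competition (the physically quoted value is ``eps^2 s``).
    gamma : float
        Raw mean delay (the physically quoted value is ``eps^2 gamma``).
    """

    a: float
    b: float
    c: float
    f: float
    eps: float
    s: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "f", "eps"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v}")
        for name in ("s", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.eps > 0.5:
            warnings.warn(
                f"eps = {self.eps:g} > 0.5: the perturbation/averaging method "
                "assumes small eps; results may be unreliable",
                stacklevel=3,
            )

    @classmethod
    def from_caption(
        cls,
        eps: float,
        a: float,
        b: float,
        c: float,
        f: float,
        eps2_s: float = 0.0,
        eps2_gamma: float = 0.0,
    ) -> "ModelParams":
        """Build from caption-notation (scaled) values ``eps^2 s``, ``eps^2 gamma``."""
        if eps <= 0:
            raise ValueError("eps must be positive")
        return cls(a=a, b=b, c=c, f=f, eps=eps,
                   s=eps2_s / eps**2, gamma=eps2_gamma / eps**2)

    @classmethod
    def from_rates(
        cls,
        a1: float,
        s_phys: float,
        b: float,
        c: float,
        f: float,
        gamma_phys: float,
        eps: float,
    ) -> "ModelParams":
        """Build from the raw ecological rates of the unscaled model."""
        a = derive_reduced_growth(a1, s_phys, c, f)
        return cls(a=a, b=b, c=c, f=f, eps=eps,
                   s=s_phys / eps**2, gamma=gamma_phys / eps**2)

    # -- derived quantities -------------------------------------------------
    @property
    def eps2_s(self) -> float:
        return self.eps**2 * self.s

    @property
    def eps2_gamma(self) -> float:
        return self.eps**2 * self.gamma

    @property
    def eps4_s_gamma(self) -> float:
        """The combination ``eps^4 s gamma`` entering the first integral."""
        return self.eps**4 * self.s * self.gamma

    @property
    def a1(self) -> float:
        """Raw prey birth rate ``a1 = a + (eps^2 s) c / f``."""
        return self.a + self.eps2_s * self.c / self.f

    @property
    def x10(self) -> float:
        return self.c / self.f

    @property
    def x20(self) -> float:
        return self.a / self.b


def equilibrium(params: ModelParams) -> Point:
    """Interior equilibrium ``(c/f, a/b)`` shared by all model reductions."""
    return Point(params.c / params.f, params.a / params.b)


def _as_xy(p):
    x1, x2 = p
    return np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)


def first_integral(p, params: ModelParams):
    """First integral ``r(x1, x2)`` of the conservative system.

    r = f x1 - c - c ln(f x1/c) + b x2 - a - a ln(b x2/a)
        + eps^4 s gamma (-c x1 + f x1^2 / 2 + c^2 / (2 f))

    It vanishes at the equilibrium ``(c/f, a/b)`` and is positive elsewhere
    in the open quadrant; ``r = K > 0`` is a closed orbit.  Accepts scalar
    or array coordinates.
    """
    x1, x2 = _as_xy(p)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("first_integral requires positive population densities")
    a, b, c, f = params.a, params.b, params.c, params.f
    e4sg = params.eps4_s_gamma
    r = (f * x1 - c - c * np.log(f * x1 / c)
         + b * x2 - a - a * np.log(b * x2 / a)
         + e4sg * (-c * x1 + 0.5 * f * x1**2 + c**2 / (2.0 * f)))
    return r if r.ndim else float(r)


def conservative_drift(p, params: ModelParams):
    """Right-hand side of the conservative system used for averaging."""
    x1, x2 = _as_xy(p)
    a, b, c, f = params.a, params.b, params.c, params.f
    e4sg = params.eps4_s_gamma
    d1 = x1 * (a - b * x2)
    d2 = x2 * (-c + f * x1) * (1.0 + e4sg * x1)
    return d1, d2


def reduced_drift(p, params: ModelParams):
    """Noise-free drift of the full reduced model (delay + self-competition).

    Relative to the conservative system this adds the O(eps^2) terms:
    the prey self-competition ``-(eps^2 s / f)(f x1 - c)`` and the delay
    feedback ``eps^2 f gamma x1 (b x2 - a)`` in the predator equation.
    """
    x1, x2 = _as_xy(p)
    a, b, c, f = params.a, params.b, params.c, params.f
    e2 = params.eps**2
    e4sg = params.eps4_s_gamma
    d1 = x1 * (a - b * x2 - e2 * params.s / f * (f * x1 - c))
    d2 = x2 * ((-c + f * x1) * (1.0 + e4sg * x1)
               + e2 * f * params.gamma * x1 * (b * x2 - a))
    return d1, d2


def exponential_delay_kernel(t, gamma: float):
    """Exponential delay kernel ``F(t) = exp(-t/gamma) / gamma``.

    Normalized to unit integral with mean delay ``gamma``.  (The humped
    kernel ``4 t exp(-2t/gamma) / gamma^2`` shares the same mean and is not
    implemented; the chain-trick validator uses the exponential kernel.)
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = np.asarray(t, dtype=float)
    return np.exp(-t / gamma) / gamma


# ---------------------------------------------------------------------------
# Level curves and periods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orbit:
    """A discretized closed level curve ``r = K`` with its quasi-period.

    ``points`` is an ``(n, 2)`` array traversed over one period at times
    ``times`` (``times[0] == 0``, ``times[-1] == period``); the first and
    last points coincide.
    """

    K: float
    points: np.ndarray
    times: np.ndarray
    period: float
    params: ModelParams = field(repr=False)

    @property
    def x1(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.points[:, 1]

    def max_level_error(self) -> float:
        """Max deviation |r(points) - K| along the stored orbit."""
        r = first_integral((self.x1, self.x2), self.params)
        return float(np.max(np.abs(r - self.K)))

    def closure_gap(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))


def _phi(x1, params: ModelParams):
    """Prey part of the first integral along the ray x2 = a/b."""
    c, f = params.c, params.f
    e4sg = params.eps4_s_gamma
    x1 = np.asarray(x1, dtype=float)
    return (f * x1 - c - c * np.log(f * x1 / c)
            + e4sg * (-c * x1 + 0.5 * f * x1**2 + c**2 / (2.0 * f)))


def _psi(x2, params: ModelParams):
    """Predator part of the first integral (the ray x1 = c/f)."""
    a, b = params.a, params.b
    x2 = np.asarray(x2, dtype=float)
    return b * x2 - a - a * np.log(b * x2 / a)


def harmonic_period(params: ModelParams) -> float:
    """Small-orbit (linearized) period ``2 pi / sqrt(a c (1 + eps^4 s gamma c/f))``."""
    a, c, f = params.a, params.c, params.f
    return 2.0 * np.pi / np.sqrt(a * c * (1.0 + params.eps4_s_gamma * c / f))


def _phi_root(K: float, params: ModelParams, upper: bool) -> float:
    """Solve phi(x1) = K for x1 on the upper (x1 > c/f) or lower branch."""
    x10 = params.x10
    fun = lambda x: _phi(x, params) - K
    if upper:
        hi = x10 * 2.0
        while fun(hi) < 0:
            hi *= 2.0
            if hi > 1e12 * x10:  # pragma: no cover - pathological level
                raise RuntimeError(f"cannot bracket level K={K} above equilibrium")
        return brentq(fun, x10, hi, xtol=1e-14, rtol=8.9e-16)
    lo = x10 * 0.5
    while fun(lo) < 0:
        lo *= 0.5
        if lo < 1e-300:  # pragma: no cover
            raise RuntimeError(f"cannot bracket level K={K} below equilibrium")
    return brentq(fun, lo, x10, xtol=1e-300, rtol=8.9e-16)


def _psi_roots(w, params: ModelParams):
    """Solve psi(x2) = w for the lower and upper x2 branches (Lambert W).

    ``b x2/a - 1 - ln(b x2/a) = w/a`` gives ``b x2 / a = -W_k(-exp(-1-w/a))``
    with branch k=0 (lower, x2 <= a/b) and k=-1 (upper).
    """
    w = np.asarray(w, dtype=float)
    v = w / params.a
    arg = -np.exp(-1.0 - v)
    lo = -lambertw(arg, k=0).real
    hi = -lambertw(arg, k=-1).real
    # lambertw loses precision near the branch point -1/e (v -> 0); seed
    # with the series u = 1 +- sqrt(2v) + 2v/3 and polish with Newton
    small = v < 1e-4
    if np.any(small):
        root = np.sqrt(2.0 * v[small])
        lo[small] = 1.0 - root + 2.0 * v[small] / 3.0
        hi[small] = 1.0 + root + 2.0 * v[small] / 3.0
    for u in (lo, hi):
        for _ in range(3):
            g = u - 1.0 - np.log(u) - v
            gp = 1.0 - 1.0 / u
            step = np.where(np.abs(gp) > 1e-300, g / np.where(gp == 0, 1.0, gp), 0.0)
            np.subtract(u, step, out=u)
    scale = params.a / params.b
    return lo * scale, hi * scale


def find_orbit(
    K: float,
    params: ModelParams,
    tol: float = 1e-6,
    n_points: int = 1024,
    ivp_tol: float = 1e-10,
    max_K: float | None = None,
) -> Orbit:
    """Compute the closed orbit of the conservative system at level ``K``.

    The start point is found by bracketed root-finding on ``r(x1, a/b) = K``
    with ``x1 > c/f`` (``r`` is monotone on that ray); the orbit is then
    traced by integrating the conservative flow with an adaptive high-order
    integrator, detecting the two crossings of the line ``x2 = a/b``, whose
    second one closes the curve.  The dense solution is resampled at
    ``n_points`` uniformly spaced times so orbit averages can use plain
    time quadrature.

    Raises if the orbit fails to close within 10 harmonic-period estimates
    or misses the start by more than ``tol``.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if max_K is not None and K > max_K:
        raise ValueError(f"K={K} exceeds configured maximum level {max_K}")
    if n_points < 512:
        n_points = 512

    x_start = _phi_root(K, params, upper=True)
    y0 = np.array([x_start, params.x20])
    t_cap = 10.0 * harmonic_period(params)

    def rhs(t, y):
        d1, d2 = conservative_drift((y[0], y[1]), params)
        return (d1, d2)

    def crossing(t, y):
        return y[1] - params.x20

    segs = []
    t0 = 0.0
    y = y0
    for direction in (-1.0, 1.0):
        crossing.terminal = True
        crossing.direction = direction
        sol = solve_ivp(rhs, (0.0, t_cap), y, method="DOP853",
                        rtol=ivp_tol, atol=ivp_tol, dense_output=True,
                        events=crossing)
        if not sol.t_events[0].size:
            raise RuntimeError(
                f"orbit at K={K} failed to close within {t_cap:g} time units; "
                "level too large or integrator tolerance too loose")
        t_ev = sol.t_events[0][0]
        segs.append((t0, t_ev, sol.sol))
        t0 += t_ev
        y = sol.y_events[0][0]

    T = t0
    times = np.linspace(0.0, T, n_points)
    pts = np.empty((n_points, 2))
    (o1, e1, d1), (o2, e2, d2) = segs
    m = times <= e1
    pts[m] = d1(times[m]).T
    pts[~m] = d2(times[~m] - e1).T
    pts[0] = y0
    pts[-1] = y0  # exact closure of the stored polyline

    gap = float(np.hypot(*(y - y0)))
    if gap > tol:
        raise RuntimeError(
            f"orbit at K={K} returned to within {gap:.3e} of its start, "
            f"exceeding tol={tol:.3e}")
    return Orbit(K=float(K), points=pts, times=times, period=float(T), params=params)


def period(K: float, params: ModelParams, **kw) -> float:
    """Quasi-period ``T(K)`` from the orbit's first-return time."""
    return find_orbit(K, params, **kw).period


def period_integrals(K: float, params: ModelParams, n_quad: int = 256):
    """``T(K)`` from the two closed line-integral forms.

    The contour integral ``T = oint dx1 / (x1 (a - b x2))`` is evaluated by
    splitting the level curve into its lower/upper predator branches
    (inverted by Lambert W) and substituting ``x1 = x1min + (x1max - x1min)
    sin^2(theta)`` to absorb the square-root turning-point singularities;
    likewise ``T = oint dx2 / (x2 (-c + f x1)(1 + eps^4 s gamma x1))`` with
    the prey branches inverted by bracketed root-finding.

    Returns
    -------
    (T_dx1, T_dx2) : tuple of float
    """
    a, b, c, f = params.a, params.b, params.c, params.f
    e4sg = params.eps4_s_gamma
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    theta = 0.5 * np.pi * 0.5 * (nodes + 1.0)
    wts = wts * 0.5 * 0.5 * np.pi

    # -- form 1: integrate in x1 -------------------------------------------
    x1min = _phi_root(K, params, upper=False)
    x1max = _phi_root(K, params, upper=True)
    span = x1max - x1min
    x1 = x1min + span * np.sin(theta) ** 2
    jac = span * 2.0 * np.sin(theta) * np.cos(theta)
    w = K - _phi(x1, params)
    w = np.maximum(w, 0.0)
    x2_lo, x2_hi = _psi_roots(w, params)
    integ = 1.0 / (x1 * (a - b * x2_lo)) + 1.0 / (x1 * (b * x2_hi - a))
    T_dx1 = float(np.sum(wts * jac * integ))

    # -- form 2: integrate in x2 -------------------------------------------
    psi_fun = lambda x2: float(_psi(x2, params)) - K
    hi = params.x20 * 2.0
    while psi_fun(hi) < 0:
        hi *= 2.0
    x2max = brentq(psi_fun, params.x20, hi, xtol=1e-14, rtol=8.9e-16)
    lo = params.x20 * 0.5
    while psi_fun(lo) < 0:
        lo *= 0.5
    x2min = brentq(psi_fun, lo, params.x20, xtol=1e-300, rtol=8.9e-16)
    span2 = x2max - x2min
    x2 = x2min + span2 * np.sin(theta) ** 2
    jac2 = span2 * 2.0 * np.sin(theta) * np.cos(theta)
    w2 = np.maximum(K - _psi(x2, params), 0.0)
    x1_lo = np.array([_phi_root(wi, params, upper=False) if wi > 0 else params.x10
                      for wi in w2])
    x1_hi = np.array([_phi_root(wi, params, upper=True) if wi > 0 else params.x10
                      for wi in w2])
    integ2 = (1.0 / (x2 * (f * x1_hi - c) * (1.0 + e4sg * x1_hi))
              + 1.0 / (x2 * (c - f * x1_lo) * (1.0 + e4sg * x1_lo)))
    T_dx2 = float(np.sum(wts * jac2 * integ2))
    return T_dx1, T_dx2


def orbit_average(orbit: Orbit, g: Callable) -> float:
    """Time average ``(1/T) oint g(x1(t), x2(t)) dt`` over one period.

    ``g`` must accept vectorized coordinate arrays ``g(x1, x2)``.
    """
    vals = np.asarray(g(orbit.x1, orbit.x2), dtype=float)
    return float(np.trapezoid(vals, orbit.times) / orbit.period)
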