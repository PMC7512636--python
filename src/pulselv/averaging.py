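"""Stochastic averaging of the first integral under Poisson white noise.

Each Poisson pulse of amplitude ``Y ~ N(0, E[Y^2])`` on channel ``i`` acts
multiplicatively on the corresponding population, ``X_i -> X_i exp(eps Y)``
(the physical, Stratonovich-interpreted pulse converted to its Ito jump
response).  The induced jump of the first integral ``R`` expands in powers
of ``eps Y`` with coefficients ``A_i1 .. A_i4`` that are polynomial in the
populations.  Averaging the drift and the first four derivate moments of
``R`` over the closed orbits ``r = K`` produces the coefficient functions
of a one-dimensional generalized Fokker-Planck-Kolmogorov (GFPK) equation
for the slow process ``R(t)``:

    dp/dt = -d/dr[(eps^2 Abar11 + eps^4 Abar12) p]
            + (1/2!) d^2/dr^2[(eps^2 Abar21 + eps^4 Abar22) p]
            - (1/3!) d^3/dr^3[eps^4 Abar3 p]
            + (1/4!) d^4/dr^4[eps^4 Abar4 p] + O(eps^6)

Truncation convention: all terms of total order beyond eps^4 are dropped,
counting the eps factors internal to the A coefficients; only the
eps-homogeneous leading parts of the A's therefore survive in the moments.
Gaussian amplitude moments are used throughout (E[Y]=E[Y^3]=0,
E[Y^4]=3 E[Y^2]^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    ModelParams,
    Orbit,
    find_orbit,
    orbit_average,
)

__all__ = [
    "NoiseSpec",
    "ACoefficientSet",
    "AveragedCoefficients",
    "a_coefficients",
    "drift_R",
    "jump_moment",
    "averaged_coefficients",
    "gaussian_averaged_coefficients",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel Poisson pulse rates and Gaussian amplitude variances.

    ``lambda_i`` are mean pulse arrival rates (1/time); ``EY2_i`` are the
    *raw* amplitude variances ``E[Y_i^2]`` (the physically quoted values
    are ``eps^2 E[Y_i^2]`` and the channel noise intensity is
    ``lambda_i eps^2 E[Y_i^2]``).  Amplitude means are fixed at zero and
    the implied fourth moments are ``3 E[Y_i^2]^2``.
    """

    lambda1: float
    lambda2: float
    EY2_1: float
    EY2_2: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "EY2_1", "EY2_2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @classmethod
    def from_caption(
        cls,
        eps: float,
        lambda1: float,
        lambda2: float,
        eps2_EY2_1: float | None = None,
        eps2_EY2_2: float | None = None,
        intensity_1: float | None = None,
        intensity_2: float | None = None,
    ) -> "NoiseSpec":
        """Build from caption notation: either ``eps^2 E[Y^2]`` per channel
        or the intensities ``lambda eps^2 E[Y^2]``."""
        if eps <= 0:
            raise ValueError("eps must be positive")

        def _resolve(lam, e2v, inten, ch):
            if e2v is not None and inten is not None:
                if abs(lam * e2v - inten) > 1e-12 * max(1.0, abs(inten)):
                    raise ValueError(
                        f"channel {ch}: eps2_EY2 and intensity are inconsistent")
            if e2v is None:
                if inten is None:
                    raise ValueError(
                        f"channel {ch}: give eps2_EY2 or intensity")
                if lam <= 0:
                    raise ValueError(
                        f"channel {ch}: intensity given but lambda is 0")
                e2v = inten / lam
            return e2v / eps**2

        return cls(
            lambda1=lambda1,
            lambda2=lambda2,
            EY2_1=_resolve(lambda1, eps2_EY2_1, intensity_1, 1),
            EY2_2=_resolve(lambda2, eps2_EY2_2, intensity_2, 2),
        )

    def intensities(self, eps: float) -> tuple[float, float]:
        """Channel noise intensities ``lambda_i eps^2 E[Y_i^2]``."""
        return (self.lambda1 * eps**2 * self.EY2_1,
                self.lambda2 * eps**2 * self.EY2_2)


@dataclass(frozen=True)
class ACoefficientSet:
    """Jump-expansion coefficients of the first integral at one point.

    ``A1k`` multiply ``(eps Y1)^k`` for prey pulses, ``A2k`` for predator
    pulses, in their standard grouped form (including internal eps^4 pieces).
    """

    A11: float
    A12: float
    A13: float
    A14: float
    A21: float
    A22: float
    A23: float
    A24: float


def a_coefficients(p, params: ModelParams) -> ACoefficientSet:
    """Evaluate the eight jump-expansion coefficients at one point."""
    x1, x2 = float(p[0]), float(p[1])
    a, b, c, f = params.a, params.b, params.c, params.f
    e4sg = params.eps4_s_gamma
    e4fsg = params.eps**4 * f * params.s * params.gamma
    u = (f * x1 - c) * (e4sg * x1 + 1.0)
    v = e4fsg * x1**2 + c
    return ACoefficientSet(
        A11=u,
        A12=0.5 * (u + v),
        A13=u / 6.0 + 0.5 * v - c / 3.0,
        A14=u / 24.0 + 7.0 * v / 24.0 - c / 4.0,
        A21=b * x2 - a,
        A22=0.5 * b * x2,
        A23=b * x2 / 6.0,
        A24=b * x2 / 24.0,
    )


def _a_leading(x1, x2, params: ModelParams):
    """eps-free leading parts of the A coefficients (vectorized).

    Channel 1: (f x1 - c, f x1/2, f x1/6, f x1/24);
    channel 2: (b x2 - a, b x2/2, b x2/6, b x2/24).
    """
    a, b, c, f = params.a, params.b, params.c, params.f
    fx = f * np.asarray(x1, dtype=float)
    bx = b * np.asarray(x2, dtype=float)
    return (fx - c, fx / 2.0, fx / 6.0, fx / 24.0,
            bx - params.a, bx / 2.0, bx / 6.0, bx / 24.0)


def drift_R(p, params: ModelParams):
    """Deterministic drift of the first integral along the reduced flow.

    dR/dt = -eps^2 (s/f) (f x1 - c)^2 (1 + eps^4 s gamma x1)
            + eps^2 f gamma x1 (b x2 - a)^2

    Self-competition dissipates ``R``; the delay feedback pumps it.
    Vectorized over coordinate arrays.
    """
    x1, x2 = np.asarray(p[0], dtype=float), np.asarray(p[1], dtype=float)
    a, b, c, f = params.a, params.b, params.c, params.f
    e2 = params.eps**2
    out = (-e2 * params.s / f * (f * x1 - c) ** 2
           * (1.0 + params.eps4_s_gamma * x1)
           + e2 * f * params.gamma * x1 * (b * x2 - a) ** 2)
    return out if out.ndim else float(out)


def _drift_R_eps2(x1, x2, params: ModelParams):
    """eps^2-homogeneous part of drift_R, divided by eps^2 (vectorized)."""
    a, b, c, f = params.a, params.b, params.c, params.f
    return (-params.s / f * (f * np.asarray(x1) - c) ** 2
            + f * params.gamma * np.asarray(x1) * (b * np.asarray(x2) - a) ** 2)


def _jump_moment_split(x1, x2, params: ModelParams, noise: NoiseSpec, n: int):
    """(c2, c4) with moment = eps^2 c2 + eps^4 c4, vectorized over points."""
    if n not in (1, 2, 3, 4):
        raise ValueError(f"derivate moment order must be in 1..4, got {n}")
    a11, a12, a13, a14, a21, a22, a23, a24 = _a_leading(x1, x2, params)
    l1, l2 = noise.lambda1, noise.lambda2
    m1, m2 = noise.EY2_1, noise.EY2_2
    z = np.zeros_like(np.asarray(x1, dtype=float))
    if n == 1:
        c2 = l1 * m1 * a12 + l2 * m2 * a22
        c4 = 3.0 * (l1 * m1**2 * a14 + l2 * m2**2 * a24)
    elif n == 2:
        c2 = l1 * m1 * a11**2 + l2 * m2 * a21**2
        c4 = 3.0 * (l1 * m1**2 * (2.0 * a11 * a13 + a12**2)
                    + l2 * m2**2 * (2.0 * a21 * a23 + a22**2))
    elif n == 3:
        c2 = z
        c4 = 9.0 * (l1 * m1**2 * a11**2 * a12 + l2 * m2**2 * a21**2 * a22)
    else:
        c2 = z
        c4 = 3.0 * (l1 * m1**2 * a11**4 + l2 * m2**2 * a21**4)
    return c2, c4


def jump_moment(p, params: ModelParams, noise: NoiseSpec, n: int):
    """n-th derivate-moment integrand of ``R``, truncated at total order eps^4.

    n=1: sum_i lambda_i (eps^2 E[Yi^2] A_i2 + 3 eps^4 E[Yi^2]^2 A_i4)
    n=2: sum_i lambda_i (eps^2 E[Yi^2] A_i1^2
                         + 3 eps^4 E[Yi^2]^2 (2 A_i1 A_i3 + A_i2^2))
    n=3: sum_i lambda_i 9 eps^4 E[Yi^2]^2 A_i1^2 A_i2
    n=4: sum_i lambda_i 3 eps^4 E[Yi^2]^2 A_i1^4

    with the A's taken at their eps-free leading parts (their internal
    eps^4 pieces only contribute at eps^6 and beyond).  Vectorized.
    """
    c2, c4 = _jump_moment_split(p[0], p[1], params, noise, n)
    out = params.eps**2 * c2 + params.eps**4 * c4
    out = np.asarray(out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AveragedCoefficients:
    """Orbit-averaged GFPK coefficient functions tabulated on an r-grid.

    ``Abar11 .. Abar4`` are the eps-stripped coefficient functions: the
    drift of the averaged equation is ``eps^2 Abar11 + eps^4 Abar12``, the
    diffusion ``eps^2 Abar21 + eps^4 Abar22``, and the third/fourth
    derivate moments ``eps^4 Abar3`` / ``eps^4 Abar4``.
    """

    r_grid: np.ndarray
    Abar11: np.ndarray
    Abar12: np.ndarray
    Abar21: np.ndarray
    Abar22: np.ndarray
    Abar3: np.ndarray
    Abar4: np.ndarray
    period: np.ndarray
    eps: float
    params: ModelParams = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (r, T, Abar11, Abar12, Abar21, Abar22, Abar3, Abar4)."""
        return pd.DataFrame({
            "r": self.r_grid, "T": self.period,
            "Abar11": self.Abar11, "Abar12": self.Abar12,
            "Abar21": self.Abar21, "Abar22": self.Abar22,
            "Abar3": self.Abar3, "Abar4": self.Abar4,
        })


def averaged_coefficients(
    params: ModelParams,
    noise: NoiseSpec,
    r_grid,
    n_orbit_points: int = 1024,
    ivp_tol: float = 1e-10,
) -> AveragedCoefficients:
    """Average drift and derivate moments over the orbits of an r-grid.

    For each level ``K`` the closed orbit is traced and the time averages

        eps^2 Abar11 + eps^4 Abar12 = < drift_R + M1 >
        eps^2 Abar21 + eps^4 Abar22 = < M2 >
        eps^4 Abar3 = < M3 >,  eps^4 Abar4 = < M4 >

    are split into their eps orders (the split is exact: every term's eps
    power is known at construction).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or r_grid.size < 2:
        raise ValueError("r_grid must be a 1-D grid with at least 2 nodes")
    if np.any(np.diff(r_grid) <= 0) or r_grid[0] <= 0:
        raise ValueError("r_grid must be strictly increasing and positive")

    n = r_grid.size
    out = {k: np.empty(n) for k in
           ("Abar11", "Abar12", "Abar21", "Abar22", "Abar3", "Abar4", "T")}
    for j, K in enumerate(r_grid):
        try:
            orb = find_orbit(K, params, n_points=n_orbit_points, ivp_tol=ivp_tol)
        except Exception as exc:  # noqa: BLE001 - annotate the failing level
            raise RuntimeError(f"orbit computation failed at r-grid node "
                               f"K={K:g} (index {j})") from exc
        out["T"][j] = orb.period

        def avg(fun):
            return orbit_average(orb, fun)

        out["Abar11"][j] = avg(lambda x1, x2: _drift_R_eps2(x1, x2, params)
                               + _jump_moment_split(x1, x2, params, noise, 1)[0])
        out["Abar12"][j] = avg(lambda x1, x2:
                               _jump_moment_split(x1, x2, params, noise, 1)[1])
        out["Abar21"][j] = avg(lambda x1, x2:
                               _jump_moment_split(x1, x2, params, noise, 2)[0])
        out["Abar22"][j] = avg(lambda x1, x2:
                               _jump_moment_split(x1, x2, params, noise, 2)[1])
        out["Abar3"][j] = avg(lambda x1, x2:
                              _jump_moment_split(x1, x2, params, noise, 3)[1])
        out["Abar4"][j] = avg(lambda x1, x2:
                              _jump_moment_split(x1, x2, params, noise, 4)[1])

    return AveragedCoefficients(
        r_grid=r_grid, period=out["T"], eps=params.eps, params=params,
        Abar11=out["Abar11"], Abar12=out["Abar12"],
        Abar21=out["Abar21"], Abar22=out["Abar22"],
        Abar3=out["Abar3"], Abar4=out["Abar4"],
    )


def gaussian_averaged_coefficients(
    params: ModelParams,
    intensities: tuple[float, float],
    r_grid,
    **kw,
) -> AveragedCoefficients:
    """Averaged coefficients for Gaussian white noise of given intensities.

    The Gaussian limit keeps only the second-order derivate moments: a
    noise specification with matching intensities ``D_i = lambda_i eps^2
    E[Y_i^2]`` is averaged and all fourth-moment (eps^4) coefficients are
    zeroed.  This is the dashed-line reference construction used when
    comparing pulse-driven and diffusion-driven ecosystems.
    """
    D1, D2 = intensities
    if D1 < 0 or D2 < 0:
        raise ValueError("intensities must be non-negative")
    e2 = params.eps**2
    noise = NoiseSpec(lambda1=1.0, lambda2=1.0,
                      EY2_1=D1 / e2, EY2_2=D2 / e2)
    coeffs = averaged_coefficients(params, noise, r_grid, **kw)
    z = np.zeros_like(coeffs.r_grid)
    return AveragedCoefficients(
        r_grid=coeffs.r_grid, period=coeffs.period, eps=params.eps,
        params=params, Abar11=coeffs.Abar11, Abar21=coeffs.Abar21,
        Abar12=z, Abar22=z.copy(), Abar3=z.copy(), Abar4=z.copy(),
    )
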