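"""Comparison with the reaction-diffusion (RD) territory model.

Two animals (or packs) with dens at the ends of the unit interval avoid
each other's scent: each animal advects toward its den at a rate
proportional to the local foreign scent density, scent is deposited at a
constant rate and decays exponentially, and there is no over-marking
response.  At steady state the scent fields are proportional to the animal
densities, which collapses the system to

    u'(x) = -kappa u(x) v(x),    v'(x) = +kappa u(x) v(x),

with the conservation conditions int_0^1 u = int_0^1 v = 1.  The sum
u + v = A is constant, giving the logistic closed form
u(x) = A / (1 + B exp(A kappa x)); A and B are fixed by the conservation
conditions (A = 2 and, analytically, B = exp(-kappa), recovered here by
bracketed root finding).  kappa is the single dimensionless parameter,
a product of five dimensional ones.

The mechanistic counterpart is the half-territory marginal with the inner
border pinned at the den; the models are compared through the integrated
squared difference of the two animal densities on a shared grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .analytic1d import reduced_marginal_half

GRID_N = 2048


@dataclass
class RDParams:
    kappa: float
    n_grid: int = GRID_N

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class RDSolution:
    x: np.ndarray
    u: np.ndarray       # left animal density
    v: np.ndarray       # right animal density
    p: np.ndarray       # left scent density (prop. to u at steady state)
    q: np.ndarray       # right scent density
    kappa: float
    B: float


def _u_profile(x, kappa, logB, A=2.0):
    # logistic profile; written to stay finite for large kappa
    expo = A * kappa * x + logB
    return A / (1.0 + np.exp(np.clip(expo, -700, 700)))


def rd_steady_state(kappa: float, n_grid: int = GRID_N) -> RDSolution:
    """Steady state of the RD model with over-marking rate zero.

    The free constant B of the logistic profile is fixed by the probability
    conservation condition int_0^1 u dx = 1 via bracketed root finding in
    log B (the companion condition for v then holds automatically since
    u + v = 2).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    x = np.linspace(0.0, 1.0, n_grid)

    def mass(logB):
        u = _u_profile(x, kappa, logB)
        return np.trapezoid(u, x) - 1.0

    lo, hi = -2.0 * kappa - 50.0, 50.0
    if mass(lo) * mass(hi) > 0:
        raise RuntimeError(
            f"conservation root not bracketed on logB in [{lo}, {hi}] for kappa={kappa}"
        )
    logB = optimize.brentq(mass, lo, hi, xtol=1e-13)
    B = math.exp(logB)
    u = _u_profile(x, kappa, logB)
    v = 2.0 - u
    return RDSolution(x=x, u=u, v=v, p=u.copy(), q=v.copy(), kappa=kappa, B=B)


# ---------------------------------------------------------------------------
# best-fit maps between kappa and (beta, eps)


def _l2_objective(u_rd: np.ndarray, p_half: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid((u_rd - p_half) ** 2, x))


def best_fit_kappa(beta: float, eps: float, kappa_bounds=(1e-2, 1e3)) -> tuple[float, float]:
    """kappa minimising the integrated squared difference between the RD
    animal density and the mechanistic half-territory marginal.

    Returns (kappa, objective).  Brent search on log kappa.
    """
    x = np.linspace(0.0, 1.0, GRID_N)
    target = reduced_marginal_half(x, beta, eps)

    def obj(logk):
        sol = rd_steady_state(math.exp(logk), GRID_N)
        return _l2_objective(sol.u, target, x)

    lo, hi = math.log(kappa_bounds[0]), math.log(kappa_bounds[1])
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    o_lo, o_hi, o_min = obj(lo), obj(hi), res.fun
    if o_min >= min(o_lo, o_hi) - 1e-15 and abs(o_lo - o_hi) < 1e-12:
        raise RuntimeError("objective is flat over the kappa bracket")
    return float(math.exp(res.x)), float(res.fun)


def best_fit_beta_eps(kappa: float, eps: float = 1e-2,
                      beta_bounds=(1e-6, 60.0)) -> tuple[float, float, float]:
    """(beta, eps, objective) minimising the same L2 distance over beta with
    eps fixed small (a small border spread never worsens the fit and leaves
    the best-fit beta unchanged)."""
    sol = rd_steady_state(kappa, GRID_N)
    x = sol.x

    def obj(logb):
        p = reduced_marginal_half(x, math.exp(logb), eps)
        return _l2_objective(sol.u, p, x)

    lo, hi = math.log(beta_bounds[0]), math.log(beta_bounds[1])
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    return float(math.exp(res.x)), eps, float(res.fun)


def step_function_distance(kappa: float, beta: float, eps: float) -> tuple[float, float]:
    """Sup-distances of (RD density, mechanistic marginal) from the joint
    limiting step function (2 on (0, 1/2), 0 on (1/2, 1)).

    In the scent-never-decays limit eps -> 0 with beta -> 0 the mechanistic
    marginal tends to the step; the RD model reaches the same step as
    kappa -> infinity, which is where the two models coincide.
    """
    x = np.linspace(1e-4, 1.0 - 1e-4, GRID_N)
    step = np.where(x < 0.5, 2.0, 0.0)
    mask = np.abs(x - 0.5) > 0.02  # the jump itself is approached non-uniformly
    u = rd_steady_state(kappa, GRID_N).u
    u = np.interp(x, np.linspace(0, 1, GRID_N), u)
    p = reduced_marginal_half(x, beta, eps)
    return float(np.abs(u - step)[mask].max()), float(np.abs(p - step)[mask].max())
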