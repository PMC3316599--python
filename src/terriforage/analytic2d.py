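"""Reduced adiabatic model of a 2D territory with fluctuating radius.

The territory is a disc centred on the CP; its dimensionless radius R
(units of the CP spacing L) fluctuates about the mean 1/2 with a
method-of-images steady state that respects R > 0.  Inside a territory of
radius R the animal follows the 2D Holgate-Okubo localising tendency:
planar density proportional to exp(-beta r), rotationally symmetric,
normalised over the disc.  Marginalising the radius gives the stationary
space-use density fitted to telemetry in the inference programme, and the
variance of the radius distribution is the analytic counterpart of the
simulated border saturation MSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class Analytic2DParams:
    beta: float
    eps: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


# ---------------------------------------------------------------------------


def radius_pdf(R, params: Analytic2DParams):
    """Steady-state density of the territory radius on (0, inf).

    Image of a Gaussian of spread eps about 1/2 reflected at R = 0:
    q(R) = G(R - 1/2) + G(R + 1/2); it integrates to one exactly.
    """
    R = np.asarray(R, float)
    e = params.eps
    out = (
        np.exp(-0.5 * ((R - 0.5) / e) ** 2) + np.exp(-0.5 * ((R + 0.5) / e) ** 2)
    ) / (e * SQRT2PI)
    return np.where(R > 0, out, 0.0)


def radius_support(params: Analytic2DParams, tail: float = 1e-12) -> tuple[float, float]:
    """Interval outside which the radius density is below ``tail``."""
    w = params.eps * math.sqrt(2.0 * math.log(1.0 / tail))
    return (max(0.0, 0.5 - w), 0.5 + w)


def disc_normaliser(beta: float, R):
    """C(beta, R) = int_0^R r exp(-beta r) dr, the Holgate-Okubo disc
    normalisation up to the angular factor 2 pi (closed form, vectorised
    in R; a series guards the small-beta*R regime)."""
    R = np.asarray(R, float)
    if np.any(R <= 0):
        raise ValueError("R must be positive")
    x = beta * R
    small = x < 1e-2  # cancellation guard; quartic series error ~ x^4/72
    with np.errstate(divide="ignore", invalid="ignore"):
        main = (1.0 - (1.0 + x) * np.exp(-x)) / max(beta, 1e-300) ** 2
    series = R * R / 2.0 * (1.0 - 2.0 * x / 3.0 + x * x / 4.0 - x**3 / 15.0)
    out = np.where(small, series, main)
    return float(out) if out.ndim == 0 else out


def disc_normaliser_quad(beta: float, R: float) -> float:
    """Adaptive quadrature of the defining integral int_0^R r e^(-beta r) dr
    (independent oracle for the closed form)."""
    from scipy.integrate import quad

    val, _ = quad(lambda r: r * math.exp(-beta * r), 0.0, R, epsabs=1e-14, epsrel=1e-13)
    return float(val)


def animal_conditional_pdf_2d(r, R: float, beta: float):
    """Planar density of the animal at radius r inside a disc of radius R:
    exp(-beta r) / (2 pi C(beta, R)) for r < R, zero outside."""
    if R <= 0:
        raise ValueError("R must be positive")
    r = np.asarray(r, float)
    dens = np.exp(-beta * r) / (2.0 * math.pi * disc_normaliser(beta, R))
    return np.where((r >= 0) & (r < R), dens, 0.0)


def _tail_integral(params: Analytic2DParams, n_grid: int = 4096):
    """(R grid, G(R) = int_R^R_hi radius_pdf / C dR) for the marginal.

    When the radius density does not vanish at R = 0 the integrand behaves
    like 1/R^2 there (the marginal diverges at the CP); a geometric grid
    resolves that end while the linear part covers the bulk.
    """
    R_lo, R_hi = radius_support(params)
    lo = max(R_lo, 1e-7)
    R = np.linspace(lo, R_hi, n_grid)
    if R_lo < 0.01:  # integrable 1/R^2 end needs log resolution
        R = np.unique(np.concatenate([np.geomspace(lo, R_hi, n_grid), R]))
    g = radius_pdf(R, params) / disc_normaliser(params.beta, R)
    seg = 0.5 * (g[1:] + g[:-1]) * np.diff(R)
    G = np.concatenate([[0.0], np.cumsum(seg)])
    return R, G[-1] - G  # integral from R to R_hi


def marginal_pdf_2d(r, params: Analytic2DParams, n_grid: int = 4096):
    """Stationary planar density of the animal at radius r from its CP.

    p(r) = exp(-beta r)/(2 pi) * int_{max(r, R_lo)}^{R_hi} q(R)/C(beta, R) dR,
    with the radius integral truncated where the radius density tail drops
    below 1e-12 and precomputed cumulatively (vectorised in r).
    """
    scalar = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, float))
    beta = params.beta
    R_lo, R_hi = radius_support(params)
    Rg, G = _tail_integral(params, n_grid)
    a = np.clip(r, Rg[0], R_hi)
    out = np.exp(-beta * r) / (2.0 * math.pi) * np.interp(a, Rg, G)
    out = np.where((r >= 0) & (r < R_hi), out, 0.0)
    return float(out[0]) if scalar else out


def marginal_radial_pdf_2d(r, params: Analytic2DParams, n_grid: int = 4096):
    """Density of the radial coordinate: f(r) = 2 pi r p(r)."""
    r = np.atleast_1d(np.asarray(r, float))
    return 2.0 * math.pi * r * np.atleast_1d(marginal_pdf_2d(r, params, n_grid))


def marginal_pdf_2d_quad(r: float, params: Analytic2DParams) -> float:
    """Adaptive-quadrature evaluation of the marginal (slow oracle for the
    cumulative-grid implementation)."""
    from scipy.integrate import quad

    R_lo, R_hi = radius_support(params)
    if not 0 <= r < R_hi:
        return 0.0
    a = max(r, R_lo, 1e-9)
    val, _ = quad(
        lambda R: float(radius_pdf(R, params)) / float(disc_normaliser(params.beta, R)),
        a, R_hi, limit=200,
    )
    return math.exp(-params.beta * r) / (2.0 * math.pi) * val


def radius_msd_from_params(params: Analytic2DParams) -> float:
    """Saturation MSD of the territory radius: the variance of radius_pdf.

    Closed form through the folded-normal moments of |X|, X ~ N(1/2, eps^2);
    this is the quantity equated with the simulator's border saturation MSD
    in the inference programme.  eps -> 0 gives 0 (frozen border).
    """
    e, mu = params.eps, 0.5
    ex2 = mu * mu + e * e
    ex = e * math.sqrt(2.0 / math.pi) * math.exp(-mu * mu / (2 * e * e)) + mu * erf(
        mu / (e * math.sqrt(2.0))
    )
    return ex2 - ex * ex


def eps_from_radius_msd(msd: float, eps_max: float = 10.0) -> float:
    """Invert :func:`radius_msd_from_params` (monotone increasing in eps)."""
    from scipy.optimize import brentq

    if msd <= 0:
        raise ValueError("msd must be positive")
    f = lambda e: radius_msd_from_params(Analytic2DParams(beta=0.0, eps=e)) - msd
    hi = eps_max
    if f(hi) < 0:
        raise ValueError(f"msd={msd} exceeds the invertible range")
    return float(brentq(f, 1e-8, hi, xtol=1e-14))


# ---------------------------------------------------------------------------
# sampling


def radial_cdf_grid(params: Analytic2DParams, n_grid: int = 2048):
    """(r, F(r)) of the radial coordinate on a fine grid."""
    _, R_hi = radius_support(params)
    r = np.linspace(0.0, R_hi, n_grid)
    f = marginal_radial_pdf_2d(r, params)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(r))])
    cdf /= cdf[-1]
    return r, cdf


def sample_relocations(
    params: Analytic2DParams,
    n: int,
    seed: int,
    cp: tuple[float, float] = (0.0, 0.0),
    L: float = 1.0,
    animal_id: str = "a0",
    dt: float = 1.0,
) -> pd.DataFrame:
    """Draw i.i.d. telemetry fixes from the stationary 2D marginal.

    Inverse-CDF sampling of the radial coordinate, uniform bearing; the
    fixes are placed around ``cp`` in physical units (radius scaled by the
    CP spacing ``L``).  Returns a DataFrame with columns
    (animal_id, x, y, t); reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["animal_id", "x", "y", "t"])
    grid, cdf = radial_cdf_grid(params)
    u = rng.uniform(size=n)
    r = np.interp(u, cdf, grid) * L
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "x": cp[0] + r * np.cos(th),
            "y": cp[1] + r * np.sin(th),
            "t": np.arange(n, dtype=float) * dt,
        }
    )
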