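"""Home-range geometry of the stationary 2D model.

The 95% MCP home range of the rotationally symmetric stationary density is
operationalised as the radius enclosing 95% of the probability mass (the
convex hull of infinitely many i.i.d. fixes converges to a mass contour for
this model); an empirical convex-hull MCP on point samples is provided
separately for data work.  A buffer zone appears when the home-range radius
falls below half the CP spacing; the exclusive-area fraction measures how
much of the home-range disc escapes the six hexagonal neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .analytic2d import Analytic2DParams, marginal_radial_pdf_2d, radius_support
from .borders import CalibrationMap
from .analytic2d import eps_from_radius_msd

HEX_NEIGHBOURS = [
    (math.cos(k * math.pi / 3.0), math.sin(k * math.pi / 3.0)) for k in range(6)
]


@dataclass
class HomeRangeResult:
    R95: float
    buffer_zone: bool
    exclusive_fraction: float


# ---------------------------------------------------------------------------


def mcp_radius(
    params: Analytic2DParams | None = None,
    level: float = 0.95,
    *,
    radial_pdf=None,
    support: float | None = None,
) -> float:
    """Radius enclosing ``level`` of the probability mass.

    Either pass model parameters, or any radial density ``radial_pdf(r)``
    (the density of the radial coordinate, i.e. already carrying the 2 pi r
    measure) with its ``support`` radius.  Bracketing bisection to 1e-8.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if radial_pdf is None:
        if params is None:
            raise ValueError("pass params or radial_pdf")
        _, rmax = radius_support(params)
        grid = np.linspace(0.0, rmax, 4096)
        f = marginal_radial_pdf_2d(grid, params)
    else:
        if support is None:
            raise ValueError("radial_pdf needs an explicit support radius")
        rmax = support
        grid = np.linspace(0.0, rmax, 4096)
        f = np.asarray([float(radial_pdf(r)) for r in grid])
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    if level == 1.0:
        return float(grid[np.argmax(cdf >= 1.0 - 1e-12)])
    func = lambda r: np.interp(r, grid, cdf) - level
    return float(optimize.brentq(func, 0.0, rmax, xtol=1e-8))


def empirical_mcp_radius(points: np.ndarray, cp, level: float = 0.95) -> float:
    """Convex-hull MCP radius on point samples: drop the (1 - level)
    farthest fixes from the CP, take the hull of the rest, and report the
    hull's maximal distance from the CP."""
    from scipy.spatial import ConvexHull

    points = np.asarray(points, float)
    d = np.hypot(points[:, 0] - cp[0], points[:, 1] - cp[1])
    keep = points[np.argsort(d)[: max(3, int(level * len(points)))]]
    hull = ConvexHull(keep)
    verts = keep[hull.vertices]
    return float(np.hypot(verts[:, 0] - cp[0], verts[:, 1] - cp[1]).max())


# ---------------------------------------------------------------------------


def _lens_area(R: float, d: float = 1.0) -> float:
    """Area of the intersection of two discs of radius R at distance d."""
    if 2 * R <= d:
        return 0.0
    return 2.0 * R * R * math.acos(d / (2.0 * R)) - 0.5 * d * math.sqrt(4.0 * R * R - d * d)


def exclusive_area_fraction(R95: float, mc_points: int = 400_000, seed: int = 1234) -> float:
    """Fraction of the home-range disc not overlapped by the six unit-spaced
    hexagonal neighbour discs.

    Pairwise lens subtraction is exact while triple intersections are
    impossible (R95 < 1/sqrt(3)); beyond that a seeded Monte-Carlo
    rasterisation of the disc is used.
    """
    if not 0 < R95 < 1:
        raise ValueError("R95 must lie in (0, 1)")
    if R95 <= 0.5:
        return 1.0
    area = math.pi * R95 * R95
    if R95 < 1.0 / math.sqrt(3.0):
        return 1.0 - 6.0 * _lens_area(R95) / area
    rng = np.random.default_rng(seed)
    # uniform points in the disc
    u = rng.uniform(size=mc_points)
    r = R95 * np.sqrt(u)
    th = rng.uniform(0.0, 2.0 * math.pi, size=mc_points)
    x, y = r * np.cos(th), r * np.sin(th)
    excl = np.ones(mc_points, dtype=bool)
    for cx, cy in HEX_NEIGHBOURS:
        excl &= (x - cx) ** 2 + (y - cy) ** 2 > R95 * R95
    return float(excl.mean())


def exclusive_area_fraction_mc(R95: float, mc_points: int = 1_000_000, seed: int = 99) -> float:
    """Monte-Carlo rasterisation oracle for the lens formula."""
    if R95 <= 0.5:
        return 1.0
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=mc_points)
    r = R95 * np.sqrt(u)
    th = rng.uniform(0.0, 2.0 * math.pi, size=mc_points)
    x, y = r * np.cos(th), r * np.sin(th)
    excl = np.ones(mc_points, dtype=bool)
    for cx, cy in HEX_NEIGHBOURS:
        excl &= (x - cx) ** 2 + (y - cy) ** 2 > R95 * R95
    return float(excl.mean())


def home_range(params: Analytic2DParams, level: float = 0.95) -> HomeRangeResult:
    R95 = mcp_radius(params, level)
    return HomeRangeResult(
        R95=R95,
        buffer_zone=R95 < 0.5,
        exclusive_fraction=exclusive_area_fraction(R95),
    )


# ---------------------------------------------------------------------------
# sigmoid summaries


def _sigmoid(x, a, b, c, d):
    return a + b / (1.0 + np.exp(-(x - c) / d))


def fit_sigmoid(x, y):
    """Least-squares 4-coefficient sigmoid a + b/(1+exp(-(x-c)/d)).

    Returns (coefficients, residual_norm); raises on a flat curve.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 6:
        raise ValueError("need at least 6 points for the sigmoid fit")
    if np.std(y) < 1e-12:
        raise ValueError("curve is flat; sigmoid fit is degenerate")
    from scipy.optimize import curve_fit

    increasing = y[-1] >= y[0]
    a0 = y.min() if increasing else y.max()
    b0 = (y.max() - y.min()) * (1 if increasing else -1)
    p0 = [a0, b0, float(np.median(x)), max((x.max() - x.min()) / 6.0, 1e-3)]
    coef, _ = curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
    resid = float(np.linalg.norm(y - _sigmoid(x, *coef)))
    return coef, resid


def sigmoid_value(x, coef):
    return _sigmoid(np.asarray(x, float), *coef)


# ---------------------------------------------------------------------------
# allometry mapping


def fraction_from_beta_Z(calibration: CalibrationMap, beta: float, Z: float,
                         level: float = 0.95) -> float:
    """Exclusive-area fraction implied by (beta, Z) through the calibrated
    saturation MSD -> eps -> R95 chain."""
    logmsd = calibration.line_intercept + calibration.line_slope * math.log(Z)
    # interpolate the per-beta lines in beta
    msd = float(np.exp(np.interp(beta, calibration.betas, logmsd)))
    eps = eps_from_radius_msd(msd)
    R95 = mcp_radius(Analytic2DParams(beta=beta, eps=eps), level)
    return exclusive_area_fraction(R95)


def exclusive_fraction_vs_mass(
    calibration: CalibrationMap,
    masses,
    exponent: float,
    beta: float,
    ref_fraction: float | None = None,
    level: float = 0.95,
):
    """Mass -> exclusive fraction -> Z table under a user-supplied allometric
    exponent (fraction proportional to mass**(-exponent), anchored at the
    smallest mass).

    Z is recovered by inverting the monotone fraction(beta, Z) composition;
    rows whose target fraction is unattainable in the calibrated range are
    flagged with NaN.
    """
    import pandas as pd

    masses = np.sort(np.asarray(masses, float))
    Z_lo, Z_hi = calibration.Zs[calibration.Zs > 0].min(), calibration.Zs.max()
    f_lo = fraction_from_beta_Z(calibration, beta, Z_lo, level)
    f_hi = fraction_from_beta_Z(calibration, beta, Z_hi, level)
    lo, hi = min(f_lo, f_hi), max(f_lo, f_hi)
    if ref_fraction is None:
        ref_fraction = hi
    rows = []
    for m in masses:
        target = ref_fraction * (m / masses[0]) ** (-exponent)
        if not lo - 1e-12 <= target <= hi + 1e-12:
            rows.append((m, target, np.nan))
            continue
        func = lambda logZ: fraction_from_beta_Z(calibration, beta, math.exp(logZ), level) - target
        a, b = math.log(Z_lo), math.log(Z_hi)
        if abs(func(a)) < 1e-9:
            Z = Z_lo
        elif abs(func(b)) < 1e-9:
            Z = Z_hi
        else:
            Z = math.exp(optimize.brentq(func, a, b, xtol=1e-10))
        rows.append((m, target, Z))
    return pd.DataFrame(rows, columns=["mass", "exclusive_fraction", "Z"])
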