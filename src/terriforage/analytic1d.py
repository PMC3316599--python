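"""Reduced adiabatic model of a 1D territorial central-place forager.

Coordinates are CP-centred and dimensionless: the focal animal's central
place sits at 0, the neighbouring CPs at -1 and +1, and all lengths are in
units of the CP spacing L.  The slow/fast timescale separation between the
subdiffusive territory borders and the diffusive animal factorises the
joint density into

    P(z1, z2, z) = q_L(z1) q_R(z2) C(z | z1, z2),

where q_L, q_R are the steady-state border densities (method-of-images
solutions of a Fokker-Planck equation with a spring about -1/2 and +1/2 and
walls at the CPs) and C is the Holgate-Okubo conditional, an exponential
decay exp(-beta |z|) truncated to the territory.

The border diffusion constant K_b and spring rate lambda enter the steady
state only through eps = sqrt(K_b / lambda), the standard deviation of the
underlying Gaussian before imaging; the transient solutions keep both and
relax on the subdiffusive clock u = sqrt(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import sici

SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class Analytic1DParams:
    """beta: dimensionless drift strength; eps: border-spread parameter.

    Optionally carry (K_b, lam) for transient work; they must satisfy
    eps**2 = K_b / lam when all three are given.
    """

    beta: float
    eps: float
    K_b: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if (self.K_b is None) != (self.lam is None):
            raise ValueError("supply K_b and lam together or not at all")
        if self.lam is not None:
            if self.lam <= 0 or self.K_b < 0:
                raise ValueError("need lam > 0 and K_b >= 0")
            if abs(self.K_b / self.lam - self.eps**2) > 1e-9 * max(1.0, self.eps**2):
                raise ValueError("eps**2 must equal K_b / lam")

    @classmethod
    def from_rates(cls, beta: float, K_b: float, lam: float) -> "Analytic1DParams":
        return cls(beta=beta, eps=math.sqrt(K_b / lam), K_b=K_b, lam=lam)


@dataclass
class DensityCurve:
    """A tabulated density: grid, values and declared support.

    Checks non-negativity and unit trapezoid mass on construction, so
    curves exported to CSV are guaranteed normalised.
    """

    grid: np.ndarray
    values: np.ndarray
    support: tuple[float, float]
    atol: float = 1e-6

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")
        mass = float(np.trapezoid(self.values, self.grid))
        if abs(mass - 1.0) > self.atol:
            raise ValueError(f"density mass {mass} is not 1 on the tabulated grid")

    @classmethod
    def from_pdf(cls, grid, values, support) -> "DensityCurve":
        """Tabulate a pdf, renormalising away the grid's quadrature error."""
        grid = np.asarray(grid, float)
        values = np.asarray(values, float)
        return cls(grid=grid, values=values / np.trapezoid(values, grid),
                   support=support)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"z": self.grid, "density": self.values})


# ---------------------------------------------------------------------------
# border densities


def _image_series(z, centre, sigma, tail=1e-12):
    """Sum of Gaussians at ``centre + n`` (all reflections of the spring
    centre through the CP walls), truncated once the omitted tail < tail."""
    z = np.asarray(z, float)
    n_max = int(np.ceil(sigma * math.sqrt(max(2.0 * math.log(1.0 / tail), 1.0)))) + 2
    out = np.zeros_like(z)
    for n in range(-n_max, n_max + 1):
        u = (z - centre + n) / sigma
        out += np.exp(-0.5 * u * u)
    return out / (sigma * SQRT2PI)


def _poisson_series(z, centre, sigma, tail=1e-12):
    """Fourier (Poisson-resummed) form of the same wrapped Gaussian."""
    z = np.asarray(z, float)
    out = np.ones_like(z)
    k = 1
    while True:
        amp = 2.0 * math.exp(-2.0 * (math.pi * k * sigma) ** 2)
        if amp < tail or k > 100000:
            break
        out += amp * np.cos(2.0 * math.pi * k * (z - centre))
        k += 1
    return out


def border_pdf(side: str, z, params: Analytic1DParams):
    """Steady-state density of the left (support (-1,0)) or right (support
    (0,1)) territory border; zero outside the support by contract."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    centre = -0.5 if side == "left" else 0.5
    lo, hi = (-1.0, 0.0) if side == "left" else (0.0, 1.0)
    z = np.asarray(z, float)
    inside = (z > lo) & (z < hi)
    dense = _image_series(z, centre, params.eps) if params.eps < 0.4 else _poisson_series(z, centre, params.eps)
    return np.where(inside, dense, 0.0)


def border_pdf_transient(z, t, params: Analytic1DParams, representation: str = "images",
                         side: str = "left", z0: float | None = None):
    """Time-dependent border density with walls at the CPs.

    The border relaxes on the subdiffusive clock u = sqrt(t): mean
    m(t) = centre + (z0 - centre) exp(-lam u) and variance
    s2(t) = eps^2 (1 - exp(-2 lam u)), so t -> infinity recovers the steady
    state and t -> 0+ concentrates at the initial border position z0
    (default: the centre).  ``representation`` selects the image series or
    its Poisson resummation; both agree pointwise.
    """
    if params.lam is None:
        raise ValueError("transient densities need K_b and lam")
    if t <= 0:
        raise ValueError("t must be positive")
    centre = -0.5 if side == "left" else 0.5
    lo, hi = (-1.0, 0.0) if side == "left" else (0.0, 1.0)
    z0 = centre if z0 is None else z0
    if not lo < z0 < hi:
        raise ValueError("z0 must lie between the CPs")
    u = math.sqrt(t)
    m = centre + (z0 - centre) * math.exp(-params.lam * u)
    s2 = params.eps**2 * (1.0 - math.exp(-2.0 * params.lam * u))
    s = math.sqrt(max(s2, 1e-300))
    z = np.asarray(z, float)
    inside = (z > lo) & (z < hi)
    tail = 1e-14
    if representation == "images":
        # reflections of m through the walls generate {m + 2n} U {2*hi - m + 2n}
        n_max = int(np.ceil(0.5 * s * math.sqrt(max(2.0 * math.log(1.0 / tail), 1.0)))) + 2
        out = np.zeros_like(z)
        for n in range(-n_max, n_max + 1):
            u1 = (z - m - 2.0 * n) / s
            u2 = (z - (2.0 * hi - m) - 2.0 * n) / s
            out += np.exp(-0.5 * u1 * u1) + np.exp(-0.5 * u2 * u2)
        out /= s * SQRT2PI
    elif representation == "poisson":
        out = np.ones_like(z)
        k = 1
        while True:
            amp = 2.0 * math.exp(-0.5 * (math.pi * k * s) ** 2)
            if amp < tail or k > 200000:
                break
            out += amp * np.cos(math.pi * k * (z - hi)) * math.cos(math.pi * k * (m - hi))
            k += 1
    else:
        raise ValueError("representation must be 'images' or 'poisson'")
    return np.where(inside, out, 0.0)


# ---------------------------------------------------------------------------
# animal densities


def animal_conditional_pdf(z, z1, z2, beta: float):
    """Holgate-Okubo conditional: density prop. to exp(-beta |z|) on (z1, z2).

    z1 < 0 < z2 are the border positions; the closed-form normalisation is
    numerically stable down to beta = 0, where the density is uniform.
    """
    if not z1 < 0 < z2:
        raise ValueError("borders must satisfy z1 < 0 < z2")
    z = np.asarray(z, float)
    if beta < 1e-12:
        norm = z2 - z1
        vals = np.ones_like(z) / norm
    else:
        norm = (-np.expm1(beta * z1) - np.expm1(-beta * z2)) / beta
        vals = np.exp(-beta * np.abs(z)) / norm
    return np.where((z > z1) & (z < z2), vals, 0.0)


def joint_pdf(z1, z2, z, params: Analytic1DParams):
    """Joint steady-state density of (left border, right border, animal)."""
    z1a, z2a, za = np.broadcast_arrays(
        np.asarray(z1, float), np.asarray(z2, float), np.asarray(z, float)
    )
    out = np.zeros_like(za)
    it = np.nditer(out, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        a, b, c = z1a[i], z2a[i], za[i]
        if -1.0 < a < 0.0 < b < 1.0 and a < c < b:
            qa = float(border_pdf("left", a, params))
            qb = float(border_pdf("right", b, params))
            out[i] = qa * qb * float(animal_conditional_pdf(c, a, b, params.beta))
    return out if out.shape else float(out)


def _gl_nodes(a, b, n=64):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


def marginal_pdf_1d(z, params: Analytic1DParams, n_quad: int = 64):
    """Marginal steady-state animal density on (-1, 1).

    Double Gauss-Legendre quadrature of the joint over the admissible
    border positions z1 in (-1, min(z, 0)), z2 in (max(z, 0), 1); the
    density vanishes at the conspecific CPs.
    """
    z = np.atleast_1d(np.asarray(z, float))
    beta, eps = params.beta, params.eps
    out = np.zeros_like(z)
    for i, zi in enumerate(z):
        hi1 = min(zi, 0.0)
        lo2 = max(zi, 0.0)
        if not (-1.0 < zi < 1.0):
            continue
        x1, w1 = _gl_nodes(-1.0, hi1, n_quad)
        x2, w2 = _gl_nodes(lo2, 1.0, n_quad)
        q1 = border_pdf("left", x1, params) * w1
        q2 = border_pdf("right", x2, params) * w2
        if beta < 1e-12:
            norm = x2[None, :] - x1[:, None]
            cond = 1.0 / norm
        else:
            norm = (-np.expm1(beta * x1)[:, None] - np.expm1(-beta * x2)[None, :]) / beta
            cond = math.exp(-beta * abs(zi)) / norm
        out[i] = q1 @ cond @ q2
    return out if out.shape != (1,) else float(out[0])


def border_msd_1d(eps: float, n_quad: int = 200) -> float:
    """Stationary border MSD about its mean +-1/2 (units of L^2), the 1D
    analogue of the radius-variance relation used in the inference step."""
    p = Analytic1DParams(beta=0.0, eps=eps)
    x, w = _gl_nodes(-1.0, 0.0, n_quad)
    q = border_pdf("left", x, p)
    return float(np.sum(w * q * (x + 0.5) ** 2))


def eps_from_border_msd(msd: float) -> float:
    """Invert :func:`border_msd_1d`; defined for msd in (0, 1/12)."""
    if not 0 < msd < 1.0 / 12.0:
        raise ValueError("1D border MSD must lie in (0, 1/12) (uniform-border limit)")
    return float(optimize.brentq(lambda e: border_msd_1d(e) - msd, 1e-6, 5.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# reduced half-territory model (reaction-diffusion comparison)


def reduced_marginal_half(z, beta: float, eps: float, n_grid: int = 4096):
    """Marginal of the animal on (0, 1) with the left border pinned at the CP.

    p(z) = int_z^1 q_R(z2) C(z | 0, z2) dz2 with the truncated-exponential
    conditional normalised on (0, z2); evaluated by cumulative trapezoid on
    a fine grid, vectorised over z.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    params = Analytic1DParams(beta=max(beta, 0.0), eps=eps)
    z = np.atleast_1d(np.asarray(z, float))
    grid = np.linspace(0.0, 1.0, n_grid)
    qR = border_pdf("right", grid, params)
    if beta < 1e-12:
        g = np.divide(qR, grid, out=np.zeros_like(grid), where=grid > 1e-12)
        prefac = np.ones_like(z)
    else:
        with np.errstate(divide="ignore"):
            g = np.divide(qR, -np.expm1(-beta * grid),
                          out=np.zeros_like(grid), where=grid > 1e-12)
        prefac = beta * np.exp(-beta * z)
    # T(z) = int_z^1 g
    rev = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(grid))])
    T_total = rev[-1]
    T = T_total - np.interp(z, grid, rev)
    out = np.where((z > 0) & (z < 1), prefac * T, 0.0)
    return out if out.shape != (1,) else float(out[0])


def reduced_marginal_limit(z, eps: float, tail: float = 1e-12):
    """One-parameter collapse of the half-territory marginal (beta -> 0).

    p(z) = -ln z + 2 sum_k (-1)^k exp(-2 pi^2 eps^2 k^2) [Ci(2 pi k) - Ci(2 pi k z)]
    on (0, 1), with Ci the cosine integral.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    z = np.atleast_1d(np.asarray(z, float))
    inside = (z > 0) & (z < 1)
    zs = np.where(inside, z, 0.5)
    out = -np.log(zs)
    k = 1
    while True:
        damp = math.exp(-2.0 * (math.pi * k * eps) ** 2)
        if damp < tail or k > 200000:
            break
        ci_k = sici(2.0 * math.pi * k)[1]
        ci_kz = sici(2.0 * math.pi * k * zs)[1]
        out += 2.0 * (-1.0) ** k * damp * (ci_k - ci_kz)
        k += 1
    out = np.where(inside, out, 0.0)
    return out if out.shape != (1,) else float(out[0])
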