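"""Simulation configuration and dimensionless conventions.

A :class:`SimConfig` holds every microscopic parameter of a run of the
territorial random-walk model: lattice geometry, jump rate, central-place
bias, active scent time and the central-place (CP) layout.  The derived
properties expose the continuum-limit quantities (diffusion constant ``D``,
drift speed ``v``) and the dimensionless groups ``beta`` and ``Z`` used
throughout the package.

Conventions (recorded in every run manifest):

* ``D = F a**2 / 2`` per axis in 1D, ``D = F a**2 / 4`` per axis in 2D
  (an attempt moves along a given axis only half of the time in 2D),
* ``v = (2p - 1) F a`` in 1D and ``v = (2p - 1) F a / 2`` in 2D,
* ``beta = v L / D`` (identical to ``2 (2p - 1) L / a`` in both dimensions),
* diffusive times ``K1 = 1 / (2 D rho**2)`` and ``K2 = 1 / (4 D rho)``,
* ``Z = T_AS / K1`` in 1D and ``Z = T_AS / K2`` in 2D.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

SQRT3_2 = math.sqrt(3.0) / 2.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one territorial random-walk simulation.

    Parameters
    ----------
    dimension:
        1 (ring of 2 animals by default) or 2 (torus of 30 animals).
    cp_sites:
        CP spacing ``L`` in units of the lattice spacing (``L / a``).
    lattice_spacing:
        Lattice constant ``a`` (length units).
    jump_rate:
        Rate ``F`` at which an animal attempts a nearest-neighbour jump.
    bias_p:
        Probability of stepping toward the CP on the next jump;
        ``0.5`` is the neutral (zero drift) value.
    active_scent_time:
        ``T_AS``; foreign scent younger than this blocks a move.
    t_max / record_every:
        Total simulated time and observable sampling interval (time units).
    n_rays:
        Number of equally spaced bearings for the 2D territory-radius
        observable.
    """

    dimension: int = 1
    cp_sites: int = 20
    lattice_spacing: float = 1.0
    jump_rate: float = 1.0
    bias_p: float = 0.5
    active_scent_time: float = 0.0
    n_animals: int | None = None
    n_rays: int = 12
    seed: int = 0
    t_max: float = 1000.0
    record_every: float = 10.0

    def __post_init__(self) -> None:
        if self.n_animals is None:
            self.n_animals = 2 if self.dimension == 1 else 30
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.dimension not in (1, 2):
            raise ConfigurationError(f"dimension must be 1 or 2, got {self.dimension}")
        if self.cp_sites < 2:
            raise ConfigurationError("cp_sites (L/a) must be at least 2")
        for name in ("lattice_spacing", "jump_rate", "t_max", "record_every"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.active_scent_time < 0:
            raise ConfigurationError("active_scent_time must be non-negative")
        if not 0.5 <= self.bias_p <= 1.0:
            raise ConfigurationError(
                "bias_p must lie in [0.5, 1] so that drift points toward the CP"
            )
        if self.dimension == 1:
            if self.n_animals < 2:
                raise ConfigurationError("1D runs need at least 2 animals")
        else:
            ncols, nrows = self._grid_shape()
            if ncols * nrows != self.n_animals:
                raise ConfigurationError(
                    f"n_animals={self.n_animals} does not factor into a "
                    "ncols x nrows CP grid with nrows even; the torus cannot "
                    "tile the hexagonal CP arrangement (dimension 2)"
                )
            if self.n_rays < 3:
                raise ConfigurationError("n_rays must be at least 3")

    # -- geometry ------------------------------------------------------
    def _grid_shape(self) -> tuple[int, int]:
        """Factor ``n_animals`` into an (ncols, nrows) CP grid, nrows even.

        Alternating half-row offsets need an even number of rows to wrap
        periodically.  The squarest admissible factorisation is used.
        """
        n = self.n_animals
        best = None
        for nrows in range(2, n + 1, 2):
            if n % nrows:
                continue
            ncols = n // nrows
            score = abs(math.log(ncols / (nrows * SQRT3_2)))
            if best is None or score < best[0]:
                best = (score, ncols, nrows)
        if best is None:
            return (n, 0)  # triggers the validate() error
        return best[1], best[2]

    @property
    def row_height(self) -> int:
        """Vertical CP spacing in sites, the nearest integer to sqrt(3)/2 L/a."""
        return max(1, round(SQRT3_2 * self.cp_sites))

    @property
    def lattice_shape(self) -> tuple[int, ...]:
        if self.dimension == 1:
            return (self.n_animals * self.cp_sites,)
        ncols, nrows = self._grid_shape()
        return (ncols * self.cp_sites, nrows * self.row_height)

    def cp_positions(self) -> np.ndarray:
        """CP lattice sites: shape (n_animals,) in 1D, (n_animals, 2) in 2D."""
        if self.dimension == 1:
            return np.arange(self.n_animals, dtype=np.int64) * self.cp_sites
        ncols, nrows = self._grid_shape()
        Lx, _ = self.lattice_shape
        cps = np.empty((self.n_animals, 2), dtype=np.int64)
        k = 0
        for j in range(nrows):
            xoff = (self.cp_sites // 2) if j % 2 else 0
            for i in range(ncols):
                cps[k, 0] = (i * self.cp_sites + xoff) % Lx
                cps[k, 1] = j * self.row_height
                k += 1
        return cps

    # -- continuum-limit quantities ------------------------------------
    @property
    def cp_spacing(self) -> float:
        """Distance L between adjacent CPs (length units)."""
        return self.cp_sites * self.lattice_spacing

    @property
    def diffusion_constant(self) -> float:
        a, F = self.lattice_spacing, self.jump_rate
        return F * a * a / 2.0 if self.dimension == 1 else F * a * a / 4.0

    @property
    def drift_speed(self) -> float:
        a, F = self.lattice_spacing, self.jump_rate
        v1 = (2.0 * self.bias_p - 1.0) * F * a
        return v1 if self.dimension == 1 else v1 / 2.0

    @property
    def beta(self) -> float:
        """Dimensionless drift strength v L / D = 2 (2p-1) L / a."""
        return self.drift_speed * self.cp_spacing / self.diffusion_constant

    @property
    def density(self) -> float:
        """Animal population density (per length in 1D, per area in 2D)."""
        if self.dimension == 1:
            return self.n_animals / (self.lattice_shape[0] * self.lattice_spacing)
        Lx, Ly = self.lattice_shape
        return self.n_animals / (Lx * Ly * self.lattice_spacing**2)

    @property
    def diffusive_time(self) -> float:
        """K1 = 1/(2 D rho^2) in 1D, K2 = 1/(4 D rho) in 2D."""
        D, rho = self.diffusion_constant, self.density
        return 1.0 / (2.0 * D * rho * rho) if self.dimension == 1 else 1.0 / (4.0 * D * rho)

    @property
    def Z(self) -> float:
        """Active scent time over the diffusive time."""
        return self.active_scent_time / self.diffusive_time

    # -- inverse maps --------------------------------------------------
    def with_dimensionless(self, beta: float | None = None, Z: float | None = None) -> "SimConfig":
        """Return a copy with bias_p / active_scent_time set from (beta, Z)."""
        kw = dataclasses.asdict(self)
        if beta is not None:
            if beta < 0:
                raise ConfigurationError("beta must be non-negative")
            p = 0.5 + beta * self.lattice_spacing / (4.0 * self.cp_spacing)
            if p > 1.0:
                raise ConfigurationError(
                    f"beta={beta} needs bias_p={p:.3f} > 1; enlarge cp_sites"
                )
            kw["bias_p"] = p
        if Z is not None:
            if Z < 0:
                raise ConfigurationError("Z must be non-negative")
            kw["active_scent_time"] = Z * self.diffusive_time
        return SimConfig(**kw)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path} does not contain a mapping")
        return cls.from_dict(data)


CONVENTIONS = {
    "K1": "1 / (2 * D * rho**2)",
    "K2": "1 / (4 * D * rho)",
    "beta": "v * L / D = 2 * (2p - 1) * L / a",
    "D": "F a^2/2 per axis (1D), F a^2/4 per axis (2D)",
    "v": "(2p - 1) F a (1D), (2p - 1) F a / 2 (2D)",
}
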