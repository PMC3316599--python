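"""Border mean-square-displacement analysis and the (beta, Z) calibration map.

The saturation MSD of the dimensionless territory border is the bridge
between the microscopic simulation and the reduced analytic model: the
analytic border-spread parameter ``eps`` is fixed by equating the variance
of the analytic border (or radius) distribution with the saturation MSD
measured here, and the inference programme inverts the calibration surface
``(beta, Z) -> saturation MSD`` to recover the active scent time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .config import SimConfig
from .lattice import TrajectoryRecord, run_replicates


@dataclass
class MSDCurve:
    times: np.ndarray
    msd: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.msd)):
            raise ValueError("MSD curve contains non-finite values")


@dataclass
class DimensionlessParams:
    Z: float
    beta: float


@dataclass
class SaturationResult:
    value: float
    saturated: bool
    relative_trend: float


def dimensionless_parameters(config: SimConfig) -> DimensionlessParams:
    """(Z, beta) of a configuration under the conventions in :mod:`config`."""
    if config.cp_spacing <= 0 or config.diffusion_constant <= 0:
        raise ValueError("cp_spacing and diffusion constant must be positive")
    return DimensionlessParams(Z=config.Z, beta=config.beta)


# ---------------------------------------------------------------------------


def _observable_matrix(rec: TrajectoryRecord) -> np.ndarray:
    """(n_samples, n_tracks) border observable in units of L."""
    L = rec.config.cp_spacing
    if rec.config.dimension == 1:
        return rec.borders_unwrapped() / L
    n_rec = rec.borders.shape[0]
    flat = rec.borders.reshape(n_rec, -1) * rec.config.lattice_spacing / L
    return flat


def compute_msd(records: list[TrajectoryRecord], reference: str = "initial",
                skip_fraction: float = 0.0) -> MSDCurve:
    """Ensemble (and, in 2D, ray-) averaged border MSD, non-dimensionalised by L^2.

    reference="initial" measures displacement from the first defined sample
    of each track (in 1D the initial border sits exactly at the mean +-L/2,
    so the saturation value estimates the stationary variance directly);
    reference="mean" measures spread about each track's time average over
    the trailing ``1 - skip_fraction`` of the run, appropriate in 2D where
    the radius grows from zero through an initial transient.
    """
    if not records:
        raise ValueError("need at least one replicate")
    cfg0 = records[0].config.to_dict()
    for r in records[1:]:
        d = r.config.to_dict()
        if {k: v for k, v in d.items() if k != "seed"} != {k: v for k, v in cfg0.items() if k != "seed"}:
            raise ValueError("replicates were run with mixed configurations")
    times = records[0].times
    acc = np.zeros(len(times))
    cnt = np.zeros(len(times))
    i0 = int(len(times) * skip_fraction)
    for rec in records:
        obs = _observable_matrix(rec)
        for j in range(obs.shape[1]):
            track = obs[:, j]
            finite = np.isfinite(track)
            if not finite.any():
                continue
            if reference == "initial":
                ref = track[np.argmax(finite)]
            elif reference == "mean":
                tail = track[i0:][np.isfinite(track[i0:])]
                if tail.size == 0:
                    continue
                ref = tail.mean()
            else:
                raise ValueError(f"unknown reference {reference!r}")
            d2 = (track - ref) ** 2
            ok = np.isfinite(d2)
            acc[ok] += d2[ok]
            cnt[ok] += 1
    msd = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    keep = cnt > 0
    return MSDCurve(times=times[keep], msd=msd[keep], n_replicates=len(records))


def detect_saturation(curve: MSDCurve, window_fraction: float = 0.4,
                      slope_tol: float = 0.2) -> SaturationResult:
    """Trailing-window slope test for MSD saturation.

    The curve is saturated when the fitted linear trend over the trailing
    window, accumulated across the window, is below ``slope_tol`` of the
    window's mean level.  The saturation value is the window mean.

    The defaults separate the slowest growth the border exclusion process
    produces from a plateau: over the trailing 40% of a run a power-law
    MSD with exponent >= 1/2 rises by at least (1/0.6)^0.5 - 1 ~ 0.29,
    while a genuine plateau's trend tends to zero; 0.2 sits between the
    two with margin for ensemble noise.
    """
    if curve.times.size < 20:
        raise ValueError("need at least 20 time points to test saturation")
    n = curve.times.size
    i0 = int(n * (1 - window_fraction))
    t, m = curve.times[i0:], curve.msd[i0:]
    level = float(m.mean())
    if level <= 0:
        return SaturationResult(value=level, saturated=True, relative_trend=0.0)
    slope = stats.linregress(t, m).slope
    rel = float(slope * (t[-1] - t[0]) / level)
    return SaturationResult(value=level, saturated=abs(rel) < slope_tol, relative_trend=rel)


def msd_loglog_exponent(curve: MSDCurve, decade: float = 10.0) -> float:
    """Log-log growth exponent fitted over the trailing factor-``decade`` of time."""
    t, m = curve.times, curve.msd
    ok = (t > 0) & (m > 0)
    t, m = t[ok], m[ok]
    sel = t >= t[-1] / decade
    return float(stats.linregress(np.log(t[sel]), np.log(m[sel])).slope)


# ---------------------------------------------------------------------------
# calibration surface


@dataclass
class CalibrationMap:
    """Grid of (beta, Z) -> saturation border MSD with per-beta trend lines.

    Trend lines are straight in log-log: log(msd_sat) = slope*log(Z) + intercept,
    one per calibrated beta, fitted over the saturated grid points.
    """

    betas: np.ndarray
    Zs: np.ndarray
    msd_sat: np.ndarray          # (n_beta, n_Z); NaN where unsaturated
    stderr: np.ndarray
    line_slope: np.ndarray       # (n_beta,)
    line_intercept: np.ndarray
    dimension: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, float)
        self.Zs = np.asarray(self.Zs, float)
        self.msd_sat = np.asarray(self.msd_sat, float)

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "betas": self.betas.tolist(),
            "Zs": self.Zs.tolist(),
            "msd_sat": self.msd_sat.tolist(),
            "stderr": np.asarray(self.stderr).tolist(),
            "line_slope": np.asarray(self.line_slope).tolist(),
            "line_intercept": np.asarray(self.line_intercept).tolist(),
            "dimension": self.dimension,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationMap":
        d = json.loads(Path(path).read_text())
        return cls(
            betas=np.array(d["betas"]), Zs=np.array(d["Zs"]),
            msd_sat=np.array(d["msd_sat"]), stderr=np.array(d["stderr"]),
            line_slope=np.array(d["line_slope"]),
            line_intercept=np.array(d["line_intercept"]),
            dimension=d["dimension"], provenance=d.get("provenance", {}),
        )

    # -- lookup --------------------------------------------------------
    def _line_lookup(self, ib: int, msd: float) -> float:
        logZ = (np.log(msd) - self.line_intercept[ib]) / self.line_slope[ib]
        return float(np.exp(logZ))

    def attainable_range(self, beta: float) -> tuple[float, float]:
        ib = self._bracket(beta)
        vals = []
        for i in ib:
            v = np.exp(self.line_intercept[i] + self.line_slope[i] * np.log(self.Zs))
            vals.append((v.min(), v.max()))
        return (min(v[0] for v in vals), max(v[1] for v in vals))

    def _bracket(self, beta: float) -> tuple[int, ...]:
        b = self.betas
        if beta < b[0] - 1e-9 or beta > b[-1] + 1e-9:
            raise ValueError(f"beta={beta} outside calibrated range [{b[0]}, {b[-1]}]")
        j = int(np.searchsorted(b, beta))
        if j < len(b) and abs(b[j] - beta) < 1e-9:
            return (j,)
        if j > 0 and abs(b[j - 1] - beta) < 1e-9:
            return (j - 1,)
        return (j - 1, j)

    def lookup_Z(self, beta: float, msd_sat: float) -> tuple[float, float]:
        """Invert the per-beta trend lines: (Z, stderr_Z).

        For beta between calibrated values the two per-beta inversions are
        interpolated linearly in beta.  Raises with the attainable interval
        when ``msd_sat`` is outside the calibrated surface for this beta.
        """
        if msd_sat <= 0:
            raise ValueError("msd_sat must be positive")
        lo, hi = self.attainable_range(beta)
        slack = 2.0  # tolerate calibration scatter at the grid edges
        if not (lo / slack <= msd_sat <= hi * slack):
            raise ValueError(
                f"msd_sat={msd_sat:.4g} outside attainable range "
                f"[{lo:.4g}, {hi:.4g}] for beta={beta}"
            )
        idx = self._bracket(beta)
        zs = [self._line_lookup(i, msd_sat) for i in idx]
        if len(zs) == 1:
            Z = zs[0]
        else:
            w = (beta - self.betas[idx[0]]) / (self.betas[idx[1]] - self.betas[idx[0]])
            Z = (1 - w) * zs[0] + w * zs[1]
        # propagate the grid scatter through the line inversion
        rel = float(np.nanmean(self.stderr / np.where(np.isnan(self.msd_sat), np.inf, self.msd_sat)))
        mean_slope = float(np.mean([abs(self.line_slope[i]) for i in idx]))
        err = Z * rel / max(mean_slope, 1e-9)
        return float(Z), float(err)


def calibrate_saturation_map(
    base_config: SimConfig,
    betas,
    Zs,
    replicates: int = 20,
    seed: int = 0,
    window_fraction: float = 0.4,
    slope_tol: float = 0.5,
) -> CalibrationMap:
    """Build the (beta, Z) -> saturation-MSD surface from simulations.

    Every grid point runs ``replicates`` independent simulations of
    ``base_config`` re-parameterised through ``with_dimensionless``;
    unsaturated points are flagged (NaN) and excluded from the per-beta
    log-log trend lines.  Reproducible for a fixed seed.
    """
    betas = np.sort(np.asarray(betas, float))
    Zs = np.sort(np.asarray(Zs, float))
    nb, nz = len(betas), len(Zs)
    msd_sat = np.full((nb, nz), np.nan)
    stderr = np.full((nb, nz), np.nan)
    ref = "initial" if base_config.dimension == 1 else "mean"
    rng_seeds = np.random.SeedSequence(seed).spawn(nb * nz)
    for i, b in enumerate(betas):
        for j, Zv in enumerate(Zs):
            cfg = base_config.with_dimensionless(beta=b, Z=Zv)
            sub = int(rng_seeds[i * nz + j].generate_state(1)[0] % (2**31 - 1))
            recs = run_replicates(cfg, replicates, sub)
            curve = compute_msd(recs, reference=ref, skip_fraction=0.5)
            sat = detect_saturation(curve, window_fraction, slope_tol)
            if sat.saturated and sat.value > 0:
                msd_sat[i, j] = sat.value
                # replicate-to-replicate scatter of the trailing mean
                tails = []
                for r in recs:
                    c1 = compute_msd([r], reference=ref, skip_fraction=0.5)
                    n0 = int(len(c1.msd) * (1 - window_fraction))
                    tails.append(c1.msd[n0:].mean())
                stderr[i, j] = float(np.std(tails) / np.sqrt(max(len(tails) - 1, 1)))
    slope = np.full(nb, np.nan)
    intercept = np.full(nb, np.nan)
    for i in range(nb):
        ok = np.isfinite(msd_sat[i]) & (Zs > 0)
        if ok.sum() >= 2:
            fit = stats.linregress(np.log(Zs[ok]), np.log(msd_sat[i, ok]))
            slope[i], intercept[i] = fit.slope, fit.intercept
    return CalibrationMap(
        betas=betas, Zs=Zs, msd_sat=msd_sat, stderr=stderr,
        line_slope=slope, line_intercept=intercept,
        dimension=base_config.dimension,
        provenance={
            "seed": seed, "replicates": replicates,
            "base_config": base_config.to_dict(),
            "reference": ref,
        },
    )
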