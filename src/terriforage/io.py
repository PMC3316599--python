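"""Reading relocation CSVs, writing run artefacts, fixture generation.

The relocation dialect is a plain comma-separated file with header
``animal_id,x,y,t`` in consistent planar units; rows with non-finite
coordinates are dropped (and counted), and out-of-order timestamps are
sorted with a warning.  Every artefact written by the package carries a
JSON run manifest recording the configuration, seeds, package version and
the dimensionless conventions in force.
"""

from __future__ import annotations

import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CONVENTIONS, SimConfig
from .inference import RelocationDataset
from .lattice import TrajectoryRecord

log = logging.getLogger("terriforage")

REQUIRED_COLUMNS = ["animal_id", "x", "y", "t"]


def read_relocations(path, min_fixes: int = 30, **dataset_kw) -> RelocationDataset:
    """Load and validate a relocation CSV.

    Raises on a missing column or an empty file; drops non-finite rows with
    a logged count; sorts timestamps per animal with a warning if needed.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no relocation rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    coords = df[["x", "y", "t"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coords.to_numpy()).all(axis=1)
    if bad.any():
        log.warning("%s: dropped %d row(s) with non-finite coordinates", path, int(bad.sum()))
        df = df[~bad]
        coords = coords[~bad]
    df = df.assign(x=coords.x, y=coords.y, t=coords.t)
    for a, grp in df.groupby("animal_id"):
        if not grp.t.is_monotonic_increasing:
            warnings.warn(f"timestamps out of order for animal {a!r}; sorting", stacklevel=2)
            break
    return RelocationDataset(data=df[REQUIRED_COLUMNS], min_fixes=min_fixes, **dataset_kw)


# ---------------------------------------------------------------------------


def run_manifest(config: SimConfig | dict, seed: int, extra: dict | None = None) -> dict:
    cfg = config.to_dict() if isinstance(config, SimConfig) else dict(config)
    m = {
        "config": cfg,
        "seed": seed,
        "package": "terriforage",
        "version": __version__,
        "conventions": dict(CONVENTIONS),
        "created": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        m.update(extra)
    return m


def write_trajectory(rec: TrajectoryRecord, out_dir, seed: int) -> Path:
    """Serialise a trajectory as a long-format CSV plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    a = rec.config.lattice_spacing
    if rec.config.dimension == 1:
        for it, t in enumerate(rec.times):
            for i in range(rec.config.n_animals):
                rows.append((t, i, rec.positions[it, i] * a, 0.0, rec.borders[it, i] * a))
        cols = ["t", "animal_id", "x", "y", "border"]
    else:
        for it, t in enumerate(rec.times):
            for i in range(rec.config.n_animals):
                rows.append(
                    (t, i, rec.positions[it, i, 0] * a, rec.positions[it, i, 1] * a,
                     rec.borders[it, i].mean() * a)
                )
        cols = ["t", "animal_id", "x", "y", "mean_radius"]
    pd.DataFrame(rows, columns=cols).to_csv(out_dir / "trajectory.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(run_manifest(rec.config, seed), indent=1))
    return out_dir / "trajectory.csv"


def save_calibration_csv(cal, path) -> None:
    """CSV companion of the JSON calibration map (long format)."""
    rows = []
    for i, b in enumerate(cal.betas):
        for j, z in enumerate(cal.Zs):
            rows.append((b, z, cal.msd_sat[i, j], cal.stderr[i, j]))
    pd.DataFrame(rows, columns=["beta", "Z", "msd_sat", "stderr"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixtures


def generate_fixture(kind: str, out_path, seed: int, *, params=None, config=None,
                     n: int = 1000, L: float = 1.0) -> Path:
    """Write a seeded synthetic relocation CSV plus its manifest.

    kind="analytic" draws i.i.d. fixes from the stationary 2D marginal
    (``params`` is an Analytic2DParams); kind="sim" runs the full 2D
    simulator (``config`` is a SimConfig) and exports every animal's
    positions.  Byte-identical for a fixed seed.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "analytic":
        from .analytic2d import sample_relocations

        if params is None:
            raise ValueError("analytic fixtures need params")
        df = sample_relocations(params, n, seed, L=L)
        meta = {"kind": kind, "beta": params.beta, "eps": params.eps, "n": n, "L": L}
    elif kind == "sim":
        from .lattice import run_simulation

        if config is None:
            raise ValueError("sim fixtures need a config")
        rec = run_simulation(config, seed=seed)
        a = config.lattice_spacing
        rows = []
        if config.dimension != 2:
            raise ValueError("sim fixtures are 2D relocation sets")
        for it, t in enumerate(rec.times):
            for i in range(config.n_animals):
                rows.append((f"a{i}", rec.positions[it, i, 0] * a, rec.positions[it, i, 1] * a, t))
        df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
        meta = {"kind": kind, "config": config.to_dict()}
    else:
        raise ValueError("kind must be 'analytic' or 'sim'")
    df.to_csv(out_path, index=False, float_format="%.8g")
    Path(str(out_path) + ".manifest.json").write_text(
        json.dumps(run_manifest(meta if kind == "analytic" else config, seed), indent=1)
    )
    return out_path
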