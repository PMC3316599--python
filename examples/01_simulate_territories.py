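"""Simulate territorial central-place foragers on a 1D ring.

Two animals deposit scent wherever they walk; scent stays active for the
active scent time T_AS and blocks the neighbour.  With a movement bias
toward each animal's central place (CP) the territory borders stop
wandering: their mean square displacement (MSD) saturates.
"""

import numpy as np

from terriforage.borders import compute_msd, detect_saturation
from terriforage.config import SimConfig
from terriforage.lattice import run_replicates

# beta = 4 (dimensionless drift strength v L / D), Z = 1 (T_AS equal to the
# diffusive time K1 = 1/(2 D rho^2))
cfg = SimConfig(dimension=1, cp_sites=20, t_max=50_000, record_every=50,
                ).with_dimensionless(beta=4.0, Z=1.0)
print(f"ring of {cfg.lattice_shape[0]} sites, 2 animals, "
      f"T_AS = {cfg.active_scent_time:.0f} (Z = {cfg.Z:.1f}), "
      f"bias p = {cfg.bias_p:.3f} (beta = {cfg.beta:.1f})")

recs = run_replicates(cfg, 50, seed=1)
curve = compute_msd(recs)          # border MSD in units of L^2
sat = detect_saturation(curve)

print(f"border MSD at t = {curve.times[-1]:.0f}: {curve.msd[-1]:.4f} L^2")
print(f"saturated: {sat.saturated}; saturation value {sat.value:.4f} L^2")
print("-> the borders fluctuate around +-L/2 with a stationary spread; the")
print("   saturation value is what the inference programme inverts for Z.")

cfg0 = cfg.with_dimensionless(beta=0.0)
sat0 = detect_saturation(compute_msd(run_replicates(cfg0, 50, seed=2)))
print(f"\nwithout the CP bias the same test reports saturated = {sat0.saturated}:")
print("   borders keep ebbing and flowing and no stable home range forms.")
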