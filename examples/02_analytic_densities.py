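"""Evaluate the reduced adiabatic densities in 1D and 2D.

The slow borders / fast animal separation factorises the stationary state
into border distributions (method-of-images Gaussians about the mid-points
between central places) and a Holgate-Okubo conditional exp(-beta r)
truncated to the territory.  Everything is in CP-centred coordinates with
lengths in units of the CP spacing L.
"""

import numpy as np

from terriforage.analytic1d import Analytic1DParams, border_pdf, marginal_pdf_1d
from terriforage.analytic2d import (
    Analytic2DParams,
    marginal_radial_pdf_2d,
    radius_msd_from_params,
    radius_pdf,
)

p1 = Analytic1DParams(beta=4.0, eps=0.12)
z = np.linspace(-1, 1, 801)
pdf = marginal_pdf_1d(z, p1)
print(f"1D marginal (beta=4, eps=0.12): peak {pdf.max():.3f} at z = "
      f"{z[np.argmax(pdf)]:.3f}, mass {np.trapezoid(pdf, z):.6f}")
print(f"   density at the conspecific CPs p(+-1) = {pdf[0]:.3f} (the animal")
print("   cannot tread there); the exponential core has decay length 1/beta.")

zb = np.linspace(-1, 0, 401)
qb = border_pdf("left", zb, p1)
print(f"left border density: mode at z = {zb[np.argmax(qb)]:.3f} (mean -1/2)")

p2 = Analytic2DParams(beta=4.0, eps=0.12)
r = np.linspace(0, 1.2, 601)
f = marginal_radial_pdf_2d(r, p2)
print(f"\n2D radial marginal: mode at r = {r[np.argmax(f)]:.3f} L, "
      f"mass {np.trapezoid(f, r):.6f}")
R = np.linspace(0, 1.5, 601)
q = radius_pdf(R, p2)
print(f"territory radius: mode at R = {R[np.argmax(q)]:.3f} L; "
      f"radius MSD = {radius_msd_from_params(p2):.5f} L^2")
print("-> the radius MSD is the analytic counterpart of the simulated border")
print("   saturation MSD: equating the two is the bridge used for inference.")
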