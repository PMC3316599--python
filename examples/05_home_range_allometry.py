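"""Home-range size, buffer zones and exclusive-area fractions.

The 95% home-range radius R95 is the radius enclosing 95% of the
stationary space-use density (units of the CP spacing).  R95 < 1/2 leaves
an unclaimed buffer strip between neighbours; beyond that the home range
overlaps the six hexagonal neighbours and the exclusive fraction falls.
"""

import numpy as np

from terriforage.analytic2d import Analytic2DParams
from terriforage.homerange import exclusive_area_fraction, fit_sigmoid, home_range, sigmoid_value

betas = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 14.0])
r95 = []
for b in betas:
    hr = home_range(Analytic2DParams(beta=b, eps=0.1))
    r95.append(hr.R95)
    print(f"beta={b:5.1f}: R95={hr.R95:.3f} L  buffer_zone={hr.buffer_zone}"
          f"  exclusive_fraction={hr.exclusive_fraction:.3f}")

coef, resid = fit_sigmoid(np.log(betas), np.array(r95))
print(f"\nsigmoid summary of R95 vs ln(beta): coefficients "
      f"{np.round(coef, 3)}, residual norm {resid:.4f}")
print(f"interpolated R95 at beta=3: {sigmoid_value(np.log(3.0), coef):.3f} L")
print("-> stronger attachment to the den shrinks the home range; once R95")
print("   drops below L/2 a wolf-style buffer zone opens between territories.")
print(f"   exclusive fraction at R95=0.60: {exclusive_area_fraction(0.60):.3f}")
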