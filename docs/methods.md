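# Methods

## The stochastic simulation model

Animals are random walkers on a 1D ring or a 2D rectangular torus.  Each
animal attempts one nearest-neighbour jump per sweep in a fresh random
order (random-sequential update); time advances by `1/(n F)` per attempt so
a sweep lasts `1/F`.  In 1D the step is toward the animal's central place
(CP) with probability `p` and away with `1−p`; at the CP (or its antipode)
the direction is symmetric.  In 2D the four move probabilities are
`(1 ± (2p−1)uᵢ)/4` with `u` the unit vector toward the CP under the
minimal image — the expected step points at the CP with a magnitude
independent of distance, which is the discrete counterpart of the
Holgate–Okubo localising tendency (constant-speed drift toward a focal
point).

After every attempt the animal re-marks the site it stands on with a
timestamp; a single `(owner, time)` record per site suffices because an
animal always stands on its own active scent, so no site can carry two
live claims.  A move is rejected — the animal stays put for that attempt —
when the target site carries foreign scent younger than the active scent
time `T_AS`; expired scent is treated as absent (deleted lazily).
Animals start on their CPs with an empty scent field.

CP layouts: 1D, `n` CPs uniformly spaced `L/a` sites apart (ring length
`n·L/a`); 2D, a triangular (hexagonal-centroid) CP grid realised on the
square lattice with alternating half-row offsets and the row height
rounded to `√3/2·L/a` sites.  An even number of CP rows is required so the
offsets wrap; `n_animals` must factor accordingly (30 → 5 columns × 6
rows).  Nearest-CP distances are within one site of `L`.

Continuum-limit constants, recorded in every run manifest: `D = Fa²/2`
(1D) or `Fa²/4` per axis (2D, because a given axis is chosen half the
time), `v = (2p−1)Fa` (1D) or half that (2D), so `β = vL/D = 2(2p−1)L/a`
in both dimensions.  Diffusive times `K₁ = 1/(2Dρ²)`, `K₂ = 1/(4Dρ)`;
`Z = T_AS/K`.

### Border observables

* **1D.**  The sites an animal marked within the last `T_AS` form a
  contiguous arc (the range of a continuous path), found as the complement
  of the largest circular gap among its active sites.  The border between
  adjacent territories is the midpoint of the interstitial gap between the
  facing arc ends; tracks are unwrapped across the periodic boundary by
  minimal-displacement continuity.  With animals started on their CPs the
  first defined border sits at ±L/2 — exactly the stationary mean — so the
  MSD referenced to the initial border estimates the stationary variance
  directly.
* **2D.**  A scent territory is the trace of a lattice walk and contains
  one-site holes, so the radius observable marches outward from the CP
  along `n_rays` (default 12) equally spaced bearings in half-site steps,
  tolerating unclaimed gaps up to 2 sites wide; active foreign scent, or a
  wider gap, ends the ray.  The radius grows from zero through an initial
  transient, so 2D border MSDs are referenced to each ray's time mean over
  the trailing half of the run rather than to the initial value.

### Saturation detection

A curve is saturated when the least-squares linear trend over the trailing
40% of the run, accumulated across that window, is below 20% of the window
mean.  The defaults separate the slowest growth this system produces from
a plateau: a power law with exponent ≥ 1/2 rises by ≥ (1/0.6)^½−1 ≈ 29%
across the window, while a plateau's trend tends to zero; 0.2 sits between
the two with margin for ensemble noise.  During calibration the tolerance
is relaxed to 0.5 because grid points run ≥ 20 border relaxation times and
small-ensemble trend estimates are noisy.  For single telemetry tracks
(time-binned squared distance from the CP, ≥ 20 bins) the flag combines
|trend| < 0.35 with an across-bin coefficient of variation < 0.35: a
wandering track shows large swings about its own median even when the
trailing trend happens to be flat (measured CV ≤ 0.26 for stationary
tracks vs ≥ 0.48 for unbounded walks at 750 fixes).

## The reduced analytic models

Working in CP-centred coordinates with lengths in units of `L`, the
timescale separation between subdiffusive borders and diffusive animals
factorises the joint stationary density into border factors times a
conditional animal density.

**Borders (1D).**  Each border performs an Ornstein–Uhlenbeck-like motion
about the midpoint between CPs with reflecting walls at the CPs
(territories cannot swallow a neighbour's den).  On the subdiffusive clock
`u = √t` the mean relaxes as `e^{−λu}` and the variance as
`ε²(1 − e^{−2λu})`; the border diffusion constant `K_b` and spring rate
`λ` enter the steady state only through `ε = √(K_b/λ)`.  The walls are
imposed by the method of images: reflections of the spring centre ∓1/2
through walls one unit apart land on every half-integer, so the steady
state is the wrapped Gaussian

```
q(z) = Σₙ G_ε(z + 1/2 + n)   on (−1, 0)   (mirror image on (0, 1)),
```

which normalises exactly by the folding argument.  Poisson resummation
gives the equivalent Fourier form `1 + 2Σ_k e^{−2π²k²ε²}(−1)^k cos 2πkz`;
both representations are implemented and agree to 1e-10, and the cosine-
integral structure of the one-parameter collapse below confirms the
period-1 wrapped form.  The image construction solves the reflected
Fokker–Planck problem exactly only up to boundary-tail corrections of
order `Φ(−1/(2ε))`; the Crank–Nicolson oracle test therefore runs in the
regime `ε ≤ 0.13` (tail < 1e-4), spanning a 20× range of spring rates.
Physically `ε ≪ 1/2` is also the only regime in which the adiabatic
picture of a small, slowly breathing border makes sense.

**Animal conditional.**  Between fixed borders the stationary density of
the biased walker is the truncated exponential `∝ e^{−β|z|}` (1D) or
`∝ e^{−βr}` on the disc of radius `R` (2D), normalised in closed form; the
2D normaliser `C(β,R) = ∫₀^R r e^{−βr} dr` is evaluated in closed form
with a quartic series below `βR < 10⁻²` to avoid cancellation, and is
cross-checked against adaptive quadrature to 1e-8.

**Marginals.**  1D: a double Gauss–Legendre quadrature of the joint over
admissible border positions (64 nodes per axis).  2D: the radius integral
`∫ q(R)/C(β,R) dR` is precomputed cumulatively on a hybrid grid —
geometric near `R = 0`, where the integrand can behave like `1/R²` (the
planar density then diverges at the CP while the radial density stays
finite), linear elsewhere — truncated where the radius density's tail
drops below 1e-12.  The marginal vanishes at the conspecific CPs in 1D and
tails off sharply at large `β` in 2D.

**Radius MSD (the inference bridge).**  The saturation MSD of the
territory radius equals the variance of the radius distribution, computed
in closed form through the folded-normal moments of `|N(1/2, ε²)|`.  It is
monotone in `ε`, vanishes in the frozen-border limit, and is the quantity
equated with the simulator's border saturation MSD.

**One-parameter collapse.**  Pinning the inner border at the den and
letting `β → 0` collapses the half-territory marginal to

```
p(z) = −ln z + 2 Σ_k (−1)^k e^{−2π²ε²k²} [Ci(2πk) − Ci(2πkz)],
```

with `Ci` the cosine integral; the implementation of the general form
converges to this limit at sup-distance < 1e-3.

## Calibration and inference

`calibrate_saturation_map` runs seeded ensembles across a `(β, Z)` grid,
stores the saturation MSD ± replicate stderr, flags unsaturated points
(excluded from fits), and fits one straight line per `β` in
`log(MSD) vs log Z` — the surface is monotone decreasing in both `β`
(stronger attraction keeps animals in a small core) and `Z` (longer-lived
scent pins the borders; the `Z → 0` limit, borders set by the CP springs
alone, is the loosest).  `lookup_Z` inverts the per-`β` lines and
interpolates linearly in `β`, with an error from the map's relative
scatter propagated through the line slope, and reports the attainable
interval when asked for an MSD off the surface.

The fit of the 2D marginal to telemetry is maximum likelihood in the
dimensionless radii `r/L` under the radial density `2πr p(r)`, evaluated
on a dense grid with log-linear interpolation (validated against direct
quadrature to 1e-3 in summed log-likelihood), multi-start Nelder–Mead
within `β ∈ [0, 40]`, `ε ∈ [0.005, 0.45]`, standard errors from the
numerical Hessian.  A histogram least-squares variant (binned radial
histogram vs the density) is exposed as a fidelity cross-check; the two
estimators agree to ~1% on clean draws but only the likelihood route
carries standard errors.  Temporal autocorrelation of fixes is ignored in the
likelihood (the paper-level model is a stationary spatial density); the
KS statistic of the radial fit is reported as a diagnostic.  CP defaults
to the coordinate-wise median of fixes, `L` to the mean nearest-neighbour
distance among CPs; both can be supplied.  Delta-method intervals
propagate `ε̂` and calibration scatter into `Ẑ` and `T̂_AS = Ẑ·K₂`.

## Home-range geometry and the RD comparison

The 95% MCP home range of the rotationally symmetric stationary density is
operationalised as the 95% probability-mass radius (bisection to 1e-8); an
empirical convex-hull MCP utility is provided for point data.  The
exclusive-area fraction subtracts the six pairwise lenses with the
unit-spaced hexagonal neighbours, exact while triple overlaps are
impossible (`R95 < 1/√3`), with a seeded Monte-Carlo rasterisation beyond
(and as an oracle: agreement within 0.2 percentage points).  `R95(β)`
curves are summarised by least-squares 4-coefficient sigmoids
`a + b/(1+e^{−(x−c)/d})`; the coefficients are a package-internal
parameterisation.  The allometry helper composes a user-supplied
`fraction ∝ mass^(−exponent)` law with the calibrated
`(β, Z) → ε → R95 → fraction` chain to tabulate mass against `Z` (the
`T_AS/K₂` ratio); no allometric exponents are built in.

The reaction-diffusion (RD) comparison solves the two-pack conspecific
avoidance model with over-marking rate zero: at steady state scent is
proportional to animal density and the system reduces to
`u' = −κuv, v' = +κuv` with `∫u = ∫v = 1`, whose solution is the logistic
profile `u = 2/(1+e^{2κ(x−1/2)})`; the free constant is fixed by bracketed
root finding on the conservation condition (landing on `B = e^{−κ}`).
Best-fit maps between `κ` and `(β, ε)` minimise the integrated squared
difference on a shared 2048-point grid; `ε` is held at 10⁻² when fitting
`β(κ)` since a small border spread never worsens the fit.  Both models
converge to the same height-2 step function in the joint limit of
never-decaying scent (`ε → 0`), weak drift (`β → 0`) and `κ → ∞`; away
from that corner their space-use predictions diverge, with best-fit `β`
monotone decreasing in `κ`.

## Synthetic data and what the tests show

`sample_relocations` draws i.i.d. fixes from the stationary 2D marginal by
inverse-CDF sampling of the radius and a uniform bearing; `generate_fixture`
additionally exports full-simulation tracks.  Simulated telemetry differs
from real data in known ways: fixes are i.i.d. or regularly sampled (no
GPS gaps or behavioural autocorrelation beyond the walk itself), the CP is
static, the habitat is homogeneous, and observation error is a uniform
within-cell jitter of ±a/2 (also applied when comparing lattice histograms
with continuum densities, as the standard continuity correction for
discrete positions).  Passing tests therefore demonstrate internal
consistency of model, calibration and inference at desk scale — not
robustness to field-data pathologies.

### Problem sizes and test design choices

All simulation-backed checks are scaled for a single desktop CPU: 1D
ensembles of 40–200 replicates of 2-animal rings (`L/a = 20`, up to 10⁵
sweeps), a 30-territory ring for the single-file subdiffusion exponent,
and 2D runs of 30 animals on `L/a = 12` tori for ≥ 25 border relaxation
times with 5–6 replicates.  Two choices deserve note:

* the subdiffusion exponent is fitted between ~5 collision times
  (`L²/D` sweeps) and the finite-size crossover (`~(NL)²/2D`): a
  2-territory ring has no single-file window (the free collective
  translation mode dominates, exponent → 1), while a 30-territory ring
  yields a stable exponent of 0.53–0.58;
* calibration monotonicity is asserted pointwise up to one joint
  replicate-stderr plus strictly on row/column means, because at 50
  replicates neighbouring grid points can sit within ensemble noise of
  each other even though the underlying surface is strictly ordered.

### Known limitations

The adiabatic densities are accurate when territories are well formed
(`Z` large enough that the scent trace covers the Voronoi cell — in
practice `Z ≳ 8` at these lattice sizes) and the border spread is small;
at short scent lifetimes and weak bias the simulated space use departs
strongly from the analytic marginal (KS ≈ 0.25 at `β = 2, Z = 4` versus
≈ 0.06 at `β = 4, Z = 8`), which is also the regime where the inference
programme should not be trusted.  The full-pipeline `β̂` carries a
downward bias of order 15–20% relative to the nominal lattice `β` because
the simulated confinement is hexagonal-cell-shaped rather than a disc;
the `T_AS` recovery absorbs most of this through the calibration lookup
(median recovery within a factor 1.5).  The transient border solutions
adopt a specific subdiffusive clock (`u = √t`, with diffusion and spring
sharing the `t^{−1/2}` factor so that their ratio — and hence the steady
state — is well defined); only the steady states are used downstream.
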