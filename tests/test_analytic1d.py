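import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from helpers import crank_nicolson_fp, ks_distance, walker_1d_confined
from terriforage import analytic1d as a1
from terriforage.analytic1d import Analytic1DParams


# ---------------------------------------------------------------------------
# border steady state


@pytest.mark.parametrize("side,centre,lo,hi", [("left", -0.5, -1, 0), ("right", 0.5, 0, 1)])
@pytest.mark.parametrize("eps", [0.03, 0.1, 0.3, 0.6])
def test_border_pdf_normalised_and_zero_outside(side, centre, lo, hi, eps):
    p = Analytic1DParams(beta=0.0, eps=eps)
    val, _ = quad(lambda z: float(a1.border_pdf(side, z, p)), lo, hi, limit=200)
    assert val == pytest.approx(1.0, abs=1e-6)
    assert a1.border_pdf(side, lo - 0.1, p) == 0.0
    assert a1.border_pdf(side, hi + 0.1, p) == 0.0


def test_border_mode_at_mean_position_for_stiff_springs():
    # large-lambda (small eps) regime: approximately Gaussian about -+1/2
    p = Analytic1DParams(beta=0.0, eps=0.05)
    z = np.linspace(-0.999, -0.001, 200_001)
    q = a1.border_pdf("left", z, p)
    assert abs(z[np.argmax(q)] + 0.5) < 1e-3
    z = np.linspace(0.001, 0.999, 200_001)
    assert abs(z[np.argmax(a1.border_pdf("right", z, p))] - 0.5) < 1e-3


@pytest.mark.parametrize("K,lam", [
    (0.0008, 0.05), (0.002, 0.2), (0.01, 1.0), (0.02, 4.0), (0.005, 0.4),
])
def test_border_steady_state_matches_fokker_planck_oracle(K, lam):
    """Long-time Crank-Nicolson integration of the border Fokker-Planck
    equation agrees with the image-series steady state (L1 < 1e-3) across a
    wide range of spring rates in the stiff-spring regime."""
    eps = np.sqrt(K / lam)
    z, P = crank_nicolson_fp(K, lam, -0.5, -1.0, 0.0, t_end=30 / lam)
    q = a1.border_pdf("left", z, Analytic1DParams(beta=0.0, eps=eps))
    L1 = np.sum(np.abs(P - q)) / len(z)
    assert L1 < 1e-3


def test_border_variance_monotone_in_eps():
    var = [a1.border_msd_1d(e) for e in (0.02, 0.05, 0.1, 0.2, 0.4, 0.8)]
    assert np.all(np.diff(var) > 0)
    # eps -> 0: variance -> eps^2; eps -> inf: uniform border limit 1/12
    assert var[0] == pytest.approx(0.02**2, rel=1e-3)
    assert var[-1] < 1.0 / 12.0


def test_eps_inversion_round_trip():
    for e in (0.04, 0.12, 0.3):
        assert a1.eps_from_border_msd(a1.border_msd_1d(e)) == pytest.approx(e, rel=1e-6)
    with pytest.raises(ValueError):
        a1.eps_from_border_msd(0.2)  # above the uniform-border limit


# ---------------------------------------------------------------------------
# transient border densities


@pytest.fixture(scope="module")
def transient_params():
    return Analytic1DParams.from_rates(beta=0.0, K_b=0.02, lam=2.0)


@pytest.mark.parametrize("t", [0.01, 0.5, 4.0, 100.0])
def test_dual_series_representations_agree(transient_params, t):
    z = np.linspace(-0.995, -0.005, 173)
    d_img = a1.border_pdf_transient(z, t, transient_params, "images")
    d_poi = a1.border_pdf_transient(z, t, transient_params, "poisson")
    assert np.abs(d_img - d_poi).max() < 1e-10


def test_transient_long_time_limit_is_steady_state(transient_params):
    z = np.linspace(-0.99, -0.01, 101)
    d_inf = a1.border_pdf_transient(z, 1e7, transient_params, "poisson")
    d_ss = a1.border_pdf("left", z, transient_params)
    assert np.abs(d_inf - d_ss).max() < 1e-6


def test_transient_short_time_concentrates_at_start(transient_params):
    z0 = -0.31
    z = np.linspace(-0.99, -0.01, 981)
    d = a1.border_pdf_transient(z, 1e-8, transient_params, "images", z0=z0)
    mass_near = np.trapezoid(np.where(np.abs(z - z0) < 0.02, d, 0.0), z)
    assert mass_near > 0.999


def test_transient_normalised_at_all_times(transient_params):
    for t in (0.05, 1.0, 50.0):
        val, _ = quad(
            lambda z: float(a1.border_pdf_transient(z, t, transient_params, "poisson")),
            -1, 0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)


def test_transient_requires_rates():
    p = Analytic1DParams(beta=0.0, eps=0.1)
    with pytest.raises(ValueError, match="transient"):
        a1.border_pdf_transient(-0.5, 1.0, p)


# ---------------------------------------------------------------------------
# conditional animal density


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    z1=st.floats(-0.95, -0.05), z2=st.floats(0.05, 0.95),
    beta=st.floats(0.0, 12.0),
)
def test_conditional_normalised_on_borders(z1, z2, beta):
    val, _ = quad(lambda z: float(a1.animal_conditional_pdf(z, z1, z2, beta)),
                  z1, z2, limit=100)
    assert val == pytest.approx(1.0, abs=1e-7)


def test_conditional_uniform_at_zero_drift():
    assert a1.animal_conditional_pdf(0.2, -0.5, 0.7, 0.0) == pytest.approx(1 / 1.2)
    # symmetric borders: even density with the mode at the CP
    z = np.linspace(-0.69, 0.69, 139)
    d = a1.animal_conditional_pdf(z, -0.7, 0.7, 3.0)
    np.testing.assert_allclose(d, d[::-1], atol=1e-12)
    assert np.argmax(d) == len(z) // 2


def test_conditional_invalid_borders():
    with pytest.raises(ValueError):
        a1.animal_conditional_pdf(0.0, 0.2, 0.5, 1.0)


def test_conditional_matches_confined_walker_histogram():
    """Stationary histogram of a biased lattice walker between reflecting
    borders agrees with the truncated-exponential conditional (KS < 0.02)."""
    p_toward, L = 0.53, 30
    samples = walker_1d_confined(p_toward, 24, 18, 1500, 30_000, seed=4)
    rng = np.random.default_rng(1)
    zsam = (samples + rng.uniform(-0.5, 0.5, len(samples))) / L
    beta = 2 * (2 * p_toward - 1) * L
    grid = np.linspace(-0.8, 0.6, 2001)
    pdf = a1.animal_conditional_pdf(grid, -0.8, 0.6, beta)
    cdf = np.concatenate([[0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    assert len(zsam) >= 1e5
    assert ks_distance(zsam, grid, cdf) < 0.02


# ---------------------------------------------------------------------------
# joint and marginal


def test_joint_gated_by_heaviside_support():
    p = Analytic1DParams(beta=2.0, eps=0.1)
    assert a1.joint_pdf(-0.5, 0.5, 0.7, p) == 0.0   # z outside (z1, z2)
    assert a1.joint_pdf(-0.5, 0.5, -0.6, p) == 0.0
    assert a1.joint_pdf(-0.5, 0.5, 0.2, p) > 0.0


def test_joint_triple_integral_is_one():
    p = Analytic1DParams(beta=1.5, eps=0.1)
    from numpy.polynomial.legendre import leggauss

    x, w = leggauss(48)
    z1, w1 = 0.5 * (x - 1.0), 0.5 * w   # (-1, 0)
    z2, w2 = 0.5 * (x + 1.0), 0.5 * w   # (0, 1)
    # integrate the conditional over z in closed form: it is normalised,
    # so the triple integral reduces to the border-product double integral
    qa = np.array([float(a1.border_pdf("left", v, p)) for v in z1])
    qb = np.array([float(a1.border_pdf("right", v, p)) for v in z2])
    total = (w1 * qa).sum() * (w2 * qb).sum()
    assert total == pytest.approx(1.0, abs=1e-5)
    # spot-check that the z-integral of the joint really is the border product
    val, _ = quad(lambda z: float(a1.joint_pdf(-0.4, 0.55, z, p)), -0.4, 0.55, limit=80)
    assert val == pytest.approx(
        float(a1.border_pdf("left", -0.4, p)) * float(a1.border_pdf("right", 0.55, p)),
        rel=1e-7,
    )


def test_joint_marginalising_animal_recovers_border_product():
    p = Analytic1DParams(beta=2.0, eps=0.12)
    z1, z2 = -0.45, 0.6
    val, _ = quad(lambda z: float(a1.joint_pdf(z1, z2, z, p)), z1, z2, limit=100)
    expected = float(a1.border_pdf("left", z1, p)) * float(a1.border_pdf("right", z2, p))
    assert val == pytest.approx(expected, rel=1e-7)


@pytest.mark.parametrize("beta,eps", [(0.0, 0.1), (2.0, 0.1), (5.0, 0.2), (1.0, 0.05)])
def test_marginal_normalised_even_and_vanishing_at_conspecific_cps(beta, eps):
    p = Analytic1DParams(beta=beta, eps=eps)
    z = np.linspace(-1, 1, 1201)
    pdf = a1.marginal_pdf_1d(z, p)
    assert np.trapezoid(pdf, z) == pytest.approx(1.0, abs=1e-4)
    np.testing.assert_allclose(pdf, pdf[::-1], atol=1e-12)
    assert pdf[0] == 0.0 and pdf[-1] == 0.0


# ---------------------------------------------------------------------------
# reduced half-territory forms


def test_reduced_marginals_normalised():
    z = np.linspace(1e-6, 1 - 1e-6, 20001)
    for eps in (0.05, 0.1):
        lim = a1.reduced_marginal_limit(z, eps)
        assert np.trapezoid(lim, z) == pytest.approx(1.0, abs=1e-3)
        for beta in (0.5, 3.0):
            half = a1.reduced_marginal_half(z, beta, eps)
            assert np.trapezoid(half, z) == pytest.approx(1.0, abs=1e-3)


def test_half_marginal_converges_to_cosine_integral_limit():
    z = np.linspace(1e-4, 1 - 1e-4, 1501)
    lim = a1.reduced_marginal_limit(z, 0.08)
    sups = []
    for beta in (0.5, 0.1, 0.02, 1e-4):
        half = a1.reduced_marginal_half(z, beta, 0.08)
        sups.append(np.abs(half - lim).max())
    assert sups[-1] < 1e-3
    assert sups[0] > sups[-1]


def test_half_marginal_step_function_in_frozen_border_small_drift_limit():
    # scent never decays (eps -> 0) with beta -> 0: height-2 step on (0, 1/2)
    z = np.linspace(0.01, 0.99, 981)
    half = a1.reduced_marginal_half(z, 1e-4, 5e-3)
    step = np.where(z < 0.5, 2.0, 0.0)
    mask = np.abs(z - 0.5) > 0.03
    assert np.abs(half - step)[mask].max() < 0.02


def test_density_curve_validates_mass_and_sign():
    from terriforage.analytic1d import DensityCurve

    grid = np.linspace(0, 1, 101)
    c = DensityCurve.from_pdf(grid, np.full(101, 3.0), support=(0.0, 1.0))
    assert np.trapezoid(c.values, c.grid) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="non-negative"):
        DensityCurve(grid=grid, values=np.linspace(-0.1, 2.1, 101), support=(0, 1))
    with pytest.raises(ValueError, match="mass"):
        DensityCurve(grid=grid, values=np.full(101, 2.0), support=(0, 1))


def test_reduced_forms_reject_bad_eps():
    with pytest.raises(ValueError):
        a1.reduced_marginal_half(0.5, 1.0, -0.1)
    with pytest.raises(ValueError):
        a1.reduced_marginal_limit(0.5, 0.0)
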