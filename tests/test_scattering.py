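"""Scattering analyses: Debye sums, Guinier fits, pair distributions,
Kratky transforms and concentration-series merging."""

import numpy as np
import pytest

import flexsome as fx
from flexsome.scattering import GuinierError
from conftest import random_cloud


@pytest.fixture(scope="module")
def sphere_model():
    return fx.ConformerModel(beads=random_cloud(50.0, 2000,
                                                np.random.default_rng(2)))


@pytest.fixture(scope="module")
def sphere_curve(sphere_model):
    return fx.debye_intensity(sphere_model, np.linspace(0, 0.12, 200))


# ----------------------------------------------------------------------- Debye

def test_single_bead_scatters_flat():
    c = fx.debye_intensity(fx.ConformerModel(beads=[[0, 0, 0]]),
                           np.linspace(0, 0.3, 10))
    assert np.allclose(c.I, 1.0)


def test_two_bead_closed_form():
    q = np.linspace(0.0, 0.3, 61)
    c = fx.debye_intensity(fx.ConformerModel(beads=[[0, 0, 0], [10, 0, 0]]), q)
    with np.errstate(invalid="ignore"):
        expect = 2 + 2 * np.where(q > 0, np.sin(10 * q) / (10 * q), 1.0)
    assert np.allclose(c.I, expect, rtol=1e-6)
    assert c.I[0] == pytest.approx(4.0)


def test_histogram_acceleration_matches_exact_debye(rng):
    model = fx.ConformerModel(beads=rng.uniform(-40, 40, (500, 3)),
                              weights=rng.uniform(0.5, 2.0, 500))
    q = np.linspace(0, 0.3, 61)
    fast = fx.debye_intensity(model, q).I
    exact = fx.debye_intensity(model, q, exact=True).I
    assert np.max(np.abs(fast - exact) / exact) < 0.005


def test_forward_scattering_is_squared_total_weight(rng):
    w = rng.uniform(0.1, 3.0, 200)
    model = fx.ConformerModel(beads=rng.uniform(0, 50, (200, 3)), weights=w)
    c = fx.debye_intensity(model, np.array([0.0, 0.1]))
    assert c.I[0] == pytest.approx(w.sum() ** 2, rel=1e-8)


# --------------------------------------------------------------------- Guinier

def test_guinier_inverts_exact_gaussian():
    q = np.linspace(0.0, 0.05, 80)
    curve = fx.ScatteringCurve(q=q, I=7.0 * np.exp(-q ** 2 * 40 ** 2 / 3))
    fit = fx.guinier_fit(curve)
    assert fit.rg == pytest.approx(40.0, abs=1e-3)
    assert fit.i0 == pytest.approx(7.0, rel=1e-6)
    assert fit.q_range_used[1] * fit.rg <= 1.3 + 1e-6


def test_guinier_on_debye_sphere_matches_model_rg(sphere_model, sphere_curve):
    fit = fx.guinier_fit(sphere_curve)
    assert fit.rg == pytest.approx(fx.model_rg(sphere_model), rel=0.02)
    assert fit.rg == pytest.approx(np.sqrt(3 / 5) * 50, rel=0.03)


def test_guinier_unbiased_under_noise():
    """Mean Rg bias < 1% over 100 noisy replicates at 1% noise."""
    q = np.linspace(0.001, 0.04, 60)
    ideal = 100.0 * np.exp(-q ** 2 * 35 ** 2 / 3)
    rng = np.random.default_rng(21)
    rgs = []
    for _ in range(100):
        noisy = ideal + rng.normal(0, 0.01 * ideal)
        rgs.append(fx.guinier_fit(fx.ScatteringCurve(
            q=q, I=noisy, sigma=0.01 * ideal)).rg)
    assert abs(np.mean(rgs) - 35.0) / 35.0 < 0.01


def test_guinier_errors():
    q = np.linspace(0, 0.1, 30)
    with pytest.raises(GuinierError):
        fx.guinier_fit(fx.ScatteringCurve(q=q, I=np.exp(+q ** 2 * 100)))
    with pytest.raises(GuinierError):
        fx.guinier_fit(fx.ScatteringCurve(q=q[:4], I=np.exp(-q[:4] ** 2)))


# ----------------------------------------------------------------------- P(r)

def test_pdist_two_beads_single_bin():
    pd_ = fx.pdist_from_model(fx.ConformerModel(beads=[[0, 0, 0], [10, 0, 0]]),
                              dr=1.0)
    assert pd_.dmax == pytest.approx(10.0)
    assert np.count_nonzero(pd_.p) == 1
    assert pd_.r[np.argmax(pd_.p)] == pytest.approx(10.0, abs=0.5)


def test_pdist_uniform_sphere_closed_form():
    cloud = random_cloud(30.0, 5000, np.random.default_rng(4))
    pd_ = fx.pdist_from_model(fx.ConformerModel(beads=cloud), dr=1.0)
    x = pd_.r / 60.0
    analytic = np.where(x <= 1, pd_.r ** 2 * (2 - 3 * x + x ** 3), 0.0)
    analytic /= np.trapezoid(analytic, pd_.r)
    assert np.max(np.abs(pd_.p - analytic)) / analytic.max() <= 0.03


def test_pdist_matches_brute_force(rng):
    beads = rng.uniform(0, 25, (100, 3))
    w = rng.uniform(0.5, 2.0, 100)
    pd_ = fx.pdist_from_model(fx.ConformerModel(beads=beads, weights=w), dr=2.0)
    hist = np.zeros_like(pd_.p)
    edges = np.concatenate([pd_.r - 1.0, [pd_.r[-1] + 1.0]])
    for i in range(100):
        for j in range(i + 1, 100):
            d = np.linalg.norm(beads[i] - beads[j])
            hist[np.searchsorted(edges, d) - 1] += w[i] * w[j]
    hist /= np.trapezoid(hist, pd_.r)
    assert np.allclose(pd_.p, hist, atol=1e-12)


def test_indirect_transform_round_trip(sphere_model):
    """P(r) recovered from the curve matches the model's own P(r)."""
    q = np.linspace(0, 0.35, 120)
    curve = fx.debye_intensity(sphere_model, q)
    curve.sigma = 0.01 * np.sqrt(np.clip(curve.I, 0, None) * curve.I.max()) + 1e-9
    dmax = fx.model_dmax(sphere_model)
    rec = fx.pdist_from_curve(curve, dmax=dmax)
    true = fx.pdist_from_model(sphere_model, dr=3.8)
    l1 = np.trapezoid(np.abs(rec.p - np.interp(rec.r, true.r, true.p)), rec.r)
    assert l1 <= 0.05
    assert np.all(rec.p >= 0)
    assert rec.p[0] == 0 and rec.p[-1] == 0


def test_indirect_transform_regularization_monotone(sphere_model):
    q = np.linspace(0, 0.35, 120)
    curve = fx.debye_intensity(sphere_model, q)
    curve.sigma = 0.01 * np.sqrt(np.clip(curve.I, 0, None) * curve.I.max()) + 1e-9
    dmax = fx.model_dmax(sphere_model)

    def curvature(alpha):
        p = fx.pdist_from_curve(curve, dmax=dmax, alpha=alpha).p
        return float(np.sum(np.diff(p, 2) ** 2))

    c1, c2_, c3 = curvature(1.0), curvature(2.0), curvature(20.0)
    assert c2_ <= c1 * (1 + 1e-9)
    assert c3 <= c2_ * (1 + 1e-9)


def test_pdist_second_moment_reproduces_rg(sphere_model):
    pd_ = fx.pdist_from_model(sphere_model, dr=1.0)
    rg = fx.model_rg(sphere_model)
    assert pd_.second_moment() == pytest.approx(2 * rg ** 2, rel=0.01)


# ---------------------------------------------------------------------- Kratky

def test_kratky_globule_peak(sphere_curve):
    fit = fx.guinier_fit(sphere_curve)
    kc = fx.normalized_kratky(sphere_curve, fit)
    peak = np.argmax(kc.y[kc.x < 3.0])
    assert kc.x[peak] == pytest.approx(np.sqrt(3), abs=0.1)
    assert kc.y[peak] == pytest.approx(3 / np.e, abs=0.05)
    assert kc.y[0] == 0.0


def test_kratky_of_constant_intensity_is_parabola():
    q = np.linspace(0, 0.2, 30)
    curve = fx.ScatteringCurve(q=q, I=np.full(30, 5.0))
    fit = fx.GuinierFit(rg=20.0, i0=5.0, q_range_used=(0.0, 0.05),
                        qrg_max=1.3, fit_r2=1.0)
    kc = fx.normalized_kratky(curve, fit)
    assert np.allclose(kc.y, kc.x ** 2)


def test_kratky_invariant_to_intensity_scale(sphere_curve):
    fit = fx.guinier_fit(sphere_curve)
    scaled = fx.ScatteringCurve(q=sphere_curve.q, I=37.0 * sphere_curve.I)
    fit_scaled = fx.guinier_fit(scaled)
    a = fx.normalized_kratky(sphere_curve, fit)
    b = fx.normalized_kratky(scaled, fit_scaled)
    assert np.allclose(a.y, b.y, rtol=1e-6)


def test_kratky_flexible_chain_plateaus():
    """A random coil keeps its Kratky transform high at large qRg (no return
    to zero), unlike the globule peak-and-decay."""
    coil = fx.sample_linker(150, [0, 0, 0], [1, 0, 0],
                            rng=np.random.default_rng(17))
    curve = fx.debye_intensity(fx.ConformerModel(beads=coil),
                               np.linspace(0, 0.3, 150))
    fit = fx.guinier_fit(curve)
    kc = fx.normalized_kratky(curve, fit)
    tail = kc.y[kc.x > 3.0]
    assert tail.size and np.all(tail > 1.0)


# ----------------------------------------------------------------------- merge

def _noisy(curve, rel, rng):
    sigma = rel * curve.I
    return fx.ScatteringCurve(q=curve.q, I=curve.I + rng.normal(0, sigma),
                              sigma=sigma)


def test_merge_scaled_duplicate_returns_reference(sphere_curve):
    ref = fx.ScatteringCurve(q=sphere_curve.q, I=sphere_curve.I,
                             sigma=0.01 * sphere_curve.I)
    doubled = fx.ScatteringCurve(q=ref.q, I=2 * ref.I, sigma=0.02 * ref.I)
    merged = fx.merge_curves([(ref, 1.0), (doubled, 2.0)])
    assert np.allclose(merged.I, ref.I, rtol=1e-10)


def test_merge_reduces_sigma_in_averaged_window(sphere_curve):
    rng = np.random.default_rng(5)
    a = _noisy(sphere_curve, 0.02, rng)
    b = _noisy(sphere_curve, 0.02, rng)
    merged = fx.merge_curves([(a, 1.0), (b, 2.0)])
    q_cross = a.q[0] + 0.2 * (a.q[-1] - a.q[0])
    high = merged.q > q_cross
    assert np.all(merged.sigma[high] <= np.minimum(a.sigma, b.sigma)[high] + 1e-12)


def test_merge_protects_low_q_from_concentration_artefacts(sphere_curve):
    """A structure-factor dip on the concentrated curve must not leak into
    the merged low-q region."""
    ref = fx.ScatteringCurve(q=sphere_curve.q, I=sphere_curve.I,
                             sigma=0.01 * sphere_curve.I)
    sf = 1.0 - 0.3 * np.exp(-(ref.q / 0.01) ** 2)  # low-q suppression
    high = fx.ScatteringCurve(q=ref.q, I=3 * ref.I * sf, sigma=0.03 * ref.I)
    merged = fx.merge_curves([(ref, 1.0), (high, 5.0)])
    q_cross = ref.q[0] + 0.2 * (ref.q[-1] - ref.q[0])
    low = merged.q < q_cross
    assert np.allclose(merged.I[low], ref.I[low], rtol=0.01)


def test_merge_requires_overlap():
    a = fx.ScatteringCurve(q=np.linspace(0.0, 0.1, 20), I=np.ones(20))
    b = fx.ScatteringCurve(q=np.linspace(0.2, 0.3, 20), I=np.ones(20))
    with pytest.raises(ValueError):
        fx.merge_curves([(a, 1.0), (b, 2.0)])
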