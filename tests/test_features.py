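"""Radial/angular feature primitives against closed forms and symbolic
oracles, and rotation invariance of the invariant products."""

import math

import numpy as np
import pytest

from gnnpot import autodiff as ad
from gnnpot.features import (RadialSpec, atomic_basis, bessel_basis,
                             invariant_products, lm_index, n_sh,
                             poly_envelope, real_gaunt_couplings,
                             real_spherical_harmonics, smooth_switch)
from gnnpot.graph import build_neighbor_list
from gnnpot import Configuration
from gnnpot.errors import ValidationError
from conftest import random_rotation

SPEC = RadialSpec(cutoff=6.0, n_bessel=8, envelope_order=5, smoothing_width=1.0)


# ------------------------------------------------------------------- bessel

def test_bessel_zero_at_cutoff_nodes():
    # e_1(r_c) = 0 and e_2(r_c/2) = 0: sin(n π r / r_c) nodes
    vals = bessel_basis(np.array([6.0 - 1e-300]), SPEC)  # formula at r_c
    vals_rc = bessel_basis(np.array([6.0]), SPEC)
    assert abs(vals_rc[0, 0]) < 1e-15
    assert abs(bessel_basis(np.array([3.0]), SPEC)[0, 1]) < 1e-15
    assert vals.shape == (1, 8)


def test_bessel_matches_symbolic_oracle(rng):
    import sympy as sp
    r_s, n_s, rc_s = sp.symbols("r n r_c", positive=True)
    expr = sp.sqrt(2 / rc_s) * sp.sin(n_s * sp.pi * r_s / rc_s) / r_s
    for _ in range(20):
        r = float(rng.uniform(0.3, 7.0))
        out = bessel_basis(np.array([r]), SPEC)[0]
        for n in (1, 4, 8):
            ref = float(expr.subs({r_s: r, n_s: n, rc_s: 6.0}))
            assert abs(out[n - 1] - ref) <= 1e-12 * max(1.0, abs(ref))


def test_bessel_rejects_nonpositive_r():
    with pytest.raises(ValidationError):
        bessel_basis(np.array([0.0]), SPEC)


# ----------------------------------------------------------------- envelopes

def test_poly_envelope_boundary_values_and_flatness():
    assert poly_envelope(np.array([0.0]), SPEC)[0] == 1.0
    assert poly_envelope(np.array([6.0]), SPEC)[0] == 0.0
    assert poly_envelope(np.array([7.5]), SPEC)[0] == 0.0
    # first two derivatives vanish at r_c (central differences, h = 1e-5)
    h = 1e-5
    f = lambda r: float(poly_envelope(np.array([r]), SPEC)[0])
    d1 = (f(6.0 + h) - f(6.0 - h)) / (2 * h)
    d2 = (f(6.0 + h) - 2 * f(6.0) + f(6.0 - h)) / h**2
    assert abs(d1) < 1e-8
    assert abs(d2) < 1e-4


def test_poly_envelope_closed_form_at_half():
    # independent evaluation of u(d) at d = 1/2, p = 5
    p = 5
    d = 0.5
    expect = (1 - (p + 1) * (p + 2) / 2 * d**p + p * (p + 2) * d**(p + 1)
              - p * (p + 1) / 2 * d**(p + 2))
    got = poly_envelope(np.array([3.0]), SPEC)[0]
    assert abs(got - expect) < 1e-14


def test_smooth_switch_boundaries_and_midpoint():
    assert smooth_switch(np.array([5.0]), SPEC)[0] == 1.0
    assert smooth_switch(np.array([6.0]), SPEC)[0] == 0.0
    assert abs(smooth_switch(np.array([5.5]), SPEC)[0] - 0.5) < 1e-14
    assert smooth_switch(np.array([2.0]), SPEC)[0] == 1.0


@pytest.mark.parametrize("env", [poly_envelope, smooth_switch])
def test_envelopes_are_c1_on_a_grid(env):
    r = np.linspace(0.05, 7.0, 2000)
    v = env(r, SPEC)
    dv = np.gradient(v, r)
    # a C1 violation shows up as an O(max-slope) jump in dv; smooth curvature
    # only contributes O(|f''| * Δr) ≈ 0.02 for the 1 Å smoothstep
    assert np.max(np.abs(np.diff(dv))) < 0.5
    assert np.all((v >= 0) & (v <= 1 + 1e-12))


def test_bessel_times_envelope_vanishes_continuously_at_cutoff():
    r = np.linspace(5.9, 6.0, 200)
    prod = bessel_basis(r, SPEC) * poly_envelope(r, SPEC)[:, None]
    assert np.all(np.abs(prod[-1]) < 1e-12)
    assert np.max(np.abs(prod[-5:])) < 1e-6


# ---------------------------------------------------- spherical harmonics

def test_y00_constant(rng):
    u = rng.normal(size=(5, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    Y = real_spherical_harmonics(u, 0)
    np.testing.assert_allclose(Y[:, 0], 0.5 / math.sqrt(math.pi), atol=1e-14)


def test_addition_theorem(rng):
    u = rng.normal(size=(20, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    Y = real_spherical_harmonics(u, 3)
    for l in range(4):
        s = (Y[:, l * l:(l + 1) ** 2] ** 2).sum(axis=1)
        np.testing.assert_allclose(s, (2 * l + 1) / (4 * math.pi), atol=1e-12)


def test_spherical_harmonics_match_sympy_oracle(rng):
    """Values at 50 random directions against sympy's complex Y_l^m combined
    into the standard real convention."""
    import sympy as sp
    theta_s, phi_s = sp.symbols("theta phi", real=True)
    for _ in range(50):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        theta = math.acos(v[2])
        phi = math.atan2(v[1], v[0])
        Y = real_spherical_harmonics(v, 3)
        for l in range(4):
            for m in range(-l, l + 1):
                ylm = sp.Ynm(l, abs(m), theta_s, phi_s).expand(func=True)
                val = complex(ylm.subs({theta_s: theta, phi_s: phi}).evalf())
                if m == 0:
                    ref = val.real
                elif m > 0:
                    ref = math.sqrt(2) * (-1) ** m * val.real
                else:
                    ref = math.sqrt(2) * (-1) ** m * val.imag
                assert abs(Y[lm_index(l, m)] - ref) < 1e-10, (l, m)


def test_non_unit_vector_rejected():
    with pytest.raises(ValidationError):
        real_spherical_harmonics(np.array([1.0, 1.0, 0.0]), 2)


def test_lmax_above_three_rejected(rng):
    u = np.array([0.0, 0.0, 1.0])
    with pytest.raises(ValidationError):
        real_spherical_harmonics(u, 4)


# --------------------------------------------------------- gaunt couplings

def test_real_gaunt_matches_quadrature_oracle(rng):
    """Coupling tensors against direct numerical integration of
    ∫ Y Y Y dΩ with a Gauss–Legendre × uniform-φ product rule (exact for
    spherical polynomials of the degrees involved)."""
    n_theta, n_phi = 12, 24
    x_gl, w_gl = np.polynomial.legendre.leggauss(n_theta)
    phi = 2 * math.pi * np.arange(n_phi) / n_phi
    ct = x_gl  # cos(theta)
    st = np.sqrt(1 - ct**2)
    dirs = np.stack([
        np.outer(st, np.cos(phi)).ravel(),
        np.outer(st, np.sin(phi)).ravel(),
        np.outer(ct, np.ones(n_phi)).ravel(),
    ], axis=1)
    weights = np.outer(w_gl, np.ones(n_phi)).ravel() * (2 * math.pi / n_phi)
    Y = real_spherical_harmonics(dirs, 3)
    triples, tensors = real_gaunt_couplings(3)
    for (l1, l2, l3), C in zip(triples, tensors):
        for i1, m1 in enumerate(range(-l1, l1 + 1)):
            for i2, m2 in enumerate(range(-l2, l2 + 1)):
                for i3, m3 in enumerate(range(-l3, l3 + 1)):
                    quad = np.sum(weights * Y[:, lm_index(l1, m1)]
                                  * Y[:, lm_index(l2, m2)]
                                  * Y[:, lm_index(l3, m3)])
                    assert abs(C[i1, i2, i3] - quad) < 1e-10, (l1, l2, l3, m1, m2, m3)


# ------------------------------------------------------ invariant products

def _random_atomic_basis(rng, pts, l_max=3, n_channels=3):
    """A_{k,lm} from an explicit neighbor environment with an exp radial."""
    r = np.linalg.norm(pts, axis=1)
    u = pts / r[:, None]
    Y = real_spherical_harmonics(u, l_max)
    R = np.exp(-np.arange(1, n_channels + 1)[None, :] * r[:, None] / 3.0)
    return np.einsum("jk,jm->km", R, Y)[None]


def test_all_zero_basis_gives_all_zero_invariants():
    A = np.zeros((2, 4, 16))
    out = invariant_products(A, 3)
    assert out.shape[0] == 2
    assert np.all(out == 0.0)


@pytest.mark.parametrize("order", [1, 2, 3])
def test_rotation_invariance_of_products(rng, order):
    pts = rng.normal(size=(6, 3)) * 2
    base = invariant_products(_random_atomic_basis(rng, pts), order)
    for _ in range(10):
        Q = random_rotation(rng)
        rot = invariant_products(_random_atomic_basis(rng, pts @ Q.T), order)
        np.testing.assert_allclose(rot, base, atol=1e-8)


def test_unsupported_order_rejected(rng):
    with pytest.raises(ValidationError):
        invariant_products(np.zeros((1, 1, 16)), 4)


def test_single_neighbor_power_spectrum_closed_form(rng):
    """One neighbor at distance r: p_{k,l} = R_{k,l}(r)² h² (2l+1)/(4π)
    by the addition theorem."""
    l_max = 3
    d = np.array([[1.2, -0.7, 2.1]])
    r = float(np.linalg.norm(d))
    cfg = Configuration(np.vstack([[0, 0, 0], d]), [18, 18])
    edges = build_neighbor_list(cfg, 6.0)
    K = 2
    h = np.array([[0.0, 0.0], [1.3, -0.4]])  # only atom 1 sends to atom 0

    def radial_map(dist):
        eb = bessel_basis(dist, SPEC)
        cols = [ad.reshape(ad.tsum(eb, axis=1), (eb.data.shape[0], 1, 1))
                for _ in range(K * (l_max + 1))]
        return ad.reshape(ad.concat(cols, axis=1),
                          (eb.data.shape[0], K, l_max + 1))

    A = atomic_basis(edges, h, SPEC, l_max, radial_map)
    inv = invariant_products(A, 2, l_max)
    R_val = bessel_basis(np.array([r]), SPEC).sum()
    # layout: [A_{k,00} (K)] + [p_{k,l} (K*(l_max+1))]
    p = inv[0, K:].reshape(K, l_max + 1)
    for k in range(K):
        for l in range(l_max + 1):
            expect = (R_val ** 2) * (h[1, k] ** 2) * (2 * l + 1) / (4 * math.pi)
            assert abs(p[k, l] - expect) < 1e-8 * max(1.0, abs(expect))


def test_atomic_basis_zero_for_isolated_atom(rng):
    cfg = Configuration([[0, 0, 0], [50.0, 0, 0]], [18, 18])
    edges = build_neighbor_list(cfg, 6.0)
    h = rng.normal(size=(2, 3))

    def _rm(dist):
        eb = bessel_basis(dist, SPEC)
        cols = [ad.reshape(ad.tsum(eb, axis=1), (eb.data.shape[0], 1, 1))
                for _ in range(3 * 4)]
        return ad.reshape(ad.concat(cols, axis=1), (eb.data.shape[0], 3, 4))

    A = atomic_basis(edges, h, SPEC, 3, _rm)
    assert A.shape == (2, 3, 16)
    assert np.all(A == 0.0)


def test_atomic_basis_linear_in_edges(rng):
    """Duplicating an edge doubles its contribution."""
    cfg = Configuration([[0, 0, 0], [2.0, 1.0, 0.5]], [18, 18])
    edges = build_neighbor_list(cfg, 6.0)
    h = rng.normal(size=(2, 2))

    def rm(dist):
        eb = bessel_basis(dist, SPEC)
        cols = [ad.reshape(ad.tsum(eb, axis=1), (eb.data.shape[0], 1, 1))
                for _ in range(2 * 3)]
        return ad.reshape(ad.concat(cols, axis=1), (eb.data.shape[0], 2, 3))

    A1 = atomic_basis(edges, h, SPEC, 2, rm)
    from gnnpot.graph import EdgeSet
    dup = EdgeSet(np.concatenate([edges.senders, edges.senders]),
                  np.concatenate([edges.receivers, edges.receivers]),
                  np.concatenate([edges.shifts, edges.shifts]),
                  np.concatenate([edges.displacements, edges.displacements]),
                  np.concatenate([edges.distances, edges.distances]))
    A2 = atomic_basis(dup, h, SPEC, 2, rm)
    np.testing.assert_allclose(A2, 2 * A1, atol=1e-12)
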