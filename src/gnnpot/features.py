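"""Radial and angular feature primitives for invariant atomic environments.

Radial features are sine Bessel functions ``e_n(r) = sqrt(2/r_c)
sin(n π r / r_c) / r`` truncated by a smooth cutoff envelope — either the
polynomial envelope ``u(d) = 1 − (p+1)(p+2)/2 d^p + p(p+2) d^{p+1} −
p(p+1)/2 d^{p+2}`` (value and first two derivatives vanish at the cutoff) or
a smoothstep switching function active on the last ``w`` Å before the cutoff.

Angular features are real spherical harmonics up to l = 3 in the standard
orthonormal real convention (no Condon–Shortley phase): for m > 0 they are
``√2·(−1)^m Re Y_l^m``, for m < 0 ``√2·(−1)^m Im Y_l^{|m|}``, and ``Y_l^0``
for m = 0.  Rotation-invariant per-atom descriptors are built from the
neighbor expansion ``A_{i,k,lm}`` as its l = 0 channel (correlation order 1),
the power spectrum ``p_{ikl} = Σ_m A²`` (order 2), and the bispectrum
``b = Σ C·A·A·A`` (order 3) with real Gaunt coupling coefficients — the
Wigner-3j couplings transformed to the real basis, computed symbolically once
per ``l_max`` and cached.

All functions accept plain numpy arrays or autodiff :class:`~gnnpot.autodiff.
Tensor` inputs; with tensor inputs the outputs stay on the tape so forces can
be differentiated through them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ValidationError
from .graph import EdgeSet


@dataclass(frozen=True)
class RadialSpec:
    """Radial feature hyperparameters (defaults: the 6 Å / 8 Bessel /
    order-5 envelope preset)."""

    cutoff: float = 6.0
    n_bessel: int = 8
    envelope_order: int = 5
    smoothing_width: float = 1.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.n_bessel < 1:
            raise ValidationError("n_bessel must be >= 1")
        if self.envelope_order < 2:
            raise ValidationError("envelope_order must be >= 2")
        if not (0 < self.smoothing_width <= self.cutoff):
            raise ValidationError("smoothing_width must be in (0, cutoff]")


def _maybe_data(out, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data if isinstance(out, Tensor) else out


def bessel_basis(r, spec: RadialSpec):
    """Sine Bessel radial basis; output shape ``r.shape + (n_bessel,)``.

    Defined by the closed form for every r > 0; truncation at the cutoff is
    the envelope's job.
    """
    r_t = ad.astensor(r)
    if np.any(r_t.data <= 0):
        raise ValidationError("bessel_basis requires r > 0")
    rc = spec.cutoff
    shape = r_t.data.shape
    rcol = ad.reshape(r_t, shape + (1,))
    freqs = np.arange(1, spec.n_bessel + 1) * math.pi / rc
    out = ad.mul(ad.div(ad.sin(ad.mul(rcol, freqs)), rcol), math.sqrt(2.0 / rc))
    return _maybe_data(out, r)


def poly_envelope(r, spec: RadialSpec):
    """Polynomial cutoff envelope u(r/r_c) in [0, 1]; 0 for r >= r_c."""
    r_t = ad.astensor(r)
    p = float(spec.envelope_order)
    d = ad.mul(r_t, 1.0 / spec.cutoff)
    u = ad.add(
        ad.add(1.0, ad.mul(ad.power(d, p), -(p + 1.0) * (p + 2.0) / 2.0)),
        ad.add(ad.mul(ad.power(d, p + 1.0), p * (p + 2.0)),
               ad.mul(ad.power(d, p + 2.0), -p * (p + 1.0) / 2.0)),
    )
    out = ad.where(r_t.data < spec.cutoff, u, ad.astensor(np.zeros_like(r_t.data)))
    return _maybe_data(out, r)


def smooth_switch(r, spec: RadialSpec):
    """Smoothstep switching envelope: 1 up to r_c − w, 0 from r_c on,
    ``1 − (6x⁵ − 15x⁴ + 10x³)`` in between."""
    r_t = ad.astensor(r)
    rc, w = spec.cutoff, spec.smoothing_width
    x = ad.mul(ad.sub(r_t, rc - w), 1.0 / w)
    s = ad.sub(1.0, ad.add(ad.sub(ad.mul(ad.power(x, 5.0), 6.0),
                                  ad.mul(ad.power(x, 4.0), 15.0)),
                           ad.mul(ad.power(x, 3.0), 10.0)))
    ones = ad.astensor(np.ones_like(r_t.data))
    zeros = ad.astensor(np.zeros_like(r_t.data))
    out = ad.where(r_t.data <= rc - w, ones,
                   ad.where(r_t.data >= rc, zeros, s))
    return _maybe_data(out, r)


# ------------------------------------------------------- spherical harmonics

L_MAX_SUPPORTED = 3


def n_sh(l_max: int) -> int:
    return (l_max + 1) ** 2


def lm_index(l: int, m: int) -> int:
    return l * l + (m + l)


@lru_cache(maxsize=8)
def _sh_monomial_matrix(l_max: int) -> np.ndarray:
    """Coefficient matrix mapping unit-vector monomials (degree ≤ l_max, in
    the fixed order built by :func:`_sh_values`) onto real spherical
    harmonics ordered by (l, m), m = −l..l."""
    if l_max > L_MAX_SUPPORTED:
        raise ValidationError(f"l_max > {L_MAX_SUPPORTED} not supported")
    n_mono = [1, 4, 10, 20][l_max]
    W = np.zeros((n_mono, n_sh(l_max)))
    W[0, 0] = 0.5 / math.sqrt(math.pi)
    if l_max >= 1:
        c1 = math.sqrt(3.0 / (4.0 * math.pi))
        W[2, 1] = c1  # y
        W[3, 2] = c1  # z
        W[1, 3] = c1  # x
    if l_max >= 2:
        c2a = 0.5 * math.sqrt(15.0 / math.pi)
        c2b = 0.25 * math.sqrt(5.0 / math.pi)
        c2c = 0.25 * math.sqrt(15.0 / math.pi)
        W[7, 4] = c2a                    # xy
        W[9, 5] = c2a                    # yz
        W[6, 6], W[0, 6] = 3 * c2b, -c2b  # 3z² − 1
        W[8, 7] = c2a                    # xz
        W[4, 8], W[5, 8] = c2c, -c2c     # x² − y²
    if l_max >= 3:
        c3m3 = 0.25 * math.sqrt(35.0 / (2.0 * math.pi))
        c3m2 = 0.5 * math.sqrt(105.0 / math.pi)
        c3m1 = 0.25 * math.sqrt(21.0 / (2.0 * math.pi))
        c30 = 0.25 * math.sqrt(7.0 / math.pi)
        c32 = 0.25 * math.sqrt(105.0 / math.pi)
        W[13, 9], W[11, 9] = 3 * c3m3, -c3m3    # y(3x² − y²)
        W[19, 10] = c3m2                        # xyz
        W[18, 11], W[2, 11] = 5 * c3m1, -c3m1   # y(5z² − 1)
        W[12, 12], W[3, 12] = 5 * c30, -3 * c30  # z(5z² − 3)
        W[17, 13], W[1, 13] = 5 * c3m1, -c3m1   # x(5z² − 1)
        W[14, 14], W[16, 14] = c32, -c32        # z(x² − y²)
        W[10, 15], W[15, 15] = c3m3, -3 * c3m3  # x(x² − 3y²)
    return W


def _sh_values(x, y, z, l_max: int):
    """Real spherical harmonics of unit-vector components shaped (..., 1);
    returns (..., (l_max+1)²).  Inputs may be Tensors (differentiable)."""
    one = ad.astensor(np.ones_like(x.data if isinstance(x, Tensor)
                                   else np.asarray(x, dtype=float)))
    monos = [one]
    if l_max >= 1:
        monos += [x, y, z]
    if l_max >= 2:
        x2, y2, z2 = ad.mul(x, x), ad.mul(y, y), ad.mul(z, z)
        xy, xz, yz = ad.mul(x, y), ad.mul(x, z), ad.mul(y, z)
        monos += [x2, y2, z2, xy, xz, yz]
    if l_max >= 3:
        monos += [ad.mul(x2, x), ad.mul(y2, y), ad.mul(z2, z),
                  ad.mul(x2, y), ad.mul(x2, z), ad.mul(y2, x), ad.mul(y2, z),
                  ad.mul(z2, x), ad.mul(z2, y), ad.mul(xy, z)]
    basis = ad.concat(monos, axis=-1)
    W = _sh_monomial_matrix(l_max).astype(basis.data.dtype)
    return ad.matmul(basis, W)


def real_spherical_harmonics(u, l_max: int):
    """Orthonormal real spherical harmonics of unit vector(s) ``u``
    (shape ``(..., 3)``), output ``(..., (l_max+1)²)`` ordered by (l, m)."""
    u_t = ad.astensor(u)
    norms = np.linalg.norm(u_t.data, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise ValidationError("real_spherical_harmonics requires unit vectors")
    single = u_t.data.ndim == 1
    if single:
        u_t = ad.reshape(u_t, (1, 3))
    x = u_t[..., 0:1]
    y = u_t[..., 1:2]
    z = u_t[..., 2:3]
    out = _sh_values(x, y, z, l_max)
    if single:
        out = ad.reshape(out, (n_sh(l_max),))
    return _maybe_data(out, u)


# -------------------------------------------------------- coupling constants

def _bispectrum_triples(l_max: int) -> list[tuple[int, int, int]]:
    triples = []
    for l1 in range(l_max + 1):
        for l2 in range(l1, l_max + 1):
            for l3 in range(l2, l_max + 1):
                if l3 > l1 + l2 or (l1 + l2 + l3) % 2:
                    continue
                triples.append((l1, l2, l3))
    return triples


@lru_cache(maxsize=8)
def real_gaunt_couplings(l_max: int):
    """Real-basis coupling tensors for every allowed (l1 ≤ l2 ≤ l3) triple.

    Returns ``(triples, tensors)`` where ``tensors[t]`` has shape
    ``(2l1+1, 2l2+1, 2l3+1)``.  Entries are real Gaunt coefficients
    ∫ Y_{l1m1} Y_{l2m2} Y_{l3m3} dΩ, evaluated symbolically (they reduce to
    Wigner-3j symbols) and cached for the lifetime of the process.
    """
    from sympy.physics.wigner import real_gaunt

    triples = _bispectrum_triples(l_max)
    tensors = []
    for l1, l2, l3 in triples:
        C = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1))
        for i1, m1 in enumerate(range(-l1, l1 + 1)):
            for i2, m2 in enumerate(range(-l2, l2 + 1)):
                for i3, m3 in enumerate(range(-l3, l3 + 1)):
                    C[i1, i2, i3] = float(real_gaunt(l1, l2, l3, m1, m2, m3))
        tensors.append(C)
    return triples, tensors


# ----------------------------------------------------------- atomic features

def _l_projector(l_max: int) -> np.ndarray:
    """0/1 matrix (l_max+1, M) mapping per-l radial values onto (l, m) slots."""
    M = n_sh(l_max)
    P = np.zeros((l_max + 1, M))
    for l in range(l_max + 1):
        P[l, l * l:(l + 1) * (l + 1)] = 1.0
    return P


def atomic_basis(edges: EdgeSet, node_scalars, spec: RadialSpec, l_max: int,
                 radial_map):
    """Neighbor expansion ``A_{i,k,lm} = Σ_{j∈N(i)} R_{k,l}(r_ij)
    Y_{lm}(r̂_ij) h_{j,k}``.

    ``radial_map`` maps distances ``(E,)`` to per-channel, per-degree radial
    values ``(E, K, l_max+1)`` (typically the envelope-weighted Bessel vector
    passed through the radial perceptron).  Aggregation is a plain sum over
    edges into the receiving atom; atoms without neighbors get a zero row.
    """
    h = ad.astensor(node_scalars)
    n_atoms, n_channels = h.data.shape
    M = n_sh(l_max)
    if len(edges) == 0:
        out = ad.astensor(np.zeros((n_atoms, n_channels, M), dtype=h.data.dtype))
        return _maybe_data(out, node_scalars)
    disp = ad.astensor(edges.displacements)
    dist = ad.astensor(edges.distances)
    return _atomic_basis_from_geometry(disp, dist, edges.senders,
                                       edges.receivers, h, n_atoms, l_max,
                                       radial_map, wrap=not isinstance(node_scalars, Tensor))


def _atomic_basis_from_geometry(disp, dist, senders, receivers, h, n_atoms,
                                l_max, radial_map, wrap=False):
    E = dist.data.shape[0]
    inv_r = ad.power(dist, -1.0)
    u = ad.mul(disp, ad.reshape(inv_r, (E, 1)))
    x, y, z = u[:, 0:1], u[:, 1:2], u[:, 2:3]
    Y = _sh_values(x, y, z, l_max)  # (E, M)
    R = radial_map(dist)  # (E, K, l_max+1)
    P = _l_projector(l_max).astype(dist.data.dtype)
    hj = ad.gather(h, senders)
    n_channels = hj.data.shape[1]
    M = P.shape[1]
    # fold channel scalars into the (small) per-l radial values first
    W = ad.mul(R, ad.reshape(hj, (E, n_channels, 1)))   # (E, K, l_max+1)
    contrib = ad.mul(ad.matmul(W, P), ad.reshape(Y, (E, 1, M)))
    A = ad.segment_sum(contrib, receivers, n_atoms)
    return A.data if wrap else A


def invariant_products(A, correlation_order: int, l_max: int | None = None):
    """Rotation-invariant per-atom features from the atomic basis.

    Order 1 contributes the l = 0 channel, order 2 adds the power spectrum
    over every l, order 3 adds the bispectrum over triangle-allowed,
    parity-even (l1 ≤ l2 ≤ l3) triples.  Output shape ``(N, K · n_inv)``.
    """
    if correlation_order not in (1, 2, 3):
        raise ValidationError("correlation_order must be 1, 2 or 3")
    A_t = ad.astensor(A)
    n_atoms, n_channels, M = A_t.data.shape
    if l_max is None:
        l_max = int(round(math.sqrt(M))) - 1
    if n_sh(l_max) != M:
        raise ValidationError("atomic basis last axis inconsistent with l_max")
    parts = [A_t[:, :, 0]]
    if correlation_order >= 2:
        Pmat = _l_projector(l_max).T.astype(A_t.data.dtype)  # (M, l_max+1)
        p = ad.rowmm(ad.mul(A_t, A_t), Pmat)
        parts.append(ad.reshape(p, (n_atoms, n_channels * (l_max + 1))))
    if correlation_order >= 3:
        triples, tensors = real_gaunt_couplings(l_max)
        for (l1, l2, l3), C in zip(triples, tensors):
            na, nb, nc = 2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1
            A1 = A_t[:, :, l1 * l1:(l1 + 1) * (l1 + 1)]
            A2 = A_t[:, :, l2 * l2:(l2 + 1) * (l2 + 1)]
            A3 = A_t[:, :, l3 * l3:(l3 + 1) * (l3 + 1)]
            Cm = C.reshape(na, nb * nc).astype(A_t.data.dtype)
            # contract a (one stacked GEMM), then b and c by broadcast-sum
            t1 = ad.reshape(ad.rowmm(A1, Cm), (n_atoms, n_channels, nb, nc))
            t2 = ad.tsum(ad.mul(t1, ad.reshape(A2, (n_atoms, n_channels, nb, 1))),
                         axis=2)
            b = ad.tsum(ad.mul(t2, A3), axis=2)
            parts.append(b)
    out = ad.concat(parts, axis=1)
    return _maybe_data(out, A)


def n_invariants(n_channels: int, correlation_order: int, l_max: int) -> int:
    n = n_channels
    if correlation_order >= 2:
        n += n_channels * (l_max + 1)
    if correlation_order >= 3:
        n += n_channels * len(_bispectrum_triples(l_max))
    return n
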