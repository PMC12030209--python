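"""Directed neighbor graphs within a cutoff, with periodic images, and the
range-correction (DPRc) edge rule for QM/MM.

Edges are strict (``0 < r < cutoff``); a pair exactly at the cutoff is
excluded — the cutoff envelope is zero there, so inclusion would be
numerically irrelevant but nondeterministic under rounding.  Under periodic
boundary conditions every image within the cutoff is enumerated (no
minimum-image assumption), so cells smaller than twice the cutoff — including
self-images of an atom — are handled correctly.  Edge order is deterministic:
sorted by sender, then receiver, then shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import MM, Configuration
from .errors import ValidationError


@dataclass
class EdgeSet:
    """Directed neighbor pairs with geometry.

    ``displacements[e] = positions[receivers[e]] - positions[senders[e]]
    + shifts[e] @ cell``; distances are the norms.
    """

    senders: np.ndarray
    receivers: np.ndarray
    shifts: np.ndarray
    displacements: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        self.senders = np.asarray(self.senders, dtype=np.int64)
        self.receivers = np.asarray(self.receivers, dtype=np.int64)
        self.shifts = np.asarray(self.shifts, dtype=np.int64).reshape(-1, 3)
        self.displacements = np.asarray(self.displacements, dtype=np.float64).reshape(-1, 3)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n = len(self.senders)
        if not (len(self.receivers) == len(self.shifts)
                == len(self.displacements) == len(self.distances) == n):
            raise ValidationError("EdgeSet arrays must have equal length")

    def __len__(self) -> int:
        return len(self.senders)


def _sort_edges(send, recv, shifts, disp, dist) -> EdgeSet:
    order = np.lexsort((shifts[:, 2], shifts[:, 1], shifts[:, 0], recv, send))
    return EdgeSet(send[order], recv[order], shifts[order],
                   disp[order], dist[order])


def _shift_bounds(cell: np.ndarray, cutoff: float) -> np.ndarray:
    # images needed along axis a: cutoff / (spacing between lattice planes a)
    inv = np.linalg.inv(cell)
    plane_dist = 1.0 / np.linalg.norm(inv, axis=1)  # rows of inv(cell)
    return np.ceil(cutoff / plane_dist).astype(int)


def build_neighbor_list(config: Configuration, cutoff: float) -> EdgeSet:
    """All directed pairs (i, j, shift) with ``0 < |r_j - r_i + shift·cell| <
    cutoff``, deterministically ordered."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    pos = config.positions
    n = config.n_atoms
    periodic = bool(config.pbc is not None and config.pbc.any())
    if not periodic:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            r = np.linalg.norm(d, axis=1)
            # query_pairs is closed at the radius; the convention here is strict
            keep = (r > 0.0) & (r < cutoff)
            pairs, d, r = pairs[keep], d[keep], r[keep]
            send = np.concatenate([pairs[:, 0], pairs[:, 1]])
            recv = np.concatenate([pairs[:, 1], pairs[:, 0]])
            disp = np.concatenate([d, -d])
            dist = np.concatenate([r, r])
        else:
            send = recv = np.zeros(0, dtype=np.int64)
            disp = np.zeros((0, 3))
            dist = np.zeros(0)
        shifts = np.zeros((len(send), 3), dtype=np.int64)
        return _sort_edges(np.asarray(send, dtype=np.int64),
                           np.asarray(recv, dtype=np.int64), shifts, disp, dist)

    cell = config.cell
    if abs(np.linalg.det(cell)) <= 1e-8:
        raise ValidationError("singular cell")
    nmax = _shift_bounds(cell, cutoff)
    # non-periodic directions get no images
    nmax = np.where(config.pbc, nmax, 0)
    rng = [np.arange(-m, m + 1) for m in nmax]
    shifts_all = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    shift_vecs = shifts_all @ cell

    sends, recvs, shs, disps, dists = [], [], [], [], []
    for k, sv in enumerate(shift_vecs):
        # displacement r_j - r_i + sv for all (i, j)
        d = pos[None, :, :] - pos[:, None, :] + sv[None, None, :]
        r = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero((r > 0.0) & (r < cutoff))
        if len(ii):
            sends.append(ii)
            recvs.append(jj)
            shs.append(np.broadcast_to(shifts_all[k], (len(ii), 3)))
            disps.append(d[ii, jj])
            dists.append(r[ii, jj])
    if sends:
        send = np.concatenate(sends).astype(np.int64)
        recv = np.concatenate(recvs).astype(np.int64)
        sh = np.concatenate(shs).astype(np.int64)
        disp = np.concatenate(disps)
        dist = np.concatenate(dists)
    else:
        send = recv = np.zeros(0, dtype=np.int64)
        sh = np.zeros((0, 3), dtype=np.int64)
        disp = np.zeros((0, 3))
        dist = np.zeros(0)
    return _sort_edges(send, recv, sh, disp, dist)


def filter_qmmm_edges(edges: EdgeSet, region: np.ndarray) -> EdgeSet:
    """Drop every edge whose sender *and* receiver are both MM atoms.

    This is the range-correction topology rule: the learned correction acts
    on QM and QM–MM interactions only, so pure MM–MM pairs never enter the
    graph.  QM–QM, QM–MM and MM–QM edges are retained; order is preserved.
    """
    region = np.asarray(region)
    if len(edges) == 0:
        return edges
    hi = max(int(edges.senders.max()), int(edges.receivers.max()))
    if hi >= len(region):
        raise ValidationError("region flags do not cover all atom indices")
    is_mm = region == MM
    keep = ~(is_mm[edges.senders] & is_mm[edges.receivers])
    return EdgeSet(edges.senders[keep], edges.receivers[keep],
                   edges.shifts[keep], edges.displacements[keep],
                   edges.distances[keep])


def recompute_geometry(config: Configuration, edges: EdgeSet) -> EdgeSet:
    """Re-evaluate displacements/distances from current positions at fixed
    topology (fixed sender/receiver/shift triples)."""
    pos = config.positions
    if len(edges) and (edges.senders.max() >= config.n_atoms
                       or edges.receivers.max() >= config.n_atoms):
        raise ValidationError("edge index out of range for configuration")
    if config.cell is not None:
        sv = edges.shifts @ config.cell
    else:
        if np.any(edges.shifts != 0):
            raise ValidationError("nonzero shifts require a cell")
        sv = np.zeros((len(edges), 3))
    disp = pos[edges.receivers] - pos[edges.senders] + sv
    dist = np.linalg.norm(disp, axis=1)
    return EdgeSet(edges.senders.copy(), edges.receivers.copy(),
                   edges.shifts.copy(), disp, dist)
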