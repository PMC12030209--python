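"""Range-corrected Δ-learning machinery.

A ΔMLP corrects a cheap base method toward an expensive reference: the
training target is ``ΔE* = E_ref − E_base`` (and likewise for forces), and
the deployed potential is the sum ``E = E_base + ΔE_MLP``.  The base is a
pluggable callable contract, not a hard dependency on any particular
semiempirical code; analytic pair potentials are bundled so the whole
workflow is self-contained.  Δ-labelled frames are ordinary
:class:`~gnnpot.core_io.LabeledFrame` objects, so the trainer is agnostic to
pure-MLP versus ΔMLP mode — Δ-learning is a data-preparation convention
plus the QM/MM graph rule.

External QM drivers can be adapted by wrapping a subprocess that maps an
extended-XYZ file to (energy in eV, forces in eV/Å) in a
:class:`BasePotential`; such adapters are deliberately out of the test
surface.
"""

from __future__ import annotations

import numpy as np

from .core_io import Configuration, Dataset, LabeledFrame
from .errors import GnnPotError, ValidationError
from .graph import build_neighbor_list


class BasePotential:
    """Callable contract: ``evaluate(config) -> (energy eV, forces eV/Å)``,
    deterministic for fixed input."""

    identifier: str = "base"

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def __call__(self, config: Configuration):
        return self.evaluate(config)


class LennardJonesPotential(BasePotential):
    """Shifted Lennard-Jones pair potential: 4ε[(σ/r)¹² − (σ/r)⁶] − shift,
    summed over pairs within r_cut; the shift zeroes each pair term at r_cut.
    Argon-like defaults."""

    def __init__(self, epsilon: float = 0.0104, sigma: float = 3.4,
                 r_cut: float = 10.0):
        if epsilon <= 0 or sigma <= 0 or r_cut <= 0:
            raise ValidationError("LJ parameters must be positive")
        self.epsilon, self.sigma, self.r_cut = epsilon, sigma, r_cut
        self.identifier = "lj"

    def _pair(self, r):
        sr6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)

    def evaluate(self, config: Configuration):
        edges = build_neighbor_list(config, self.r_cut)
        if len(edges) and edges.distances.min() < 1e-6:
            raise GnnPotError("overlapping atoms (r < 1e-6 Å)")
        energy = 0.0
        forces = np.zeros_like(config.positions)
        if len(edges):
            r = edges.distances
            shift = self._pair(self.r_cut)
            # each pair appears as two directed edges -> half weights
            energy = 0.5 * float(np.sum(self._pair(r) - shift))
            sr6 = (self.sigma / r) ** 6
            dEdr = 4.0 * self.epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            # dE/dr_i for edge (i->j): -dEdr * u_ij ; half weight per directed edge
            u = edges.displacements / r[:, None]
            contrib = 0.5 * dEdr[:, None] * u
            np.add.at(forces, edges.senders, contrib)
            np.add.at(forces, edges.receivers, -contrib)
        return energy, forces


class HarmonicBondPotential(BasePotential):
    """½k(r − r0)² over an explicit bond topology (list of index pairs)."""

    def __init__(self, k: float, r0: float, topology):
        if k <= 0 or r0 <= 0:
            raise ValidationError("harmonic parameters must be positive")
        self.k, self.r0 = float(k), float(r0)
        self.topology = [(int(i), int(j)) for i, j in topology]
        self.identifier = "harmonic"

    def evaluate(self, config: Configuration):
        pos = config.positions
        energy = 0.0
        forces = np.zeros_like(pos)
        for i, j in self.topology:
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            if r < 1e-6:
                raise GnnPotError("overlapping atoms (r < 1e-6 Å)")
            energy += 0.5 * self.k * (r - self.r0) ** 2
            f = self.k * (r - self.r0) * d / r  # force on i is +f
            forces[i] += f
            forces[j] -= f
        return float(energy), forces


class GaussianPairPerturbation(BasePotential):
    """Smooth short-range pair term ``A·exp(−r²/2λ²)`` with analytic forces —
    the closed-form stand-in for a 'reference minus base' residual."""

    def __init__(self, amplitude: float = 0.02, length_scale: float = 1.5,
                 r_cut: float = 6.0):
        self.amplitude, self.length_scale, self.r_cut = amplitude, length_scale, r_cut
        self.identifier = "gaussian_pair"

    def evaluate(self, config: Configuration):
        edges = build_neighbor_list(config, self.r_cut)
        energy = 0.0
        forces = np.zeros_like(config.positions)
        if len(edges):
            r = edges.distances
            g = self.amplitude * np.exp(-r * r / (2.0 * self.length_scale ** 2))
            energy = 0.5 * float(np.sum(g))
            dEdr = -r / self.length_scale ** 2 * g
            u = edges.displacements / r[:, None]
            contrib = 0.5 * dEdr[:, None] * u
            np.add.at(forces, edges.senders, contrib)
            np.add.at(forces, edges.receivers, -contrib)
        return energy, forces


class SumPotential(BasePotential):
    """Sum of two base potentials (itself a BasePotential, so composable)."""

    def __init__(self, first: BasePotential, second: BasePotential):
        self.first, self.second = first, second
        self.identifier = f"{first.identifier}+{second.identifier}"

    def evaluate(self, config: Configuration):
        e1, f1 = self.first.evaluate(config)
        e2, f2 = self.second.evaluate(config)
        return e1 + e2, f1 + f2


def lj_potential(epsilon: float = 0.0104, sigma: float = 3.4,
                 r_cut: float = 10.0) -> BasePotential:
    return LennardJonesPotential(epsilon, sigma, r_cut)


def harmonic_bond_potential(k: float, r0: float, topology) -> BasePotential:
    return HarmonicBondPotential(k, r0, topology)


# -------------------------------------------------------------- Δ machinery

def delta_targets(reference: Dataset, base: BasePotential) -> Dataset:
    """Δ-labelled dataset: per frame, ΔE* = E_ref − E_base(config) and
    ΔF* = F_ref − F_base(config); configurations unchanged."""
    frames = []
    for idx, frame in enumerate(reference):
        frame.require_labels()
        try:
            e_base, f_base = base.evaluate(frame.config)
        except Exception as e:
            raise GnnPotError(f"base potential failed on frame {idx}: {e}") from e
        frames.append(LabeledFrame(frame.config, frame.energy - e_base,
                                   frame.forces - f_base))
    return Dataset(frames, provenance=reference.provenance + f"/delta-{base.identifier}")


class _ModelPotential(BasePotential):
    """A trained model exposed through the BasePotential contract."""

    def __init__(self, model):
        self.model = model
        self.identifier = f"mlp:{model.spec.name}"

    def evaluate(self, config: Configuration):
        from .potential import compute_forces
        res = compute_forces(self.model, config)
        return res.total_energy, res.forces


def as_base_potential(model) -> BasePotential:
    return _ModelPotential(model)


def combined_potential(base: BasePotential, mlp) -> BasePotential:
    """The deployed ΔMLP potential: energy = E_base + ΔE_MLP, forces add;
    the result is itself a BasePotential, so Δ layers compose."""
    mlp_pot = mlp if isinstance(mlp, BasePotential) else as_base_potential(mlp)
    return SumPotential(base, mlp_pot)
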