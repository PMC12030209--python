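"""Synthetic desk-scale datasets with exact labels.

Three families mirror the statistical structure the method assumes:

* ``lj_cluster`` — random argon-like clusters sampled around local minima of
  the shifted Lennard-Jones potential (packed at a minimum separation of
  0.8σ, locally relaxed, then Gaussian-jittered), labelled with the analytic
  energy and forces;
* ``perturbed_pair`` — the same geometries labelled by LJ **plus** a smooth
  Gaussian pair term ``A·exp(−r²/2λ²)`` standing in for a
  "reference minus base" residual, with the base potential returned
  alongside so the true Δ has a closed form;
* ``qmmm_scene`` — QM core clusters with MM atoms at controlled distances,
  including a radial one-parameter family that walks a single MM atom across
  the model cutoff.

Every label satisfies force = −∇(generating energy) analytically, and all
generators are bit-reproducible under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core_io import MM, QM, Configuration, Dataset, LabeledFrame
from .deltamlp import (BasePotential, GaussianPairPerturbation,
                       LennardJonesPotential, SumPotential)
from .errors import GnnPotError, ValidationError

ARGON_Z = 18


@dataclass(frozen=True)
class ToySpec:
    family: str = "lj_cluster"   # lj_cluster | perturbed_pair | qmmm_scene
    n_frames: int = 500
    n_atoms: int = 8
    elements: tuple = (ARGON_Z,)
    displacement_scale: float = 0.15  # Å of Gaussian jitter around minima
    amplitude: float = 0.02           # eV, Δ perturbation
    length_scale: float = 1.5         # Å, Δ perturbation (kept ≤ cutoff/3)
    epsilon: float = 0.0104           # eV (argon-like LJ)
    sigma: float = 3.4                # Å
    r_cut: float = 10.0               # Å, LJ truncation
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_atoms < 1:
            raise ValidationError("counts must be positive")
        if self.displacement_scale <= 0:
            raise ValidationError("displacement scale must be positive")


def _lj_energy_grad(flat: np.ndarray, n: int, eps: float, sig: float):
    """Dense LJ (no cutoff) energy and gradient, for the local relaxation."""
    pos = flat.reshape(n, 3)
    d = pos[None, :, :] - pos[:, None, :]
    r2 = np.sum(d * d, axis=-1)
    iu = np.triu_indices(n, 1)
    r2p = r2[iu]
    sr6 = (sig * sig / r2p) ** 3
    e = 4.0 * eps * np.sum(sr6 * sr6 - sr6)
    coef = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r2p  # dE/dr / r
    grad = np.zeros_like(pos)
    dv = d[iu]
    contrib = coef[:, None] * dv
    np.add.at(grad, iu[0], contrib)
    np.add.at(grad, iu[1], -contrib)
    return e, grad.ravel()


def _pack_cluster(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Sequential random insertion at minimum separation 0.8σ inside a ball."""
    radius = 0.75 * sigma * max(1.0, n ** (1.0 / 3.0))
    for _ in range(40):  # frame-level restarts
        pts: list[np.ndarray] = []
        ok = True
        for _atom in range(n):
            for _try in range(300):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p = u * radius * rng.uniform() ** (1.0 / 3.0)
                if all(np.linalg.norm(p - q) >= 0.8 * sigma for q in pts):
                    pts.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise GnnPotError(f"could not pack {n} atoms at 0.8σ separation")


def _sample_positions(rng: np.random.Generator, spec: ToySpec) -> np.ndarray:
    pos = _pack_cluster(rng, spec.n_atoms, spec.sigma)
    if spec.n_atoms > 1:
        res = minimize(_lj_energy_grad, pos.ravel(), jac=True,
                       args=(spec.n_atoms, spec.epsilon, spec.sigma),
                       method="L-BFGS-B",
                       options={"maxiter": 200, "gtol": 1e-6})
        pos = res.x.reshape(spec.n_atoms, 3)
    pos = pos + rng.normal(scale=spec.displacement_scale, size=pos.shape)
    return pos - pos.mean(axis=0)


def _labelled_frames(spec: ToySpec, potential: BasePotential) -> Dataset:
    rng = np.random.default_rng(spec.seed)
    elements = np.array([spec.elements[i % len(spec.elements)]
                         for i in range(spec.n_atoms)], dtype=np.int64)
    frames = []
    for _ in range(spec.n_frames):
        cfg = Configuration(_sample_positions(rng, spec), elements)
        e, f = potential.evaluate(cfg)
        frames.append(LabeledFrame(cfg, e, f))
    return Dataset(frames, provenance=f"synthetic/{spec.family}/seed{spec.seed}")


def gen_lj_frames(spec: ToySpec) -> Dataset:
    """Labelled Lennard-Jones cluster frames."""
    if spec.family != "lj_cluster":
        raise ValidationError("gen_lj_frames requires family='lj_cluster'")
    base = LennardJonesPotential(spec.epsilon, spec.sigma, spec.r_cut)
    return _labelled_frames(spec, base)


def gen_delta_pair(spec: ToySpec) -> tuple[Dataset, BasePotential]:
    """Reference dataset (base + smooth Gaussian pair residual) and the base.

    ``delta_targets(reference, base)`` recovers the closed-form perturbation
    exactly, which is what makes parameter-recovery tests possible.
    """
    if spec.family != "perturbed_pair":
        raise ValidationError("gen_delta_pair requires family='perturbed_pair'")
    base = LennardJonesPotential(spec.epsilon, spec.sigma, spec.r_cut)
    perturbation = GaussianPairPerturbation(spec.amplitude, spec.length_scale)
    reference = _labelled_frames(spec, SumPotential(base, perturbation))
    return reference, base


def gen_qmmm_scene(n_qm: int, n_mm: int, geometry: str = "shell",
                   seed: int = 0, cutoff: float = 6.0,
                   element: int = ARGON_Z) -> Configuration:
    """A QM core cluster surrounded by MM atoms at controlled distances
    straddling the cutoff; region flags set accordingly."""
    if n_qm < 1:
        raise ValidationError("need at least one QM atom")
    if geometry not in ("shell", "lattice"):
        raise ValidationError("geometry must be 'shell' or 'lattice'")
    rng = np.random.default_rng(seed)
    core = _pack_cluster(rng, n_qm, 3.4) if n_qm > 1 else np.zeros((1, 3))
    core = core - core.mean(axis=0)
    mm_pts = []
    if geometry == "shell":
        for _ in range(n_mm):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            mm_pts.append(u * rng.uniform(0.6 * cutoff, 1.4 * cutoff))
    else:
        spacing = 3.0
        kmax = int(np.ceil(1.4 * cutoff / spacing))
        grid = [np.array([i, j, k], dtype=float) * spacing
                for i in range(-kmax, kmax + 1)
                for j in range(-kmax, kmax + 1)
                for k in range(-kmax, kmax + 1)]
        grid = [g for g in grid
                if np.min(np.linalg.norm(core - g, axis=1)) > 2.0]
        order = rng.permutation(len(grid))
        mm_pts = [grid[i] for i in order[:n_mm]]
    positions = np.vstack([core] + [np.asarray(mm_pts).reshape(-1, 3)]) \
        if n_mm else core
    region = np.array([QM] * n_qm + [MM] * n_mm)
    elements = np.full(n_qm + n_mm, element, dtype=np.int64)
    return Configuration(positions, elements, region)


def gen_qmmm_radial_family(cutoff: float = 6.0, n_points: int = 41,
                           element: int = ARGON_Z,
                           span: float = 1.0) -> list[Configuration]:
    """One QM atom at the origin, one MM atom walking radially from
    ``cutoff − span`` to ``cutoff + span`` — the boundary-smoothness probe."""
    configs = []
    for d in np.linspace(cutoff - span, cutoff + span, n_points):
        positions = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        configs.append(Configuration(positions,
                                     np.array([element, element]),
                                     np.array([QM, MM])))
    return configs
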