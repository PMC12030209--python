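"""Scaled-down benchmark experiments.

Desk-scale analogues of the full training protocol, with every knob set by
the experiment definition rather than the caller: a Lennard-Jones cluster
convergence run (500 frames of 8 atoms, 19:1 split, 20k Adam steps with the
standard schedule) and the Δ-learning comparison (ΔMLP versus pure MLP on
the perturbed-pair family at an equal 1500-step budget, repeated over
seeds).  Both are exercised by the test suite and by the reproduction
script; problem sizes are chosen so a run completes on a single CPU in
minutes while the statistics (force MAE relative to label RMS, Δ-advantage
margin) are stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import KCAL_PER_EV, split_dataset
from .deltamlp import combined_potential, delta_targets
from .potential import create_model, small_spec
from .synthetic import ToySpec, gen_delta_pair, gen_lj_frames
from .training import TrainConfig, evaluate_metrics, train

LJ_CONVERGENCE_STEPS = 20_000
DELTA_BUDGET_STEPS = 1_500


@dataclass
class ConvergenceResult:
    force_mae_ev: float        # test-set force MAE, eV/Å
    label_force_rms_ev: float  # RMS of test-label force components, eV/Å
    ratio: float               # force_mae / label_rms
    energy_mae_kcal: float
    final_loss: float


def lj_convergence(seed: int, n_frames: int = 500, n_atoms: int = 8,
                   n_steps: int = LJ_CONVERGENCE_STEPS,
                   precision: str = "float64") -> ConvergenceResult:
    """Train the desk-scale preset on LJ clusters and report test force MAE
    relative to the label force RMS."""
    data = gen_lj_frames(ToySpec(n_frames=n_frames, n_atoms=n_atoms,
                                 seed=seed))
    tr, te = split_dataset(data, (19, 1), seed)
    model = create_model(small_spec([18], seed=seed, precision=precision))
    cfg = TrainConfig(n_steps=n_steps, seed=seed, precision=precision,
                      log_every=max(1, n_steps // 20))
    model, history = train(model, tr, cfg)
    metrics = evaluate_metrics(model, te)
    label_rms = float(np.sqrt(np.mean(
        np.concatenate([f.forces.ravel() for f in te]) ** 2)))
    f_mae_ev = metrics.f_mae / KCAL_PER_EV
    return ConvergenceResult(
        force_mae_ev=f_mae_ev,
        label_force_rms_ev=label_rms,
        ratio=f_mae_ev / label_rms,
        energy_mae_kcal=metrics.e_mae,
        final_loss=history.records[-1]["loss"],
    )


def training_reproducible(seed: int, n_steps: int = 200) -> bool:
    """Two FP64 runs under one seed must produce bitwise-identical
    parameters."""
    data = gen_lj_frames(ToySpec(n_frames=40, n_atoms=8, seed=seed))
    model = create_model(small_spec([18], seed=seed))
    cfg = TrainConfig(n_steps=n_steps, seed=seed, precision="float64",
                      log_every=n_steps)
    m1, _ = train(model, data, cfg)
    m2, _ = train(model, data, cfg)
    return all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)


@dataclass
class DeltaAdvantageResult:
    seed: int
    delta_force_mae_kcal: float  # combined base+correction vs reference
    pure_force_mae_kcal: float   # direct fit of the reference


def delta_advantage(seed: int, n_frames: int = 200, n_atoms: int = 8,
                    n_steps: int = DELTA_BUDGET_STEPS) -> DeltaAdvantageResult:
    """ΔMLP versus pure MLP at an equal training budget on the
    perturbed-pair family; both evaluated on the same held-out reference."""
    reference, base = gen_delta_pair(
        ToySpec(family="perturbed_pair", n_frames=n_frames, n_atoms=n_atoms,
                seed=seed))
    tr, te = split_dataset(reference, (19, 1), seed)
    budget = TrainConfig(n_steps=n_steps, seed=seed, precision="float64",
                         log_every=n_steps)

    delta_model = create_model(small_spec([18], seed=seed))
    delta_model, _ = train(delta_model, delta_targets(tr, base), budget)
    met_delta = evaluate_metrics(combined_potential(base, delta_model), te)

    pure_model = create_model(small_spec([18], seed=seed))
    pure_model, _ = train(pure_model, tr, budget)
    met_pure = evaluate_metrics(pure_model, te)

    return DeltaAdvantageResult(seed, met_delta.f_mae, met_pure.f_mae)
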