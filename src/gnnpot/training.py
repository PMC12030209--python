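"""Training protocol for the potential.

The schedule follows the benchmark convention of the ecosystem this package
targets: Adam with a learning rate decaying geometrically from ``lr_start``
(default 1e-3) to ``lr_stop`` (default 3.51e-8) over ``n_steps`` (default
1e6); energy/force loss weights tied linearly to the learning rate so the
energy weight ramps 1 → 20 eV⁻² while the force weight anneals 100 → 1
eV⁻²Å² as the LR decays; batch size ⌈256/N⌉ for frames of N atoms, with
frames bucketed by atom count so the rule is well-defined per batch.

Per-frame loss: ``w_E (ΔE/N)² + w_F · (1/3N) Σ |ΔF|²``, averaged over the
batch.  The force term makes the parameter gradient a derivative of a
derivative; the autodiff engine's ``create_graph`` mode handles that.

Evaluation reports energy MAE/RMSE over per-frame totals (kcal/mol;
per-atom normalisation available) and force MAE/RMSE over all 3N components
(kcal/(mol·Å)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .core_io import KCAL_PER_EV, Configuration, Dataset
from .deltamlp import BasePotential
from .errors import TrainingDivergenceError, ValidationError
from .potential import (EnergyForceResult, PotentialModel, _forward_batch,
                        _prepare_single, compute_forces, fit_bias)


@dataclass
class TrainConfig:
    n_steps: int = 1_000_000
    lr_start: float = 1e-3
    lr_stop: float = 3.51e-8
    w_e_start: float = 1.0
    w_e_stop: float = 20.0
    w_f_start: float = 100.0
    w_f_stop: float = 1.0
    batch_numerator: int = 256
    precision: str | None = None  # None -> model precision
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValidationError("n_steps must be >= 0")
        if not (0 < self.lr_stop < self.lr_start):
            raise ValidationError("need 0 < lr_stop < lr_start")
        for fld in ("w_e_start", "w_e_stop", "w_f_start", "w_f_stop"):
            if getattr(self, fld) <= 0:
                raise ValidationError(f"{fld} must be positive")
        if self.batch_numerator < 1:
            raise ValidationError("batch_numerator must be >= 1")
        if self.precision not in (None, "float32", "float64"):
            raise ValidationError("precision must be float32, float64 or None")


@dataclass
class LossWeights:
    w_e: float  # eV^-2
    w_f: float  # eV^-2 Å^2


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)  # dicts: step, lr, w_e, w_f, loss

    def log(self, **kw):
        if self.records and kw["step"] <= self.records[-1]["step"]:
            raise ValidationError("history steps must be strictly increasing")
        self.records.append(kw)


@dataclass
class MetricsTable:
    e_mae: float   # kcal/mol
    e_rmse: float  # kcal/mol
    f_mae: float   # kcal/(mol·Å)
    f_rmse: float  # kcal/(mol·Å)

    def __str__(self):
        return ("          MAE        RMSE\n"
                f"Energy  {self.e_mae:10.6f} {self.e_rmse:10.6f}  kcal/mol\n"
                f"Force   {self.f_mae:10.6f} {self.f_rmse:10.6f}  kcal/(mol·Å)")


# ------------------------------------------------------------------ schedule

def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Geometric decay through the two endpoint learning rates."""
    if not (0 <= step <= cfg.n_steps):
        raise ValidationError(f"step {step} outside [0, {cfg.n_steps}]")
    if cfg.n_steps == 0:
        return cfg.lr_start
    return cfg.lr_start * (cfg.lr_stop / cfg.lr_start) ** (step / cfg.n_steps)


def loss_weights_at(lr: float, cfg: TrainConfig) -> LossWeights:
    """LR-tied linear interpolation between start and stop weights."""
    if not (cfg.lr_stop * (1 - 1e-12) <= lr <= cfg.lr_start * (1 + 1e-12)):
        raise ValidationError(f"lr {lr} outside schedule range")
    x = lr / cfg.lr_start
    return LossWeights(
        w_e=cfg.w_e_stop * (1.0 - x) + cfg.w_e_start * x,
        w_f=cfg.w_f_stop * (1.0 - x) + cfg.w_f_start * x,
    )


def batch_size_for(n_atoms: int, cfg: TrainConfig) -> int:
    if n_atoms < 1:
        raise ValidationError("n_atoms must be >= 1")
    return max(1, math.ceil(cfg.batch_numerator / n_atoms))


def loss(pred: EnergyForceResult, ref, w: LossWeights) -> float:
    """Single-frame loss value (arithmetic reference, numpy only)."""
    n = ref.config.n_atoms
    if pred.forces is None or ref.forces is None:
        raise ValidationError("loss requires forces on both sides")
    if pred.forces.shape != ref.forces.shape:
        raise ValidationError("force shape mismatch")
    de = (pred.total_energy - ref.energy) / n
    df = pred.forces - ref.forces
    return float(w.w_e * de * de + w.w_f * np.mean(df * df))


# ------------------------------------------------------------------- metrics

def evaluate_metrics(predictor, data: Dataset, per_atom: bool = False) -> MetricsTable:
    """MAE/RMSE of energies and force components against labels.

    ``predictor`` is a trained :class:`PotentialModel` or any
    :class:`BasePotential` (e.g. a combined ΔMLP potential).
    """
    e_res, f_res = [], []
    for frame in data:
        frame.require_labels()
        if isinstance(predictor, BasePotential):
            e, f = predictor.evaluate(frame.config)
        else:
            r = compute_forces(predictor, frame.config)
            e, f = r.total_energy, r.forces
        de = e - frame.energy
        if per_atom:
            de /= frame.config.n_atoms
        e_res.append(de)
        f_res.append((f - frame.forces).ravel())
    e_res = np.asarray(e_res) * KCAL_PER_EV
    f_res = np.concatenate(f_res) * KCAL_PER_EV
    return MetricsTable(
        e_mae=float(np.mean(np.abs(e_res))),
        e_rmse=float(np.sqrt(np.mean(e_res ** 2))),
        f_mae=float(np.mean(np.abs(f_res))),
        f_rmse=float(np.sqrt(np.mean(f_res ** 2))),
    )


def committee_deviation(models: list, config: Configuration) -> float:
    """Query-by-committee criterion: maximum over atoms of the standard
    deviation of the force vector across models (component-wise variance
    summed, square-rooted), in eV/Å."""
    if len(models) < 2:
        raise ValidationError("committee needs at least 2 models")
    tables = {tuple(m.spec.elements) for m in models}
    if len(tables) != 1:
        raise ValidationError("committee models must share one element table")
    forces = np.stack([compute_forces(m, config).forces for m in models])
    mean = forces.mean(axis=0)
    var = ((forces - mean) ** 2).mean(axis=0).sum(axis=1)  # (N,)
    return float(np.sqrt(var).max())


# ------------------------------------------------------------------ training

class _Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= (lr * (self.m[k] / c1)
                  / (np.sqrt(self.v[k] / c2) + self.eps)).astype(p.dtype)


def _prepare_frames(model: PotentialModel, data: Dataset, dt):
    """Cache per-frame graph topology and geometry once; frames are static."""
    cache = []
    for frame in data:
        frame.require_labels()
        edges, shift_vecs, elem_idx, qm_mask = _prepare_single(model, frame.config)
        cache.append({
            "pos": frame.config.positions.astype(dt),
            "senders": edges.senders, "receivers": edges.receivers,
            "shift_vecs": shift_vecs.astype(dt),
            "elem_idx": elem_idx, "qm_mask": qm_mask,
            "n": frame.config.n_atoms,
            "energy": dt(frame.energy),
            "forces": frame.forces.astype(dt),
        })
    return cache


def _assemble_batch(frames: list):
    """Concatenate cached frames into one batched graph with index offsets."""
    n_frames = len(frames)
    offsets = np.cumsum([0] + [f["n"] for f in frames])
    pos = np.concatenate([f["pos"] for f in frames])
    senders = np.concatenate([f["senders"] + offsets[i]
                              for i, f in enumerate(frames)])
    receivers = np.concatenate([f["receivers"] + offsets[i]
                                for i, f in enumerate(frames)])
    shift_vecs = np.concatenate([f["shift_vecs"] for f in frames])
    elem_idx = np.concatenate([f["elem_idx"] for f in frames])
    qm_mask = np.concatenate([f["qm_mask"] for f in frames])
    frame_index = np.concatenate([np.full(f["n"], i, dtype=np.int64)
                                  for i, f in enumerate(frames)])
    e_ref = np.array([f["energy"] for f in frames])
    f_ref = np.concatenate([f["forces"] for f in frames])
    n_per = np.array([f["n"] for f in frames], dtype=np.float64)
    return (pos, senders, receivers, shift_vecs, elem_idx, qm_mask,
            frame_index, n_frames, e_ref, f_ref, n_per)


def train(model: PotentialModel, data: Dataset,
          cfg: TrainConfig) -> tuple[PotentialModel, TrainHistory]:
    """Fit the per-element bias, then run the Adam protocol.

    Batches are sampled with replacement under ``cfg.seed`` from atom-count
    buckets (a uniformly drawn frame selects the bucket; the batch size is
    ⌈batch_numerator/N⌉ for that bucket's N).  Fully reproducible for a
    fixed (seed, precision).
    """
    model = model.copy()
    spec = model.spec
    dt = np.float64 if (cfg.precision or spec.precision) == "float64" else np.float32
    if cfg.precision is not None and cfg.precision != spec.precision:
        model.params = {k: v.astype(dt) for k, v in model.params.items()}

    model.bias = fit_bias(data, spec.elements)
    history = TrainHistory()
    if cfg.n_steps == 0:
        return model, history

    cache = _prepare_frames(model, data, dt)
    buckets: dict[int, list[int]] = {}
    for i, f in enumerate(cache):
        buckets.setdefault(f["n"], []).append(i)
    bucket_of_frame = np.array([f["n"] for f in cache])

    rng = np.random.default_rng(cfg.seed)
    adam = _Adam(model.params)
    param_names = sorted(model.params)

    for step in range(cfg.n_steps):
        lr = lr_at_step(step, cfg)
        w = loss_weights_at(lr, cfg)
        pick = int(rng.integers(len(cache)))
        n_bucket = int(bucket_of_frame[pick])
        members = buckets[n_bucket]
        bsz = batch_size_for(n_bucket, cfg)
        idx = rng.choice(len(members), size=bsz, replace=True)
        batch = [cache[members[i]] for i in idx]

        (pos_np, senders, receivers, shift_vecs, elem_idx, qm_mask,
         frame_index, n_frames, e_ref, f_ref, n_per) = _assemble_batch(batch)

        pos = ad.astensor(pos_np)
        pos.requires_grad = True
        params_t = {}
        for k in param_names:
            t = ad.astensor(model.params[k])
            t.requires_grad = True
            params_t[k] = t

        frame_e, _ = _forward_batch(spec, params_t, model.bias, pos, elem_idx,
                                    qm_mask, senders, receivers, shift_vecs,
                                    frame_index, n_frames)
        (gpos,) = ad.grad(ad.tsum(frame_e), [pos], create_graph=True)
        f_pred = ad.neg(gpos)

        de = ad.mul(ad.sub(frame_e, e_ref.astype(dt)), (1.0 / n_per).astype(dt))
        loss_e = ad.mul(ad.tsum(ad.mul(de, de)), 1.0 / n_frames)
        df = ad.sub(f_pred, f_ref.astype(dt))
        loss_f = ad.mul(ad.tsum(ad.mul(df, df)), 1.0 / df.data.size)
        total_loss = ad.add(ad.mul(loss_e, dt(w.w_e)), ad.mul(loss_f, dt(w.w_f)))

        loss_val = float(total_loss.data)
        if not np.isfinite(loss_val):
            raise TrainingDivergenceError(step)

        grads_t = ad.grad(total_loss, [params_t[k] for k in param_names])
        grads = {k: np.asarray(g.data) for k, g in zip(param_names, grads_t)}
        adam.step(model.params, grads, lr)

        if step % cfg.log_every == 0 or step == cfg.n_steps - 1:
            history.log(step=step, lr=lr, w_e=w.w_e, w_f=w.w_f, loss=loss_val)
    return model, history
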