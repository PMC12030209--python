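"""The trainable invariant message-passing potential.

Architecture (symmetry order 0 — scalar messages only): per message-passing
layer, each atom expands its filtered neighborhood in an atomic basis
``A_{i,k,lm}`` (envelope-weighted Bessel radial perceptron × real spherical
harmonics × neighbor channel scalars), contracts it into rotation-invariant
products up to the configured correlation order, maps those to per-channel
messages ``m_i`` through a linear layer, updates the node state residually
(``h ← h + m``) and reads out a per-layer atomic energy through a small
bias-free gated perceptron of the message.  Because every readout path runs
through the messages, an atom with an empty (filtered) neighborhood
contributes exactly its per-element bias — and exactly zero if it is an MM
atom, whose bias is suppressed by the range-correction rule.

Forces are obtained by reverse-mode differentiation of the total energy with
respect to positions; for periodic systems differentiation runs through the
displacement vectors at fixed integer image shifts.

Models are serialized to a self-contained ``.gpt`` zip archive: a versioned
JSON header, one little-endian binary blob per named parameter, and a
SHA-256 manifest for tamper detection.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core_io import QM, Configuration, Dataset
from .errors import (GnnPotError, ModelFormatError, UnknownElementError,
                     ValidationError)
from .features import (RadialSpec, _atomic_basis_from_geometry, bessel_basis,
                       invariant_products, n_invariants, poly_envelope,
                       smooth_switch)
from .graph import build_neighbor_list, filter_qmmm_edges

FORMAT_VERSION = "gnnpot-model/1"


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of a registered model preset."""

    name: str = "invariant_mace_s"
    elements: tuple = (1,)
    cutoff: float = 6.0
    n_bessel: int = 8
    envelope: str = "polynomial"     # "polynomial" | "switch"
    envelope_order: int = 5
    smoothing_width: float = 1.0
    l_max: int = 3
    correlation_order: int = 3
    n_channels: int = 256
    n_message_layers: int = 2
    radial_hidden: tuple = (64, 64, 64)
    readout_width: int = 16
    precision: str = "float64"       # "float32" | "float64"
    seed: int = 0

    def __post_init__(self):
        if not self.elements:
            raise ValidationError("element table must be non-empty")
        if len(set(self.elements)) != len(self.elements):
            raise ValidationError("element table has duplicates")
        if any(int(z) < 1 for z in self.elements):
            raise ValidationError("atomic numbers must be positive")
        for fld in ("n_bessel", "n_channels", "n_message_layers",
                    "readout_width", "l_max", "correlation_order"):
            if int(getattr(self, fld)) < 1:
                raise ValidationError(f"{fld} must be positive")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.l_max > 3:
            raise ValidationError("bundled presets support l_max <= 3")
        if self.envelope not in ("polynomial", "switch"):
            raise ValidationError("envelope must be 'polynomial' or 'switch'")
        if self.precision not in ("float32", "float64"):
            raise ValidationError("precision must be float32 or float64")

    @property
    def dtype(self):
        return np.float64 if self.precision == "float64" else np.float32

    def radial_spec(self) -> RadialSpec:
        return RadialSpec(self.cutoff, self.n_bessel, self.envelope_order,
                          self.smoothing_width)


@dataclass
class EnergyForceResult:
    total_energy: float
    atomic_energies: np.ndarray
    forces: np.ndarray | None = None


@dataclass
class PotentialModel:
    """Spec + named parameter arrays + per-element energy bias (eV)."""

    spec: ModelSpec
    params: dict
    bias: np.ndarray  # aligned with spec.elements

    def __post_init__(self):
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.bias.shape != (len(self.spec.elements),):
            raise ValidationError("bias must cover the element table")

    def element_index(self, elements: np.ndarray) -> np.ndarray:
        table = {int(z): i for i, z in enumerate(self.spec.elements)}
        try:
            return np.array([table[int(z)] for z in elements], dtype=np.int64)
        except KeyError as e:
            raise UnknownElementError(
                f"element Z={e.args[0]} not in model table {list(self.spec.elements)}"
            ) from None

    def copy(self) -> "PotentialModel":
        return PotentialModel(self.spec,
                              {k: v.copy() for k, v in self.params.items()},
                              self.bias.copy())


# ------------------------------------------------------------------ registry

_REGISTRY: dict = {}


def register_model(name: str, constructor) -> None:
    """Register a model constructor (spec -> PotentialModel) under a unique
    name; the plugin point for alternative architectures."""
    if name in _REGISTRY:
        raise ValidationError(f"model name already registered: {name!r}")
    _REGISTRY[name] = constructor


def registered_models() -> list[str]:
    return sorted(_REGISTRY)


def create_model(spec: ModelSpec) -> PotentialModel:
    try:
        ctor = _REGISTRY[spec.name]
    except KeyError:
        raise ValidationError(
            f"unknown model {spec.name!r}; registered models: {registered_models()}"
        ) from None
    return ctor(spec)


# ------------------------------------------------------------- construction

def _init_params(spec: ModelSpec) -> dict:
    """Deterministic uniform fan-in initialisation from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    dt = spec.dtype
    K, L = spec.n_channels, spec.l_max
    n_inv = n_invariants(K, spec.correlation_order, L)
    params = {}

    def uniform(name, shape, fan_in):
        lim = np.sqrt(1.0 / max(fan_in, 1))
        params[name] = rng.uniform(-lim, lim, size=shape).astype(dt)

    uniform("embed", (len(spec.elements), K), 1)
    for t in range(spec.n_message_layers):
        widths = (spec.n_bessel,) + tuple(spec.radial_hidden) + (K * (L + 1),)
        for i in range(len(widths) - 1):
            uniform(f"layer{t}.radial.W{i}", (widths[i], widths[i + 1]), widths[i])
            uniform(f"layer{t}.radial.b{i}", (widths[i + 1],), widths[i])
        uniform(f"layer{t}.product.W", (n_inv, K), n_inv)
        uniform(f"layer{t}.readout.V", (K, spec.readout_width), K)
        uniform(f"layer{t}.readout.v", (spec.readout_width, 1), spec.readout_width)
    return params


def _build_invariant_model(spec: ModelSpec) -> PotentialModel:
    return PotentialModel(spec, _init_params(spec),
                          np.zeros(len(spec.elements)))


register_model("invariant_mace_s", _build_invariant_model)
register_model("invariant_small", _build_invariant_model)


def mace_s_spec(elements, seed: int = 0, precision: str = "float32",
                **overrides) -> ModelSpec:
    """The large invariant preset: 256 channels, spherical harmonics to
    order 3, correlation order 3, 2 message layers, 6 Å cutoff, 8 Bessel
    functions, order-5 polynomial envelope."""
    kw = dict(name="invariant_mace_s", elements=tuple(int(z) for z in elements),
              cutoff=6.0, n_bessel=8, envelope="polynomial", envelope_order=5,
              l_max=3, correlation_order=3, n_channels=256,
              n_message_layers=2, radial_hidden=(64, 64, 64),
              precision=precision, seed=seed)
    kw.update(overrides)
    return ModelSpec(**kw)


def small_spec(elements, seed: int = 0, precision: str = "float64",
               **overrides) -> ModelSpec:
    """Desk-scale preset for experiments and tests: 8 channels, l_max 2,
    correlation order 3, one message layer, narrower radial perceptron."""
    kw = dict(name="invariant_small", elements=tuple(int(z) for z in elements),
              cutoff=6.0, n_bessel=8, envelope="polynomial", envelope_order=5,
              l_max=2, correlation_order=3, n_channels=8,
              n_message_layers=1, radial_hidden=(32, 32), readout_width=8,
              precision=precision, seed=seed)
    kw.update(overrides)
    return ModelSpec(**kw)


# -------------------------------------------------------------- forward pass

def _linear(x, W, b=None):
    y = ad.matmul(x, W)
    return y if b is None else ad.add(y, b)


def _radial_map(spec: ModelSpec, params, prefix: str, dist):
    """Envelope-weighted Bessel vector → radial perceptron → (E, K, l_max+1),
    multiplied once more by the envelope so edge terms vanish smoothly (value
    and slope) at the cutoff."""
    rspec = spec.radial_spec()
    env_fn = poly_envelope if spec.envelope == "polynomial" else smooth_switch
    env = env_fn(dist, rspec)                       # (E,)
    eb = bessel_basis(dist, rspec)                  # (E, n_bessel)
    E = dist.data.shape[0]
    x = ad.mul(eb, ad.reshape(env, (E, 1)))
    n_hidden = len(spec.radial_hidden)
    for i in range(n_hidden):
        x = ad.silu(_linear(x, params[f"{prefix}.W{i}"], params[f"{prefix}.b{i}"]))
    x = _linear(x, params[f"{prefix}.W{n_hidden}"], params[f"{prefix}.b{n_hidden}"])
    R = ad.reshape(x, (E, spec.n_channels, spec.l_max + 1))
    return ad.mul(R, ad.reshape(env, (E, 1, 1)))


def _forward_batch(spec: ModelSpec, params, bias, pos: Tensor, elem_idx,
                   qm_mask, senders, receivers, shift_vecs, frame_index,
                   n_frames: int):
    """Core evaluation on a (possibly multi-frame) batched graph.

    Returns (per-frame energies, per-atom energies) as Tensors.
    """
    n_atoms = pos.data.shape[0]
    dt = pos.data.dtype
    h = ad.gather(params["embed"], elem_idx)
    readout_sum = None
    if len(senders):
        disp = ad.add(ad.sub(ad.gather(pos, receivers), ad.gather(pos, senders)),
                      shift_vecs.astype(dt))
        dist = ad.power(ad.tsum(ad.mul(disp, disp), axis=1), 0.5)
    for t in range(spec.n_message_layers):
        if len(senders) == 0:
            break
        A = _atomic_basis_from_geometry(
            disp, dist, senders, receivers, h, n_atoms, spec.l_max,
            lambda d, _t=t: _radial_map(spec, params, f"layer{_t}.radial", d))
        B = invariant_products(A, spec.correlation_order, spec.l_max)
        # rowmm keeps each atom's energy bitwise independent of batch size
        m = ad.rowmm(B, params[f"layer{t}.product.W"])
        e_t = ad.rowmm(ad.silu(ad.rowmm(m, params[f"layer{t}.readout.V"])),
                       params[f"layer{t}.readout.v"])
        e_t = ad.reshape(e_t, (n_atoms,))
        readout_sum = e_t if readout_sum is None else ad.add(readout_sum, e_t)
        h = ad.add(h, m)
    bias_atoms = np.asarray(bias, dtype=dt)[np.asarray(elem_idx)] * qm_mask.astype(dt)
    atomic = ad.add(readout_sum, bias_atoms) if readout_sum is not None \
        else ad.astensor(bias_atoms)
    frame_e = ad.segment_sum(ad.reshape(atomic, (n_atoms, 1)), frame_index,
                             n_frames)
    return ad.reshape(frame_e, (n_frames,)), atomic


def _prepare_single(model: PotentialModel, config: Configuration):
    edges = build_neighbor_list(config, model.spec.cutoff)
    edges = filter_qmmm_edges(edges, config.region)
    if config.cell is not None:
        shift_vecs = edges.shifts @ config.cell
    else:
        shift_vecs = np.zeros((len(edges), 3))
    elem_idx = model.element_index(config.elements)
    qm_mask = config.region == QM
    return edges, shift_vecs, elem_idx, qm_mask


def forward_energy(model: PotentialModel, config: Configuration) -> EnergyForceResult:
    """Total and per-atom energies (eV) of a configuration."""
    edges, shift_vecs, elem_idx, qm_mask = _prepare_single(model, config)
    dt = model.spec.dtype
    with ad.no_grad():
        pos = ad.astensor(config.positions.astype(dt))
        params = {k: ad.astensor(v) for k, v in model.params.items()}
        frame_e, atomic = _forward_batch(
            model.spec, params, model.bias, pos, elem_idx, qm_mask,
            edges.senders, edges.receivers, shift_vecs,
            np.zeros(config.n_atoms, dtype=np.int64), 1)
    total = float(frame_e.data[0])
    atomic_np = np.asarray(atomic.data, dtype=np.float64)
    if not np.isfinite(total) or not np.all(np.isfinite(atomic_np)):
        raise GnnPotError("model produced non-finite energy")
    return EnergyForceResult(total, atomic_np)


def compute_forces(model: PotentialModel, config: Configuration) -> EnergyForceResult:
    """Energies plus forces = −∂E/∂positions via reverse-mode autodiff."""
    edges, shift_vecs, elem_idx, qm_mask = _prepare_single(model, config)
    dt = model.spec.dtype
    pos = ad.astensor(config.positions.astype(dt))
    pos.requires_grad = True
    params = {k: ad.astensor(v) for k, v in model.params.items()}
    frame_e, atomic = _forward_batch(
        model.spec, params, model.bias, pos, elem_idx, qm_mask,
        edges.senders, edges.receivers, shift_vecs,
        np.zeros(config.n_atoms, dtype=np.int64), 1)
    total_t = ad.tsum(frame_e)
    (gpos,) = ad.grad(total_t, [pos])
    forces = -np.asarray(gpos.data, dtype=np.float64)
    total = float(total_t.data)
    atomic_np = np.asarray(atomic.data, dtype=np.float64)
    if not (np.isfinite(total) and np.all(np.isfinite(atomic_np))
            and np.all(np.isfinite(forces))):
        raise GnnPotError("model produced non-finite energy or forces")
    return EnergyForceResult(total, atomic_np, forces)


# ------------------------------------------------------------------ fit_bias

def fit_bias(dataset: Dataset, element_table) -> np.ndarray:
    """Least-squares per-element atomic energy offsets over QM atoms.

    Solves ``E_frame ≈ Σ_Z count_Z(QM) · E0(Z)``; MM atoms contribute no
    column, so their bias is structurally zero.
    """
    table = [int(z) for z in element_table]
    rows, ys = [], []
    for frame in dataset:
        frame.require_labels()
        cfg = frame.config
        qm = cfg.region == QM
        rows.append([int(np.sum((cfg.elements == z) & qm)) for z in table])
        ys.append(frame.energy)
    X = np.asarray(rows, dtype=np.float64)
    y = np.asarray(ys, dtype=np.float64)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


# -------------------------------------------------------------- serialization

def serialize_model(model: PotentialModel, path) -> None:
    """Write a ``.gpt`` archive: header.json + params/*.bin + manifest.json."""
    spec_dict = asdict(model.spec)
    spec_dict["elements"] = list(model.spec.elements)
    spec_dict["radial_hidden"] = list(model.spec.radial_hidden)
    header = {
        "format_version": FORMAT_VERSION,
        "units": {"energy": "eV", "length": "Angstrom"},
        "spec": spec_dict,
        "parameters": {k: {"shape": list(v.shape), "dtype": str(v.dtype)}
                       for k, v in model.params.items()},
        "bias": [float(b) for b in model.bias],
    }
    manifest = {}
    blobs = {}
    for k, v in model.params.items():
        raw = np.ascontiguousarray(v).astype(v.dtype.newbyteorder("<")).tobytes()
        blobs[f"params/{k}.bin"] = raw
        manifest[f"params/{k}.bin"] = hashlib.sha256(raw).hexdigest()
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name, raw in blobs.items():
            zf.writestr(name, raw)
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))


def inspect_model(path) -> dict:
    """Read only the archive header (spec, units, parameter shapes)."""
    with zipfile.ZipFile(path) as zf:
        return json.loads(zf.read("header.json"))


def load_model(path) -> PotentialModel:
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("format_version") != FORMAT_VERSION:
                raise ModelFormatError(
                    f"unsupported model format {header.get('format_version')!r}; "
                    f"this build reads {FORMAT_VERSION!r}")
            manifest = json.loads(zf.read("manifest.json"))
            params = {}
            for name, meta in header["parameters"].items():
                entry = f"params/{name}.bin"
                raw = zf.read(entry)
                digest = hashlib.sha256(raw).hexdigest()
                if manifest.get(entry) != digest:
                    raise ModelFormatError(f"checksum mismatch for {entry}: "
                                           "archive corrupt or tampered")
                arr = np.frombuffer(raw, dtype=np.dtype(meta["dtype"]).newbyteorder("<"))
                params[name] = arr.reshape(meta["shape"]).astype(meta["dtype"])
    except zipfile.BadZipFile as e:
        raise ModelFormatError(f"not a model archive: {e}") from None
    sd = dict(header["spec"])
    sd["elements"] = tuple(sd["elements"])
    sd["radial_hidden"] = tuple(sd["radial_hidden"])
    spec = ModelSpec(**sd)
    return PotentialModel(spec, params, np.asarray(header["bias"]))
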