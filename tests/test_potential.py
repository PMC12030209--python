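"""Model symmetries, QM/MM range-correction behavior, autodiff forces,
bias fitting and serialization."""

import numpy as np
import pytest

from gnnpot import (Configuration, Dataset, LabeledFrame, compute_forces,
                    create_model, fit_bias, forward_energy, inspect_model,
                    load_model, mace_s_spec, register_model,
                    registered_models, serialize_model, small_spec)
from gnnpot.core_io import MM, QM
from gnnpot.errors import (ModelFormatError, UnknownElementError,
                           ValidationError)
from conftest import random_cluster, random_rotation


# ------------------------------------------------------------------ registry

def test_create_with_unregistered_name_lists_available():
    spec = small_spec([18])
    object.__setattr__(spec, "name", "no_such_model")
    with pytest.raises(ValidationError, match="invariant_mace_s"):
        from gnnpot import create_model as cm
        cm(spec)


def test_duplicate_registration_rejected():
    with pytest.raises(ValidationError):
        register_model("invariant_small", lambda s: None)


def test_mace_s_preset_has_256_channels():
    spec = mace_s_spec([1, 6, 8])
    assert spec.n_channels == 256
    assert spec.l_max == 3 and spec.correlation_order == 3
    assert spec.n_message_layers == 2 and spec.n_bessel == 8
    assert spec.cutoff == 6.0 and spec.envelope_order == 5


def test_same_seed_same_parameters_bitwise():
    m1 = create_model(small_spec([18], seed=3))
    m2 = create_model(small_spec([18], seed=3))
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])
    m3 = create_model(small_spec([18], seed=4))
    assert any(not np.array_equal(m3.params[k], m1.params[k])
               for k in m1.params)


def test_unknown_element_raises(argon_model):
    cfg = Configuration([[0, 0, 0]], [6])
    with pytest.raises(UnknownElementError):
        forward_energy(argon_model, cfg)


# ------------------------------------------------------------- DPRc rules

def test_mm_only_system_energy_exactly_zero(argon_model, rng):
    pos = rng.normal(size=(5, 3)) * 2
    cfg = Configuration(pos, np.full(5, 18), region=[MM] * 5)
    res = forward_energy(argon_model, cfg)
    assert res.total_energy == 0.0
    assert np.all(res.atomic_energies == 0.0)


def test_isolated_qm_atom_energy_equals_bias(argon_model):
    model = argon_model.copy()
    model.bias = np.array([-3.25])
    cfg = Configuration([[0.0, 0.0, 0.0]], [18])
    assert forward_energy(model, cfg).total_energy == -3.25


def test_distant_mm_atom_changes_nothing_even_near_other_mm(argon_model):
    # QM pair at origin; two MM atoms ~1 Å apart, both > cutoff from all QM
    qm = np.array([[0, 0, 0], [3.0, 0, 0]])
    mm_far = np.array([[20.0, 0, 0]])
    mm_pair = np.array([[20.0, 0, 0], [20.0, 1.0, 0]])
    e1 = forward_energy(argon_model, Configuration(
        np.vstack([qm, mm_far]), np.full(3, 18),
        region=[QM, QM, MM])).total_energy
    e2 = forward_energy(argon_model, Configuration(
        np.vstack([qm, mm_pair]), np.full(4, 18),
        region=[QM, QM, MM, MM])).total_energy
    e0 = forward_energy(argon_model, Configuration(
        qm, np.full(2, 18))).total_energy
    assert e1 == e0
    assert e2 == e0


def test_energy_smooth_across_cutoff_for_mm_qm_distance(argon_model):
    """E(d) for one MM atom approaching one QM atom is continuous with a
    continuous first derivative across d = r_c."""
    rc = argon_model.spec.cutoff
    d = np.arange(rc - 0.05, rc + 0.05, 1e-3)
    energies = []
    for di in d:
        cfg = Configuration([[0, 0, 0], [di, 0, 0]], [18, 18],
                            region=[QM, MM])
        energies.append(forward_energy(argon_model, cfg).total_energy)
    energies = np.array(energies)
    assert np.max(np.abs(np.diff(energies))) < 1e-7  # no value jump
    d1 = np.diff(energies) / 1e-3
    assert np.max(np.abs(np.diff(d1))) < 1e-3  # no slope jump


def test_locality_distant_atom_adds_only_its_bias(argon_model, rng):
    model = argon_model.copy()
    model.bias = np.array([1.7])
    cfg = random_cluster(rng, n=4)
    e0 = forward_energy(model, cfg).total_energy
    far = np.vstack([cfg.positions, [[500.0, 0, 0]]])
    e1 = forward_energy(model, Configuration(far, np.full(5, 18))).total_energy
    assert abs(e1 - (e0 + 1.7)) < 1e-12


def test_extensivity_two_noninteracting_copies(argon_model, rng):
    cfg = random_cluster(rng, n=4)
    e0 = forward_energy(argon_model, cfg).total_energy
    both = np.vstack([cfg.positions, cfg.positions + [200.0, 0, 0]])
    e2 = forward_energy(argon_model,
                        Configuration(both, np.full(8, 18))).total_energy
    assert abs(e2 - 2 * e0) < 1e-12


# ------------------------------------------------------------- symmetries

def test_energy_invariance_rotation_translation_permutation(argon_model, rng):
    for _ in range(10):
        cfg = random_cluster(rng, n=6)
        e0 = forward_energy(argon_model, cfg).total_energy
        Q = random_rotation(rng)
        t = rng.normal(size=3) * 10
        perm = rng.permutation(6)
        moved = Configuration(cfg.positions[perm] @ Q.T + t, np.full(6, 18))
        e1 = forward_energy(argon_model, moved).total_energy
        assert abs(e1 - e0) <= 1e-9 * max(1.0, abs(e0))


def test_force_rotation_equivariance(argon_model, rng):
    cfg = random_cluster(rng, n=5)
    F = compute_forces(argon_model, cfg).forces
    Q = random_rotation(rng)
    F_rot = compute_forces(
        argon_model, Configuration(cfg.positions @ Q.T, cfg.elements)).forces
    np.testing.assert_allclose(F_rot, F @ Q.T, atol=1e-10)


def test_forces_sum_to_zero_isolated_system(argon_model, rng):
    cfg = random_cluster(rng, n=6)
    F = compute_forces(argon_model, cfg).forces
    assert np.max(np.abs(F.sum(axis=0))) < 1e-8


def test_forces_match_central_differences(argon_model, rng):
    h = 1e-4
    for _ in range(3):
        cfg = random_cluster(rng, n=4)
        F = compute_forces(argon_model, cfg).forces
        for (i, j) in [(0, 0), (1, 2), (3, 1)]:
            p = cfg.positions.copy(); p[i, j] += h
            ep = forward_energy(argon_model, cfg.with_positions(p)).total_energy
            p[i, j] -= 2 * h
            em = forward_energy(argon_model, cfg.with_positions(p)).total_energy
            assert abs(-(ep - em) / (2 * h) - F[i, j]) < 1e-5


def test_forces_under_pbc_match_central_differences(rng):
    model = create_model(small_spec([18], seed=2, cutoff=4.0))
    cell = np.eye(3) * 5.0
    pos = rng.uniform(size=(4, 3)) @ cell
    cfg = Configuration(pos, np.full(4, 18), cell=cell, pbc=[True] * 3)
    F = compute_forces(model, cfg).forces
    h = 1e-4
    for (i, j) in [(0, 1), (2, 0)]:
        p = pos.copy(); p[i, j] += h
        ep = forward_energy(model, cfg.with_positions(p)).total_energy
        p[i, j] -= 2 * h
        em = forward_energy(model, cfg.with_positions(p)).total_energy
        assert abs(-(ep - em) / (2 * h) - F[i, j]) < 1e-5


def test_atomic_energies_sum_to_total(argon_model, rng):
    cfg = random_cluster(rng, n=7)
    res = forward_energy(argon_model, cfg)
    assert abs(res.atomic_energies.sum() - res.total_energy) \
        <= 1e-6 * max(1.0, abs(res.total_energy))


# --------------------------------------------------------------- fit_bias

def test_fit_bias_isolated_atoms_exact():
    cfgs = [Configuration([[0, 0, 0]], [1]),
            Configuration([[0, 0, 0]], [8])]
    frames = [LabeledFrame(cfgs[0], -13.6, np.zeros((1, 3))),
              LabeledFrame(cfgs[1], -75.0, np.zeros((1, 3)))]
    bias = fit_bias(Dataset(frames), [1, 8])
    np.testing.assert_allclose(bias, [-13.6, -75.0], atol=1e-12)


def test_fit_bias_linear_composition_zero_residual(rng):
    e0 = {1: -0.5, 8: -2.0}
    frames = []
    for _ in range(6):
        n = int(rng.integers(2, 6))
        els = rng.choice([1, 8], size=n)
        cfg = Configuration(rng.normal(size=(n, 3)) * 3, els)
        energy = sum(e0[int(z)] for z in els)
        frames.append(LabeledFrame(cfg, energy, np.zeros((n, 3))))
    bias = fit_bias(Dataset(frames), [1, 8])
    np.testing.assert_allclose(bias, [-0.5, -2.0], atol=1e-10)


def test_fit_bias_matches_normal_equations(rng):
    frames = []
    X = []
    y = []
    for _ in range(12):
        n = int(rng.integers(2, 7))
        els = rng.choice([1, 6, 8], size=n)
        cfg = Configuration(rng.normal(size=(n, 3)) * 3, els)
        energy = float(rng.normal())
        frames.append(LabeledFrame(cfg, energy, np.zeros((n, 3))))
        X.append([np.sum(els == z) for z in (1, 6, 8)])
        y.append(energy)
    bias = fit_bias(Dataset(frames), [1, 6, 8])
    X = np.array(X, dtype=float); y = np.array(y)
    expect = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(bias, expect, atol=1e-8)


def test_fit_bias_ignores_mm_atoms(rng):
    # frames whose MM atoms must not contribute count columns
    cfg = Configuration(rng.normal(size=(3, 3)) * 4, [18, 18, 18],
                        region=[QM, MM, MM])
    frames = [LabeledFrame(cfg, -1.0, np.zeros((3, 3)))]
    bias = fit_bias(Dataset(frames), [18])
    np.testing.assert_allclose(bias, [-1.0], atol=1e-12)


# ----------------------------------------------------------- serialization

def test_save_load_bit_identical_predictions(argon_model, rng, tmp_path):
    path = tmp_path / "m.gpt"
    serialize_model(argon_model, path)
    back = load_model(path)
    for _ in range(10):
        cfg = random_cluster(rng, n=5)
        assert forward_energy(back, cfg).total_energy \
            == forward_energy(argon_model, cfg).total_energy


def test_header_only_inspection(argon_model, tmp_path):
    path = tmp_path / "m.gpt"
    serialize_model(argon_model, path)
    header = inspect_model(path)
    assert header["format_version"] == "gnnpot-model/1"
    assert header["spec"]["n_channels"] == argon_model.spec.n_channels
    assert header["units"]["energy"] == "eV"


def test_tampered_payload_detected(argon_model, tmp_path):
    import zipfile
    path = tmp_path / "m.gpt"
    serialize_model(argon_model, path)
    with zipfile.ZipFile(path) as zf:
        names = zf.namelist()
        blobs = {n: zf.read(n) for n in names}
    victim = next(n for n in names if n.startswith("params/"))
    raw = bytearray(blobs[victim])
    raw[7] ^= 0xFF
    blobs[victim] = bytes(raw)
    with zipfile.ZipFile(path, "w") as zf:
        for n, b in blobs.items():
            zf.writestr(n, b)
    with pytest.raises(ModelFormatError, match="checksum"):
        load_model(path)


def test_version_mismatch_rejected(argon_model, tmp_path):
    import json
    import zipfile
    path = tmp_path / "m.gpt"
    serialize_model(argon_model, path)
    with zipfile.ZipFile(path) as zf:
        blobs = {n: zf.read(n) for n in zf.namelist()}
    header = json.loads(blobs["header.json"])
    header["format_version"] = "gnnpot-model/99"
    blobs["header.json"] = json.dumps(header)
    with zipfile.ZipFile(path, "w") as zf:
        for n, b in blobs.items():
            zf.writestr(n, b)
    with pytest.raises(ModelFormatError, match="format"):
        load_model(path)
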