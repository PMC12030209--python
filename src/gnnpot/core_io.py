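"""Atomistic domain types and extended-XYZ I/O.

Internal units are eV and Å throughout the package; kcal/mol appears only in
reported metrics.  Coordinates are Cartesian with 0-based atom indexing.  The
QM/MM partition is a per-atom flag (``"QM"`` / ``"MM"``); a configuration with
no explicit flags is all-QM.

The extended-XYZ dialect understood here uses a ``key=value`` comment line
with ``Lattice="..."``, ``Properties=...``, ``energy=...`` and optional
``pbc="T T T"`` keys, and per-atom columns declared by ``Properties`` —
``species:S:1:pos:R:3`` always, plus ``forces:R:3`` and ``region:S:1`` when
present.  Floats are written with shortest round-trip ``repr`` so a
write/read cycle is bit-faithful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .elements import atomic_number, symbol
from .errors import ParseError, UnlabeledFrameError, ValidationError

KCAL_PER_EV = 23.060548  # kcal/mol per eV, reporting only

QM = "QM"
MM = "MM"


@dataclass
class Configuration:
    """Atomic geometry: positions (Å), atomic numbers, QM/MM flags, cell."""

    positions: np.ndarray
    elements: np.ndarray
    region: np.ndarray | None = None
    cell: np.ndarray | None = None
    pbc: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be (N, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValidationError("configuration needs at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite positions")
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.shape != (n,):
            raise ValidationError("elements must be length N")
        if np.any(self.elements < 1):
            raise ValidationError("atomic numbers must be positive")
        if self.region is None:
            self.region = np.full(n, QM, dtype="<U2")
        else:
            self.region = np.asarray(self.region, dtype="<U2")
            if self.region.shape != (n,):
                raise ValidationError("region must be length N")
            bad = set(self.region) - {QM, MM}
            if bad:
                raise ValidationError(f"region flags must be QM/MM, got {sorted(bad)}")
        if self.pbc is None:
            self.pbc = np.zeros(3, dtype=bool)
        else:
            self.pbc = np.asarray(self.pbc, dtype=bool)
            if self.pbc.shape != (3,):
                raise ValidationError("pbc must be 3 booleans")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64)
            if self.cell.shape != (3, 3):
                raise ValidationError("cell must be 3x3")
        if self.pbc.any():
            if self.cell is None:
                raise ValidationError("periodic configuration requires a cell")
            if abs(np.linalg.det(self.cell)) <= 1e-8:
                raise ValidationError("singular cell (|det| <= 1e-8 Å³)")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def with_positions(self, positions: np.ndarray) -> "Configuration":
        return Configuration(positions, self.elements.copy(),
                             self.region.copy(),
                             None if self.cell is None else self.cell.copy(),
                             self.pbc.copy())


@dataclass
class LabeledFrame:
    """A configuration plus (optional) total energy (eV) and forces (eV/Å).

    Unlabeled frames are legal as inference input; the trainer rejects them.
    """

    config: Configuration
    energy: float | None = None
    forces: np.ndarray | None = None

    def __post_init__(self):
        if self.energy is not None:
            self.energy = float(self.energy)
            if not np.isfinite(self.energy):
                raise ValidationError("non-finite energy label")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=np.float64)
            if self.forces.shape != (self.config.n_atoms, 3):
                raise ValidationError("forces must be (N, 3)")
            if not np.all(np.isfinite(self.forces)):
                raise ValidationError("non-finite force labels")

    @property
    def is_labeled(self) -> bool:
        return self.energy is not None and self.forces is not None

    def require_labels(self) -> None:
        if not self.is_labeled:
            raise UnlabeledFrameError("frame has no energy/force labels")


@dataclass
class Dataset:
    """An ordered collection of frames sharing the eV/Å convention."""

    frames: list[LabeledFrame]
    provenance: str = ""

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("dataset must be non-empty")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> LabeledFrame:
        return self.frames[i]


# ------------------------------------------------------------------ parsing

_KEYVAL = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KEYVAL.finditer(line)}


def _parse_properties(prop: str) -> list[tuple[str, str, int]]:
    toks = prop.split(":")
    if len(toks) % 3 != 0:
        raise ParseError(f"malformed Properties string: {prop!r}")
    out = []
    for i in range(0, len(toks), 3):
        name, kind, ncol = toks[i], toks[i + 1], int(toks[i + 2])
        out.append((name, kind, ncol))
    return out


def read_extxyz(path, forces_key: str = "forces") -> Dataset:
    """Read an extended-XYZ file into a :class:`Dataset`.

    Per-frame ``energy`` comes from the comment line, per-atom forces from a
    ``forces`` column (configurable via ``forces_key``), and region flags from
    a ``region`` column when present (all-QM otherwise).
    """
    frames: list[LabeledFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 1}: missing comment line")
        info = _parse_comment(lines[i + 1])
        props = _parse_properties(info.get("Properties", "species:S:1:pos:R:3"))
        col_names = []
        col_of = {}
        c = 0
        for name, kind, ncol in props:
            col_of[name] = (c, ncol)
            col_names.append(name)
            c += ncol
        ncols = c
        atom_lines = lines[i + 2:i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError(f"line {i + 1}: header declares {natoms} atoms "
                             f"but only {len(atom_lines)} atom lines remain")
        rows = []
        for j, ln in enumerate(atom_lines):
            toks = ln.split()
            if len(toks) != ncols:
                raise ParseError(f"line {i + 3 + j}: expected {ncols} columns, "
                                 f"got {len(toks)}")
            rows.append(toks)
        if "species" not in col_of or "pos" not in col_of:
            raise ParseError("Properties must declare species and pos columns")
        sc, _ = col_of["species"]
        elements = np.array([atomic_number(r[sc]) for r in rows], dtype=np.int64)
        pc, _ = col_of["pos"]
        positions = np.array([[float(r[pc + k]) for k in range(3)] for r in rows])
        region = None
        if "region" in col_of:
            rc, _ = col_of["region"]
            region = np.array([r[rc] for r in rows], dtype="<U2")
        forces = None
        if forces_key in col_of:
            fc, _ = col_of[forces_key]
            forces = np.array([[float(r[fc + k]) for k in range(3)] for r in rows])
        cell = None
        pbc = None
        if "Lattice" in info:
            cell = np.array([float(x) for x in info["Lattice"].split()],
                            dtype=np.float64).reshape(3, 3)
        if "pbc" in info:
            pbc = np.array([t in ("T", "True", "true") for t in info["pbc"].split()])
        elif cell is not None:
            pbc = np.ones(3, dtype=bool)
        energy = float(info["energy"]) if "energy" in info else None
        config = Configuration(positions, elements, region, cell, pbc)
        frames.append(LabeledFrame(config, energy, forces))
        i += 2 + natoms
    if not frames:
        raise ParseError(f"no frames found in {path}")
    return Dataset(frames, provenance=str(path))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_extxyz(dataset: Dataset, path) -> None:
    """Write a dataset as extended XYZ (see module docstring for the dialect)."""
    with open(path, "w") as fh:
        for frame in dataset:
            cfg = frame.config
            n = cfg.n_atoms
            has_region = bool(np.any(cfg.region == MM))
            prop = "species:S:1:pos:R:3"
            if frame.forces is not None:
                prop += ":forces:R:3"
            if has_region:
                prop += ":region:S:1"
            keys = []
            if cfg.cell is not None:
                keys.append('Lattice="' + " ".join(_fmt(x) for x in cfg.cell.ravel()) + '"')
            keys.append(f"Properties={prop}")
            if frame.energy is not None:
                keys.append(f"energy={_fmt(frame.energy)}")
            if cfg.pbc.any():
                keys.append('pbc="' + " ".join("T" if b else "F" for b in cfg.pbc) + '"')
            fh.write(f"{n}\n")
            fh.write(" ".join(keys) + "\n")
            for a in range(n):
                cols = [symbol(int(cfg.elements[a]))]
                cols += [_fmt(x) for x in cfg.positions[a]]
                if frame.forces is not None:
                    cols += [_fmt(x) for x in frame.forces[a]]
                if has_region:
                    cols.append(str(cfg.region[a]))
                fh.write(" ".join(cols) + "\n")


def split_dataset(dataset: Dataset, ratio: tuple[int, int] = (19, 1),
                  seed: int = 0) -> tuple[Dataset, Dataset]:
    """Deterministic shuffled split; sizes ⌊n·a/(a+b)⌋ and the remainder."""
    a, b = int(ratio[0]), int(ratio[1])
    if a <= 0 or b <= 0:
        raise ValidationError("split ratio components must be positive")
    n = len(dataset)
    if n < 2:
        raise ValidationError("need at least 2 frames to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_first = (n * a) // (a + b)
    first = [dataset.frames[i] for i in perm[:n_first]]
    second = [dataset.frames[i] for i in perm[n_first:]]
    return (Dataset(first, provenance=dataset.provenance + "/train"),
            Dataset(second, provenance=dataset.provenance + "/test"))
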