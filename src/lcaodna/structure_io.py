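"""Molecular structures: types, XYZ/PDB input-output, bond detection, and
geometric construction of stacked B-DNA dimers.

Coordinates are Cartesian Å.  Only the four elements of the all-valence
parameterization (C, N, O, H) are accepted.  Atom indexing is 0-based
everywhere in the API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # biotite handles the fixed-column PDB dialect
    import biotite.structure as _bst
    from biotite.structure.io.pdb import PDBFile as _PDBFile
except ImportError:  # pragma: no cover - biotite is a hard dependency
    _bst = None

from .constants import COVALENT_RADII, MIN_DISTANCE, SUPPORTED_ELEMENTS


class ElementError(ValueError):
    """An element outside the supported C/N/O/H set."""


class ParseError(ValueError):
    """A malformed structure record."""


class GeometryError(ValueError):
    """Physically impossible geometry (clashing or overlapping atoms)."""


@dataclass(frozen=True)
class Atom:
    """A single atom: chemical symbol plus Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise ElementError(
                f"unsupported element {self.element!r}; supported: "
                f"{', '.join(SUPPORTED_ELEMENTS)}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position}")
        object.__setattr__(self, "position", pos)


@dataclass
class Molecule:
    """An ordered collection of atoms with an optional bond list.

    ``bonds`` stores each unordered pair (i, j) once with i < j, 0-based.
    ``meta`` carries per-atom PDB metadata (names, residues, chains) when the
    molecule came from a PDB file, so bases can be pruned from oligomers.
    """

    name: str
    atoms: list
    bonds: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            pair = (min(i, j), max(i, j))
            if pair in seen:
                raise ValueError(f"bond {pair} listed twice")
            seen.add(pair)
            norm.append(pair)
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of positions in Å (a copy)."""
        return np.array([a.position for a in self.atoms])

    @property
    def formula(self) -> str:
        """Hill-order molecular formula, e.g. ``C5H5N5``."""
        counts = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        parts = []
        for el in ("C", "H", "N", "O"):
            if el in counts:
                parts.append(el + (str(counts[el]) if counts[el] > 1 else ""))
        return "".join(parts)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Molecule":
        """Copy of this molecule with replaced coordinates (bonds kept)."""
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [Atom(a.element, c) for a, c in zip(self.atoms, coords)]
        return Molecule(name or self.name, atoms, list(self.bonds), dict(self.meta))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Apply the rigid motion r → R r + t."""
        return self.with_coords(self.coords @ np.asarray(rotation, float).T
                                + np.asarray(translation, float))


@dataclass
class BasePair:
    """Two H-bonded bases; base2's atom indices follow base1's in the pair."""

    base1: Molecule
    base2: Molecule
    name: str = ""

    @property
    def n_atoms(self) -> int:
        return self.base1.n_atoms + self.base2.n_atoms

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([self.base1.coords, self.base2.coords])

    @property
    def elements(self) -> list:
        return self.base1.elements + self.base2.elements

    def transformed(self, rotation, translation) -> "BasePair":
        return BasePair(self.base1.transformed(rotation, translation),
                        self.base2.transformed(rotation, translation), self.name)


@dataclass
class Dimer:
    """Two stacked base pairs, labeled by the step name (e.g. ``"GG"``)."""

    pair1: BasePair
    pair2: BasePair
    label: str = ""

    def __post_init__(self):
        for frag in (self.pair1.base1, self.pair1.base2,
                     self.pair2.base1, self.pair2.base2):
            if frag.n_atoms == 0:  # pragma: no cover - Molecule enforces this
                raise ValueError("empty fragment in dimer")


# ---------------------------------------------------------------------------
# XYZ

def _parse_xyz(text: str, name: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ file (line 1)")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}")
    atoms = []
    for ln, line in enumerate(lines[2:2 + count], start=3):
        tokens = line.split()
        if len(tokens) < 4:
            raise ParseError(f"line {ln}: expected 'element x y z', got {line!r}")
        element = tokens[0].capitalize()
        try:
            xyz = [float(t) for t in tokens[1:4]]
        except ValueError:
            raise ParseError(f"line {ln}: non-numeric coordinate in {line!r}")
        atoms.append(Atom(element, xyz))
    if len(atoms) != count:
        raise ParseError(f"XYZ header promises {count} atoms, found {len(atoms)}")
    comment = lines[1].strip() if len(lines) > 1 else ""
    return Molecule(name or comment or "molecule", atoms)


def _format_xyz(mol: Molecule, comment: str | None = None) -> str:
    out = [str(mol.n_atoms), comment if comment is not None else mol.name]
    for a in mol.atoms:
        x, y, z = a.position
        out.append(f"{a.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDB

def _parse_pdb(path, name: str) -> Molecule:
    pdb = _PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    atoms = []
    names, res_names, res_ids, chains = [], [], [], []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize()
        if not element:
            element = "".join(c for c in str(arr.atom_name[i]) if c.isalpha())[:1]
        atoms.append(Atom(element, np.asarray(arr.coord[i], float)))
        names.append(str(arr.atom_name[i]))
        res_names.append(str(arr.res_name[i]))
        res_ids.append(int(arr.res_id[i]))
        chains.append(str(arr.chain_id[i]))
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    meta = {"atom_names": names, "res_names": res_names,
            "res_ids": res_ids, "chain_ids": chains}
    return Molecule(name, atoms, meta=meta)


def _write_pdb(path, fragments, res_names, chain_ids) -> None:
    """Write fragments as successive residues (HETATM records via biotite)."""
    total = sum(m.n_atoms for m in fragments)
    arr = _bst.AtomArray(total)
    k = 0
    for rid, (mol, res, chain) in enumerate(zip(fragments, res_names, chain_ids), 1):
        counters = {}
        for a in mol.atoms:
            counters[a.element] = counters.get(a.element, 0) + 1
            arr.coord[k] = a.position
            arr.element[k] = a.element
            arr.atom_name[k] = f"{a.element}{counters[a.element]}"
            arr.res_name[k] = res
            arr.res_id[k] = rid
            arr.chain_id[k] = chain
            arr.hetero[k] = True
            k += 1
    pdb = _PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Public I/O

def load_structure(path, fmt: str | None = None, name: str | None = None) -> Molecule:
    """Read a molecule from an XYZ or PDB file.

    Parameters
    ----------
    path:
        File path.
    fmt:
        ``"xyz"`` or ``"pdb"``; inferred from the suffix when omitted.
    name:
        Optional molecule label; defaults to the file stem.

    Bonds are left empty — call :func:`detect_bonds` afterwards.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    label = name or path.stem
    if fmt == "xyz":
        return _parse_xyz(path.read_text(), label)
    if fmt == "pdb":
        return _parse_pdb(path, label)
    raise ValueError(f"unsupported format {fmt!r}; use 'xyz' or 'pdb'")


def loads_xyz(text: str, name: str = "molecule") -> Molecule:
    """Parse XYZ text directly."""
    return _parse_xyz(text, name)


def save_structure(obj, path, fmt: str | None = None) -> None:
    """Write a Molecule, BasePair, or Dimer to XYZ or PDB.

    In PDB output each base becomes its own residue; a dimer's two pairs go
    to residues 1–2 (chain A base1, chain B base2) and 3–4.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        mol = as_molecule(obj)
        path.write_text(_format_xyz(mol))
        return
    if fmt != "pdb":
        raise ValueError(f"unsupported format {fmt!r}")
    if isinstance(obj, Molecule):
        _write_pdb(path, [obj], [obj.name[:3].upper() or "MOL"], ["A"])
    elif isinstance(obj, BasePair):
        _write_pdb(path, [obj.base1, obj.base2],
                   [obj.base1.name[:3].upper(), obj.base2.name[:3].upper()],
                   ["A", "B"])
    elif isinstance(obj, Dimer):
        frags = [obj.pair1.base1, obj.pair1.base2, obj.pair2.base1, obj.pair2.base2]
        _write_pdb(path, frags, [m.name[:3].upper() for m in frags],
                   ["A", "B", "A", "B"])
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def split_residues(mol: Molecule) -> list:
    """Split a PDB-derived molecule into per-residue fragments, in order of
    first appearance.  Each fragment keeps its own metadata slice."""
    meta = mol.meta
    if "res_ids" not in meta:
        return [mol]
    keys = list(zip(meta["chain_ids"], meta["res_ids"]))
    order = []
    groups = {}
    for idx, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(idx)
    fragments = []
    for key in order:
        idxs = groups[key]
        sub_meta = {field: [meta[field][i] for i in idxs]
                    for field in ("atom_names", "res_names", "res_ids", "chain_ids")}
        res_name = sub_meta["res_names"][0]
        fragments.append(Molecule(f"{res_name}_{key[0]}{key[1]}",
                                  [mol.atoms[i] for i in idxs], meta=sub_meta))
    return fragments


def as_base_pair(mol: Molecule, name: str = "") -> BasePair:
    """Interpret a two-residue structure as a base pair."""
    frags = split_residues(mol)
    if len(frags) != 2:
        raise ParseError(f"expected 2 residues for a base pair, got {len(frags)}")
    return BasePair(frags[0], frags[1], name or mol.name)


def as_dimer(mol: Molecule, label: str = "") -> Dimer:
    """Interpret a four-residue structure as a stacked dimer (residues in
    file order: pair1 base1, pair1 base2, pair2 base1, pair2 base2)."""
    frags = split_residues(mol)
    if len(frags) != 4:
        raise ParseError(f"expected 4 residues for a dimer, got {len(frags)}")
    return Dimer(BasePair(frags[0], frags[1]), BasePair(frags[2], frags[3]),
                 label or mol.name)


def as_molecule(obj) -> Molecule:
    """Flatten a Molecule/BasePair/Dimer into a single Molecule (bonds dropped
    for composite objects)."""
    if isinstance(obj, Molecule):
        return obj
    if isinstance(obj, BasePair):
        atoms = obj.base1.atoms + obj.base2.atoms
        return Molecule(obj.name or "pair", list(atoms))
    if isinstance(obj, Dimer):
        atoms = (obj.pair1.base1.atoms + obj.pair1.base2.atoms
                 + obj.pair2.base1.atoms + obj.pair2.base2.atoms)
        return Molecule(obj.label or "dimer", list(atoms))
    raise TypeError(f"cannot flatten {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Bond detection

def detect_bonds(mol: Molecule, scale: float = 1.15) -> Molecule:
    """Return a copy of ``mol`` with bonds assigned by the covalent-radius
    criterion: i–j bonded iff |ri − rj| ≤ scale · (rcov_i + rcov_j).

    Raises :class:`GeometryError` if any two atoms are closer than 0.4 Å.
    """
    coords = mol.coords
    n = mol.n_atoms
    radii = np.array([COVALENT_RADII[e] for e in mol.elements])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    clash = dist[iu] < MIN_DISTANCE
    if np.any(clash):
        i = iu[0][clash][0]
        j = iu[1][clash][0]
        raise GeometryError(
            f"atoms {i} and {j} are {dist[i, j]:.3f} Å apart (< {MIN_DISTANCE} Å)")
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = (dist <= cutoff)
    bonds = [(int(i), int(j)) for i, j in zip(*iu) if bonded[i, j]]
    return Molecule(mol.name, list(mol.atoms), bonds, dict(mol.meta))


# ---------------------------------------------------------------------------
# Ideal stacking

def rotation_about_z(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about +z."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_ideal_dimer(pair1: BasePair, pair2: BasePair,
                      rise: float = 3.4, twist: float = 36.0,
                      label: str = "") -> Dimer:
    """Stack two base pairs into an ideal B-DNA step.

    Both pairs must be expressed in the standard base-pair reference frame
    (mid-frame at the origin, helix axis = +z along the 5'→3' direction of
    strand I).  ``pair2`` is rotated by ``twist`` degrees about +z and then
    translated by ``rise`` Å along +z; ``pair1`` is left untouched.
    """
    moved = pair2.transformed(rotation_about_z(twist), np.array([0.0, 0.0, rise]))
    return Dimer(pair1, moved, label or f"{pair1.name}/{pair2.name}")
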