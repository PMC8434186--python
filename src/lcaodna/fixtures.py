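"""Packaged reference geometries: nucleobases, Watson–Crick pairs, ideal
B-DNA dimers, and the heterocycle benchmark set.

Nucleobase heavy atoms follow the standard nucleic-acid base reference frame
convention: each base is planar (z = 0), expressed in the coordinate frame
whose origin sits at the pair center, with x̂ toward the major groove, ŷ
along the pairing axis toward the reference strand, and ẑ along the helix
axis (5'→3' of the reference strand).  A Watson–Crick pair is assembled by
placing the complementary base at (x, −y, −z) of its own standard
coordinates; this reproduces ideal hydrogen-bond geometry by construction.
Hydrogens, absent from the standard tables, are built geometrically
(trigonal ring/amino positions, tetrahedral methyl).

The remaining heterocycles of the benchmark set are MMFF94-optimized
geometries stored as XYZ text under ``lcaodna/data``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .structure_io import (Atom, BasePair, Dimer, Molecule, build_ideal_dimer,
                           detect_bonds, load_structure, rotation_about_z,
                           save_structure)

# bond lengths for constructed hydrogens (Å)
_CH_AROMATIC = 1.082
_CH_METHYL = 1.092
_NH = 1.009

#: Standard-frame heavy-atom coordinates (Å, z = 0 unless listed).
#: Atom order fixes the 0-based indexing of the packaged fixtures.
STD_HEAVY = {
    "adenine": [
        ("N9", -1.291, 4.498), ("C8", 0.024, 4.897), ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771), ("C6", 0.369, 1.398), ("N6", 1.611, 0.909),
        ("N1", -0.668, 0.532), ("C2", -1.912, 1.023), ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ],
    "guanine": [
        ("N9", -1.289, 4.551), ("C8", 0.023, 4.962), ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833), ("C6", 0.424, 1.460), ("O6", 1.554, 0.955),
        ("N1", -0.700, 0.641), ("C2", -1.999, 1.087), ("N2", -2.949, 0.139),
        ("N3", -2.342, 2.364), ("C4", -1.265, 3.177),
    ],
    "thymine": [
        ("N1", -1.284, 4.500), ("C2", -1.462, 3.135), ("O2", -2.562, 2.608),
        ("N3", -0.298, 2.407), ("C4", 0.994, 2.897), ("O4", 1.944, 2.119),
        ("C5", 1.106, 4.338), ("C7", 2.466, 4.961), ("C6", -0.024, 5.057),
    ],
    "cytosine": [
        ("N1", -1.285, 4.542), ("C2", -1.472, 3.158), ("O2", -2.628, 2.709),
        ("N3", -0.391, 2.344), ("C4", 0.837, 2.868), ("N4", 1.875, 2.027),
        ("C5", 1.056, 4.275), ("C6", -0.023, 5.068),
    ],
    "uracil": [
        ("N1", -1.284, 4.500), ("C2", -1.462, 3.131), ("O2", -2.563, 2.608),
        ("N3", -0.302, 2.397), ("C4", 0.989, 2.884), ("O4", 1.935, 2.094),
        ("C5", 1.089, 4.311), ("C6", -0.024, 5.053),
    ],
}

#: Hydrogen construction rules: (parent, kind, neighbors...).
#: kind "ring": one in-plane H on the external bisector of two neighbors;
#: kind "amino": two in-plane H completing the trigonal amine;
#: kind "methyl": three tetrahedral H, one in the base plane.
_H_RULES = {
    "adenine": [("C8", "ring", "N9", "N7"), ("C2", "ring", "N1", "N3"),
                ("N9", "ring", "C8", "C4"), ("N6", "amino", "C6")],
    "guanine": [("C8", "ring", "N9", "N7"), ("N1", "ring", "C6", "C2"),
                ("N9", "ring", "C8", "C4"), ("N2", "amino", "C2")],
    "thymine": [("N1", "ring", "C2", "C6"), ("N3", "ring", "C2", "C4"),
                ("C6", "ring", "N1", "C5"), ("C7", "methyl", "C5")],
    "cytosine": [("N1", "ring", "C2", "C6"), ("C5", "ring", "C4", "C6"),
                 ("C6", "ring", "N1", "C5"), ("N4", "amino", "C4")],
    "uracil": [("N1", "ring", "C2", "C6"), ("N3", "ring", "C2", "C4"),
               ("C5", "ring", "C4", "C6"), ("C6", "ring", "N1", "C5")],
}

#: Watson–Crick complements, reference strand → partner.
WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

BASE_NAMES = {"A": "adenine", "T": "thymine", "G": "guanine",
              "C": "cytosine", "U": "uracil"}
BASE_LETTER = {v: k for k, v in BASE_NAMES.items()}

#: Heterocycles of the benchmark set shipped as MMFF94 XYZ files.
HETEROCYCLES = (
    "purine_9h", "purine_7h", "aminopurine_2", "pyrazine", "pyrimidine",
    "pyridazine", "pyrazine_14_dioxide", "imidazole_1h", "pyrazole_1h",
    "benzimidazole_1h", "indazole_1h", "indazole_2h", "azaindole_7",
)


def _h_positions(name: str, heavy: dict) -> list:
    """Construct hydrogen positions for a standard base."""
    out = []
    normal = np.array([0.0, 0.0, 1.0])
    for rule in _H_RULES[name]:
        parent, kind = rule[0], rule[1]
        p = heavy[parent]
        length = _NH if parent.startswith("N") else (
            _CH_METHYL if kind == "methyl" else _CH_AROMATIC)
        if kind == "ring":
            u1 = _unit(heavy[rule[2]] - p)
            u2 = _unit(heavy[rule[3]] - p)
            out.append((f"H{parent[1:]}", p + length * _unit(-(u1 + u2))))
        elif kind == "amino":
            v = _unit(p - heavy[rule[2]])  # along the C→N bond
            perp = np.cross(normal, v)
            for sign, tag in ((+1, "1"), (-1, "2")):
                d = _unit(np.cos(np.deg2rad(60)) * v
                          + sign * np.sin(np.deg2rad(60)) * perp)
                out.append((f"H{parent[1:]}{tag}", p + length * d))
        elif kind == "methyl":
            v = _unit(p - heavy[rule[2]])  # along C(ring)→C(methyl)
            perp = _unit(np.cross(normal, v))
            cos_t, sin_t = 1.0 / 3.0, np.sqrt(8.0) / 3.0
            for k, phi in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3), 1):
                d = (cos_t * v + sin_t * (np.cos(phi) * perp
                                          + np.sin(phi) * normal))
                out.append((f"H{parent[1:]}{k}", p + length * d))
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def nucleobase(which: str, with_bonds: bool = True) -> Molecule:
    """Return a nucleobase in its standard base frame.

    ``which`` is a one-letter code (A, T, G, C, U) or a full lowercase name.
    """
    name = BASE_NAMES.get(which.upper(), which.lower())
    if name not in STD_HEAVY:
        raise KeyError(f"unknown base {which!r}")
    heavy = {lbl: np.array([x, y, 0.0]) for lbl, x, y in STD_HEAVY[name]}
    atoms = [Atom(lbl[0], pos) for lbl, pos in heavy.items()]
    labels = [lbl for lbl, *_ in STD_HEAVY[name]]
    for lbl, pos in _h_positions(name, heavy):
        atoms.append(Atom("H", pos))
        labels.append(lbl)
    mol = Molecule(name, atoms, meta={"atom_labels": labels})
    return detect_bonds(mol) if with_bonds else mol


#: Canonical B-DNA propeller twist (degrees) in this package's intra-pair
#: convention (positive here; the crystallographic surveys that define the
#: consensus magnitude ~11.4° use a y-axis of opposite sense, hence report
#: it negative).  Coplanar Watson–Crick pairs are an idealization real
#: B-DNA never adopts; the canonical propeller is part of the close-to-ideal
#: reference geometry, and stacking overlaps depend on it strongly.
CANONICAL_PROPELLER = 11.4


def watson_crick_pair(letter: str,
                      propeller: float = CANONICAL_PROPELLER) -> BasePair:
    """Watson–Crick pair X·Xcompl with X on the reference strand.

    The pair is expressed in its standard base-pair frame: mid-frame origin
    at (0, 0, 0), helix axis along +z.  The complementary base is the
    standard geometry mapped through (x, −y, −z).  ``propeller`` (degrees,
    package sign convention; 0 gives a strictly coplanar pair) is applied as
    a ±propeller/2 counter-rotation of the two bases about the pair y-axis.
    """
    letter = letter.upper()
    if letter not in WC_COMPLEMENT:
        raise KeyError(f"no Watson–Crick complement for {letter!r}")
    base1 = nucleobase(letter)
    base2 = nucleobase(WC_COMPLEMENT[letter])
    flipped = base2.coords * np.array([1.0, -1.0, -1.0])
    base2 = base2.with_coords(flipped)
    if propeller:
        half = np.deg2rad(propeller / 2.0)
        rot_plus = _roty(half)
        rot_minus = _roty(-half)
        base1 = base1.with_coords(base1.coords @ rot_plus.T)
        base2 = base2.with_coords(base2.coords @ rot_minus.T)
    return BasePair(base1, base2, name=f"{letter}-{WC_COMPLEMENT[letter]}")


def _roty(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def ideal_step_dimer(step: str, rise: float = 3.4, twist: float = 36.0,
                     propeller: float = CANONICAL_PROPELLER) -> Dimer:
    """Close-to-ideal B-DNA dimer for a dinucleotide step, e.g. ``"GG"``.

    ``step`` names the two reference-strand bases 5'→3'; the second pair is
    rotated by ``twist`` about +z and raised by ``rise`` along +z.  Pairs
    carry the canonical propeller twist unless overridden.
    """
    step = step.upper()
    if len(step) != 2 or any(s not in WC_COMPLEMENT for s in step):
        raise ValueError(f"step must be two of A/T/G/C, got {step!r}")
    return build_ideal_dimer(watson_crick_pair(step[0], propeller),
                             watson_crick_pair(step[1], propeller),
                             rise=rise, twist=twist, label=step)


def ideal_stack(sequence: str, rise: float = 3.4, twist: float = 36.0,
                propeller: float = CANONICAL_PROPELLER) -> list:
    """Ideal B-DNA stack of Watson–Crick pairs for a reference-strand
    sequence (5'→3'): pair k is rotated by k·twist about +z and raised by
    k·rise along +z."""
    pairs = []
    for k, letter in enumerate(sequence.upper()):
        pair = watson_crick_pair(letter, propeller)
        R = rotation_about_z(k * twist)
        pairs.append(pair.transformed(R, np.array([0.0, 0.0, k * rise])))
    return pairs


def _data_dir():
    return resources.files("lcaodna") / "data"


def heterocycle(name: str) -> Molecule:
    """Load a packaged heterocycle geometry (MMFF94, XYZ) with bonds."""
    if name in BASE_NAMES or name in STD_HEAVY:
        return nucleobase(name)
    path = _data_dir() / f"{name}.xyz"
    if not path.is_file():
        raise KeyError(f"no packaged geometry for {name!r}")
    return detect_bonds(load_structure(path, fmt="xyz", name=name))


def packaged_molecules() -> list:
    """Names of every packaged single-molecule geometry."""
    return [*STD_HEAVY, *HETEROCYCLES]


def write_fixture_files(out_dir) -> list:
    """Write all packaged geometries to ``out_dir`` (bases and pairs as PDB,
    heterocycles as XYZ, the four unique-step ideal dimers as PDB).

    Returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in STD_HEAVY:
        path = out / f"{name}.pdb"
        save_structure(nucleobase(name), path)
        written.append(path)
    for letter in ("A", "G"):
        pair = watson_crick_pair(letter)
        path = out / f"pair_{pair.name.replace('-', '')}.pdb"
        save_structure(pair, path)
        written.append(path)
    for step in ("GG", "TC", "AA", "AT"):
        path = out / f"dimer_{step}.pdb"
        save_structure(ideal_step_dimer(step), path)
        written.append(path)
    for name in HETEROCYCLES:
        src = _data_dir() / f"{name}.xyz"
        path = out / f"{name}.xyz"
        path.write_text(src.read_text())
        written.append(path)
    return written
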