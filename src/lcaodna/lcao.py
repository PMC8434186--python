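"""All-valence LCAO Hamiltonian: assembly, diagonalization, orbital
character, and oscillator strengths.

The molecular wave function is expanded in 2s, 2px, 2py, 2pz orbitals on C,
N, O and the 1s orbital on H, with an orthonormal basis (overlap = identity).
Diagonal elements are fixed per-orbital on-site energies; off-diagonal
blocks between bonded atoms are Slater–Koster two-center couplings with
Harrison 1/d² magnitudes.  Between the two bases of a Watson–Crick pair
(hydrogen-bond range and beyond) the 1/d² law is replaced by an exponential
decay anchored at a reference covalent distance d0.

The ionization energy is approximated by −E(HOMO) and the excitation energy
by the HOMO–LUMO gap; orbital character (π/σ/n) is assigned by projecting p
coefficients on the local base-plane normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_A, HARTREE_EV, MIN_DISTANCE, ORBITALS, VALENCE_ELECTRONS
from .params import LcaoParameters
from .structure_io import BasePair, GeometryError, Molecule

_P_AXES = {"px": 0, "py": 1, "pz": 2}

#: Energy window (eV) inside which two frontier levels count as degenerate.
DEGENERACY_TOL = 1e-6


class UnsupportedSystemError(ValueError):
    """Open-shell (odd-electron) systems are outside the model."""


@dataclass(frozen=True)
class OrbitalBasis:
    """Ordered valence basis: one (atom index, orbital label) per entry,
    grouped by atom in atom order."""

    entries: tuple

    @classmethod
    def for_elements(cls, elements) -> "OrbitalBasis":
        entries = []
        for idx, el in enumerate(elements):
            for orb in ORBITALS[el]:
                entries.append((idx, orb))
        return cls(tuple(entries))

    @property
    def size(self) -> int:
        return len(self.entries)

    def atom_slices(self, n_atoms: int) -> list:
        """Per-atom slices into the basis, in atom order."""
        starts = {}
        counts = {}
        for pos, (idx, _) in enumerate(self.entries):
            starts.setdefault(idx, pos)
            counts[idx] = counts.get(idx, 0) + 1
        return [slice(starts[i], starts[i] + counts[i]) for i in range(n_atoms)]


@dataclass
class Spectrum:
    """Result of diagonalizing an LCAO Hamiltonian.

    ``coefficients[:, k]`` is the k-th molecular orbital in the basis order
    of ``basis``.  ``characters``/``pi_weights`` are filled by
    :func:`classify_character`.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    basis: OrbitalBasis
    n_electrons: int
    homo_index: int
    lumo_index: int
    characters: list | None = None
    pi_weights: np.ndarray | None = None
    degenerate_frontier: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def homo_energy(self) -> float:
        return float(self.energies[self.homo_index])

    @property
    def lumo_energy(self) -> float:
        return float(self.energies[self.lumo_index])

    @property
    def ionization_energy(self) -> float:
        """−E(HOMO), the model's vertical ionization energy."""
        return -self.homo_energy

    @property
    def excitation_energy(self) -> float:
        """E(LUMO) − E(HOMO), the model's first excitation energy."""
        return self.lumo_energy - self.homo_energy

    def frontier(self, selector) -> int:
        """Resolve an MO selector: "HOMO", "LUMO", "HOMO-1", "LUMO+2", or an
        integer index."""
        if isinstance(selector, (int, np.integer)):
            idx = int(selector)
            if not 0 <= idx < len(self.energies):
                raise IndexError(f"MO index {idx} out of range")
            return idx
        sel = str(selector).upper().replace(" ", "")
        for anchor, base in (("HOMO", self.homo_index), ("LUMO", self.lumo_index)):
            if sel.startswith(anchor):
                offset = int(sel[len(anchor):]) if sel != anchor else 0
                idx = base + offset
                if not 0 <= idx < len(self.energies):
                    raise IndexError(f"{selector} out of range")
                return idx
        raise ValueError(f"cannot resolve MO selector {selector!r}")


# ---------------------------------------------------------------------------
# Two-center couplings

def _channel_strengths(d: float, params: LcaoParameters, regime: str) -> dict:
    if regime == "harrison":
        pref = params.hbar2_over_m / d**2
    elif regime == "exponential":
        pref = (params.hbar2_over_m / params.d0**2
                * np.exp(-params.beta * (d - params.d0)))
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return {key: params.chi[key] * pref for key in params.chi}


def slater_koster_block(atom_i, atom_j, params: LcaoParameters,
                        regime: str = "harrison") -> np.ndarray:
    """Slater–Koster coupling block ⟨i-orbitals|H|j-orbitals⟩ (eV).

    Rows run over atom i's orbitals, columns over atom j's, in s, px, py, pz
    order.  Direction cosines are those of the vector from i to j; the s–p
    cross terms carry opposite signs for ⟨s_i|H|p_j⟩ and ⟨p_i|H|s_j⟩.  Every
    H 1s orbital taking part multiplies the element by the damping factor b.
    """
    delta = np.asarray(atom_j.position, float) - np.asarray(atom_i.position, float)
    d = float(np.linalg.norm(delta))
    if d <= MIN_DISTANCE:
        raise GeometryError(f"atoms {d:.3f} Å apart (≤ {MIN_DISTANCE} Å)")
    u = delta / d
    v = _channel_strengths(d, params, regime)
    orbs_i = ORBITALS[atom_i.element]
    orbs_j = ORBITALS[atom_j.element]
    block = np.empty((len(orbs_i), len(orbs_j)))
    for a, oi in enumerate(orbs_i):
        for b_, oj in enumerate(orbs_j):
            if oi == "s" and oj == "s":
                val = v["ss_sigma"]
            elif oi == "s":
                val = u[_P_AXES[oj]] * v["sp_sigma"]
            elif oj == "s":
                val = -u[_P_AXES[oi]] * v["sp_sigma"]
            else:
                ua, ub = u[_P_AXES[oi]], u[_P_AXES[oj]]
                val = ua * ub * (v["pp_sigma"] - v["pp_pi"])
                if oi == oj:
                    val += v["pp_pi"]
            block[a, b_] = val
    if atom_i.element == "H":
        block *= params.b
    if atom_j.element == "H":
        block *= params.b
    return block


# ---------------------------------------------------------------------------
# Hamiltonians

def _onsite_diagonal(elements, basis: OrbitalBasis, params: LcaoParameters):
    diag = np.empty(basis.size)
    for pos, (idx, orb) in enumerate(basis.entries):
        shell = "s" if orb == "s" else "p"
        diag[pos] = params.onsite[(elements[idx], shell)]
    return diag


def build_hamiltonian(mol: Molecule, params: LcaoParameters | None = None):
    """Assemble the intra-molecular LCAO Hamiltonian.

    Returns ``(H, basis)`` with H real symmetric (eV).  Couplings appear only
    between bonded atoms (Harrison 1/d² regime); everything else is zero.
    """
    params = params or LcaoParameters()
    if mol.n_atoms > 1 and not mol.bonds:
        warnings.warn(f"molecule {mol.name!r} has no bonds; "
                      "Hamiltonian will be diagonal (isolated atoms)")
    basis = OrbitalBasis.for_elements(mol.elements)
    H = np.diag(_onsite_diagonal(mol.elements, basis, params))
    slices = basis.atom_slices(mol.n_atoms)
    for i, j in mol.bonds:
        block = slater_koster_block(mol.atoms[i], mol.atoms[j], params, "harrison")
        H[slices[i], slices[j]] = block
        H[slices[j], slices[i]] = block.T
    return H, basis


def build_pair_hamiltonian(pair: BasePair, params: LcaoParameters | None = None,
                           cross_cutoff: float = 10.0):
    """Assemble the Hamiltonian of an H-bonded base pair.

    Intra-base blocks are identical to :func:`build_hamiltonian`; every
    cross-base atom pair within ``cross_cutoff`` Å is coupled with the
    exponential distance law (valid beyond covalent range).
    """
    params = params or LcaoParameters()
    b1 = pair.base1 if pair.base1.bonds else _auto_bonds(pair.base1)
    b2 = pair.base2 if pair.base2.bonds else _auto_bonds(pair.base2)
    H1, basis1 = build_hamiltonian(b1, params)
    H2, basis2 = build_hamiltonian(b2, params)
    n1 = basis1.size
    elements = b1.elements + b2.elements
    basis = OrbitalBasis.for_elements(elements)
    H = np.zeros((basis.size, basis.size))
    H[:n1, :n1] = H1
    H[n1:, n1:] = H2
    slices = basis.atom_slices(len(elements))
    for i, atom_i in enumerate(b1.atoms):
        for j, atom_j in enumerate(b2.atoms):
            d = np.linalg.norm(atom_j.position - atom_i.position)
            if d <= cross_cutoff:
                block = slater_koster_block(atom_i, atom_j, params, "exponential")
                H[slices[i], slices[b1.n_atoms + j]] = block
                H[slices[b1.n_atoms + j], slices[i]] = block.T
    return H, basis


def _auto_bonds(mol: Molecule) -> Molecule:
    from .structure_io import detect_bonds
    return detect_bonds(mol)


# ---------------------------------------------------------------------------
# Diagonalization and electron filling

def count_valence_electrons(elements) -> int:
    return sum(VALENCE_ELECTRONS[el] for el in elements)


def solve(H: np.ndarray, basis: OrbitalBasis, system) -> Spectrum:
    """Diagonalize ``H`` and fill electrons pairwise.

    ``system`` is the Molecule or BasePair the Hamiltonian was built from
    (used for the electron count and downstream geometry queries).
    """
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hamiltonian must be symmetric")
    energies, coeff = np.linalg.eigh(H)
    n_el = count_valence_electrons(system.elements)
    if n_el % 2:
        raise UnsupportedSystemError(
            f"{getattr(system, 'name', '?')} has {n_el} valence electrons; "
            "only closed shells are supported")
    homo = n_el // 2 - 1
    lumo = homo + 1
    degenerate = bool(
        (homo > 0 and abs(energies[homo] - energies[homo - 1]) < DEGENERACY_TOL)
        or (lumo + 1 < len(energies)
            and abs(energies[lumo + 1] - energies[lumo]) < DEGENERACY_TOL)
        or abs(energies[lumo] - energies[homo]) < DEGENERACY_TOL)
    return Spectrum(energies=energies, coefficients=coeff, basis=basis,
                    n_electrons=n_el, homo_index=homo, lumo_index=lumo,
                    degenerate_frontier=degenerate,
                    meta={"system": system})


def solve_molecule(mol: Molecule, params: LcaoParameters | None = None,
                   classify: bool = True) -> Spectrum:
    """Convenience: bonds → Hamiltonian → spectrum (→ characters)."""
    params = params or LcaoParameters()
    work = mol if mol.bonds else _auto_bonds(mol)
    H, basis = build_hamiltonian(work, params)
    spec = solve(H, basis, work)
    if classify:
        classify_character(spec, work)
    return spec


def solve_pair(pair: BasePair, params: LcaoParameters | None = None,
               classify: bool = True, cross_cutoff: float = 10.0) -> Spectrum:
    """Convenience: pair Hamiltonian → spectrum (→ characters)."""
    params = params or LcaoParameters()
    H, basis = build_pair_hamiltonian(pair, params, cross_cutoff)
    spec = solve(H, basis, pair)
    if classify:
        classify_character(spec, pair)
    return spec


# ---------------------------------------------------------------------------
# Orbital character

def _plane_normal(coords: np.ndarray):
    """Least-squares plane normal of heavy-atom coordinates, or None if the
    points are (near-)collinear."""
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered)
    if len(svals) < 2 or svals[1] < 1e-6:
        return None
    return vt[2]


def classify_character(spec: Spectrum, system) -> list:
    """Label every MO π, σ, n, or mixed; stores labels and π-weights on
    ``spec`` and returns the labels.

    The π-weight of an MO is the squared norm of its p coefficients
    projected on the local base normal (per base, for a pair).  π-weight
    > 0.5 ⇒ π.  Occupied σ orbitals whose weight on N/O lone-pair-type
    components (2s and in-plane 2p on N/O) exceeds 0.5 are labeled n.
    """
    if isinstance(system, BasePair):
        fragments = [(system.base1, 0),
                     (system.base2, system.base1.n_atoms)]
    else:
        fragments = [(system, 0)]
    n_basis = spec.basis.size
    atom_normal = {}
    for frag, offset in fragments:
        heavy = np.array([a.position for a in frag.atoms if a.element != "H"])
        normal = _plane_normal(heavy) if len(heavy) >= 3 else None
        for local_idx in range(frag.n_atoms):
            atom_normal[offset + local_idx] = normal
    if any(v is None for v in atom_normal.values()):
        spec.characters = ["mixed"] * n_basis
        spec.pi_weights = np.full(n_basis, np.nan)
        return spec.characters

    elements = {}
    for frag, offset in fragments:
        for local_idx, atom in enumerate(frag.atoms):
            elements[offset + local_idx] = atom.element

    # gather p-coefficient vectors per atom
    entry_atom = np.array([idx for idx, _ in spec.basis.entries])
    labels = []
    pi_weights = np.zeros(n_basis)
    n_atoms = max(entry_atom) + 1
    slices = spec.basis.atom_slices(n_atoms)
    for k in range(n_basis):
        c = spec.coefficients[:, k]
        pi_w = 0.0
        lone_w = 0.0
        for idx in range(n_atoms):
            sl = slices[idx]
            comp = c[sl]
            if elements[idx] == "H":
                continue
            normal = atom_normal[idx]
            p_vec = comp[1:4]
            p_out = float(np.dot(p_vec, normal))
            pi_w += p_out**2
            if elements[idx] in ("N", "O"):
                lone_w += comp[0]**2 + float(np.dot(p_vec, p_vec)) - p_out**2
        pi_weights[k] = pi_w
        if pi_w > 0.5:
            labels.append("pi")
        elif k <= spec.homo_index and lone_w > 0.5:
            labels.append("n")
        else:
            labels.append("sigma")
    spec.characters = labels
    spec.pi_weights = pi_weights
    return labels


def frontier_by_character(spec: Spectrum, character: str = "pi",
                          occupied: bool = True) -> int:
    """Index of the frontier MO of a given character: the highest occupied
    (or lowest unoccupied) MO labeled ``character``.

    Requires :func:`classify_character` to have run.
    """
    if spec.characters is None:
        raise ValueError("run classify_character first")
    if occupied:
        rng = range(spec.homo_index, -1, -1)
    else:
        rng = range(spec.lumo_index, len(spec.energies))
    for k in rng:
        if spec.characters[k] == character:
            return k
    raise LookupError(f"no {'occupied' if occupied else 'unoccupied'} "
                      f"{character} orbital found")


# ---------------------------------------------------------------------------
# Oscillator strength

def oscillator_strength(spec: Spectrum, system, from_mo="HOMO", to_mo="LUMO"):
    """Transition dipole (point approximation) and oscillator strength.

    The dipole keeps only same-atom, same-orbital coefficient products:
    d = −e Σ c_to* r_atom c_from (e·Å).  The oscillator strength is
    f = (2/3) (E/Ha) (|d| / e·bohr)² with E the transition energy.

    Returns ``(f, dipole_vector)``.
    """
    k_from = spec.frontier(from_mo)
    k_to = spec.frontier(to_mo)
    if k_from == k_to:
        raise ValueError("zero transition: from_mo and to_mo are the same MO")
    if isinstance(system, BasePair):
        positions = system.coords
    else:
        positions = system.coords
    c_from = spec.coefficients[:, k_from]
    c_to = spec.coefficients[:, k_to]
    entry_atom = np.array([idx for idx, _ in spec.basis.entries])
    weights = c_to * c_from  # same-entry products only
    dipole = -(weights[:, None] * positions[entry_atom]).sum(axis=0)
    energy = abs(spec.energies[k_to] - spec.energies[k_from])
    f = (2.0 / 3.0) * (energy / HARTREE_EV) * (np.dot(dipole, dipole) / BOHR_A**2)
    return float(f), dipole
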