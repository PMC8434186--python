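"""Inter-base-pair transfer integrals and maximum transfer percentage.

The transfer integral between two stacked base pairs (monomers) is the
matrix element of the stack Hamiltonian between one monomer's frontier MO
and the other's:

    t = Σ c₁* V c₂,

where V collects the exponential-regime Slater–Koster couplings between the
atoms of the two monomers and c₁, c₂ are the frontier-MO coefficient vectors
of the separately solved monomers.  Together with the on-site energy
difference Δ of the two frontier levels it fixes the maximum transfer
percentage

    p = (2t)² / ((2t)² + Δ²),

the peak probability of finding a carrier on the monomer where it did not
start during coherent two-level oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lcao import (OrbitalBasis, Spectrum, frontier_by_character,
                   slater_koster_block, solve_pair)
from .params import LcaoParameters
from .structure_io import BasePair, Dimer, GeometryError

#: Monomers closer than this (any cross-atom distance, Å) overlap unphysically.
MIN_STACK_DISTANCE = 1.5

#: Frontier window (eV): σ levels within this of the frontier π level get
#: their own report rows.
SIGMA_WINDOW = 0.5


class UndefinedTransferError(ValueError):
    """p is undefined when both t and Δ vanish."""


@dataclass(frozen=True)
class TransferResult:
    """Transfer integral t (eV, signed), on-site difference Δ = E₁ − E₂ (eV),
    maximum transfer percentage p, and the MO selectors used."""

    t: float
    delta: float
    p: float
    orbital: tuple

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p = {self.p} outside [0, 1]")


def max_transfer_percentage(t: float, delta: float) -> float:
    """p = (2t)² / ((2t)² + Δ²); undefined at t = Δ = 0."""
    four_t2 = (2.0 * t) ** 2
    if four_t2 == 0.0 and delta == 0.0:
        raise UndefinedTransferError("p undefined for t = Δ = 0")
    return four_t2 / (four_t2 + delta**2)


def _fix_phase(c: np.ndarray) -> np.ndarray:
    """Deterministic MO phase: largest-magnitude coefficient positive."""
    k = int(np.argmax(np.abs(c)))
    return c if c[k] >= 0 else -c


def _cross_coupling_matrix(pair1: BasePair, pair2: BasePair,
                           params: LcaoParameters,
                           cutoff: float = 10.0) -> np.ndarray:
    """Exponential-regime coupling matrix between all orbitals of pair1 and
    all orbitals of pair2."""
    atoms1 = pair1.base1.atoms + pair1.base2.atoms
    atoms2 = pair2.base1.atoms + pair2.base2.atoms
    basis1 = OrbitalBasis.for_elements([a.element for a in atoms1])
    basis2 = OrbitalBasis.for_elements([a.element for a in atoms2])
    sl1 = basis1.atom_slices(len(atoms1))
    sl2 = basis2.atom_slices(len(atoms2))
    V = np.zeros((basis1.size, basis2.size))
    min_d = np.inf
    for i, ai in enumerate(atoms1):
        for j, aj in enumerate(atoms2):
            d = float(np.linalg.norm(aj.position - ai.position))
            min_d = min(min_d, d)
            if d <= cutoff:
                V[sl1[i], sl2[j]] = slater_koster_block(ai, aj, params,
                                                        "exponential")
    if min_d < MIN_STACK_DISTANCE:
        raise GeometryError(
            f"monomers overlap: closest cross-distance {min_d:.2f} Å "
            f"< {MIN_STACK_DISTANCE} Å")
    return V


def transfer_integral(dimer: Dimer, params: LcaoParameters | None = None,
                      orbital_1="HOMO", orbital_2="HOMO",
                      spectra: tuple | None = None) -> TransferResult:
    """Transfer integral between frontier MOs of a stacked dimer's monomers.

    Each monomer (base pair) is solved independently; ``spectra`` may pass
    pre-solved ``(Spectrum, Spectrum)`` to avoid recomputation.  Δ follows
    the convention monomer1 − monomer2 in the 5'→3' step order.
    """
    params = params or LcaoParameters()
    if spectra is None:
        spec1 = solve_pair(dimer.pair1, params)
        spec2 = solve_pair(dimer.pair2, params)
    else:
        spec1, spec2 = spectra
    k1 = spec1.frontier(orbital_1)
    k2 = spec2.frontier(orbital_2)
    V = _cross_coupling_matrix(dimer.pair1, dimer.pair2, params)
    c1 = _fix_phase(spec1.coefficients[:, k1])
    c2 = _fix_phase(spec2.coefficients[:, k2])
    t = float(c1 @ V @ c2)
    delta = float(spec1.energies[k1] - spec2.energies[k2])
    try:
        p = max_transfer_percentage(t, delta)
    except UndefinedTransferError:
        p = 0.0
    return TransferResult(t=t, delta=delta, p=p, orbital=(orbital_1, orbital_2))


def _channel_selectors(spec: Spectrum):
    """Frontier MO indices per carrier channel for one monomer.

    Returns {"hole": [...], "electron": [...]}: the frontier π MO always,
    plus any σ MO within SIGMA_WINDOW of it (split π/σ* frontier regions).
    """
    channels = {}
    for occupied, key in ((True, "hole"), (False, "electron")):
        anchor = spec.homo_index if occupied else spec.lumo_index
        try:
            k_pi = frontier_by_character(spec, "pi", occupied=occupied)
        except LookupError:
            k_pi = anchor
        selected = [k_pi]
        e_pi = spec.energies[k_pi]
        rng = (range(spec.homo_index, -1, -1) if occupied
               else range(spec.lumo_index, len(spec.energies)))
        for k in rng:
            if k == k_pi or spec.characters[k] == "pi":
                continue
            if abs(spec.energies[k] - e_pi) <= SIGMA_WINDOW:
                selected.append(k)
        channels[key] = selected
    return channels


def dimer_report(dimer: Dimer, params: LcaoParameters | None = None) -> pd.DataFrame:
    """Transfer table for one dimer: hole (HOMO↔HOMO) and electron
    (LUMO↔LUMO) channels, plus separate rows for near-frontier σ levels.

    Columns: channel, mo1, mo2, character, E1_eV, E2_eV, t_meV, abs_t_meV,
    delta_meV, p.
    """
    params = params or LcaoParameters()
    spec1 = solve_pair(dimer.pair1, params)
    spec2 = solve_pair(dimer.pair2, params)
    ch1 = _channel_selectors(spec1)
    ch2 = _channel_selectors(spec2)
    rows = []
    for channel in ("hole", "electron"):
        for k1 in ch1[channel]:
            for k2 in ch2[channel]:
                char = (spec1.characters[k1], spec2.characters[k2])
                if char[0] != char[1]:
                    continue  # report like-with-like channels
                res = transfer_integral(dimer, params, k1, k2,
                                        spectra=(spec1, spec2))
                rows.append({
                    "channel": channel,
                    "mo1": k1 - (spec1.homo_index if channel == "hole"
                                 else spec1.lumo_index),
                    "mo2": k2 - (spec2.homo_index if channel == "hole"
                                 else spec2.lumo_index),
                    "character": char[0],
                    "E1_eV": round(float(spec1.energies[k1]), 4),
                    "E2_eV": round(float(spec2.energies[k2]), 4),
                    "t_meV": round(res.t * 1e3, 1),
                    "abs_t_meV": round(abs(res.t) * 1e3, 1),
                    "delta_meV": round(res.delta * 1e3, 1),
                    "p": round(res.p, 4),
                })
    return pd.DataFrame(rows)
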