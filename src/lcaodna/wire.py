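"""Tight-binding wire model of a B-DNA stack.

Each site is one base pair (monomer); the Hamiltonian is the nearest-
neighbor chain

    H = Σ_α E_α |α⟩⟨α| + Σ_α t_{α,α+1} (|α⟩⟨α+1| + |α+1⟩⟨α|),

with E_α the monomer's HOMO (hole) or LUMO (electron) energy and t the
inter-monomer transfer integral.  Coherent carrier dynamics follows the
time-dependent Schrödinger equation iħ dA/dt = H A, solved spectrally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HBAR_EV_FS
from .params import LcaoParameters
from .structure_io import BasePair, Dimer, GeometryError
from .transfer import transfer_integral
from .lcao import solve_pair

#: Consecutive monomers further apart than this (centroid distance, Å) are
#: not a stacked wire.
MAX_STACK_GAP = 6.0


class NormalizationError(ValueError):
    """Initial wire state does not have unit norm."""


@dataclass(frozen=True)
class WireModel:
    """On-site energies E_α (eV, length N) and nearest-neighbor hops
    t_{α,α+1} (eV, length N−1)."""

    onsite: np.ndarray
    hops: np.ndarray

    def __post_init__(self):
        onsite = np.atleast_1d(np.asarray(self.onsite, float))
        hops = np.atleast_1d(np.asarray(self.hops, float)) if np.size(self.hops) \
            else np.empty(0)
        if len(hops) != max(len(onsite) - 1, 0):
            raise ValueError(
                f"need {len(onsite) - 1} hops for {len(onsite)} sites, "
                f"got {len(hops)}")
        if not (np.all(np.isfinite(onsite)) and np.all(np.isfinite(hops))):
            raise ValueError("wire parameters must be finite")
        object.__setattr__(self, "onsite", onsite)
        object.__setattr__(self, "hops", hops)

    @property
    def n_sites(self) -> int:
        return len(self.onsite)

    def hamiltonian(self) -> np.ndarray:
        H = np.diag(self.onsite)
        idx = np.arange(self.n_sites - 1)
        H[idx, idx + 1] = self.hops
        H[idx + 1, idx] = self.hops
        return H


@dataclass(frozen=True)
class WireState:
    """Site amplitudes A_α at a given time (fs); Σ|A_α|² = 1."""

    amplitudes: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, complex)
        if abs(np.sum(np.abs(amp) ** 2) - 1.0) > 1e-9:
            raise NormalizationError("wire state must have unit norm")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def occupations(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


def site_state(n_sites: int, site: int) -> WireState:
    """Carrier fully localized on one monomer at t = 0."""
    amp = np.zeros(n_sites, complex)
    amp[site] = 1.0
    return WireState(amp, 0.0)


def wire_eigenstates(model: WireModel):
    """Eigenenergies (ascending, eV) and occupation matrix.

    Returns ``(energies, occupations)`` with ``occupations[j, k] = |v_jk|²``,
    the weight of eigenstate k on monomer j; each column sums to 1.
    """
    energies, vectors = np.linalg.eigh(model.hamiltonian())
    return energies, np.abs(vectors) ** 2


def propagate(model: WireModel, initial: WireState, times) -> list:
    """Evolve the wire state to each requested time (fs), spectrally:
    A(t) = Σ_k ⟨v_k|A(0)⟩ exp(−i E_k t/ħ) v_k."""
    if not isinstance(initial, WireState):
        initial = WireState(np.asarray(initial, complex))
    energies, vectors = np.linalg.eigh(model.hamiltonian())
    weights = vectors.T @ initial.amplitudes
    out = []
    for t in np.atleast_1d(times):
        phases = np.exp(-1j * energies * (float(t) - initial.time) / HBAR_EV_FS)
        out.append(WireState(vectors @ (weights * phases), float(t)))
    return out


def max_offsite_occupation(model: WireModel, start: int = 0, other: int = 1,
                           n_times: int = 4001) -> float:
    """Peak occupation of site ``other`` when the carrier starts on ``start``,
    sampled densely over several oscillation periods."""
    H = model.hamiltonian()
    scale = max(np.max(np.abs(model.hops)), 1e-6)
    period = np.pi * HBAR_EV_FS / scale
    times = np.linspace(0.0, 4 * period, n_times)
    states = propagate(model, site_state(model.n_sites, start), times)
    return max(s.occupations[other] for s in states)


def build_wire_from_dimers(pairs, params: LcaoParameters | None = None,
                           orbital: str = "HOMO") -> WireModel:
    """Wire-model parameters for a stack of base pairs.

    ``pairs`` is a sequence of :class:`BasePair` in 5'→3' order; each is
    solved independently for its frontier energies, and hops come from the
    transfer integral between consecutive pairs.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty monomer sequence")
    params = params or LcaoParameters()
    spectra = [solve_pair(p, params) for p in pairs]
    onsite = [s.energies[s.frontier(orbital)] for s in spectra]
    hops = []
    for a in range(len(pairs) - 1):
        c1 = pairs[a].coords.mean(axis=0)
        c2 = pairs[a + 1].coords.mean(axis=0)
        gap = float(np.linalg.norm(c2 - c1))
        if gap >= MAX_STACK_GAP:
            raise GeometryError(
                f"monomers {a} and {a + 1} are {gap:.1f} Å apart "
                f"(≥ {MAX_STACK_GAP} Å): not a stacked wire")
        res = transfer_integral(Dimer(pairs[a], pairs[a + 1]), params,
                                orbital, orbital,
                                spectra=(spectra[a], spectra[a + 1]))
        hops.append(res.t)
    return WireModel(np.array(onsite), np.array(hops))
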