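"""Base reference frames and intra-base-pair parameters.

Each base of a Watson–Crick pair carries a right-handed orthonormal frame
fitted to its six-membered ring.  The six intra-pair parameters — shear,
stretch, stagger (translations, Å) and buckle, propeller twist, opening
(rotations, degrees) — describe the relative placement of the two bases via
the mid-frame convention: the translation vector is expressed in the average
of the two frames, and the relative rotation is decomposed as a rotation
vector whose x, y, z components in the mid-frame are buckle, propeller and
opening respectively.

Sign conventions (fixed here, asserted by the test suite):

==========  =======================================================
parameter   positive sense
==========  =======================================================
shear       base2 origin displaced along +x of the mid-frame
stretch     base2 origin displaced along +y of the mid-frame
stagger     base2 origin displaced along +z of the mid-frame
buckle      base2 frame rotated right-handedly about mid-frame +x
propeller   base2 frame rotated right-handedly about mid-frame +y
opening     base2 frame rotated right-handedly about mid-frame +z
==========  =======================================================

Under exchange of the two bases (fitted-frame path), stagger and opening
change sign while shear, stretch, buckle and propeller are preserved: the
ŷ-toward-partner rule rotates the swapped reference frame by 180° about ẑ,
which cancels the sign flips the exchange alone would otherwise produce on
shear and buckle.  This symmetry table is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Molecule, detect_bonds

#: 180° rotation about x: maps the complementary-strand base frame into the
#: orientation of the reference strand (y and z flipped, x kept).
STRAND_FLIP = np.diag([1.0, -1.0, -1.0])


class FrameError(ValueError):
    """Raised when a base frame cannot be fitted (degenerate geometry)."""


@dataclass(frozen=True)
class BasePairParams:
    """The six intra-base-pair parameters."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def __post_init__(self):
        values = (self.shear, self.stretch, self.stagger,
                  self.buckle, self.propeller, self.opening)
        if not all(np.isfinite(values)):
            raise ValueError("base-pair parameters must be finite")
        for angle in (self.buckle, self.propeller, self.opening):
            if not -180.0 < angle <= 180.0:
                raise ValueError(f"angle {angle} outside (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger,
                         self.buckle, self.propeller, self.opening])


def six_membered_ring(mol: Molecule) -> list:
    """Indices of the six-membered ring used for frame fitting.

    For fused bicyclics (purines) this is the pyrimidine-like six-ring.  Among
    several six-rings the one with the most nitrogens (ties: lowest indices)
    is chosen, deterministically.
    """
    work = mol if mol.bonds else detect_bonds(mol)
    graph = nx.Graph(work.bonds)
    rings = [sorted(c) for c in nx.minimum_cycle_basis(graph) if len(c) == 6]
    if not rings:
        raise FrameError(f"no six-membered ring found in {mol.name!r}")
    rings.sort(key=lambda r: (-sum(mol.atoms[i].element == "N" for i in r), r))
    return rings[0]


def fit_base_frame(mol: Molecule, toward: np.ndarray | None = None):
    """Least-squares frame of a base: (rotation matrix with columns x̂ ŷ ẑ,
    origin).

    The origin is the six-ring centroid and ẑ the least-squares ring normal.
    When ``toward`` (a point, Å) is given, ŷ is the in-plane unit vector from
    the origin toward it — for a Watson–Crick pair, pass the partner base's
    ring centroid so ŷ points along the pairing direction.  Otherwise ŷ is
    the in-plane direction toward the first ring atom.  x̂ = ŷ × ẑ completes
    a right-handed triad; the sign of ẑ follows the ring's traversal order
    (counterclockwise seen from +ẑ).
    """
    ring = six_membered_ring(mol)
    coords = mol.coords[ring]
    origin = coords.mean(axis=0)
    centered = coords - origin
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-6:
        raise FrameError(f"ring atoms of {mol.name!r} are collinear")
    normal = vt[2]
    # orient the normal by the ring traversal (cycle order, not sorted order)
    graph = nx.Graph((mol if mol.bonds else detect_bonds(mol)).bonds)
    cycle = _ring_cycle(graph, ring)
    sense = np.zeros(3)
    pts = mol.coords[cycle] - origin
    for k in range(6):
        sense += np.cross(pts[k], pts[(k + 1) % 6])
    if np.dot(sense, normal) < 0:
        normal = -normal
    if toward is None:
        y_raw = centered[0]
    else:
        y_raw = np.asarray(toward, float) - origin
    y = y_raw - np.dot(y_raw, normal) * normal
    ny = np.linalg.norm(y)
    if ny < 1e-8:
        raise FrameError("in-plane reference direction degenerate")
    y /= ny
    x = np.cross(y, normal)
    return np.column_stack([x, y, normal]), origin


def _ring_cycle(graph: nx.Graph, ring: list) -> list:
    """Order ring atom indices along the cycle, starting at the smallest
    index and moving toward its smaller-index ring neighbor."""
    members = set(ring)
    start = min(ring)
    neighbors = sorted(n for n in graph.neighbors(start) if n in members)
    cycle = [start, neighbors[0]]
    while len(cycle) < 6:
        nxt = [n for n in graph.neighbors(cycle[-1])
               if n in members and n != cycle[-2]]
        if not nxt:
            raise FrameError("six-ring is not a simple cycle")
        cycle.append(min(nxt))
    return cycle


def pair_reference_frames(base1: Molecule, base2: Molecule):
    """Fit the standardized frames of a Watson–Crick pair.

    base1 keeps its fitted frame; base2's fitted frame (anti-parallel ẑ by
    construction, ŷ toward base1) is flipped by 180° about its x̂ so both
    frames nearly coincide for an ideal pair.  Returns ((R1, o1), (R2f, o2)).
    """
    ring1 = six_membered_ring(base1)
    ring2 = six_membered_ring(base2)
    c1 = base1.coords[ring1].mean(axis=0)
    c2 = base2.coords[ring2].mean(axis=0)
    R1, o1 = fit_base_frame(base1, toward=c2)
    R2, o2 = fit_base_frame(base2, toward=c1)
    if np.dot(R2[:, 2], R1[:, 2]) > 0:
        # traversal-order sign put ẑ₂ parallel to ẑ₁; rebuild with ẑ flipped
        R2 = np.column_stack([np.cross(R2[:, 1], -R2[:, 2]), R2[:, 1], -R2[:, 2]])
    return (R1, o1), (R2 @ STRAND_FLIP, o2)


def mid_frame(R1: np.ndarray, R2: np.ndarray,
              o1: np.ndarray, o2: np.ndarray):
    """Geodesic mean of two frames (quaternion mean) and midpoint origin."""
    rot = Rotation.from_matrix(np.stack([R1, R2])).mean()
    return rot.as_matrix(), 0.5 * (np.asarray(o1) + np.asarray(o2))


def base_pair_parameters(base1: Molecule, base2: Molecule,
                         ref_frames=None) -> BasePairParams:
    """Compute the six intra-base-pair parameters.

    Parameters
    ----------
    base1, base2:
        The two bases (base1 on the reference strand).
    ref_frames:
        Optional ``((R1, origin1), (R2, origin2))`` with rotation-matrix
        columns x̂ ŷ ẑ.  Both frames must already be in the standardized
        (same-handed) orientation — identical frames mean a perfectly
        aligned pair.  When omitted, frames are fitted from the ring atoms
        and base2's frame is flipped into the reference orientation.
    """
    if ref_frames is None:
        (R1, o1), (R2, o2) = pair_reference_frames(base1, base2)
    else:
        (R1, o1), (R2, o2) = ref_frames
        R1, R2 = np.asarray(R1, float), np.asarray(R2, float)
        o1, o2 = np.asarray(o1, float), np.asarray(o2, float)
        for R in (R1, R2):
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
                raise FrameError("supplied frame is not orthonormal")
            if np.linalg.det(R) < 0:
                raise FrameError("supplied frame is left-handed")
    Rm, _ = mid_frame(R1, R2, o1, o2)
    shear, stretch, stagger = Rm.T @ (o2 - o1)
    rotvec_lab = Rotation.from_matrix(R2 @ R1.T).as_rotvec(degrees=True)
    buckle, propeller, opening = Rm.T @ rotvec_lab
    return BasePairParams(shear, stretch, stagger, buckle, propeller, opening)
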