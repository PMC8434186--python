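# Methods

## Electronic-structure model

The Hamiltonian is an orthogonal-basis (extended-Hückel-like) tight-binding
model over all valence orbitals: H 1s and C/N/O 2s, 2p.  Overlap is taken
as the identity exactly — no Löwdin orthogonalization — so eigenvectors are
orthonormal in the coefficient sense and the completeness sum
Σ<sub>k</sub>|c<sub>iν,k</sub>|² = 1 holds per basis entry.

Diagonal elements are per-shell constants (see README) fitted, in the
original parameterization, to experimental ionization and excitation
energies of the five nucleobases; they are not re-optimized here.
Off-diagonal blocks exist only between *bonded* atoms within a molecule and
follow the Slater–Koster angular decomposition for s/p orbitals with the
sign convention ⟨s<sub>i</sub>|H|p<sub>j</sub>⟩ = +ξ V<sub>spσ</sub>,
⟨p<sub>i</sub>|H|s<sub>j</sub>⟩ = −ξ V<sub>spσ</sub> (ξ the direction
cosine of the i→j unit vector).  The damping factor b = 0.70 multiplies a
matrix element once per participating H 1s orbital, i.e. b² for H–H.

Two distance laws set the coupling magnitude:

* **Harrison, 1/d²** — used at covalent distances (bonded atoms):
  V<sub>χ</sub> = χ ħ²/(m d²), ħ²/m = 7.6199682 eV·Å².
* **Exponential** — used beyond covalent range: hydrogen bonds inside a
  Watson–Crick pair and all couplings between stacked monomers:
  V<sub>χ</sub> = χ ħ²/(m d₀²) exp(−β(d − d₀)), d₀ = 1.35 Å.

The decay rate β is a configurable parameter because the defining exponent
can be read either as 2/d₀ (Å⁻¹) or as a bare 2 Å⁻¹.  Both are
implemented; the default is β = 2/d₀ ≈ 1.4815 Å⁻¹, fixed once by a
calibration against the published guanine-tract hole couplings (the bare-2
reading gives stacking couplings roughly a factor four too small — e.g.
31 meV instead of ~116 meV for the GG step — and was rejected).  The same β
governs hydrogen-bond and stacking couplings alike; H-orbital damping b is
applied uniformly in both regimes.

Cross-fragment couplings are evaluated for every atom pair within 10 Å.
At that distance the exponential factor is below 1e−5 of its d₀ value, so
the cutoff is numerically invisible; it only bounds the work.

### Electron filling and observables

Valence electrons (H 1, C 4, N 5, O 6) are filled pairwise; only
closed-shell systems are supported (odd counts raise).  HOMO is orbital
n/2−1 (0-based), LUMO the next one; degeneracies within 1e−6 eV at the
frontier set a flag rather than changing index assignment.  The vertical
ionization energy is approximated as −E(HOMO) and the excitation energy as
the orbital-energy gap; both are one-electron estimates with no
self-consistency or relaxation, which is the main systematic limitation of
the model.

Orbital character: per base, a least-squares plane is fitted to the heavy
atoms and each MO's p coefficients are projected on the plane normal.
π-weight > 0.5 labels the MO π; occupied non-π MOs dominated (> 0.5 weight)
by N/O 2s and in-plane 2p components are labeled n (lone-pair-like), the
rest σ.  Weights are stored so users can re-threshold.  Benchmarks use the
π channel (highest occupied π, lowest unoccupied π) because that is what
the gas-phase π photoemission and π→π* absorption bands measure; for
pyridazine (n-type HOMO) and the azoles (σ* LUMO) this differs from the
plain frontier gap.

Oscillator strengths use the point-dipole approximation: only same-atom,
same-orbital coefficient products contribute, d = −e Σ c<sub>L</sub>
r<sub>ν</sub> c<sub>H</sub>, and f = ⅔ (E/Ha)(|d|/e·a₀)² with
1 Ha = 27.211386 eV, a₀ = 0.529177 Å.

## Geometries

The published parameterization comes without atomic coordinates, so
computed observables are geometry-sensitive; the packaged geometries are
therefore defined explicitly:

* **Nucleobases** — heavy atoms at the standard nucleic-acid base
  reference-frame coordinates (the consensus crystallographic geometry used
  by base-pair analysis tools), hydrogens constructed geometrically:
  in-plane trigonal ring/amino H (N–H 1.009 Å, aromatic C–H 1.082 Å) and a
  tetrahedral methyl on thymine (C–H 1.092 Å, one H in plane).
* **Watson–Crick pairs** — the complementary base placed at (x, −y, −z) of
  its own standard coordinates, which is exactly the standard frame's
  pairing construction and yields donor–acceptor distances of 2.87–3.05 Å
  with no optimization.
* **Propeller twist** — strictly coplanar pairs are an idealization real
  B-DNA never adopts, and stacking couplings depend on propeller strongly:
  for coplanar pairs the purine–purine coupling of the AG step cancels
  almost exactly (~0.1 meV), which is qualitatively wrong.  Pairs therefore
  carry the canonical B-DNA propeller twist of 11.4° (package sign
  convention; crystallographic surveys quote the same magnitude with
  negative sign because their y-axis runs the other way), applied as a
  ±5.7° counter-rotation of the two rigid bases about the pair y-axis.
  `propeller=0` recovers the coplanar limit.  Pair frontier energies are
  insensitive to this choice (< 2 meV); stacking couplings are not.
* **Ideal steps** — successive pairs related by a 36° right-handed twist
  about the global z axis through the mid-frame origin plus a 3.4 Å rise.
  The helix-axis position is a convention (the reference frame origin);
  sensitivity to a ±1.5 Å axis offset was characterized (tens of percent on
  stacking couplings) and the origin-axis convention retained.
* **Benchmark heterocycles** — MMFF94-optimized geometries generated once
  (scripts/make_geometries.py, fixed seed) and stored as XYZ text.  These
  are force-field geometries, not experimental ones; for the five
  nucleobases, where both were available, the two agree to ~0.015 Å in mean
  interatomic distances.

Bond detection uses the covalent-radius criterion
|r<sub>i</sub>−r<sub>j</sub>| ≤ 1.15 (r<sub>cov,i</sub>+r<sub>cov,j</sub>)
with Cordero radii (H 0.31, C 0.76, N 0.71, O 0.66 Å); this reproduces the
ring connectivity of every packaged molecule.  Distances under 0.4 Å are
rejected as clashes.

## Base-pair frames and intra-pair parameters

Each base's frame is fitted to its six-membered ring (for purines, the
diazine ring, selected as the six-cycle richest in nitrogen): origin at the
ring centroid, ẑ the least-squares normal oriented by ring traversal, ŷ
the in-plane direction toward the partner base, x̂ = ŷ × ẑ.  The partner
base's frame is flipped 180° about x̂ into the reference orientation.
Shear/stretch/stagger are the components of the origin displacement in the
mean (mid) frame; buckle/propeller/opening are the x/y/z mid-frame
components of the relative rotation vector.  This mid-frame decomposition
is origin-symmetric, and because ŷ always points toward the partner, base
exchange negates stagger and opening while preserving shear, stretch,
buckle and propeller (asserted in the tests).  The convention is documented
as this package's own; it is deliberately close to, but not claimed
identical with, the web-service conventions used in the charge-transfer
literature (whose exact frame-fitting atom sets are unpublished).

Because the fitted ŷ tracks the pairing direction, the *stretch* value for
a fitted pair is the inter-centroid distance (~5.6 Å), not a deviation from
rest; for deformation studies only changes in the parameters are
meaningful.

## Transfer integrals and wire model

Monomers (base pairs) are solved independently; the transfer integral is
t = c₁ᵀ V c₂ with V the exponential-regime Slater–Koster matrix over all
inter-monomer atom pairs within 10 Å.  MO phases after diagonalization are
arbitrary, so the API fixes the phase (largest-magnitude coefficient
positive) and reports the signed t, while tables show |t| in meV.  Δ is
monomer 1 minus monomer 2 in 5'→3' step order.  Dimer reports include
separate rows for σ levels within 0.5 eV of the frontier π level (split
π*/σ* electron channels occur for G·C-containing steps).

The wire model is strictly nearest-neighbor.  Coherent dynamics is
propagated spectrally, A(t) = Σ ⟨v<sub>k</sub>|A(0)⟩ e^{−iE_k t/ħ}
v<sub>k</sub> with ħ = 0.6582119569 eV·fs, which conserves norm and energy
to machine precision by construction; an independent fixed-step RK4
integration agrees to 1e−6 over 100 fs in the tests.  The two-site peak
off-site occupation equals (2t)²/((2t)²+Δ²) analytically at
t* = πħ/√((2t)²+Δ²), which the tests exploit for exact comparison.
Transport (transmission/current) is out of scope; the module stops at
eigenspectra and coherent transfer.

## What the fixtures do and do not show

The packaged geometries are static, idealized, gas-phase structures: no
solvent, counterions, backbone, thermal motion, or charge relaxation.
Tests passing on them show that the implementation realizes the model
faithfully and reproduces the published benchmark numbers under documented
geometric conventions — not that the model is accurate for solvated,
dynamical DNA.  MD-derived PDB snapshots can be analyzed through the same
pipeline, inheriting all the model's approximations.

## Numerical choices

* Symmetric eigensolver (LAPACK `eigh`); eigenvalues ascending; no
  degeneracy re-ordering.
* Frontier degeneracy tolerance 1e−6 eV (flag only).
* Geometry clash threshold 0.4 Å; stacked monomers must keep all
  cross-distances above 1.5 Å.
* Wire construction requires consecutive monomer centroids within 6 Å.
* Character threshold 0.5 on π-weight; collinear fragments label every MO
  `mixed` rather than guessing.
* Problem sizes throughout are small (≤ ~180 basis functions for a dimer
  monomer pair), so every published-value check runs in well under a second.
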