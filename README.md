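# lcaodna

Semi-empirical, all-valence LCAO electronic structure for nucleic-acid bases
and related heterocycles, and the tight-binding parameters it implies for
charge transfer along B-DNA.

The package is aimed at people modelling DNA-mediated charge transfer —
molecular electronics, oxidative damage, or dynamics on MD-derived
structures — who need frontier-orbital energies and inter-base-pair
couplings in milliseconds rather than hours, with an explicit, inspectable
model.

## The model

The molecular wave function is expanded in every valence orbital:
2s, 2p<sub>x</sub>, 2p<sub>y</sub>, 2p<sub>z</sub> on C, N, O and 1s on H,
with an orthonormal basis (overlap ≈ identity).  The Hamiltonian has

* fixed **on-site energies** per orbital shell
  (E<sub>H(1s)</sub> = −13.64, E<sub>C(2s)</sub> = −13.18,
  E<sub>C(2p)</sub> = −6.70, E<sub>N(2s)</sub> = −14.51,
  E<sub>N(2p)</sub> = −9.55, E<sub>O(2s)</sub> = −15.03,
  E<sub>O(2p)</sub> = −11.52 eV);
* **Slater–Koster two-center couplings** between bonded atoms, with
  Harrison-type magnitudes V<sub>χ</sub> = χ ħ²/(m d²) and channel constants
  χ<sub>ssσ</sub> = −1.32, χ<sub>spσ</sub> = −1.42, χ<sub>ppσ</sub> = 2.22,
  χ<sub>ppπ</sub> = −0.73; each participating H 1s orbital damps the element
  by b = 0.70;
* beyond covalent range (hydrogen bonds, base-pair stacking) the distance
  law switches to V<sub>χ</sub> = χ ħ²/(m d₀²) exp(−β(d − d₀)) with
  d₀ = 1.35 Å and β = 2/d₀.

Diagonalization and pairwise electron filling give the spectrum; −E(HOMO)
approximates the vertical ionization energy, the HOMO–LUMO gap the first
excitation energy.  π/σ/n character comes from projecting p coefficients on
the base-plane normal, and transition oscillator strengths from the
point-dipole approximation f = ⅔ (E/Ha) (|d|/e·a₀)².

For stacked base pairs the package computes the transfer integral
t = ⟨λ|H|λ′⟩ between monomer frontier orbitals, the on-site energy
difference Δ, and the maximum transfer percentage
p = (2t)² / ((2t)² + Δ²) — the ingredients of a nearest-neighbor
tight-binding wire model H = Σ E<sub>α</sub>|α⟩⟨α| + Σ t<sub>α,α+1</sub>
(|α⟩⟨α+1| + h.c.) whose coherent dynamics the `wire` module propagates.

Packaged geometries: the five nucleobases in the standard base reference
frame, Watson–Crick A·T / G·C pairs assembled by the standard frame's
pairing rule (with the canonical B-DNA propeller twist), ideal stacked
dimers (3.4 Å rise, 36° twist), and an MMFF94-optimized benchmark set of
thirteen further heterocycles.  MD-derived structures can be supplied as
multi-residue PDB files.

## Worked example

Nucleobase benchmark against experimental gas-phase data:

```
$ lcao benchmark --subset nucleobases
molecule   I_calc  E_calc  f_calc  I_exp  E_exp  I_cc  E_cc
adenine      8.45    4.24   0.337   8.44   4.84  8.23  5.04
guanine      8.30    4.21   0.259   8.24   4.51  7.83  4.85
thymine      9.14    4.84   0.311   9.14   4.69  9.03  5.17
cytosine     8.72    4.60   0.323   8.94   4.64  8.67  4.64
uracil       8.97    4.77   0.284   9.50   4.79  9.44  5.27
# RMSPE ionization vs experiment: 2.75%
# RMSPE excitation vs experiment: 6.47%
```

`I_calc`/`E_calc` are the computed π ionization energy (−E of the highest
occupied π orbital) and π→π* excitation energy in eV, `f_calc` the
oscillator strength; the `exp` and `cc` columns are experimental and
coupled-cluster reference values from the packaged table.  Over the full
18-molecule set (`--subset all`) the ionization RMSPE is 3.25% and the
excitation RMSPE 7.02%.

Hole coupling across an ideal guanine tract step:

```
$ lcao transfer --ideal GG --orbitals homo
channel  mo1  mo2  character  E1_eV    E2_eV    t_meV   abs_t_meV  delta_meV  p
hole     0    0    pi         -8.2975  -8.2975  -119.7  119.7      -0.0       1.0
```

The two G·C monomers are identical, so Δ = 0 and the carrier oscillates
completely between them (p = 1) with a coupling of ≈120 meV.  For the mixed
TC step (`--ideal TC`) the monomer HOMOs differ by 149 meV, the coupling is
175 meV, and p drops to 0.85.

The same quantities are available from Python:

```python
from lcaodna import fixtures, solve_pair
from lcaodna.transfer import transfer_integral

res = transfer_integral(fixtures.ideal_step_dimer("GG"))
print(res.t, res.delta, res.p)   # -0.1197 eV, 0.0 eV, 1.0
```

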