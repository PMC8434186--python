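import numpy as np
import pytest

from lcaodna import LcaoParameters, fixtures
from lcaodna.constants import HBAR2_OVER_M
from lcaodna.lcao import (OrbitalBasis, UnsupportedSystemError,
                          build_hamiltonian, build_pair_hamiltonian,
                          classify_character, oscillator_strength,
                          slater_koster_block, solve, solve_molecule,
                          solve_pair, Spectrum)
from lcaodna.structure_io import Atom, BasePair, GeometryError, Molecule

from conftest import random_rigid_motion


def _hh(d, params):
    return slater_koster_block(Atom("H", [0, 0, 0]), Atom("H", [d, 0, 0]),
                               params, "harrison")


class TestSlaterKosterBlock:
    def test_hh_harrison_value(self, params):
        # b applied once per H orbital: b^2 * chi_ss * hbar^2/(m d^2)
        expected = 0.70**2 * (-1.32) * HBAR2_OVER_M / 1.35**2
        assert _hh(1.35, params)[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-2.70, abs=0.005)

    def test_px_py_coupling_vanishes_along_z(self, params):
        block = slater_koster_block(Atom("C", [0, 0, 0]), Atom("C", [0, 0, 1.4]),
                                    params, "harrison")
        # px (row 1) - py (col 2): both direction cosines are zero
        assert block[1, 2] == 0.0

    def test_pz_pz_sigma_vs_pi_limits(self, params):
        pref = HBAR2_OVER_M / 1.4**2
        along_z = slater_koster_block(Atom("C", [0, 0, 0]),
                                      Atom("C", [0, 0, 1.4]), params, "harrison")
        along_x = slater_koster_block(Atom("C", [0, 0, 0]),
                                      Atom("C", [1.4, 0, 0]), params, "harrison")
        assert along_z[3, 3] == pytest.approx(params.chi["pp_sigma"] * pref)
        assert along_x[3, 3] == pytest.approx(params.chi["pp_pi"] * pref)

    def test_sp_sign_antisymmetry(self, params):
        block = slater_koster_block(Atom("C", [0, 0, 0]), Atom("N", [1.3, 0, 0]),
                                    params, "harrison")
        # <s_i|H|px_j> and <px_i|H|s_j> carry opposite signs
        assert block[0, 1] == pytest.approx(-block[1, 0])

    def test_harrison_inverse_square_scaling(self, params):
        lam = 1.7
        b1 = _hh(1.0, params)[0, 0]
        b2 = _hh(lam, params)[0, 0]
        assert b2 == pytest.approx(b1 / lam**2, rel=1e-14)

    def test_exponential_regime_envelope(self, params):
        # V(d) = V(d0) * exp(-beta (d - d0)) exactly
        d_values = np.linspace(1.35, 8.0, 20)
        vals = np.array([slater_koster_block(
            Atom("C", [0, 0, 0]), Atom("C", [d, 0, 0]),
            params, "exponential")[0, 0] for d in d_values])
        v0 = params.chi["ss_sigma"] * HBAR2_OVER_M / params.d0**2
        np.testing.assert_allclose(
            vals, v0 * np.exp(-params.beta * (d_values - params.d0)), rtol=1e-12)

    def test_too_close_raises(self, params):
        with pytest.raises(GeometryError):
            _hh(0.3, params)


class TestBuildHamiltonian:
    def test_adenine_dimensions_and_trace(self, adenine, params):
        H, basis = build_hamiltonian(adenine, params)
        assert H.shape == (45, 45)  # 10 heavy x 4 + 5 H x 1
        onsite = [params.onsite[(el, "s" if orb == "s" else "p")]
                  for el, orb in ((adenine.elements[i], o)
                                  for i, o in basis.entries)]
        assert np.trace(H) == pytest.approx(sum(onsite))
        assert np.allclose(H, H.T)

    def test_single_carbon_diagonal(self, params):
        mol = Molecule("C", [Atom("C", [0, 0, 0])])
        H, _ = build_hamiltonian(mol, params)
        np.testing.assert_allclose(np.diag(H), [-13.18, -6.70, -6.70, -6.70])
        assert np.count_nonzero(H - np.diag(np.diag(H))) == 0

    def test_no_bonds_warns(self, params):
        mol = Molecule("pair_of_atoms",
                       [Atom("H", [0, 0, 0]), Atom("H", [20, 0, 0])])
        with pytest.warns(UserWarning, match="no bonds"):
            build_hamiltonian(mol, params)

    def test_two_site_closed_form(self, params):
        mol = Molecule("H2", [Atom("H", [0, 0, 0]), Atom("H", [1.0, 0, 0])],
                       bonds=[(0, 1)])
        H, basis = build_hamiltonian(mol, params)
        spec = solve(H, basis, mol)
        E0 = params.onsite[("H", "s")]
        V = abs(H[0, 1])
        np.testing.assert_allclose(spec.energies, [E0 - V, E0 + V], atol=1e-12)


class TestPairHamiltonian:
    def test_at_pair_dimensions(self, at_pair, params):
        H, basis = build_pair_hamiltonian(at_pair, params)
        assert H.shape == (87, 87)  # adenine 45 + thymine 42

    def test_decoupled_limit_is_union_of_fragments(self, at_pair, params):
        far = BasePair(at_pair.base1,
                       at_pair.base2.transformed(np.eye(3), [0, 0, 50.0]),
                       "A-T-far")
        spec = solve_pair(far, params, classify=False)
        s1 = solve_molecule(at_pair.base1, params, classify=False)
        s2 = solve_molecule(far.base2, params, classify=False)
        union = np.sort(np.concatenate([s1.energies, s2.energies]))
        np.testing.assert_allclose(spec.energies, union, atol=1e-10)

    def test_gc_pair_homo_close_to_published(self, gc_pair, params):
        spec = solve_pair(gc_pair, params)
        assert spec.homo_energy == pytest.approx(-8.30, abs=0.2)


class TestSolve:
    def test_adenine_electron_filling(self, adenine, params):
        spec = solve_molecule(adenine, params)
        assert spec.n_electrons == 50  # 5C*4 + 5N*5 + 5H*1
        assert spec.homo_index == 24
        assert spec.lumo_index == 25

    def test_eigenvector_orthonormality_and_completeness(self, adenine, params):
        spec = solve_molecule(adenine, params)
        gram = spec.coefficients.T @ spec.coefficients
        np.testing.assert_allclose(gram, np.eye(45), atol=1e-8)
        # completeness per basis entry: sum over MOs of |c|^2 = 1
        np.testing.assert_allclose((spec.coefficients**2).sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_odd_electron_count_rejected(self, params):
        mol = Molecule("H", [Atom("H", [0, 0, 0])])
        H, basis = build_hamiltonian(mol, params)
        with pytest.raises(UnsupportedSystemError):
            solve(H, basis, mol)

    def test_rigid_motion_leaves_spectrum(self, uracil, params, rng):
        ref = solve_molecule(uracil, params, classify=False).energies
        for _ in range(10):
            R, t = random_rigid_motion(rng)
            moved = solve_molecule(uracil.transformed(R, t), params,
                                   classify=False)
            assert np.max(np.abs(moved.energies - ref)) < 1e-8


class TestCharacter:
    def test_pure_pz_mo_is_pi(self, params):
        spec = solve_molecule(fixtures.nucleobase("U"), params)
        # uracil lies exactly in z=0: every MO separates cleanly
        for k, label in enumerate(spec.characters):
            if label == "pi":
                assert spec.pi_weights[k] > 0.99
            else:
                assert spec.pi_weights[k] < 0.01

    def test_nucleobase_frontier_characters(self, params):
        for letter in "AGTCU":
            spec = solve_molecule(fixtures.nucleobase(letter), params)
            assert spec.characters[spec.homo_index] == "pi"

    def test_collinear_geometry_labeled_mixed(self, params):
        mol = Molecule("chain", [Atom("C", [0, 0, 0]), Atom("C", [1.3, 0, 0]),
                                 Atom("C", [2.6, 0, 0])],
                       bonds=[(0, 1), (1, 2)])
        H, basis = build_hamiltonian(mol, params)
        spec = solve(H, basis, mol)
        classify_character(spec, mol)
        assert set(spec.characters) == {"mixed"}


class TestHuckelEquivalence:
    """For an exactly planar molecule the pz sector decouples and equals an
    independently built Hückel-type matrix."""

    PLANAR = ["adenine", "guanine", "cytosine", "uracil"]  # thymine's methyl
    # hydrogens leave the plane, so it is excluded from the strict check

    @pytest.mark.parametrize("name", PLANAR)
    def test_pz_sector_matches_huckel_oracle(self, name, params):
        mol = fixtures.nucleobase(name)
        assert np.allclose(mol.coords[:, 2], 0.0)
        H, basis = build_hamiltonian(mol, params)
        pz_pos = [i for i, (_, orb) in enumerate(basis.entries) if orb == "pz"]
        other = [i for i in range(basis.size) if i not in pz_pos]
        # sector decoupling
        assert np.max(np.abs(H[np.ix_(pz_pos, other)])) == 0.0
        # independent Hückel construction over heavy atoms
        heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
        huckel = np.zeros((len(heavy), len(heavy)))
        for a, i in enumerate(heavy):
            huckel[a, a] = params.onsite[(mol.atoms[i].element, "p")]
        for i, j in mol.bonds:
            if mol.atoms[i].element == "H" or mol.atoms[j].element == "H":
                continue
            a, b = heavy.index(i), heavy.index(j)
            d = np.linalg.norm(mol.atoms[i].position - mol.atoms[j].position)
            v = params.chi["pp_pi"] * HBAR2_OVER_M / d**2
            huckel[a, b] = huckel[b, a] = v
        np.testing.assert_allclose(H[np.ix_(pz_pos, pz_pos)], huckel,
                                   atol=1e-12)


class TestOscillatorStrength:
    def test_disjoint_support_gives_zero(self, params):
        basis = OrbitalBasis.for_elements(["H", "H"])
        mol = Molecule("H2", [Atom("H", [0, 0, 0]), Atom("H", [1, 0, 0])])
        spec = Spectrum(energies=np.array([-10.0, -5.0]),
                        coefficients=np.array([[1.0, 0.0], [0.0, 1.0]]),
                        basis=basis, n_electrons=2, homo_index=0, lumo_index=1)
        f, dipole = oscillator_strength(spec, mol)
        assert f == 0.0
        np.testing.assert_allclose(dipole, 0.0)

    def test_hand_evaluated_two_site_dipole(self, params):
        # c_H = (0.6, 0.8), c_L = (-0.8, 0.6), atoms at 0 and (1,0,0):
        # d = -(0.6*(-0.8)*r1 + 0.8*0.6*r2) = (-0.48, 0, 0) e*A and
        # f = (2/3)(5/27.211386)(0.48/0.529177)^2 = 0.100788
        basis = OrbitalBasis.for_elements(["H", "H"])
        mol = Molecule("H2", [Atom("H", [0, 0, 0]), Atom("H", [1, 0, 0])])
        spec = Spectrum(energies=np.array([-10.0, -5.0]),
                        coefficients=np.array([[0.6, -0.8], [0.8, 0.6]]),
                        basis=basis, n_electrons=2, homo_index=0, lumo_index=1)
        f, dipole = oscillator_strength(spec, mol)
        np.testing.assert_allclose(dipole, [-0.48, 0, 0], atol=1e-12)
        assert f == pytest.approx(0.10078795591461605, rel=1e-9)

    def test_same_mo_rejected(self, adenine, params):
        spec = solve_molecule(adenine, params)
        with pytest.raises(ValueError, match="zero transition"):
            oscillator_strength(spec, adenine, "HOMO", "HOMO")
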