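import numpy as np
import pytest

from lcaodna import fixtures
from lcaodna.constants import HBAR_EV_FS
from lcaodna.structure_io import BasePair
from lcaodna.transfer import max_transfer_percentage
from lcaodna.wire import (NormalizationError, WireModel, WireState,
                          build_wire_from_dimers, max_offsite_occupation,
                          propagate, site_state, wire_eigenstates)


class TestEigenstates:
    def test_single_site(self):
        energies, occ = wire_eigenstates(WireModel([-8.3], []))
        np.testing.assert_allclose(energies, [-8.3])
        np.testing.assert_allclose(occ, [[1.0]])

    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_uniform_open_chain_closed_form(self, n):
        E, t = -8.0, 0.1
        model = WireModel([E] * n, [t] * (n - 1))
        energies, occ = wire_eigenstates(model)
        k = np.arange(1, n + 1)
        expected = np.sort(E + 2 * t * np.cos(k * np.pi / (n + 1)))
        np.testing.assert_allclose(energies, expected, atol=1e-10)
        np.testing.assert_allclose(occ.sum(axis=0), 1.0, atol=1e-12)

    def test_two_site_closed_form(self):
        E1, E2, t = -8.0, -8.3, 0.05
        energies, _ = wire_eigenstates(WireModel([E1, E2], [t]))
        mean, half = (E1 + E2) / 2, np.sqrt(((E1 - E2) / 2) ** 2 + t**2)
        np.testing.assert_allclose(energies, [mean - half, mean + half],
                                   atol=1e-12)


class TestPropagation:
    def test_rabi_oscillation_period_and_amplitude(self):
        t = 0.02
        model = WireModel([-8.0, -8.0], [t])
        period = np.pi * HBAR_EV_FS / abs(t)  # full transfer at T/2... T
        states = propagate(model, site_state(2, 0),
                           [0.0, period / 2, period])
        assert states[1].occupations[1] == pytest.approx(1.0, abs=1e-10)
        assert states[2].occupations[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("t,delta", [(0.02, 0.0), (0.05, 0.1),
                                         (0.01, 0.002), (0.002, 0.05)])
    def test_max_offsite_occupation_equals_p(self, t, delta):
        model = WireModel([0.0, -delta], [t])
        # analytic peak time: pi hbar / sqrt((2t)^2 + delta^2)
        t_peak = np.pi * HBAR_EV_FS / np.sqrt((2 * t) ** 2 + delta**2)
        state = propagate(model, site_state(2, 0), [t_peak])[0]
        p = max_transfer_percentage(t, delta)
        assert state.occupations[1] == pytest.approx(p, abs=1e-10)

    def test_decoupled_sites_static(self):
        model = WireModel([-8.0, -8.5, -7.9], [0.0, 0.0])
        init = WireState(np.sqrt([0.5, 0.3, 0.2]))
        for state in propagate(model, init, np.linspace(0, 50, 7)):
            np.testing.assert_allclose(state.occupations, [0.5, 0.3, 0.2],
                                       atol=1e-12)

    def test_norm_and_energy_conservation(self):
        rng = np.random.default_rng(7)
        model = WireModel(rng.normal(-8, 0.2, 6), rng.normal(0, 0.05, 5))
        H = model.hamiltonian()
        init = site_state(6, 2)
        e0 = None
        for state in propagate(model, init, np.linspace(0, 500, 101)):
            assert abs(np.sum(state.occupations) - 1.0) < 1e-9
            energy = np.real(np.conj(state.amplitudes) @ H @ state.amplitudes)
            e0 = energy if e0 is None else e0
            assert abs(energy - e0) < 1e-9

    def test_agrees_with_rk4_oracle(self):
        model = WireModel([-8.0, -8.1, -7.95, -8.05], [0.03, -0.02, 0.04])
        H = model.hamiltonian()
        dt = 0.001
        steps = 100_000  # 100 fs
        A = site_state(4, 0).amplitudes.copy()

        def deriv(a):
            return (-1j / HBAR_EV_FS) * (H @ a)

        for _ in range(steps):
            k1 = deriv(A)
            k2 = deriv(A + dt / 2 * k1)
            k3 = deriv(A + dt / 2 * k2)
            k4 = deriv(A + dt * k3)
            A = A + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        spectral = propagate(model, site_state(4, 0), [100.0])[0]
        np.testing.assert_allclose(spectral.amplitudes, A, atol=1e-6)

    def test_time_reversal(self):
        model = WireModel([-8.0, -8.2, -8.1], [0.02, 0.05])
        fwd = propagate(model, site_state(3, 1), [37.0])[0]
        back = propagate(model, fwd, [0.0])[0]
        np.testing.assert_allclose(back.amplitudes, site_state(3, 1).amplitudes,
                                   atol=1e-8)

    def test_long_time_mean_is_half_p(self):
        t, delta = 0.03, 0.04
        model = WireModel([0.0, -delta], [t])
        times = np.linspace(0, 20000, 40001)
        occ2 = np.array([s.occupations[1]
                         for s in propagate(model, site_state(2, 0), times)])
        p = max_transfer_percentage(t, delta)
        assert np.mean(occ2) == pytest.approx(p / 2, abs=2e-3)

    def test_unnormalized_initial_state_rejected(self):
        with pytest.raises(NormalizationError):
            WireState(np.array([1.0, 1.0]))


class TestBuildWire:
    def test_poly_g_wire_is_uniform(self, params):
        pairs = fixtures.ideal_stack("GGGGG")
        model = build_wire_from_dimers(pairs, params, "HOMO")
        assert model.n_sites == 5
        np.testing.assert_allclose(model.onsite, model.onsite[0], atol=1e-9)
        np.testing.assert_allclose(np.abs(model.hops), np.abs(model.hops[0]),
                                   atol=1e-9)

    def test_mixed_wire_internal_consistency(self, params):
        from lcaodna.transfer import transfer_integral
        from lcaodna.structure_io import Dimer
        pairs = fixtures.ideal_stack("GAT")
        model = build_wire_from_dimers(pairs, params, "HOMO")
        for a in range(2):
            res = transfer_integral(Dimer(pairs[a], pairs[a + 1]), params)
            assert model.hops[a] == pytest.approx(res.t, abs=1e-12)
            delta = model.onsite[a] - model.onsite[a + 1]
            assert res.p == pytest.approx(
                max_transfer_percentage(model.hops[a], delta), abs=1e-12)

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValueError, match="empty"):
            build_wire_from_dimers([], params)

    def test_max_offsite_occupation_matches_formula(self):
        model = WireModel([0.0, -0.04], [0.03])
        p = max_transfer_percentage(0.03, 0.04)
        assert max_offsite_occupation(model) == pytest.approx(p, abs=1e-4)
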