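"""Lattice geometry, crossbridge springs, titin, and the mechanics solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import sarcvae as sv
from sarcvae.lattice import (HalfSarcomereState, axial_site_force,
                             build_lattice, cross_sectional_area,
                             crossbridge_energy, crossbridge_force,
                             head_geometry, titin_force, total_elastic_energy,
                             solve_isometric_balance)
from sarcvae.params import (ConfigurationError, CrossbridgeSpringParams,
                            LatticeConfig, ModelConfig)

SPR = CrossbridgeSpringParams()


class TestBuild:
    def test_head_and_site_counts(self):
        cfg = ModelConfig()
        st_ = build_lattice(cfg)
        lat = cfg.lattice
        assert st_.n_heads == lat.n_thick * lat.nodes_per_thick * lat.heads_per_node
        assert st_.site_state.size == lat.n_thin * lat.nodes_per_thin
        assert np.all(st_.head_state == 1)
        assert np.all(st_.site_state == 1)

    def test_resting_force_is_titin_only(self, reduced_config):
        st_ = build_lattice(reduced_config)
        lat = reduced_config.lattice
        expected = lat.n_thick * lat.titin_a  # exp(0) at the rest gap
        assert st_.boundary_force() == pytest.approx(expected, rel=1e-12)

    def test_geometry_independent_of_seed(self, reduced_config):
        a = build_lattice(reduced_config, seed=1)
        b = build_lattice(reduced_config, seed=99)
        assert np.array_equal(a.x_thick, b.x_thick)
        assert np.array_equal(a.x_thin, b.x_thin)
        assert np.array_equal(a.head_site, b.head_site)

    def test_monotone_node_positions(self, reduced_config):
        st_ = build_lattice(reduced_config)
        assert np.all(np.diff(st_.x_thick, axis=1) > 0)
        assert np.all(np.diff(st_.x_thin, axis=1) < 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            LatticeConfig(thick_repeat=-1.0)
        with pytest.raises(ConfigurationError):
            LatticeConfig(n_thick=3)  # not a packable count
        with pytest.raises(ConfigurationError):
            # thick filament longer than the half-sarcomere
            build_lattice(ModelConfig(lattice=LatticeConfig(
                half_sarcomere_length=100.0)))


class TestSprings:
    def test_zero_strain_energy_and_force(self):
        for state, (r0, th0) in (("weak", (SPR.r_W, SPR.theta_W_rad)),
                                 ("strong", (SPR.r_S, SPR.theta_S_rad))):
            assert crossbridge_energy(r0, th0, state, SPR) == 0.0
            fr, ft = crossbridge_force(r0, th0, state, SPR)
            assert fr == 0.0 and ft == 0.0

    def test_hand_evaluated_quadratic(self):
        # 1 nm of radial strain at k_r = 5 KT/nm^2 stores 2.5 KT
        e = crossbridge_energy(SPR.r_W + 1.0, SPR.theta_W_rad, "weak", SPR)
        assert e == pytest.approx(2.5)

    @given(st.floats(10.0, 30.0), st.floats(0.1, 2.5))
    @settings(max_examples=50, deadline=None)
    def test_energies_nonnegative_and_minimized_at_rest(self, r, theta):
        for state in ("weak", "strong"):
            assert crossbridge_energy(r, theta, state, SPR) >= 0.0

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            crossbridge_energy(20.0, 1.0, "half", SPR)

    @given(st.floats(-18.0, 24.0), st.floats(12.0, 18.0))
    @settings(max_examples=100, deadline=None)
    def test_axial_force_is_energy_gradient(self, dx, gap):
        """Central-difference check of the axial force used by the solver."""
        for state in ("weak", "strong"):
            h = 1e-5
            rp, tp = head_geometry(dx + h, gap)
            rm, tm = head_geometry(dx - h, gap)
            du = (crossbridge_energy(rp, tp, state, SPR)
                  - crossbridge_energy(rm, tm, state, SPR)) / (2 * h)
            f = axial_site_force(dx, gap, state, SPR, kt=1.0)
            assert f == pytest.approx(-du, rel=1e-5, abs=1e-7)

    def test_axial_force_sign_reverses_at_rest_offset(self):
        dx_rest = np.sqrt(SPR.r_W ** 2 - 14.61 ** 2)
        below = axial_site_force(dx_rest - 2.0, 14.61, "weak", SPR)
        above = axial_site_force(dx_rest + 2.0, 14.61, "weak", SPR)
        assert below * above < 0


class TestTitinAndArea:
    def test_titin_at_zero_extension(self):
        assert titin_force(0.0, LatticeConfig()) == pytest.approx(220.0)

    def test_titin_exponential_doubling(self):
        lat = LatticeConfig()
        dl = 150.0
        ratio = titin_force(dl + np.log(2) / lat.titin_b, lat) / titin_force(dl, lat)
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_titin_monotone(self):
        dl = np.linspace(-100, 500, 500)
        assert np.all(np.diff(titin_force(dl, LatticeConfig())) > 0)

    def test_area_hexagonal_unit_cell(self):
        lat = LatticeConfig()
        manual = 4 * lat.lattice_spacing ** 2 * np.sin(np.deg2rad(60)) * 1e-12
        assert cross_sectional_area(lat) == pytest.approx(manual, rel=1e-12)

    def test_area_quadruples_with_spacing(self):
        a1 = cross_sectional_area(LatticeConfig(lattice_spacing=42.0))
        a2 = cross_sectional_area(LatticeConfig(lattice_spacing=84.0))
        assert a2 == pytest.approx(4 * a1)


def _bind_heads(state: HalfSarcomereState, head_ids, head_states):
    for h, s in zip(head_ids, head_states):
        state.head_state[h] = s
        g, j = state.head_thin[h], state.head_site[h]
        state.site_state[g, j] = 4


def _energy_oracle(state: HalfSarcomereState):
    """Direct minimization of the total elastic energy (independent path)."""
    shapes = (state.x_thick.shape, state.x_thin.shape)
    n1 = state.x_thick.size

    def unpack(x):
        state.x_thick = x[:n1].reshape(shapes[0])
        state.x_thin = x[n1:].reshape(shapes[1])

    def objective(x):
        unpack(x)
        return total_elastic_energy(state)

    x0 = np.concatenate([state.x_thick.ravel(), state.x_thin.ravel()])
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 2000})
    unpack(res.x)
    return state


class TestMechanicsSolver:
    def test_no_bound_heads_rest_positions(self, reduced_config):
        st_ = build_lattice(reduced_config)
        solve_isometric_balance(st_)
        # titin preload stretches the thick filament slightly; thin at rest
        assert np.allclose(st_.x_thin, st_.x_thin_rest, atol=1e-9)
        assert np.all(st_.x_thick >= st_.x_thick_rest - 1e-12)

    @pytest.mark.parametrize("n_bound", [1, 2, 3])
    def test_solver_matches_energy_minimization(self, reduced_config, n_bound):
        st_ = build_lattice(reduced_config)
        # pick heads with distinct filaments/sites and favourable offsets
        order = np.argsort(-st_.head_dx())
        chosen = [h for h in order if 5 < st_.head_dx()[h] < 15][:n_bound]
        _bind_heads(st_, chosen, [3] * len(chosen))
        solve_isometric_balance(st_)
        solved_thick = st_.x_thick.copy()
        solved_thin = st_.x_thin.copy()

        fresh = build_lattice(reduced_config)
        _bind_heads(fresh, chosen, [3] * len(chosen))
        _energy_oracle(fresh)
        assert np.max(np.abs(fresh.x_thick - solved_thick)) < 1e-4
        assert np.max(np.abs(fresh.x_thin - solved_thin)) < 1e-4

    def test_newtons_third_law_across_lattice(self, reduced_config):
        st_ = build_lattice(reduced_config)
        order = np.argsort(-st_.head_dx())
        chosen = [h for h in order if 5 < st_.head_dx()[h] < 15][:3]
        _bind_heads(st_, chosen, [3, 2, 3])
        solve_isometric_balance(st_)
        lat = reduced_config.lattice
        # M-line reaction: tension of every first thick segment
        m_line = sum(lat.k_thick_segment
                     * ((st_.x_thick[f, 0] - lat.crown_spacing))
                     for f in range(lat.n_thick))
        # crossbridge reaction forces transmitted through the thick filament
        z_disc = st_.boundary_force()
        assert m_line == pytest.approx(z_disc, rel=1e-8)

    def test_doubling_stiffness_halves_displacement(self):
        from sarcvae.lattice import _chain_solve
        rest = np.arange(1, 11, dtype=float)
        loads = np.zeros(10)
        loads[4] = 12.0
        u1 = _chain_solve(rest, loads, 100.0) - rest
        u2 = _chain_solve(rest, loads, 200.0) - rest
        assert np.allclose(u1, 2 * u2)

    def test_active_force_zero_without_attachments(self, reduced_config):
        st_ = build_lattice(reduced_config)
        solve_isometric_balance(st_)
        lat = reduced_config.lattice
        passive = np.sum(titin_force(st_.titin_extension(), lat))
        assert st_.boundary_force() == pytest.approx(passive, abs=1e-8)
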