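"""Pair potentials, forces, RK4 integration and its conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ioncage.constants import K_E, MASS_U
from ioncage.ion_dynamics import (
    DynamicsConfig,
    PairPotentialParams,
    collision_potential,
    integrate,
    screened_pair_potential,
    total_force,
    total_potential_energy,
)
from ioncage.synthetic_data import SimCell

NO_WALL = PairPotentialParams(D=0.0)  # pure screened Coulomb


class TestPairPotentials:
    def test_unscreened_coulomb_value(self):
        # 2e * 2e at the disulfide bond length
        assert screened_pair_potential(2, 2, 2.08, 0.0) == pytest.approx(
            4 * K_E / 2.08, rel=1e-12
        )

    def test_screening_length_identity(self):
        v0 = screened_pair_potential(1, 1, 2.0, 0.0)
        assert screened_pair_potential(1, 1, 2.0, 0.5) == pytest.approx(
            v0 * np.exp(-1.0)
        )

    def test_neutral_partner_feels_nothing(self):
        assert screened_pair_potential(0, 3, 1.5, 0.2) == 0.0

    def test_collision_boundary_and_outside(self):
        assert collision_potential(2.1, 27.2, 2.0, 2.1) == 0.0
        assert collision_potential(5.0, 27.2, 2.0, 2.1) == 0.0

    def test_collision_origin_value(self):
        D, a, re = 27.2, 2.0, 2.1
        assert collision_potential(0.0, D, a, re) == pytest.approx(
            D * (1 - np.exp(a * re)) ** 2
        )

    @given(
        r=st.floats(0.5, 10.0),
        q=st.integers(1, 8),
        kappa=st.floats(0.0, 3.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_screened_force_never_exceeds_unscreened(self, r, q, kappa):
        """|F_screened| / |F_unscreened| = (1 + kr) e^{-kr} <= 1."""
        f_s = K_E * q * q * np.exp(-kappa * r) * (1 + kappa * r) / r**2
        f_0 = K_E * q * q / r**2
        assert f_s <= f_0 * (1 + 1e-12)


class TestForces:
    def _random_cluster(self, n=10, seed=4):
        rng = np.random.default_rng(seed)
        # spread atoms so every pair stays inside the interaction cutoff
        pos = rng.uniform(0, 4.0, size=(n, 3))
        while True:
            d = pos[:, None] - pos[None, :]
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            if r.min() > 0.8:
                break
            i = np.unravel_index(np.argmin(r), r.shape)[0]
            pos[i] = rng.uniform(0, 4.0, 3)
        elements = ["S", "S"] + ["O", "C", "N", "H"] * 2
        cell = SimCell(
            edge_length=np.inf,
            periodic=False,
            elements=elements[:n],
            positions=pos,
            bridge=(0, 1),
            charges=rng.integers(0, 4, size=n).astype(float),
        )
        return cell

    def test_newtons_third_law(self):
        cell = SimCell(
            edge_length=np.inf,
            periodic=False,
            elements=["S", "S"],
            positions=[[0, 0, 0], [2.5, 0.4, -0.3]],
            bridge=(0, 1),
            charges=[2.0, 2.0],
        )
        f = total_force(cell, kappa=0.3)
        assert np.allclose(f[0], -f[1], rtol=1e-12, atol=1e-12)

    def test_force_is_minus_gradient_of_potential(self):
        """Central finite differences of the total pair energy reproduce the
        analytic forces on a random 10-atom cluster."""
        cell = self._random_cluster()
        kappa = 0.4
        f = total_force(cell, kappa)
        h = 1e-5
        num = np.zeros_like(f)
        for i in range(cell.n_atoms):
            for k in range(3):
                for sgn in (+1, -1):
                    pos = cell.positions.copy()
                    pos[i, k] += sgn * h
                    shifted = SimCell(
                        edge_length=np.inf,
                        periodic=False,
                        elements=cell.elements,
                        positions=pos,
                        bridge=cell.bridge,
                        charges=cell.charges,
                    )
                    num[i, k] += -sgn * total_potential_energy(shifted, kappa) / (
                        2 * h
                    )
        scale = np.abs(f).max()
        assert np.allclose(num, f, atol=scale * 1e-5)

    def test_strong_screening_reduces_to_isolated_pair(self):
        """At large kappa only the nearest image contributes."""
        iso = SimCell(
            edge_length=np.inf,
            periodic=False,
            elements=["S", "S"],
            positions=[[0, 0, 0], [2.0, 0, 0]],
            bridge=(0, 1),
            charges=[1.0, 1.0],
        )
        per = SimCell(
            edge_length=12.0,
            periodic=True,
            elements=["S", "S"],
            positions=[[5.0, 6.0, 6.0], [7.0, 6.0, 6.0]],
            bridge=(0, 1),
            charges=[1.0, 1.0],
        )
        kappa = 3.0
        f_iso = total_force(iso, kappa)
        f_per = total_force(per, kappa)
        assert np.allclose(f_iso[0], f_per[0], rtol=1e-9, atol=1e-12)

    def test_overlapping_atoms_raise_naming_the_pair(self):
        cell = SimCell(
            edge_length=np.inf,
            periodic=False,
            elements=["S", "S", "O"],
            positions=[[0, 0, 0], [2.0, 0, 0], [0, 0, 0]],
            bridge=(0, 1),
        )
        with pytest.raises(ValueError, match="0 and 2"):
            total_force(cell, 0.0)


class TestIntegration:
    def test_neutral_cell_stays_at_rest(self, supercell):
        cfg = DynamicsConfig(dt=0.05, t_end=10.0)
        traj = integrate(supercell, np.zeros(supercell.n_atoms), 0.0, config=cfg)
        assert np.allclose(traj.ss_distance, traj.ss_distance[0])
        assert traj.kinetic[-1] == 0.0

    def test_two_body_coulomb_explosion_energy(self, ss_pair):
        """+1/+1 from 2.08 Å, kappa = 0: total energy equals the closed-form
        initial Coulomb energy K_E/2.08 = 6.923 eV at all times."""
        cfg = DynamicsConfig(dt=0.01, t_end=100.0)
        traj = integrate(
            ss_pair, np.ones((2, 1)), 0.0, params=NO_WALL, config=cfg
        )
        e0 = K_E / 2.08
        total = traj.kinetic + traj.potential
        assert np.max(np.abs(total - e0)) / e0 < 1e-3
        # most of the potential already converted at 100 fs
        assert traj.kinetic[-1] > 0.7 * e0

    def test_screening_lowers_final_kinetic_energy(self, ss_pair):
        cfg = DynamicsConfig(dt=0.01, t_end=100.0)
        t0 = integrate(ss_pair, np.ones((2, 1)), 0.0, params=NO_WALL, config=cfg)
        t1 = integrate(ss_pair, np.ones((2, 1)), 0.7, params=NO_WALL, config=cfg)
        assert t1.kinetic[-1] < t0.kinetic[-1]

    def test_rk4_order_on_energy_drift(self, ss_pair):
        """Halving dt cuts the energy drift by ~2^4 (frozen charges, no
        wall contact, kappa = 0)."""
        drifts = []
        for dt in (0.4, 0.2):
            cfg = DynamicsConfig(dt=dt, t_end=40.0, output_stride=2.0)
            traj = integrate(
                ss_pair, np.full((2, 1), 3.0), 0.0, params=NO_WALL, config=cfg
            )
            e = traj.kinetic + traj.potential
            drifts.append(np.max(np.abs(e - e[0])))
        ratio = drifts[0] / drifts[1]
        assert 6.0 < ratio < 50.0

    def test_two_body_matches_adaptive_reference(self, ss_pair):
        """RK4 trajectory vs an independent adaptive integration (DOP853)
        of the radial two-body problem, < 1e-4 Å everywhere."""
        from scipy.integrate import solve_ivp

        q1 = q2 = 2.0
        mu = (32.06 * MASS_U) / 2.0  # reduced mass of the S-S pair

        def rhs(t, y):
            r, v = y
            return [v, K_E * q1 * q2 / (mu * r * r)]

        ref = solve_ivp(
            rhs,
            (0.0, 60.0),
            [2.08, 0.0],
            method="DOP853",
            rtol=1e-11,
            atol=1e-13,
            dense_output=True,
        )
        cfg = DynamicsConfig(dt=0.01, t_end=60.0)
        traj = integrate(
            ss_pair, np.full((2, 1), 2.0), 0.0, params=NO_WALL, config=cfg
        )
        r_ref = ref.sol(traj.times)[0]
        assert np.max(np.abs(traj.ss_distance - r_ref)) < 1e-4

    def test_instability_guard_suggests_smaller_dt(self, ss_pair):
        cfg = DynamicsConfig(dt=3.0, t_end=30.0)
        with pytest.raises(RuntimeError, match="reduce dt"):
            integrate(
                ss_pair, np.full((2, 1), 8.0), 0.0, params=NO_WALL, config=cfg
            )

    def test_frozen_shell_atoms_do_not_move(self):
        rng = np.random.default_rng(2)
        from ioncage.synthetic_data import generate_supercell

        cell = generate_supercell(
            target_atom_count=120, seed=3, free_radius=4.0
        )
        q = np.ones(cell.n_atoms)
        cfg = DynamicsConfig(dt=0.05, t_end=5.0)
        traj = integrate(cell, q, 0.2, config=cfg, record_positions=True)
        frozen = ~cell.mobile
        assert frozen.any()
        assert np.allclose(
            traj.positions[-1][frozen], traj.positions[0][frozen]
        )
        moved = np.linalg.norm(
            traj.positions[-1][cell.mobile] - traj.positions[0][cell.mobile],
            axis=1,
        )
        assert moved.max() > 1e-3
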