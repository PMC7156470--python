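"""Rate equations, electron trapping, screening and charge sampling."""

import numpy as np
import pytest

from ioncage.plasma_model import (
    ChargeStatePopulations,
    PlasmaState,
    advance_rate_equations,
    electron_fate,
    sample_ion_charges,
    screening_parameter,
    solve_rate_equations,
)
from ioncage.pump_probe import FLUENCE, PulsePair
from ioncage.synthetic_data import SimCell


class TestScreeningParameter:
    def test_empty_gas(self):
        assert screening_parameter(0.0, 0.0) == 0.0

    def test_square_root_density_scaling(self):
        k1 = screening_parameter(0.01, 10.0)
        assert screening_parameter(0.04, 10.0) == pytest.approx(2 * k1)

    def test_si_rederivation(self):
        """lambda = 1/kappa agrees with the SI Debye length to 1e-6."""
        n_e, t_e = 0.01, 10.0  # Å^-3, eV
        eps0 = 8.8541878128e-12
        e = 1.602176634e-19
        n_si = n_e * 1e30  # m^-3
        lam_si = np.sqrt(eps0 * t_e * e / (n_si * e * e))  # m, with kT in eV
        lam = 1.0 / screening_parameter(n_e, t_e)  # Å
        # limited by the package-wide k_e = 14.3996 eV·Å (6 significant digits)
        assert lam == pytest.approx(lam_si * 1e10, rel=2e-5)


class TestElectronFate:
    def test_barrier_arithmetic(self):
        plasma = PlasmaState(escaped_charge=100.0, sample_radius=1000.0)
        assert plasma.barrier == pytest.approx(1.43996)

    def test_fast_electron_escapes_neutral_sample(self):
        plasma = PlasmaState(sample_radius=1000.0)
        assert electron_fate(7000.0, plasma) == "escaped"

    def test_slow_electron_is_stopped_inside_the_crystal(self):
        """A 200 eV secondary has a few-nm range and cannot leave a 100 nm
        crystal even when no Coulomb barrier has built up yet."""
        plasma = PlasmaState(sample_radius=1000.0)
        assert electron_fate(200.0, plasma) == "trapped"

    def test_zero_energy_electron_trapped_by_any_barrier(self):
        plasma = PlasmaState(escaped_charge=1.0, sample_radius=1000.0)
        assert electron_fate(0.0, plasma) == "trapped"


class TestRateEquations:
    def test_no_drivers_no_change(self, rates):
        pops = ChargeStatePopulations({"C": 10, "S": 2}, rates)
        plasma = PlasmaState()
        new_pops, new_plasma = advance_rate_equations(pops, plasma, rates, 0.0, 1.0)
        for sym in pops.occ:
            assert np.array_equal(new_pops.occ[sym], pops.occ[sym])
        assert new_plasma.n_e == 0.0

    def test_photoionization_only_closed_form(self, rates):
        """Single-channel decay: neutral fraction = exp(-sigma * F_total)."""
        sigma = rates["H"].photo_cross_section[0]
        f = 1.0 / (sigma * 100.0)  # sigma*f*T = 1 over T = 100 fs
        hist = solve_rate_equations({"H": 50}, rates, lambda t: f, 100.0, dt=0.02)
        frac = hist.occ["H"][-1, 0] / 50.0
        assert frac == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_population_conservation_over_full_pulse(self, rates, supercell):
        pulse = PulsePair(delay=40.0, total_fluence=FLUENCE["med"])
        hist = solve_rate_equations(
            supercell.element_counts(), rates, pulse.flux, t_end=90.0
        )
        for sym, n0 in supercell.element_counts().items():
            tot = hist.occ[sym].sum(axis=1)
            assert np.allclose(tot, n0, rtol=1e-9)

    def test_charge_balance_and_state_sanity(self, rates, supercell):
        pulse = PulsePair(delay=20.0, total_fluence=FLUENCE["low"])
        hist = solve_rate_equations(
            supercell.element_counts(), rates, pulse.flux, t_end=70.0
        )
        ions = sum(
            (np.arange(hist.occ[s].shape[1]) * hist.occ[s]).sum(axis=1)
            for s in hist.occ
        )
        electrons = hist.trapped + hist.escaped + hist.hot
        assert np.allclose(ions, electrons, rtol=1e-9, atol=1e-9)
        assert np.all(hist.t_e >= 0)
        assert np.all(np.isfinite(hist.kappa))

    def test_sulfur_reaches_highest_mean_charge(self, rates, supercell):
        pulse = PulsePair(delay=60.0, total_fluence=FLUENCE["med"])
        hist = solve_rate_equations(
            supercell.element_counts(), rates, pulse.flux, t_end=110.0
        )
        final = hist.final_mean_charges()
        assert final["S"] == max(final.values())

    def test_halving_dt_converges_mean_charges(self, rates):
        counts = {"H": 60, "C": 16, "N": 4, "O": 20, "S": 2}
        pulse = PulsePair(delay=20.0, total_fluence=FLUENCE["low"])
        h1 = solve_rate_equations(counts, rates, pulse.flux, 70.0, dt=0.25)
        h2 = solve_rate_equations(counts, rates, pulse.flux, 70.0, dt=0.125)
        for sym in counts:
            a, b = h1.mean_charge(sym)[-1], h2.mean_charge(sym)[-1]
            assert a == pytest.approx(b, rel=1e-3, abs=1e-6)


class TestChargeSampling:
    def _flat_history(self, rates, counts, n_t=5):
        hist = solve_rate_equations(counts, rates, lambda t: 0.0, 1.0, dt=0.25)
        return hist

    def test_frozen_neutral_populations_sample_zero(self, rates, supercell):
        hist = self._flat_history(rates, supercell.element_counts())
        q = sample_ion_charges(hist, supercell, seed=3)
        assert not q.any()

    def test_staircases_never_decrease(self, rates, supercell):
        pulse = PulsePair(delay=40.0, total_fluence=FLUENCE["med"])
        hist = solve_rate_equations(
            supercell.element_counts(), rates, pulse.flux, t_end=90.0
        )
        q = sample_ion_charges(hist, supercell, seed=5)
        assert np.all(np.diff(q.astype(int), axis=1) >= 0)

    def test_marginal_distribution_matches_populations(self, rates):
        """Ensemble-average sampled charge converges to the population mean
        (many independent atoms of one element = many seeds for one atom)."""
        n = 4000
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 40.0, size=(n + 2, 3))
        pos[0], pos[1] = [0, 0, 0], [2.08, 0, 0]
        cell = SimCell(
            edge_length=np.inf,
            periodic=False,
            elements=["S", "S"] + ["O"] * n,
            positions=pos,
            bridge=(0, 1),
        )
        pulse = PulsePair(delay=20.0, total_fluence=FLUENCE["low"])
        hist = solve_rate_equations({"S": 2, "O": n}, rates, pulse.flux, 60.0)
        q = sample_ion_charges(hist, cell, seed=11)
        mu = hist.mean_charge("O")[-1]
        sampled = q[2:, -1].astype(float)
        se = sampled.std() / np.sqrt(n)
        assert abs(sampled.mean() - mu) < 3 * se + 1e-9
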