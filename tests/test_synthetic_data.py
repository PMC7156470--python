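"""Generators: supercell packing, vacuum fixture, reflections, PDB cut-out."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ioncage.constants import COVALENT_RADIUS
from ioncage.synthetic_data import (
    ReflectionSet,
    cutout_from_pdb,
    generate_reference_intensities,
    generate_supercell,
    generate_vacuum_disulfide,
)


class TestSupercell:
    def test_default_cell_matches_study_conditions(self, supercell):
        """14 Å cube, ~300 atoms, one tracked S-S bridge at 2.08 Å."""
        assert supercell.edge_length == 14.0
        assert abs(supercell.n_atoms - 300) <= 30
        assert supercell.ss_distance() == pytest.approx(2.08, abs=1e-9)
        assert supercell.element_counts()["S"] == 2
        assert np.all(supercell.positions >= 0)
        assert np.all(supercell.positions < 14.0)

    def test_minimal_cell_is_bare_motif(self):
        cell = generate_supercell(target_atom_count=4, seed=0)
        assert cell.n_atoms == 4
        assert sorted(cell.elements) == ["C", "C", "S", "S"]

    def test_same_seed_reproduces_coordinates(self):
        a = generate_supercell(seed=7)
        b = generate_supercell(seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.elements, b.elements)

    def test_no_pair_inside_contact_radius(self, supercell):
        """Packing keeps every pair at or beyond the collision radius."""
        pos = supercell.positions
        L = supercell.edge_length
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.round(d / L)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        radii = np.array([COVALENT_RADIUS[e] for e in supercell.elements])
        re = radii[:, None] + radii[None, :]
        np.fill_diagonal(r, np.inf)
        # the bonded cystine motif (atoms 0-3) is the only allowed contact
        mask = np.ones_like(r, dtype=bool)
        mask[:4, :4] = False
        assert np.all(r[mask] >= re[mask] - 1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_composition_is_seed_independent(self, seed):
        cell = generate_supercell(target_atom_count=120, seed=seed)
        counts = cell.element_counts()
        assert sum(counts.values()) == 120
        assert counts["S"] == 2

    def test_infeasible_packing_reports_achieved_count(self):
        with pytest.raises(RuntimeError, match=r"placed \d+ of"):
            generate_supercell(
                edge_length=6.0, target_atom_count=900, min_distance=1.5, seed=0
            )

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            generate_supercell(edge_length=4.0)  # < 2 * bond length
        with pytest.raises(ValueError):
            generate_supercell(sulfur_fraction=0.5)


class TestVacuumDisulfide:
    def test_geometry_and_momentum(self):
        cell = generate_vacuum_disulfide(2.08)
        assert cell.n_atoms == 4
        assert not cell.periodic
        assert cell.ss_distance() == pytest.approx(2.08)
        com = (cell.masses[:, None] * cell.positions).sum(0) / cell.masses.sum()
        assert np.allclose(com, 0.0, atol=1e-12)
        assert np.allclose(cell.velocities, 0.0)
        assert cell.mobile.all()

    def test_invalid_bond_length(self):
        with pytest.raises(ValueError):
            generate_vacuum_disulfide(0.0)


PDB_FIXTURE = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1
ATOM      1  CB  CYS A  26       8.000  10.000  10.000  1.00  0.00           C
ATOM      2  SG  CYS A  26       9.500  10.500  10.000  1.00  0.00           S
ATOM      3  SG  CYS A  84      11.400  10.900  10.300  1.00  0.00           S
ATOM      4  CB  CYS A  84      12.900  11.400  10.500  1.00  0.00           C
ATOM      5  O   HOH A 100       4.000   4.500   3.500  1.00  0.00           O
ATOM      6  N   GLY A   2      15.000  14.000  13.000  1.00  0.00           N
END
"""


class TestPdbCutout:
    def test_cutout_tracks_bridge_and_recentres(self):
        cell = cutout_from_pdb(PDB_FIXTURE, (("A", 26), ("A", 84)), 14.0)
        assert cell.n_atoms == 6
        i, j = cell.bridge
        assert cell.elements[i] == cell.elements[j] == "S"
        # SG-SG distance preserved through the shift
        assert cell.ss_distance() == pytest.approx(
            np.linalg.norm([11.4 - 9.5, 10.9 - 10.5, 10.3 - 10.0]), abs=1e-6
        )
        assert np.all(cell.positions >= 0) and np.all(cell.positions < 14.0)

    def test_half_open_boundary_rule(self):
        """An atom exactly on the upper cube face is excluded."""
        # SG midpoint is (10.45, 10.7, 10.15); lo corner = mid - 3
        pdb = PDB_FIXTURE.replace(
            "ATOM      6  N   GLY A   2      15.000  14.000  13.000",
            "ATOM      6  N   GLY A   2      13.450  10.000  10.000",
        )
        cell = cutout_from_pdb(pdb, (("A", 26), ("A", 84)), 6.0)
        # lo_x = 10.45 - 3 = 7.45; 13.450 == lo_x + 6.0 exactly -> excluded
        assert "N" not in cell.element_counts()

    def test_missing_bridge_is_descriptive(self):
        with pytest.raises(ValueError, match="B:26"):
            cutout_from_pdb(PDB_FIXTURE, (("B", 26), ("A", 84)), 14.0)

    def test_edge_too_small_for_bridge(self):
        with pytest.raises(ValueError, match="edge_length"):
            cutout_from_pdb(PDB_FIXTURE, (("A", 26), ("A", 84)), 3.0)

    def test_xyz_roundtrip_to_pdb_precision(self):
        cell = cutout_from_pdb(PDB_FIXTURE, (("A", 26), ("A", 84)), 14.0)
        text = cell.to_xyz()
        lines = text.strip().splitlines()
        assert int(lines[0]) == cell.n_atoms
        coords = np.array(
            [[float(x) for x in ln.split()[1:]] for ln in lines[2:]]
        )
        assert np.allclose(coords, cell.positions, atol=5e-4)


class TestReferenceIntensities:
    def test_flat_wilson_plot_at_zero_b(self):
        refl = generate_reference_intensities(50_000, wilson_b=0.0, seed=2)
        lo = refl.intensity[refl.s < np.median(refl.s)].mean()
        hi = refl.intensity[refl.s >= np.median(refl.s)].mean()
        assert lo == pytest.approx(hi, rel=0.05)

    def test_wilson_b_recovered_by_log_linear_fit(self):
        """Least-squares fit of ln<I> vs s² recovers the generating B."""
        refl = generate_reference_intensities(100_000, wilson_b=20.0, seed=3)
        bins = np.quantile(refl.s, np.linspace(0, 1, 21))
        idx = np.clip(np.digitize(refl.s, bins) - 1, 0, 19)
        s2 = np.array([(refl.s[idx == b] ** 2).mean() for b in range(20)])
        lin = np.array([np.log(refl.intensity[idx == b].mean()) for b in range(20)])
        slope = np.polyfit(s2, lin, 1)[0]
        assert -slope / 2.0 == pytest.approx(20.0, rel=0.05)

    def test_cumulative_distribution_is_acentric(self):
        refl = generate_reference_intensities(100_000, wilson_b=0.0, seed=4)
        z = refl.intensity / refl.intensity.mean()
        grid = np.linspace(0.1, 4.0, 30)
        emp = np.searchsorted(np.sort(z), grid) / len(z)
        assert np.abs(emp - (1 - np.exp(-grid))).max() < 0.01

    def test_csv_roundtrip(self, tmp_path):
        refl = generate_reference_intensities(100, wilson_b=10.0, seed=1)
        path = tmp_path / "refl.csv"
        refl.to_csv(path)
        back = ReflectionSet.from_csv(path)
        assert np.allclose(back.s, refl.s)
        assert np.allclose(back.intensity, refl.intensity)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_reference_intensities(0)
        with pytest.raises(ValueError):
            generate_reference_intensities(10, s_range=(0.0, 0.5))
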