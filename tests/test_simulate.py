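"""Gaussian map simulation: kernel constants, oracle equivalence, grids, parsing."""

import gemmi
import numpy as np
import pytest

from cryoenhance import (
    AtomicStructure,
    GridSpec,
    auto_grid_for_structure,
    gaussian_constants,
    read_structure,
    simulate_map,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   1       2.000   1.200   0.500  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C
END
"""


def brute_force_map(structure, kernel, grid):
    """No-cutoff double loop over (voxel, atom) — the independent oracle."""
    out = np.zeros(grid.shape)
    for ix in range(grid.shape[0]):
        for iy in range(grid.shape[1]):
            for iz in range(grid.shape[2]):
                y = np.array(grid.origin) + np.array([ix, iy, iz]) * np.array(
                    grid.voxel_size)
                for z, pos, occ in zip(structure.atomic_numbers,
                                       structure.positions,
                                       structure.occupancies):
                    d2 = float(((pos - y) ** 2).sum())
                    out[ix, iy, iz] += kernel.C * z * occ * np.exp(-kernel.k * d2)
    return out


class TestGaussianConstants:
    def test_unit_k_construction(self):
        r0 = np.sqrt(np.pi) / 0.9
        spec = gaussian_constants(r0)
        assert spec.k == pytest.approx(1.0, rel=1e-12)
        assert spec.C == pytest.approx(np.pi**-1.5, rel=1e-12)

    def test_direct_arithmetic(self):
        spec = gaussian_constants(3.0)
        assert spec.k == pytest.approx(np.pi / 2.7**2, rel=1e-12)
        assert spec.C == pytest.approx((np.pi / 2.7**2 / np.pi) ** 1.5, rel=1e-12)

    @pytest.mark.parametrize("r0", [1.0, 2.45, 3.55, 7.0])
    def test_normalization_identity(self, r0):
        spec = gaussian_constants(r0)
        assert spec.C * (np.pi / spec.k) ** 1.5 == pytest.approx(1.0, rel=1e-12)

    def test_cutoff_keeps_peak_fraction(self):
        spec = gaussian_constants(4.0)
        assert np.exp(-spec.k * spec.cutoff_radius**2) <= 1e-4 * (1 + 1e-12)

    def test_alternative_parenthesization(self):
        spec = gaussian_constants(3.0, k_convention="squared-ratio")
        assert spec.k == pytest.approx((np.pi / 2.7) ** 2, rel=1e-12)


class TestSimulateMap:
    def test_single_atom_closed_form(self):
        r0 = np.sqrt(np.pi) / 0.9  # k = 1
        kernel = gaussian_constants(r0)
        structure = AtomicStructure(["C"], [6], [[4.0, 4.0, 4.0]], [1.0])
        grid = GridSpec((9, 9, 9), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        dmap = simulate_map(structure, kernel, grid)
        peak = 6 * np.pi**-1.5
        assert dmap.data[4, 4, 4] == pytest.approx(peak, rel=1e-12)
        assert dmap.data[4, 4, 5] == pytest.approx(peak * np.exp(-1.0), rel=1e-12)

    def test_linearity_two_identical_atoms(self):
        kernel = gaussian_constants(3.0)
        grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        one = simulate_map(AtomicStructure(["C"], [6], [[3.5, 3.5, 3.5]], [1.0]),
                           kernel, grid)
        two = simulate_map(
            AtomicStructure(["C", "C"], [6, 6],
                            [[3.5, 3.5, 3.5], [3.5, 3.5, 3.5]], [1.0, 1.0]),
            kernel, grid)
        np.testing.assert_allclose(two.data, 2 * one.data, rtol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        n = 20
        structure = AtomicStructure(
            ["C"] * n,
            rng.integers(6, 9, n),
            rng.uniform(3, 13, (n, 3)),
            np.ones(n),
        )
        kernel = gaussian_constants(4.0)
        grid = GridSpec((16, 16, 16), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        fast = simulate_map(structure, kernel, grid).data
        slow = brute_force_map(structure, kernel, grid)
        assert np.abs(fast - slow).max() <= 1e-4 * slow.max()

    def test_unit_integral_per_atomic_number(self):
        # C normalizes each atom's Gaussian to integrate to A_i
        kernel = gaussian_constants(3.0)
        voxel = 0.25 / np.sqrt(kernel.k)
        n = int(np.ceil(12.0 / voxel))
        grid = GridSpec((n, n, n), (voxel,) * 3, (0.0, 0.0, 0.0))
        center = [n * voxel / 2] * 3
        dmap = simulate_map(AtomicStructure(["O"], [8], [center], [1.0]), kernel, grid)
        integral = dmap.data.sum() * voxel**3
        assert integral == pytest.approx(8.0, rel=0.01)

    def test_translation_equivariance_by_whole_voxels(self, rng):
        kernel = gaussian_constants(4.0)
        grid = GridSpec((20, 20, 20), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        pos = rng.uniform(7, 10, (5, 3))
        s1 = AtomicStructure(["C"] * 5, [6] * 5, pos, np.ones(5))
        s2 = AtomicStructure(["C"] * 5, [6] * 5, pos + [2.0, 0.0, 0.0], np.ones(5))
        m1 = simulate_map(s1, kernel, grid).data
        m2 = simulate_map(s2, kernel, grid).data
        np.testing.assert_allclose(m2[6:16], m1[4:14], atol=1e-9)

    def test_structure_outside_grid_warns_and_zeroes(self):
        kernel = gaussian_constants(3.0)
        grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        far = AtomicStructure(["C"], [6], [[100.0, 100.0, 100.0]], [1.0])
        with pytest.warns(UserWarning, match="outside"):
            dmap = simulate_map(far, kernel, grid)
        assert not dmap.data.any()

    def test_occupancy_weighting(self):
        kernel = gaussian_constants(3.0)
        grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        full = simulate_map(AtomicStructure(["C"], [6], [[4, 4, 4]], [1.0]),
                            kernel, grid)
        half = simulate_map(AtomicStructure(["C"], [6], [[4, 4, 4]], [0.5]),
                            kernel, grid)
        np.testing.assert_allclose(half.data, 0.5 * full.data, rtol=1e-12)


class TestAutoGrid:
    def test_single_atom_symmetric_box(self):
        s = AtomicStructure(["C"], [6], [[0.0, 0.0, 0.0]], [1.0])
        grid = auto_grid_for_structure(s, voxel_size=1.0, padding=4.0)
        assert grid.shape == (9, 9, 9)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_span_arithmetic(self):
        s = AtomicStructure(["C", "C"], [6, 6], [[0, 0, 0], [10, 0, 0]], [1, 1])
        grid = auto_grid_for_structure(s, voxel_size=1.0, padding=5.0)
        assert grid.shape[0] == 21

    def test_atoms_are_interior(self, helix_structure):
        grid = auto_grid_for_structure(helix_structure, 1.0, padding=4.0)
        lo = np.array(grid.origin)
        hi = lo + (np.array(grid.shape) - 1) * np.array(grid.voxel_size)
        margin = 4.0 - 1.0
        assert (helix_structure.positions >= lo + margin - 1e-9).all()
        assert (helix_structure.positions <= hi - margin + 1e-9).all()


class TestReadStructure:
    def test_minimal_pdb_atomic_numbers(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        s = read_structure(path)
        assert list(s.atomic_numbers) == [7, 6, 8]

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        s = read_structure(path)
        assert len(s) == 1
        assert s.positions[0, 0] == pytest.approx(1.0)

    def test_pdb_and_mmcif_agree(self, tmp_path):
        pdb_path = tmp_path / "mini.pdb"
        pdb_path.write_text(MINIMAL_PDB)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "mini.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = read_structure(pdb_path)
        b = read_structure(cif_path)
        assert list(a.atomic_numbers) == list(b.atomic_numbers)
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-3)

    def test_hydrogen_exclusion_flag(self, tmp_path):
        path = tmp_path / "h.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00"
            "           N\n"
            "ATOM      2  H   ALA A   1       0.500   0.500   0.000  1.00  0.00"
            "           H\nEND\n"
        )
        with_h = read_structure(path, include_hydrogens=True)
        without = read_structure(path, include_hydrogens=False)
        assert len(with_h) == 2
        assert len(without) == 1
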