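import numpy as np
import pytest

from qsar3d.conformers import LJ_EPSILON, lj_epsilon
from qsar3d.fields import (
    COULOMB_CONSTANT,
    FieldBlock,
    FieldError,
    GridSpec,
    ProbeSpec,
    assemble_descriptors,
    build_grid,
    comfa_blocks,
    comfa_fields,
    comsia_blocks,
    comsia_fields,
    filter_columns,
    read_grid_map,
    write_grid_map,
)


class TestGrid:
    def test_single_atom_default_box(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]])
        grid = build_grid([mol], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_larger_margin_gives_superset(self, toy_mol_factory):
        mol = toy_mol_factory(["C", "O"], [[0.3, -1.2, 0.7], [2.1, 0.4, -0.9]])
        small = build_grid([mol], spacing=2.0, margin=4.0)
        large = build_grid([mol], spacing=2.0, margin=6.0)
        pts_small = {tuple(p) for p in small.points().round(9)}
        pts_large = {tuple(p) for p in large.points().round(9)}
        assert pts_small <= pts_large

    def test_all_atoms_strictly_inside(self, dmp, dbp):
        grid = build_grid([dmp, dbp])
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        coords = np.vstack([dmp.coords, dbp.coords])
        assert np.all(coords > lo) and np.all(coords < hi)

    def test_empty_input_errors(self):
        with pytest.raises(FieldError):
            build_grid([])

    def test_point_order_lexicographic(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(2, 2, 2))
        pts = grid.points()
        # z varies fastest, then y, then x
        assert np.array_equal(pts[:3], [[0, 0, 0], [0, 0, 1], [0, 1, 0]])
        assert grid.n_points == 8


class TestComfa:
    def test_far_point_decays(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]], charges=[0.0])
        grid = GridSpec(origin=(50.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        steric, elec, excl = comfa_fields(mol, grid)
        assert abs(steric[0]) < 1e-4
        assert not excl[0]

    def test_point_inside_atom_clipped(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]])
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        steric, _, excl = comfa_fields(mol, grid)
        assert steric[0] == 30.0
        assert excl[0]

    def test_neutral_atom_zero_electrostatics(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]], charges=[0.0])
        grid = GridSpec(origin=(-4.0, -4.0, -4.0), spacing=2.0, dims=(5, 5, 5))
        _, elec, _ = comfa_fields(mol, grid)
        assert np.all(elec == 0.0)

    def test_two_atom_hand_oracle(self, toy_mol_factory):
        # one grid point at (4,0,0); atoms C at origin and O at (1,0,0)
        mol = toy_mol_factory(["C", "O"], [[0, 0, 0], [1, 0, 0]], charges=[0.1, -0.3])
        probe = ProbeSpec()
        grid = GridSpec(origin=(4.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        steric, elec, _ = comfa_fields(mol, grid, probe)
        expected_lj = 0.0
        from rdkit import Chem

        pt = Chem.GetPeriodicTable()
        for elem, pos, q in (("C", 0.0, 0.1), ("O", 1.0, -0.3)):
            r = 4.0 - pos
            rmin = pt.GetRvdw(pt.GetAtomicNumber(elem)) + probe.steric_radius
            eps = np.sqrt(LJ_EPSILON[elem] * probe.steric_epsilon)
            expected_lj += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        expected_elec = sum(
            COULOMB_CONSTANT * q / (4.0 - pos) ** 2 for pos, q in ((0.0, 0.1), (1.0, -0.3))
        )
        assert steric[0] == pytest.approx(expected_lj, abs=1e-10)
        assert elec[0] == pytest.approx(expected_elec, abs=1e-10)

    def test_excluded_electrostatics_replaced_by_column_mean(self, toy_mol_factory):
        # molecule A sits on the grid point (excluded), B and C are 3 A away
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        a = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]], charges=[0.5])
        b = toy_mol_factory(["C"], [[3.0, 0.0, 0.0]], charges=[0.2])
        c = toy_mol_factory(["C"], [[0.0, 3.0, 0.0]], charges=[-0.4])
        S, E = comfa_blocks([a, b, c], grid)
        _, eb, _ = comfa_fields(b, grid)
        _, ec, _ = comfa_fields(c, grid)
        assert E.matrix[0, 0] == pytest.approx((eb[0] + ec[0]) / 2)


class TestComsia:
    def test_atom_at_grid_point_contribution(self, toy_mol_factory):
        mol = toy_mol_factory(
            ["C"], [[0.0, 0.0, 0.0]], charges=[0.25], hydrophobic=[0.5],
            donor=[True], acceptor=[True],
        )
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        vals = comsia_fields(mol, grid)
        assert vals["CoMSIA_E"][0] == pytest.approx(-0.25)
        assert vals["CoMSIA_H"][0] == pytest.approx(-0.5)
        assert vals["CoMSIA_D"][0] == pytest.approx(-1.0)
        assert vals["CoMSIA_A"][0] == pytest.approx(-1.0)
        assert vals["CoMSIA_S"][0] == pytest.approx(-float(mol.vdw_radius[0] ** 3))

    def test_decay_to_zero(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]], charges=[1.0])
        grid = GridSpec(origin=(40.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        vals = comsia_fields(mol, grid)
        for arr in vals.values():
            assert abs(arr[0]) < 1e-12

    def test_two_atom_hand_oracle(self, toy_mol_factory):
        mol = toy_mol_factory(
            ["C", "O"], [[0, 0, 0], [1.5, 0, 0]], charges=[0.2, -0.4]
        )
        grid = GridSpec(origin=(1.0, 1.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        vals = comsia_fields(mol, grid, ProbeSpec(alpha=0.3))
        r2 = [1.0 + 1.0, 0.25 + 1.0]
        expected = -(0.2 * np.exp(-0.3 * r2[0]) + (-0.4) * np.exp(-0.3 * r2[1]))
        assert vals["CoMSIA_E"][0] == pytest.approx(expected, abs=1e-12)

    def test_everywhere_finite_and_bounded(self, dmp):
        grid = build_grid([dmp])
        vals = comsia_fields(dmp, grid)
        for kind, arr in vals.items():
            assert np.all(np.isfinite(arr))
        bound = float(np.abs(dmp.charges).sum())
        assert np.max(np.abs(vals["CoMSIA_E"])) <= bound + 1e-12

    def test_missing_annotations_error(self, toy_mol_factory):
        mol = toy_mol_factory(["C"], [[0.0, 0.0, 0.0]])
        mol.charges = None
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        with pytest.raises(FieldError, match="charges"):
            comsia_fields(mol, grid)


class TestTranslationInvariance:
    def test_fields_unchanged_when_grid_moves_with_molecule(self, dmp):
        grid = build_grid([dmp])
        shift = np.array([3.1, -2.7, 0.9])
        moved = dmp.with_coords(dmp.coords + shift)
        s0, e0, _ = comfa_fields(dmp, grid)
        s1, e1, _ = comfa_fields(moved, grid.translate(shift))
        assert np.max(np.abs(s0 - s1)) < 1e-10
        assert np.max(np.abs(e0 - e1)) < 1e-10
        c0 = comsia_fields(dmp, grid)
        c1 = comsia_fields(moved, grid.translate(shift))
        for kind in c0:
            assert np.max(np.abs(c0[kind] - c1[kind])) < 1e-10


class TestFilterAndAssemble:
    def _block(self, matrix, kind="CoMFA_S"):
        return FieldBlock(kind, np.asarray(matrix, float),
                          np.ones(np.asarray(matrix).shape[1], bool))

    def test_constant_column_masked(self):
        block = self._block([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        out = filter_columns(block, min_sigma=0.1)
        assert list(out.mask) == [False, True]

    def test_zero_threshold_keeps_all(self):
        block = self._block([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        out = filter_columns(block, min_sigma=0.0)
        assert out.mask.all()

    def test_known_stdevs(self):
        m = np.zeros((3, 4))
        m[:, 2] = [0.0, 5.0, 10.0]  # only varying column
        out = filter_columns(self._block(m), min_sigma=1.0)
        assert list(np.flatnonzero(out.mask)) == [2]

    def test_all_masked_errors(self):
        block = self._block(np.ones((3, 3)))
        with pytest.raises(FieldError, match="lower the threshold"):
            filter_columns(block, min_sigma=0.5)

    def test_single_block_scaling(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        block = self._block(m)
        X, index_map = assemble_descriptors([block])
        assert np.allclose(X, m / m.std(ddof=0))
        assert index_map == [("CoMFA_S", 0), ("CoMFA_S", 1)]

    def test_duplicate_blocks_identical_ranges(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        X, _ = assemble_descriptors(
            [self._block(m, "CoMFA_S"), self._block(m.copy(), "CoMFA_E")]
        )
        assert np.allclose(X[:, :2], X[:, 2:])

    def test_index_map_bijection(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((4, 6))
        block = filter_columns(self._block(m), min_sigma=0.0)
        block.mask[1] = False
        X, index_map = assemble_descriptors([block])
        assert len(index_map) == X.shape[1]
        assert len(set(index_map)) == len(index_map)
        retained = [j for j in range(6) if j != 1]
        assert [g for _, g in index_map] == retained

    def test_mismatched_compound_counts_error(self):
        a = self._block(np.ones((3, 2)) * [[1], [2], [3]])
        b = self._block(np.ones((4, 2)) * [[1], [2], [3], [4]], "CoMFA_E")
        with pytest.raises(FieldError, match="compounds"):
            assemble_descriptors([a, b])


class TestReproducibility:
    def test_bit_identical_descriptor_matrices(self, dataset):
        from qsar3d.pipeline import RunConfig, build_descriptors

        smiles = {a: dataset.registry[a].smiles for a in ("DMP", "DEP", "DAP")}
        cfg = RunConfig(method="comsia")
        X1, im1, g1, _ = build_descriptors(dict(smiles), cfg)
        X2, im2, g2, _ = build_descriptors(dict(smiles), cfg)
        assert np.array_equal(X1, X2)
        assert im1 == im2 and g1 == g2


class TestGridMapIO:
    def test_round_trip(self, tmp_path):
        grid = GridSpec(origin=(-2.0, 0.0, 1.0), spacing=2.0, dims=(2, 3, 2))
        values = np.linspace(-1, 1, grid.n_points)
        path = tmp_path / "field.grid.txt"
        write_grid_map(grid, values, path)
        grid2, values2 = read_grid_map(path)
        assert grid2 == grid
        assert np.array_equal(values, values2)


def test_lj_epsilon_defaults():
    eps = lj_epsilon(["C", "O", "Xx"])
    assert eps[0] == LJ_EPSILON["C"]
    assert eps[2] == 0.1
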