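"""Lattice geometry and interaction-field computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldqsar.chem_data import Atom, Molecule
from fieldqsar.fields import (
    COULOMB_CONSTANT,
    GridSpec,
    apply_min_sigma,
    assemble_descriptor_matrix,
    build_grid,
    compute_mif,
    coulomb_energy,
    get_probe,
    lj_energy,
    load_vdw_table,
)


def _atom(sybyl="C.3", pos=(0, 0, 0), charge=0.0):
    return Atom(sybyl.split(".")[0], sybyl, np.array(pos, dtype=float), charge)


def _mol(mol_id, atoms):
    return Molecule(mol_id, atoms, [])


@pytest.fixture(scope="module")
def probe():
    return get_probe("C.3")


class TestBuildGrid:
    def test_two_atom_box_point_counts(self, probe):
        m = _mol("m", [_atom(pos=(0, 0, 0)), _atom(pos=(3, 0, 0))])
        grid = build_grid([m], spacing=1.0, extension=5.0)
        assert grid.npoints == (14, 11, 11)

    def test_single_atom_coarse_grid(self, probe):
        m = _mol("m", [_atom()])
        with pytest.warns(UserWarning):  # spacing 5 outside the usual range
            grid = build_grid([m], spacing=5.0, extension=5.0)
        assert grid.npoints == (3, 3, 3)

    def test_zero_spacing_is_an_error(self):
        m = _mol("m", [_atom()])
        with pytest.raises(ValueError):
            build_grid([m], spacing=0.0, extension=5.0)

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            build_grid([], spacing=1.0, extension=5.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_npoints_matches_brute_force_enumeration(self, seed):
        """Point count equals brute-force marching from the box edge."""
        rng = np.random.default_rng(seed)
        lo = rng.uniform(-10, 0, 3)
        hi = lo + rng.uniform(0.5, 12, 3)
        spacing = rng.uniform(0.3, 3.0)
        extension = rng.uniform(5.0, 10.0)
        atoms = [_atom(pos=lo), _atom(pos=hi)]
        grid = build_grid([_mol("m", atoms)], spacing, extension, force=True)
        for axis in range(3):
            span = (hi[axis] + extension) - (lo[axis] - extension)
            count = 1
            while (count) * spacing <= span + 1e-9:
                count += 1
            assert grid.npoints[axis] == count

    def test_margin_spans_at_least_extension_minus_spacing(self):
        rng = np.random.default_rng(5)
        atoms = [_atom(pos=rng.uniform(-4, 4, 3)) for _ in range(6)]
        m = _mol("m", atoms)
        grid = build_grid([m], spacing=2.0, extension=6.0)
        coords = m.coords_array()
        lo_margin = coords.min(axis=0) - np.asarray(grid.origin)
        hi_margin = grid.max_corner() - coords.max(axis=0)
        assert np.all(lo_margin >= 6.0 - 2.0 - 1e-9)
        assert np.all(hi_margin >= 6.0 - 2.0 - 1e-9)

    def test_point_ordering_is_x_fastest(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, npoints=(3, 2, 2),
                        extension=0.0)
        pts = grid.points()
        np.testing.assert_allclose(pts[0], [0, 0, 0])
        np.testing.assert_allclose(pts[1], [1, 0, 0])
        np.testing.assert_allclose(pts[3], [0, 1, 0])
        np.testing.assert_allclose(pts[6], [0, 0, 1])
        for k in (0, 1, 3, 6, 11):
            np.testing.assert_allclose(grid.point(k), pts[k])


class TestPairEnergies:
    def test_lj_minimum_depth_and_decay(self, probe):
        a = _atom("O.3")
        r_o, eps_o = load_vdw_table()["O.3"]
        rij = probe.vdw_radius + r_o
        eps = np.sqrt(probe.well_depth * eps_o)
        assert lj_energy(probe, a, rij) == pytest.approx(-eps, abs=1e-12)
        assert abs(lj_energy(probe, a, 10 * rij)) < 1e-5 * eps
        # r = R/2: (2^12 - 2*2^6) = 3968 epsilon
        assert lj_energy(probe, a, rij / 2) == pytest.approx(3968 * eps, rel=1e-12)

    def test_lj_unknown_type_names_it(self, probe):
        with pytest.raises(KeyError, match="X.9"):
            lj_energy(probe, _atom("X.9"), 3.0)

    @pytest.mark.parametrize(
        "qp,qa,r,dielectric,expected",
        [
            (1.0, 1.0, 1.0, 1.0, COULOMB_CONSTANT),
            (1.0, 0.0, 2.0, 1.0, 0.0),
            (1.0, -0.5, 2.0, "distance_dependent", COULOMB_CONSTANT * -0.5 / 4),
        ],
    )
    def test_coulomb_closed_form(self, qp, qa, r, dielectric, expected):
        assert coulomb_energy(qp, qa, r, dielectric) == pytest.approx(
            expected, abs=1e-10)

    def test_closed_form_oracle_over_random_draws(self, probe):
        """1000 random (type, r) draws against the explicit 12-6 + Coulomb
        formulas evaluated independently."""
        rng = np.random.default_rng(42)
        table = load_vdw_table()
        types = list(table)
        for _ in range(1000):
            t = types[rng.integers(len(types))]
            r = float(rng.uniform(0.5, 12.0))
            radius, depth = table[t]
            rij = probe.vdw_radius + radius
            eps = np.sqrt(probe.well_depth * depth)
            expected_lj = eps * ((rij / r) ** 12 - 2 * (rij / r) ** 6)
            assert lj_energy(probe, _atom(t), r) == pytest.approx(
                expected_lj, abs=max(1e-10, 1e-10 * abs(expected_lj)))
            q = float(rng.uniform(-1, 1))
            expected_c = 332.0716 * 1.0 * q / r ** 2
            assert coulomb_energy(1.0, q, r) == pytest.approx(expected_c, abs=1e-10)


class TestComputeMif:
    def test_single_atom_minimum_and_zero_charge(self, probe):
        a = _atom("C.3", (0, 0, 0), 0.0)
        rij = 2 * probe.vdw_radius
        eps = probe.well_depth
        grid = GridSpec(origin=(rij, 0, 0), spacing=1.0, npoints=(1, 1, 1),
                        extension=0.0)
        steric, ele = compute_mif([_mol("m", [a])], grid, probe, cutoff=30.0)
        assert steric.matrix[0, 0] == pytest.approx(-eps, abs=1e-12)
        assert ele.matrix[0, 0] == 0.0

    def test_point_on_nucleus_truncates_to_cutoff(self, probe):
        a = _atom("C.3", (0, 0, 0), 0.0)
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, npoints=(1, 1, 1),
                        extension=0.0)
        steric, _ = compute_mif([_mol("m", [a])], grid, probe, cutoff=30.0)
        assert steric.matrix[0, 0] == 30.0

    def test_additivity_against_single_atom_oracle(self, probe):
        """Two-atom molecule = sum of its single-atom fields (pre-cutoff)."""
        a1 = _atom("C.3", (-2, 0, 0), 0.2)
        a2 = _atom("N.3", (2, 0, 0), -0.3)
        grid = GridSpec(origin=(0, 4, 0), spacing=1.0, npoints=(1, 1, 1),
                        extension=0.0)
        s12, e12 = compute_mif([_mol("m", [a1, a2])], grid, probe, cutoff=1e9)
        s1, e1 = compute_mif([_mol("m", [a1])], grid, probe, cutoff=1e9)
        s2, e2 = compute_mif([_mol("m", [a2])], grid, probe, cutoff=1e9)
        assert s12.matrix[0, 0] == pytest.approx(
            s1.matrix[0, 0] + s2.matrix[0, 0], abs=1e-10)
        assert e12.matrix[0, 0] == pytest.approx(
            e1.matrix[0, 0] + e2.matrix[0, 0], abs=1e-10)

    def test_equidistant_point_doubles_single_atom_value(self, probe):
        a1 = _atom("C.3", (-3, 0, 0), 0.0)
        a2 = _atom("C.3", (3, 0, 0), 0.0)
        d = 4.0
        yoff = np.sqrt(d ** 2 - 3.0 ** 2)
        grid = GridSpec(origin=(0, yoff, 0), spacing=1.0, npoints=(1, 1, 1),
                        extension=0.0)
        s, _ = compute_mif([_mol("m", [a1, a2])], grid, probe, cutoff=30.0)
        single = lj_energy(probe, a1, d)
        assert s.matrix[0, 0] == pytest.approx(2 * single, abs=1e-10)

    def test_cutoff_bounds_every_entry(self, default_fixture):
        for block in (default_fixture.steric, default_fixture.electrostatic):
            assert np.all(np.abs(block.matrix) <= block.cutoff + 1e-12)

    def test_translation_equivariance(self, probe):
        rng = np.random.default_rng(0)
        atoms = [_atom("C.3", rng.uniform(-2, 2, 3), float(rng.uniform(-0.3, 0.3)))
                 for _ in range(4)]
        m = _mol("m", atoms)
        grid = build_grid([m], 1.5, 5.0)
        s1, e1 = compute_mif([m], grid, probe, cutoff=30.0)
        shift = np.array([3.7, -1.2, 0.9])
        m2 = m.with_coords(m.coords_array() + shift)
        grid2 = GridSpec(origin=tuple(np.asarray(grid.origin) + shift),
                         spacing=grid.spacing, npoints=grid.npoints,
                         extension=grid.extension)
        s2, e2 = compute_mif([m2], grid2, probe, cutoff=30.0)
        np.testing.assert_allclose(s2.matrix, s1.matrix, atol=1e-10)
        np.testing.assert_allclose(e2.matrix, e1.matrix, atol=1e-10)

    def test_missing_charges_refused_with_molecule_list(self, probe):
        bad = Molecule("uncharged", [Atom("C", "C.3", np.zeros(3), None)], [])
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, npoints=(2, 2, 2),
                        extension=0.0)
        with pytest.raises(ValueError, match="uncharged"):
            compute_mif([bad], grid, probe, cutoff=30.0)

    def test_buried_points_filled_with_column_mean(self, probe):
        # one bulky molecule buries the point; the other does not
        big = _mol("big", [_atom("C.3", (0, 0, 0), 0.5)])
        small = _mol("small", [_atom("H", (4, 0, 0), 0.1)])
        grid = GridSpec(origin=(0.2, 0, 0), spacing=1.0, npoints=(1, 1, 1),
                        extension=0.0)
        _, ele = compute_mif([big, small], grid, probe, cutoff=30.0)
        # the buried row (big) is replaced by the mean over non-buried rows
        assert ele.matrix[0, 0] == pytest.approx(ele.matrix[1, 0], abs=1e-12)


class TestMinSigma:
    def _block(self, matrix, probe):
        n_pts = matrix.shape[1]
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, npoints=(n_pts, 1, 1),
                        extension=0.0)
        from fieldqsar.fields import FieldBlock
        return FieldBlock("steric", matrix, grid, probe, 30.0,
                          [f"m{k}" for k in range(matrix.shape[0])])

    def test_constant_column_masked(self, probe):
        m = np.column_stack([np.ones(5), np.arange(5.0)])
        out = apply_min_sigma(self._block(m, probe), 0.05)
        assert out.column_mask.tolist() == [False, True]

    def test_min_sigma_zero_keeps_everything(self, probe):
        m = np.column_stack([np.ones(5), np.arange(5.0)])
        out = apply_min_sigma(self._block(m, probe), 0.0)
        assert out.column_mask.all()

    def test_boundary_column_is_kept(self, probe):
        rng = np.random.default_rng(3)
        cols = []
        for target_sd in (0.04, 0.05, 0.6):
            v = rng.normal(size=8)
            v = v / v.std(ddof=1) * target_sd
            cols.append(v)
        out = apply_min_sigma(self._block(np.column_stack(cols), probe), 0.05)
        assert out.column_mask.tolist() == [False, True, True]


class TestAssemble:
    def test_single_field_equals_masked_block(self, default_fixture):
        fx = default_fixture
        dm = assemble_descriptor_matrix([fx.steric, fx.electrostatic], "Ste")
        np.testing.assert_array_equal(dm.X, fx.steric.retained)
        assert all(t == "steric" for t, _ in dm.provenance)

    def test_both_unscaled_concatenates(self, default_fixture):
        fx = default_fixture
        dm = assemble_descriptor_matrix(
            [fx.steric, fx.electrostatic], "Both", scaling="none")
        n_ste = fx.steric.retained.shape[1]
        n_ele = fx.electrostatic.retained.shape[1]
        assert dm.X.shape[1] == n_ste + n_ele
        assert np.all(dm.scales == 1.0)

    def test_block_scaling_equalizes_total_variance(self, default_fixture):
        fx = default_fixture
        dm = assemble_descriptor_matrix([fx.steric, fx.electrostatic], "Both")
        prov = np.array([t for t, _ in dm.provenance])
        Xs = dm.X_scaled
        v_ste = Xs[:, prov == "steric"].var(axis=0, ddof=1).sum()
        v_ele = Xs[:, prov == "electrostatic"].var(axis=0, ddof=1).sum()
        assert v_ste == pytest.approx(v_ele, rel=1e-8)

    def test_grid_mismatch_rejected(self, default_fixture, probe):
        from dataclasses import replace
        fx = default_fixture
        other = replace(fx.electrostatic,
                        grid=GridSpec(origin=(0, 0, 0), spacing=2.0,
                                      npoints=fx.grid.npoints, extension=5.0))
        with pytest.raises(ValueError, match="grid"):
            assemble_descriptor_matrix([fx.steric, other], "Both")
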