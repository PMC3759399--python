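import numpy as np
import pytest

from chemscreen.atom_properties import PROPERTY_IDS
from chemscreen.descriptors import (
    DescriptorConfig,
    DescriptorGroupSpec,
    FeatureMatrix,
    MinMaxScaler,
    assemble_feature_matrix,
    autocorrelation_2d,
    autocorrelation_3d,
    radial_distribution,
    rdf_grid,
    scalar_descriptors,
    weighted_property,
)
from chemscreen.molgraph import Molecule, NoGeometryError

from conftest import make_molecule


def brute_force_ac2d(dist, p, n_bins):
    """Independent double-loop oracle for the topological autocorrelation."""
    out = np.zeros(n_bins)
    n = len(p)
    for i in range(n):
        out[0] += p[i] * p[i]
        for j in range(i + 1, n):
            d = dist[i, j]
            if 1 <= d < n_bins:
                out[d] += p[i] * p[j]
    return out


def brute_force_rdf(coords, p, grid, b):
    out = np.zeros(len(grid))
    n = len(p)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[i] - coords[j])
            out += p[i] * p[j] * np.exp(-b * (grid - d) ** 2)
    return out


class TestScalars:
    def test_methane(self, methane):
        mw, hbd, hba, logp, charge, tpsa = scalar_descriptors(methane)
        assert mw == pytest.approx(16.04, abs=0.01)
        assert (hbd, hba, charge) == (0, 0, 0)

    def test_water_donor_acceptor_convention(self, water):
        _, hbd, hba, _, _, _ = scalar_descriptors(water)
        assert hbd == 1 and hba == 1

    def test_acetate_net_charge(self, acetate):
        assert scalar_descriptors(acetate)[4] == -1


class TestAutocorrelation2D:
    def test_two_bonded_atoms_hand_values(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)])
        out = autocorrelation_2d(mol, np.array([1.0, 2.0]), n_bins=4)
        assert out.tolist() == [5.0, 2.0, 0.0, 0.0]

    def test_all_zero_properties(self, cyclohexane):
        out = autocorrelation_2d(cyclohexane, np.zeros(6))
        assert (out == 0).all()

    def test_single_atom_self_pair(self, methane):
        out = autocorrelation_2d(methane, np.array([3.0]))
        assert out[0] == 9.0 and (out[1:] == 0).all()

    def test_matches_brute_force(self, small_library, rng):
        from chemscreen.molgraph import topological_distances

        for mol in small_library[:15]:
            p = rng.normal(size=mol.n_atoms)
            dist = topological_distances(mol)
            np.testing.assert_allclose(
                autocorrelation_2d(mol, p, 11),
                brute_force_ac2d(dist, p, 11),
                rtol=1e-12, atol=1e-12,
            )


class TestAutocorrelation3D:
    def test_two_atoms_hand_values(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)],
                            coords=[[0, 0, 0], [1.5, 0, 0]])
        out = autocorrelation_3d(mol, np.array([1.0, 1.0]), n_bins=4)
        assert out.tolist() == [2.0, 1.0, 0.0, 0.0]

    def test_boundary_pair_goes_to_upper_bin(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)],
                            coords=[[0, 0, 0], [1.0, 0, 0]])
        out = autocorrelation_3d(mol, np.array([1.0, 1.0]), n_bins=4, bin_width=1.0)
        assert out.tolist() == [2.0, 1.0, 0.0, 0.0]

    def test_no_coordinates_raises(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)])
        with pytest.raises(NoGeometryError):
            autocorrelation_3d(mol, np.ones(2))


class TestRadialDistribution:
    def test_closed_form_single_pair(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)],
                            coords=[[0, 0, 0], [1.0, 0, 0]])
        grid = rdf_grid()
        out = radial_distribution(mol, np.ones(2), grid, b=100.0)
        g = dict(zip(np.round(grid, 10), out))
        assert g[1.0] == pytest.approx(1.0)
        assert g[1.1] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_single_atom_zero(self, methane):
        assert (radial_distribution(methane, np.array([2.0])) == 0).all()

    def test_matches_brute_force(self, small_library, rng):
        grid = rdf_grid()
        for mol in small_library[:10]:
            p = rng.normal(size=mol.n_atoms)
            coords = mol.coords_array()
            np.testing.assert_allclose(
                radial_distribution(mol, p, grid),
                brute_force_rdf(coords, p, grid, 100.0),
                atol=1e-12,
            )


class TestWeighting:
    def test_elementwise_product(self):
        out = weighted_property(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert out.tolist() == [3.0, 8.0]

    def test_identity_and_zero(self):
        p = np.array([1.5, -2.0])
        assert weighted_property(p, np.ones(2)).tolist() == p.tolist()
        assert (weighted_property(p, np.zeros(2)) == 0).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_property(np.ones(2), np.ones(3))


class TestInvariance:
    def _permute(self, mol, perm):
        from chemscreen.molgraph import Atom

        inv = {old: new for new, old in enumerate(perm)}
        atoms = [mol.atoms[old] for old in perm]
        bonds = [(inv[i], inv[j], o) for i, j, o in mol.bonds]
        return Molecule(atoms=atoms, bonds=bonds, id=mol.id)

    def test_atom_permutation_invariance(self, small_library, rng):
        from chemscreen.descriptors import featurize_molecule

        config = DescriptorConfig.default()
        for mol in small_library[:4]:
            perm = rng.permutation(mol.n_atoms)
            row_a = featurize_molecule(mol, config)
            row_b = featurize_molecule(self._permute(mol, list(perm)), config)
            np.testing.assert_allclose(row_a, row_b, atol=1e-9)

    def test_rotation_translation_invariance(self, small_library, rng):
        from scipy.spatial.transform import Rotation

        for mol in small_library[:6]:
            p = rng.normal(size=mol.n_atoms)
            rot = Rotation.random(random_state=11).as_matrix()
            shifted = mol.coords_array() @ rot.T + np.array([5.0, -3.0, 1.0])
            base_ac = autocorrelation_3d(mol, p)
            base_rdf = radial_distribution(mol, p)
            moved_ac = autocorrelation_3d(mol, p, coords=shifted)
            moved_rdf = radial_distribution(mol, p, coords=shifted)
            np.testing.assert_allclose(base_ac, moved_ac, atol=1e-9)
            np.testing.assert_allclose(base_rdf, moved_rdf, atol=1e-9)


class TestAssembly:
    def test_default_catalog_dimensions(self):
        config = DescriptorConfig.default()
        assert len(config.groups) == 60
        assert config.total_length == 1284

    def test_feature_matrix_default_columns(self, small_library):
        fm = assemble_feature_matrix(small_library[:5])
        assert fm.frame.shape == (5, 1284)
        assert len(fm.group_columns) == 60
        assert not fm.frame.isna().any().any()

    def test_scalars_only_config(self, small_library):
        fm = assemble_feature_matrix(small_library[:3], DescriptorConfig.scalars_only())
        assert fm.frame.shape == (3, 6)

    def test_3d_groups_require_coords(self):
        mol = make_molecule(["C", "C"], [(0, 1, 1)])
        with pytest.raises(NoGeometryError):
            assemble_feature_matrix([mol], DescriptorConfig.default())

    def test_config_json_round_trip(self, tmp_path):
        config = DescriptorConfig.default()
        path = tmp_path / "config.json"
        config.to_json(path)
        back = DescriptorConfig.from_json(path)
        assert back.total_length == config.total_length
        assert back.group_names == config.group_names

    def test_matrix_csv_round_trip(self, small_library, tmp_path):
        fm = assemble_feature_matrix(small_library[:4])
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.compound_ids == fm.compound_ids
        np.testing.assert_allclose(back.frame.to_numpy(), fm.frame.to_numpy(), rtol=1e-9)

    def test_group_spec_validation(self):
        with pytest.raises(ValueError):
            DescriptorGroupSpec(name="bad", kind="scalar", n_bins=2)
        with pytest.raises(ValueError):
            DescriptorGroupSpec(name="bad", kind="nope")


class TestMinMaxScaler:
    def test_train_only_fit_and_constant_columns(self):
        x = np.array([[0.0, 5.0], [2.0, 5.0], [4.0, 5.0]])
        scaler = MinMaxScaler().fit(x)
        z = scaler.transform(x)
        assert z[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert (z[:, 1] == 0).all()
        # out-of-range test data maps outside [0, 1] rather than being clipped
        assert scaler.transform(np.array([[8.0, 5.0]]))[0, 0] == 2.0
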