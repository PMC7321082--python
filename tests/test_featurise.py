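import itertools

import numpy as np
import pytest

from kedge.featurise import (
    CMConfig,
    CoulombMatrix,
    FeaturisationError,
    RDCConfig,
    cm_feature,
    coulomb_matrix,
    featurise_batch,
    flatten_cm,
    max_encoded_radius,
    rdc,
    read_feature_table,
    required_cm_dimension,
    sort_cm,
    unflatten_cm,
    write_feature_table,
)
from kedge.structures import AtomSite, AtomicCluster, local_environment

from conftest import random_cluster, random_rotation, transform_cluster


def naive_coulomb_matrix(cluster, n):
    """Independent double-loop evaluation of the CM entries."""
    sub_d = sorted(
        range(len(cluster)),
        key=lambda i: (
            np.linalg.norm(cluster.sites[i].position - cluster.absorber.position),
            i,
        ),
    )[:n]
    sites = [cluster.sites[i] for i in sub_d]
    m = np.zeros((n, n))
    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            if i == j:
                m[i, j] = 0.5 * si.z**2.4
            else:
                m[i, j] = si.z * sj.z / np.linalg.norm(si.position - sj.position)
    return m


def naive_rdc(cluster, config):
    """Independent pair-enumeration evaluation of the distribution curve."""
    sub = local_environment(cluster, config.cutoff)
    out = np.zeros(len(config.grid))
    w = config.weights(sub.charges)
    for i in range(len(sub)):
        for j in range(i + 1, len(sub)):
            r = np.linalg.norm(sub.sites[i].position - sub.sites[j].position)
            out += w[i] * w[j] * np.exp(-config.alpha * (r - config.grid) ** 2)
    return out


class TestCoulombMatrix:
    def test_single_hydrogen(self):
        c = AtomicCluster([AtomSite(1, [0, 0, 0])])
        m = coulomb_matrix(c, CMConfig(n_atoms=1)).matrix
        np.testing.assert_allclose(m, [[0.5]])

    def test_hydrogen_pair_at_unit_distance(self):
        c = AtomicCluster([AtomSite(1, [0, 0, 0]), AtomSite(1, [1, 0, 0])])
        m = coulomb_matrix(c, CMConfig(n_atoms=2)).matrix
        np.testing.assert_allclose(m, [[0.5, 1.0], [1.0, 0.5]])

    def test_single_iron_free_atom_term(self):
        # 0.5 * 26**2.4 evaluated independently beforehand
        c = AtomicCluster([AtomSite(26, [0, 0, 0])])
        m = coulomb_matrix(c, CMConfig(n_atoms=1)).matrix
        np.testing.assert_allclose(m, [[1244.2453875152546]], rtol=1e-12)

    def test_matches_naive_double_loop_with_zero_fill(self, rng):
        c = random_cluster(rng, n_atoms=12)
        m = coulomb_matrix(c, CMConfig(n_atoms=20)).matrix
        np.testing.assert_allclose(
            m[:12, :12], naive_coulomb_matrix(c, 12), rtol=1e-12
        )
        assert np.all(m[12:, :] == 0) and np.all(m[:, 12:] == 0)

    def test_distance_scaling_only_rescales_off_diagonal(self, rng):
        c = random_cluster(rng, n_atoms=8)
        s = 2.5
        scaled = AtomicCluster(
            [AtomSite(site.z, site.position * s) for site in c.sites],
            c.absorber_index,
        )
        m1 = coulomb_matrix(c, CMConfig(n_atoms=8)).matrix
        m2 = coulomb_matrix(scaled, CMConfig(n_atoms=8)).matrix
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(m2[off], m1[off] / s, rtol=1e-12)
        np.testing.assert_allclose(np.diag(m2), np.diag(m1), rtol=1e-15)

    def test_bohr_unit_switch_rescales(self, rng):
        c = random_cluster(rng, n_atoms=5)
        a = coulomb_matrix(c, CMConfig(n_atoms=5, length_unit="angstrom")).matrix
        b = coulomb_matrix(c, CMConfig(n_atoms=5, length_unit="bohr")).matrix
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(b[off], a[off] * 0.529177210903, rtol=1e-12)


class TestSortCM:
    def test_already_sorted_unchanged(self):
        m = np.array([[10.0, 2.0], [2.0, 1.0]])
        out = sort_cm(CoulombMatrix(m)).matrix
        np.testing.assert_array_equal(out, m)

    def test_row_norms_non_increasing(self, rng):
        for _ in range(20):
            a = rng.normal(size=(7, 7))
            m = sort_cm(CoulombMatrix(a + a.T)).matrix
            norms = np.linalg.norm(m, axis=1)
            assert np.all(np.diff(norms) <= 1e-12)

    def test_matches_exhaustive_permutation_search(self, rng):
        a = rng.normal(size=(6, 6))
        m = a + a.T
        norms = np.linalg.norm(m, axis=1)
        best = None
        for perm in itertools.permutations(range(6)):
            seq = norms[list(perm)]
            if np.all(np.diff(seq) <= 0):
                best = list(perm)
                break
        expected = m[np.ix_(best, best)]
        np.testing.assert_allclose(
            sort_cm(CoulombMatrix(m)).matrix, expected, rtol=1e-12
        )

    def test_zero_padding_rows_sort_to_end(self, rng):
        c = random_cluster(rng, n_atoms=4)
        m = sort_cm(coulomb_matrix(c, CMConfig(n_atoms=6))).matrix
        assert np.all(m[4:, :] == 0)


class TestFlatten:
    def test_two_by_two_definition(self):
        m = CoulombMatrix(np.array([[1.0, 2.0], [2.0, 3.0]]))
        np.testing.assert_array_equal(flatten_cm(m).values, [1.0, 2.0, 3.0])

    def test_length_formula(self):
        assert CMConfig(n_atoms=20).feature_length == 210
        c = AtomicCluster([AtomSite(26, [0, 0, 0])])
        assert len(cm_feature(c, CMConfig(n_atoms=20))) == 210

    def test_round_trip_bijection(self, rng):
        a = rng.normal(size=(5, 5))
        m = CoulombMatrix(a + a.T)
        np.testing.assert_allclose(unflatten_cm(flatten_cm(m)).matrix, m.matrix)


class TestRDC:
    def test_lone_absorber_is_zero_vector(self):
        c = AtomicCluster([AtomSite(26, [0, 0, 0])])
        assert np.all(rdc(c, RDCConfig(n_points=100)).values == 0)

    def test_single_unit_charge_pair(self):
        c = AtomicCluster([AtomSite(1, [0, 0, 0]), AtomSite(1, [2, 0, 0])])
        config = RDCConfig(alpha=10.0, cutoff=4.0, grid=np.linspace(0, 8, 801))
        vals = rdc(c, config).values
        np.testing.assert_allclose(vals, np.exp(-10.0 * (2.0 - config.grid) ** 2))
        i = np.argmax(vals)
        assert config.grid[i] == pytest.approx(2.0)
        assert vals[i] == pytest.approx(1.0)

    def test_three_atoms_match_pair_enumeration(self, rng):
        c = random_cluster(rng, n_atoms=3)
        config = RDCConfig(n_points=200)
        np.testing.assert_allclose(
            rdc(c, config).values, naive_rdc(c, config), rtol=1e-12, atol=1e-300
        )

    def test_unit_weights_reduce_to_distance_kernel(self):
        c = AtomicCluster([AtomSite(26, [0, 0, 0]), AtomSite(8, [1.5, 0, 0])])
        config = RDCConfig(
            n_points=100, weight_property={26: 1.0, 8: 1.0}
        )
        expected = np.exp(-config.alpha * (1.5 - config.grid) ** 2)
        np.testing.assert_allclose(rdc(c, config).values, expected)

    def test_grid_spans_twice_cutoff_by_default(self):
        config = RDCConfig(cutoff=4.0)
        assert config.grid[0] == 0.0
        assert config.grid[-1] == pytest.approx(8.0)
        assert len(config.grid) == 800

    def test_larger_alpha_never_widens_fwhm(self):
        c = AtomicCluster([AtomSite(26, [0, 0, 0]), AtomSite(8, [2.0, 0, 0])])
        grid = np.linspace(0, 8, 4001)
        widths = []
        for alpha in (0.5, 2.0, 10.0, 50.0, 200.0):
            vals = rdc(c, RDCConfig(alpha=alpha, grid=grid)).values
            above = grid[vals >= 0.5 * vals.max()]
            widths.append(above[-1] - above[0])
        assert np.all(np.diff(widths) <= 1e-12)


class TestInvariance:
    @pytest.mark.parametrize("representation", ["cm", "rdc"])
    def test_rigid_motion_and_permutation_invariance(self, rng, representation):
        c = random_cluster(rng, n_atoms=14)
        if representation == "cm":
            ref = cm_feature(c, CMConfig(n_atoms=20)).values
            feat = lambda cl: cm_feature(cl, CMConfig(n_atoms=20)).values
        else:
            config = RDCConfig(n_points=200)
            ref = rdc(c, config).values
            feat = lambda cl: rdc(cl, config).values
        for _ in range(10):
            moved = transform_cluster(
                c,
                random_rotation(rng),
                rng.uniform(-10, 10, size=3),
                rng.permutation(len(c)),
            )
            np.testing.assert_allclose(feat(moved), ref, rtol=1e-10, atol=1e-12)


class TestBatch:
    def test_three_valid_clusters(self, rng):
        clusters = [random_cluster(rng, n_atoms=6, label=f"c{i}") for i in range(3)]
        df, failures = featurise_batch(clusters, "rdc", RDCConfig(n_points=50))
        assert df.shape == (3, 50)
        assert list(df.index) == ["c0", "c1", "c2"]
        assert failures == []

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            df, failures = featurise_batch([], "cm")
        assert df.empty and failures == []

    def test_one_corrupt_cluster_collected(self, rng):
        clusters = [random_cluster(rng, n_atoms=6, label=f"c{i}") for i in range(9)]
        clusters.insert(4, None)  # corrupt entry
        df, failures = featurise_batch(clusters, "rdc", RDCConfig(n_points=50))
        assert df.shape == (9, 50)
        assert len(failures) == 1
        assert failures[0].index == 4

    def test_all_corrupt_raises(self):
        with pytest.raises(FeaturisationError):
            featurise_batch([None, None], "rdc", RDCConfig(n_points=50))

    def test_unknown_representation(self):
        with pytest.raises(ValueError, match="representation"):
            featurise_batch([], "soap")


class TestRadiusDiagnostics:
    def test_single_shell_geometry(self, rng):
        sites = [AtomSite(26, [0, 0, 0])]
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sites += [AtomSite(8, 3.0 * d) for d in dirs]
        c = AtomicCluster(sites, 0)
        assert max_encoded_radius(c, 20) == pytest.approx(3.0)

    def test_lone_absorber(self):
        c = AtomicCluster([AtomSite(26, [0, 0, 0])])
        assert max_encoded_radius(c, 20) == 0.0
        assert required_cm_dimension(c, 4.0) == 1

    def test_sorted_distance_oracle(self, rng):
        c = random_cluster(rng, n_atoms=30, box=6.0)
        d = np.sort(c.distances_to_absorber())
        for n in (1, 10, 20, 30):
            assert max_encoded_radius(c, n) == pytest.approx(d[n - 1])
        assert max_encoded_radius(c, 50) == pytest.approx(d[-1])

    def test_count_within_radius(self, rng):
        sites = [AtomSite(26, [0, 0, 0])]
        dirs = rng.normal(size=(24, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = rng.uniform(1.5, 3.9, size=24)
        sites += [AtomSite(8, r * d) for r, d in zip(radii, dirs)]
        c = AtomicCluster(sites, 0)
        assert required_cm_dimension(c, 4.0) == 25

    def test_brute_force_count_oracle(self, rng):
        c = random_cluster(rng, n_atoms=25, box=6.0)
        expected = sum(
            1
            for s in c.sites
            if np.linalg.norm(s.position - c.absorber.position) <= 3.5
        )
        assert required_cm_dimension(c, 3.5) == expected

    def test_encoded_radius_bounds_nth_neighbour(self, rng):
        # by construction the N-th nearest atom lies exactly at the radius
        c = random_cluster(rng, n_atoms=25, box=6.0)
        r = max_encoded_radius(c, 20)
        assert required_cm_dimension(c, r) >= 20


def test_feature_table_round_trip(tmp_path, rng):
    clusters = [random_cluster(rng, n_atoms=6, label=f"c{i}") for i in range(4)]
    df, _ = featurise_batch(clusters, "cm", CMConfig(n_atoms=10))
    write_feature_table(df, tmp_path / "feats.csv")
    back = read_feature_table(tmp_path / "feats.csv")
    np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), rtol=1e-14)
    assert back.attrs["representation"] == "cm"
    assert back.attrs["config_hash"] == df.attrs["config_hash"]
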