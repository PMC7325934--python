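import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import cca as skbio_cca
from skbio.stats.ordination import pcoa as skbio_pcoa

from amplicore import multivariate as mv


def _euclid_dm(points, ids):
    return mv.DistanceMatrix(ids, squareform(pdist(points)))


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        table = pd.DataFrame({"a": [1, 1], "b": [1, 1], "c": [0, 2]})
        dm = mv.bray_curtis(table)
        assert dm.data[0, 1] == 0.0
        table2 = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        assert mv.bray_curtis(table2).data[0, 1] == 1.0

    def test_hand_computed_value(self):
        table = pd.DataFrame({"a": [1, 1], "b": [1, 0]})
        assert mv.bray_curtis(table).data[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="empty"):
            mv.bray_curtis(pd.DataFrame({"ok": [1], "empty": [0]}))

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(70)
        table = pd.DataFrame(rng.integers(0, 50, size=(20, 8)))
        dm = mv.bray_curtis(table)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)


class TestPCoA:
    def test_euclidean_round_trip(self):
        points = np.array([[0.0, 0], [3, 0], [0, 4], [5, 5]])
        res = mv.pcoa(_euclid_dm(points, list("abcd")))
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rebuilt, squareform(pdist(points)), atol=1e-8)

    def test_equilateral_three_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = mv.pcoa(mv.DistanceMatrix(list("abc"), d))
        assert res.eigenvalues.size == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(71)
        points = rng.random((6, 3))
        dm = _euclid_dm(points, [f"s{i}" for i in range(6)])
        res = mv.pcoa(dm)
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dm.data**2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            mv.pcoa(mv.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(72)
        table = pd.DataFrame(rng.integers(1, 50, size=(15, 7)))
        dm = mv.bray_curtis(table)
        ours = mv.pcoa(dm)
        theirs = skbio_pcoa(SkbioDM(dm.data, [str(i) for i in dm.ids]))
        ref_eig = np.sort(theirs.eigvals[theirs.eigvals > 1e-10].to_numpy())[::-1]
        np.testing.assert_allclose(ours.eigenvalues, ref_eig, atol=1e-8)


class TestHCluster:
    def test_hand_worked_upgma_heights(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0.0]])
        res = mv.hcluster(mv.DistanceMatrix(list("ABC"), d), "group_average")
        np.testing.assert_allclose(res.linkage[:, 2], [2.0, 6.0])

    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(73)
        points = rng.random((5, 3))
        points[3] = points[1]
        dm = _euclid_dm(points, [f"s{i}" for i in range(5)])
        res = mv.hcluster(dm, "group_average")
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {1, 3}

    def test_newick_leaf_count(self):
        rng = np.random.default_rng(74)
        dm = _euclid_dm(rng.random((7, 2)), [f"leaf{i}" for i in range(7)])
        res = mv.hcluster(dm, "ward")
        assert all(f"leaf{i}:" in res.newick for i in range(7))
        assert res.newick.count(",") == 6

    def test_ultrametric_upgma(self):
        rng = np.random.default_rng(75)
        table = pd.DataFrame(rng.integers(1, 40, size=(12, 6)))
        dm = mv.bray_curtis(table)
        res = mv.hcluster(dm, "group_average")
        from scipy.cluster.hierarchy import cophenet

        coph = cophenet(res.linkage)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()
        assert coph.max() <= res.linkage[-1, 2] + 1e-12

    def test_unknown_linkage(self):
        with pytest.raises(ValueError):
            mv.hcluster(mv.DistanceMatrix(["a", "b"], np.zeros((2, 2))), "single")


class TestPermanova:
    def _clusters(self, n_per, gap, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(0, 0.05, (n_per, 2)), rng.normal(gap, 0.05, (n_per, 2))]
        )
        ids = [f"s{i:02d}" for i in range(2 * n_per)]
        return _euclid_dm(pts, ids), np.array(["a"] * n_per + ["b"] * n_per)

    def test_p_at_least_permutation_floor(self):
        dm, labels = self._clusters(5, 10, 76)
        res = mv.permanova(dm, labels, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_deterministic_given_seed_and_order_invariant(self):
        dm, labels = self._clusters(5, 3, 77)
        r1 = mv.permanova(dm, labels, n_perm=199, seed=5)
        r2 = mv.permanova(dm, labels, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value
        # shuffle sample order, keep the same sample->label map
        perm = np.random.default_rng(0).permutation(len(dm.ids))
        dm_shuffled = mv.DistanceMatrix(
            [dm.ids[i] for i in perm], dm.data[np.ix_(perm, perm)]
        )
        labels_map = dict(zip(dm.ids, labels))
        r3 = mv.permanova(dm_shuffled, labels_map, n_perm=199, seed=5)
        assert r3.p_value == r1.p_value
        assert r3.pseudo_f == pytest.approx(r1.pseudo_f)

    def test_pseudo_f_matches_reference_implementation(self):
        dm, labels = self._clusters(6, 2, 78)
        ours = mv.permanova(dm, labels, n_perm=99, seed=1)
        theirs = skbio_permanova(
            SkbioDM(dm.data, dm.ids), grouping=list(labels), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        dm, _ = self._clusters(4, 1, 79)
        with pytest.raises(ValueError):
            mv.permanova(dm, np.array(["a"] * 8), n_perm=99)


class TestCCA:
    def _community(self, seed=80, n=12, m=8):
        rng = np.random.default_rng(seed)
        taxa = pd.DataFrame(
            rng.integers(1, 60, size=(n, m)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(m)],
        )
        env = pd.DataFrame(
            rng.random((n, 2)) * 10, index=taxa.index, columns=["thg", "tc"]
        )
        return taxa, env

    def test_one_env_variable_one_axis(self):
        taxa, env = self._community()
        res = mv.cca_fit(taxa, env[["thg"]])
        assert res.eigenvalues.size == 1

    def test_eigenvalues_bounded_by_ca_and_unit(self):
        taxa, env = self._community(81)
        res = mv.cca_fit(taxa, env)
        assert (res.eigenvalues >= 0).all() and (res.eigenvalues <= 1).all()
        for i, lam in enumerate(res.eigenvalues):
            assert lam <= res.ca_eigenvalues[i] + 1e-10

    def test_total_inertia_equals_chi_square_route(self):
        taxa, env = self._community(82)
        res = mv.cca_fit(taxa, env)
        assert res.total_inertia == pytest.approx(mv.chi_square_inertia(taxa))

    def test_group_indicator_recovers_partition_axis(self):
        # two sample groups with disjoint taxa: the group indicator explains
        # essentially all of the leading correspondence axis
        taxa = pd.DataFrame(
            0, index=[f"s{i}" for i in range(8)], columns=[f"t{j}" for j in range(4)]
        )
        rng = np.random.default_rng(83)
        taxa.iloc[:4, :2] = rng.integers(20, 40, size=(4, 2))
        taxa.iloc[4:, 2:] = rng.integers(20, 40, size=(4, 2))
        env = pd.DataFrame(
            {"group": [0.0] * 4 + [1.0] * 4}, index=taxa.index
        )
        res = mv.cca_fit(taxa, env, pretransform_env=False)
        assert res.eigenvalues[0] >= 0.9 * res.ca_eigenvalues[0]

    def test_matches_reference_implementation(self):
        taxa, env = self._community(84)
        ours = mv.cca_fit(taxa, env, pretransform_env=False)
        theirs = skbio_cca(taxa, env)
        ref_eig = theirs.eigvals.to_numpy()[: ours.eigenvalues.size]
        np.testing.assert_allclose(ours.eigenvalues, ref_eig, atol=1e-10)

    def test_constant_env_column_named(self):
        taxa, env = self._community(85)
        env["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            mv.cca_fit(taxa, env)

    def test_collinear_env_rejected_with_condition_number(self):
        taxa, env = self._community(86)
        env["thg2"] = env["thg"] * 2.0
        with pytest.raises(ValueError, match="condition number"):
            mv.cca_fit(taxa, env, pretransform_env=False)

    def test_misaligned_samples_rejected(self):
        taxa, env = self._community(87)
        with pytest.raises(ValueError, match="aligned"):
            mv.cca_fit(taxa, env.iloc[::-1])
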