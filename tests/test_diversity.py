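import numpy as np
import pandas as pd
import pytest

from microrewire.diversity import (DistanceMatrix, alpha_table,
                                   beta_dispersion, bray_curtis,
                                   compare_alpha, pcoa, permanova, shannon,
                                   simpson)
from microrewire.feature_table import (FeatureTable, attach_metadata,
                                       to_relative)


def _rel(values, samples=None, groups=None, taxa=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=taxa, columns=samples)
    meta = None
    ft = FeatureTable(data, mode="counts")
    if groups is not None:
        meta = pd.DataFrame({"sample_id": samples,
                             "dataset": ["D1"] * len(samples),
                             "group": groups})
        ft = attach_metadata(ft, meta)
    return to_relative(ft)


class TestAlphaIndices:
    def test_shannon_worked_values(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))
        assert shannon([1.0]) == 0.0
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.03972, abs=1e-5)

    def test_shannon_base_option(self):
        assert shannon([0.25] * 4, base=2) == pytest.approx(2.0)

    def test_simpson_worked_values(self):
        assert simpson([0.25] * 4) == pytest.approx(0.75)
        assert simpson([1.0]) == 0.0
        assert simpson([0.5, 0.5]) == pytest.approx(0.5)
        assert simpson([0.5, 0.5], inverse=True) == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(12))
        q = rng.permutation(p)
        assert shannon(p) == pytest.approx(shannon(q))
        assert simpson(p) == pytest.approx(simpson(q))

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            shannon([-0.1, 1.1])
        with pytest.raises(ValueError):
            simpson([0.3, 0.3])

    def test_bounds(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 10)))
            obs = (p > 0).sum()
            assert 0 <= shannon(p) <= np.log(obs) + 1e-12
            assert 0 <= simpson(p) <= 1 - 1 / obs + 1e-12


class TestAlphaTable:
    def test_observed_counts_nonzero_taxa(self):
        ft = _rel([[0.5, 0.0], [0.5, 0.2], [0.0, 0.8]],
                  groups=["case", "control"])
        tab = alpha_table(ft)
        assert list(tab["observed"]) == [2, 2]
        assert len(tab) == 2
        assert tab.loc["S0", "shannon"] == pytest.approx(np.log(2))

    def test_compare_alpha_exact_small_sample(self):
        # H-values disjoint between groups of 2: exact two-sided p = 1/3
        alpha = pd.DataFrame({
            "observed": [1, 2, 3, 4],
            "shannon": [1.0, 2.0, 3.0, 4.0],
            "simpson": [0.1, 0.2, 0.3, 0.4],
            "group": ["case", "case", "control", "control"],
        }, index=["S1", "S2", "S3", "S4"])
        res = compare_alpha(alpha)
        assert res.loc["shannon", "p"] == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        alpha = pd.DataFrame({
            "observed": [3, 4, 3, 4],
            "shannon": [1.0, 2.0, 1.0, 2.0],
            "simpson": [0.5, 0.6, 0.5, 0.6],
            "group": ["case", "case", "control", "control"],
        }, index=list("abcd"))
        res = compare_alpha(alpha)
        assert res.loc["shannon", "p"] > 0.6


class TestBrayCurtis:
    def test_worked_values(self):
        ft = _rel(np.array([[0.5, 0.0], [0.0, 0.5], [0.5, 0.5]]))
        dm = bray_curtis(ft)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_identity_symmetry_bounds(self, rng):
        x = rng.dirichlet(np.ones(6), size=8).T
        dm = bray_curtis(_rel(x))
        assert np.allclose(np.diag(dm.values), 0)
        assert np.allclose(dm.values, dm.values.T)
        assert (dm.values >= 0).all() and (dm.values <= 1 + 1e-12).all()

    def test_identical_columns_zero(self):
        ft = _rel(np.array([[0.3, 0.3], [0.7, 0.7]]))
        assert bray_curtis(ft).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        ft = _rel(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert bray_curtis(ft).values[0, 1] == pytest.approx(1.0)


def _euclidean_dm(points):
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix([f"S{i}" for i in range(len(points))], d)


class TestPcoa:
    def test_collinear_points(self):
        dm = _euclidean_dm([[0.0], [1.0], [2.0]])
        res = pcoa(dm, k=2)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0, 0.0],
                                   atol=1e-10)
        axis1 = res.coordinates["PC1"].to_numpy()
        assert np.allclose(np.abs(axis1), [1.0, 0.0, 1.0], atol=1e-8)

    def test_recovers_euclidean_distances(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = _euclidean_dm(pts)
        res = pcoa(dm, k=6)
        coords = res.coordinates.to_numpy()
        from scipy.spatial.distance import pdist, squareform
        d_hat = squareform(pdist(coords))
        np.testing.assert_allclose(d_hat, dm.values, atol=1e-8)

    def test_equilateral_degenerate_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(["a", "b", "c"], d)
        res = pcoa(dm, k=2)
        pos = res.eigenvalues[res.eigenvalues > 0]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_procrustes_recovery(self, rng):
        """Embedding known coordinates reproduces them up to rotation."""
        from scipy.spatial import procrustes
        pts = rng.normal(size=(10, 2))
        res = pcoa(_euclidean_dm(pts), k=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-12

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.dirichlet(np.ones(5), size=6).T
        dm = bray_curtis(_rel(x))
        res = pcoa(dm, k=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.ids))
        np.testing.assert_allclose(
            np.sort(res.eigenvalues)[::-1][:3],
            ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_k_out_of_range(self):
        dm = _euclidean_dm([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            pcoa(dm, k=3)


class TestPermanova:
    def test_separated_clusters_significant(self, rng):
        a = rng.normal(0, 1, size=(10, 2))
        b = rng.normal(100, 1, size=(10, 2))
        dm = _euclidean_dm(np.vstack([a, b]))
        groups = ["g1"] * 10 + ["g2"] * 10
        res = permanova(dm, groups, n_permutations=999, seed=5)
        assert res.p <= 0.005
        assert res.r2 > 0.9

    def test_sample_order_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        dm = _euclidean_dm(pts)
        res1 = permanova(dm, groups, n_permutations=99, seed=1)
        perm = rng.permutation(12)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        res2 = permanova(dm2, groups[perm], n_permutations=99, seed=1)
        assert res1.f == pytest.approx(res2.f)

    def test_matches_scikit_bio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        pts = rng.normal(size=(14, 3))
        groups = ["a"] * 7 + ["b"] * 7
        dm = _euclidean_dm(pts)
        res = permanova(dm, groups, n_permutations=9, seed=0)
        ref = sk_permanova(skbio.DistanceMatrix(dm.values, dm.ids),
                           grouping=list(groups), permutations=9)
        assert res.f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_rejected(self, rng):
        dm = _euclidean_dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 6)

    def test_deterministic_p_under_seed(self, rng):
        dm = _euclidean_dm(rng.normal(size=(10, 2)))
        groups = ["a"] * 5 + ["b"] * 5
        p1 = permanova(dm, groups, n_permutations=199, seed=42).p
        p2 = permanova(dm, groups, n_permutations=199, seed=42).p
        assert p1 == p2


class TestBetaDispersion:
    def test_identical_group_zero_dispersion(self):
        pts = [[0, 0], [0, 0], [0, 0], [1, 0], [2, 0], [3, 0]]
        dm = _euclidean_dm(pts)
        res = beta_dispersion(dm, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(res.distances.iloc[:3], 0.0)

    def test_mirror_groups_equal_dispersion(self, rng):
        a = rng.normal(size=(20, 2))
        b = -a  # mirror image: identical spread
        dm = _euclidean_dm(np.vstack([a, b]))
        res = beta_dispersion(dm, ["a"] * 20 + ["b"] * 20)
        mean_a = res.distances.iloc[:20].mean()
        mean_b = res.distances.iloc[20:].mean()
        assert mean_a == pytest.approx(mean_b, rel=1e-9)
        assert res.p > 0.99

    def test_tight_vs_diffuse_group_detected(self, rng):
        tight = rng.normal(0, 0.1, size=(50, 3))
        diffuse = rng.normal(0, 3.0, size=(50, 3))
        dm = _euclidean_dm(np.vstack([tight, diffuse]))
        res = beta_dispersion(dm, ["t"] * 50 + ["d"] * 50)
        assert res.f > 10
        assert res.p < 0.05

    def test_singleton_group_warns(self, rng):
        dm = _euclidean_dm(rng.normal(size=(4, 2)))
        with pytest.warns(UserWarning, match="single sample"):
            res = beta_dispersion(dm, ["a", "b", "b", "b"])
        assert res.distances.iloc[0] == 0.0
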