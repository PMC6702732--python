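import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from virosift import clustering, profiles
from virosift.clustering import (
    classify_signature,
    cluster_profiles,
    correlation_matrix,
    correlation_to_distance,
    cut_clusters,
    to_newick,
    upgma,
)
from virosift.profiles import ZProfile

from _oracles import upgma_heights
from conftest import random_profile


def _z(contig_id, values, **kw):
    v = np.asarray(values, dtype=float)
    return ZProfile(contig_id, (v - v.mean()) / v.std(), **kw)


def _random_dist(rng, n):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        zs = [_z("a", rng.random(42)), _z("b", rng.random(42))]
        corr = correlation_matrix(zs)
        assert np.allclose(np.diag(corr), 1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(2)
        v = rng.random(42)
        corr = correlation_matrix([_z("a", v), _z("b", -v)])
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        zs = [_z(f"p{i}", rng.random(42)) for i in range(3)]
        corr = correlation_matrix(zs)
        for i in range(3):
            for j in range(3):
                x, y = zs[i].values, zs[j].values
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_excluded(self):
        rng = np.random.default_rng(4)
        zs = [
            _z("a", rng.random(42)),
            _z("b", rng.random(42)),
            ZProfile("flat", np.zeros(42), degenerate=True),
        ]
        corr = correlation_matrix(zs)
        assert "flat" not in corr.index

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            correlation_matrix([ZProfile("flat", np.zeros(42), degenerate=True)])

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(5)
        vs = [rng.random(42) for _ in range(4)]
        c1 = correlation_matrix([_z(f"x{i}", v) for i, v in enumerate(vs)])
        c2 = correlation_matrix([_z(f"y{i}", v) for i, v in enumerate(vs)])
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_spearman_supported(self):
        rng = np.random.default_rng(6)
        zs = [_z(f"p{i}", rng.random(42)) for i in range(3)]
        corr = correlation_matrix(zs, method="spearman")
        from scipy.stats import spearmanr

        expected = spearmanr(zs[0].values, zs[1].values).statistic
        assert corr.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


class TestUpgma:
    def test_two_leaves(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        Z, ids = upgma(d, ids=["a", "b"])
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)

    def test_three_leaf_hand_example(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6 -> merge (A,B)@0.2 then (AB,C)@0.6
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        Z, ids = upgma(d, ids=["A", "B", "C"])
        assert Z[0, 2] == pytest.approx(0.2)
        assert Z[1, 2] == pytest.approx(0.6)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = _random_dist(rng, 8)
            Z, _ = upgma(d)
            assert np.allclose(Z[:, 2], upgma_heights(d))

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            d = _random_dist(rng, 10)
            Z, _ = upgma(d)
            ref = linkage(squareform(d), method="average")
            assert np.allclose(np.sort(Z[:, 2]), np.sort(ref[:, 2]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        d = _random_dist(rng, 12)
        Z, _ = upgma(d)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(10)
        d = _random_dist(rng, 9)
        perm = rng.permutation(9)
        Z1, _ = upgma(d)
        Z2, _ = upgma(d[np.ix_(perm, perm)])
        assert np.allclose(Z1[:, 2], Z2[:, 2])

    def test_non_symmetric_rejected(self):
        d = np.array([[0.0, 0.1], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            upgma(d)

    def test_nonzero_diagonal_rejected(self):
        d = np.array([[0.5, 0.1], [0.1, 0.5]])
        with pytest.raises(ValueError, match="diagonal"):
            upgma(d)


class TestCutClusters:
    @pytest.fixture
    def three_leaf(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        return upgma(d, ids=["A", "B", "C"])

    def test_k_equals_leaves(self, three_leaf):
        Z, ids = three_leaf
        assignments = cut_clusters(Z, ids, k=3)
        assert len(set(assignments.values())) == 3

    def test_k_one(self, three_leaf):
        Z, ids = three_leaf
        assert set(cut_clusters(Z, ids, k=1).values()) == {1}

    def test_k_two_splits_c(self, three_leaf):
        Z, ids = three_leaf
        a = cut_clusters(Z, ids, k=2)
        assert a["A"] == a["B"] != a["C"]

    def test_k_out_of_range(self, three_leaf):
        Z, ids = three_leaf
        with pytest.raises(ValueError):
            cut_clusters(Z, ids, k=0)
        with pytest.raises(ValueError):
            cut_clusters(Z, ids, k=4)


class TestNewick:
    def test_structure_and_parse(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        Z, ids = upgma(d, ids=["A", "B", "C"])
        nwk = to_newick(Z, ids)
        assert nwk.endswith(";")
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
        depths = tree.depths()
        leaf_depths = [d for c, d in depths.items() if c.name]
        assert np.allclose(leaf_depths, 0.3)  # ultrametric: root height 0.6/2


class TestClassifySignature:
    def _mean_z(self, plus=None, minus=None):
        v = np.full(42, -0.3)
        for size, val in (plus or {}).items():
            v[size - 15] = val
        for size, val in (minus or {}).items():
            v[21 + size - 15] = val
        return v

    def test_sirna_rule(self):
        z = self._mean_z(plus={21: 3.0}, minus={21: 3.0})
        assert classify_signature(z, 0.5) == "sirna"

    def test_mixed_rule(self):
        band = {s: 2.0 for s in range(23, 30)}
        z = self._mean_z(plus={21: 3.0}, minus={21: 3.0, **band})
        assert classify_signature(z, 0.5) == "sirna_pirna_mixed"

    def test_pirna_negative_biased(self):
        z = self._mean_z(minus={s: 2.0 for s in range(23, 30)})
        assert classify_signature(z, 0.1) == "pirna_negative_biased"

    def test_pirna_positive_biased(self):
        z = self._mean_z(plus={s: 2.0 for s in range(23, 30)})
        assert classify_signature(z, 0.9) == "pirna_positive_biased"

    def test_flat_profile_unassigned(self):
        assert classify_signature(np.zeros(42), 0.5) == "unassigned"

    def test_band_enrichment_without_bias_unassigned(self):
        z = self._mean_z(minus={s: 2.0 for s in range(23, 30)})
        assert classify_signature(z, 0.5) == "unassigned"


class TestEndToEndClustering:
    def test_synthetic_fixture_recovers_classes(self, small_profiles):
        passing = profiles.filter_profiles(small_profiles, min_reads=100)
        zs = [profiles.zscore(p) for p in passing]
        fracs = {p.contig_id: profiles.strand_fraction(p) for p in passing}
        model = cluster_profiles(zs, fracs, k=3)
        by_class: dict[str, set[int]] = {}
        for cid, cl in model.assignments.items():
            by_class.setdefault(cid.rsplit("_", 1)[0], set()).add(cl)
        # each generating class lands in exactly one cluster
        assert all(len(v) == 1 for v in by_class.values())
        sirna_cluster = by_class["sirna"].pop()
        pirna_cluster = by_class["pirna"].pop()
        assert model.signatures[sirna_cluster] == "sirna"
        assert model.signatures[pirna_cluster] == "pirna_negative_biased"
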