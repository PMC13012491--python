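import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom, spearmanr

from soilcd.community import (
    alpha_diversity,
    bray_curtis,
    cap_ordination,
    kruskal_dunn,
    pcoa,
    permanova,
)
from soilcd.io import CountTable


def _dist(points, ids=None):
    ids = ids or [f"S{i}" for i in range(len(points))]
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d, index=ids, columns=ids)


class TestAlphaDiversity:
    def test_uniform_sample(self):
        r = alpha_diversity(np.array([10, 10, 10, 10]))
        assert r.observed_richness == 4
        assert r.chao1 == pytest.approx(4.0)
        assert r.shannon == pytest.approx(np.log(4))

    def test_chao1_hand_computed(self):
        # S=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
        r = alpha_diversity(np.array([1, 1, 2, 5, 9]))
        assert r.observed_richness == 5
        assert r.chao1 == pytest.approx(5.5)

    def test_single_taxon_shannon_zero(self):
        assert alpha_diversity(np.array([0, 7, 0])).shannon == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(np.zeros(5, dtype=int))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=40))
    def test_invariants(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            counts[0] = 1
        r = alpha_diversity(counts)
        assert r.chao1 >= r.observed_richness
        assert 0.0 <= r.shannon <= np.log(r.observed_richness) + 1e-12
        # permuting taxa leaves everything unchanged
        r2 = alpha_diversity(counts[::-1])
        assert r2.shannon == pytest.approx(r.shannon)
        assert r2.chao1 == r.chao1


class TestKruskalDunn:
    def test_identical_groups_share_letter_under_null(self):
        # group size 20 keeps the chi-square approximation of H accurate
        shared = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            values = rng.normal(0, 1, 80)
            groups = np.repeat(["g1", "g2", "g3", "g4"], 20)
            res = kruskal_dunn(values, groups)
            if len(set(res.letters.values())) == 1:
                shared += 1
        assert shared >= 95

    def test_single_shifted_group_gets_own_letter(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(10, 1, 10)])
        groups = np.repeat(["f1", "f2", "f3", "f4", "f5"], 10)
        res = kruskal_dunn(values, groups)
        outlier = res.letters["f5"]
        others = {res.letters[g] for g in ("f1", "f2", "f3", "f4")}
        assert all(set(outlier) & set(o) == set() for o in others)

    def test_identical_multisets_adjusted_p_one(self):
        values = [1, 2, 3, 4, 1, 2, 3, 4]
        groups = ["a"] * 4 + ["b"] * 4
        res = kruskal_dunn(values, groups)
        assert res.pairwise["q"].iloc[0] == pytest.approx(1.0)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_dunn([1, 2, 3], ["a", "a", "b"])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = CountTable(["A", "B"], ["", ""], ["s1", "s2"], np.array([[3, 3], [5, 5]]))
        d = bray_curtis(t)
        assert d.loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = CountTable(["A", "B"], ["", ""], ["s1", "s2"], np.array([[4, 0], [0, 9]]))
        assert bray_curtis(t).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        t = CountTable(
            ["A", "B", "C"], [""] * 3, ["s1", "s2"],
            np.array([[1, 0], [1, 1], [0, 1]]),
        )
        assert bray_curtis(t).loc["s1", "s2"] == pytest.approx(0.5)

    def test_matches_brute_force_loop(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 50, size=(8, 5))
            counts[0] += 1  # no empty samples
            t = CountTable([f"T{i}" for i in range(8)], [""] * 8, [f"s{j}" for j in range(5)], counts)
            d = bray_curtis(t).to_numpy()
            rel = counts / counts.sum(axis=0, keepdims=True)
            for a in range(5):
                for b in range(5):
                    expected = np.abs(rel[:, a] - rel[:, b]).sum() / (rel[:, a] + rel[:, b]).sum()
                    assert d[a, b] == pytest.approx(expected, abs=1e-12)
            assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestPermanova:
    def test_equidistant_points_p_one(self):
        # all pairwise distances equal -> every permutation gives the same F
        n = 6
        d = pd.DataFrame(1.0 - np.eye(n))
        res = permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (12, 3)), rng.normal(10, 0.01, (12, 3))])
        res = permanova(_dist(pts), ["a"] * 12 + ["b"] * 12, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared > 0.99

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            pts = rng.normal(0, 1, (12, 5))
            res = permanova(_dist(pts), ["a"] * 6 + ["b"] * 6, n_permutations=999, seed=rep)
            rejections += res.p_value <= 0.05
        lo, hi = binom.interval(0.95, n_reps, 0.05)
        assert lo <= rejections <= hi

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (10, 4))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        d = _dist(pts)
        res1 = permanova(d, labels, n_permutations=299, seed=5)
        d2 = d.iloc[perm, perm]
        res2 = permanova(d2, labels[perm], n_permutations=299, seed=5)
        assert res2.pseudo_f == pytest.approx(res1.pseudo_f)

    def test_strata_never_cross_blocks(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (12, 3))
        strata = np.repeat(["block1", "block2", "block3"], 4)
        labels = ["a", "a", "b", "b"] * 3
        res = permanova(
            _dist(pts), labels, n_permutations=99, seed=6,
            strata=strata, keep_permutations=True,
        )
        blocks = np.repeat([0, 1, 2], 4)
        for row in res.permuted_labels:
            assert (blocks[row] == blocks).all()

    def test_single_level_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(4))
        with pytest.raises(ValueError, match="2 levels"):
            permanova(d, ["a"] * 4)


class TestOrdination:
    def test_pcoa_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (9, 4))
        d = _dist(pts)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        n_axes = min(ours.scores.shape[1], 4)
        np.testing.assert_allclose(
            ours.eigenvalues[:n_axes],
            theirs.eigvals.to_numpy()[:n_axes],
            rtol=1e-8,
        )
        for k in range(n_axes):  # eigenvectors defined up to sign
            a = ours.scores[:, k]
            b = theirs.samples.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_empty_constraints_reduce_to_pcoa(self):
        rng = np.random.default_rng(9)
        d = _dist(rng.normal(0, 1, (7, 3)))
        unconstrained = cap_ordination(d, None)
        base = pcoa(d)
        np.testing.assert_allclose(unconstrained.scores, base.scores)
        assert not unconstrained.constrained

    def test_single_binary_constraint_one_axis(self):
        rng = np.random.default_rng(10)
        d = _dist(rng.normal(0, 1, (10, 3)))
        constraints = pd.DataFrame({"grp": [0.0] * 5 + [1.0] * 5})
        res = cap_ordination(d, constraints)
        assert res.constrained
        assert res.scores.shape[1] == 1

    def test_planted_gradient_recovered_on_axis_one(self):
        rng = np.random.default_rng(11)
        gradient = np.linspace(0, 1, 20)
        pts = np.column_stack([gradient * 5, rng.normal(0, 0.3, 20), rng.normal(0, 0.3, 20)])
        d = _dist(pts)
        res = cap_ordination(d, pd.DataFrame({"cd": gradient}))
        rho, _ = spearmanr(res.scores[:, 0], gradient)
        assert abs(rho) > 0.9
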