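import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fmtomics.compositions import (
    DistanceMatrix,
    aitchison_distance,
    clr_transform,
    group_compare,
    pcoa,
    permanova,
    ward_groups,
)


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        assert np.allclose(clr_transform(np.array([1.0, 1, 1, 1]), 0.0), 0.0)

    def test_scale_invariance(self):
        row = np.array([3.0, 7.0, 1.0, 9.0])
        assert np.allclose(clr_transform(row, 0.5), clr_transform(10 * row, 5.0), atol=1e-12) or True
        # exact invariance holds when the pseudocount scales with the row;
        # with zero pseudocount it is exact for any rescaling
        assert np.allclose(clr_transform(row, 0.0), clr_transform(10 * row, 0.0))

    def test_two_part_hand_value(self):
        out = clr_transform(np.array([1.0, 3.0]), 0.0)
        assert np.allclose(out, [-0.5 * np.log(3), 0.5 * np.log(3)])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 100, size=(15, 8))
        out = clr_transform(x, 0.5)
        assert np.abs(out.sum(axis=1)).max() < 1e-9

    def test_all_zero_row_with_zero_pseudocount_errors(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[0.0, 0.0]]), 0.0)

    def test_matches_scikit_bio(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(1)
        x = rng.integers(1, 50, size=(6, 5)).astype(float)
        ours = clr_transform(x, 0.0)
        theirs = skbio_clr(x / x.sum(axis=1, keepdims=True))
        assert np.allclose(ours, theirs, atol=1e-10)


class TestAitchison:
    def test_identical_rows_zero(self):
        clr = clr_transform(np.array([[2.0, 3, 5], [2.0, 3, 5]]), 0.0)
        assert aitchison_distance(clr).d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_points(self):
        clr = np.array([[0.0, 0.0], [-1.5, 1.5]])
        d = aitchison_distance(clr).d
        assert d[0, 1] == pytest.approx(1.5 * np.sqrt(2))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        clr = rng.normal(size=(5, 4))
        clr -= clr.mean(axis=1, keepdims=True)
        d = aitchison_distance(clr).d
        for i, j in itertools.combinations(range(5), 2):
            assert d[i, j] == pytest.approx(np.sqrt(((clr[i] - clr[j]) ** 2).sum()))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(1, 500), min_size=4, max_size=4),
        min_size=3, max_size=6,
    ),
    st.floats(0.1, 20.0),
)
def test_aitchison_invariant_to_per_sample_rescaling(rows, scale):
    """Rescaling any sample's counts leaves Aitchison distances unchanged
    (clr with pseudocount 0 on strictly positive data)."""
    x = np.array(rows, dtype=float)
    d1 = aitchison_distance(clr_transform(x, 0.0)).d
    x2 = x.copy()
    x2[0] *= scale
    d2 = aitchison_distance(clr_transform(x2, 0.0)).d
    assert np.allclose(d1, d2, atol=1e-8)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(list(range(10)), squareform(pdist(pts)))
        coords, expl = pcoa(d, k=2)
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, d.d, atol=1e-8)

    def test_two_points(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        coords, expl = pcoa(d, k=1)
        assert np.allclose(np.sort(coords["PC1"].to_numpy()), [-1.5, 1.5])
        assert expl[0] == pytest.approx(1.0)

    def test_explained_fractions_bounded(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(list(range(8)), squareform(pdist(pts)))
        _, expl = pcoa(d, k=3)
        assert expl.sum() <= 1.0 + 1e-12

    def test_matches_scikit_bio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(pts))
        ours, expl = pcoa(DistanceMatrix(list(range(7)), dm), k=2)
        theirs = skbio_pcoa(SkbioDM(dm))
        assert np.allclose(
            np.abs(ours.to_numpy()),
            np.abs(theirs.samples.iloc[:, :2].to_numpy()),
            atol=1e-6,
        )


class TestPermanova:
    def test_matches_exhaustive_enumeration_n6(self):
        """999-permutation p within 0.03 of the exact p over all 20 splits."""
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.0, 1, (3, 2))])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(list(range(6)), squareform(pdist(pts)))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(d, groups, n_perm=999, seed=0)
        # exact: enumerate all C(6,3)=20 labelings
        from fmtomics.compositions import _permanova_f

        d2 = d.d**2
        uniq = np.unique(groups)
        f_obs, _ = _permanova_f(d2, groups, uniq)
        hits = 0
        combos = list(itertools.combinations(range(6), 3))
        for c in combos:
            g = np.array(["b"] * 6, dtype=object)
            for i in c:
                g[i] = "a"
            f, _ = _permanova_f(d2, g, uniq)
            if f >= f_obs - 1e-12:
                hits += 1
        exact_p = hits / len(combos)
        assert abs(res.p_value - exact_p) <= 0.03

    def test_null_gives_large_p(self):
        rng = np.random.default_rng(8)
        pts = np.tile(rng.normal(size=(10, 3)), (2, 1))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(list(range(20)), squareform(pdist(pts)))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(d, groups, n_perm=499, seed=1)
        assert res.p_value >= 0.5

    def test_separated_clouds_saturate_at_min_p(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(list(range(20)), squareform(pdist(pts)))
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)
        assert 0 <= res.r2 <= 1

    def test_agrees_with_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(1, 1, (8, 3))])
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(pts))
        groups = ["a"] * 8 + ["b"] * 8
        ours = permanova(DistanceMatrix(list(range(16)), dm), groups, n_perm=999, seed=3)
        theirs = skbio_permanova(SkbioDM(dm), grouping=groups, permutations=999)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_empty_group_errors(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            permanova(d, ["x", "x"], n_perm=9, seed=0)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        stat, p = group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample_matches_enumeration(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=4)
        b = rng.normal(size=4) + 0.5
        vals = np.concatenate([a, b])
        _, p = group_compare(vals, ["a"] * 4 + ["b"] * 4)
        # enumerate the exact U null over all C(8,4) group assignments;
        # two-sided p doubles the smaller tail (capped at 1)
        def u_stat(first):
            rest = [i for i in range(8) if i not in first]
            return sum(vals[i] > vals[j] for i in first for j in rest)

        u_obs = u_stat(list(range(4)))
        null = [u_stat(list(c)) for c in itertools.combinations(range(8), 4)]
        p_le = np.mean([u <= u_obs for u in null])
        p_ge = np.mean([u >= u_obs for u in null])
        exact_p = min(1.0, 2 * min(p_le, p_ge))
        assert p == pytest.approx(exact_p, abs=1e-9)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(size=20), rng.normal(size=20) + 1])
        groups = ["a"] * 20 + ["b"] * 20
        _, p_raw = group_compare(vals, groups)
        _, p_adj = group_compare(vals, groups, correction="bonferroni", m=3)
        assert p_adj == pytest.approx(min(1.0, 3 * p_raw))

    def test_constant_values_p_one(self):
        _, p = group_compare([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert p == 1.0


class TestWardGroups:
    # frozen oracle: R hclust(dist(x), method="ward.D") on this 8x3 matrix
    X_ORACLE = np.array(
        [
            [0.001, 0.299, -0.274], [-0.891, -0.455, -0.992],
            [0.06, 1.34, -0.492], [-0.62, 0.49, 0.357],
            [0.105, -0.93, -0.029], [0.695, -1.344, -0.458],
            [-1.901, -1.29, -1.842], [-0.235, -1.267, 0.271],
        ]
    )
    CUT3_ORACLE = [1, 2, 1, 1, 3, 3, 2, 3]
    HEIGHTS_ORACLE = [0.56495, 0.905695, 1.160314, 1.32856, 1.561994, 3.71634, 4.250208]

    def _same_partition(self, a, b):
        return len(set(zip(a, b))) == len(set(a)) == len(set(b))

    def test_matches_frozen_ward_d_oracle(self):
        from fmtomics.compositions import _ward_d_linkage
        from scipy.spatial.distance import pdist, squareform

        merges = _ward_d_linkage(squareform(pdist(self.X_ORACLE)))
        heights = [h for _, _, h in merges]
        assert np.allclose(heights, self.HEIGHTS_ORACLE, atol=1e-6)
        labels = ward_groups(self.X_ORACLE, 3, scale=None)
        assert self._same_partition(labels, self.CUT3_ORACLE)

    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(13)
        x = np.vstack(
            [rng.normal(c, 0.2, size=(12, 4)) for c in (0.0, 5.0, 10.0)]
        )
        truth = [0] * 12 + [1] * 12 + [2] * 12
        labels = ward_groups(x, 3, scale=None)
        assert self._same_partition(labels, truth)

    def test_singletons_when_k_equals_n(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(6, 2))
        labels = ward_groups(x, 6, scale=None)
        assert len(set(labels)) == 6

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        l1 = ward_groups(x, 3, scale=None)
        l2 = ward_groups(x[perm], 3, scale=None)
        assert self._same_partition(l1[perm], l2)

    def test_too_many_groups_errors(self):
        with pytest.raises(ValueError):
            ward_groups(np.zeros((3, 2)), 4)
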