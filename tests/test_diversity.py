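"""Shannon, Bray-Curtis, stratified PERMANOVA and PERMDISP behavior."""

import itertools

import numpy as np
import pytest

from ecoresp.core_io import IntegrityError, OguCountTable
from ecoresp.diversity import (
    DistanceMatrix,
    bray_curtis,
    permanova_stratified,
    permdisp,
    shannon,
)


class TestShannon:
    def test_uniform_four_taxa(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_single_taxon_zero(self):
        assert shannon([5.0, 0.0, 0.0]) == 0.0

    def test_counts_1_1_2(self):
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert shannon([1, 1, 2]) == pytest.approx(expected)
        assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = OguCountTable(["a", "b"], ["x", "y"], np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = OguCountTable(["a", "b"], ["x", "y"], np.array([[3.0, 0.0], [0.0, 5.0]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = OguCountTable(
            ["a", "b"], ["x", "y", "z"], np.array([[2.0, 0.0, 2.0], [1.0, 1.0, 1.0]])
        )
        assert bray_curtis(t).values[0, 1] == pytest.approx(3 / 7)

    def test_range_symmetry_identity(self, sim_small):
        table, _, _, _ = sim_small
        sub = OguCountTable(
            table.sample_ids[:15], table.ogu_ids, table.values[:15]
        )
        d = bray_curtis(sub).values
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_all_zero_row_errors(self):
        t = OguCountTable(["a", "b"], ["x"], np.array([[0.0], [1.0]]))
        with pytest.raises(IntegrityError):
            bray_curtis(t)


def _brute_force_stratified(d: np.ndarray, labels, strata):
    """Independent enumeration oracle for the stratified permutation p."""
    labels = np.asarray(labels, dtype=object)
    strata = np.asarray(strata, dtype=object)
    n = labels.size

    def pseudo_f(codes):
        uniq = sorted(set(codes))
        d2 = d**2
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in uniq:
            idx = np.flatnonzero(np.asarray(codes, dtype=object) == g)
            if idx.size > 1:
                ss_w += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
        a = len(uniq)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(labels)
    per_stratum = []
    stratum_idx = []
    for s in sorted(set(strata)):
        idx = np.flatnonzero(strata == s)
        stratum_idx.append(idx)
        per_stratum.append(sorted(set(itertools.permutations(labels[idx]))))
    total = ge = 0
    for combo in itertools.product(*per_stratum):
        perm = np.empty(n, dtype=object)
        for idx, labs in zip(stratum_idx, combo):
            perm[idx] = labs
        total += 1
        if pseudo_f(perm) >= f_obs - 1e-12:
            ge += 1
    return ge / total


class TestPermanova:
    @pytest.fixture
    def dm6(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(6)], d)

    def test_exact_matches_enumeration_oracle(self, dm6):
        labels = ["A", "B", "A", "B", "A", "B"]
        strata = ["x", "x", "x", "y", "y", "y"]
        res = permanova_stratified(dm6, labels, strata, method="exact")
        assert res.p_value == pytest.approx(
            _brute_force_stratified(dm6.values, labels, strata)
        )
        assert res.strata_used

    def test_single_stratum_equals_plain_and_oracle(self, dm6):
        labels = ["A", "A", "A", "B", "B", "B"]
        res = permanova_stratified(dm6, labels, None, method="exact")
        oracle = _brute_force_stratified(dm6.values, labels, ["u"] * 6)
        assert res.p_value == pytest.approx(oracle)
        assert not res.strata_used

    def test_exact_agrees_with_skbio_statistic(self, dm6):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        labels = ["A", "A", "A", "B", "B", "B"]
        res = permanova_stratified(dm6, labels, None, n_perm=99, seed=0)
        sk = sk_permanova(
            skbio.DistanceMatrix(dm6.values, dm6.sample_ids), labels, permutations=99
        )
        assert res.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_perfect_separation_min_p(self):
        # two coincident clusters, far apart: F_obs maximal over permutations
        d = np.zeros((6, 6))
        d[:3, 3:] = 10.0
        d[3:, :3] = 10.0
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        labels = ["A"] * 3 + ["B"] * 3
        res = permanova_stratified(dm, labels, None, method="exact")
        # 20 arrangements, ties of F only at the 2 label-swap images
        assert res.p_value == pytest.approx(2 / 20)

    def test_null_calibration_p_roughly_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(60):
            pts = rng.normal(size=(12, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            strata = ["x"] * 6 + ["y"] * 6
            ps.append(
                permanova_stratified(dm, labels, strata, n_perm=99,
                                     seed=int(rng.integers(2**31))).p_value
            )
        assert 0.25 < np.mean(ps) < 0.75

    def test_degenerate_strata_error_and_warning(self, dm6):
        labels = ["A", "A", "A", "A", "B", "A"]
        strata = ["x", "x", "x", "y", "y", "y"]
        with pytest.warns(UserWarning, match="single label level"):
            permanova_stratified(dm6, labels, strata, n_perm=19, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            permanova_stratified(dm6, ["A", "A", "A", "B", "B", "B"],
                                 ["x", "x", "x", "y", "y", "y"], n_perm=19)


class TestPermdisp:
    def test_symmetric_groups_f_near_zero(self):
        # two congruent equilateral triangles far apart
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        pts = np.vstack([tri, tri + [100.0, 0.0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = permdisp(dm, ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_planted_dispersion_difference_detected(self):
        rng = np.random.default_rng(2)
        tight = rng.normal(0, 1.0, size=(20, 4))
        spread = rng.normal(0, 5.0, size=(20, 4))
        pts = np.vstack([tight, spread])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(40)], d)
        res = permdisp(dm, ["A"] * 20 + ["B"] * 20, n_perm=199, seed=1)
        assert res.p_value <= 0.05

    def test_group_of_size_one_rejected(self):
        d = np.array([[0, 1.0, 2], [1, 0, 1], [2, 1, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], d)
        with pytest.raises(ValueError, match="size 1"):
            permdisp(dm, ["A", "A", "B"], n_perm=19)

    def test_agrees_with_skbio_centroid_distances(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permdisp as sk_permdisp

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(14, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(14)], d)
        groups = ["A"] * 7 + ["B"] * 7
        res = permdisp(dm, groups, n_perm=99, seed=0)
        sk = sk_permdisp(
            skbio.DistanceMatrix(d, dm.sample_ids), groups, permutations=99,
            test="centroid",
        )
        assert res.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-6)
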