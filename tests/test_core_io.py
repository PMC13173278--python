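"""Table I/O round trips, normalization, prevalence and shared statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoresp.core_io import (
    IntegrityError,
    OguCountTable,
    SampleMetadata,
    TableParseError,
    bh_adjust,
    compute_prevalence,
    read_ogu_table,
    spearman,
    rank_sum_test,
    tss_normalize,
    write_ogu_table,
)


class TestTableIO:
    @pytest.mark.parametrize("dialect", ["tsv_dense", "biom_triplet"])
    def test_round_trip_identity(self, tmp_path, small_table, dialect):
        path = tmp_path / "table.tsv"
        write_ogu_table(small_table, path, dialect)
        assert read_ogu_table(path, dialect) == small_table

    def test_dense_read_preserves_values_and_order(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\toB\toA\ns2\t2\t0\ns1\t0\t3\ns3\t1\t1\n")
        t = read_ogu_table(path)
        assert t.sample_ids == ["s2", "s1", "s3"]
        assert t.ogu_ids == ["oB", "oA"]
        assert t.values.tolist() == [[2, 0], [0, 3], [1, 1]]

    def test_triplet_single_cell(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\togu_id\tvalue\ns1\to2\t3\n")
        t = read_ogu_table(path, "biom_triplet")
        assert t.values.tolist() == [[3.0]]
        assert t.sample_ids == ["s1"] and t.ogu_ids == ["o2"]

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\to1\to2\ns1\t1\tx9\n")
        with pytest.raises(TableParseError, match="s1.*o2"):
            read_ogu_table(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(IntegrityError, match="duplicate"):
            OguCountTable(["s1", "s1"], ["o1"], np.ones((2, 1)))

    def test_negative_values_rejected(self):
        with pytest.raises(IntegrityError, match="negative"):
            OguCountTable(["s1"], ["o1"], np.array([[-1.0]]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_table_round_trip_both_dialects(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        vals = rng.integers(0, 50, size=(n, m)).astype(float)
        if vals.sum() == 0:
            vals[0, 0] = 1
        t = OguCountTable([f"s{i}" for i in range(n)], [f"o{j}" for j in range(m)], vals)
        d = tmp_path_factory.mktemp("rt")
        for dialect in ("tsv_dense", "biom_triplet"):
            write_ogu_table(t, d / "x.tsv", dialect)
            assert read_ogu_table(d / "x.tsv", dialect) == t


class TestTss:
    def test_rows_sum_to_one_and_zeros_preserved(self, small_table):
        rel = tss_normalize(small_table)
        assert rel.is_relative
        assert np.allclose(rel.values.sum(axis=1), 1.0)
        assert ((small_table.values == 0) == (rel.values == 0)).all()

    def test_known_rows(self):
        t = OguCountTable(["a", "b"], ["x", "y", "z"],
                          np.array([[2.0, 2.0, 0.0], [1.0, 0.0, 3.0]]))
        rel = tss_normalize(t)
        assert np.allclose(rel.values[0], [0.5, 0.5, 0.0])
        assert np.allclose(rel.values[1], [0.25, 0.0, 0.75])

    def test_idempotent(self, small_table):
        once = tss_normalize(small_table)
        twice = tss_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_all_zero_row_reports_sample(self):
        t = OguCountTable(["good", "bad"], ["x"], np.array([[1.0], [0.0]]))
        with pytest.raises(IntegrityError, match="bad"):
            tss_normalize(t)


class TestPrevalence:
    def test_counts_and_mean_relabund(self):
        meta = {
            f"s{i}": SampleMetadata(f"s{i}", f"ds{i // 2}", "R") for i in range(4)
        }
        rel = OguCountTable(
            [f"s{i}" for i in range(4)], ["o1", "o2"],
            np.array([[0.1, 0.9], [0.0, 1.0], [0.2, 0.8], [0.0, 1.0]]),
            is_relative=True,
        )
        prof = compute_prevalence(rel, meta)["o1"]
        assert prof.sample_prevalence == 2
        assert prof.dataset_prevalence == 2
        assert prof.sample_prevalence_frac == pytest.approx(0.5)
        assert prof.mean_relabund == pytest.approx(0.075)

    def test_absent_ogu_all_zero(self, small_meta):
        t = OguCountTable(
            ["s1", "s2", "s3", "s4"], ["o1", "o2"],
            np.array([[1.0, 0], [2.0, 0], [1.0, 0], [3.0, 0]]),
        )
        prof = compute_prevalence(t, small_meta)["o2"]
        assert (prof.sample_prevalence, prof.dataset_prevalence) == (0, 0)
        assert prof.mean_relabund == 0.0

    def test_dataset_prevalence_bounded_by_sample_prevalence(self, sim_small):
        table, smeta, _, _ = sim_small
        for prof in compute_prevalence(table, smeta).values():
            assert prof.dataset_prevalence <= max(prof.sample_prevalence, 0) or (
                prof.sample_prevalence == 0 and prof.dataset_prevalence == 0
            )
            assert prof.dataset_prevalence <= 3

    def test_threshold_monotonicity(self, sim_small):
        table, smeta, _, _ = sim_small
        lo = compute_prevalence(table, smeta, detection_threshold=0.0)
        hi = compute_prevalence(table, smeta, detection_threshold=5.0)
        for ogu in table.ogu_ids:
            assert hi[ogu].sample_prevalence <= lo[ogu].sample_prevalence
            assert hi[ogu].dataset_prevalence <= lo[ogu].dataset_prevalence

    def test_missing_metadata_errors(self, small_table):
        with pytest.raises(IntegrityError, match="metadata"):
            compute_prevalence(small_table, {})


def _bh_oracle(ps):
    """Brute-force step-up: smallest slope bound over the tail ranks."""
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.5], [0.02, 0.5]),
        ],
    )
    def test_hand_values(self, ps, expected):
        assert bh_adjust(ps) == pytest.approx(expected)

    def test_all_permutations_match_oracle(self):
        base = [0.001, 0.02, 0.04, 0.2, 0.6, 1.0]
        for k in range(1, 7):
            for perm in itertools.permutations(base[:k]):
                assert bh_adjust(list(perm)) == pytest.approx(_bh_oracle(list(perm)))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        ps = rng.random(50)
        adj = bh_adjust(ps)
        assert (adj >= ps - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSpearman:
    def test_perfect_and_inverse(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_signals(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestRankSum:
    def test_complete_separation_exact_p(self):
        _, p = rank_sum_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_all_tied_gives_one(self):
        _, p = rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0
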