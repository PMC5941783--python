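"""Demultiplexing: index matching, read classification, count tables."""

import random

import numpy as np
import pytest

from indexswap.demux import (
    AMBIGUOUS,
    NO_MATCH,
    Demultiplexer,
    ReadClass,
    SwapCountTable,
    UndefinedRateError,
    match_index,
    swap_rate,
    tabulate,
)
from indexswap.index_sets import (
    DualIndexSet,
    IndexConstraints,
    IndexEntry,
    IndexSetError,
    design_index_set,
)
from indexswap.simulate import ReadRecord, simulate_pool

from conftest import make_config

Q_HIGH = chr(37 + 33) * 8
Q_LOW = chr(10 + 33) * 8


def oracle_match(observed, candidates, max_mismatch):
    hits = [
        i
        for i, c in enumerate(candidates)
        if sum(a != b for a, b in zip(observed, c)) <= max_mismatch
    ]
    if not hits:
        return NO_MATCH
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def _mutate(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


class TestMatchIndex:
    def test_exact_match_position(self, sheet6):
        cands = sheet6.i7_list
        assert match_index(cands[2], cands, max_mismatch=0) == 2

    def test_single_mismatch_resolves_in_distance_3_set(self, sheet6):
        rng = random.Random(0)
        cands = sheet6.i7_list
        obs = _mutate(cands[3], [5], rng)
        assert match_index(obs, cands, max_mismatch=1) == 3

    def test_second_qualifying_candidate_is_ambiguous(self):
        cands = ["AAAAAAAA", "AAAAAAAT"]
        assert match_index("AAAAAAAA", cands, max_mismatch=1) is AMBIGUOUS

    def test_no_match(self, sheet6):
        assert (
            match_index("NNNNNNNN".replace("N", "A"), ["CCCCCCCC"], 1)
            is NO_MATCH
        )

    def test_agrees_with_exhaustive_scan(self):
        """500 random queries against a distance->=3 candidate set."""
        rng = random.Random(2024)
        cands = design_index_set(12, IndexConstraints(), seed=55).i7_list
        for _ in range(500):
            roll = rng.random()
            if roll < 0.4:
                obs = rng.choice(cands)
            elif roll < 0.8:
                obs = _mutate(rng.choice(cands), rng.sample(range(8), rng.randint(1, 2)), rng)
            else:
                obs = "".join(rng.choice("ACGT") for _ in range(8))
            assert match_index(obs, cands, 1) == oracle_match(obs, cands, 1)

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            match_index("AAAAAAAA", [], 1)


def _record(i7, i5, q7=Q_HIGH, q5=Q_HIGH):
    return ReadRecord("r", i7, i5, q7, q5)


class TestClassify:
    def test_matched(self, sheet6):
        dm = Demultiplexer(sheet6)
        e = sheet6.entries[0]
        a = dm.classify_record(_record(e.i7, e.i5))
        assert a.read_class is ReadClass.MATCHED
        assert a.sample_id == e.sample_id
        assert a.i7_owner == a.i5_owner == e.sample_id

    def test_swapped_pair_names_both_owners(self, sheet6):
        dm = Demultiplexer(sheet6)
        ea, eb = sheet6.entries[0], sheet6.entries[1]
        a = dm.classify_record(_record(ea.i7, eb.i5))
        assert a.read_class is ReadClass.SWAPPED
        assert (a.i7_owner, a.i5_owner) == (ea.sample_id, eb.sample_id)
        assert a.sample_id is None

    def test_quality_filter_precedes_matching(self, sheet6):
        dm = Demultiplexer(sheet6)
        e = sheet6.entries[0]
        a = dm.classify_record(_record(e.i7, e.i5, q5=Q_LOW))
        assert a.read_class is ReadClass.LOW_QUALITY

    def test_foreign_index_goes_undetermined(self, sheet6):
        dm = Demultiplexer(sheet6, max_mismatch=0)
        e = sheet6.entries[0]
        foreign = "ACACACAC" if "ACACACAC" not in sheet6.i7_list else "GTGTGTGT"
        a = dm.classify_record(_record(foreign, e.i5))
        assert a.read_class is ReadClass.UNDETERMINED

    def test_redundant_sheet_rejected(self):
        ds = DualIndexSet(
            [
                IndexEntry("a", "ACGTACGT", "TGCATGCA"),
                IndexEntry("b", "ACGTACGT", "CATGCATG"),
            ]
        )
        with pytest.raises(IndexSetError):
            Demultiplexer(ds)


class TestTabulate:
    def test_partition_conserves_stream_length(self, sheet6):
        cfg = make_config(
            sheet6, 10_000, seed=21,
            p_swap_i7=0.05, p_swap_i5=0.1, index_error_rate=0.02,
        )
        table, grid = tabulate(simulate_pool(cfg), sheet6)
        assert (
            int(table.matrix.sum())
            + table.undetermined_count
            + table.low_quality_count
            == table.total_reads
            == 10_000
        )
        assert grid.classified_total == int(table.matrix.sum())
        assert grid.swapped_total == table.swapped_count

    def test_zero_swap_is_diagonal_only(self, sheet6):
        cfg = make_config(sheet6, 5_000, seed=22)
        table, _ = tabulate(simulate_pool(cfg), sheet6)
        off = table.matrix.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_all_36_combinations_populated_under_heavy_swapping(self, sheet6):
        cfg = make_config(sheet6, 50_000, seed=23, p_swap_i7=0.4, p_swap_i5=0.4)
        table, _ = tabulate(simulate_pool(cfg), sheet6)
        assert table.matrix.shape == (6, 6)
        assert (table.matrix > 0).all()
        # each row's modal cell is its correct (diagonal) combination
        assert (table.matrix.argmax(axis=1) == np.arange(6)).all()


class TestSwapRate:
    def test_diagonal_only_is_zero(self, sheet6):
        table = SwapCountTable.empty(sheet6.sample_ids)
        np.fill_diagonal(table.matrix, 100)
        table.total_reads = 600
        assert swap_rate(table) == 0.0

    def test_mixture_scale_counts_round_to_worked_example_rate(self):
        """34,219,842 swapped of 842,853,260 qualifying reads -> 0.0406."""
        table = SwapCountTable.empty(["a", "b"])
        table.matrix[0, 0] = 842_853_260 - 34_219_842
        table.matrix[0, 1] = 34_219_842
        table.total_reads = 842_853_260
        assert round(swap_rate(table), 4) == 0.0406

    def test_zero_denominator_raises(self, sheet6):
        table = SwapCountTable.empty(sheet6.sample_ids)
        table.undetermined_count = 5
        table.total_reads = 5
        with pytest.raises(UndefinedRateError):
            swap_rate(table)

    def test_invariant_under_sample_permutation(self, sheet6):
        cfg = make_config(sheet6, 8_000, seed=25, p_swap_i5=0.2)
        records = list(simulate_pool(cfg))
        rate = swap_rate(tabulate(records, sheet6)[0])
        shuffled = DualIndexSet(list(reversed(sheet6.entries)))
        assert swap_rate(tabulate(records, shuffled)[0]) == rate


def test_exact_mode_matches_truth_classification(sheet6):
    """Error-free reads: demux calls equal truth-derived calls read-for-read."""
    cfg = make_config(sheet6, 20_000, seed=26, p_swap_i7=0.1, p_swap_i5=0.15)
    dm = Demultiplexer(sheet6, max_mismatch=0)
    for rec in simulate_pool(cfg):
        a = dm.classify_record(rec)
        if rec.i7_source == rec.i5_source:
            assert a.read_class is ReadClass.MATCHED
            assert a.sample_id == rec.i7_source
        else:
            assert a.read_class is ReadClass.SWAPPED
            assert (a.i7_owner, a.i5_owner) == (rec.i7_source, rec.i5_source)
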