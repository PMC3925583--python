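"""Level-wise mining: singleton filtering, prefix joins, pruning, full runs."""

import numpy as np
import pytest

from bitclose import (
    BitTable,
    ConfigError,
    MemoryGuardError,
    MiningConfig,
    enumerate_frequent_bruteforce,
    frequent_singletons,
    join_candidates,
    mine_frequent,
    prune,
)
from bitclose.core import IndexTable
from bitclose.miner import LevelResult, _next_level

from conftest import random_instance


def _frequent_set(levels):
    return {
        (tup, int(s))
        for lvl in levels
        for tup, s in zip(lvl.index_table.rows, lvl.supports)
    }


class TestFrequentSingletons:
    def test_toy4_minsupp2(self, toy4):
        lvl = frequent_singletons(toy4, MiningConfig(minsupp=2))
        assert lvl.index_table.rows == [(0,), (1,), (2,)]
        assert lvl.supports.tolist() == [3, 3, 3]
        assert lvl.bit_table.n_rows == 4

    def test_toy4_minsupp4_empty(self, toy4):
        lvl = frequent_singletons(toy4, MiningConfig(minsupp=4))
        assert lvl.is_empty()

    def test_all_ones(self):
        B = BitTable.from_dense(np.ones((5, 4), dtype=np.int8))
        lvl = frequent_singletons(B, MiningConfig(minsupp=5))
        assert lvl.n_itemsets == 4
        assert (lvl.supports == 5).all()

    def test_zero_rows_deleted_and_row_ids_updated(self):
        # row 1 only contains the infrequent item 2
        B = BitTable.from_dense([[1, 1, 0], [0, 0, 1], [1, 1, 0]])
        lvl = frequent_singletons(B, MiningConfig(minsupp=2))
        assert lvl.bit_table.row_ids.tolist() == [0, 2]
        assert lvl.index_table.rows == [(0,), (1,)]


class TestJoinCandidates:
    def _level(self, tuples, n_rows=4):
        vals = np.ones((n_rows, len(tuples)), dtype=np.int8)
        return LevelResult(
            level=len(tuples[0]),
            bit_table=BitTable(vals, np.arange(n_rows), level=len(tuples[0])),
            index_table=IndexTable(list(tuples)),
            supports=np.full(len(tuples), n_rows),
        )

    def test_blocks_at_level_three(self):
        # AB, AC, AD, BC -> ABC, ABD, ACD; BC has no block partner
        lvl = self._level([(0, 1), (0, 2), (0, 3), (1, 2)])
        tuples = [tup for tup, _ in join_candidates(lvl, use_subset_filter=False)]
        assert tuples == [(0, 1, 2), (0, 1, 3), (0, 2, 3)]

    def test_all_pairs_at_level_two(self):
        lvl = self._level([(0,), (1,), (2,)])
        tuples = [tup for tup, _ in join_candidates(lvl)]
        assert tuples == [(0, 1), (0, 2), (1, 2)]

    def test_disjoint_prefixes_produce_nothing(self):
        lvl = self._level([(0, 1), (2, 3)])
        assert join_candidates(lvl) == []

    def test_subset_filter_discards_unsupported_candidates(self):
        # ABC needs BC; with only AB, AC, BD present it must be discarded
        lvl = self._level([(0, 1), (0, 2), (1, 3)])
        assert [t for t, _ in join_candidates(lvl)] == []
        unfiltered = [t for t, _ in join_candidates(lvl, use_subset_filter=False)]
        assert unfiltered == [(0, 1, 2)]

    def test_candidate_columns_are_hadamard_products(self, toy4):
        lvl = frequent_singletons(toy4, MiningConfig(minsupp=2))
        for tup, col in join_candidates(lvl):
            i, j = tup
            assert np.array_equal(col, toy4.values[:, i] * toy4.values[:, j])


class TestPrune:
    def test_toy4_level2_minsupp3_empty(self, toy4):
        cfg = MiningConfig(minsupp=3)
        lvl1 = frequent_singletons(toy4, cfg)
        lvl2 = prune(join_candidates(lvl1), lvl1, cfg)
        assert lvl2.is_empty()

    def test_toy4_level2_minsupp2_keeps_all_pairs_and_rows(self, toy4):
        cfg = MiningConfig(minsupp=2)
        lvl1 = frequent_singletons(toy4, cfg)
        lvl2 = prune(join_candidates(lvl1), lvl1, cfg)
        assert lvl2.index_table.rows == [(0, 1), (0, 2), (1, 2)]
        assert lvl2.supports.tolist() == [2, 2, 2]
        assert lvl2.bit_table.n_rows == 4

    def test_toy3_level2_only_ab_survives(self, toy3):
        cfg = MiningConfig(minsupp=2)
        lvl1 = frequent_singletons(toy3, cfg)
        lvl2 = prune(join_candidates(lvl1), lvl1, cfg)
        assert lvl2.index_table.rows == [(0, 1)]
        assert lvl2.supports.tolist() == [3]
        assert lvl2.bit_table.n_rows == 3


class TestMineFrequent:
    def test_toy4_minsupp2(self, toy4):
        freq = _frequent_set(mine_frequent(toy4, MiningConfig(minsupp=2)))
        assert freq == {
            ((0,), 3), ((1,), 3), ((2,), 3),
            ((0, 1), 2), ((0, 2), 2), ((1, 2), 2),
        }

    def test_toy4_minsupp1_adds_triple(self, toy4):
        freq = _frequent_set(mine_frequent(toy4, MiningConfig(minsupp=1)))
        assert len(freq) == 7
        assert ((0, 1, 2), 1) in freq

    def test_empty_table(self):
        B = BitTable.from_dense(np.zeros((0, 0), dtype=np.int8))
        assert mine_frequent(B, MiningConfig(minsupp=1)) == []

    def test_max_level_caps_itemset_size(self, toy4):
        levels = mine_frequent(toy4, MiningConfig(minsupp=1, max_level=2))
        assert max(l.level for l in levels) == 2

    def test_bad_config_rejected(self, toy4):
        with pytest.raises((ConfigError, TypeError)):
            mine_frequent(toy4, "not a config")

    def test_memory_guard_trips_with_tiny_cap(self):
        rng = np.random.default_rng(3)
        B = BitTable.from_dense((rng.random((30, 20)) < 0.5).astype(np.int8))
        with pytest.raises(MemoryGuardError):
            mine_frequent(B, MiningConfig(minsupp=1, cell_cap=50))


class TestMinerProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_enumeration(self, seed):
        B, cfg = random_instance(seed)
        mined = _frequent_set(mine_frequent(B, cfg))
        brute = {(it.items, it.support) for it in enumerate_frequent_bruteforce(B, cfg)}
        assert mined == brute

    @pytest.mark.parametrize("seed", range(10))
    def test_anti_monotonicity_in_output(self, seed):
        B, cfg = random_instance(seed)
        freq = dict(_frequent_set(mine_frequent(B, cfg)))
        for tup, s in freq.items():
            for d in range(len(tup)):
                sub = tup[:d] + tup[d + 1 :]
                if sub:
                    assert sub in freq and freq[sub] >= s

    @pytest.mark.parametrize("seed", range(10))
    def test_row_deletion_is_lossless(self, seed):
        B, cfg = random_instance(seed)
        kept = _frequent_set(
            mine_frequent(B, MiningConfig(minsupp=cfg.minsupp, delete_zero_rows=False))
        )
        assert kept == _frequent_set(mine_frequent(B, cfg))

    @pytest.mark.parametrize("seed", range(10))
    def test_subset_filter_does_not_change_output(self, seed):
        B, cfg = random_instance(seed)
        off = _frequent_set(
            mine_frequent(B, MiningConfig(minsupp=cfg.minsupp, use_subset_filter=False))
        )
        assert off == _frequent_set(mine_frequent(B, cfg))

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_minsupp(self, seed):
        B, cfg = random_instance(seed)
        lo = _frequent_set(mine_frequent(B, MiningConfig(minsupp=cfg.minsupp)))
        hi = _frequent_set(mine_frequent(B, MiningConfig(minsupp=cfg.minsupp + 2)))
        assert {t for t, _ in hi} <= {t for t, _ in lo}

    @pytest.mark.parametrize("seed", range(6))
    def test_fused_step_equals_explicit_join_prune(self, seed):
        B, cfg = random_instance(seed)
        lvl = frequent_singletons(B, cfg)
        while not lvl.is_empty():
            fused = _next_level(lvl, cfg)
            explicit = prune(join_candidates(lvl), lvl, cfg)
            if fused is None:
                assert explicit.is_empty()
                break
            assert fused.index_table.rows == explicit.index_table.rows
            assert fused.supports.tolist() == explicit.supports.tolist()
            assert np.array_equal(fused.bit_table.values, explicit.bit_table.values)
            assert np.array_equal(fused.bit_table.row_ids, explicit.bit_table.row_ids)
            lvl = fused
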