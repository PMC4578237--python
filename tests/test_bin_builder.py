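"""Block calling, masking, bin construction and the lossless-expansion property."""

import numpy as np
import pandas as pd
import pytest

from nambin import bin_builder as bb
from nambin.bin_builder import Block, CODE_COMMON, CODE_DIVERSE, CODE_NA
from nambin.genotype_hmm import HMMParams


class TestCallBlocks:
    def test_midpoint_breakpoint(self):
        blocks, bp = bb.call_blocks([0, 0, 1], [100, 200, 300])
        assert [(b.start, b.end, b.genotype) for b in blocks] == [(100, 200, 0), (300, 300, 1)]
        assert list(bp) == [250]

    def test_single_state_one_block(self):
        blocks, bp = bb.call_blocks([1, 1, 1, 1], [10, 20, 30, 40])
        assert len(blocks) == 1 and len(bp) == 0
        assert blocks[0].n_snps == 4

    @pytest.mark.parametrize("seed", range(6))
    def test_block_count_equals_transitions_plus_one(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.integers(-1, 2, size=60)
        pos = np.sort(rng.choice(10**6, size=60, replace=False))
        blocks, _ = bb.call_blocks(states, pos)
        informative = states[states >= 0]
        if len(informative) == 0:
            assert blocks == []
        else:
            n_trans = int((informative[1:] != informative[:-1]).sum())
            assert len(blocks) == n_trans + 1


class TestMaskShortBlocks:
    def _block(self, length, n_snps, genotype=1):
        return Block(ril="r", chrom="chr1", start=10**6,
                     end=10**6 + length - 1, genotype=genotype, n_snps=n_snps)

    def test_short_and_thin_masked(self):
        surv, masked = bb.mask_short_blocks([self._block(1_400_000, 4)])
        assert surv == [] and len(masked) == 1

    def test_long_but_thin_kept(self):
        surv, masked = bb.mask_short_blocks([self._block(1_600_000, 3)])
        assert len(surv) == 1 and masked == []

    def test_short_but_dense_kept(self):
        surv, masked = bb.mask_short_blocks([self._block(1_400_000, 6)])
        assert len(surv) == 1 and masked == []

    def test_flanks_remerged_after_masking(self):
        blocks = [
            Block("r", "chr1", 1, 3_000_000, 0, 50),
            Block("r", "chr1", 3_100_000, 3_200_000, 1, 3),   # masked
            Block("r", "chr1", 3_300_000, 6_000_000, 0, 40),
        ]
        surv, masked = bb.mask_short_blocks(blocks)
        assert len(masked) == 1
        assert len(surv) == 1
        assert surv[0].start == 1 and surv[0].end == 6_000_000
        assert surv[0].n_snps == 90


class TestFamilyBins:
    def _intervals(self):
        # 2 RILs on a 1000-bp chromosome with breakpoints at 250 / 750
        return {
            "r1": {"chr1": [(1, 250, 0), (251, 1000, 1)]},
            "r2": {"chr1": [(1, 750, 0), (751, 1000, 1)]},
        }

    def test_two_rils_three_bins(self):
        bm = bb.build_family_bins(self._intervals(), {"chr1": 1000})
        assert bm.n_bins == 3
        assert list(bm.bins["start"]) == [1, 251, 751]
        assert list(bm.bins["end"]) == [250, 750, 1000]
        assert list(bm.genotypes[0]) == [CODE_COMMON, CODE_DIVERSE, CODE_DIVERSE]
        assert list(bm.genotypes[1]) == [CODE_COMMON, CODE_COMMON, CODE_DIVERSE]

    def test_identical_rils_single_bin(self):
        iv = {"r1": {"chr1": [(1, 1000, 0)]}, "r2": {"chr1": [(1, 1000, 0)]}}
        bm = bb.build_family_bins(iv, {"chr1": 1000})
        assert bm.n_bins == 1

    def test_single_ril_family_rejected(self):
        with pytest.raises(ValueError, match="two RILs"):
            bb.build_family_bins({"r1": {"chr1": [(1, 1000, 0)]}}, {"chr1": 1000})

    @pytest.mark.parametrize("seed", range(5))
    def test_lossless_expansion(self, seed):
        # expanding the bins back to positions reproduces each RIL's intervals
        rng = np.random.default_rng(seed)
        length = 100_000
        intervals = {}
        for r in range(4):
            cuts = np.sort(rng.choice(np.arange(1000, length - 1000), size=3,
                                      replace=False))
            vals = [int(v) for v in rng.integers(-1, 2, size=4)]
            bounds = [0, *cuts, length]
            intervals[f"r{r}"] = {"chr1": [
                (bounds[i] + 1, bounds[i + 1], vals[i]) for i in range(4)]}
        bm = bb.build_family_bins(intervals, {"chr1": length})
        probe = np.sort(rng.choice(length, size=200, replace=False)) + 1
        expanded = bb.expand_to_sites(bm, "chr1", probe)
        for i, r in enumerate(intervals):
            for p, got in zip(probe, expanded[i]):
                val = next(v for s, e, v in intervals[r]["chr1"] if s <= p <= e)
                want = CODE_NA if val == -1 else (CODE_DIVERSE if val == 1 else CODE_COMMON)
                assert got == want


class TestMergeSmallBins:
    def _map(self, spans, genos):
        bins = pd.DataFrame({"chrom": "chr1",
                             "start": [s for s, _ in spans],
                             "end": [e for _, e in spans]})
        return bb.BinMap(bins=bins, lines=["r1", "r2"],
                         genotypes=np.array(genos, dtype=np.int8).T)

    def test_small_bin_merged_into_next(self):
        bm = self._map([(1, 3000), (3001, 103_000)],
                       [[0, 0], [2, 2]])
        merged = bb.merge_small_bins(bm)
        assert merged.n_bins == 1
        assert merged.bins["start"].iat[0] == 1
        assert merged.bins["end"].iat[0] == 103_000

    def test_exactly_5kb_kept(self):
        bm = self._map([(1, 5000), (5001, 105_000)], [[0, 0], [2, 2]])
        assert bb.merge_small_bins(bm).n_bins == 2

    def test_last_small_bin_merges_backward(self):
        bm = self._map([(1, 100_000), (100_001, 102_000)], [[0, 0], [2, 2]])
        merged = bb.merge_small_bins(bm)
        assert merged.n_bins == 1
        assert merged.bins["end"].iat[0] == 102_000

    def test_conflicting_genotypes_become_missing(self):
        bm = self._map([(1, 3000), (3001, 103_000)], [[0, 2], [2, 0]])
        merged = bb.merge_small_bins(bm)
        # larger constituent wins where they disagree... both disagree: NA
        assert merged.n_bins == 1
        assert list(merged.genotypes[:, 0]) == [CODE_NA, CODE_NA]


class TestImputeTransitionBins:
    CHROMS = [("chr1", 1_000_000, 10.0)]

    def _map(self, genos):
        n = len(genos[0])
        width = 1_000_000 // n
        bins = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * width + 1,
                             "end": (np.arange(n) + 1) * width})
        return bb.BinMap(bins=bins, lines=[f"r{i}" for i in range(len(genos))],
                         genotypes=np.array(genos, dtype=np.int8))

    def test_agreeing_flanks_filled(self):
        bm = self._map([[0, CODE_NA, 0]])
        out, unresolved = bb.impute_transition_bins(bm, self.CHROMS)
        assert list(out.genotypes[0]) == [0, 0, 0]
        assert unresolved == []

    def test_disagreeing_flanks_use_hmm_posterior(self):
        # NA closer (in cM) to the diverse flank takes its state
        bm = self._map([[0, 0, 0, CODE_NA, 2]])
        out, _ = bb.impute_transition_bins(bm, self.CHROMS, HMMParams())
        from nambin.genotype_hmm import posterior
        mids_cm = ((bm.bins["start"] + bm.bins["end"]) / 2 / 1_000_000 * 10.0).to_numpy()
        p1 = posterior(np.array([0, 0, 0, -1, 1]), mids_cm, HMMParams())
        want = CODE_DIVERSE if p1[3] > 0.5 else CODE_COMMON
        assert out.genotypes[0, 3] == want

    def test_no_missing_is_identity(self):
        bm = self._map([[0, 2, 0], [2, 2, 0]])
        out, _ = bb.impute_transition_bins(bm, self.CHROMS)
        assert np.array_equal(out.genotypes, bm.genotypes)

    def test_all_missing_chromosome_reported(self):
        bm = self._map([[CODE_NA, CODE_NA], [0, 2]])
        out, unresolved = bb.impute_transition_bins(bm, self.CHROMS)
        assert unresolved == [("r0", "chr1")]
        assert (out.genotypes[0] == CODE_NA).all()
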