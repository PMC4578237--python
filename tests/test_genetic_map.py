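"""Haldane distances, segregation tests, composite selection and assembly."""

import numpy as np
import pandas as pd
import pytest

from nambin import genetic_map as gm, synthetic_data as sd
from nambin.bin_builder import BinMap, CODE_NA


class TestDistances:
    def test_zero_discordance(self):
        col = np.array([0, 2, 0, 2] * 10)
        R, r, d, linked = gm.rf_between_bins(col, col)
        assert R == 0 and r == 0 and d == 0 and linked

    def test_third_discordance_closed_form(self):
        # R = 1/3 -> r = 0.25 -> d = -50 ln(0.5) = 34.657 cM
        col1 = np.array([0] * 60)
        col2 = np.array([2] * 20 + [0] * 40)
        R, r, d, linked = gm.rf_between_bins(col1, col2)
        assert np.isclose(R, 1 / 3)
        assert np.isclose(r, 0.25)
        assert np.isclose(d, 34.657359, atol=1e-5)

    def test_half_discordance_unlinked(self):
        col1 = np.array([0, 2] * 20)
        col2 = np.array([0] * 20 + [2] * 20)
        R, r, d, linked = gm.rf_between_bins(col1, col2)
        assert not linked and r == 0.5

    def test_too_few_informative_rejected(self):
        col = np.array([0, 2, CODE_NA] * 5)
        with pytest.raises(ValueError, match="informative"):
            gm.rf_between_bins(col, col)

    def test_haldane_round_trip(self):
        d = np.linspace(1e-6, 100, 200)
        assert np.allclose(gm.haldane_cm(gm.inverse_haldane(d)), d, atol=1e-9)


class TestFamilyMap:
    def _sim_map(self, n_ril, seed):
        lines, fam, codes, positions = sd.simulate_bin_genotypes(
            1, n_ril, [("chr1", 200_000_000, 200.0)], 400, seed=seed)
        width = 200_000_000 // 400
        bins = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(400) * width + 1,
                             "end": (np.arange(400) + 1) * width})
        bm = BinMap(bins=bins, lines=lines, genotypes=codes)
        return gm.build_family_map(bm)

    def test_simulated_length_within_ten_percent(self):
        gmap = self._sim_map(500, seed=11)
        est = gmap.chrom_length_cm("chr1")
        assert abs(est - 200.0) / 200.0 < 0.10

    def test_single_bin_zero_length(self):
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [1000]})
        bm = BinMap(bins=bins, lines=[f"r{i}" for i in range(40)],
                    genotypes=np.array([[0]] * 40, dtype=np.int8))
        gmap = gm.build_family_map(bm)
        assert gmap.chrom_length_cm("chr1") == 0.0

    def test_more_rils_reduce_length_spread(self):
        # Monte-Carlo: doubling RILs must shrink the spread of length estimates
        small = [self._sim_map(100, seed=s).chrom_length_cm("chr1") for s in range(20, 28)]
        large = [self._sim_map(400, seed=s).chrom_length_cm("chr1") for s in range(30, 38)]
        assert np.std(large) < np.std(small)


class TestCompositeSelection:
    def _origins(self, polymorphic_families, n_ril=4, n_sites=3):
        rng = np.random.default_rng(0)
        out = {}
        for f in ("famA", "famB", "famC", "famD"):
            org = np.full((n_ril, n_sites), -1, dtype=np.int8)
            for j in range(n_sites):
                if f in polymorphic_families[j]:
                    col = rng.integers(0, 2, size=n_ril)
                    col[0], col[1] = 0, 1  # guarantee polymorphism
                    org[:, j] = col
            out[f] = ([f"{f}_r{i}" for i in range(n_ril)], org)
        return out

    def test_threshold_strictly_more_than(self):
        poly = [{"famA", "famB"}, {"famA", "famB", "famC"}, {"famA"}]
        origins = self._origins(poly)
        positions = pd.DataFrame({"chrom": "chr1", "pos": [100, 200, 300]})
        keep, lines, enc = gm.select_composite_markers(origins, positions,
                                                       min_families=2)
        assert list(keep) == [False, True, False]

    def test_monomorphic_family_coded_missing(self):
        poly = [{"famA", "famB", "famC"}]
        origins = self._origins(poly, n_sites=1)
        positions = pd.DataFrame({"chrom": "chr1", "pos": [100]})
        keep, lines, enc = gm.select_composite_markers(origins, positions,
                                                       min_families=2)
        famD_rows = [i for i, l in enumerate(lines) if l.startswith("famD")]
        assert (enc[famD_rows] == CODE_NA).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = 20
        origins = {}
        for f in ("fa", "fb", "fc"):
            org = rng.integers(-1, 2, size=(6, n_sites)).astype(np.int8)
            origins[f] = ([f"{f}{i}" for i in range(6)], org)
        positions = pd.DataFrame({"chrom": "chr1",
                                  "pos": np.arange(n_sites) * 1000 + 1})
        keep, _, _ = gm.select_composite_markers(origins, positions, min_families=1)
        for j in range(n_sites):
            count = sum(
                1 for f in origins
                if (origins[f][1][:, j] == 0).any() and (origins[f][1][:, j] == 1).any())
            assert keep[j] == (count > 1)


class TestSegregation:
    def test_balanced_not_distorted(self):
        chi2, p, distorted = gm.segregation_test(np.array([1] * 50 + [0] * 50))
        assert chi2 == 0 and p == 1.0 and not distorted

    def test_70_30_distorted(self):
        chi2, p, distorted = gm.segregation_test(np.array([1] * 70 + [0] * 30))
        assert np.isclose(chi2, 16.0)
        assert np.isclose(p, 6.33e-5, rtol=1e-2)
        assert distorted

    def test_55_45_not_distorted(self):
        chi2, p, distorted = gm.segregation_test(np.array([1] * 55 + [0] * 45))
        assert np.isclose(chi2, 1.0) and not distorted

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="no informative"):
            gm.segregation_test(np.full(10, CODE_NA))


def _encoded_binmap(codes, chrom="chr1", width=500_000):
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[1]
    bins = pd.DataFrame({"chrom": chrom, "start": np.arange(n) * width + 1,
                         "end": (np.arange(n) + 1) * width})
    return BinMap(bins=bins, lines=[f"r{i}" for i in range(codes.shape[0])],
                  genotypes=codes)


class TestCompositeAssembly:
    def _simulated_encoding(self, seed=3, n_ril=200, n_bins=80, chroms=1):
        lines, fam, codes, positions = sd.simulate_bin_genotypes(
            1, n_ril, [(f"chr{c+1}", 100_000_000, 100.0) for c in range(chroms)],
            n_bins, seed=seed)
        enc = np.where(codes == -1, CODE_NA, np.where(codes == 0, 1, 0)).astype(np.int8)
        frames = []
        for c in range(chroms):
            width = 100_000_000 // n_bins
            frames.append(pd.DataFrame({
                "chrom": f"chr{c+1}", "start": np.arange(n_bins) * width + 1,
                "end": (np.arange(n_bins) + 1) * width}))
        bins = pd.concat(frames, ignore_index=True)
        return BinMap(bins=bins, lines=lines, genotypes=enc)

    def test_two_chromosomes_two_linkage_groups(self):
        bm = self._simulated_encoding(chroms=2)
        labels = gm.linkage_groups(bm, lod_threshold=10.0)
        chroms = bm.bins["chrom"].to_numpy()
        assert len(set(labels[chroms == "chr1"])) == 1
        assert len(set(labels[chroms == "chr2"])) == 1
        assert set(labels[chroms == "chr1"]).isdisjoint(labels[chroms == "chr2"])

    def test_clean_markers_all_retained_physical_order(self):
        bm = self._simulated_encoding()
        cmap = gm.assemble_composite_map(bm)
        assert len(cmap.markers) == bm.n_bins
        assert (cmap.markers["pos"].diff().dropna() > 0).all()
        assert (cmap.markers["cm"].diff().dropna() >= 0).all()

    def test_framework_markers_never_distorted(self):
        bm = self._simulated_encoding(seed=5)
        # push one marker far off the 1:1 ratio
        bm.genotypes[: int(0.95 * bm.genotypes.shape[0]), 10] = 1
        cmap = gm.assemble_composite_map(bm)
        fw = cmap.markers[cmap.markers["framework"]]
        assert not fw["distorted"].any()

    def test_noisy_conflicting_marker_excluded(self):
        rng = np.random.default_rng(7)
        bm = self._simulated_encoding(seed=6)
        # 30% genotyping error creates distortion-free chaos in one marker:
        # also skew it so the distortion flag fires
        col = bm.genotypes[:, 40].copy()
        flip = rng.random(len(col)) < 0.30
        col[flip] = 1 - np.clip(col[flip], 0, 1)
        col[:60] = 1
        bm.genotypes[:, 40] = col
        cmap = gm.assemble_composite_map(bm)
        assert "jbin00040" not in set(cmap.markers["marker"])
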