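"""Simulator moments against closed forms, determinism, and truth invariants."""

import numpy as np
import pytest

from nambin import synthetic_data as sd
from nambin.io_formats import CALL_H, CALL_NA


def small_config(**kw):
    defaults = dict(n_families=2, rils_per_family=30, seed=1,
                    chromosomes=[("chr1", 50_000_000, 100.0)], snp_density=2e-5)
    defaults.update(kw)
    return sd.SimConfig(**defaults)


class TestFounders:
    def test_polymorphic_fraction_matches_binomial(self):
        # P(polymorphic in family) = 2 p (1-p) = 0.5 at p = 0.5
        cfg = small_config(snp_density=2e-5, maf=0.5, seed=3,
                           chromosomes=[("chr1", 50_000_000, 100.0)])
        founders = sd.simulate_founders(cfg)
        n = len(founders.positions["chr1"])
        k = int(founders.polymorphic("fam0", "chr1").sum())
        se = np.sqrt(n * 0.5 * 0.5)
        assert abs(k - 0.5 * n) < 5 * se

    def test_zero_sites(self):
        cfg = small_config(snp_density=0.0)
        founders = sd.simulate_founders(cfg)
        assert len(founders.positions["chr1"]) == 0

    def test_deterministic_under_seed(self):
        cfg = small_config(seed=9)
        f1 = sd.simulate_founders(cfg)
        f2 = sd.simulate_founders(cfg)
        assert np.array_equal(f1.common["chr1"], f2.common["chr1"])
        assert np.array_equal(f1.positions["chr1"], f2.positions["chr1"])


class TestGamete:
    def test_zero_length_no_crossovers(self):
        rng = np.random.default_rng(0)
        parent = (sd._const_hap(0), sd._const_hap(1))
        for _ in range(20):
            _, xo = sd.simulate_gamete(parent, 0.0, rng)
            assert len(xo) == 0

    def test_poisson_mean(self):
        rng = np.random.default_rng(1)
        parent = (sd._const_hap(0), sd._const_hap(1))
        counts = [len(sd.simulate_gamete(parent, 200.0, rng)[1]) for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 2.0) < 5 * se

    def test_crossovers_sorted_inside(self):
        rng = np.random.default_rng(2)
        parent = (sd._const_hap(0), sd._const_hap(1))
        for _ in range(50):
            _, xo = sd.simulate_gamete(parent, 150.0, rng)
            assert np.all(np.diff(xo) >= 0)
            assert np.all((xo > 0) & (xo < 150.0))


class TestSSD:
    def test_f7_junction_count(self):
        # selfed-RIL map expansion: ~2 junctions per Morgan at fixation,
        # slightly fewer at F7
        cfg = small_config(rils_per_family=500, n_families=1, seed=5,
                           chromosomes=[("chr1", 200_000_000, 200.0)],
                           snp_density=1e-6)
        founders = sd.simulate_founders(cfg)
        _, truth = sd.simulate_ssd_family(founders, cfg)
        counts = [truth.n_breakpoints(r) for r in truth.segments]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 4.0) < 5 * se + 0.5  # F7 sits just under the asymptote

    def test_residual_het_decay(self):
        # unlinked-limit expectation: (1/2)^g of the F1 het fraction
        cfg = small_config(rils_per_family=300, n_families=1, seed=6,
                           missing_rate=0.0, error_rate=0.0, het_undercall_rate=0.0)
        founders, truth, clean, _ = sd.simulate_panel(cfg)
        poly = founders.polymorphic("fam0", "chr1")
        het_frac = (clean.calls[:, poly] == CALL_H).mean()
        expected = 0.5 ** cfg.selfing_generations
        assert expected / 2 < het_frac < expected * 2.5  # linkage inflates slightly

    def test_no_selfing_gives_f1(self):
        cfg = small_config(selfing_generations=0, n_families=1,
                           missing_rate=0.0, error_rate=0.0, het_undercall_rate=0.0)
        founders, truth, clean, _ = sd.simulate_panel(cfg)
        poly = founders.polymorphic("fam0", "chr1")
        assert (clean.calls[:, poly] == CALL_H).all()

    def test_segments_tile_chromosome(self):
        cfg = small_config(seed=8)
        _, truth, _, _ = sd.simulate_panel(cfg)
        for ril, segs in truth.segments.items():
            assert segs[0][1] == 1
            assert segs[-1][2] == 50_000_000
            for a, b in zip(segs, segs[1:]):
                assert b[1] == a[2] + 1
            assert all(g in (0, 2) for _, _, _, g in segs)


class TestNoise:
    def test_all_missing(self):
        cfg = small_config(missing_rate=1.0)
        _, _, clean, noisy = sd.simulate_panel(cfg)
        assert (noisy.calls == CALL_NA).all()

    def test_noise_free_identity(self):
        cfg = small_config(missing_rate=0.0, error_rate=0.0, het_undercall_rate=0.0)
        _, _, clean, noisy = sd.simulate_panel(cfg)
        assert np.array_equal(clean.calls, noisy.calls)

    def test_missing_fraction_binomial(self):
        cfg = small_config(rils_per_family=100, missing_rate=0.3, seed=12)
        _, _, clean, noisy = sd.simulate_panel(cfg)
        n = clean.calls.size
        frac = (noisy.calls == CALL_NA).mean()
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < 5 * se

    def test_determinism(self):
        cfg = small_config(seed=13)
        _, _, _, n1 = sd.simulate_panel(cfg)
        _, _, _, n2 = sd.simulate_panel(cfg)
        assert np.array_equal(n1.calls, n2.calls)


class TestPhenotype:
    def _sim(self, qtl, h2=1.0, seed=2, **kw):
        cfg = small_config(n_families=2, rils_per_family=40, seed=seed, **kw)
        _, truth, clean, _ = sd.simulate_panel(cfg)
        fam_means = {f: 70.0 for f in cfg.family_names()}
        pheno = sd.simulate_phenotype(truth, clean.family_of, qtl, n_envs=2,
                                      n_reps=1, h2=h2, family_means=fam_means,
                                      env_sd=0.0, seed=seed)
        return truth, clean, pheno

    def test_no_qtl_no_noise_equals_family_mean(self):
        truth, clean, pheno = self._sim([], h2=1.0)
        assert np.allclose(pheno.df["value"], 70.0)

    def test_single_qtl_two_classes_two_days_apart(self):
        qtl = [{"chrom": "chr1", "pos": 25_000_000,
                "effects": {"fam0": 1.0, "fam1": 1.0}}]
        truth, clean, pheno = self._sim(qtl, h2=1.0)
        vals = np.sort(pheno.df["value"].unique())
        hom = [v for v in vals if not np.isclose(v, 71.0)]  # drop het class (code 1)
        assert np.isclose(min(hom), 70.0) and np.isclose(max(hom), 72.0)

    def test_qtl_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            self._sim([{"chrom": "chr9", "pos": 1, "effects": {"fam0": 1.0}}])

    def test_deterministic(self):
        qtl = [{"chrom": "chr1", "pos": 25_000_000, "effects": {"fam0": 0.5}}]
        _, _, p1 = self._sim(qtl, h2=0.8)
        _, _, p2 = self._sim(qtl, h2=0.8)
        assert p1 == p2


class TestOutlierInjection:
    def test_noop(self):
        cfg = small_config(seed=21)
        _, _, _, noisy = sd.simulate_panel(cfg)
        out, labels = sd.inject_outliers(noisy, 0, 0)
        assert labels == [] and np.array_equal(out.calls, noisy.calls)

    def test_single_family_contamination_rejected(self):
        cfg = small_config(n_families=1, seed=22)
        _, _, _, noisy = sd.simulate_panel(cfg)
        with pytest.raises(ValueError, match="two families"):
            sd.inject_outliers(noisy, 1, 0)

    def test_injected_excess_het_ratio(self):
        cfg = small_config(seed=23)
        _, _, _, noisy = sd.simulate_panel(cfg)
        out, labels = sd.inject_outliers(noisy, 0, 3, seed=5)
        for line, reason in labels:
            assert reason == "excess_het"
            i = out.lines.index(line)
            obs = out.calls[i] != CALL_NA
            ratio = (out.calls[i][obs] == CALL_H).mean()
            assert ratio > 0.10

    def test_labels_are_existing_lines(self):
        cfg = small_config(seed=24)
        _, _, _, noisy = sd.simulate_panel(cfg)
        out, labels = sd.inject_outliers(noisy, 2, 2, seed=6)
        assert {l for l, _ in labels} <= set(noisy.lines)
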