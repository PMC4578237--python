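"""Nested-effect scans, permutation thresholds, stepwise selection, LOD CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nambin import joint_linkage as jl, synthetic_data as sd


def _panel(n_fam=5, n_ril=100, n_markers=60, seed=0, positions=False):
    lines, fam, codes, pos = sd.simulate_bin_genotypes(
        n_fam, n_ril, [("chr1", 100_000_000, 100.0)], n_markers, seed=seed)
    return jl.MarkerPanel(codes.copy(), lines, fam,
                          positions=pos if positions else None), lines, fam, codes


class TestNestedTest:
    def test_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        codes = np.array([[0, 2], [2, 0], [0, 0], [2, 2],
                          [0, 2], [2, 2], [0, 0], [2, 0]], dtype=float)
        lines = [f"l{i}" for i in range(8)]
        fam = {l: ("A" if i < 4 else "B") for i, l in enumerate(lines)}
        y = rng.normal(size=8) + 0.8 * codes[:, 0]
        panel = jl.MarkerPanel(codes.copy(), lines, fam)
        F, P, q = jl.nested_marker_test(y, panel, 0)
        # from-scratch normal equations
        D0 = np.zeros((8, 2))
        D0[:4, 0] = 1
        D0[4:, 1] = 1
        x = codes[:, 0]
        xA = np.where(np.arange(8) < 4, x - x[:4].mean(), 0)
        xB = np.where(np.arange(8) >= 4, x - x[4:].mean(), 0)
        D1 = np.column_stack([D0, xA, xB])
        rss0 = np.sum((y - D0 @ np.linalg.lstsq(D0, y, rcond=None)[0]) ** 2)
        rss1 = np.sum((y - D1 @ np.linalg.lstsq(D1, y, rcond=None)[0]) ** 2)
        Fh = ((rss0 - rss1) / 2) / (rss1 / 4)
        assert np.isclose(F, Fh)
        assert q == 2

    def test_null_pvalues_uniform(self):
        # marker orthogonal to y: repeated null P-values pass a KS test
        panel, lines, fam, codes = _panel(n_fam=3, n_ril=60, n_markers=1, seed=1)
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(400):
            y = rng.normal(size=len(lines))
            _, P, _ = jl.nested_marker_test(y, panel, 0)
            pvals.append(P)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_fit_underflows(self):
        panel, lines, fam, codes = _panel(n_fam=2, n_ril=50, n_markers=3, seed=3)
        x = np.nan_to_num(panel.codes[:, 1], nan=1.0)
        y = 2.0 * x
        _, P, _ = jl.nested_marker_test(y, panel, 1)
        assert P < 1e-30

    def test_fast_scan_equals_slow_path(self):
        panel, lines, fam, codes = _panel(seed=4)
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(lines))
        F_fast, P_fast = jl._scan_null(y, panel)
        for j in (0, 17, 59):
            F, P, _ = jl.nested_marker_test(y, panel, j)
            assert np.isclose(F_fast[j], F) and np.isclose(P_fast[j], P)


class TestPermutationThreshold:
    def test_sidak_on_independent_markers(self):
        # independent markers: threshold approximates 1-(1-a)^(1/K)
        rng = np.random.default_rng(6)
        n, K = 400, 40
        lines = [f"l{i}" for i in range(n)]
        fam = {l: f"f{i % 4}" for i, l in enumerate(lines)}
        codes = rng.choice([0.0, 2.0], size=(n, K))
        panel = jl.MarkerPanel(codes.copy(), lines, fam)
        y = rng.normal(size=n)
        thr = jl.permutation_threshold(y, panel, alpha=0.05, n_perm=2000, rng=rng)
        sidak = 1 - 0.95 ** (1 / K)
        assert 0.4 * sidak < thr.p_enter < 2.5 * sidak

    def test_alpha_one_is_max_minimum(self):
        panel, lines, fam, codes = _panel(seed=7)
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(lines))
        minima = jl.permutation_minima(y, panel, 100,
                                       np.random.default_rng(9))
        thr = jl.permutation_threshold(y, panel, alpha=1.0, n_perm=100,
                                       rng=np.random.default_rng(9))
        assert np.isclose(thr.p_enter, np.max(minima))

    def test_deterministic_under_seed(self):
        panel, lines, fam, codes = _panel(seed=10)
        y = np.random.default_rng(11).normal(size=len(lines))
        t1 = jl.permutation_threshold(y, panel, n_perm=150, rng=np.random.default_rng(1))
        t2 = jl.permutation_threshold(y, panel, n_perm=150, rng=np.random.default_rng(1))
        assert t1.p_enter == t2.p_enter

    def test_too_few_permutations_rejected(self):
        panel, lines, fam, codes = _panel(seed=12)
        y = np.zeros(len(lines))
        with pytest.raises(ValueError, match="n_perm"):
            jl.permutation_threshold(y, panel, n_perm=50)


class TestStepwise:
    def test_strong_orthogonal_effects_match_best_subset(self):
        # 6 markers, strong effects on 2: stepwise equals exhaustive best
        # subset by BIC-like RSS comparison when effects are orthogonal
        rng = np.random.default_rng(13)
        n = 240
        lines = [f"l{i}" for i in range(n)]
        fam = {l: f"f{i % 2}" for i, l in enumerate(lines)}
        codes = rng.choice([0.0, 2.0], size=(n, 6))
        y = 1.5 * codes[:, 1] + 2.0 * codes[:, 4] + rng.normal(0, 0.5, n)
        panel = jl.MarkerPanel(codes.copy(), lines, fam)
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-4)
        model = jl.stepwise_select(y, panel, thr)
        assert sorted(model.selected) == [1, 4]

    def test_forced_terms_never_removed(self):
        panel, lines, fam, codes = _panel(seed=14)
        y = np.random.default_rng(15).normal(size=len(lines))
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-6)
        model = jl.stepwise_select(y, panel, thr)
        assert model.forced_terms == ["family"]

    def test_rss_decreases_with_each_selection(self):
        panel, lines, fam, codes = _panel(seed=16)
        rng = np.random.default_rng(17)
        x1 = np.nan_to_num(panel.codes[:, 10], nan=1.0)
        x2 = np.nan_to_num(panel.codes[:, 40], nan=1.0)
        y = x1 + 0.7 * x2 + rng.normal(0, 1, len(lines))
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-4)
        m0 = jl.stepwise_select(y, panel, thr, max_steps=1)
        m2 = jl.stepwise_select(y, panel, thr)
        assert m2.rss <= m0.rss


class TestLODProfile:
    def _fitted(self, seed=18):
        panel, lines, fam, codes = _panel(n_markers=40, seed=seed, positions=True)
        rng = np.random.default_rng(seed + 1)
        x = np.nan_to_num(panel.codes[:, 20], nan=1.0)
        y = 1.2 * x + rng.normal(0, 1, len(lines))
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-4)
        model = jl.stepwise_select(y, panel, thr)
        return y, panel, model

    def test_lod_closed_form(self):
        # RSS ratio 10^0.2 at n=100 gives LOD (100/2)*0.2 = 10
        n = 100
        lod = (n / 2.0) * np.log10(10 ** 0.2)
        assert np.isclose(lod, 10.0)

    def test_profile_peak_at_true_marker(self):
        y, panel, model = self._fitted()
        assert 20 in model.selected
        prof = jl.lod_profile(y, panel, model, 20)
        assert prof.loc[prof["lod"].idxmax(), "marker"] == 20

    def test_lod_nonnegative_and_window_bounded(self):
        y, panel, model = self._fitted(seed=21)
        k = model.selected[0]
        prof = jl.lod_profile(y, panel, model, k)
        assert (prof["lod"] >= 0).all()
        assert len(prof) <= 9

    def test_chromosome_end_truncates_window(self):
        y, panel, model = self._fitted(seed=24)
        prof = jl.lod_profile(y, panel, model, 1)
        assert prof["marker"].min() == 0


class TestCI2LOD:
    def test_three_marker_example(self):
        prof = pd.DataFrame({"marker": [10, 11, 12], "lod": [3.0, 8.0, 3.0]})
        ci = jl.ci_2lod(prof)
        assert (ci["lo_marker"], ci["hi_marker"]) == (10, 12)
        assert not ci["truncated"]

    def test_peak_only_degenerate(self):
        prof = pd.DataFrame({"marker": [5], "lod": [9.0]})
        ci = jl.ci_2lod(prof)
        assert ci["lo_marker"] == ci["hi_marker"] == 5
        assert ci["truncated"]

    def test_flat_profile_flagged(self):
        prof = pd.DataFrame({"marker": [1, 2, 3], "lod": [4.0, 4.0, 4.0]})
        ci = jl.ci_2lod(prof)
        assert ci["truncated"]
        assert (ci["lo_marker"], ci["hi_marker"]) == (1, 3)


class TestAlleleEffects:
    def test_noiseless_effect_exact(self):
        panel, lines, fam, codes = _panel(n_fam=2, n_ril=80, n_markers=10, seed=25)
        x = np.nan_to_num(panel.codes[:, 4], nan=1.0)
        y = 70 + 1.0 * x
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-4)
        model = jl.stepwise_select(y, panel, thr)
        assert model.selected == [4]
        eff = jl.allele_effects(y, panel, model)[4]
        assert np.allclose(eff["effect"], 1.0, atol=1e-8)

    def test_family_specific_effect_recovered(self):
        rng = np.random.default_rng(26)
        panel, lines, fam, codes = _panel(n_fam=3, n_ril=150, n_markers=10, seed=27)
        x = np.nan_to_num(panel.codes[:, 2], nan=1.0)
        in_f0 = np.array([fam[l] == "fam0" for l in lines])
        y = np.where(in_f0, 1.0 * x, 0.0) + rng.normal(0, 0.3, len(lines))
        thr = jl.SelectionThreshold(alpha=0.05, n_permutations=0, p_enter=1e-4)
        model = jl.stepwise_select(y, panel, thr)
        assert 2 in model.selected
        eff = jl.allele_effects(y, panel, model)[2].set_index("family")
        assert abs(eff.loc["fam0", "effect"] - 1.0) < 0.15
        assert eff.loc["fam0", "p"] < 0.05
        for f in ("fam1", "fam2"):
            assert abs(eff.loc[f, "effect"]) < 0.15

    def test_null_marker_significance_calibrated(self):
        # ~5% of family effects significant when the marker does nothing
        rng = np.random.default_rng(28)
        hits = total = 0
        panel, lines, fam, codes = _panel(n_fam=5, n_ril=60, n_markers=1, seed=29)
        for _ in range(200):
            y = rng.normal(size=len(lines))
            model = jl.QTLModel(forced_terms=["family"], selected=[0],
                                families=panel.families, n_obs=len(y))
            eff = jl.allele_effects(y, panel, model)[0]
            hits += int((eff["p"] < 0.05).sum())
            total += len(eff)
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)
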