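"""NAM-style synthetic populations with known truth.

Emulates the structure of a nested association mapping panel: several RIL
families that share one common parent, each family derived from a cross to a
distinct diverse parent and advanced by single seed descent (SSD) to F7.
Meiosis uses no-interference Poisson crossovers (Haldane model), a uniform
cM<->bp relation per chromosome by default, and low-coverage GBS noise is
layered on top (missing calls, allele flips, heterozygote undercalling).

Truth is retained at every level: per-RIL parental-origin segments and
breakpoints, founder haplotypes, and the family-nested additive QTL effects
driving simulated phenotypes.

All randomness flows from one seed through named, hierarchical streams
(:meth:`SimConfig.rng`), so any subset of the simulation is reproducible on
its own.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CALL_A, CALL_B, CALL_H, CALL_NA, GenotypeMatrix, PhenotypeTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic NAM panel.

    Defaults mirror the emulated design: ~180-200 RILs per family, F7 lines
    (six generations of selfing after the F1), and stand-in GBS noise rates
    (missing 0.3, allele error 0.01, het undercall 0.5) exposed here because
    the real per-call rates are not published.
    """

    n_families: int = 2
    rils_per_family: int = 200
    #: list of (name, length_bp, length_cM)
    chromosomes: list = field(default_factory=lambda: [("chr1", 200_000_000, 200.0)])
    snp_density: float = 5e-5          # SNP sites per bp (all families pooled)
    maf: float = 0.5                   # founder allele-frequency spectrum (scalar or (lo, hi))
    selfing_generations: int = 6       # F1 + 6 selfings = F7
    missing_rate: float = 0.3
    error_rate: float = 0.01
    het_undercall_rate: float = 0.5
    residual_het_target: float | None = None   # informational; implied by selfing depth
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "error_rate", "het_undercall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, length_bp, length_cm in self.chromosomes:
            if length_bp <= 0 or length_cm < 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, *key):
        """Named child generator: ``config.rng('founders')`` etc."""
        ints = [self.seed & 0x7FFFFFFF]
        for k in key:
            if isinstance(k, str):
                ints.append(zlib.crc32(k.encode()))
            else:
                ints.append(int(k) & 0xFFFFFFFF)
        return np.random.default_rng(np.random.SeedSequence(ints))

    def family_names(self):
        return [f"fam{i}" for i in range(self.n_families)]

    def draw_maf(self, rng, n):
        if np.isscalar(self.maf):
            return np.full(n, float(self.maf))
        lo, hi = self.maf
        return rng.uniform(lo, hi, size=n)


@dataclass
class FounderSet:
    """Founder haplotypes: one common parent plus one diverse parent per family.

    Haplotypes are 0/1 arrays over sites (which of the site's two allele
    symbols the founder carries).
    """

    chromosomes: list
    positions: dict          # chrom -> int array (1-based bp, strictly increasing)
    alleles: dict            # chrom -> (allele_a array, allele_b array)
    common: dict             # chrom -> 0/1 int8 array
    diverse: dict            # family -> {chrom -> 0/1 int8 array}

    def polymorphic(self, family, chrom):
        return self.common[chrom] != self.diverse[family][chrom]


@dataclass
class TruthSet:
    """Simulator ground truth.

    ``segments`` holds each RIL's homozygous parental-origin mosaic as
    (chrom, start bp, end bp, genotype) tuples with genotype 0 = common-parent
    homozygote, 2 = diverse-parent homozygote; residual-heterozygous stretches
    are collapsed into this mosaic (absorbed when both flanks agree, split at
    their midpoint when they disagree), matching the resolution at which an
    inbred line's genome is scored.  ``raw_segments`` keeps the uncollapsed
    diplotype mosaic with genotype 1 for heterozygous stretches.
    """

    chrom_lengths: dict
    segments: dict           # ril -> [(chrom, start, end, 0|2)]
    qtl: list = field(default_factory=list)
    raw_segments: dict | None = None

    def breakpoints(self, ril, chrom=None):
        """Internal boundaries of the collapsed mosaic (bp of segment ends)."""
        out = {}
        for c in self.chrom_lengths:
            segs = [s for s in self.segments[ril] if s[0] == c]
            out[c] = np.array([s[2] for s in segs[:-1]], dtype=np.int64)
        if chrom is not None:
            return out[chrom]
        return out

    def n_breakpoints(self, ril):
        return sum(len(v) for v in self.breakpoints(ril).values())

    def genotype_at(self, ril, chrom, pos, raw=True):
        source = self.raw_segments if (raw and self.raw_segments) else self.segments
        for c, s, e, g in source[ril]:
            if c == chrom and s <= pos <= e:
                return g
        raise KeyError(f"{chrom}:{pos} not covered for {ril}")


# ---------------------------------------------------------------------------
# haplotypes as step functions over genetic (cM) coordinates
# ---------------------------------------------------------------------------
# A haplotype is (cuts, origins): interior boundaries (sorted cM floats) and
# len(cuts)+1 origin labels; origin i applies on [cuts[i-1], cuts[i]).

def _const_hap(origin):
    return np.empty(0), np.array([origin], dtype=np.int8)


def _simplify(cuts, origins):
    if len(cuts) == 0:
        return cuts, origins
    keep = origins[1:] != origins[:-1]
    return cuts[keep], np.concatenate([origins[:1], origins[1:][keep]])


def _slice_hap(hap, lo, hi):
    """Origins and interior cuts of ``hap`` restricted to [lo, hi)."""
    cuts, origins = hap
    i = np.searchsorted(cuts, lo, side="right")
    j = np.searchsorted(cuts, hi, side="left")
    return cuts[i:j], origins[i:j + 1]


def simulate_gamete(parent, length_cm, rng):
    """One meiotic product of a diplotype.

    Crossover count is Poisson with mean ``length_cm / 100`` (no
    interference); positions are uniform in genetic coordinates.  Returns the
    gamete haplotype and the sorted crossover positions (cM).
    """
    h1, h2 = parent
    n_xo = rng.poisson(length_cm / 100.0)
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    start = int(rng.integers(2))
    bounds = np.concatenate([[0.0], xo, [length_cm]])
    cuts_out, origins_out = [], []
    for k in range(len(bounds) - 1):
        src = (h1, h2)[(start + k) % 2]
        c, o = _slice_hap(src, bounds[k], bounds[k + 1])
        if k > 0:
            cuts_out.append([bounds[k]])
        cuts_out.append(c)
        origins_out.append(o)
    cuts = np.concatenate(cuts_out) if cuts_out else np.empty(0)
    origins = np.concatenate(origins_out)
    return _simplify(cuts, origins), xo


def _origins_at(hap, x_cm):
    cuts, origins = hap
    return origins[np.searchsorted(cuts, x_cm, side="right")]


def _self_one_generation(diplo, length_cm, rng):
    g1, _ = simulate_gamete(diplo, length_cm, rng)
    g2, _ = simulate_gamete(diplo, length_cm, rng)
    return (g1, g2)


def simulate_ril_diplotype(length_cm, selfing_generations, rng):
    """F1 (one chromosome from each parent) advanced by SSD selfing."""
    diplo = (_const_hap(0), _const_hap(1))
    for _ in range(selfing_generations):
        diplo = _self_one_generation(diplo, length_cm, rng)
    return diplo


def _diplotype_genotype_segments(diplo, length_cm):
    """Merge the two haplotypes into (cut positions, genotype codes 0/1/2)."""
    (c1, o1), (c2, o2) = diplo
    cuts = np.union1d(c1, c2)
    mids = np.concatenate([[0.0], cuts, [length_cm]])
    mids = (mids[:-1] + mids[1:]) / 2.0
    g = _origins_at((c1, o1), mids).astype(np.int16) + _origins_at((c2, o2), mids)
    return _simplify(cuts, g.astype(np.int8))


def _cm_to_bp(x_cm, length_cm, length_bp):
    if length_cm == 0:
        return np.full_like(np.asarray(x_cm, dtype=float), length_bp, dtype=np.int64)
    bp = np.rint(np.asarray(x_cm, dtype=float) / length_cm * length_bp).astype(np.int64)
    return np.clip(bp, 1, length_bp)


def _segments_bp(cuts_cm, values, length_cm, length_bp, chrom):
    """cM step function -> 1-based inclusive bp segments tiling the chromosome."""
    bp_cuts = _cm_to_bp(cuts_cm, length_cm, length_bp) if len(cuts_cm) else np.empty(0, np.int64)
    ends = np.concatenate([bp_cuts, [length_bp]]).astype(np.int64)
    segs = []
    start = 1
    for v, end in zip(values, ends):
        if end >= start:  # drop segments collapsed to zero bp by rounding
            segs.append((chrom, start, int(end), int(v)))
            start = int(end) + 1
    # merge adjacent equal-genotype segments (can appear after bp rounding)
    merged = [list(segs[0])]
    for s in segs[1:]:
        if s[3] == merged[-1][3]:
            merged[-1][2] = s[2]
        else:
            merged.append(list(s))
    return [tuple(s) for s in merged]


def _collapse_het(segs):
    """Replace heterozygous stretches by their homozygous flanks.

    A het run flanked by identical homozygous genotypes (or lying at a
    chromosome end) is absorbed; one flanked by differing genotypes is split
    at its midpoint.  Returns None if the whole chromosome is heterozygous.
    """
    hom = [list(s) for s in segs if s[3] != 1]
    if not hom:
        return None
    out = [hom[0]]
    for s in hom[1:]:
        if s[3] == out[-1][3]:
            out[-1][2] = s[2]
        else:
            mid = (out[-1][2] + s[1]) // 2  # split any gap (het run) between them
            out[-1][2] = mid
            s[1] = mid + 1
            out.append(s)
    out[0][1] = segs[0][1]
    out[-1][2] = segs[-1][2]
    return [tuple(s) for s in out]


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------

def simulate_founders(config):
    """Draw SNP positions and founder haplotypes.

    Each site gets a population allele frequency from the MAF spectrum; every
    founder (common parent included) draws its allele from that frequency, so
    a site is polymorphic within a family iff the diverse parent differs from
    the common parent there (probability ``2 p (1-p)``).
    """
    rng = config.rng("founders")
    positions, alleles, common, diverse = {}, {}, {}, {f: {} for f in config.family_names()}
    for name, length_bp, _ in config.chromosomes:
        n = int(round(config.snp_density * length_bp))
        if n > 0:
            pos = np.sort(rng.choice(length_bp, size=min(n, length_bp), replace=False)) + 1
        else:
            pos = np.empty(0, dtype=np.int64)
        n = len(pos)
        positions[name] = pos.astype(np.int64)
        a_idx = rng.integers(4, size=n)
        b_idx = (a_idx + rng.integers(1, 4, size=n)) % 4
        alleles[name] = (_BASES[a_idx], _BASES[b_idx])
        p = config.draw_maf(rng, n)
        common[name] = (rng.random(n) < p).astype(np.int8)
        for f in config.family_names():
            diverse[f][name] = (rng.random(n) < p).astype(np.int8)
    return FounderSet(chromosomes=list(config.chromosomes), positions=positions,
                      alleles=alleles, common=common, diverse=diverse)


def simulate_ssd_family(founders, config, family=None, ril_names=None):
    """Simulate one family's F7 RILs; returns (diplotypes, TruthSet).

    ``diplotypes`` maps RIL -> {chrom -> (hap, hap)} in parental-origin space
    (0 = common parent, 1 = diverse parent).
    """
    family = family or config.family_names()[0]
    fam_index = config.family_names().index(family)
    if not any(founders.polymorphic(family, c[0]).any() for c in config.chromosomes):
        raise ValueError(f"founders of {family} are monomorphic everywhere")
    n = config.rils_per_family
    ril_names = ril_names or [f"{family}_ril{i:04d}" for i in range(n)]
    rng = config.rng("meiosis", fam_index)
    diplotypes, segments, raw_segments = {}, {}, {}
    chrom_lengths = {c[0]: c[1] for c in config.chromosomes}
    for ril in ril_names:
        diplotypes[ril], segs_all, raw_all = {}, [], []
        for name, length_bp, length_cm in config.chromosomes:
            diplo = simulate_ril_diplotype(length_cm, config.selfing_generations, rng)
            diplotypes[ril][name] = diplo
            cuts, g = _diplotype_genotype_segments(diplo, length_cm)
            raw = _segments_bp(cuts, g * 1, length_cm, length_bp, name)
            # genotype code: origin sum 0/1/2 == common hom / het / diverse hom
            raw_all.extend(raw)
            hom = _collapse_het(raw)
            if hom is not None:
                segs_all.extend(hom)
        segments[ril] = segs_all
        raw_segments[ril] = raw_all
    truth = TruthSet(chrom_lengths=chrom_lengths, segments=segments,
                     raw_segments=raw_segments)
    return diplotypes, truth


def true_genotype_matrix(founders, diplotypes, family_of, config):
    """Noise-free four-state calls of the simulated RILs at the SNP sites."""
    rils = list(diplotypes)
    sites_frames, calls_cols = [], []
    for name, length_bp, length_cm in config.chromosomes:
        pos = founders.positions[name]
        if len(pos) == 0:
            continue
        x_cm = pos / length_bp * length_cm
        a_sym, b_sym = founders.alleles[name]
        sites_frames.append(pd.DataFrame({
            "chrom": name, "pos": pos, "allele_a": a_sym, "allele_b": b_sym}))
        block = np.empty((len(rils), len(pos)), dtype=np.int8)
        for i, ril in enumerate(rils):
            fam = family_of[ril]
            h1, h2 = diplotypes[ril][name]
            o1 = _origins_at(h1, x_cm)
            o2 = _origins_at(h2, x_cm)
            hap_c, hap_d = founders.common[name], founders.diverse[fam][name]
            al1 = np.where(o1 == 0, hap_c, hap_d)
            al2 = np.where(o2 == 0, hap_c, hap_d)
            block[i] = np.where(al1 == al2, np.where(al1 == 0, CALL_A, CALL_B), CALL_H)
        calls_cols.append(block)
    sites = pd.concat(sites_frames, ignore_index=True) if sites_frames else pd.DataFrame(
        columns=["chrom", "pos", "allele_a", "allele_b"])
    calls = np.hstack(calls_cols) if calls_cols else np.zeros((len(rils), 0), np.int8)
    return GenotypeMatrix(lines=rils, family_of=dict(family_of), sites=sites, calls=calls)


def apply_gbs_noise(matrix, config, rng=None):
    """Low-coverage GBS noise: per call, independently,

    * set missing with probability ``missing_rate``;
    * a surviving homozygote flips to the other homozygote with probability
      ``error_rate``;
    * a surviving heterozygote is reported as a random homozygote with
      probability ``het_undercall_rate``.
    """
    rng = rng or config.rng("gbs-noise")
    calls = matrix.calls.copy()
    shape = calls.shape
    miss = rng.random(shape) < config.missing_rate
    flip = rng.random(shape) < config.error_rate
    undercall = rng.random(shape) < config.het_undercall_rate
    random_hom = rng.integers(2, size=shape).astype(np.int8)
    is_hom = (calls == CALL_A) | (calls == CALL_B)
    calls = np.where(is_hom & flip, 1 - calls, calls)
    calls = np.where((matrix.calls == CALL_H) & undercall, random_hom, calls)
    calls = np.where(miss | (matrix.calls == CALL_NA), CALL_NA, calls)
    return GenotypeMatrix(lines=list(matrix.lines), family_of=dict(matrix.family_of),
                          sites=matrix.sites.copy(), calls=calls.astype(np.int8))


def simulate_panel(config):
    """Full panel: founders, all families' RILs, truth, clean + noisy calls.

    Returns (founders, truth, clean GenotypeMatrix, noisy GenotypeMatrix).
    """
    founders = simulate_founders(config)
    diplotypes, family_of = {}, {}
    truth = None
    for fam in config.family_names():
        d, t = simulate_ssd_family(founders, config, family=fam)
        diplotypes.update(d)
        family_of.update({ril: fam for ril in d})
        if truth is None:
            truth = t
        else:
            truth.segments.update(t.segments)
            truth.raw_segments.update(t.raw_segments)
    clean = true_genotype_matrix(founders, diplotypes, family_of, config)
    noisy = apply_gbs_noise(clean, config)
    return founders, truth, clean, noisy


def founder_genotype_matrix(founders, config):
    """Founders as a GenotypeMatrix (common parent + each diverse parent).

    The common parent is listed once under family ``common``; each diverse
    parent is named ``P_<family>`` and assigned to its family.
    """
    lines = ["P_common"] + [f"P_{f}" for f in config.family_names()]
    family_of = {"P_common": "common"}
    family_of.update({f"P_{f}": f for f in config.family_names()})
    sites_frames, cols = [], []
    for name, length_bp, _ in config.chromosomes:
        pos = founders.positions[name]
        if len(pos) == 0:
            continue
        a_sym, b_sym = founders.alleles[name]
        sites_frames.append(pd.DataFrame({
            "chrom": name, "pos": pos, "allele_a": a_sym, "allele_b": b_sym}))
        block = np.empty((len(lines), len(pos)), dtype=np.int8)
        block[0] = np.where(founders.common[name] == 0, CALL_A, CALL_B)
        for i, f in enumerate(config.family_names(), start=1):
            block[i] = np.where(founders.diverse[f][name] == 0, CALL_A, CALL_B)
        cols.append(block)
    sites = pd.concat(sites_frames, ignore_index=True)
    return GenotypeMatrix(lines=lines, family_of=family_of, sites=sites,
                          calls=np.hstack(cols))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(truth, family_of, qtl, n_envs=6, n_reps=2, h2=0.9,
                       family_means=None, env_sd=2.0, var_ge=0.0, rng=None, seed=0):
    """Family-nested additive QTL phenotypes over a multi-environment trial.

    ``qtl`` is a list of dicts ``{"chrom", "pos", "effects": {family: days}}``.
    A line's genetic value is its family mean plus, per QTL, the family's
    additive allele effect times the line's genotype code (0 = common-parent
    homozygote, 2 = diverse, 1 = residual het), so the effect equals half the
    difference between the two homozygous classes.  Residual error variance is
    set so the line-mean broad-sense heritability matches ``h2``.
    """
    rng = rng or np.random.default_rng(seed)
    rils = sorted(truth.segments)
    fams = sorted({family_of[r] for r in rils})
    if family_means is None:
        family_means = {f: 70.0 + 2.0 * rng.standard_normal() for f in fams}
    for q in qtl:
        L = truth.chrom_lengths.get(q["chrom"])
        if L is None or not 1 <= q["pos"] <= L:
            raise ValueError(f"QTL at {q['chrom']}:{q['pos']} outside simulated genome")
    g = np.array([
        family_means[family_of[r]]
        + sum(q["effects"].get(family_of[r], 0.0) * truth.genotype_at(r, q["chrom"], q["pos"])
              for q in qtl)
        for r in rils
    ])
    var_g = float(np.var(g))
    if h2 >= 1.0 or var_g == 0.0:
        var_e = 0.0
    else:
        var_e = max(0.0, (var_g / h2 - var_g - var_ge / n_envs) * n_envs * n_reps)
    env_eff = rng.normal(0.0, env_sd, size=n_envs)
    records = []
    for e in range(n_envs):
        ge = (rng.normal(0.0, np.sqrt(var_ge), size=len(rils))
              if var_ge > 0 else np.zeros(len(rils)))
        for rep in range(n_reps):
            noise = (rng.normal(0.0, np.sqrt(var_e), size=len(rils))
                     if var_e > 0 else np.zeros(len(rils)))
            vals = g + env_eff[e] + ge + noise
            records.extend(
                (r, f"env{e}", rep + 1, v) for r, v in zip(rils, vals))
    df = pd.DataFrame(records, columns=["line", "env", "rep", "value"])
    return PhenotypeTable(df=df)


# ---------------------------------------------------------------------------
# outlier injection
# ---------------------------------------------------------------------------

def inject_outliers(matrix, n_contaminants=0, n_excess_het=0, rng=None, seed=0):
    """Plant known QC failures; returns (matrix, labels).

    Contaminants are lines whose calls are replaced by a copy of a line from a
    *different* family (the label and family assignment stay put).  Excess-het
    lines have heterozygous calls forced in until their het ratio exceeds 10 %.
    """
    rng = rng or np.random.default_rng(seed)
    families = matrix.families()
    if n_contaminants > 0 and len(families) < 2:
        raise ValueError("contamination requires at least two families")
    calls = matrix.calls.copy()
    lines = list(matrix.lines)
    chosen = rng.choice(len(lines), size=n_contaminants + n_excess_het, replace=False)
    labels = []
    for idx in chosen[:n_contaminants]:
        fam = matrix.family_of[lines[idx]]
        donors = [i for i, l in enumerate(lines) if matrix.family_of[l] != fam]
        donor = int(rng.choice(donors))
        calls[idx] = calls[donor]
        labels.append((lines[idx], "contaminant"))
    for idx in chosen[n_contaminants:]:
        n_sites = calls.shape[1]
        force = rng.random(n_sites) < 0.15
        calls[idx, force & (calls[idx] != CALL_NA)] = CALL_H
        labels.append((lines[idx], "excess_het"))
    out = GenotypeMatrix(lines=lines, family_of=dict(matrix.family_of),
                         sites=matrix.sites.copy(), calls=calls)
    return out, labels


# ---------------------------------------------------------------------------
# direct bin-genotype simulation (for QTL-scale experiments)
# ---------------------------------------------------------------------------

def simulate_bin_genotypes(n_families, rils_per_family, chromosomes, bins_per_chrom,
                           selfing_generations=6, seed=0, family_prefix="fam"):
    """Simulate F7 RIL genotypes directly at evenly spaced bin positions.

    Skips the SNP/noise layer: uses the same SSD meiosis model and reads each
    RIL's diplotype at ``bins_per_chrom`` evenly spaced marker positions.
    Returns (lines, family_of, codes, positions) with codes 0 (common hom),
    2 (diverse hom) and -1 (residual het, treated as missing downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        zlib.crc32(b"bin-genotypes")]))
    lines, family_of, rows = [], {}, []
    pos_frames = []
    for name, length_bp, length_cm in chromosomes:
        mids_cm = (np.arange(bins_per_chrom) + 0.5) / bins_per_chrom * length_cm
        mids_bp = _cm_to_bp(mids_cm, length_cm, length_bp)
        pos_frames.append(pd.DataFrame({"chrom": name, "pos": mids_bp, "cm": mids_cm}))
    positions = pd.concat(pos_frames, ignore_index=True)
    for f in range(n_families):
        fam = f"{family_prefix}{f}"
        for i in range(rils_per_family):
            ril = f"{fam}_ril{i:04d}"
            lines.append(ril)
            family_of[ril] = fam
            row = []
            for (name, length_bp, length_cm), frame in zip(chromosomes, pos_frames):
                diplo = simulate_ril_diplotype(length_cm, selfing_generations, rng)
                x = frame["cm"].to_numpy()
                s = _origins_at(diplo[0], x).astype(np.int16) + _origins_at(diplo[1], x)
                row.append(np.where(s == 1, -1, s).astype(np.int8))
            rows.append(np.concatenate(row))
    codes = np.vstack(rows)
    return lines, family_of, codes, positions
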