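"""From decoded per-site parental origins to recombination bins.

A *block* is a maximal run of sites decoded to the same parental origin for
one RIL; a *breakpoint* sits at the transition between two blocks of
different origin and is placed at the midpoint between the flanking observed
sites.  Blocks that are both short (< 1,500 kb) and thinly supported
(< 5 sequenced SNPs) are masked as missing to avoid calling false double
recombination; flanking blocks of equal origin are then re-merged.

A family's *recombination bins* partition each chromosome at the union of
all RILs' breakpoints; adjacent intervals with identical genotype columns
across all RILs are merged, so expanding bins back to SNP coordinates
reproduces every RIL's post-mask decoded genotype exactly.  Bins smaller
than 5 kb are merged into the next bin, and remaining missing bin genotypes
(transition regions) are imputed from the flanking bins or, where the flanks
disagree, by the same two-state HMM run over the RIL's bin sequence.

Bin genotypes are coded 0 (common-parent homozygote), 2 (diverse-parent
homozygote) and -1 (missing), matching the composite-map convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_hmm import HMMParams, posterior

CODE_COMMON = 0
CODE_DIVERSE = 2
CODE_NA = -1


@dataclass
class Block:
    ril: str
    chrom: str
    start: int          # first observed SNP position (1-based)
    end: int            # last observed SNP position
    genotype: int       # 0 common / 1 diverse (origin space)
    n_snps: int


@dataclass
class BinMap:
    """Ordered recombination bins with per-RIL genotype codes."""

    bins: pd.DataFrame          # columns chrom, start, end (1-based inclusive)
    lines: list
    genotypes: np.ndarray       # (n_lines, n_bins) int8 in {0, 2, -1}

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.lines), len(self.bins)):
            raise ValueError("genotype matrix shape does not match bins/lines")

    @property
    def n_bins(self):
        return len(self.bins)

    def chrom_slice(self, chrom):
        mask = (self.bins["chrom"] == chrom).to_numpy()
        return np.flatnonzero(mask)

    def widths(self):
        return (self.bins["end"] - self.bins["start"] + 1).to_numpy()

    def __eq__(self, other):
        if not isinstance(other, BinMap):
            return NotImplemented
        return (self.lines == other.lines
                and self.bins.reset_index(drop=True).equals(other.bins.reset_index(drop=True))
                and np.array_equal(self.genotypes, other.genotypes))


# ---------------------------------------------------------------------------
# blocks and breakpoints
# ---------------------------------------------------------------------------

def call_blocks(states, positions, ril="ril", chrom="chr"):
    """Maximal same-origin runs; returns (blocks, breakpoints).

    ``states`` codes 0/1/-1 per site; missing sites are skipped, so a run may
    span them.  Breakpoints are midpoints between the last site of one block
    and the first site of the next.
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    keep = states >= 0
    s = states[keep]
    p = positions[keep]
    if len(s) == 0:
        return [], np.empty(0, dtype=np.int64)
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(s)]])
    blocks = [
        Block(ril=ril, chrom=chrom, start=int(p[a]), end=int(p[b - 1]),
              genotype=int(s[a]), n_snps=int(b - a))
        for a, b in zip(starts, ends)
    ]
    bp = np.array([(blocks[k].end + blocks[k + 1].start) // 2
                   for k in range(len(blocks) - 1)], dtype=np.int64)
    return blocks, bp


def mask_short_blocks(blocks, min_bp=1_500_000, min_snps=5, conjunction=True):
    """Mask thin short blocks; re-merge equal-origin flanks.

    A block is masked iff its physical span is under ``min_bp`` *and* it has
    fewer than ``min_snps`` sequenced SNPs (set ``conjunction=False`` to mask
    on either condition alone).  Returns (surviving blocks, masked blocks);
    surviving neighbours with equal origin are merged across the masked gap,
    the merged support being the sum of the surviving constituents' SNPs.
    """
    surviving, masked = [], []
    for b in blocks:
        short = (b.end - b.start + 1) < min_bp
        thin = b.n_snps < min_snps
        if (short and thin) if conjunction else (short or thin):
            masked.append(b)
        else:
            surviving.append(b)
    merged = []
    for b in surviving:
        if merged and merged[-1].genotype == b.genotype:
            prev = merged[-1]
            merged[-1] = replace(prev, end=b.end, n_snps=prev.n_snps + b.n_snps)
        else:
            merged.append(replace(b))
    return merged, masked


def blocks_to_site_states(blocks, positions):
    """Post-mask decoded genotype per site (oracle for the lossless check).

    Sites inside a surviving block's span take its origin; all others are -1.
    """
    positions = np.asarray(positions)
    out = np.full(len(positions), -1, dtype=np.int8)
    for b in blocks:
        out[(positions >= b.start) & (positions <= b.end)] = b.genotype
    return out


def ril_intervals(surviving, masked, chrom_length):
    """Tile [1, chrom_length] with (start, end, origin-or--1) for one RIL.

    The first and last surviving blocks extend to the chromosome ends.
    Between consecutive surviving blocks the boundary is the inter-site
    midpoint when the transition was direct, but the uncovered stretch stays
    missing when one or more masked blocks sat in between (the transition
    region whose genotype is later imputed).
    """
    if not surviving:
        return [(1, int(chrom_length), -1)]
    masked_pos = np.array(sorted(b.start for b in masked), dtype=np.int64)
    out = []
    first, last = surviving[0], surviving[-1]
    lead_masked = (masked_pos < first.start).any() if len(masked_pos) else False
    tail_masked = (masked_pos > last.end).any() if len(masked_pos) else False
    cursor = 1
    if lead_masked:
        out.append((1, first.start - 1, -1))
        cursor = first.start
    for k, b in enumerate(surviving):
        if k + 1 < len(surviving):
            nxt = surviving[k + 1]
            gap_masked = ((masked_pos > b.end) & (masked_pos < nxt.start)).any() \
                if len(masked_pos) else False
            if gap_masked:
                out.append((cursor, b.end, b.genotype))
                out.append((b.end + 1, nxt.start - 1, -1))
                cursor = nxt.start
            else:
                mid = (b.end + nxt.start) // 2
                out.append((cursor, mid, b.genotype))
                cursor = mid + 1
        else:
            if tail_masked:
                out.append((cursor, b.end, b.genotype))
                out.append((b.end + 1, int(chrom_length), -1))
            else:
                out.append((cursor, int(chrom_length), b.genotype))
    return [(s, e, g) for s, e, g in out if e >= s]


# ---------------------------------------------------------------------------
# family bins
# ---------------------------------------------------------------------------

def build_family_bins(intervals_by_ril, chrom_lengths):
    """Partition chromosomes at all RILs' boundaries and merge equal columns.

    ``intervals_by_ril`` maps RIL -> {chrom -> [(start, end, origin/-1)]}.
    Returns a BinMap whose expansion back to any position reproduces each
    RIL's interval value there (lossless compression of the post-mask
    genotypes).
    """
    lines = list(intervals_by_ril)
    if len(lines) < 2:
        raise ValueError("family bin calling needs at least two RILs")
    frames, cols = [], []
    for chrom, length in chrom_lengths.items():
        cut_set = set()
        for ril in lines:
            for s, e, _ in intervals_by_ril[ril].get(chrom, []):
                if e < length:
                    cut_set.add(e)
        cuts = np.array(sorted(cut_set), dtype=np.int64)
        edges = np.concatenate([cuts, [length]])
        starts = np.concatenate([[1], cuts + 1])
        geno = np.full((len(lines), len(edges)), CODE_NA, dtype=np.int8)
        for i, ril in enumerate(lines):
            for s, e, g in intervals_by_ril[ril].get(chrom, []):
                if g >= 0:
                    lo = np.searchsorted(starts, s)
                    hi = np.searchsorted(edges, e)
                    geno[i, lo:hi + 1] = CODE_DIVERSE if g == 1 else CODE_COMMON
        # merge adjacent identical columns (NA-equal)
        keep = np.ones(len(edges), dtype=bool)
        for k in range(1, len(edges)):
            if np.array_equal(geno[:, k], geno[:, k - 1]):
                keep[k] = False
        merged_starts, merged_ends, merged_cols = [], [], []
        k = 0
        while k < len(edges):
            j = k + 1
            while j < len(edges) and not keep[j]:
                j += 1
            merged_starts.append(int(starts[k]))
            merged_ends.append(int(edges[j - 1]))
            merged_cols.append(geno[:, k])
            k = j
        frames.append(pd.DataFrame({"chrom": chrom, "start": merged_starts,
                                    "end": merged_ends}))
        cols.append(np.column_stack(merged_cols))
    bins = pd.concat(frames, ignore_index=True)
    genotypes = np.hstack(cols) if cols else np.zeros((len(lines), 0), np.int8)
    return BinMap(bins=bins, lines=lines, genotypes=genotypes)


def expand_to_sites(bin_map, chrom, positions):
    """Per-RIL genotype codes at arbitrary positions (bin expansion)."""
    idx = bin_map.chrom_slice(chrom)
    sub = bin_map.bins.iloc[idx]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    j = np.searchsorted(ends, np.asarray(positions))
    j = np.clip(j, 0, len(idx) - 1)
    ok = (np.asarray(positions) >= starts[j]) & (np.asarray(positions) <= ends[j])
    out = bin_map.genotypes[:, idx[j]]
    out[:, ~ok] = CODE_NA
    return out


def merge_small_bins(bin_map, min_bp=5000):
    """Merge every bin narrower than ``min_bp`` (strict '<') into the next bin.

    The last bin of a chromosome merges backward instead.  The merged
    genotype column starts from the larger constituent; its missing entries
    are filled from the smaller one and disagreements become missing.
    """
    frames, cols = [], []
    for chrom in bin_map.bins["chrom"].unique():
        idx = bin_map.chrom_slice(chrom)
        rows = [[int(bin_map.bins["start"].iat[k]), int(bin_map.bins["end"].iat[k]),
                 bin_map.genotypes[:, k].copy()] for k in idx]
        k = 0
        while len(rows) > 1 and k < len(rows):
            s, e, g = rows[k]
            if e - s + 1 < min_bp:
                j = k + 1 if k + 1 < len(rows) else k - 1
                rows[j] = _merge_two(rows[k], rows[j])
                rows.pop(k)
            else:
                k += 1
        frames.append(pd.DataFrame({"chrom": chrom,
                                    "start": [r[0] for r in rows],
                                    "end": [r[1] for r in rows]}))
        cols.extend(r[2] for r in rows)
    bins = pd.concat(frames, ignore_index=True)
    return BinMap(bins=bins, lines=list(bin_map.lines),
                  genotypes=np.column_stack(cols))


def _merge_two(a, b):
    sa, ea, ga = a
    sb, eb, gb = b
    big, small = (ga, gb) if (ea - sa) >= (eb - sb) else (gb, ga)
    merged = big.copy()
    fill = (merged == CODE_NA) & (small != CODE_NA)
    merged[fill] = small[fill]
    conflict = (big != CODE_NA) & (small != CODE_NA) & (big != small)
    merged[conflict] = CODE_NA
    return [min(sa, sb), max(ea, eb), merged]


def impute_transition_bins(bin_map, chromosomes, params=None):
    """Fill missing bin genotypes; returns (BinMap, unresolved RIL/chrom list).

    A missing entry whose flanking non-missing bins agree takes their value;
    otherwise the RIL's bin sequence is decoded with the two-state HMM (bin
    midpoints in cM via the chromosome's uniform cM/bp relation) and the
    maximum-posterior state fills the gap.  RILs missing an entire chromosome
    are left missing and reported.
    """
    params = params or HMMParams()
    geno = bin_map.genotypes.copy()
    unresolved = []
    chrom_info = {c[0]: (c[1], c[2]) for c in chromosomes}
    for chrom in bin_map.bins["chrom"].unique():
        idx = bin_map.chrom_slice(chrom)
        length_bp, length_cm = chrom_info[chrom]
        mids_bp = ((bin_map.bins["start"].to_numpy()[idx]
                    + bin_map.bins["end"].to_numpy()[idx]) / 2.0)
        mids_cm = mids_bp / length_bp * length_cm
        block = geno[:, idx]
        for i in range(block.shape[0]):
            row = block[i]
            if (row == CODE_NA).all():
                unresolved.append((bin_map.lines[i], chrom))
                continue
            if (row == CODE_NA).any():
                block[i] = _fill_row(row, mids_cm, params)
        geno[:, idx] = block
    return BinMap(bins=bin_map.bins.copy(), lines=list(bin_map.lines),
                  genotypes=geno), unresolved


def _fill_row(row, mids_cm, params):
    out = row.copy()
    na = np.flatnonzero(row == CODE_NA)
    obs_idx = np.flatnonzero(row != CODE_NA)
    need_hmm = False
    for k in na:
        left = obs_idx[obs_idx < k]
        right = obs_idx[obs_idx > k]
        if len(left) and len(right) and row[left[-1]] == row[right[0]]:
            out[k] = row[left[-1]]
        elif len(left) and not len(right):
            out[k] = row[left[-1]]
        elif len(right) and not len(left):
            out[k] = row[right[0]]
        else:
            need_hmm = True
    if need_hmm:
        obs = np.where(row == CODE_NA, -1, (row == CODE_DIVERSE).astype(int))
        p1 = posterior(obs, mids_cm, params)
        fill = np.where(p1 > 0.5, CODE_DIVERSE, CODE_COMMON).astype(np.int8)
        still = out == CODE_NA
        out[still] = fill[still]
    return out


def binmap_breakpoints(bin_map, ril):
    """Inferred breakpoints per chromosome for one RIL.

    A breakpoint is recorded between consecutive non-missing bin genotypes
    that differ, at the midpoint of the uncovered stretch (which is just the
    shared bin boundary when no missing bins intervene).
    """
    i = bin_map.lines.index(ril)
    out = {}
    for chrom in bin_map.bins["chrom"].unique():
        idx = bin_map.chrom_slice(chrom)
        row = bin_map.genotypes[i, idx]
        ends = bin_map.bins["end"].to_numpy()[idx]
        starts = bin_map.bins["start"].to_numpy()[idx]
        obs = np.flatnonzero(row != CODE_NA)
        bps = []
        for a, b in zip(obs, obs[1:]):
            if row[a] != row[b]:
                bps.append((int(ends[a]) + int(starts[b]) - 1) // 2)
        out[chrom] = np.array(bps, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# whole-family driver
# ---------------------------------------------------------------------------

def family_bin_map(origins, site_index, sites, lines, chromosomes, params=None,
                   min_block_bp=1_500_000, min_block_snps=5, min_bin_bp=5000):
    """Decoded origins -> imputed family BinMap (the full per-family chain).

    ``origins`` is the RIL x retained-site origin matrix (-1 missing) from
    the HMM decoding step; ``sites`` the family site table; ``chromosomes``
    the (name, bp, cM) list.  Returns (skeleton BinMap before small-bin
    merging, final imputed BinMap, unresolved list).
    """
    params = params or HMMParams()
    chrom_lengths = {c[0]: c[1] for c in chromosomes}
    retained = sites.iloc[site_index]
    intervals = {ril: {} for ril in lines}
    for name, length_bp, length_cm in chromosomes:
        mask = (retained["chrom"] == name).to_numpy()
        pos = retained["pos"].to_numpy()[mask]
        for i, ril in enumerate(lines):
            blocks, _ = call_blocks(origins[i][mask], pos, ril=ril, chrom=name)
            surv, masked = mask_short_blocks(blocks, min_block_bp, min_block_snps)
            intervals[ril][name] = ril_intervals(surv, masked, length_bp)
    skeleton = build_family_bins(intervals, chrom_lengths)
    merged = merge_small_bins(skeleton, min_bin_bp)
    imputed, unresolved = impute_transition_bins(merged, chromosomes, params)
    return skeleton, imputed, unresolved
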