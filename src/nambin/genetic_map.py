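"""Genetic maps from recombination bins: per-family and multi-family composite.

Distances
---------
Observed discordance R between two bins in selfed RILs overstates the
meiotic recombination fraction because junctions accumulate over the selfing
generations; the Haldane-Waddington relation R = 2r/(1+2r) inverts to
r = R/(2-2R), and the Haldane map function d = -50*ln(1-2r) cM converts r to
distance (no interference).

Composite maps
--------------
Markers polymorphic in enough families (strictly more than ``min_families``)
are encoded 1 (common-parent allele) / 0 (diverse allele) / NA (het, missing
or family-monomorphic) across all RILs, binned like a single family, tested
for segregation distortion against the expected 1:1 ratio (1-df chi-square,
P < 0.05), and assembled: non-distorted markers form a framework map in
physical order (the reference genome anchors order, so likelihood is used
only for distances, with recombination fractions pooled over families);
distorted markers are inserted at their physical rank and excluded when
their genetic position conflicts with the flanking framework interval.
Linkage groups are checked by single-linkage clustering at a pairwise
linkage LOD of 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bin_builder import BinMap, CODE_NA

UNLINKED_CAP_CM = 50.0


@dataclass
class GeneticMap:
    """Ordered markers with physical and genetic positions.

    ``markers`` columns: marker, chrom, pos (bp), cm, distorted (bool),
    framework (bool).  cM is non-decreasing within a chromosome and
    framework markers are never distorted.
    """

    markers: pd.DataFrame
    log: list = field(default_factory=list)

    def chrom_length_cm(self, chrom):
        sub = self.markers[self.markers["chrom"] == chrom]
        return float(sub["cm"].max() - sub["cm"].min()) if len(sub) else 0.0

    def total_length_cm(self):
        return float(sum(self.chrom_length_cm(c) for c in self.markers["chrom"].unique()))


# ---------------------------------------------------------------------------
# recombination fractions and distances
# ---------------------------------------------------------------------------

def haldane_cm(r):
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * r)


def inverse_haldane(d_cm):
    d_cm = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-d_cm / 50.0))


def ril_correction(R):
    """Haldane-Waddington: observed RIL discordance -> meiotic r."""
    R = np.asarray(R, dtype=float)
    return R / (2.0 - 2.0 * R)


def rf_between_bins(col1, col2, min_informative=30):
    """(R observed, r meiotic, d cM, linked) between two genotype columns.

    Columns are codes over the same RILs (any two-level coding; NA = -1).
    Raises when fewer than ``min_informative`` RILs carry both bins.
    ``linked`` is False when the corrected r reaches 0.5, in which case d is
    capped at :data:`UNLINKED_CAP_CM`.
    """
    col1 = np.asarray(col1)
    col2 = np.asarray(col2)
    both = (col1 != CODE_NA) & (col2 != CODE_NA)
    n = int(both.sum())
    if n < min_informative:
        raise ValueError(f"only {n} jointly informative RILs (< {min_informative})")
    R = float((col1[both] != col2[both]).mean())
    r = float(ril_correction(min(R, 0.999)))
    if r >= 0.5:
        return R, 0.5, UNLINKED_CAP_CM, False
    return R, r, float(haldane_cm(r)), True


def linkage_lod(col1, col2):
    """LOD for linkage (r < 0.5) from observed discordance, 1-df test."""
    col1 = np.asarray(col1)
    col2 = np.asarray(col2)
    both = (col1 != CODE_NA) & (col2 != CODE_NA)
    n = int(both.sum())
    if n == 0:
        return 0.0
    k = int((col1[both] != col2[both]).sum())
    R = max(k / n, 1e-12)
    if R >= 0.5:
        return 0.0
    return k * np.log10(2.0 * R) + (n - k) * np.log10(2.0 * (1.0 - R))


# ---------------------------------------------------------------------------
# per-family map
# ---------------------------------------------------------------------------

def build_family_map(bin_map, min_informative=30):
    """Genetic map of one family's bins, ordered physically.

    cM positions are the cumulative sum of adjacent-bin Haldane distances;
    unlinked adjacent bins contribute the 50 cM cap and are logged.
    """
    rows, log = [], []
    for chrom in bin_map.bins["chrom"].unique():
        idx = bin_map.chrom_slice(chrom)
        cm = 0.0
        for seq, k in enumerate(idx):
            if seq > 0:
                prev = idx[seq - 1]
                _, _, d, linked = rf_between_bins(
                    bin_map.genotypes[:, prev], bin_map.genotypes[:, k],
                    min_informative=min_informative)
                if not linked:
                    log.append(f"unlinked adjacent bins {prev}->{k} on {chrom}; "
                               f"capped at {UNLINKED_CAP_CM} cM")
                cm += d
            rows.append({
                "marker": f"bin{k:05d}", "chrom": chrom,
                "pos": int((bin_map.bins['start'].iat[k] + bin_map.bins['end'].iat[k]) // 2),
                "cm": cm, "distorted": False, "framework": True,
            })
    return GeneticMap(markers=pd.DataFrame(rows), log=log)


# ---------------------------------------------------------------------------
# composite encoding and bins
# ---------------------------------------------------------------------------

def select_composite_markers(origin_matrices, positions, min_families=2):
    """Choose markers polymorphic in strictly more than ``min_families`` families
    and build the pooled composite encoding.

    ``origin_matrices`` maps family -> (lines, origin matrix) where the
    origin matrix codes 0 (common-parent origin), 1 (diverse), -1 (missing)
    over a shared site table ``positions`` (chrom, pos).  Sites a family has
    no data for are all -1 in its matrix.  The encoding designates the
    common-parent allele as 1 and the diverse allele as 0; markers
    monomorphic within a family are missing for that family's RILs.

    Returns (kept site mask, lines, encoding matrix with codes 1/0/-1).
    """
    fams = list(origin_matrices)
    n_sites = len(positions)
    poly_count = np.zeros(n_sites, dtype=int)
    for fam in fams:
        _, org = origin_matrices[fam]
        has0 = (org == 0).any(axis=0)
        has1 = (org == 1).any(axis=0)
        poly_count += (has0 & has1)
    keep = poly_count > min_families
    lines, blocks = [], []
    for fam in fams:
        fam_lines, org = origin_matrices[fam]
        sub = org[:, keep]
        has0 = (sub == 0).any(axis=0)
        has1 = (sub == 1).any(axis=0)
        mono = ~(has0 & has1)
        enc = np.where(sub == -1, CODE_NA, 1 - sub)  # origin 0 (common) -> code 1
        enc[:, mono] = CODE_NA
        lines.extend(fam_lines)
        blocks.append(enc.astype(np.int8))
    encoding = np.vstack(blocks) if blocks else np.zeros((0, int(keep.sum())), np.int8)
    return keep, lines, encoding


def composite_bins(encoding, positions, chrom_lengths, lines, min_bin_bp=5000):
    """Combine consecutive sites with identical code columns into joint bins.

    Mirrors the single-family bin construction: columns equal under NA-equal
    comparison merge; bins narrower than ``min_bin_bp`` merge into the next.
    Bin coordinates extend to chromosome ends and to inter-site midpoints.
    """
    from .bin_builder import merge_small_bins

    frames, cols = [], []
    for chrom, length in chrom_lengths.items():
        mask = (positions["chrom"] == chrom).to_numpy()
        pos = positions["pos"].to_numpy()[mask]
        enc = encoding[:, mask]
        if len(pos) == 0:
            continue
        # group runs of identical columns
        starts_run = [0]
        for j in range(1, len(pos)):
            if not np.array_equal(enc[:, j], enc[:, j - 1]):
                starts_run.append(j)
        starts_run.append(len(pos))
        run_start, run_end, run_col = [], [], []
        for a, b in zip(starts_run[:-1], starts_run[1:]):
            run_start.append(a)
            run_end.append(b - 1)
            run_col.append(enc[:, a])
        edges = []
        for k in range(len(run_start)):
            if k == 0:
                s = 1
            else:
                s = (pos[run_end[k - 1]] + pos[run_start[k]]) // 2 + 1
            e = length if k == len(run_start) - 1 else (pos[run_end[k]] + pos[run_start[k + 1]]) // 2
            edges.append((int(s), int(e)))
        frames.append(pd.DataFrame({"chrom": chrom,
                                    "start": [e[0] for e in edges],
                                    "end": [e[1] for e in edges]}))
        cols.append(np.column_stack(run_col))
    bins = pd.concat(frames, ignore_index=True)
    geno = np.hstack(cols)
    # reuse the BinMap container; codes here are 1/0/-1 rather than 0/2/-1
    bm = BinMap(bins=bins, lines=list(lines), genotypes=geno)
    return merge_small_bins(bm, min_bp=min_bin_bp)


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

def segregation_test(column, alpha=0.05):
    """1-df chi-square of the observed 1:0 code counts against 1:1.

    Returns (chi2, P, distorted).  Raises on a column with no informative
    calls.
    """
    column = np.asarray(column)
    obs = column != CODE_NA
    n1 = int((column[obs] == 1).sum())
    n0 = int((column[obs] == 0).sum())
    n = n1 + n0
    if n == 0:
        raise ValueError("no informative calls for segregation test")
    chi2 = (n1 - n0) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, p < alpha


# ---------------------------------------------------------------------------
# composite map assembly
# ---------------------------------------------------------------------------

def linkage_groups(bin_map, lod_threshold=10.0):
    """Single-linkage marker clusters at pairwise linkage LOD >= threshold."""
    from scipy.sparse import csgraph, csr_matrix

    g = bin_map.genotypes
    m = g.shape[1]
    obs = (g != CODE_NA)
    x1 = np.where(obs, g == 1, 0).astype(np.float32)
    x0 = np.where(obs, g == 0, 0).astype(np.float32)
    n_shared = (x1 + x0).T @ (x1 + x0)
    n_disc = x1.T @ x0 + x0.T @ x1
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n_shared > 0, n_disc / np.maximum(n_shared, 1), 0.5)
    R = np.clip(R, 1e-12, 0.5)
    lod = n_disc * np.log10(2 * R) + (n_shared - n_disc) * np.log10(2 * (1 - R))
    lod[R >= 0.5] = 0.0
    adj = csr_matrix(lod >= lod_threshold)
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    return labels


def assemble_composite_map(bin_map, lod_threshold=10.0, alpha=0.05,
                           min_informative=30, order_conflict_tol_cm=2.0):
    """Framework map plus distorted markers, physical order, pooled distances.

    Markers are clustered into linkage groups (error if a group spans two
    chromosomes — a sign of upstream contamination); non-distorted markers
    form the framework with cM from pooled recombination fractions between
    physically adjacent framework markers; each distorted marker is inserted
    at its physical rank with cM from its left framework neighbour and
    excluded when that genetic position overshoots the flanking framework
    interval by more than ``order_conflict_tol_cm``.
    """
    labels = linkage_groups(bin_map, lod_threshold)
    chroms = bin_map.bins["chrom"].to_numpy()
    for lab in np.unique(labels):
        grp_chroms = set(chroms[labels == lab])
        if len(grp_chroms) > 1:
            raise ValueError(f"linkage group {lab} spans chromosomes {sorted(grp_chroms)}")
    flags = []
    for k in range(bin_map.n_bins):
        _, _, distorted = segregation_test(bin_map.genotypes[:, k], alpha=alpha)
        flags.append(distorted)
    flags = np.asarray(flags)
    rows, log = [], []
    for chrom in bin_map.bins["chrom"].unique():
        idx = bin_map.chrom_slice(chrom)
        fw = [k for k in idx if not flags[k]]
        # framework chain: each marker's distance comes from the nearest
        # preceding framework marker with enough jointly informative RILs
        # (markers informative in disjoint family subsets can share no RILs)
        cm_of = {}
        cm = 0.0
        anchors = []
        for k in fw:
            d = None
            for prev in reversed(anchors[-50:]):
                try:
                    _, _, d, linked = rf_between_bins(
                        bin_map.genotypes[:, prev], bin_map.genotypes[:, k],
                        min_informative=min_informative)
                except ValueError:
                    continue
                if not linked:
                    log.append(f"unlinked framework markers {prev}->{k} on {chrom}")
                d = max(0.0, cm_of[prev] + d - cm)
                break
            if anchors and d is None:
                log.append(f"framework marker {k} on {chrom} shares too few RILs "
                           f"with its predecessors; placed at the running position")
                d = 0.0
            cm += d or 0.0
            cm_of[k] = cm
            anchors.append(k)
        for k in idx:
            if flags[k]:
                left = [f for f in fw if f < k]
                right = [f for f in fw if f > k]
                cm_k = None
                for prev in reversed(left[-50:]):
                    try:
                        _, _, d_left, _ = rf_between_bins(
                            bin_map.genotypes[:, prev], bin_map.genotypes[:, k],
                            min_informative=min_informative)
                    except ValueError:
                        continue
                    cm_k = cm_of[prev] + d_left
                    break
                if cm_k is None:
                    for nxt in right[:50]:
                        try:
                            _, _, d_right, _ = rf_between_bins(
                                bin_map.genotypes[:, k], bin_map.genotypes[:, nxt],
                                min_informative=min_informative)
                        except ValueError:
                            continue
                        cm_k = max(0.0, cm_of[nxt] - d_right)
                        break
                if cm_k is None:
                    log.append(f"marker {k} on {chrom} excluded: no informative "
                               f"neighbours")
                    continue
                if right and cm_k > cm_of[right[0]] + order_conflict_tol_cm:
                    log.append(f"marker {k} on {chrom} excluded: genetic position "
                               f"conflicts with physical order")
                    continue
                cm_of[k] = cm_k
        for k in sorted(cm_of):
            rows.append({
                "marker": f"jbin{k:05d}", "chrom": chrom,
                "pos": int((bin_map.bins['start'].iat[k] + bin_map.bins['end'].iat[k]) // 2),
                "cm": cm_of[k], "distorted": bool(flags[k]),
                "framework": not flags[k],
            })
    markers = pd.DataFrame(rows)
    # enforce non-decreasing cM in physical order (inserted markers between
    # framework anchors may not decrease; clip tiny inversions)
    for chrom in markers["chrom"].unique():
        sel = markers["chrom"] == chrom
        markers.loc[sel, "cm"] = np.maximum.accumulate(markers.loc[sel, "cm"].to_numpy())
    return GeneticMap(markers=markers, log=log)
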