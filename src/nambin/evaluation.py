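"""Truth-comparison metrics for simulated panels.

These are the quantities the pipeline reports when a simulator TruthSet is
available: breakpoint precision/recall, per-site parental-origin accuracy,
map-length error, and QTL detection summaries.
"""

from __future__ import annotations

import numpy as np

from .bin_builder import binmap_breakpoints


def _boundary_index(bin_map, chrom, x):
    """Index of the bin whose end is the first boundary at or past ``x``."""
    idx = bin_map.chrom_slice(chrom)
    ends = bin_map.bins["end"].to_numpy()[idx]
    return np.searchsorted(ends, np.asarray(x), side="left")


def match_breakpoints(bin_map, truth, lines=None, chroms=None):
    """Breakpoint recall and spurious-call rate against simulator truth.

    An inferred breakpoint is a bin boundary (the shared edge of bins k and
    k+1).  A true breakpoint t, lying inside bin j, counts as *recovered
    within one bin boundary* when some inferred boundary of the same RIL
    touches bin j or one of its neighbours, i.e. when k is within
    [j-2, j+1].  Spurious breakpoints are inferred boundaries matching no
    true breakpoint under the same rule.

    Returns a dict with recovered / true / spurious counts and rates.
    """
    lines = lines if lines is not None else bin_map.lines
    chroms = chroms if chroms is not None else list(bin_map.bins["chrom"].unique())
    n_true = n_rec = n_inferred = n_spur = 0
    for ril in lines:
        inferred = binmap_breakpoints(bin_map, ril)
        for chrom in chroms:
            tb = truth.breakpoints(ril, chrom)
            ib = inferred.get(chrom, np.empty(0, dtype=np.int64))
            tj = _boundary_index(bin_map, chrom, tb) if len(tb) else np.empty(0, int)
            ik = _boundary_index(bin_map, chrom, ib) if len(ib) else np.empty(0, int)
            n_true += len(tb)
            n_inferred += len(ib)
            for j in tj:
                if len(ik) and np.any((ik >= j - 2) & (ik <= j + 1)):
                    n_rec += 1
            for k in ik:
                if not len(tj) or not np.any((tj >= k - 1) & (tj <= k + 2)):
                    n_spur += 1
    return {
        "n_true": n_true,
        "n_recovered": n_rec,
        "n_inferred": n_inferred,
        "n_spurious": n_spur,
        "recall": n_rec / n_true if n_true else float("nan"),
        "spurious_rate": n_spur / n_true if n_true else float("nan"),
    }


def origin_accuracy(decoded, positions, truth, lines, chrom):
    """Fraction of confidently decoded sites matching the true origin.

    Sites inside residual-heterozygous truth segments are excluded (the
    two-state decoder has no het state to be right or wrong about).
    """
    num = den = 0
    for i, ril in enumerate(lines):
        segs = [s for s in truth.raw_segments[ril] if s[0] == chrom]
        ends = np.array([s[2] for s in segs])
        gvals = np.array([s[3] for s in segs])
        tg = gvals[np.searchsorted(ends, positions)]
        d = np.asarray(decoded[i])
        use = (d >= 0) & (tg != 1)
        num += int((np.where(d[use] == 1, 2, 0) == tg[use]).sum())
        den += int(use.sum())
    return num / den if den else float("nan")


def map_length_error(gmap, true_cm_by_chrom):
    """Relative error of estimated chromosome map lengths."""
    out = {}
    for chrom, true_cm in true_cm_by_chrom.items():
        sub = gmap.markers[gmap.markers["chrom"] == chrom]
        est = float(sub["cm"].max() - sub["cm"].min()) if len(sub) else 0.0
        out[chrom] = {"estimated_cm": est, "true_cm": true_cm,
                      "rel_error": abs(est - true_cm) / true_cm if true_cm else float("nan")}
    return out
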