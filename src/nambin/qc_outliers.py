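"""Outlier-line screens for NAM RIL panels.

Two screens, each preceded by its own site filter:

* **Contaminants** (lines carrying non-parental alleles): after a loose site
  filter (taxa coverage > 10 %, MAF > 0.01, site coverage > 20 %), a
  neighbor-joining tree per chromosome on identity-by-state (IBS) distances
  places every line next to its parents; a line whose nearest founder, on a
  majority of chromosomes, belongs to another family is flagged.  The tree is
  exported for manual review; the flag itself comes from the nearest-founder
  rule so the screen is automatic and reproducible.
* **Excess heterozygosity**: after a stringent per-family filter (site
  coverage > 66 %, MAF > 0.25), any line with het ratio strictly above 10 %
  is flagged.

All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CALL_A, CALL_B, CALL_H, CALL_NA, GenotypeMatrix


@dataclass
class SiteFilter:
    min_taxa_coverage: float = 0.10
    min_maf: float = 0.01
    min_site_coverage: float = 0.20

    def __post_init__(self):
        for f in (self.min_taxa_coverage, self.min_maf, self.min_site_coverage):
            if not 0.0 <= f <= 1.0:
                raise ValueError("site-filter thresholds must lie in [0, 1]")


@dataclass
class OutlierReport:
    line: str
    reason: str          # "contaminant" | "excess_het" | "unevaluable"
    evidence: dict


def site_stats(calls):
    """(MAF, site call rate) per column; het calls count one of each allele."""
    n_a = (calls == CALL_A).sum(axis=0)
    n_b = (calls == CALL_B).sum(axis=0)
    n_h = (calls == CALL_H).sum(axis=0)
    alleles_a = 2 * n_a + n_h
    alleles_b = 2 * n_b + n_h
    total = alleles_a + alleles_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(alleles_a, alleles_b) / np.maximum(total, 1), 0.0)
    call_rate = (calls != CALL_NA).mean(axis=0)
    return maf, call_rate


def filter_sites(matrix, flt=None):
    """Apply the site/line filter; all thresholds are strict ('>').

    Sites must satisfy MAF > min_maf and call rate > min_site_coverage; lines
    must satisfy call rate > min_taxa_coverage.  Removing everything is not an
    error: an empty matrix is returned (callers get a clear empty result).
    """
    flt = flt or SiteFilter()
    maf, site_cov = site_stats(matrix.calls)
    keep_sites = (maf > flt.min_maf) & (site_cov > flt.min_site_coverage)
    reduced = matrix.subset_sites(keep_sites)
    if reduced.n_sites == 0:
        return reduced
    taxa_cov = (reduced.calls != CALL_NA).mean(axis=1)
    keep_lines = [l for l, c in zip(reduced.lines, taxa_cov) if c > flt.min_taxa_coverage]
    return reduced.subset_lines(keep_lines)


# ---------------------------------------------------------------------------
# contaminant scan
# ---------------------------------------------------------------------------

def ibs_distance_matrix(calls):
    """Pairwise IBS distance: 1 - fraction of agreeing shared non-missing calls.

    A het compared against a homozygote counts as half a mismatch; pairs with
    zero overlap get distance NaN.
    """
    n = calls.shape[0]
    obs = (calls != CALL_NA).astype(np.float32)
    a = (calls == CALL_A).astype(np.float32)
    b = (calls == CALL_B).astype(np.float32)
    h = (calls == CALL_H).astype(np.float32)
    shared = obs @ obs.T
    agree = a @ a.T + b @ b.T + h @ h.T
    half = h @ (a + b).T
    half = half + half.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - (agree + 0.5 * half) / shared
    dist[shared == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist.astype(float)


def nj_tree(dist, names):
    """Neighbor-joining tree (scikit-bio) from a square distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = np.nan_to_num(np.asarray(dist, dtype=float), nan=1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return nj(DistanceMatrix(d, ids=list(names)))


def nj_contaminant_scan(matrix, founder_matrix, flt=None, make_trees=False,
                        margin=0.05):
    """Flag lines whose nearest founder is consistently from another family.

    Per chromosome, IBS similarity of each line to every founder is computed
    on the jointly filtered matrix; a line votes contaminant on a chromosome
    when some other family's diverse parent is strictly closer than its own
    family's diverse parent, and is flagged on a strict majority of
    chromosomes (ties break toward "not flagged").  The shared common parent
    carries no family information and is excluded from the comparison.

    ``margin`` guards against noise votes from lines whose mosaic happens to
    be almost entirely common-parent (such lines are nearly equidistant from
    every diverse parent): a chromosome only votes contaminant when the
    foreign parent is closer by more than this IBS margin, far below the
    ~0.25 separation a genuine cross-family copy shows.

    Returns (reports, trees) where trees maps chromosome -> skbio TreeNode
    (empty dict unless ``make_trees``).
    """
    if len(matrix.families()) < 2:
        raise ValueError("contaminant scan needs at least two families")
    flt = flt or SiteFilter()
    joint = GenotypeMatrix(
        lines=list(matrix.lines) + list(founder_matrix.lines),
        family_of={**matrix.family_of, **founder_matrix.family_of},
        sites=matrix.sites.copy(),
        calls=np.vstack([matrix.calls, founder_matrix.calls]),
    )
    joint = filter_sites(joint, flt)
    ril_lines = [l for l in matrix.lines if l in joint.lines]
    founder_lines = [l for l in founder_matrix.lines if l in joint.lines]
    unevaluable = [l for l in matrix.lines if l not in joint.lines]
    chroms = joint.sites["chrom"].unique()
    votes = pd.DataFrame(False, index=ril_lines, columns=range(len(chroms)))
    no_overlap = pd.DataFrame(False, index=ril_lines, columns=range(len(chroms)))
    trees = {}
    f_idx = [joint.lines.index(l) for l in founder_lines]
    f_fam = [joint.family_of[l] for l in founder_lines]
    for ci, chrom in enumerate(chroms):
        sub = joint.subset_sites((joint.sites["chrom"] == chrom).to_numpy())
        dist = ibs_distance_matrix(sub.calls)
        if make_trees:
            trees[chrom] = nj_tree(dist, sub.lines)
        for l in ril_lines:
            i = sub.lines.index(l)
            fam = sub.family_of[l]
            d_f = dist[i, f_idx]
            if np.all(np.isnan(d_f)):
                no_overlap.loc[l, ci] = True
                continue
            # the common parent is every family's parent, so only the diverse
            # parents discriminate family membership
            own = [d for d, ff in zip(d_f, f_fam) if ff == fam]
            other = [d for d, ff in zip(d_f, f_fam) if ff not in ("common", fam)]
            if not own or not other:
                continue
            own_best = np.nanmin(own)
            other_best = np.nanmin(other)
            # strict: some non-family diverse parent clearly closer than own
            votes.loc[l, ci] = bool(other_best < own_best - margin)
    reports = []
    for l in ril_lines:
        if no_overlap.loc[l].all():
            reports.append(OutlierReport(l, "unevaluable", {"chromosomes": 0}))
        elif votes.loc[l].sum() > len(chroms) / 2:
            reports.append(OutlierReport(
                l, "contaminant",
                {"chromosomes_voting": int(votes.loc[l].sum()),
                 "n_chromosomes": len(chroms)}))
    for l in unevaluable:
        reports.append(OutlierReport(l, "unevaluable", {"reason": "filtered out"}))
    return reports, trees


# ---------------------------------------------------------------------------
# excess heterozygosity scan
# ---------------------------------------------------------------------------

def excess_het_scan(matrix, flt=None, het_threshold=0.10):
    """Flag lines with het ratio strictly above ``het_threshold``.

    Sites are filtered per family with the stringent screen (site coverage
    > 66 %, MAF > 0.25) before the ratio is computed; the ratio is H calls
    over non-missing calls on the retained sites.
    """
    flt = flt or SiteFilter(min_taxa_coverage=0.0, min_maf=0.25, min_site_coverage=0.66)
    reports = []
    for fam in matrix.families():
        fam_m = matrix.family_matrix(fam)
        maf, cov = site_stats(fam_m.calls)
        keep = (maf > flt.min_maf) & (cov > flt.min_site_coverage)
        calls = fam_m.calls[:, keep]
        for i, line in enumerate(fam_m.lines):
            n_obs = int((calls[i] != CALL_NA).sum())
            if n_obs == 0:
                reports.append(OutlierReport(line, "unevaluable", {"retained_calls": 0}))
                continue
            ratio = float((calls[i] == CALL_H).sum() / n_obs)
            if ratio > het_threshold:
                reports.append(OutlierReport(
                    line, "excess_het", {"het_ratio": ratio, "retained_calls": n_obs}))
    return reports


def remove_outliers(matrix, reports):
    """Drop every line flagged contaminant or excess_het."""
    flagged = {r.line for r in reports if r.reason in ("contaminant", "excess_het")}
    keep = [l for l in matrix.lines if l not in flagged]
    return matrix.subset_lines(keep)
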