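"""Joint-linkage QTL mapping across NAM families.

The response (per-line BLUP) is regressed on forced family main effects plus
marker effects *nested within families*: at a given bin each family gets its
own allele-substitution slope, because each family segregates for a
different diverse-parent allele against the shared common parent.  Marker
terms enter and leave by stepwise selection against a genome-wide P-value
threshold calibrated by permutation (trait values shuffled within family so
the forced family structure is preserved).  For each selected QTL a LOD
profile over the four flanking markers per side gives a 2-LOD support
interval, and per-family allele effects are tested against the reference
(common-parent) effect with t-tests.

Marker coding is 0 (common-parent homozygote) / 2 (diverse) with missing
cells mean-imputed within family; a family where the marker does not
segregate contributes no slope.  In combined two-panel designs the reference
term distinguishing the two common parents is constant within family and is
therefore absorbed by the forced family effects; it is listed among the
forced terms for bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bin_builder import CODE_NA


@dataclass
class SelectionThreshold:
    alpha: float
    n_permutations: int
    p_enter: float

    def __post_init__(self):
        if not 0.0 < self.p_enter < 1.0:
            raise ValueError("p_enter must lie in (0, 1)")


@dataclass
class QTLModel:
    """Fitted joint-linkage model."""

    forced_terms: list
    selected: list                    # marker indices, selection order
    families: list
    effects: dict = field(default_factory=dict)    # marker -> DataFrame
    profiles: dict = field(default_factory=dict)   # marker -> DataFrame(idx, lod)
    intervals: dict = field(default_factory=dict)  # marker -> dict
    log: list = field(default_factory=list)
    rss: float = float("nan")
    n_obs: int = 0


class MarkerPanel:
    """Pre-processed marker matrix for nested-effect regression.

    ``codes``: lines x markers with 0/2/CODE_NA; within-family monomorphic
    markers are treated as missing for that family.  Builds, per marker, the
    family-centered nested design columns used throughout.
    """

    def __init__(self, codes, lines, family_of, positions=None):
        self.codes = np.asarray(codes, dtype=float)
        self.codes[self.codes == CODE_NA] = np.nan
        self.lines = list(lines)
        self.families = sorted({family_of[l] for l in lines})
        self.fam_idx = np.array([self.families.index(family_of[l]) for l in lines])
        self.positions = positions
        n, m = self.codes.shape
        self.n_lines, self.n_markers = n, m
        self.fam_masks = [self.fam_idx == f for f in range(len(self.families))]
        # family-centered, NaN-imputed-to-0 codes; segregation bookkeeping
        self.X = np.zeros((n, m), dtype=float)
        self.segregating = np.zeros((len(self.families), m), dtype=bool)
        for f, mask in enumerate(self.fam_masks):
            block = self.codes[mask]
            cnt = (~np.isnan(block)).sum(axis=0)
            mean = np.where(cnt > 0, np.nansum(block, axis=0) / np.maximum(cnt, 1), 0.0)
            centered = block - mean[None, :]
            centered[np.isnan(centered)] = 0.0
            self.X[mask] = centered
            mn = np.nanmin(block, axis=0, initial=np.inf)
            mx = np.nanmax(block, axis=0, initial=-np.inf)
            self.segregating[f] = np.isfinite(mn) & np.isfinite(mx) & (mn < mx)
            self.X[np.ix_(mask, ~self.segregating[f])] = 0.0
        self.q = self.segregating.sum(axis=0)  # nested slopes per marker

    def family_design(self):
        D = np.zeros((self.n_lines, len(self.families)))
        D[np.arange(self.n_lines), self.fam_idx] = 1.0
        return D

    def nested_columns(self, j):
        """Design columns of marker j: one centered column per segregating family."""
        cols = []
        for f, mask in enumerate(self.fam_masks):
            if self.segregating[f, j]:
                col = np.zeros(self.n_lines)
                col[mask] = self.X[mask, j]
                cols.append(col)
        return np.column_stack(cols) if cols else np.zeros((self.n_lines, 0))

    def segregating_families(self, j):
        return [self.families[f] for f in range(len(self.families))
                if self.segregating[f, j]]


# ---------------------------------------------------------------------------
# nested marker F-test
# ---------------------------------------------------------------------------

def _fit_rss(design, y):
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return float(((y - fitted) ** 2).sum()), rank, coef


def nested_marker_test(y, panel, j, covariate_markers=()):
    """F-test of adding marker j's family-nested term to the current model.

    The current model holds the forced family effects and the nested terms of
    ``covariate_markers``.  Returns (F, P, q) with q = number of segregating
    families (the numerator df).  Markers segregating nowhere return
    (nan, nan, 0).
    """
    q = int(panel.q[j])
    if q == 0:
        return float("nan"), float("nan"), 0
    base_cols = [panel.family_design()] + [panel.nested_columns(k) for k in covariate_markers]
    base = np.hstack(base_cols)
    full = np.hstack([base, panel.nested_columns(j)])
    rss0, rank0, _ = _fit_rss(base, y)
    rss1, rank1, _ = _fit_rss(full, y)
    df_num = rank1 - rank0
    df_den = len(y) - rank1
    if df_num == 0 or df_den <= 0 or rss1 <= 0:
        return float("nan"), float("nan"), q
    F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    P = float(stats.f.sf(F, df_num, df_den))
    return float(F), P, df_num


def _scan_null(y, panel, y_is_centered=False):
    """Vectorized nested-marker scan against the family-means-only model.

    Returns (F array, P array) over all markers.  Exploits the orthogonality
    of family-centered nested columns across markers: the model SS of marker
    j is sum over families of (x_f' y_f)^2 / (x_f' x_f).
    """
    if y_is_centered:
        yc = y
    else:
        yc = y.astype(float).copy()
        for mask in panel.fam_masks:
            yc[mask] -= yc[mask].mean()
    rss0 = float(yc @ yc)
    ss = np.zeros(panel.n_markers)
    for f, mask in enumerate(panel.fam_masks):
        Xf = panel.X[mask]
        cross = Xf.T @ yc[mask]
        ssx = (Xf ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(ssx > 0, cross ** 2 / np.maximum(ssx, 1e-300), 0.0)
        ss += term
    q = np.maximum(panel.q, 1)
    df_den = len(y) - len(panel.families) - panel.q
    rss1 = np.maximum(rss0 - ss, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss / q) / (rss1 / np.maximum(df_den, 1))
    P = stats.f.sf(F, panel.q, df_den)
    P[panel.q == 0] = np.nan
    F[panel.q == 0] = np.nan
    return F, P


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(y, panel, alpha=0.05, n_perm=1000, rng=None, seed=0):
    """Genome-wide P_enter from within-family permutations.

    Each permutation shuffles trait values within family (family means are
    forced model terms, so the permuted null preserves them), scans all
    markers against the family-means model and records the minimum P; the
    threshold is the empirical alpha-quantile of these minima, taken as the
    floor(alpha * n_perm)-th order statistic (inverted CDF), the standard
    choice for permutation-based genome-wide thresholds.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng or np.random.default_rng(seed)
    minima = permutation_minima(y, panel, n_perm, rng)
    k = max(int(np.floor(alpha * n_perm)), 1)
    p_enter = float(np.sort(minima)[k - 1])
    return SelectionThreshold(alpha=alpha, n_permutations=n_perm, p_enter=p_enter)


def permutation_minima(y, panel, n_perm, rng):
    """Min-over-markers P for each within-family permutation (vectorized).

    All permutations are scanned at once: per family, the centered trait
    block is column-shuffled via random sort keys and the nested-scan model
    SS accumulated with one matrix product per family.
    """
    yc = np.asarray(y, dtype=float).copy()
    for mask in panel.fam_masks:
        yc[mask] -= yc[mask].mean()
    ss = np.zeros((panel.n_markers, n_perm))
    rss0 = float(yc @ yc)
    for mask in panel.fam_masks:
        block = yc[mask]
        order = np.argsort(rng.random((mask.sum(), n_perm)), axis=0)
        Yp = block[order]                      # (n_f, n_perm)
        Xf = panel.X[mask]
        cross = Xf.T @ Yp                      # (m, n_perm)
        ssx = (Xf ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ss += np.where(ssx[:, None] > 0,
                           cross ** 2 / np.maximum(ssx, 1e-300)[:, None], 0.0)
    q = panel.q[:, None]
    df_den = (len(yc) - len(panel.families) - panel.q)[:, None]
    rss1 = np.maximum(rss0 - ss, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss / np.maximum(q, 1)) / (rss1 / np.maximum(df_den, 1))
    P = stats.f.sf(F, q, df_den)
    P[panel.q == 0] = np.nan
    return np.nanmin(P, axis=0)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(y, panel, threshold, p_exit=None, max_steps=40,
                    forced_terms=("family",)):
    """Forward-backward selection of family-nested marker effects.

    Forward: add the smallest-P marker while P < P_enter.  Backward: drop any
    selected marker whose removal P exceeds P_exit (default = P_enter).
    Family terms (and, in combined designs, the reference term they absorb)
    are never candidates for removal.  Iterates to a fixed point.
    """
    p_enter = threshold.p_enter
    p_exit = p_exit if p_exit is not None else p_enter
    y = np.asarray(y, dtype=float)
    model = QTLModel(forced_terms=list(forced_terms), selected=[],
                     families=list(panel.families), n_obs=len(y))
    for _ in range(max_steps):
        changed = False
        # forward
        cand_p = _candidate_pvalues(y, panel, model.selected)
        j_best = int(np.nanargmin(cand_p)) if np.isfinite(cand_p).any() else -1
        if j_best >= 0 and cand_p[j_best] < p_enter:
            model.selected.append(j_best)
            changed = True
        # backward
        removed = True
        while removed and len(model.selected) > 0:
            removed = False
            drop_p = {}
            for j in model.selected:
                others = [k for k in model.selected if k != j]
                _, P, _ = nested_marker_test(y, panel, j, covariate_markers=others)
                drop_p[j] = P if np.isfinite(P) else 1.0
            worst = max(drop_p, key=drop_p.get)
            if drop_p[worst] > p_exit:
                model.selected.remove(worst)
                model.log.append(f"backward: removed marker {worst} (P={drop_p[worst]:.3g})")
                removed = True
                changed = True
        if not changed:
            break
    design = np.hstack([panel.family_design()]
                       + [panel.nested_columns(k) for k in model.selected])
    model.rss, _, _ = _fit_rss(design, y)
    return model


def _candidate_pvalues(y, panel, selected):
    """P-values for adding each non-selected marker to the current model."""
    if not selected:
        _, P = _scan_null(y, panel)
        P = P.copy()
    else:
        base = np.hstack([panel.family_design()]
                         + [panel.nested_columns(k) for k in selected])
        Q, _ = np.linalg.qr(base)
        y_r = y - Q @ (Q.T @ y)
        rss0 = float(y_r @ y_r)
        rank0 = base.shape[1] - _rank_deficiency(base)
        P = np.full(panel.n_markers, np.nan)
        for j in range(panel.n_markers):
            if panel.q[j] == 0:
                continue
            Xj = panel.nested_columns(j)
            Xr = Xj - Q @ (Q.T @ Xj)
            g = Xr.T @ Xr
            rank_j = np.linalg.matrix_rank(g, tol=1e-8)
            if rank_j == 0:
                continue  # collinear with current model
            coef = np.linalg.lstsq(Xr, y_r, rcond=None)[0]
            ss = float(y_r @ (Xr @ coef))
            df_den = len(y) - rank0 - rank_j
            rss1 = max(rss0 - ss, 1e-300)
            if df_den <= 0:
                continue
            F = (ss / rank_j) / (rss1 / df_den)
            P[j] = stats.f.sf(F, rank_j, df_den)
    for j in selected:
        P[j] = np.nan
    return P


def _rank_deficiency(a):
    return a.shape[1] - np.linalg.matrix_rank(a, tol=1e-8)


# ---------------------------------------------------------------------------
# LOD profiles and support intervals
# ---------------------------------------------------------------------------

def lod_profile(y, panel, model, qtl_marker, n_flank=4):
    """LOD over the QTL's marker and up to ``n_flank`` markers per side.

    For each candidate position c the QTL's own term is swapped out for c's
    nested term while every other selected QTL stays in as a covariate:
    LOD(c) = (n/2) * log10(RSS_without / RSS_with).  Candidates are taken
    along the panel's marker order within the QTL's chromosome.
    """
    y = np.asarray(y, dtype=float)
    others = [k for k in model.selected if k != qtl_marker]
    base = np.hstack([panel.family_design()]
                     + [panel.nested_columns(k) for k in others])
    rss_without, _, _ = _fit_rss(base, y)
    candidates = _window(panel, qtl_marker, n_flank)
    n = len(y)
    rows = []
    for c in candidates:
        full = np.hstack([base, panel.nested_columns(c)])
        rss_with, _, _ = _fit_rss(full, y)
        lod = (n / 2.0) * np.log10(max(rss_without, 1e-300) / max(rss_with, 1e-300))
        rows.append({"marker": int(c), "lod": float(max(lod, 0.0))})
    return pd.DataFrame(rows)


def _window(panel, j, n_flank):
    if panel.positions is None:
        lo = max(0, j - n_flank)
        hi = min(panel.n_markers - 1, j + n_flank)
        return list(range(lo, hi + 1))
    chrom = panel.positions["chrom"].iloc[j]
    same = np.flatnonzero((panel.positions["chrom"] == chrom).to_numpy())
    pos_in = int(np.flatnonzero(same == j)[0])
    lo = max(0, pos_in - n_flank)
    hi = min(len(same) - 1, pos_in + n_flank)
    return [int(k) for k in same[lo:hi + 1]]


def ci_2lod(profile, drop=2.0):
    """2-LOD support interval over a profile DataFrame (marker, lod).

    Walks outward from the peak while LOD stays within ``drop`` of the peak
    and includes the first marker below the drop on each side; if the drop is
    never reached before the window edge the interval is truncated there and
    flagged.  Returns dict with marker index bounds, peak, and flag.
    """
    lods = profile["lod"].to_numpy()
    markers = profile["marker"].to_numpy()
    peak_pos = int(np.argmax(lods))
    cut = lods[peak_pos] - drop
    lo = peak_pos
    while lo > 0 and lods[lo - 1] >= cut:
        lo -= 1
    if lo > 0:
        lo -= 1          # include the first marker below the drop
        lo_trunc = False
    else:
        lo_trunc = lods[lo] >= cut
    hi = peak_pos
    while hi < len(lods) - 1 and lods[hi + 1] >= cut:
        hi += 1
    if hi < len(lods) - 1:
        hi += 1
        hi_trunc = False
    else:
        hi_trunc = lods[hi] >= cut
    return {
        "peak_marker": int(markers[peak_pos]),
        "lo_marker": int(markers[lo]),
        "hi_marker": int(markers[hi]),
        "truncated": bool(lo_trunc or hi_trunc),
        "peak_lod": float(lods[peak_pos]),
    }


def interval_physical(panel, interval):
    """(chrom, bp lo, bp hi, cM lo, cM hi) of a marker-index interval."""
    p = panel.positions
    lo, hi = interval["lo_marker"], interval["hi_marker"]
    out = {"chrom": p["chrom"].iloc[lo], "bp_lo": int(p["pos"].iloc[lo]),
           "bp_hi": int(p["pos"].iloc[hi])}
    if "cm" in p.columns:
        out["cm_lo"] = float(p["cm"].iloc[lo])
        out["cm_hi"] = float(p["cm"].iloc[hi])
    return out


# ---------------------------------------------------------------------------
# allele effects
# ---------------------------------------------------------------------------

def allele_effects(y, panel, model):
    """Per-family additive allele effects at each selected QTL.

    Effects are the family-nested slopes of the final model on the 0/2
    genotype coding: one unit of code is one allele substitution, so the
    slope is the additive allele effect (half the difference between the two
    homozygous classes).  Each effect is t-tested against the reference
    (common-parent) effect, which is the model baseline (zero), at the
    requested level; P-values are left uncorrected.
    """
    y = np.asarray(y, dtype=float)
    blocks = [panel.family_design()]
    col_info = [("family", f) for f in panel.families]
    for k in model.selected:
        blocks.append(panel.nested_columns(k))
        col_info.extend((k, fam) for fam in panel.segregating_families(k))
    design = np.hstack(blocks)
    n, p = design.shape
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df_den = n - rank
    sigma2 = float(resid @ resid) / df_den
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    out = {}
    for k in model.selected:
        rows = []
        for idx, (term, fam) in enumerate(col_info):
            if term != k:
                continue
            b = float(coef[idx])
            s = float(se[idx])
            t = b / s if s > 0 else np.inf * np.sign(b)
            P = float(2 * stats.t.sf(abs(t), df_den)) if np.isfinite(t) else 0.0
            rows.append({"family": fam, "effect": b, "se": s, "t": t, "p": P})
        out[k] = pd.DataFrame(rows)
    model.effects = out
    return out


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def joint_linkage_scan(y, panel, alpha=0.05, n_perm=1000, rng=None, seed=0,
                       n_flank=4, forced_terms=("family",)):
    """Threshold, stepwise model, profiles, intervals and effects in one call."""
    rng = rng or np.random.default_rng(seed)
    thr = permutation_threshold(y, panel, alpha=alpha, n_perm=n_perm, rng=rng)
    model = stepwise_select(y, panel, thr, forced_terms=forced_terms)
    for k in model.selected:
        prof = lod_profile(y, panel, model, k, n_flank=n_flank)
        model.profiles[k] = prof
        interval = ci_2lod(prof)
        if panel.positions is not None:
            interval.update(interval_physical(panel, interval))
        model.intervals[k] = interval
    allele_effects(y, panel, model)
    model.log.append(f"p_enter={thr.p_enter:.3g} (alpha={alpha}, {n_perm} permutations)")
    return model, thr
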