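"""Per-family inference of which observed allele came from the common parent.

Low-coverage GBS gives the RILs' alleles but not, directly, the parental
phase of each SNP.  Within one family every RIL is a mosaic of exactly two
parental haplotypes, so the correct per-site assignment is the one under
which RIL chromosomes switch parental origin as rarely as possible.  This is
a maximum-parsimony criterion:

    minimize  sum over adjacent site pairs of the number of RILs (observed at
    both sites, heterozygotes treated as missing) whose alleles imply a
    parental-origin switch under the candidate assignment pair,

solved exactly by a two-state shortest path (dynamic program) along the
physical site order.  The global sign is unidentifiable from RIL data alone;
it is anchored to known common-parent calls when supplied, else to the
majority allele of the first retained site.

Low-confidence sites are then removed by a resampling screen: RILs are
bootstrapped and the parsimony assignment recomputed on overlapping windows
of sites; a site's confidence q_j is the fraction of resampled windows whose
(sign-aligned) assignment agrees with the full-data assignment.  Published
Bayesian refinements of this step do not document their parameterization,
so this resampling-agreement score is the package's own, fully specified
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CALL_A, CALL_B, CALL_H, CALL_NA

#: assignment code: 0 means allele A is the common-parent allele at the site
A_IS_COMMON = 0
B_IS_COMMON = 1


@dataclass
class ParentalAssignment:
    """Per-site parental assignment for one family.

    ``assignment[j]`` is 0 (allele A is the common parent's) or 1; ``q[j]``
    is the resampling confidence in [0, 1] (1.0 before refinement).
    ``site_index`` maps each retained site back to the family matrix columns.
    """

    site_index: np.ndarray
    assignment: np.ndarray
    q: np.ndarray

    def __len__(self):
        return len(self.site_index)


def _binary_calls(calls):
    """Allele calls with het -> missing: 0 (A), 1 (B), -1 (missing)."""
    out = calls.astype(np.int8).copy()
    out[(calls == CALL_H) | (calls == CALL_NA)] = -1
    return out


def prefilter_family_sites(matrix, min_maf=0.05, tag_bp=64):
    """Family-level site filter before parental inference.

    Removes sites with within-family MAF < ``min_maf`` (strict '<'); among
    runs of sites within ``tag_bp`` of their predecessor (a proxy for SNPs on
    the same sequencing tag), keeps only the site with the highest call rate.
    """
    from .qc_outliers import site_stats

    maf, call_rate = site_stats(matrix.calls)
    keep = maf >= min_maf
    keep &= call_rate > 0
    reduced = matrix.subset_sites(keep)
    if reduced.n_sites == 0:
        return reduced
    rates = (reduced.calls != CALL_NA).mean(axis=0)
    sites = reduced.sites
    keep2 = np.ones(reduced.n_sites, dtype=bool)
    # group consecutive sites whose inter-site gap is < tag_bp (same chrom)
    start = 0
    for j in range(1, reduced.n_sites + 1):
        new_group = (
            j == reduced.n_sites
            or sites["chrom"].iat[j] != sites["chrom"].iat[j - 1]
            or sites["pos"].iat[j] - sites["pos"].iat[j - 1] >= tag_bp
        )
        if new_group:
            if j - start > 1:
                group = np.arange(start, j)
                best = group[np.argmax(rates[group])]
                keep2[group] = False
                keep2[best] = True
            start = j
    return reduced.subset_sites(keep2)


# ---------------------------------------------------------------------------
# parsimony DP
# ---------------------------------------------------------------------------

def _edge_costs(calls_bin):
    """Switch counts for each adjacent site pair.

    Returns (cost_same, cost_flip): cost_same[j] is the number of RILs whose
    calls differ between sites j and j+1 (a switch if a_j == a_{j+1});
    cost_flip[j] counts equal calls (a switch if the assignment flips).
    """
    left = calls_bin[:, :-1]
    right = calls_bin[:, 1:]
    obs = (left >= 0) & (right >= 0)
    diff = ((left != right) & obs).sum(axis=0)
    same = ((left == right) & obs).sum(axis=0)
    return diff.astype(np.int64), same.astype(np.int64)


def _dp_min_switches(cost_same, cost_flip):
    """Two-state shortest path; ties prefer no flip, then assignment 0.

    Returns (assignment starting at 0 convention resolved by tie rule,
    minimal total switch count).
    """
    n = len(cost_same) + 1
    f = np.zeros((n, 2))
    back = np.zeros((n, 2), dtype=np.int8)
    for j in range(1, n):
        for a in (0, 1):
            stay = f[j - 1, a] + cost_same[j - 1]
            move = f[j - 1, 1 - a] + cost_flip[j - 1]
            if stay <= move:          # tie -> agree with previous site
                f[j, a] = stay
                back[j, a] = a
            else:
                f[j, a] = move
                back[j, a] = 1 - a
    a_end = 0 if f[n - 1, 0] <= f[n - 1, 1] else 1
    assignment = np.empty(n, dtype=np.int8)
    assignment[n - 1] = a_end
    for j in range(n - 1, 0, -1):
        assignment[j - 1] = back[j, assignment[j]]
    return assignment, float(min(f[n - 1]))


def _dp_min_switches_batch(cost_same, cost_flip):
    """Vectorized two-state DP over many windows at once.

    ``cost_same``/``cost_flip`` have shape (n_windows, w-1); returns
    assignments of shape (n_windows, w) with the same tie rule as
    :func:`_dp_min_switches`.
    """
    n_win, m = cost_same.shape
    w = m + 1
    f = np.zeros((n_win, 2))
    back = np.zeros((n_win, w, 2), dtype=np.int8)
    for j in range(1, w):
        stay0 = f[:, 0] + cost_same[:, j - 1]
        move0 = f[:, 1] + cost_flip[:, j - 1]
        stay1 = f[:, 1] + cost_same[:, j - 1]
        move1 = f[:, 0] + cost_flip[:, j - 1]
        take_move0 = move0 < stay0
        take_move1 = move1 < stay1
        back[:, j, 0] = np.where(take_move0, 1, 0)
        back[:, j, 1] = np.where(take_move1, 0, 1)
        f = np.column_stack([np.where(take_move0, move0, stay0),
                             np.where(take_move1, move1, stay1)])
    assignment = np.empty((n_win, w), dtype=np.int8)
    assignment[:, w - 1] = np.where(f[:, 0] <= f[:, 1], 0, 1)
    rows = np.arange(n_win)
    for j in range(w - 1, 0, -1):
        assignment[:, j - 1] = back[rows, j, assignment[:, j]]
    return assignment


def switch_count(calls_bin, assignment):
    """Objective value of an assignment (oracle-friendly re-count)."""
    cost_same, cost_flip = _edge_costs(calls_bin)
    flips = assignment[:-1] != assignment[1:]
    return int(np.where(flips, cost_flip, cost_same).sum())


def infer_assignment_parsimony(matrix, anchor=None):
    """Maximum-parsimony parental assignment for one family matrix.

    ``anchor``, if given, is a vector of known common-parent calls over the
    matrix's sites (CALL_A/CALL_B/CALL_NA) used to fix the global sign;
    otherwise the majority allele of the first retained site is taken as the
    common parent's.  Heterozygous observed calls are ignored (treated
    missing).  All-missing sites are excluded before inference.
    """
    calls_bin = _binary_calls(matrix.calls)
    informative = (calls_bin >= 0).any(axis=0)
    site_index = np.flatnonzero(informative)
    if len(site_index) == 0:
        return ParentalAssignment(site_index, np.empty(0, np.int8), np.empty(0))
    sub = calls_bin[:, site_index]
    if (sub >= 0).any(axis=1).sum() < 2:
        raise ValueError("parsimony inference needs at least two RILs with calls")
    cost_same, cost_flip = _edge_costs(sub)
    assignment, _ = _dp_min_switches(cost_same, cost_flip)
    assignment = _fix_sign(assignment, sub, site_index, anchor)
    return ParentalAssignment(site_index=site_index, assignment=assignment,
                              q=np.ones(len(site_index)))


def _fix_sign(assignment, sub, site_index, anchor):
    if anchor is not None:
        anchor = np.asarray(anchor)
        anc = anchor[site_index]
        known = (anc == CALL_A) | (anc == CALL_B)
        if known.any():
            # assignment==0 says allele A is common; agree when anchor call is A
            agree = (assignment[known] == np.where(anc[known] == CALL_A, 0, 1)).sum()
            if agree * 2 < known.sum():
                return (1 - assignment).astype(np.int8)
            return assignment
    col = sub[:, 0]
    n_a = int((col == 0).sum())
    n_b = int((col == 1).sum())
    majority_common = A_IS_COMMON if n_a >= n_b else B_IS_COMMON
    if assignment[0] != majority_common:
        return (1 - assignment).astype(np.int8)
    return assignment


def het_tract_mask(calls, window=7, min_h=2):
    """Mask calls inside residual-heterozygosity tracts.

    In an F7 RIL a heterozygous tract is genotyped as a mixture of H calls
    and *random* homozygote calls (undercalled hets), which would otherwise
    be decoded as spurious short blocks.  Since allele-call errors only turn
    one homozygote into the other, H calls concentrate in genuine het tracts:
    any run of ``window`` consecutive observed calls containing at least
    ``min_h`` H calls is masked wholesale.  Returns a boolean matrix over
    ``calls``' shape (True = drop this call).
    """
    calls = np.asarray(calls)
    mask = np.zeros(calls.shape, dtype=bool)
    kernel = np.ones(window, dtype=int)
    for i in range(calls.shape[0]):
        obs_idx = np.flatnonzero(calls[i] != CALL_NA)
        if len(obs_idx) == 0:
            continue
        is_h = (calls[i, obs_idx] == CALL_H).astype(int)
        if len(obs_idx) < window:
            if is_h.sum() >= min_h:
                mask[i, obs_idx] = True
            continue
        counts = np.convolve(is_h, kernel, mode="valid")
        hit = np.zeros(len(obs_idx) + 1, dtype=int)
        bad = np.flatnonzero(counts >= min_h)
        hit[bad] += 1
        hit[bad + window] -= 1
        covered = np.cumsum(hit[:-1]) > 0
        mask[i, obs_idx[covered]] = True
    return mask


def origin_coded_calls(matrix, pa, mask_het_tracts=True, het_window=7, het_min_h=2):
    """Recode RIL calls to parental origin using an assignment.

    Returns (origins, site_index): origins is RIL x retained-site with 0 =
    common-parent origin, 1 = diverse, -1 = missing (het included).  By
    default calls falling in residual-heterozygosity tracts (see
    :func:`het_tract_mask`) are also set missing, so the undercalled random
    homozygotes inside them cannot masquerade as recombination.
    """
    calls = matrix.calls[:, pa.site_index]
    calls_bin = _binary_calls(calls)
    if mask_het_tracts:
        calls_bin[het_tract_mask(calls, window=het_window, min_h=het_min_h)] = -1
    origins = np.where(calls_bin < 0, -1, calls_bin ^ pa.assignment[None, :])
    return origins.astype(np.int8), pa.site_index


# ---------------------------------------------------------------------------
# resampling refinement
# ---------------------------------------------------------------------------

def _window_starts(n_sites, w):
    if w >= n_sites:
        return np.array([0])
    step = max(1, w // 2)
    starts = np.arange(0, n_sites - w + 1, step)
    if starts[-1] != n_sites - w:
        starts = np.append(starts, n_sites - w)
    return starts


def refine_by_resampling(matrix, pa, n_resamples=200, window_w=15, q_min=0.9, rng=None):
    """Resampling confidence q_j per site; sites with q_j < q_min are dropped.

    Per resample, RILs are drawn with replacement and the parsimony DP re-run
    on overlapping windows of ``window_w`` sites (stride w/2).  Each window's
    assignment is sign-aligned to the full-data assignment (majority vote
    within the window) and per-site agreement recorded; q_j averages over all
    (resample, window) pairs covering site j.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = rng or np.random.default_rng(0)
    calls_bin = _binary_calls(matrix.calls)[:, pa.site_index]
    n_ril, n_sites = calls_bin.shape
    if n_sites == 0:
        return pa
    starts = _window_starts(n_sites, min(window_w, n_sites))
    w = min(window_w, n_sites)
    agree = np.zeros(n_sites)
    count = np.zeros(n_sites)
    full = pa.assignment
    for _ in range(n_resamples):
        boot = rng.integers(n_ril, size=n_ril)
        weights = np.bincount(boot, minlength=n_ril).astype(np.int64)
        cost_same, cost_flip = _weighted_edge_costs(calls_bin, weights)
        if w > 1:
            idx = starts[:, None] + np.arange(w - 1)[None, :]
            assignments = _dp_min_switches_batch(cost_same[idx], cost_flip[idx])
        else:
            assignments = np.zeros((len(starts), 1), dtype=np.int8)
        win_idx = starts[:, None] + np.arange(w)[None, :]
        ref = full[win_idx]
        eq = assignments == ref
        flip_win = eq.sum(axis=1) * 2 < w  # sign-align each window
        eq[flip_win] = ~eq[flip_win]
        np.add.at(agree, win_idx.ravel(), eq.ravel())
        np.add.at(count, win_idx.ravel(), 1)
    q = np.where(count > 0, agree / np.maximum(count, 1), 1.0)
    keep = q >= q_min
    return ParentalAssignment(site_index=pa.site_index[keep],
                              assignment=pa.assignment[keep], q=q[keep])


def infer_and_refine(matrix, anchor=None, n_resamples=200, window_w=15, q_min=0.9,
                     rng=None, n_rounds=2):
    """Parsimony inference with iterated resampling screens.

    Low-quality sites (for instance family-monomorphic SNPs whose apparent
    polymorphism is pure calling error) contribute uninformative, noisy edges
    that can flip the parsimony chain's sign for a whole stretch of sites, so
    a single screen judged against the corrupted full-data assignment is not
    enough.  Each round therefore drops sites with q_j < q_min and re-runs
    the parsimony DP on the retained set before the next screen; window-level
    sign alignment makes q_j insensitive to which global stretch a run landed
    in.  Returns the final :class:`ParentalAssignment` (q from the last
    screen) expressed in the original matrix's site indices.
    """
    rng = rng or np.random.default_rng(0)
    current = matrix
    index_map = np.arange(matrix.n_sites)
    pa = None
    for _ in range(n_rounds):
        pa = infer_assignment_parsimony(current, anchor=anchor)
        pa = refine_by_resampling(current, pa, n_resamples=n_resamples,
                                  window_w=window_w, q_min=q_min, rng=rng)
        keep_cols = index_map[pa.site_index]
        mask = np.zeros(current.n_sites, dtype=bool)
        mask[pa.site_index] = True
        current = current.subset_sites(mask)
        if anchor is not None:
            anchor = np.asarray(anchor)[pa.site_index]
        index_map = keep_cols
    final = infer_assignment_parsimony(current, anchor=anchor)
    return ParentalAssignment(site_index=index_map[final.site_index],
                              assignment=final.assignment,
                              q=pa.q[final.site_index])


def _weighted_edge_costs(calls_bin, weights):
    left = calls_bin[:, :-1]
    right = calls_bin[:, 1:]
    obs = (left >= 0) & (right >= 0)
    wcol = weights[:, None]
    diff = (wcol * ((left != right) & obs)).sum(axis=0)
    same = (wcol * ((left == right) & obs)).sum(axis=0)
    return diff, same
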