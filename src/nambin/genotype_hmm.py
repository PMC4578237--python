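"""Two-state HMM decoding of parental origin along a RIL chromosome.

After parental inference each RIL's calls are origin-coded (0 = common
parent, 1 = diverse parent, heterozygotes already set to missing).  Single
miscalls from low-coverage sequencing show up as isolated flips inside long
parental blocks; posterior (forward-backward) decoding under a two-state
model corrects them.

Model
-----
* States: common / diverse parental origin.
* Transition probability between adjacent sites separated by d Morgans:
  ``0.5 * (1 - exp(-2 * rho * d))`` with junction rate ``rho`` per Morgan
  (default 2.0, the selfed-RIL map expansion; equivalently 0.02 per cM).
* Emission: observed origin equals the state with probability 1 - epsilon,
  is flipped with probability epsilon; missing sites emit nothing.
* Decoding: posterior state per site; sites whose maximum posterior falls
  below ``p_min`` (default 0.99) are reported missing, which feeds the
  transition-region missing rule downstream.  Posterior decoding is used
  instead of Viterbi precisely so that this confidence threshold exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


@dataclass
class HMMParams:
    epsilon: float = 0.01        # emission (allele-call) error
    rho: float = 2.0             # junction rate per Morgan (0.02 per cM)
    p_min: float = 0.99          # posterior confidence floor; below -> missing

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def transition_probs(pos_cm, rho):
    """Per-gap switch probability 0.5*(1-exp(-2 rho d_Morgan)), capped at 0.5."""
    d_morgan = np.diff(np.asarray(pos_cm, dtype=float)) / 100.0
    if (d_morgan < 0).any():
        raise ValueError("positions must be non-decreasing in cM")
    return np.minimum(0.5, 0.5 * (1.0 - np.exp(-2.0 * rho * d_morgan)))


def posterior(obs, pos_cm, params):
    """Forward-backward posterior P(state=diverse | data) per site.

    ``obs`` codes 0 (common), 1 (diverse), -1 (missing).  Accepts a single
    sequence (n_sites,) or a batch (n_seq, n_sites) sharing positions.
    Returns an array of the same leading shape with columns summing to one
    against the complementary state.
    """
    obs = np.asarray(obs)
    single = obs.ndim == 1
    if single:
        obs = obs[None, :]
    n_seq, n = obs.shape
    if n == 0:
        return np.zeros((0,)) if single else np.zeros((n_seq, 0))
    t = transition_probs(pos_cm, params.rho)
    eps = params.epsilon
    # emission likelihood for state 0 / state 1 per observation
    e0 = np.where(obs == -1, 1.0, np.where(obs == 0, 1.0 - eps, eps))
    e1 = np.where(obs == -1, 1.0, np.where(obs == 1, 1.0 - eps, eps))
    alpha = np.empty((n_seq, n, 2))
    scale = np.empty((n_seq, n))
    alpha[:, 0, 0] = 0.5 * e0[:, 0]
    alpha[:, 0, 1] = 0.5 * e1[:, 0]
    scale[:, 0] = alpha[:, 0].sum(axis=1)
    alpha[:, 0] /= scale[:, 0, None]
    for j in range(1, n):
        stay = 1.0 - t[j - 1]
        a0 = (alpha[:, j - 1, 0] * stay + alpha[:, j - 1, 1] * t[j - 1]) * e0[:, j]
        a1 = (alpha[:, j - 1, 1] * stay + alpha[:, j - 1, 0] * t[j - 1]) * e1[:, j]
        s = a0 + a1
        alpha[:, j, 0] = a0 / s
        alpha[:, j, 1] = a1 / s
        scale[:, j] = s
    beta = np.ones((n_seq, 2))
    post = np.empty((n_seq, n))
    post[:, n - 1] = alpha[:, n - 1, 1]
    for j in range(n - 2, -1, -1):
        stay = 1.0 - t[j]
        b0 = (stay * e0[:, j + 1] * beta[:, 0] + t[j] * e1[:, j + 1] * beta[:, 1])
        b1 = (t[j] * e0[:, j + 1] * beta[:, 0] + stay * e1[:, j + 1] * beta[:, 1])
        norm = b0 + b1
        beta = np.column_stack([b0 / norm, b1 / norm])
        raw0 = alpha[:, j, 0] * beta[:, 0]
        raw1 = alpha[:, j, 1] * beta[:, 1]
        post[:, j] = raw1 / (raw0 + raw1)
    return post[0] if single else post


def decode_ril(obs, pos_cm, params=None):
    """Posterior-decoded parental origin per site.

    Returns states coded 0 (common), 1 (diverse), -1 (missing: maximum
    posterior below ``p_min``).  Accepts single sequences or batches.
    """
    params = params or HMMParams()
    p1 = posterior(obs, pos_cm, params)
    state = (p1 > 0.5).astype(np.int8)
    conf = np.maximum(p1, 1.0 - p1)
    return np.where(conf < params.p_min, -1, state).astype(np.int8)


def posterior_bruteforce(obs, pos_cm, params):
    """Exhaustive path-sum posterior, for small instances only (oracle)."""
    obs = np.asarray(obs)
    n = len(obs)
    if n > 16:
        raise ValueError("brute-force oracle limited to 16 sites")
    t = transition_probs(pos_cm, params.rho)
    eps = params.epsilon
    mass1 = np.zeros(n)
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        p = 0.5
        for j in range(n):
            if obs[j] != -1:
                p *= (1.0 - eps) if obs[j] == path[j] else eps
            if j > 0:
                p *= t[j - 1] if path[j] != path[j - 1] else 1.0 - t[j - 1]
        total += p
        mass1 += p * np.asarray(path)
    return mass1 / total


def fit_epsilon(decoded, observed, prior_epsilon=0.01, min_calls=1000):
    """Mismatch fraction between confident decoded states and observed calls.

    Falls back to ``prior_epsilon`` when fewer than ``min_calls`` sites are
    both decoded (confidently) and observed.
    """
    decoded = np.asarray(decoded).ravel()
    observed = np.asarray(observed).ravel()
    use = (decoded >= 0) & (observed >= 0)
    if use.sum() < min_calls:
        return float(prior_epsilon)
    return float((decoded[use] != observed[use]).mean())
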