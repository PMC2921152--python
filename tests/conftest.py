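"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ldbscreen.hmm import MotifHMM
from ldbscreen.pwm import MotifMatrix, build_pwm_from_site


@pytest.fixture
def uniform_bg():
    return np.array([0.25, 0.25, 0.25, 0.25])


@pytest.fixture
def skewed_bg():
    return np.array([0.3, 0.2, 0.2, 0.3])


@pytest.fixture
def small_matrix():
    return build_pwm_from_site("ACGT", pseudocount=0.1, motif_id="small")


def brute_force_hmm_likelihood(hmm: MotifHMM, seq_ints) -> float:
    """Sum the joint probability over every state path (independent oracle)."""
    W, tau = hmm.width, hmm.tau
    A = np.zeros((W + 1, W + 1))
    A[0, 0] = 1 - tau
    A[0, 1] = tau
    for i in range(1, W):
        A[i, i + 1] = 1.0
    A[W, 0] = 1.0
    pi = np.zeros(W + 1)
    pi[0], pi[1] = 1 - tau, tau
    E = np.vstack([hmm.background, hmm.matrix.probs.T])
    total = 0.0
    T = len(seq_ints)
    for path in itertools.product(range(W + 1), repeat=T):
        p = pi[path[0]] * E[path[0], seq_ints[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * E[path[t], seq_ints[t]]
            if p == 0.0:
                break
        else:
            total += p
    return total


def brute_force_hmm_likelihood_batch(hmm: MotifHMM, seqs: np.ndarray) -> np.ndarray:
    """Path-enumeration likelihoods for an (n, T) batch of encoded sequences.

    Enumerates every state path once, drops zero-probability paths, and
    multiplies emissions across the batch; mathematically identical to the
    per-sequence oracle but usable for exhaustive alphabets.
    """
    n, T = seqs.shape
    W, tau = hmm.width, hmm.tau
    A = np.zeros((W + 1, W + 1))
    A[0, 0] = 1 - tau
    A[0, 1] = tau
    for i in range(1, W):
        A[i, i + 1] = 1.0
    A[W, 0] = 1.0
    pi = np.zeros(W + 1)
    pi[0], pi[1] = 1 - tau, tau
    E = np.vstack([hmm.background, hmm.matrix.probs.T])
    total = np.zeros(n)
    for path in itertools.product(range(W + 1), repeat=T):
        ptrans = pi[path[0]]
        for t in range(1, T):
            ptrans *= A[path[t - 1], path[t]]
            if ptrans == 0.0:
                break
        if ptrans == 0.0:
            continue
        emis = np.ones(n)
        for t, state in enumerate(path):
            emis *= E[state, seqs[:, t]]
        total += ptrans * emis
    return total


def step_up_fdr_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up rule, written independently."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def enumerate_null_distribution(matrix: MotifMatrix, background: np.ndarray):
    """Window-score null distribution by enumerating all 4^W windows.

    Returns (grid scores, probabilities) on the same integer grid the
    package uses, so the comparison with the dynamic program is exact.
    """
    from ldbscreen.pwm import grid_log_odds

    lo = grid_log_odds(matrix, background)[:, :4]
    W = matrix.width
    scores = {}
    for window in itertools.product(range(4), repeat=W):
        s = int(sum(lo[j, b] for j, b in enumerate(window)))
        pr = float(np.prod([background[b] for b in window]))
        scores[s] = scores.get(s, 0.0) + pr
    keys = np.array(sorted(scores))
    return keys, np.array([scores[k] for k in keys])
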