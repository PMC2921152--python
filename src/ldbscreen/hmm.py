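"""Whole-promoter motif scoring with a hidden Markov model.

Each binding-site matrix is expanded into a small HMM: a background state B
emitting background base frequencies, plus one match state per matrix column.
From B the chain either stays in background (probability 1 - tau) or enters a
site (tau); once inside, match states are traversed left to right with
probability 1 and the last column returns to background.  Because B is
re-enterable, the model naturally accounts for several binding sites of
varying affinity in one promoter.

A promoter's score is the log-likelihood ratio between this model and the
background-only model, computed with the forward algorithm in log space; both
strands are scored and the larger value taken.  Score shifts between a target
and a background promoter set are then assessed with a one-sided rank-sum
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .pwm import DNA, MotifMatrix, PromoterSet, _check_background


@dataclass
class MotifHMM:
    """Background state plus a left-to-right block of match states.

    Transitions: B->B (1-tau), B->M1 (tau), Mi->Mi+1 (1), MW->B (1).  The
    initial distribution mirrors B's outgoing probabilities (1-tau on B, tau
    on M1) so a site may start at the first base.  Emissions: B emits the
    background frequencies, Mi emits matrix column i.  N bases are treated as
    uninformative (emission probability 1 in every state and in the
    background-only model, so they cancel in the likelihood ratio).
    """

    matrix: MotifMatrix
    background: np.ndarray
    tau: float

    def __post_init__(self):
        self.background = _check_background(self.background)
        if not 0 < self.tau < 1:
            raise ValueError("site-entry rate tau must be in (0, 1)")

    @property
    def width(self) -> int:
        return self.matrix.width

    def log_emissions(self) -> tuple[np.ndarray, np.ndarray]:
        """(log background emissions, log match emissions), each with an N column.

        Background: shape (5,); match: shape (W, 5).  The N column is 0
        (= log 1) in both, making N bases uninformative.
        """
        with np.errstate(divide="ignore"):
            lb = np.log(self.background)
            lm = np.log(self.matrix.probs.T)  # (W, 4)
        lb = np.concatenate([lb, [0.0]])
        lm = np.concatenate([lm, np.zeros((self.width, 1))], axis=1)
        return lb, lm


def build_motif_hmm(matrix: MotifMatrix, background, tau: float | None = None,
                    promoter_length: int = 500) -> MotifHMM:
    """Convenience constructor; tau defaults to one expected site per promoter."""
    if tau is None:
        tau = 1.0 / promoter_length
    return MotifHMM(matrix, np.asarray(background, dtype=float), tau)


def forward_loglik(hmm: MotifHMM, encoded: np.ndarray) -> np.ndarray:
    """Log-likelihood of each encoded sequence under the HMM (natural log).

    ``encoded``: (n, T) int matrix with A=0..T=3, N=4.  Sums the forward
    variable over all end states, so partial sites at the 3' end are allowed.
    """
    encoded = np.atleast_2d(encoded)
    n, T = encoded.shape
    if T == 0:
        raise ValueError("sequences must be non-empty")
    W = hmm.width
    lb, lm = hmm.log_emissions()
    log_stay = math.log1p(-hmm.tau)
    log_enter = math.log(hmm.tau)

    with np.errstate(divide="ignore", invalid="ignore"):
        # alpha[:, 0] is B, alpha[:, i] is Mi
        alpha = np.full((n, W + 1), -np.inf)
        x = encoded[:, 0]
        alpha[:, 0] = log_stay + lb[x]
        alpha[:, 1] = log_enter + lm[0, x]
        for t in range(1, T):
            x = encoded[:, t]
            new = np.empty_like(alpha)
            new[:, 0] = np.logaddexp(alpha[:, 0] + log_stay, alpha[:, W]) + lb[x]
            new[:, 1] = alpha[:, 0] + log_enter + lm[0, x]
            if W > 1:
                new[:, 2:] = alpha[:, 1:W] + lm[1:, x].T
            alpha = new
        return logsumexp(alpha, axis=1)


def background_loglik(hmm: MotifHMM, encoded: np.ndarray) -> np.ndarray:
    """Log-likelihood under the background-only (i.i.d.) model."""
    encoded = np.atleast_2d(encoded)
    lb = np.concatenate([np.log(hmm.background), [0.0]])
    return lb[encoded].sum(axis=1)


def score_promoter_hmm(hmm: MotifHMM, sequence: str) -> float:
    """Log-likelihood-ratio score of one promoter, max over both strands."""
    ps = PromoterSet({"fwd": sequence})
    return float(score_promoters(hmm, ps)[0])


def score_promoters(hmm: MotifHMM, promoters: PromoterSet) -> np.ndarray:
    """Scores for every promoter in a set (order follows ``promoters.ids``)."""
    _, enc = promoters.encoded()
    if enc.shape[1] == 0:
        raise ValueError("sequences must be non-empty")
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    enc_rc = comp[enc[:, ::-1]]
    bg = background_loglik(hmm, enc)  # strand-symmetric only if bg is; score each strand vs its own bg
    bg_rc = background_loglik(hmm, enc_rc)
    fwd = forward_loglik(hmm, enc) - bg
    rev = forward_loglik(hmm, enc_rc) - bg_rc
    return np.maximum(fwd, rev)


def demon_enrichment(target_scores, background_scores) -> float:
    """One-sided rank-sum p-value for target scores exceeding background scores.

    Uses the normal approximation with tie correction; when both samples have
    at most 8 observations the p-value is computed by exact enumeration of the
    rank-sum permutation distribution instead.
    """
    t = np.asarray(target_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if t.size == 0 or b.size == 0:
        raise ValueError("score vectors must be non-empty")
    if t.size <= 8 and b.size <= 8:
        return _exact_ranksum_p(t, b)
    res = stats.mannwhitneyu(t, b, alternative="greater",
                             method="asymptotic", use_continuity=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p  # all-tied data carries no evidence


def _exact_ranksum_p(t: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([t, b])
    ranks = stats.rankdata(pooled)
    observed = ranks[: t.size].sum()
    total = 0
    at_least = 0
    for idx in combinations(range(pooled.size), t.size):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            at_least += 1
    return at_least / total
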