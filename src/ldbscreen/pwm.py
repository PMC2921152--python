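"""Position weight matrices, promoter containers, and threshold-scan site finding.

The threshold-scan method finds putative binding-site occurrences by sliding a
log-odds-scored window over both strands of each upstream region and calling a
promoter a "hit" when at least one window reaches a score threshold.  The
threshold is taken from the *exact* null score distribution of the matrix under
an order-0 background model, computed by dynamic programming over matrix
columns (scores are discretised to a fixed grid so the convolution is exact).
Set-level over-representation of hits is then assessed with an upper-tail
hypergeometric test against a background gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: score-grid resolution (log2 units); window scores and the exact null
#: distribution share this grid, so threshold comparisons are exact on it
SCORE_GRID = 1e-2
#: per-column log-odds floor replacing log2(0) for zero-probability bases
SCORE_FLOOR = -100.0


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PromoterSet:
    """Gene-id-keyed collection of upstream sequences.

    Sequences are the bases immediately 5' of the transcription start, written
    5'->3' on the gene's strand; positions are 0-based, half-open.  Ids must be
    unique; lengths must be uniform unless ``ragged=True``.
    """

    def __init__(self, sequences: Mapping[str, str], ragged: bool = False):
        seqs = {str(g): str(s).upper() for g, s in sequences.items()}
        if len(seqs) != len(sequences):
            raise ValueError("duplicate gene ids in promoter set")
        for g, s in seqs.items():
            if set(s) - set("ACGTN"):
                raise ValueError(f"promoter {g!r} contains non-ACGTN characters")
        lengths = {len(s) for s in seqs.values()}
        if not ragged and len(lengths) > 1:
            raise ValueError(f"promoter lengths are not uniform: {sorted(lengths)}")
        self._seqs = seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._seqs

    def __getitem__(self, gene_id: str) -> str:
        return self._seqs[gene_id]

    def __iter__(self):
        return iter(self._seqs)

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def items(self):
        return self._seqs.items()

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self._seqs]
        if missing:
            raise KeyError(f"gene ids absent from promoter set: {missing}")
        return PromoterSet({g: self._seqs[g] for g in ids})

    def base_frequencies(self) -> np.ndarray:
        """Empirical A/C/G/T frequencies pooled over all sequences (N ignored)."""
        counts = np.zeros(4)
        for s in self._seqs.values():
            for b, i in BASE_INDEX.items():
                counts[i] += s.count(b)
        total = counts.sum()
        if total == 0:
            raise ValueError("no A/C/G/T bases in promoter set")
        return counts / total

    def encoded(self) -> tuple[list[str], np.ndarray]:
        """Ids plus an (n, L) int8 matrix (A=0,C=1,G=2,T=3,N=4); uniform length only."""
        lengths = {len(s) for s in self._seqs.values()}
        if len(lengths) > 1:
            raise ValueError("cannot encode a ragged promoter set as a matrix")
        lut = np.full(256, 4, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        ids = list(self._seqs)
        mat = np.stack(
            [lut[np.frombuffer(self._seqs[g].encode(), dtype=np.uint8)] for g in ids]
        )
        return ids, mat

    @classmethod
    def from_fasta(cls, path, ragged: bool = False) -> "PromoterSet":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        return cls(records, ragged=ragged)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=g, description="") for g, s in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class MotifMatrix:
    """Column-stochastic base-probability representation of a binding site."""

    motif_id: str
    probs: np.ndarray  # shape (4, W), columns sum to 1
    source: str = "constructed"  # "transfac" | "constructed"
    pseudocount: float = 0.0
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("matrix must have shape (4, W)")
        if self.width < 2:
            raise ValueError("matrix width must be >= 2")
        if np.any(self.probs < 0):
            raise ValueError("matrix probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.probs.argmax(axis=0))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2(p/background) per base and column, with zeros floored."""
        background = _check_background(background)
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / background[:, None])
        return np.where(np.isfinite(lo), lo, SCORE_FLOOR)


def build_pwm_from_site(site: str, pseudocount: float = 0.1,
                        motif_id: str = "constructed") -> MotifMatrix:
    """Build a single-site matrix from a linear binding-site sequence.

    Each column starts as a 0/1 indicator of the observed base and is then
    softened with a symmetric pseudocount so related sites are also
    recognised: the observed base gets (1+eps)/(1+4*eps), every other base
    eps/(1+4*eps).
    """
    if not site:
        raise ValueError("site sequence is empty")
    site = site.upper()
    bad = [i for i, b in enumerate(site) if b not in BASE_INDEX]
    if bad:
        raise ValueError(f"invalid characters at positions {bad} in site {site!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    eps = float(pseudocount)
    probs = np.full((4, len(site)), eps / (1 + 4 * eps))
    for j, b in enumerate(site):
        probs[BASE_INDEX[b], j] = (1 + eps) / (1 + 4 * eps)
    return MotifMatrix(motif_id, probs, source="constructed", pseudocount=eps)


def load_transfac_matrices(path, pseudocount: float = 0.0) -> list[MotifMatrix]:
    """Read TRANSFAC flat-file matrix records into probability matrices.

    Counts in each column are converted to probabilities with an additive
    pseudocount: p = (count + eps) / (column_total + 4*eps).
    """
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "TRANSFAC", strict=False)
    except Exception as exc:  # parser reports id/line in its message
        raise ValueError(f"malformed TRANSFAC file {path}: {exc}") from exc
    out = []
    for rec in records:
        motif_id = rec.get("ID") or rec.get("AC") or rec.name or "unnamed"
        counts = np.array([rec.counts[b] for b in DNA], dtype=float)
        if counts.size == 0:
            raise ValueError(f"TRANSFAC record {motif_id!r} has no count rows")
        totals = counts.sum(axis=0)
        if np.any(totals <= 0) and pseudocount == 0:
            raise ValueError(f"TRANSFAC record {motif_id!r} has an all-zero column")
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
        out.append(
            MotifMatrix(str(motif_id), probs, source="transfac",
                        pseudocount=pseudocount, counts=counts)
        )
    return out


def write_transfac_matrices(matrices: Iterable[MotifMatrix], path) -> None:
    """Write matrices as TRANSFAC flat records (counts if kept, else probabilities)."""
    with open(path, "w") as fh:
        for m in matrices:
            values = m.counts if m.counts is not None else m.probs
            fh.write(f"ID {m.motif_id}\nBF unknown\nP0      A      C      G      T\n")
            for j in range(m.width):
                row = "  ".join(f"{values[i, j]:10.6g}" for i in range(4))
                fh.write(f"{j + 1:02d}  {row}  {DNA[values[:, j].argmax()]}\n")
            fh.write("XX\n//\n")


def _check_background(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return bg / bg.sum()


class ScoreDistribution:
    """Exact distribution of a matrix's window log-odds score under the background.

    Scores are held on an integer grid of ``SCORE_GRID`` log2 units.  Built by
    convolving the per-column score distributions (dynamic programming), which
    is exact on the grid.
    """

    def __init__(self, grid_scores: np.ndarray, probs: np.ndarray):
        order = np.argsort(grid_scores)
        self.grid_scores = np.asarray(grid_scores)[order]
        self.probs = np.asarray(probs)[order]
        self._tail = np.cumsum(self.probs[::-1])[::-1]  # P(X >= grid_scores[i])

    @property
    def scores(self) -> np.ndarray:
        """Support of the distribution in log2 units."""
        return self.grid_scores * SCORE_GRID

    def tail_prob(self, grid_score: int) -> float:
        """P(score >= grid_score) under the background model."""
        i = np.searchsorted(self.grid_scores, grid_score, side="left")
        return float(self._tail[i]) if i < len(self._tail) else 0.0

    def threshold(self, quantile: float) -> tuple[int, float]:
        """Smallest grid score whose upper-tail probability is <= 1 - quantile.

        Returns (grid threshold, exact tail probability at the threshold); the
        tail probability is the per-window false-hit rate of the ``>=`` rule.
        """
        if not 0 < quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        alpha = 1.0 - quantile
        # _tail is non-increasing over ascending scores
        idx = np.searchsorted(-self._tail, -alpha, side="left")
        if idx == len(self.grid_scores):
            # even the maximum score is more probable than alpha: threshold above support
            return int(self.grid_scores[-1] + 1), 0.0
        return int(self.grid_scores[idx]), float(self._tail[idx])


def grid_log_odds(matrix: MotifMatrix, background) -> np.ndarray:
    """(W, 5) integer-grid log-odds, transposed to column-major with an N row.

    Row index is the matrix column, second index the base (A,C,G,T,N); N gets
    the score floor so windows containing N can never reach a hit threshold.
    """
    lo = matrix.log_odds(background)  # (4, W)
    grid = np.rint(lo / SCORE_GRID).astype(np.int64).T  # (W, 4)
    n_col = np.full((matrix.width, 1), int(round(SCORE_FLOOR / SCORE_GRID)), dtype=np.int64)
    return np.concatenate([grid, n_col], axis=1)


def exact_null_distribution(matrix: MotifMatrix, background) -> ScoreDistribution:
    """Exact window-score null distribution by column-wise convolution."""
    background = _check_background(background)
    lo = grid_log_odds(matrix, background)[:, :4]  # (W, 4)
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for j in range(matrix.width):
        s = (scores[:, None] + lo[j][None, :]).ravel()
        p = (probs[:, None] * background[None, :]).ravel()
        scores, inverse = np.unique(s, return_inverse=True)
        probs = np.zeros_like(scores, dtype=float)
        np.add.at(probs, inverse, p)
    return ScoreDistribution(scores, probs)


@dataclass
class PrimaScan:
    """Per-gene hit calls from a threshold scan of both strands."""

    motif_id: str
    threshold_grid: int
    per_window_rate: float  # exact null P(window score >= threshold)
    hits: pd.Series  # bool per gene_id
    positions: pd.DataFrame  # gene_id, position (forward-strand start), strand, score
    n_skipped_windows: int  # windows containing N

    @property
    def threshold(self) -> float:
        return self.threshold_grid * SCORE_GRID


def scan_prima(promoters: PromoterSet, motif: MotifMatrix,
               background_freqs=None,
               score_threshold_quantile: float = 0.999) -> PrimaScan:
    """Threshold scan of every window on both strands of each promoter.

    The threshold is set from the exact null score distribution of the matrix
    under the (order-0) background; a gene is a hit iff at least one window
    scores at or above it.  Windows containing N are skipped and counted.
    Reported positions are forward-strand 0-based site starts.
    """
    ids, mat = promoters.encoded()
    L = mat.shape[1]
    W = motif.width
    if W > L:
        raise ValueError(f"motif width {W} exceeds promoter length {L}")
    bg = (promoters.base_frequencies() if background_freqs is None
          else _check_background(background_freqs))
    null = exact_null_distribution(motif, bg)
    thr, rate = null.threshold(score_threshold_quantile)
    lo = grid_log_odds(motif, bg)  # (W, 5)

    rows = []
    hit = np.zeros(len(ids), dtype=bool)
    n_skipped = 0
    nw = L - W + 1
    for strand, m in (("+", mat), ("-", _revcomp_matrix(mat))):
        sc = np.zeros((len(ids), nw), dtype=np.int64)
        for i in range(W):
            sc += lo[i][m[:, i:i + nw]]
        is_n = (m == 4).astype(np.int32)
        cum = np.concatenate(
            [np.zeros((len(ids), 1), dtype=np.int32), np.cumsum(is_n, axis=1)], axis=1)
        has_n = (cum[:, W:] - cum[:, :-W]) > 0
        n_skipped += int(has_n.sum())
        ok = (sc >= thr) & ~has_n
        hit |= ok.any(axis=1)
        gi, wj = np.nonzero(ok)
        pos = wj if strand == "+" else L - W - wj
        for g, p, s in zip(gi, pos, sc[gi, wj]):
            rows.append((ids[g], int(p), strand, float(s * SCORE_GRID)))
    positions = pd.DataFrame(rows, columns=["gene_id", "position", "strand", "score"])
    positions = positions.sort_values(["gene_id", "position"]).reset_index(drop=True)
    return PrimaScan(motif.motif_id, thr, rate, pd.Series(hit, index=ids),
                     positions, n_skipped)


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[mat[:, ::-1]]


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n).

    N: background genes, K: background hits, n: target genes (a subset of the
    background), k: target hits.
    """
    if not (0 <= n <= N and 0 <= K <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hits_to_bed(positions: pd.DataFrame, width: int, name: str) -> pd.DataFrame:
    """Hit positions as BED6-style rows (0-based, half-open, strand column)."""
    return pd.DataFrame({
        "chrom": positions["gene_id"],
        "start": positions["position"],
        "end": positions["position"] + width,
        "name": name,
        "score": positions["score"],
        "strand": positions["strand"],
    })
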