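"""Set-level binding-site enrichment by the threshold-scan and HMM methods.

For every matrix in a library and every gene set (typically "all", "down" and
"up" selections from the expression screen), two p-values are produced:

* threshold-scan ("prima"): promoters are hit-called by ``scan_prima`` and
  target hits are tested against the background gene set with the upper-tail
  hypergeometric test — the target set is a subset of the background set;
* HMM ("demon"): every promoter is scored by the forward algorithm and target
  scores are compared to the scores of the remaining background promoters
  with a one-sided rank-sum test.

Within each method x gene-set stratum, p-values are FDR-corrected across the
matrix library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import fdr_adjust
from .hmm import build_motif_hmm, demon_enrichment, score_promoters
from .pwm import (MotifMatrix, PromoterSet, hypergeom_enrichment, scan_prima)

METHODS = ("prima", "demon")


@dataclass
class EnrichmentResult:
    motif_id: str
    method: str
    gene_set: str
    p: float
    q: float | None = None
    k: int | None = None  # target hits (threshold-scan)
    n: int | None = None  # target size
    K: int | None = None  # background hits
    N: int | None = None  # background size
    median_target_score: float | None = None
    median_background_score: float | None = None


def run_enrichment(promoters: PromoterSet,
                   target_sets: dict[str, list] | list,
                   background_ids: list,
                   matrices: list[MotifMatrix],
                   methods: tuple[str, ...] = METHODS,
                   fdr_threshold: float = 0.05,
                   score_threshold_quantile: float = 0.999,
                   background_freqs=None,
                   tau: float | None = None) -> pd.DataFrame:
    """Per matrix x method x gene-set enrichment with per-stratum FDR.

    ``target_sets`` maps a set label ("all"/"down"/"up" or similar) to gene
    ids; a plain list is treated as a single set labelled "all".  Every
    target set must be a subset of ``background_ids`` and all ids must be
    present in the promoter set.
    """
    if isinstance(target_sets, (list, tuple)):
        target_sets = {"all": list(target_sets)}
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected subset of {METHODS}")
    background_ids = list(background_ids)
    bg_index = {g: i for i, g in enumerate(background_ids)}
    missing = [g for g in background_ids if g not in promoters]
    for label, ids in target_sets.items():
        missing += [g for g in ids if g not in promoters]
        outside = [g for g in ids if g not in bg_index]
        if outside:
            raise ValueError(
                f"target set {label!r} is not a subset of the background: {outside}")
    if missing:
        raise ValueError(f"gene ids absent from promoter set: {sorted(set(missing))}")
    if not matrices:
        return _as_frame([])

    bg_promoters = promoters.subset(background_ids)
    if background_freqs is None:
        background_freqs = bg_promoters.base_frequencies()
    L = len(bg_promoters[background_ids[0]])
    results: list[EnrichmentResult] = []
    for matrix in matrices:
        if "prima" in methods:
            scan = scan_prima(bg_promoters, matrix, background_freqs,
                              score_threshold_quantile)
            K = int(scan.hits.sum())
            N = len(background_ids)
            for label, ids in target_sets.items():
                k = int(scan.hits.loc[ids].sum())
                p = hypergeom_enrichment(k, len(ids), K, N)
                results.append(EnrichmentResult(
                    matrix.motif_id, "prima", label, p,
                    k=k, n=len(ids), K=K, N=N))
        if "demon" in methods:
            hmm = build_motif_hmm(matrix, background_freqs, tau=tau,
                                  promoter_length=L)
            scores = pd.Series(score_promoters(hmm, bg_promoters),
                               index=background_ids)
            for label, ids in target_sets.items():
                tgt = scores.loc[ids].to_numpy()
                rest = scores.drop(index=ids).to_numpy()
                if rest.size == 0:
                    raise ValueError(
                        f"target set {label!r} covers the whole background; "
                        "no promoters remain for comparison")
                p = demon_enrichment(tgt, rest)
                results.append(EnrichmentResult(
                    matrix.motif_id, "demon", label, p,
                    n=len(ids), N=len(background_ids),
                    median_target_score=float(np.median(tgt)),
                    median_background_score=float(np.median(rest))))
    return _as_frame(results)


def _as_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["motif_id", "method", "gene_set", "p", "q", "k", "n", "K", "N",
            "median_target_score", "median_background_score"]
    if not results:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([r.__dict__ for r in results])
    for (_, _), idx in df.groupby(["method", "gene_set"]).groups.items():
        df.loc[idx, "q"] = fdr_adjust(df.loc[idx, "p"].to_numpy())
    return df[cols].sort_values(["method", "gene_set", "q", "p"]).reset_index(drop=True)


def random_matrices(n: int, width: int, seed: int, concentration: float = 0.5,
                    prefix: str = "decoy") -> list[MotifMatrix]:
    """Dirichlet-random decoy matrices for null calibration and FDR strata."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        probs = rng.dirichlet([concentration] * 4, size=width).T
        out.append(MotifMatrix(f"{prefix}{i + 1:03d}", probs))
    return out
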