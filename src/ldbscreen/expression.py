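"""Candidate target-gene selection from two-channel array data.

Stages mirror standard two-colour practice: per-array low-intensity
filtering, within-array print-tip loess normalization of the log-ratio M
against mean log-intensity A, between-array quantile normalization of the
log2 channel intensities, a per-gene fixed-effect ANOVA contrasting
trans-heteroallelic mutant arrays with their corresponding heterozygote
controls, Benjamini-Hochberg FDR correction, and partitioning of the selected
genes by direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

ELEMENT_COLUMNS = ["element_id", "gene_id", "array_id", "printtip",
                   "channel1", "channel2"]
DESIGN_COLUMNS = ["array_id", "contrast_pair", "genotype"]


@dataclass
class ArrayExperiment:
    """Per-element two-channel intensities plus the array-level design.

    ``elements`` columns: element_id, gene_id, array_id, printtip, channel1,
    channel2 (non-negative raw intensities) and optionally ``filtered``.
    Duplicate elements per gene are deliberately kept as separate replicates.
    ``design`` columns: array_id, contrast_pair, genotype ("mutant" for a
    trans-heteroallelic combination, "control" for its heterozygote).
    """

    elements: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        missing = set(ELEMENT_COLUMNS) - set(self.elements.columns)
        if missing:
            raise ValueError(f"element table lacks columns: {sorted(missing)}")
        if (self.elements[["channel1", "channel2"]] < 0).any().any():
            raise ValueError("channel intensities must be non-negative")
        missing_d = set(DESIGN_COLUMNS) - set(self.design.columns)
        if missing_d:
            raise ValueError(f"design table lacks columns: {sorted(missing_d)}")
        bad = set(self.design["genotype"]) - {"mutant", "control"}
        if bad:
            raise ValueError(f"unknown genotype classes: {sorted(bad)}")
        unannotated = set(self.elements["array_id"]) - set(self.design["array_id"])
        if unannotated:
            raise ValueError(f"arrays without design annotation: {sorted(unannotated)}")

    @property
    def array_ids(self) -> list:
        return list(self.design["array_id"])


@dataclass
class NormalizedExperiment:
    """Per-element log-ratio M and mean log2 intensity A after normalization.

    ``data`` columns: element_id, gene_id, array_id, printtip, M, A, filtered.
    The two adjusted log2 channel intensities are recoverable as A +/- M/2.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    meta: dict = field(default_factory=dict)


def filter_low_intensity(exp: ArrayExperiment) -> ArrayExperiment:
    """Flag elements below the per-array median intensity in *both* channels.

    The comparison is strict, so with all-equal intensities nothing is
    flagged; no other background correction is applied.
    """
    el = exp.elements.copy()
    med = el.groupby("array_id")[["channel1", "channel2"]].transform("median")
    el["filtered"] = ((el["channel1"] < med["channel1"])
                      & (el["channel2"] < med["channel2"]))
    return ArrayExperiment(el, exp.design)


def normalize_within_array(exp: ArrayExperiment, span: float = 0.3) -> NormalizedExperiment:
    """Print-tip loess: per array and print-tip group, remove the M-vs-A trend.

    A locally weighted (tricube, locally linear) regression of M on A is
    fitted within each (array, print-tip) group and subtracted from M; A is
    unchanged.  Elements flagged ``filtered`` do not contribute to the fit but
    still receive the correction.
    """
    el = exp.elements.copy()
    if "filtered" not in el.columns:
        el["filtered"] = False
    ch = el[["channel1", "channel2"]].to_numpy(dtype=float)
    if (ch <= 0).any():
        raise ValueError("log-ratio normalization requires strictly positive intensities")
    l1, l2 = np.log2(ch[:, 0]), np.log2(ch[:, 1])
    el["M"] = l1 - l2
    el["A"] = 0.5 * (l1 + l2)

    for (array_id, tip), idx in el.groupby(["array_id", "printtip"]).groups.items():
        sub = el.loc[idx]
        fit_rows = sub.index[~sub["filtered"]]
        if len(fit_rows) == 0:
            raise ValueError(f"empty print-tip group: array {array_id!r}, tip {tip!r}")
        if len(fit_rows) < 10:
            raise ValueError(
                f"print-tip group too small for loess (need >= 10 elements): "
                f"array {array_id!r}, tip {tip!r} has {len(fit_rows)}")
        a = el.loc[fit_rows, "A"].to_numpy()
        m = el.loc[fit_rows, "M"].to_numpy()
        trend = lowess(m, a, frac=span, it=3, return_sorted=False)
        # evaluate the fitted trend at every element of the group
        order = np.argsort(a)
        all_a = el.loc[idx, "A"].to_numpy()
        el.loc[idx, "M"] = el.loc[idx, "M"].to_numpy() - np.interp(
            all_a, a[order], trend[order])
    out = el[["element_id", "gene_id", "array_id", "printtip", "M", "A", "filtered"]]
    return NormalizedExperiment(out.reset_index(drop=True), exp.design.copy(),
                                meta={"within": "printtip-loess", "span": span})


def normalize_between_arrays(norm: NormalizedExperiment) -> NormalizedExperiment:
    """Quantile normalization across arrays of the log2 channel intensities.

    The two adjusted channel intensity vectors of every array are normalized
    jointly: each of the 2 x n_arrays columns is mapped onto the mean of the
    across-column order statistics (ties receive the interpolated mean), then
    M and A are recomputed.  All arrays must carry identical element sets.
    """
    df = norm.data
    arrays = list(norm.design["array_id"])
    if len(arrays) < 2:
        raise ValueError("between-array normalization requires >= 2 arrays")
    pivot_m = df.pivot(index="element_id", columns="array_id", values="M")
    pivot_a = df.pivot(index="element_id", columns="array_id", values="A")
    if pivot_m.isna().any().any():
        raise ValueError("arrays have unequal element sets; complete sets required")
    l1 = (pivot_a + pivot_m / 2).to_numpy()
    l2 = (pivot_a - pivot_m / 2).to_numpy()
    cols = np.concatenate([l1, l2], axis=1)  # (n_elements, 2*n_arrays)
    n = cols.shape[0]
    mean_sorted = np.sort(cols, axis=0).mean(axis=1)
    out = np.empty_like(cols)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(cols.shape[1]):
        ranks = stats.rankdata(cols[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    k = len(pivot_m.columns)
    q1, q2 = out[:, :k], out[:, k:]
    new_m = pd.DataFrame(q1 - q2, index=pivot_m.index, columns=pivot_m.columns)
    new_a = pd.DataFrame((q1 + q2) / 2, index=pivot_m.index, columns=pivot_m.columns)
    data = df.copy()
    key = list(zip(data["element_id"], data["array_id"]))
    data["M"] = [new_m.at[e, a] for e, a in key]
    data["A"] = [new_a.at[e, a] for e, a in key]
    meta = dict(norm.meta, between="quantile")
    return NormalizedExperiment(data, norm.design.copy(), meta)


def anova_differential(norm: NormalizedExperiment, min_reps: int = 2) -> pd.DataFrame:
    """Per-gene fixed-effect ANOVA of M across hybridizations.

    The model is M ~ contrast_pair + genotype with genotype the mutant /
    control factor; the genotype term's partial F-test gives the raw p-value
    and its coefficient (mutant - control, log2) the effect and direction.
    Genes with fewer than ``min_reps`` unfiltered observations in either
    genotype class get a missing p-value and are excluded from FDR correction
    downstream.  Filtered elements are excluded.
    """
    df = norm.data
    if "filtered" in df.columns:
        df = df[~df["filtered"]]
    design = norm.design.set_index("array_id")
    merged = df.merge(norm.design, on="array_id", how="left")

    results = {}
    cache: dict = {}
    for gene, sub in merged.groupby("gene_id", sort=True):
        counts = sub["genotype"].value_counts()
        if counts.get("mutant", 0) < min_reps or counts.get("control", 0) < min_reps:
            results[gene] = (np.nan, np.nan, np.nan, None)
            continue
        key = tuple(sorted(zip(sub["array_id"], sub["element_id"])))
        if key not in cache:
            pairs = pd.get_dummies(sub["contrast_pair"], drop_first=True, dtype=float)
            geno = (sub["genotype"] == "mutant").to_numpy(dtype=float)
            Xf = np.column_stack([np.ones(len(sub)), pairs.to_numpy(), geno])
            Xr = Xf[:, :-1]
            cache[key] = (np.linalg.pinv(Xf), np.linalg.pinv(Xr), Xf, Xr,
                          geno.sum(), len(sub) - geno.sum())
        pf, pr, Xf, Xr, _, _ = cache[key]
        y = sub["M"].to_numpy()
        bf = pf @ y
        rss_f = float(((y - Xf @ bf) ** 2).sum())
        br = pr @ y
        rss_r = float(((y - Xr @ br) ** 2).sum())
        df_f = len(y) - np.linalg.matrix_rank(Xf)
        effect = float(bf[-1])
        num = max(rss_r - rss_f, 0.0)
        if df_f <= 0:
            results[gene] = (np.nan, np.nan, effect, None)
            continue
        if rss_f <= 1e-28:
            if num <= 1e-28:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
        else:
            F = num / (rss_f / df_f)
            p = float(stats.f.sf(F, 1, df_f))
        direction = None
        if effect < 0:
            direction = "down"
        elif effect > 0:
            direction = "up"
        results[gene] = (F, p, effect, direction)

    out = pd.DataFrame.from_dict(
        results, orient="index", columns=["F", "p", "effect", "direction"])
    out.index.name = "gene_id"
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out[["F", "p", "q", "effect", "direction"]]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1).

    Missing values propagate and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    vals = p[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def select_targets(de: pd.DataFrame, threshold: float = 0.05) -> dict[str, list]:
    """Split genes with q below threshold into down- and up-regulated lists."""
    sel = de[(de["q"] < threshold) & de["direction"].notna()]
    return {
        "down": sorted(sel.index[sel["direction"] == "down"]),
        "up": sorted(sel.index[sel["direction"] == "up"]),
    }
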