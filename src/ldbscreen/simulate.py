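"""Seeded generators for every input the pipeline consumes.

The generators emulate the study designs downstream stages assume: a set of
two-channel hybridizations with print-tip structure contrasting
trans-heteroallelic mutants with heterozygote controls, fixed-length upstream
sequences with binding sites planted at chosen affinity and rate, multinomial
wing-notching severity outcomes, and binomial bristle-duplication outcomes.
Every generator is a pure function of its configuration and seed; all
randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ArrayExperiment
from .pwm import DNA, MotifMatrix, PromoterSet, revcomp
from .screen import BristleCross, SeverityDistribution


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults mirror the emulated designs: 22 two-channel hybridizations with
    duplicate array elements and print-tip groups, ~14k-transcript platforms
    scaled to ``n_genes``, 500 bp upstream regions at Drosophila-like 43% GC,
    binding sites planted at 2 per target promoter versus 0.2 per background
    promoter, and a 10% differentially expressed fraction at one log2 unit.
    """

    seed: int = 0
    n_genes: int = 2000
    n_arrays: int = 22
    n_printtips: int = 4
    de_fraction: float = 0.1
    de_log2_effect: float = 1.0
    noise_sd: float = 0.25
    promoter_length: int = 500
    background_gc: float = 0.43
    plant_rate_target: float = 2.0
    plant_rate_background: float = 0.2
    affinity_jitter: float = 0.1
    # array-technology nuisance parameters exercised by normalization
    n_duplicates: int = 2  # elements per gene (kept un-averaged downstream)
    dye_bias_sd: float = 0.3  # per-array additive log2 dye offset
    tip_curvature: float = 0.3  # scale of per-tip intensity-dependent distortion
    base_mean: float = 10.0  # mean log2 abundance
    base_sd: float = 1.5

    def __post_init__(self):
        for name in ("n_genes", "n_arrays", "n_printtips", "promoter_length",
                     "n_duplicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("de_fraction", "background_gc"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("noise_sd", "affinity_jitter", "plant_rate_target",
                     "plant_rate_background", "dye_bias_sd", "tip_curvature"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(1, n + 1)]


def generate_promoter_set(config: SimulationConfig, n: int,
                          seed: int | None = None,
                          ids: list[str] | None = None) -> PromoterSet:
    """Draw ``n`` upstream sequences i.i.d. per position from the GC background.

    Base probabilities are ((1-gc)/2, gc/2, gc/2, (1-gc)/2) for A, C, G, T.
    """
    if n < 1:
        raise ValueError("number of promoters must be >= 1")
    if config.promoter_length < 1:
        raise ValueError("promoter length must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gc = config.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=(n, config.promoter_length), p=probs)
    letters = np.array(list(DNA))
    ids = gene_ids(n) if ids is None else list(ids)
    return PromoterSet(
        {g: "".join(letters[row]) for g, row in zip(ids, draws)})


def sample_site(matrix: MotifMatrix, rng: np.random.Generator,
                affinity_jitter: float = 0.0) -> str:
    """Sample one site string column-by-column from the matrix.

    ``affinity_jitter`` in [0, 1] mixes each column toward uniform,
    broadening the affinity spectrum of planted sites.
    """
    lam = min(float(affinity_jitter), 1.0)
    probs = (1 - lam) * matrix.probs + lam * 0.25
    cols = [rng.choice(4, p=probs[:, j] / probs[:, j].sum())
            for j in range(matrix.width)]
    return "".join(DNA[i] for i in cols)


def plant_motif_sites(promoters: PromoterSet, motif: MotifMatrix,
                      rate: float, affinity_jitter: float,
                      seed: int) -> tuple[PromoterSet, pd.DataFrame]:
    """Write a Poisson(rate) number of sampled sites into each promoter.

    Sites are placed at non-overlapping uniform positions on a uniformly
    chosen strand; position collisions are resampled up to 100 times, after
    which the site is dropped with a warning.  The annotation table records
    promoter id, 0-based start, strand, the sampled site (5'->3' on its
    strand) and the forward-strand text written into the sequence.
    """
    if rate < 0:
        raise ValueError("planting rate must be non-negative")
    rng = np.random.default_rng(seed)
    W = motif.width
    rows = []
    out = {}
    for gene, seq in promoters.items():
        if W > len(seq):
            raise ValueError(
                f"motif width {W} exceeds promoter length {len(seq)}")
        k = rng.poisson(rate) if rate > 0 else 0
        occupied: list[tuple[int, int]] = []
        chars = list(seq)
        for _ in range(k):
            site = sample_site(motif, rng, affinity_jitter)
            placed = False
            for _attempt in range(100):
                pos = int(rng.integers(0, len(seq) - W + 1))
                if all(pos + W <= a or pos >= b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                warnings.warn(
                    f"dropped a planted site in {gene}: no free position "
                    "after 100 attempts")
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else revcomp(site)
            chars[pos:pos + W] = planted
            occupied.append((pos, pos + W))
            rows.append((gene, pos, strand, site, planted))
        out[gene] = "".join(chars)
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "position", "strand", "site", "planted"])
    return PromoterSet(out), annotation


def generate_expression_experiment(
        config: SimulationConfig) -> tuple[ArrayExperiment, pd.DataFrame]:
    """Two-channel intensities with print-tip distortion plus a DE truth table.

    Channel 2 carries a common reference sample; channel 1 the genotype
    sample of each array.  Arrays alternate mutant / control within two
    contrast pairs.  Intensities are built on the log2 scale as
    base + dye bias + print-tip intensity-dependent distortion + genotype
    effect + noise, then exponentiated.  A random ``de_fraction`` of genes
    carries +/- ``de_log2_effect`` on mutant arrays; signs are recorded in
    the truth table.
    """
    if config.n_arrays < 4:
        raise ValueError("at least 4 arrays are required (2 per genotype class)")
    n_de = int(round(config.de_fraction * config.n_genes))
    if config.de_fraction > 0 and n_de < 1:
        raise ValueError("de_fraction * n_genes must be >= 1 when de_fraction > 0")
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)

    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(config.n_genes)
    effect[de_idx] = signs * config.de_log2_effect
    truth = pd.DataFrame({
        "gene_id": [genes[i] for i in de_idx],
        "sign": signs.astype(int),
        "log2_effect": signs * config.de_log2_effect,
    }).sort_values("gene_id").reset_index(drop=True)

    base = rng.normal(config.base_mean, config.base_sd, size=config.n_genes)
    n_el = config.n_genes * config.n_duplicates
    el_gene = np.repeat(np.arange(config.n_genes), config.n_duplicates)
    order = rng.permutation(n_el)  # spots are laid out irrespective of gene id
    el_gene = el_gene[order]
    dup_no = np.concatenate([np.tile(np.arange(config.n_duplicates), config.n_genes)])[order]
    tips = (np.arange(n_el) * config.n_printtips) // n_el  # contiguous sectors

    design_rows = []
    frames = []
    for a in range(config.n_arrays):
        pair = f"pair{(a // 2) % 2 + 1}"
        genotype = "mutant" if a % 2 == 0 else "control"
        array_id = f"array{a + 1:02d}"
        design_rows.append((array_id, pair, genotype))

        dye = rng.normal(0, config.dye_bias_sd) if config.dye_bias_sd > 0 else 0.0
        c_lin = rng.normal(0, config.tip_curvature, size=config.n_printtips)
        c_quad = rng.normal(0, config.tip_curvature, size=config.n_printtips)
        b = base[el_gene]
        # smooth intensity-dependent curve per tip; clipping keeps the
        # distortion in the few-tenths-of-a-log2-unit range real print-tip
        # trends show, instead of exploding at abundance extremes
        z = np.clip((b - config.base_mean) / config.base_sd, -2.0, 2.0)
        distort = (c_lin[tips] * z + c_quad[tips] * (z ** 2 - 1) / np.sqrt(2)) \
            if config.tip_curvature > 0 else 0.0
        g_eff = effect[el_gene] if genotype == "mutant" else 0.0
        noise1 = rng.normal(0, config.noise_sd, size=n_el) if config.noise_sd > 0 else 0.0
        noise2 = rng.normal(0, config.noise_sd, size=n_el) if config.noise_sd > 0 else 0.0
        l2 = b + noise2
        l1 = b + g_eff + dye + distort + noise1
        frames.append(pd.DataFrame({
            "element_id": [f"{genes[g]}_e{d + 1}" for g, d in zip(el_gene, dup_no)],
            "gene_id": [genes[g] for g in el_gene],
            "array_id": array_id,
            "printtip": tips,
            "channel1": np.exp2(l1),
            "channel2": np.exp2(l2),
        }))
    elements = pd.concat(frames, ignore_index=True)
    design = pd.DataFrame(design_rows,
                          columns=["array_id", "contrast_pair", "genotype"])
    return ArrayExperiment(elements, design), truth


def simulate_wing_cross(control_probs, shift: float, n_flies: int, seed: int,
                        genotype: str = "test",
                        sex: str = "female") -> SeverityDistribution:
    """Multinomial severity counts from an exponentially tilted class law.

    Class probabilities are control_probs[c] * exp(shift * c), renormalized;
    positive shift moves mass toward the severe classes, shift = 0 reproduces
    the control law in expectation, and classes with zero control probability
    stay at zero for any finite shift.
    """
    probs = np.asarray(control_probs, dtype=float)
    if probs.ndim != 1 or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
        raise ValueError("control_probs must be non-negative and sum to 1")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    classes = np.arange(1, probs.size + 1, dtype=float)
    if np.isinf(shift):
        # limiting tilt: all mass on the most (or least) severe supported class
        support = np.nonzero(probs > 0)[0]
        top = support.max() if shift > 0 else support.min()
        w = np.zeros_like(probs)
        w[top] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = np.log(probs) + shift * classes
        logw -= logw[np.isfinite(logw)].max()
        w = np.exp(logw)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_flies, w / w.sum())
    return SeverityDistribution(genotype, sex, counts)


def simulate_bristle_cross(p_dup: float, n_flies: int, seed: int,
                           genotype: str = "test",
                           role: str = "test") -> BristleCross:
    """Binomial duplicated-bristle count for one cross."""
    if not 0 <= p_dup <= 1:
        raise ValueError("p_dup must lie in [0, 1]")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)
    d = int(rng.binomial(n_flies, p_dup))
    return BristleCross(genotype, n_flies, d, role=role)
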