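"""Plain-text readers and writers for the pipeline's table dialects.

Everything is tab-delimited with a header row: element tables
(element_id, gene_id, array_id, printtip, channel1, channel2), array design
tables (array_id, contrast_pair, genotype), gene lists (one id per line),
severity tables (genotype, sex, class, count) and bristle tables
(genotype, role, n, d).  FASTA promoters go through Biopython.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ArrayExperiment, DESIGN_COLUMNS, ELEMENT_COLUMNS
from .screen import BristleCross, SeverityDistribution


def write_experiment(exp: ArrayExperiment, elements_path, design_path) -> None:
    exp.elements.to_csv(elements_path, sep="\t", index=False)
    exp.design.to_csv(design_path, sep="\t", index=False)


def read_experiment(elements_path, design_path) -> ArrayExperiment:
    elements = pd.read_csv(elements_path, sep="\t")
    design = pd.read_csv(design_path, sep="\t")
    missing = set(ELEMENT_COLUMNS) - set(elements.columns)
    if missing:
        raise ValueError(f"{elements_path}: missing columns {sorted(missing)}")
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"{design_path}: missing columns {sorted(missing)}")
    return ArrayExperiment(elements, design)


def write_gene_list(ids, path) -> None:
    with open(path, "w") as fh:
        for g in ids:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_severity_tables(dists: list[SeverityDistribution], path) -> None:
    rows = [(d.genotype, d.sex, c + 1, int(n))
            for d in dists for c, n in enumerate(d.counts)]
    pd.DataFrame(rows, columns=["genotype", "sex", "class", "count"]).to_csv(
        path, sep="\t", index=False)


def read_severity_tables(path) -> list[SeverityDistribution]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (genotype, sex), sub in df.groupby(["genotype", "sex"], sort=False):
        n_classes = int(sub["class"].max())
        counts = np.zeros(n_classes, dtype=int)
        for _, row in sub.iterrows():
            counts[int(row["class"]) - 1] = int(row["count"])
        out.append(SeverityDistribution(genotype, sex, counts))
    return out


def write_bristle_table(crosses: list[BristleCross], path) -> None:
    rows = [(c.genotype, c.role, c.n, c.d) for c in crosses]
    pd.DataFrame(rows, columns=["genotype", "role", "n", "d"]).to_csv(
        path, sep="\t", index=False)


def read_bristle_table(path) -> list[BristleCross]:
    df = pd.read_csv(path, sep="\t")
    return [BristleCross(str(r["genotype"]), int(r["n"]), int(r["d"]),
                         role=str(r["role"]))
            for _, r in df.iterrows()]
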