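"""Statistics and calling rules of the dominant-modifier screens.

Two assays are covered.  The wing assay scores notching severity of a
sensitized genotype on an ordinal 1..C class scheme (C = 6 for the
dLMO-overexpression background) and compares a test cross with its control by
a tie-corrected rank test, calling enhancement when the test distribution is
stochastically more severe.  The bristle assay scores presence of duplicated
scutellar bristles: the control cross yields a pseudocount rate
p = (d+1)/(n+1) and each test cross is evaluated with exact binomial tail
probabilities at that rate, with FDR correction across the screen.  A
Table-1-style gene x sensitizer code table (+ enhancer, - suppressor, 0 no
interaction, n not tested) is parsed and summarized into the screen's
headline counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .expression import fdr_adjust

CODES = {"+", "-", "0", "n"}
_CODE_NORMALIZE = str.maketrans({"−": "-", "–": "-"})  # unicode minus/dash


@dataclass
class SeverityDistribution:
    """Ordinal class counts (1..C) of one genotype and sex."""

    genotype: str
    sex: str  # "female" | "male"
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1-D vector of non-negative integers")

    @property
    def n_classes(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> np.ndarray:
        """Per-fly class values (one entry per counted fly)."""
        return np.repeat(np.arange(1, self.n_classes + 1), self.counts)


@dataclass
class BristleCross:
    """Fly counts of one bristle cross: n flies scored, d with duplications."""

    genotype: str
    n: int
    d: int
    role: str = "test"  # "control" | "test"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("total fly count must be >= 1")
        if not 0 <= self.d <= self.n:
            raise ValueError("duplicated count must satisfy 0 <= d <= n")
        if self.role not in {"control", "test"}:
            raise ValueError("role must be 'control' or 'test'")


@dataclass
class InteractionCall:
    """Final interaction designation of one gene against one sensitizer."""

    gene: str
    sensitizer: str
    code: str  # "+", "-", "0", "n"
    direction: str | None = None  # "enhancer" | "suppressor"
    p: float | None = None
    q: float | None = None
    conflict: bool = False


@dataclass
class WingTestResult:
    p: float
    direction: str | None  # "enhancer" | "suppressor" | None
    statistic: float
    # the source publication names this comparison after the Wilcoxon
    # signed-rank test; the statistic appropriate for two independent fly
    # populations, implemented here, is the rank-sum (Mann-Whitney) form
    method: str = "rank-sum (reported as Wilcoxon)"


def wing_severity_test(test: SeverityDistribution,
                       control: SeverityDistribution) -> WingTestResult:
    """Two-sided tie-corrected rank test of two ordinal severity samples.

    Direction is "enhancer" when the test sample is stochastically more
    severe (higher mean rank) than the control, "suppressor" when less.
    """
    if test.n_classes != control.n_classes:
        raise ValueError(
            f"class schemes differ: test has {test.n_classes}, "
            f"control has {control.n_classes}")
    if test.total < 10 or control.total < 10:
        raise ValueError("both samples must contain at least 10 flies")
    tv, cv = test.expand(), control.expand()
    pooled = np.concatenate([tv, cv])
    if np.all(pooled == pooled[0]):
        return WingTestResult(1.0, None, float(tv.size * cv.size) / 2)
    res = stats.mannwhitneyu(tv, cv, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    u = float(res.statistic)
    mid = tv.size * cv.size / 2
    direction = "enhancer" if u > mid else ("suppressor" if u < mid else None)
    return WingTestResult(float(res.pvalue), direction, u)


def call_wing_interactor(gene: str, sensitizer: str,
                         allele_results: dict[str, dict[str, WingTestResult]],
                         alpha: float = 0.05) -> InteractionCall:
    """Concordance rule turning per-allele, per-sex tests into one designation.

    A gene is an interactor ("+" or "-") iff every significant result agrees
    in direction and either (a) every allele is significant in both sexes, or
    (b) at least one allele is significant in both sexes and every other
    allele is significant in at least one sex.  Conflicting significant
    directions give "0" with a conflict flag.
    """
    if not allele_results:
        raise ValueError("at least one allele result is required")
    sig_dirs = set()
    per_allele_sig = {}
    for allele, sexes in allele_results.items():
        missing = {"female", "male"} - set(sexes)
        if missing:
            raise ValueError(f"allele {allele!r} lacks results for {sorted(missing)}")
        nsig = 0
        for res in sexes.values():
            if res.p < alpha and res.direction is not None:
                nsig += 1
                sig_dirs.add(res.direction)
        per_allele_sig[allele] = nsig
    min_p = min(res.p for sexes in allele_results.values() for res in sexes.values())
    if not sig_dirs:
        return InteractionCall(gene, sensitizer, "0", None, min_p)
    if len(sig_dirs) > 1:
        return InteractionCall(gene, sensitizer, "0", None, min_p, conflict=True)
    direction = sig_dirs.pop()
    nsigs = list(per_allele_sig.values())
    qualifies = all(n == 2 for n in nsigs) or (
        any(n == 2 for n in nsigs) and all(n >= 1 for n in nsigs))
    if not qualifies:
        return InteractionCall(gene, sensitizer, "0", direction, min_p)
    code = "+" if direction == "enhancer" else "-"
    return InteractionCall(gene, sensitizer, code, direction, min_p)


def bristle_control_rate(control: BristleCross) -> float:
    """Pseudocount phenotype frequency of the control cross: (d+1)/(n+1)."""
    if control.role != "control":
        raise ValueError("control rate must be computed from a control cross")
    return (control.d + 1) / (control.n + 1)


@dataclass
class BristleTestResult:
    genotype: str
    p: float
    direction: str | None
    p_enhancement: float  # P(X >= d) under Binomial(m, p_hat)
    p_suppression: float  # P(X <= d)


def bristle_binomial_test(test: BristleCross, p_hat: float) -> BristleTestResult:
    """Exact binomial tails of the test cross count at the control rate.

    X ~ Binomial(m, p_hat) with m the test-cross fly total; the enhancement
    tail is P(X >= d), the suppression tail P(X <= d).  The reported p is the
    smaller tail and the direction the corresponding side.
    """
    if test.role != "test":
        raise ValueError("binomial test applies to a test cross")
    if not 0 < p_hat <= 1:
        raise ValueError("control rate must lie in (0, 1]")
    m, d = test.n, test.d
    p_enh = float(stats.binom.sf(d - 1, m, p_hat))
    p_sup = float(stats.binom.cdf(d, m, p_hat))
    if math.isclose(p_enh, p_sup, rel_tol=0, abs_tol=0):
        direction, p = None, p_enh
    elif p_enh < p_sup:
        direction, p = "enhancer", p_enh
    else:
        direction, p = "suppressor", p_sup
    return BristleTestResult(test.genotype, p, direction, p_enh, p_sup)


def bristle_fdr_and_call(results: list[BristleTestResult], sensitizer: str,
                         fdr_threshold: float = 0.05) -> list[InteractionCall]:
    """FDR-correct a bristle screen and call directions at the q threshold."""
    if not results:
        raise ValueError("no bristle test results to correct")
    q = fdr_adjust([r.p for r in results])
    calls = []
    for r, qi in zip(results, q):
        if qi < fdr_threshold and r.direction is not None:
            code = "+" if r.direction == "enhancer" else "-"
        else:
            code = "0"
        calls.append(InteractionCall(r.genotype, sensitizer, code,
                                     r.direction, r.p, float(qi)))
    return calls


@dataclass
class ScreenTable:
    """Gene x sensitizer interaction codes (Table-1 dialect)."""

    data: pd.DataFrame  # index: dgrc id; columns: symbol + sensitizer columns

    SENSITIZERS = ("Dlmo", "ssdp", "Chip")

    def __post_init__(self):
        for col in self.SENSITIZERS:
            if col not in self.data.columns:
                raise ValueError(f"screen table lacks sensitizer column {col!r}")

    @property
    def n_genes(self) -> int:
        return len(self.data)


def parse_screen_table(path) -> ScreenTable:
    """Read and validate a TSV of interaction codes; cells must be +, -, 0 or n."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df = df.set_index(df.columns[0])
    for col in ScreenTable.SENSITIZERS:
        if col not in df.columns:
            raise ValueError(f"screen table lacks sensitizer column {col!r}")
        df[col] = df[col].str.strip().str.translate(_CODE_NORMALIZE)
        bad = df.index[~df[col].isin(CODES)]
        if len(bad):
            raise ValueError(
                f"invalid interaction code {df.loc[bad[0], col]!r} "
                f"at gene {bad[0]!r}, column {col!r}")
    return ScreenTable(df)


def load_packaged_screen_table() -> ScreenTable:
    """The packaged replica of the published gene x sensitizer code table."""
    with resources.as_file(
            resources.files("ldbscreen.data").joinpath("table1.tsv")) as p:
        return parse_screen_table(p)


@dataclass
class ScreenSummary:
    """Headline counts derived from a screen table.

    ``per_sensitizer`` holds tested / interacting / enhancer / suppressor
    counts per column.  The bristle block combines the ssdp and Chip columns:
    role counts are distinct genes per role (a gene enhancing one sensitizer
    and suppressing the other carries both roles), alongside distinct-gene
    counts.  Percentages are reported to one decimal.
    """

    per_sensitizer: dict[str, dict[str, float]]
    bristle: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_sensitizer).T


def summarize_screen(table: ScreenTable) -> ScreenSummary:
    df = table.data
    per = {}
    for col in ScreenTable.SENSITIZERS:
        codes = df[col]
        tested = int((codes != "n").sum())
        enh = int((codes == "+").sum())
        sup = int((codes == "-").sum())
        interacting = enh + sup
        per[col] = {
            "tested": tested,
            "interacting": interacting,
            "enhancers": enh,
            "suppressors": sup,
            "interacting_pct": round(100 * interacting / tested, 1) if tested else 0.0,
            "enhancer_pct_of_interacting":
                round(100 * enh / interacting, 1) if interacting else 0.0,
            "suppressor_pct_of_interacting":
                round(100 * sup / interacting, 1) if interacting else 0.0,
        }

    ssdp, chip = df["ssdp"], df["Chip"]
    tested = (ssdp != "n") | (chip != "n")
    enh_genes = (ssdp == "+") | (chip == "+")
    sup_genes = (ssdp == "-") | (chip == "-")
    both_nonzero = ssdp.isin({"+", "-"}) & chip.isin({"+", "-"})
    bristle = {
        "tested": int(tested.sum()),
        "interacting_genes": int((enh_genes | sup_genes).sum()),
        "interacting_roles": int(enh_genes.sum() + sup_genes.sum()),
        "enhancer_genes": int(enh_genes.sum()),
        "ssdp_enhancers": int((ssdp == "+").sum()),
        "chip_enhancers": int((chip == "+").sum()),
        "both_enhancers": int(((ssdp == "+") & (chip == "+")).sum()),
        "suppressor_genes": int(sup_genes.sum()),
        "ssdp_suppressors": int((ssdp == "-").sum()),
        "chip_suppressors": int((chip == "-").sum()),
        "both_suppressors": int(((ssdp == "-") & (chip == "-")).sum()),
        "both_sensitizers_interacting": int(both_nonzero.sum()),
    }
    notes = [
        "both-sensitizer interactor count is derived from the table codes; "
        f"{bristle['both_sensitizers_interacting']} genes carry a non-zero code "
        "in both the ssdp and Chip columns",
    ]
    return ScreenSummary(per, bristle, notes)
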