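"""End-to-end orchestration: simulate -> expression -> motifs -> screen -> report.

Stages communicate only through files under the output directory, one
subdirectory per stage, each with a JSON manifest recording parameters, seed
and SHA-256 checksums of inputs and outputs, so any stage can be re-run in
isolation and a fixed seed gives byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ldbio
from .enrichment import random_matrices, run_enrichment
from .expression import (anova_differential, filter_low_intensity,
                         normalize_between_arrays, normalize_within_array,
                         select_targets)
from .pwm import PromoterSet, build_pwm_from_site, hits_to_bed, scan_prima
from .screen import (bristle_binomial_test, bristle_control_rate,
                     bristle_fdr_and_call, load_packaged_screen_table,
                     summarize_screen, wing_severity_test)
from .simulate import (SimulationConfig, generate_expression_experiment,
                       generate_promoter_set, plant_motif_sites,
                       simulate_bristle_cross, simulate_wing_cross)

log = logging.getLogger("ldbscreen")

STAGES = ("simulate", "expression", "motifs", "screen", "report")

#: synthetic stand-in for the single-stranded poly-pyrimidine binding site;
#: the published site sequence is not packaged here, so this placeholder is
#: NON-CANONICAL and only defines a site of realistic width and composition
PLACEHOLDER_SSDP_SITE = "CTCTTTCTTTCTCT"

#: default wing severity-class law of the sensitized control (6 classes,
#: mass concentrated in the mild classes as in a weakly notched background)
DEFAULT_WING_CONTROL_PROBS = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "ldbscreen_out"
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        glob = raw.get("global", {})
        return cls(
            seed=int(glob.get("seed", 0)),
            outdir=str(glob.get("outdir", "ldbscreen_out")),
            stages=tuple(glob.get("stages", STAGES)),
            simulate=raw.get("simulate", {}),
            expression=raw.get("expression", {}),
            motifs=raw.get("motifs", {}),
            screen=raw.get("screen", {}),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, seed: int, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _preflight(config: PipelineConfig, out: Path) -> None:
    """Check that every enabled stage will find its inputs before running."""
    produced = set()
    requirements = {
        "expression": [("simulate", "elements.tsv"), ("simulate", "design.tsv")],
        "motifs": [("simulate", "promoters.fasta"),
                   ("expression", "targets_down.txt"),
                   ("expression", "targets_up.txt")],
        "screen": [("simulate", "wing.tsv"), ("simulate", "bristle.tsv")],
    }
    for stage in config.stages:
        for dep_stage, fname in requirements.get(stage, []):
            if dep_stage in produced or dep_stage in config.stages[
                    : config.stages.index(stage)]:
                continue
            path = out / dep_stage / fname
            if not path.exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires {path} but stage {dep_stage!r} "
                    "is not enabled and the file does not exist")
        produced.add(stage)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns stage manifests.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _preflight(config, out)
    manifests = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            runner = globals()[f"_stage_{stage}"]
            runner(config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest_path = out / stage / "manifest.json"
        if manifest_path.exists():
            manifests[stage] = json.loads(manifest_path.read_text())
    return manifests


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    stage_dir = out / "simulate"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.simulate)
    site = params.pop("ssdp_site", PLACEHOLDER_SSDP_SITE)
    pseudocount = params.pop("site_pseudocount", 0.1)
    sim = SimulationConfig(seed=config.seed, **params)

    exp, truth = generate_expression_experiment(sim)
    genes = sorted(set(exp.elements["gene_id"]))
    promoters = generate_promoter_set(sim, len(genes), seed=config.seed + 1,
                                      ids=genes)
    matrix = build_pwm_from_site(site, pseudocount, motif_id="planted")
    down = set(truth.loc[truth["sign"] < 0, "gene_id"])
    target_prom = promoters.subset([g for g in genes if g in down])
    bg_prom = promoters.subset([g for g in genes if g not in down])
    planted_t, ann_t = plant_motif_sites(target_prom, matrix,
                                         sim.plant_rate_target,
                                         sim.affinity_jitter, config.seed + 2)
    planted_b, ann_b = plant_motif_sites(bg_prom, matrix,
                                         sim.plant_rate_background,
                                         sim.affinity_jitter, config.seed + 3)
    merged = PromoterSet({g: (planted_t[g] if g in planted_t else planted_b[g])
                          for g in genes})
    annotation = pd.concat([ann_t, ann_b], ignore_index=True)

    wing = [simulate_wing_cross(DEFAULT_WING_CONTROL_PROBS, 0.0, 600,
                                config.seed + 4, "control", sex)
            for sex in ("female", "male")]
    for i, shift in enumerate((0.0, 0.5, -0.5)):
        for j, sex in enumerate(("female", "male")):
            wing.append(simulate_wing_cross(
                DEFAULT_WING_CONTROL_PROBS, shift, 110,
                config.seed + 10 + 2 * i + j, f"cross{i + 1}", sex))
    bristle = [simulate_bristle_cross(0.25, 400, config.seed + 20,
                                      "control", role="control")]
    for i, mult in enumerate((1.0, 2.0, 0.3)):
        bristle.append(simulate_bristle_cross(
            min(0.25 * mult, 1.0), 120, config.seed + 21 + i, f"cross{i + 1}"))

    merged.to_fasta(stage_dir / "promoters.fasta")
    annotation.to_csv(stage_dir / "planted_sites.tsv", sep="\t", index=False)
    ldbio.write_experiment(exp, stage_dir / "elements.tsv", stage_dir / "design.tsv")
    truth.to_csv(stage_dir / "truth.tsv", sep="\t", index=False)
    ldbio.write_severity_tables(wing, stage_dir / "wing.tsv")
    ldbio.write_bristle_table(bristle, stage_dir / "bristle.tsv")
    (stage_dir / "planted_site.txt").write_text(site + "\n")
    outputs = [stage_dir / f for f in
               ("promoters.fasta", "planted_sites.tsv", "elements.tsv",
                "design.tsv", "truth.tsv", "wing.tsv", "bristle.tsv",
                "planted_site.txt")]
    _write_manifest(stage_dir, "simulate", config.seed,
                    dict(config.simulate), [], outputs)


def _stage_expression(config: PipelineConfig, out: Path) -> None:
    stage_dir = out / "expression"
    stage_dir.mkdir(exist_ok=True)
    params = {"fdr": 0.05, "span": 0.3, **config.expression}
    inputs = [out / "simulate" / "elements.tsv", out / "simulate" / "design.tsv"]
    exp = ldbio.read_experiment(*inputs)
    exp = filter_low_intensity(exp)
    norm = normalize_within_array(exp, span=params["span"])
    norm = normalize_between_arrays(norm)
    de = anova_differential(norm)
    targets = select_targets(de, threshold=params["fdr"])
    de.to_csv(stage_dir / "de_results.tsv", sep="\t")
    ldbio.write_gene_list(targets["down"], stage_dir / "targets_down.txt")
    ldbio.write_gene_list(targets["up"], stage_dir / "targets_up.txt")
    outputs = [stage_dir / f for f in
               ("de_results.tsv", "targets_down.txt", "targets_up.txt")]
    _write_manifest(stage_dir, "expression", config.seed, params, inputs, outputs)


def _stage_motifs(config: PipelineConfig, out: Path) -> None:
    stage_dir = out / "motifs"
    stage_dir.mkdir(exist_ok=True)
    params = {"n_decoys": 10, "quantile": 0.999, "fdr": 0.05,
              "site_pseudocount": 0.1, **config.motifs}
    inputs = [out / "simulate" / "promoters.fasta",
              out / "expression" / "targets_down.txt",
              out / "expression" / "targets_up.txt",
              out / "simulate" / "planted_site.txt"]
    promoters = PromoterSet.from_fasta(inputs[0])
    down = ldbio.read_gene_list(inputs[1])
    up = ldbio.read_gene_list(inputs[2])
    site = inputs[3].read_text().strip()
    matrices = [build_pwm_from_site(site, params["site_pseudocount"],
                                    motif_id="planted")]
    matrices += random_matrices(params["n_decoys"], matrices[0].width,
                                seed=config.seed + 30)
    sets = {"all": sorted(set(down) | set(up)), "down": down, "up": up}
    sets = {k: v for k, v in sets.items() if v}
    background = promoters.ids
    result = run_enrichment(promoters, sets, background, matrices,
                            fdr_threshold=params["fdr"],
                            score_threshold_quantile=params["quantile"])
    result.to_csv(stage_dir / "enrichment.tsv", sep="\t", index=False)
    scan = scan_prima(promoters, matrices[0],
                      score_threshold_quantile=params["quantile"])
    hits_to_bed(scan.positions, matrices[0].width, "planted").to_csv(
        stage_dir / "planted_hits.bed", sep="\t", index=False, header=False)
    outputs = [stage_dir / "enrichment.tsv", stage_dir / "planted_hits.bed"]
    _write_manifest(stage_dir, "motifs", config.seed, params, inputs, outputs)


def _stage_screen(config: PipelineConfig, out: Path) -> None:
    stage_dir = out / "screen"
    stage_dir.mkdir(exist_ok=True)
    params = {"alpha": 0.05, "fdr": 0.05, **config.screen}
    inputs = [out / "simulate" / "wing.tsv", out / "simulate" / "bristle.tsv"]

    wing = ldbio.read_severity_tables(inputs[0])
    controls = {d.sex: d for d in wing if d.genotype == "control"}
    rows = []
    for d in wing:
        if d.genotype == "control":
            continue
        res = wing_severity_test(d, controls[d.sex])
        rows.append((d.genotype, d.sex, res.p, res.direction or "none",
                     res.p < params["alpha"]))
    wing_df = pd.DataFrame(
        rows, columns=["genotype", "sex", "p", "direction", "significant"])
    wing_df.to_csv(stage_dir / "wing_results.tsv", sep="\t", index=False)

    bristle = ldbio.read_bristle_table(inputs[1])
    control = next(c for c in bristle if c.role == "control")
    p_hat = bristle_control_rate(control)
    tests = [bristle_binomial_test(c, p_hat) for c in bristle if c.role == "test"]
    calls = bristle_fdr_and_call(tests, "ssdp", fdr_threshold=params["fdr"])
    bristle_df = pd.DataFrame(
        [(c.gene, c.code, c.direction or "none", c.p, c.q) for c in calls],
        columns=["genotype", "code", "direction", "p", "q"])
    bristle_df.to_csv(stage_dir / "bristle_results.tsv", sep="\t", index=False)

    summary = summarize_screen(load_packaged_screen_table())
    payload = {"per_sensitizer": summary.per_sensitizer,
               "bristle": summary.bristle, "notes": summary.notes,
               "control_rate": p_hat}
    (stage_dir / "table_summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    outputs = [stage_dir / f for f in
               ("wing_results.tsv", "bristle_results.tsv", "table_summary.json")]
    _write_manifest(stage_dir, "screen", config.seed, params, inputs, outputs)


def _stage_report(config: PipelineConfig, out: Path) -> None:
    make_report(out)


def make_report(outdir) -> Path:
    """Aggregate stage outputs into a plain-text report (+ plots when possible).

    Missing stage outputs mark their section absent; the report is written
    regardless.
    """
    out = Path(outdir)
    stage_dir = out / "report"
    stage_dir.mkdir(parents=True, exist_ok=True)
    lines = ["LDB/CHIP screen pipeline report", "=" * 33, ""]
    n_sections = 0

    de_path = out / "expression" / "de_results.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        sel = de[de["q"] < 0.05]
        lines += ["Differential expression",
                  f"  genes tested: {de['p'].notna().sum()}",
                  f"  selected at FDR 0.05: {len(sel)} "
                  f"(down {int((sel['direction'] == 'down').sum())}, "
                  f"up {int((sel['direction'] == 'up').sum())})", ""]
        n_sections += 1
    else:
        lines += ["Differential expression: absent", ""]

    enr_path = out / "motifs" / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        lines.append("Binding-site enrichment (top row per method x set)")
        if len(enr):
            top = enr.sort_values("q").groupby(["method", "gene_set"]).head(1)
            for _, r in top.iterrows():
                lines.append(f"  {r['method']:6s} {r['gene_set']:5s} "
                             f"{r['motif_id']:12s} p={r['p']:.3g} q={r['q']:.3g}")
        lines.append("")
        n_sections += 1
    else:
        lines += ["Binding-site enrichment: absent", ""]

    summ_path = out / "screen" / "table_summary.json"
    if summ_path.exists():
        summary = json.loads(summ_path.read_text())
        lines.append("Genetic screen summary (gene x sensitizer table)")
        for col, stats_ in summary["per_sensitizer"].items():
            lines.append(
                f"  {col}: tested {stats_['tested']}, interacting "
                f"{stats_['interacting']} ({stats_['interacting_pct']}%), "
                f"{stats_['enhancers']} enhancers / {stats_['suppressors']} suppressors")
        b = summary["bristle"]
        lines.append(
            f"  bristle screens combined: {b['tested']} tested, "
            f"{b['interacting_roles']} interacting roles "
            f"({b['enhancer_genes']} enhancer, {b['suppressor_genes']} suppressor)")
        lines.append("")
        n_sections += 1
    else:
        lines += ["Genetic screen summary: absent", ""]

    lines.append(f"sections present: {n_sections}")
    report = stage_dir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    _try_plots(out, stage_dir)
    return report


def _try_plots(out: Path, stage_dir: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    enr_path = out / "motifs" / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        sub = enr[enr["gene_set"] == "down"]
        if len(sub):
            fig, ax = plt.subplots(figsize=(6, 3))
            for method, grp in sub.groupby("method"):
                ax.scatter(grp["motif_id"], -np.log10(grp["q"].clip(lower=1e-300)),
                           label=method, s=12)
            ax.set_ylabel("-log10 q")
            ax.tick_params(axis="x", labelrotation=90, labelsize=6)
            ax.legend()
            fig.tight_layout()
            fig.savefig(stage_dir / "enrichment_down.png", dpi=100)
            plt.close(fig)
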