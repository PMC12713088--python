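"""File-driven pipeline stages: simulate → quantify → targets → diff →
integrate → motifs → report.

Each stage reads its inputs from and writes its outputs to a run
directory, so stages can be re-run independently and the whole chain is a
deterministic function of the configuration (timestamps never enter the
written artifacts). The report lists every computed statistic with the
operation and parameters that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import genome_io as gio
from .complex_targets import TargetSet, define_complex_targets, overlap_enrichment, upset_decomposition
from .differential import DiffThresholds, call_differential, calls_to_frame, count_by_direction
from .genome_io import bound_genes
from .integrative import (
    decile_assign,
    decile_distribution,
    partition_subclasses,
    rna_chip_combination,
    subclass_table,
    target_fraction_among_degs,
)
from .motifs import classify_peaks, cooccurrence_test, group_signal_summary, read_pwm, scan_peaks, write_pwm
from .stats_core import pearson_corr_matrix
from .synthetic import COMPLEX_FACTORS, PEAT_FACTORS, PRC2_FACTORS, TRHT_TRHD_FACTORS, SimConfig, simulate_study

_TWO_TAIL = {"minlike": "min_likelihood", "double": "double_one_tail"}


@dataclass(frozen=True)
class RunConfig:
    """Analysis-side configuration; simulation fields live in ``sim``."""

    seed: int = 0
    upstream_window: int = 1000
    two_tail: str = "minlike"
    motif_threshold: float = 0.95
    mutant: str = "jmj14"
    decile_signal: str = "mark_wt_rpkm"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.two_tail not in _TWO_TAIL:
            raise ValueError("two_tail must be 'minlike' or 'double'")
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from a flat YAML file plus keyword overrides.

    Simulation fields are given under the ``sim_`` prefix (or a nested
    ``sim`` mapping). Unknown keys are rejected by name.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    sim_kwargs: dict[str, Any] = dict(data.pop("sim", {}) or {})
    run_kwargs: dict[str, Any] = {}
    run_fields = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for key, value in data.items():
        if key in run_fields:
            run_kwargs[key] = value
        elif key.startswith("sim_") and key[4:] in sim_fields:
            sim_kwargs[key[4:]] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    unknown = set(sim_kwargs) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulation key(s) {sorted(unknown)}")
    # tuples arrive from YAML as lists
    for key, value in list(sim_kwargs.items()):
        if isinstance(value, list):
            sim_kwargs[key] = tuple(value)
    if "seed" in run_kwargs and "seed" not in sim_kwargs:
        sim_kwargs["seed"] = run_kwargs["seed"]
    return RunConfig(sim=SimConfig(**sim_kwargs), **run_kwargs)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate the synthetic study and write every raw input file."""
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg.sim)
    gio.write_gene_table(study.genes, outdir / "genes.tsv")
    gio.write_fasta(study.sequences, outdir / "genome.fa")
    for factor, plist in study.peaks.items():
        gio.write_bed(plist, outdir / f"peaks_{factor}.bed")
    gio.write_counts(study.binding_counts, outdir / "binding_counts.tsv")
    for geno, cm in study.mark_counts.items():
        gio.write_counts(cm, outdir / f"mark_counts_{geno}.tsv")
    for geno, cm in study.rna_counts.items():
        gio.write_counts(cm, outdir / f"rna_counts_{geno}.tsv")
    write_pwm(study.pwm_a, outdir / "pwm_a.tsv")
    write_pwm(study.pwm_b, outdir / "pwm_b.tsv")

    truth = study.truth
    truth.occupancy.to_csv(outdir / "truth_occupancy.tsv", sep="\t", index_label="gene_id")
    truth.planted_marks.to_csv(outdir / "truth_planted_marks.tsv", sep="\t", index_label="gene_id")
    truth.planted_expression.to_csv(
        outdir / "truth_planted_expression.tsv", sep="\t", index_label="gene_id"
    )
    if truth.motif_classes is not None:
        pd.Series(truth.motif_classes, name="class").rename_axis("peak_id").to_csv(
            outdir / "truth_motif_classes.tsv", sep="\t"
        )
        truth.motif_placements.to_csv(outdir / "truth_motif_placements.tsv", sep="\t", index=False)


def stage_quantify(cfg: RunConfig, outdir: Path) -> None:
    """Gene-level RPKM of binding counts and the sample correlation matrix."""
    genes = gio.read_gene_table(outdir / "genes.tsv")
    counts = gio.read_counts(outdir / "binding_counts.tsv")
    signal = gio.rpkm(counts, genes)
    signal.values.to_csv(outdir / "binding_rpkm.tsv", sep="\t", index_label="gene_id")
    corr = pearson_corr_matrix(signal.values, transform="log2p1")
    corr.to_csv(outdir / "binding_correlation.tsv", sep="\t", index_label="sample")


def _factor_bound_sets(cfg: RunConfig, outdir: Path) -> dict[str, set[str]]:
    genes = gio.read_gene_table(outdir / "genes.tsv")
    bound: dict[str, set[str]] = {}
    for factors in COMPLEX_FACTORS.values():
        for f in factors:
            peaks = gio.read_bed(outdir / f"peaks_{f}.bed")
            gene_peaks, _ = gio.assign_peaks_to_genes(peaks, genes, cfg.upstream_window)
            bound[f] = bound_genes(gene_peaks)
    return bound


def _target_sets(cfg: RunConfig, outdir: Path) -> dict[str, TargetSet]:
    bound = _factor_bound_sets(cfg, outdir)
    return {
        "TRHT": define_complex_targets(bound, ["TRB1", "ICU11", "HTH1"], "TRHT"),
        "TRHD": define_complex_targets(bound, ["TRB1", "ICU11", "ZDP2"], "TRHD"),
        "TRHT_TRHD": define_complex_targets(bound, list(TRHT_TRHD_FACTORS), "TRHT_TRHD"),
        "PEAT": define_complex_targets(bound, list(PEAT_FACTORS), "PEAT"),
        "PRC2": define_complex_targets(bound, list(PRC2_FACTORS), "PRC2"),
    }


def stage_targets(cfg: RunConfig, outdir: Path) -> None:
    """Target sets by co-binding, UpSet decomposition, pairwise enrichment."""
    sets = _target_sets(cfg, outdir)
    universe = len(gio.read_gene_table(outdir / "genes.tsv"))
    rows = [
        {"set": label, "gene_id": g}
        for label, ts in sets.items()
        for g in sorted(ts.gene_ids)
    ]
    pd.DataFrame(rows, columns=["set", "gene_id"]).to_csv(
        outdir / "target_sets.tsv", sep="\t", index=False
    )
    combos = upset_decomposition([sets["TRHT"], sets["TRHD"]])
    pd.DataFrame(
        [{"combination": "+".join(sorted(c)), "count": n} for c, n in sorted(
            combos.items(), key=lambda kv: "+".join(sorted(kv[0])))],
    ).to_csv(outdir / "upset_trht_trhd.tsv", sep="\t", index=False)
    conv = _TWO_TAIL[cfg.two_tail]
    enr = []
    for a, b in (("TRHT", "TRHD"), ("TRHT_TRHD", "PEAT"), ("TRHT_TRHD", "PRC2"), ("PEAT", "PRC2")):
        r = overlap_enrichment(sets[a], sets[b], universe, tail_convention=conv)
        enr.append({"set_a": a, "set_b": b, **dataclasses.asdict(r)})
    pd.DataFrame(enr).to_csv(outdir / "overlap_enrichment.tsv", sep="\t", index=False)


def stage_diff(cfg: RunConfig, outdir: Path) -> None:
    """Differential mark and expression calls for the configured mutant."""
    geno = cfg.mutant
    summary = []
    for kind, preset in (("mark", "mark"), ("rna", "deg")):
        wt = gio.read_counts(outdir / f"{kind}_counts_WT.tsv")
        mut = gio.read_counts(outdir / f"{kind}_counts_{geno}.tsv")
        calls = call_differential(wt, mut, DiffThresholds.preset(preset))
        calls_to_frame(calls).to_csv(outdir / f"diff_{kind}_{geno}.tsv", sep="\t")
        n_up, n_down, n_unchanged = count_by_direction(calls)
        summary.append({"assay": kind, "genotype": geno, "preset": preset,
                        "n_up": n_up, "n_down": n_down, "n_unchanged": n_unchanged})
    pd.DataFrame(summary).to_csv(outdir / "diff_summary.tsv", sep="\t", index=False)


def stage_integrate(cfg: RunConfig, outdir: Path) -> None:
    """Subclasses, dependence ratios, deciles, RNA x mark combination."""
    sets = _target_sets(cfg, outdir)
    part = partition_subclasses(
        sets["TRHT_TRHD"], sets["PEAT"].gene_ids, sets["PRC2"].gene_ids
    )
    pd.Series(part.counts()).rename_axis("subclass_field").rename("count").to_csv(
        outdir / "subclass_counts.tsv", sep="\t"
    )
    mark = pd.read_csv(outdir / f"diff_mark_{cfg.mutant}.tsv", sep="\t", index_col=0)
    mark_up = set(mark.index[mark["status"] == "up"])
    subclass_table(part, mark_up).to_csv(outdir / "dependence_ratios.tsv", sep="\t")

    genes = gio.read_gene_table(outdir / "genes.tsv")
    wt_counts = gio.read_counts(outdir / "mark_counts_WT.tsv")
    wt_rpkm = gio.rpkm(wt_counts, genes).values.mean(axis=1)
    assignment = decile_assign(wt_rpkm.to_dict())
    dist = decile_distribution(assignment, mark_up)
    pd.DataFrame({"decile": range(1, 11), "n_mark_up": dist,
                  "decile_size": assignment.sizes()}).to_csv(
        outdir / "decile_distribution.tsv", sep="\t", index=False
    )

    from .differential import DiffCall

    rna = pd.read_csv(outdir / f"diff_rna_{cfg.mutant}.tsv", sep="\t", index_col=0)
    mark_calls = [
        DiffCall(g, float(r["log2fc"]), float(r["pvalue"]), float(r["qvalue"]), r["status"])
        for g, r in mark.iterrows()
    ]
    rna_calls = [
        DiffCall(g, float(r["log2fc"]), float(r["pvalue"]), float(r["qvalue"]), r["status"])
        for g, r in rna.iterrows()
    ]
    up_degs = {c.gene_id for c in rna_calls if c.status == "up"}
    combo = rna_chip_combination(up_degs, sets["TRHT_TRHD"], mark_calls)
    fracs = target_fraction_among_degs(rna_calls, sets["TRHT_TRHD"])
    pd.Series({**combo, **{k: (np.nan if v is None else v) for k, v in fracs.items()}}).rename_axis(
        "statistic"
    ).rename("value").to_csv(outdir / "rna_chip_combination.tsv", sep="\t")


def stage_motifs(cfg: RunConfig, outdir: Path) -> None:
    """Scan TRB1 peaks for both motifs; classify and test co-occurrence."""
    seqs = gio.read_fasta(outdir / "genome.fa")
    peaks = gio.read_bed(outdir / "peaks_TRB1.bed")
    pwm_a = read_pwm(outdir / "pwm_a.tsv")
    pwm_b = read_pwm(outdir / "pwm_b.tsv")
    hits_a = scan_peaks(peaks, seqs, pwm_a, cfg.motif_threshold)
    hits_b = scan_peaks(peaks, seqs, pwm_b, cfg.motif_threshold)
    classes = classify_peaks(peaks, hits_a, hits_b)
    pd.Series(classes, name="class").rename_axis("peak_id").to_csv(
        outdir / "peak_motif_classes.tsv", sep="\t"
    )
    res = cooccurrence_test(classes)
    pd.Series(res).rename_axis("statistic").rename("value").to_csv(
        outdir / "motif_cooccurrence.tsv", sep="\t"
    )
    signal = pd.DataFrame({"TRB1": {p.peak_id: p.score for p in peaks}})
    group_signal_summary(classes, signal).to_csv(outdir / "motif_group_signal.tsv", sep="\t")


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    """Assemble a provenance-stamped markdown report from the stage TSVs."""
    lines = ["# chromtargets run report", ""]
    lines.append("## Conventions")
    lines.append(f"- two-tailed hypergeometric convention: {_TWO_TAIL[cfg.two_tail]}")
    lines.append("- FDR procedure: Benjamini-Hochberg step-up")
    lines.append(f"- peak-to-gene upstream window: {cfg.upstream_window} bp")
    lines.append(f"- motif presence threshold: {cfg.motif_threshold} of max log-odds score")
    lines.append(f"- seed: {cfg.seed}")
    lines.append("")
    sections = [
        ("Target-set overlap enrichment (overlap_enrichment)", "overlap_enrichment.tsv"),
        ("UpSet decomposition of TRHT vs TRHD (upset_decomposition)", "upset_trht_trhd.tsv"),
        ("Differential call summary (call_differential + count_by_direction)", "diff_summary.tsv"),
        ("Subclass counts (partition_subclasses)", "subclass_counts.tsv"),
        ("Demethylation-dependence ratios (dependence_ratio)", "dependence_ratios.tsv"),
        ("Decile distribution of mark-up genes (decile_assign/_distribution)", "decile_distribution.tsv"),
        ("RNA x mark combination (rna_chip_combination, target_fraction_among_degs)", "rna_chip_combination.tsv"),
        ("Motif co-occurrence (classify_peaks + cooccurrence_test)", "motif_cooccurrence.tsv"),
    ]
    for title, fname in sections:
        path = outdir / fname
        if not path.exists():
            continue
        lines.append(f"## {title}")
        lines.append("```")
        lines.append(path.read_text().rstrip())
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))


STAGES = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "targets": stage_targets,
    "diff": stage_diff,
    "integrate": stage_integrate,
    "motifs": stage_motifs,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """All stages in dependency order; returns the report path."""
    outdir = Path(outdir)
    for name in ("simulate", "quantify", "targets", "diff", "integrate", "motifs", "report"):
        try:
            STAGES[name](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return outdir / "report.md"
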