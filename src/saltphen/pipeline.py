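"""End-to-end orchestration: config → staged analysis → rendered report.

Stages run in dependency order and independently of each other: assay tables
feed group statistics and the tolerance index; clone FASTAs feed methylation
summaries and DMR tests; Ct tables feed fold changes; aligned CDS pairs feed
the mutation/motif report.  Stages whose inputs are absent are skipped with a
log line, so a partial config yields a partial report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from saltphen import __version__, io as sio
from saltphen import methylome as meth
from saltphen import molecular, tolerance
from saltphen.assay import percent_change
from saltphen.stats import fisher_lsd
from saltphen.tolerance import IndicatorSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "load_config", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    output_dir: str = "saltphen_out"
    seed: int = 0
    alpha: float = 0.05
    assay_csv: Optional[str] = None
    relative_values_tsv: Optional[str] = None
    indicators: list[dict] = field(default_factory=list)
    ct_csv: Optional[str] = None
    reference_gene: str = "actin"
    methylome: dict = field(default_factory=dict)
    cds_pairs: list[dict] = field(default_factory=list)
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        m = self.methylome
        if m:
            window = int(m.get("window", 100))
            step = int(m.get("step", 50))
            if window <= 0 or not 0 < step <= window:
                raise ValueError("require window > 0 and 0 < step <= window")

    def indicator_specs(self) -> tuple[IndicatorSpec, ...]:
        if not self.indicators:
            return tolerance.DEFAULT_INDICATORS
        return tuple(
            IndicatorSpec(
                d["id"], d.get("name", d["id"]), d["tissue"], d["polarity"], d["assay"]
            )
            for d in self.indicators
        )


@dataclass
class RunReport:
    provenance: dict
    assay_means: Optional[pd.DataFrame] = None
    percent_changes: Optional[pd.DataFrame] = None
    standardized: Optional[pd.DataFrame] = None
    scores: Optional[pd.Series] = None
    ranking: Optional[list] = None
    methylation_summaries: Optional[pd.DataFrame] = None
    dmrs: Optional[pd.DataFrame] = None
    fold_changes: Optional[pd.DataFrame] = None
    mutations: Optional[dict] = None


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    cfg = RunConfig(**known)
    cfg.raw = raw
    return cfg


def validate_inputs(config: RunConfig) -> list[str]:
    """Check every referenced file against its schema; collect all violations."""
    violations: list[str] = []
    if config.assay_csv:
        if not Path(config.assay_csv).exists():
            violations.append(f"{config.assay_csv}: file not found")
        else:
            violations += sio.validate_assay_csv(config.assay_csv)
    if config.ct_csv:
        if not Path(config.ct_csv).exists():
            violations.append(f"{config.ct_csv}: file not found")
        else:
            violations += sio.validate_ct_csv(config.ct_csv)
    fasta_paths = []
    for region in config.methylome.get("regions", []):
        fasta_paths.append(region.get("reference_fasta"))
        fasta_paths.extend(region.get("samples", {}).values())
    fasta_paths.extend(d.get("fasta") for d in config.cds_pairs)
    for p in fasta_paths:
        if not p:
            continue
        if not Path(p).exists():
            violations.append(f"{p}: file not found")
        else:
            violations += sio.validate_fasta(p)
    return violations


def _assay_stage(config: RunConfig, report: RunReport) -> None:
    df = sio.read_assay_csv(config.assay_csv)
    means = (
        df.groupby(["assay", "tissue", "genotype", "treatment"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    # LSD letters across genotypes, per assay × tissue × treatment
    letters = []
    for (assay_name, tissue, treatment), sub in df.groupby(["assay", "tissue", "treatment"]):
        groups = {g: s["value"].tolist() for g, s in sub.groupby("genotype")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        lsd = fisher_lsd(groups, alpha=config.alpha)
        for genotype, letter in lsd.letters.items():
            letters.append(
                {
                    "assay": assay_name,
                    "tissue": tissue,
                    "treatment": treatment,
                    "genotype": genotype,
                    "letters": letter,
                }
            )
    if letters:
        means = means.merge(
            pd.DataFrame(letters), on=["assay", "tissue", "genotype", "treatment"], how="left"
        )
    report.assay_means = means

    wide = means.pivot_table(
        index=["assay", "tissue", "genotype"], columns="treatment", values="mean"
    ).reset_index()
    if {"control", "salt"} <= set(wide.columns):
        wide["percent_change"] = [
            percent_change(c, s) for c, s in zip(wide["control"], wide["salt"])
        ]
        report.percent_changes = wide


def _tolerance_stage(config: RunConfig, report: RunReport) -> None:
    if config.relative_values_tsv:
        relative, polarities = sio.read_relative_values_tsv(config.relative_values_tsv)
    elif report.percent_changes is not None:
        specs = config.indicator_specs()
        rows, polarities = {}, {}
        pc = report.percent_changes.set_index(["assay", "tissue", "genotype"])
        genotypes = sorted(pc.index.get_level_values("genotype").unique())
        for spec in specs:
            try:
                rel = {
                    g: tolerance.relative_value(
                        pc.loc[(spec.assay, spec.tissue, g), "salt"],
                        pc.loc[(spec.assay, spec.tissue, g), "control"],
                    )
                    for g in genotypes
                }
            except KeyError:
                logger.info("indicator %s: assay data absent, skipped", spec.index_id)
                continue
            rows[spec.index_id] = rel
            polarities[spec.index_id] = spec.polarity
        if not rows:
            return
        relative = pd.DataFrame.from_dict(rows, orient="index")
    else:
        return
    sv, scores, ranking = tolerance.assess(relative, polarities)
    report.standardized = sv
    report.scores = scores
    report.ranking = ranking


def _methylome_stage(config: RunConfig, report: RunReport) -> None:
    m = config.methylome
    window = int(m.get("window", 100))
    step = int(m.get("step", 50))
    alpha = float(m.get("alpha", config.alpha))
    summaries, dmr_rows = [], []
    for region_cfg in m.get("regions", []):
        ref = sio.read_reference(region_cfg["reference_fasta"])
        calls_by_sample = {}
        for name, fasta in region_cfg.get("samples", {}).items():
            clone_set = sio.read_clone_set(fasta)
            alignments = meth.align_clones(ref, clone_set.clones)
            calls = meth.call_methylation(ref, alignments)
            calls_by_sample[name] = calls
            summary = meth.summarize_context(calls)
            for ctx in ("CG", "CHG", "CHH", "total"):
                mc, uc = summary.counts.get(ctx, (0, 0))
                summaries.append(
                    {
                        "region_id": ref.region_id,
                        "sample": name,
                        "genotype": clone_set.genotype,
                        "tissue": clone_set.tissue,
                        "treatment": clone_set.treatment,
                        "context": ctx,
                        "methylated": mc,
                        "unmethylated": uc,
                        "percent": summary.percent(ctx),
                    }
                )
        for pair in region_cfg.get("comparisons", []):
            a, b = pair
            tests = meth.call_dmrs(
                calls_by_sample[a], calls_by_sample[b], len(ref), window, step, alpha
            )
            for t in tests:
                dmr_rows.append(
                    {
                        "region_id": ref.region_id,
                        "sample_a": a,
                        "sample_b": b,
                        "start": t.start + ref.offset,
                        "end": t.end + ref.offset,
                        "meth_a": t.meth_a,
                        "unmeth_a": t.unmeth_a,
                        "meth_b": t.meth_b,
                        "unmeth_b": t.unmeth_b,
                        "p_value": t.p_value,
                        "direction": t.direction,
                        "is_dmr": t.is_dmr,
                    }
                )
    if summaries:
        report.methylation_summaries = pd.DataFrame(summaries)
    if dmr_rows:
        report.dmrs = pd.DataFrame(dmr_rows)


def _qpcr_stage(config: RunConfig, report: RunReport) -> None:
    ct = sio.read_ct_csv(config.ct_csv)
    report.fold_changes = molecular.fold_change_table(ct, config.reference_gene)


def _mutation_stage(config: RunConfig, report: RunReport) -> None:
    out = {}
    for pair_cfg in config.cds_pairs:
        records = sio.read_fasta(pair_cfg["fasta"])
        if len(records) != 2:
            raise ValueError(f"{pair_cfg['fasta']}: expected an aligned pair (2 records)")
        a, b = (str(r.seq) for r in records)
        summary = molecular.classify_mutations(a, b)
        entry: dict[str, Any] = {
            "deletion_events": summary.deletion_events,
            "deleted_bases": summary.deleted_bases,
            "insertion_events": summary.insertion_events,
            "transitions": summary.transitions,
            "transversions": summary.transversions,
            "substitutions": [list(s) for s in summary.substitutions],
        }
        aa_pair = {}
        for rec in records:
            cds = str(rec.seq).replace("-", "")
            if len(cds) >= 3:
                aa = molecular.translate_cds(cds)
                aa_pair[rec.id] = {
                    "protein": aa,
                    "motifs": {
                        h.motif: {"present": h.present, "positions": list(h.positions)}
                        for h in molecular.find_motifs(aa)
                    },
                }
        entry["proteins"] = aa_pair
        out[pair_cfg.get("name", Path(pair_cfg["fasta"]).stem)] = entry
    if out:
        report.mutations = out


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str, decimals: int = 3) -> None:
        df.round(decimals).to_csv(outdir / name, sep="\t", index=False)

    if report.assay_means is not None:
        tsv(report.assay_means, "assay_means.tsv", 2)
    if report.percent_changes is not None:
        tsv(report.percent_changes, "percent_change.tsv", 2)
    if report.standardized is not None:
        table2 = report.standardized.copy().round(3)
        table2.loc["Mean"] = report.scores.round(3)
        ordinal = {1: "1st", 2: "2nd", 3: "3rd"}
        table2.loc["Rank"] = [
            ordinal.get(t.rank, f"{t.rank}th")
            for t in sorted(report.ranking, key=lambda t: list(table2.columns).index(t.genotype))
        ]
        table2.index.name = "indicator"
        table2.to_csv(outdir / "tolerance_index.tsv", sep="\t")
    if report.methylation_summaries is not None:
        tsv(report.methylation_summaries, "methylation_summary.tsv", 2)
    if report.dmrs is not None:
        df = report.dmrs.copy()
        df["p_value"] = df["p_value"].map(lambda p: f"{p:.4g}")
        df.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    if report.fold_changes is not None:
        tsv(report.fold_changes, "fold_changes.tsv", 3)
    if report.mutations is not None:
        (outdir / "mutations.json").write_text(json.dumps(report.mutations, indent=2))

    machine = {"provenance": report.provenance}
    if report.scores is not None:
        machine["tolerance_scores"] = report.scores.to_dict()
        machine["ranks"] = {t.genotype: t.rank for t in report.ranking}
    if report.fold_changes is not None:
        machine["fold_changes"] = report.fold_changes.to_dict(orient="records")
    if report.dmrs is not None:
        machine["n_dmrs"] = int(report.dmrs["is_dmr"].sum())
    (outdir / "report.json").write_text(json.dumps(machine, indent=2, default=float))


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute every stage whose inputs are configured; render the report.

    Raises on schema violations (all collected first) and on stage errors.
    """
    violations = validate_inputs(config)
    if violations:
        raise ValueError("input validation failed:\n" + "\n".join(violations))
    config_hash = hashlib.sha256(
        json.dumps(config.raw or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = RunReport(
        provenance={
            "saltphen_version": __version__,
            "config_sha256": config_hash,
            "seed": config.seed,
        }
    )
    if config.assay_csv:
        _assay_stage(config, report)
    else:
        logger.info("assay stage skipped: no assay_csv configured")
    if config.relative_values_tsv or report.percent_changes is not None:
        _tolerance_stage(config, report)
    else:
        logger.info("tolerance stage skipped: no relative values available")
    if config.methylome.get("regions"):
        _methylome_stage(config, report)
    else:
        logger.info("methylome stage skipped: no regions configured")
    if config.ct_csv:
        _qpcr_stage(config, report)
    else:
        logger.info("qPCR stage skipped: no ct_csv configured")
    if config.cds_pairs:
        _mutation_stage(config, report)
    else:
        logger.info("mutation stage skipped: no cds_pairs configured")
    if write:
        _write_outputs(report, Path(config.output_dir))
    return report
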