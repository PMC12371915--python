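"""End-to-end orchestration: simulate -> call -> profile -> DMC -> dystropy -> SNP.

Every report is a TSV whose first line is a comment carrying the tool
version, the run seed and a hash of the configuration, so that a report can
always be traced to the exact run that produced it.  Re-running with an
identical configuration and inputs reproduces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import assign_reads, call_methylation, conversion_qc, MethylationMatrix
from .dmc import DmcModelSpec, call_dmcs, fit_many_sites, DELTA_THRESHOLD, ALPHA
from .dystropy import (call_dystropic_genes, classify_directions,
                       expression_concordance)
from .panel import load_panel
from .profiling import group_summary, profile_regions
from .snp import association_scan, detect_variants, write_vcf
from .synthetic import PRESETS, make_fixture

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "call", "profile", "dmc", "dystropy", "snp")

log = logging.getLogger("amplimeth")


@dataclass
class RunConfig:
    out_dir: str = "amplimeth_run"
    seed: int = 0
    # inputs (ignored for stages fed by an enabled simulate stage)
    panel_fasta: str | None = None
    cgi_bed: str | None = None
    variants_tsv: str | None = None
    reads_dir: str | None = None
    sample_sheet: str | None = None
    expression_tsv: str | None = None
    x_linked: list[str] = field(default_factory=list)
    # simulate stage
    preset: str = "tiny"
    sim_depth: float | None = None
    # thresholds
    min_depth: int = 10
    max_mismatch_rate: float = 0.1
    delta_threshold: float = DELTA_THRESHOLD
    alpha: float = ALPHA
    min_alt_fraction: float = 0.2
    qc_threshold: float = 0.05
    # stage toggles
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "stages":
                cfg.stages.update(v)
            else:
                setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems = []
    if not 0 < config.alpha < 1:
        problems.append("alpha must be in (0,1)")
    if config.delta_threshold < 0:
        problems.append("delta_threshold must be non-negative")
    if config.min_depth < 1:
        problems.append("min_depth must be at least 1")
    if not 0 <= config.max_mismatch_rate <= 1:
        problems.append("max_mismatch_rate must be in [0,1]")
    if not 0 < config.min_alt_fraction < 1:
        problems.append("min_alt_fraction must be in (0,1)")
    for s in config.stages:
        if s not in STAGES:
            problems.append(f"unknown stage {s!r}")
    if config.stages.get("simulate"):
        if config.preset not in PRESETS:
            problems.append(
                f"preset must be one of {', '.join(PRESETS)}")
    else:
        for name in ("panel_fasta", "sample_sheet"):
            path = getattr(config, name)
            if any(config.stages.get(s) for s in STAGES[1:]):
                if path is None:
                    problems.append(f"{name} is required when simulate is off")
                elif not Path(path).exists():
                    problems.append(f"{name}: file not found: {path}")
        if config.stages.get("call"):
            if config.reads_dir is None:
                problems.append("reads_dir is required for the call stage")
            elif not Path(config.reads_dir).exists():
                problems.append(f"reads_dir: directory not found: {config.reads_dir}")
    try:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        problems.append(f"out_dir not writable: {exc}")
    return problems


def _write_tsv(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA",
                     float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages in dependency order; returns report paths."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"amplimeth {__version__} seed={config.seed} config={config.config_hash()}"

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    reports: dict[str, Path] = {}
    try:
        log.info("run start: %s", stamp)
        enabled = config.stages

        panel = truth = None
        fastq_by_sample = None
        sheet = None

        if enabled.get("simulate"):
            log.info("simulate: preset=%s seed=%d", config.preset, config.seed)
            fixture = make_fixture(config.preset, config.seed,
                                   out_dir=out / "sim", depth=config.sim_depth)
            panel, truth = fixture.panel, fixture.truth
            fastq_by_sample = {s: p for s, p in fixture.reads.fastq_paths.items()}
            sheet = truth.samples
            if panel.x_linked:
                config.x_linked = sorted(panel.x_linked)
            reports["sample_sheet"] = out / "sim" / "sample_sheet.tsv"
        else:
            if any(enabled.get(s) for s in STAGES[1:]):
                panel = load_panel(config.panel_fasta, config.cgi_bed,
                                   config.variants_tsv,
                                   x_linked=config.x_linked)
                sheet = pd.read_csv(config.sample_sheet, sep="\t",
                                    index_col="sample_id")
            if enabled.get("call"):
                reads_dir = Path(config.reads_dir)
                fastq_by_sample = {}
                for sample in sheet.index:
                    for suffix in (".fastq.gz", ".fastq"):
                        p = reads_dir / f"{sample}{suffix}"
                        if p.exists():
                            fastq_by_sample[sample] = p
                            break
                    else:
                        raise FileNotFoundError(
                            f"call stage: no FASTQ for sample {sample!r} in "
                            f"{reads_dir}")

        matrix = None
        assignments = None
        if enabled.get("call"):
            if fastq_by_sample is None:
                raise RuntimeError(
                    "stage 'call' needs reads: enable 'simulate' or set reads_dir")
            log.info("call: assigning %d samples", len(fastq_by_sample))
            assignments = assign_reads(fastq_by_sample, panel,
                                       max_mismatch_rate=config.max_mismatch_rate)
            log.info("call: %d assigned, discarded=%s",
                     len(assignments.assignments), dict(assignments.discarded))
            matrix = call_methylation(assignments, panel,
                                      min_depth=config.min_depth,
                                      samples=sheet.index)
            matrix.to_tsv(out / "methylation_matrix.tsv", header_comment=stamp)
            reports["methylation_matrix"] = out / "methylation_matrix.tsv"
            qc = conversion_qc(assignments, panel, config.qc_threshold)
            _write_tsv(qc, out / "conversion_qc.tsv", stamp)
            reports["conversion_qc"] = out / "conversion_qc.tsv"

        def need_matrix(stage: str) -> MethylationMatrix:
            if matrix is not None:
                return matrix
            path = out / "methylation_matrix.tsv"
            if not path.exists():
                raise RuntimeError(
                    f"stage {stage!r} needs the methylation matrix: enable "
                    "'call' or place methylation_matrix.tsv in the output dir")
            return MethylationMatrix.from_tsv(path, min_depth=config.min_depth)

        summary = None
        if enabled.get("profile"):
            m = need_matrix("profile")
            log.info("profile: %d sites", m.meth.shape[1])
            _write_tsv(profile_regions(m), out / "region_profiles.tsv", stamp)
            summary = group_summary(m, sheet)
            _write_tsv(summary, out / "group_summary.tsv", stamp)
            reports["region_profiles"] = out / "region_profiles.tsv"
            reports["group_summary"] = out / "group_summary.tsv"

        dmc_report = None
        if enabled.get("dmc"):
            m = need_matrix("dmc")
            pct = m.percent
            x_cols = [c for c in pct.columns
                      if c.split(":", 1)[0] in set(config.x_linked)]
            a_cols = [c for c in pct.columns if c not in x_cols]
            parts = []
            fits = fit_many_sites(pct[a_cols], sheet, DmcModelSpec())
            fits["stratum"] = "all"
            parts.append(fits)
            for sex in sorted(sheet["sex"].unique()) if x_cols else []:
                idx = sheet[sheet["sex"] == sex].index
                idx = [i for i in idx if i in pct.index]
                f = fit_many_sites(pct.loc[idx, x_cols], sheet,
                                   DmcModelSpec(stratify_sex=True))
                f["stratum"] = sex
                parts.append(f)
            fits_all = pd.concat(parts, ignore_index=True)
            dmc_report = pd.concat(
                [call_dmcs(g, config.delta_threshold, config.alpha)
                 for _, g in fits_all.groupby("stratum", sort=True)],
                ignore_index=True)
            _write_tsv(dmc_report, out / "dmc_report.tsv", stamp)
            reports["dmc_report"] = out / "dmc_report.tsv"
            log.info("dmc: %d significant calls",
                     int(dmc_report["significant"].sum()))

        if enabled.get("dystropy"):
            if dmc_report is None:
                raise RuntimeError(
                    "stage 'dystropy' needs DMC results: enable 'dmc'")
            m = need_matrix("dystropy")
            if summary is None:
                summary = group_summary(m, sheet)
            calls = classify_directions(
                dmc_report[dmc_report["stratum"] == "all"], summary)
            _write_tsv(calls, out / "direction_calls.tsv", stamp)
            site_to_gene = {panel.site_id(s): panel.regions[s.region_id].gene
                            for s in panel.all_sites()}
            genes = call_dystropic_genes(
                calls, {k: site_to_gene.get(k, k.split(":")[0])
                        for k in calls["site_id"]})
            _write_tsv(genes, out / "gene_dystropy.tsv", stamp)
            reports["direction_calls"] = out / "direction_calls.tsv"
            reports["gene_dystropy"] = out / "gene_dystropy.tsv"
            if config.expression_tsv:
                expr = pd.read_csv(config.expression_tsv, sep="\t", comment="#")
                meth_dirs = {}
                calls_g = calls.assign(
                    gene=calls["site_id"].map(lambda s: site_to_gene.get(
                        s, s.split(":")[0])))
                for gene, block in calls_g.groupby("gene"):
                    sig = block[block["pattern"] != "flat"]
                    pick = sig.iloc[0] if len(sig) else block.iloc[0]
                    meth_dirs[gene] = (pick["dir_hd"], pick["dir_lc"])
                conc = expression_concordance(meth_dirs, expr)
                _write_tsv(conc, out / "expression_concordance.tsv", stamp)
                reports["expression_concordance"] = out / "expression_concordance.tsv"

        if enabled.get("snp"):
            if assignments is None:
                raise RuntimeError(
                    "stage 'snp' needs read assignments: enable 'call'")
            calls = detect_variants(assignments, panel,
                                    min_alt_fraction=config.min_alt_fraction,
                                    min_depth=config.min_depth)
            write_vcf(calls, panel, out / "variants.vcf", header_comment=stamp)
            reports["variants"] = out / "variants.vcf"
            m = need_matrix("snp")
            assoc_parts = []
            for c in calls:
                if c.ambiguity == "both" or c.possible_polymerase_error:
                    continue
                assoc_parts.append(association_scan(m.percent, c, sheet))
            assoc = (pd.concat(assoc_parts, ignore_index=True) if assoc_parts
                     else pd.DataFrame(columns=["site_id", "variant_id",
                                                "scope", "kw_p", "pairwise_mw",
                                                "testable", "reason"]))
            _write_tsv(assoc, out / "snp_association.tsv", stamp)
            reports["snp_association"] = out / "snp_association.tsv"
            log.info("snp: %d variants called", len(calls))

        log.info("run complete: %d reports", len(reports))
    finally:
        log.removeHandler(handler)
        handler.close()
    return reports
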