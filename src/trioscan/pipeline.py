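"""End-to-end pipeline: QC -> trios -> scan -> null -> cascade -> regions -> genes.

Every run writes a manifest (full configuration echo, seed, package version,
per-stage record counts) alongside the stage tables, so any run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .annotate import annotate_results, read_gene_table
from .genotypes import apply_marker_qc, build_trios
from .plink import read_plink
from .scan import (
    ScanConfig,
    apply_results_cascade,
    build_empirical_null,
    call_regions,
    manhattan_table,
    regions_table,
    results_table,
    scan,
)

logger = logging.getLogger(__name__)

STAGES = ("read", "qc", "trios", "scan", "null", "cascade", "regions", "annotate", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds with their standard defaults."""

    genotypes: str = ""
    dialect: str | None = None
    gene_table: str | None = None
    out_dir: str = "trioscan_out"
    seed: int = 0
    profile: str = "desk"  # MCMC profile: "study" = 110,000/10,000, "desk" = 11,000/1,000
    min_call_rate: float = 0.95
    autosomes_only: bool = True
    min_offspring: int = 10
    min_parents: int = 2
    parent_rule: str = "or"
    region_min_offspring: int = 20
    trd_magnitude_gate: float = 0.2
    bf_decisive: float = 100.0
    null_margin: float = 0.001
    null_reps: int = 10_000
    dic_margin: float = 3.0
    window_bp: int = 250_000
    max_gap_bp: int = 1_000_000
    min_region_snps: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            seed=self.seed,
            profile=self.profile,
            min_offspring=self.min_offspring,
            min_parents=self.min_parents,
            parent_rule=self.parent_rule,
            bf_decisive=self.bf_decisive,
            dic_margin=self.dic_margin,
        )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure is re-raised as :class:`StageError` carrying the stage
    name so callers can map it to a distinct exit code.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage_counts: dict[str, dict] = {}

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    logger.info("trioscan %s seed=%d profile=%s", __version__, cfg.seed, cfg.profile)

    g = _stage("read", lambda: read_plink(cfg.genotypes, cfg.dialect))
    stage_counts["read"] = {"samples": g.n_samples, "variants": g.n_variants}

    def do_qc():
        gq, report = apply_marker_qc(g, cfg.min_call_rate, cfg.autosomes_only)
        report.to_tsv(out / "qc_report.tsv")
        return gq, report

    gq, qc_report = _stage("qc", do_qc)
    stage_counts["qc"] = {"variants_pass": qc_report.n_pass, "variants_removed": qc_report.n_input - qc_report.n_pass}

    def do_trios():
        if not gq.pedigree:
            raise ValueError("no pedigree records (sire/dam columns) in the family file")
        return build_trios(gq)

    trios = _stage("trios", do_trios)
    stage_counts["trios"] = trios.counts()

    scan_cfg = cfg.scan_config()
    results = _stage("scan", lambda: scan(trios, scan_cfg))
    stage_counts["scan"] = {
        "snps": len(results),
        "analyzed": sum(r.analyzed for r in results),
        "skipped": sum(not r.analyzed for r in results),
    }

    null = _stage(
        "null",
        lambda: build_empirical_null(trios, cfg.null_margin, cfg.null_reps, seed=cfg.seed, cfg=scan_cfg),
    )
    stage_counts["null"] = {"n_reps": null.n_reps, "threshold": null.threshold_at_margin}

    cascade = _stage(
        "cascade",
        lambda: apply_results_cascade(results, null, cfg.region_min_offspring, cfg.trd_magnitude_gate),
    )
    cascade.to_frame().to_csv(out / "cascade_report.tsv", sep="\t", index=False)
    stage_counts["cascade"] = {"pass_all": cascade.n_pass_all, "decisive": cascade.n_decisive}
    results_table(results).to_csv(out / "scan_results.tsv", sep="\t", index=False)
    manhattan_table(results).to_csv(out / "manhattan.tsv", sep="\t", index=False)

    regions = _stage("regions", lambda: call_regions(results, cfg.max_gap_bp, cfg.min_region_snps))
    regions_table(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    stage_counts["regions"] = {"n_regions": len(regions)}

    if cfg.gene_table:
        def do_annotate():
            genes = read_gene_table(cfg.gene_table)
            snp_df, region_df, n_genes = annotate_results(results, regions, genes, cfg.window_bp)
            snp_df.to_csv(out / "annotation_snps.tsv", sep="\t", index=False)
            region_df.to_csv(out / "annotation_regions.tsv", sep="\t", index=False)
            return n_genes

        n_genes = _stage("annotate", do_annotate)
        stage_counts["annotate"] = {"distinct_genes": n_genes}

    manifest = {
        "package": "trioscan",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stage_counts": stage_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    logger.info("pipeline complete: %s", out)
    logger.removeHandler(handler)
    handler.close()
    return out


def run_from_manifest(manifest_path) -> Path:
    """Re-run a pipeline from a previously written manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_pipeline(RunConfig(**manifest["config"]))
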