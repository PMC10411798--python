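"""SNP-by-SNP distortion scan, empirical null, filtering cascade, regions.

The scan fits all three distortion models at every SNP passing the minimum
informativeness filter, computes Bayes factors and DIC, and classifies the
inheritance pattern. Chance distortion is controlled twice: by the Jeffreys
decisive Bayes-factor gate (BF > 100) and by an empirical null distribution
of the distortion-magnitude estimator built by gene-dropping -- re-drawing
offspring genotypes under Mendelian transmission conditional on the observed
parent genotypes, which preserves the informativeness structure the estimator
sees. Candidate SNPs surviving the cascade are chained into physically linked
regions of shared pattern.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AB, MISSING, TrioSet
from .inference import (
    LOG10_DECISIVE,
    InferenceResult,
    McmcConfig,
    PatternCall,
    fit_model,
    select_pattern,
)
from .models import MODEL_TAGS
from .transmission import TransmissionSummary, passes_informativeness, summarize_all


@dataclass
class ScanConfig:
    seed: int = 0
    profile: str = "desk"  # "desk" (11,000/1,000 iterations) or "study" (110,000/10,000)
    thin: int = 10
    proposal_sd: float = 0.05
    min_offspring: int = 10
    min_parents: int = 2
    parent_rule: str = "or"
    informative_mode: str = "inclusive"
    bf_decisive: float = 100.0
    dic_margin: float = 3.0
    grid_size: int = 201

    def mcmc(self, seed: int) -> McmcConfig:
        base = McmcConfig.study if self.profile == "study" else McmcConfig.desk
        cfg = base(seed=seed, thin=self.thin)
        cfg.proposal_sd = self.proposal_sd
        return cfg


@dataclass
class SnpTrdResult:
    variant: object  # VariantRecord
    summary: TransmissionSummary
    results: dict[str, InferenceResult] = field(default_factory=dict)
    pattern: PatternCall | None = None
    skip_reason: str | None = None
    above_null_threshold: bool | None = None
    passes_offspring_gate: bool | None = None
    passes_magnitude_gate: bool | None = None
    passes_region_criteria: bool | None = None

    @property
    def analyzed(self) -> bool:
        return self.skip_reason is None

    @property
    def trd_magnitude(self) -> float:
        return self.pattern.magnitude if self.pattern else float("nan")

    @property
    def log10_bf(self) -> float:
        """log10 Bayes factor of the winning model."""
        if not self.pattern:
            return float("nan")
        return self.results[self.pattern.model_tag].log10_bf

    @property
    def decisive(self) -> bool:
        return self.analyzed and self.log10_bf > LOG10_DECISIVE


def snp_seed(base_seed: int, snp_id: str, stream: int = 0) -> int:
    """Deterministic per-SNP seed, independent of processing order."""
    h = zlib.crc32(f"{snp_id}:{stream}".encode())
    return int((h ^ (base_seed * 2654435761)) % (2**31))


def scan(trios: TrioSet, cfg: ScanConfig | None = None) -> list[SnpTrdResult]:
    """Fit all three models at every SNP; deterministic given ``cfg.seed``."""
    cfg = cfg or ScanConfig()
    if trios.n_trios == 0:
        raise ValueError("empty trio set")
    summaries = summarize_all(trios, informative_mode=cfg.informative_mode)
    out: list[SnpTrdResult] = []
    for variant, summary in zip(trios.genotypes.variants, summaries):
        res = SnpTrdResult(variant=variant, summary=summary)
        if summary.n_informative_offspring == 0:
            res.skip_reason = "no heterozygous parents"
        elif not passes_informativeness(summary, cfg.min_offspring, cfg.min_parents, cfg.parent_rule):
            res.skip_reason = (
                f"insufficient informativeness ({summary.n_informative_offspring} offspring, "
                f"{summary.n_informative_sires} sires, {summary.n_informative_dams} dams)"
            )
        else:
            for k, tag in enumerate(MODEL_TAGS):
                mcfg = cfg.mcmc(seed=snp_seed(cfg.seed, variant.id, k))
                res.results[tag] = fit_model(summary, tag, mcfg, grid_size=cfg.grid_size)
            res.pattern = select_pattern(
                res.results["allelic_overall"],
                res.results["allelic_parent_specific"],
                res.results["genotypic"],
                dic_margin=cfg.dic_margin,
            )
        out.append(res)
    return out


@dataclass
class NullDistribution:
    """Empirical distribution of the |TRD| estimator under Mendelian gene-drop."""

    magnitudes: np.ndarray
    margin: float
    n_reps: int
    seed: int

    @property
    def threshold_at_margin(self) -> float:
        return self.quantile_at(self.margin)

    def quantile_at(self, margin: float) -> float:
        return float(np.quantile(self.magnitudes, 1.0 - margin))


def _null_structure(trios: TrioSet, cfg: ScanConfig) -> list[tuple[int, int]]:
    """Per informative SNP: (# one-het-parent trios, # het x het trios)."""
    calls = trios.genotypes.calls
    summaries = summarize_all(trios, informative_mode=cfg.informative_mode)
    out = []
    for j, summary in enumerate(summaries):
        if not passes_informativeness(summary, cfg.min_offspring, cfg.min_parents, cfg.parent_rule):
            continue
        sgt = calls[trios.sire_idx, j]
        dgt = calls[trios.dam_idx, j]
        ogt = calls[trios.off_idx, j]
        complete = (sgt != MISSING) & (dgt != MISSING) & (ogt != MISSING)
        s_het = sgt[complete] == AB
        d_het = dgt[complete] == AB
        n2 = int((s_het & d_het).sum())
        n1 = int((s_het ^ d_het).sum())
        out.append((n1, n2))
    return out


def build_empirical_null(
    trios: TrioSet,
    margin: float = 0.001,
    n_reps: int = 10_000,
    seed: int = 0,
    cfg: ScanConfig | None = None,
) -> NullDistribution:
    """Gene-drop null distribution of the overall-allelic |TRD| estimator.

    Offspring genotypes are re-drawn under Mendelian transmission conditional
    on the observed parent genotypes of each informative SNP (replicates are
    spread over SNPs round-robin), and the posterior-mean magnitude estimate
    is recorded for each replicate. The estimator is evaluated with its exact
    conjugate closed form (Beta posterior), which is what the sampler
    estimates for this model. The threshold at margin ``m`` is the ``1 - m``
    empirical quantile.
    """
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must be in (0, 1)")
    if n_reps < 1.0 / margin:
        raise ValueError(f"n_reps={n_reps} too small for margin={margin}; need >= {int(np.ceil(1 / margin))}")
    cfg = cfg or ScanConfig()
    structures = _null_structure(trios, cfg)
    if not structures:
        raise ValueError("no SNP passes the informativeness filter; cannot build a null")
    rng = np.random.default_rng(seed)
    reps_per = np.bincount(np.arange(n_reps) % len(structures), minlength=len(structures))
    mags = np.empty(n_reps)
    pos = 0
    for (n1, n2), r in zip(structures, reps_per):
        if r == 0:
            continue
        # one-het-parent trios resolve directly; het x het trios resolve both
        # transmissions for AA/BB offspring and are ambiguous for AB
        k1 = rng.binomial(n1, 0.5, size=r)
        n_aa = rng.binomial(n2, 0.25, size=r)
        n_bb = rng.binomial(n2 - n_aa, 1.0 / 3.0)  # P(BB | not AA) = (1/4)/(3/4)
        m_ab = n2 - n_aa - n_bb
        k_a = k1 + 2 * n_aa
        n_tot = n1 + 2 * (n_aa + n_bb)
        post_mean = (k_a + m_ab + 1.0) / (n_tot + 2.0 * m_ab + 2.0)
        mags[pos : pos + r] = np.abs(post_mean - 0.5)
        pos += r
    return NullDistribution(magnitudes=np.sort(mags), margin=margin, n_reps=n_reps, seed=seed)


@dataclass
class CascadeReport:
    n_analyzed: int
    n_decisive: int
    n_above_null: int
    n_offspring_gate: int
    n_magnitude_gate: int
    n_pass_all: int
    null_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gate": [
                    "analyzed",
                    "decisive_bf",
                    "above_null_threshold",
                    "informative_offspring",
                    "trd_magnitude",
                    "pass_all",
                ],
                "count": [
                    self.n_analyzed,
                    self.n_decisive,
                    self.n_above_null,
                    self.n_offspring_gate,
                    self.n_magnitude_gate,
                    self.n_pass_all,
                ],
            }
        )


def apply_results_cascade(
    results: list[SnpTrdResult],
    null: NullDistribution | None = None,
    min_offspring: int = 20,
    magnitude_gate: float = 0.2,
) -> CascadeReport:
    """Flag each analyzed SNP on the four candidate-region gates.

    Gates (all strict inequalities, recorded separately on each result):
    decisive Bayes factor (> 100), |TRD| above the empirical-null threshold,
    informative offspring count (> ``min_offspring``), and |TRD| magnitude
    (> ``magnitude_gate``).
    """
    thr = null.threshold_at_margin if null is not None else 0.0
    counts = dict(analyzed=0, decisive=0, above=0, off=0, mag=0, all_=0)
    for r in results:
        if not r.analyzed:
            r.above_null_threshold = None
            r.passes_region_criteria = False
            continue
        counts["analyzed"] += 1
        r.above_null_threshold = bool(r.trd_magnitude > thr)
        r.passes_offspring_gate = bool(r.summary.n_informative_offspring > min_offspring)
        r.passes_magnitude_gate = bool(r.trd_magnitude > magnitude_gate)
        r.passes_region_criteria = bool(
            r.decisive and r.above_null_threshold and r.passes_offspring_gate and r.passes_magnitude_gate
        )
        counts["decisive"] += r.decisive
        counts["above"] += r.above_null_threshold
        counts["off"] += r.passes_offspring_gate
        counts["mag"] += r.passes_magnitude_gate
        counts["all_"] += r.passes_region_criteria
    return CascadeReport(
        n_analyzed=counts["analyzed"],
        n_decisive=counts["decisive"],
        n_above_null=counts["above"],
        n_offspring_gate=counts["off"],
        n_magnitude_gate=counts["mag"],
        n_pass_all=counts["all_"],
        null_threshold=thr,
    )


@dataclass
class TrdRegion:
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    pattern: str
    magnitude_min: float
    magnitude_max: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def call_regions(
    results: list[SnpTrdResult],
    max_gap_bp: int = 1_000_000,
    min_snps: int = 2,
) -> list[TrdRegion]:
    """Chain cascade-passing SNPs of shared pattern into physical regions.

    Greedy chaining along each chromosome: consecutive SNPs with the same
    pattern label at most ``max_gap_bp`` apart join a region; regions need at
    least ``min_snps`` members.
    """
    passing = [r for r in results if r.passes_region_criteria]
    passing.sort(key=lambda r: (str(r.variant.chrom), r.variant.pos_bp))
    regions: list[TrdRegion] = []
    chain: list[SnpTrdResult] = []

    def flush():
        if len(chain) >= min_snps:
            mags = [r.trd_magnitude for r in chain]
            regions.append(
                TrdRegion(
                    chrom=str(chain[0].variant.chrom),
                    start_bp=min(r.variant.pos_bp for r in chain),
                    end_bp=max(r.variant.pos_bp for r in chain),
                    snp_ids=[r.variant.id for r in chain],
                    pattern=chain[0].pattern.label,
                    magnitude_min=min(mags),
                    magnitude_max=max(mags),
                )
            )
        chain.clear()

    for r in passing:
        if chain and (
            str(r.variant.chrom) != str(chain[-1].variant.chrom)
            or r.pattern.label != chain[-1].pattern.label
            or r.variant.pos_bp - chain[-1].variant.pos_bp > max_gap_bp
        ):
            flush()
        chain.append(r)
    flush()
    return regions


def results_table(results: list[SnpTrdResult]) -> pd.DataFrame:
    """One row per SNP: counts, per-model log10 BF and DIC, pattern, gates."""
    rows = []
    for r in results:
        row = {
            "snp_id": r.variant.id,
            "chrom": r.variant.chrom,
            "pos_bp": r.variant.pos_bp,
            "allele_a": r.variant.allele_a,
            "allele_b": r.variant.allele_b,
            "n_informative_offspring": r.summary.n_informative_offspring,
            "n_informative_sires": r.summary.n_informative_sires,
            "n_informative_dams": r.summary.n_informative_dams,
            "n_mendel_errors": r.summary.n_mendel_errors,
            "skip_reason": r.skip_reason or "",
        }
        for tag in MODEL_TAGS:
            res = r.results.get(tag)
            row[f"log10_bf_{tag}"] = res.log10_bf if res else np.nan
            row[f"dic_{tag}"] = res.dic if res else np.nan
        row["pattern"] = r.pattern.label if r.pattern else ""
        row["pattern_tie"] = r.pattern.tie if r.pattern else False
        row["trd_magnitude"] = r.trd_magnitude
        row["log10_bf"] = r.log10_bf
        row["decisive"] = r.decisive
        row["above_null_threshold"] = r.above_null_threshold
        row["passes_region_criteria"] = r.passes_region_criteria
        rows.append(row)
    return pd.DataFrame(rows)


def regions_table(regions: list[TrdRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": g.chrom,
                "start_bp": g.start_bp,
                "end_bp": g.end_bp,
                "n_snps": g.n_snps,
                "pattern": g.pattern,
                "magnitude_min": g.magnitude_min,
                "magnitude_max": g.magnitude_max,
                "snp_ids": ",".join(g.snp_ids),
            }
            for g in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "pattern", "magnitude_min", "magnitude_max", "snp_ids"],
    )


def manhattan_table(results: list[SnpTrdResult]) -> pd.DataFrame:
    """(chrom, pos, log10 BF, pattern) export for external plotting."""
    rows = [
        {
            "chrom": r.variant.chrom,
            "pos_bp": r.variant.pos_bp,
            "log10_bf": r.log10_bf,
            "pattern": r.pattern.label if r.pattern else "",
        }
        for r in results
        if r.analyzed
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "log10_bf", "pattern"])
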