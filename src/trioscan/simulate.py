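"""Synthetic trio genotype panels with known injected transmission distortion.

The generator emulates the structure the scan assumes: biallelic autosomal
SNPs with configurable allele frequencies, parent genotypes in Hardy-Weinberg
proportions, a mating design that reuses a small pool of sires and dams across
many trios (default 154 trios over 47 sires and 93 dams, the structure of a
single-breed trio study), Mendelian transmission at null loci, and distorted
transmission at chosen loci under either the allelic or the genotypic model.
Optional genotyping error and missingness stressors corrupt calls after
transmission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .genotypes import MISSING, GenotypeMatrix, TrioSet, VariantRecord, build_trios
from .models import AllelicParams, GenotypicParams, ParentSpecificParams
from .plink import write_plink


@dataclass(frozen=True)
class TrdLocus:
    """An injected distortion: SNP index, model tag, and true parameters."""

    snp_index: int
    model_tag: str
    params: AllelicParams | ParentSpecificParams | GenotypicParams

    def __post_init__(self) -> None:
        if self.model_tag not in models.MODEL_TAGS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        if not self.params.in_space():
            raise ValueError(f"injected params {self.params} outside the parametric space")


@dataclass
class SimConfig:
    n_trios: int = 154
    n_sires: int = 47
    n_dams: int = 93
    n_snps: int = 500
    maf: float | tuple[float, float] = (0.05, 0.5)
    trd_loci: list[TrdLocus] = field(default_factory=list)
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    n_chrom: int = 31
    snp_spacing_bp: int = 100_000
    mating: str = "round_robin"  # or "random"

    def __post_init__(self) -> None:
        if self.n_sires > self.n_trios or self.n_dams > self.n_trios:
            raise ValueError("parent pool sizes cannot exceed the number of trios")
        for rate in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for locus in self.trd_loci:
            if not 0 <= locus.snp_index < self.n_snps:
                raise ValueError(f"trd locus index {locus.snp_index} out of range")


def _maf_per_snp(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.maf, (int, float)):
        return np.full(cfg.n_snps, float(cfg.maf))
    lo, hi = cfg.maf
    return rng.uniform(lo, hi, size=cfg.n_snps)


def _variants(cfg: SimConfig) -> list[VariantRecord]:
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chrom))
    out = []
    for i in range(cfg.n_snps):
        chrom = 1 + i // per_chrom
        rank = i % per_chrom
        out.append(
            VariantRecord(
                id=f"snp{i:06d}",
                chrom=str(chrom),
                pos_bp=(rank + 1) * cfg.snp_spacing_bp,
                allele_a="A",
                allele_b="B",
            )
        )
    return out


def simulate_parents(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Parent genotypes drawn from Hardy-Weinberg proportions per SNP."""
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = _maf_per_snp(cfg, rng)
    n_parents = cfg.n_sires + cfg.n_dams
    calls = rng.binomial(2, freqs[None, :], size=(n_parents, cfg.n_snps)).astype(np.int8)
    samples = [f"S{i:04d}" for i in range(cfg.n_sires)] + [f"D{i:04d}" for i in range(cfg.n_dams)]
    return GenotypeMatrix(samples=samples, variants=_variants(cfg), calls=calls)


def _transmit(parent_gt: np.ndarray, p_a: float, rng: np.random.Generator) -> np.ndarray:
    """Allele (0=A, 1=B) transmitted by each parent; hets transmit A w.p. p_a."""
    out = (parent_gt // 2).astype(np.int8)  # hom: obligate allele
    het = parent_gt == 1
    out[het] = (rng.random(int(het.sum())) >= p_a).astype(np.int8)
    return out


def simulate_offspring(
    sire_gt: np.ndarray,
    dam_gt: np.ndarray,
    model_tag: str | None = None,
    params=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Offspring genotype codes for one SNP given parent genotype arrays.

    ``model_tag=None`` simulates Mendelian transmission. Allelic distortion
    biases the transmitted allele of each heterozygous parent; genotypic
    distortion draws the offspring genotype from the mating-type distribution
    of the genotypic model (non-informative matings are unchanged).
    """
    rng = rng or np.random.default_rng()
    sire_gt = np.asarray(sire_gt)
    dam_gt = np.asarray(dam_gt)
    if model_tag in (None, "null"):
        return (_transmit(sire_gt, 0.5, rng) + _transmit(dam_gt, 0.5, rng)).astype(np.int8)
    if model_tag == "allelic_overall":
        pa = 0.5 + params.alpha
        return (_transmit(sire_gt, pa, rng) + _transmit(dam_gt, pa, rng)).astype(np.int8)
    if model_tag == "allelic_parent_specific":
        return (
            _transmit(sire_gt, 0.5 + params.alpha_s, rng) + _transmit(dam_gt, 0.5 + params.alpha_d, rng)
        ).astype(np.int8)
    if model_tag == "genotypic":
        off = (_transmit(sire_gt, 0.5, rng) + _transmit(dam_gt, 0.5, rng)).astype(np.int8)
        for mating, mask in (
            ("hetxhet", (sire_gt == 1) & (dam_gt == 1)),
            ("homAAxhet", ((sire_gt == 1) & (dam_gt == 0)) | ((sire_gt == 0) & (dam_gt == 1))),
            ("homBBxhet", ((sire_gt == 1) & (dam_gt == 2)) | ((sire_gt == 2) & (dam_gt == 1))),
        ):
            n = int(mask.sum())
            if n:
                probs = models.genotypic_offspring_probs(mating, params)
                off[mask] = rng.choice(3, size=n, p=probs).astype(np.int8)
        return off
    raise ValueError(f"unknown model_tag {model_tag!r}")


def corrupt(
    calls: np.ndarray,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int, int]:
    """Apply missingness then genotyping error to a call matrix.

    Each call is independently set MISSING with ``missing_rate``; surviving
    calls are perturbed to a uniformly chosen *different* genotype with
    ``error_rate``. Returns ``(corrupted, n_errors, n_missing)``.
    """
    for rate in (error_rate, missing_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = rng or np.random.default_rng()
    out = calls.copy()
    present = out != MISSING
    miss = present & (rng.random(out.shape) < missing_rate)
    out[miss] = MISSING
    survivors = (out != MISSING) & (rng.random(out.shape) < error_rate)
    n_err = int(survivors.sum())
    if n_err:
        # shift by 1 or 2 (mod 3) -> uniformly one of the two other genotypes
        shift = rng.integers(1, 3, size=n_err).astype(np.int8)
        out[survivors] = (out[survivors] + shift) % 3
    return out, n_err, int(miss.sum())


@dataclass
class TrioPanel:
    """A simulated panel: complete trios plus the injection truth table."""

    trios: TrioSet
    truth: pd.DataFrame
    config: SimConfig


def _mating_design(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if cfg.mating == "round_robin":
        sires = np.arange(cfg.n_trios) % cfg.n_sires
        dams = np.arange(cfg.n_trios) % cfg.n_dams
    elif cfg.mating == "random":
        sires = rng.integers(0, cfg.n_sires, cfg.n_trios)
        dams = rng.integers(0, cfg.n_dams, cfg.n_trios)
    else:
        raise ValueError(f"unknown mating design {cfg.mating!r}")
    return sires, dams


def simulate_panel(cfg: SimConfig) -> TrioPanel:
    """Generate a full trio panel with the configured injected distortions."""
    rng = np.random.default_rng(cfg.seed)
    parents = simulate_parents(cfg, rng)
    sire_of, dam_of = _mating_design(cfg, rng)
    sire_calls = parents.calls[: cfg.n_sires][sire_of]  # n_trios x n_snps
    dam_calls = parents.calls[cfg.n_sires :][dam_of]
    trd_by_index = {l.snp_index: l for l in cfg.trd_loci}
    off_calls = np.empty((cfg.n_trios, cfg.n_snps), dtype=np.int8)
    for j in range(cfg.n_snps):
        locus = trd_by_index.get(j)
        off_calls[:, j] = simulate_offspring(
            sire_calls[:, j],
            dam_calls[:, j],
            model_tag=locus.model_tag if locus else None,
            params=locus.params if locus else None,
            rng=rng,
        )
    calls = np.vstack([parents.calls, off_calls])
    samples = parents.samples + [f"O{i:04d}" for i in range(cfg.n_trios)]
    if cfg.missing_rate > 0 or cfg.genotyping_error_rate > 0:
        calls, _, _ = corrupt(calls, cfg.genotyping_error_rate, cfg.missing_rate, rng)
    pedigree = [
        (f"O{i:04d}", f"S{sire_of[i]:04d}", f"D{dam_of[i]:04d}") for i in range(cfg.n_trios)
    ]
    g = GenotypeMatrix(samples=samples, variants=parents.variants, calls=calls, pedigree=pedigree)
    rows = []
    for locus in sorted(cfg.trd_loci, key=lambda l: l.snp_index):
        p = locus.params
        rows.append(
            {
                "snp_id": parents.variants[locus.snp_index].id,
                "snp_index": locus.snp_index,
                "model_tag": locus.model_tag,
                "alpha": getattr(p, "alpha", np.nan),
                "alpha_s": getattr(p, "alpha_s", np.nan),
                "alpha_d": getattr(p, "alpha_d", np.nan),
                "alpha_g": getattr(p, "alpha_g", np.nan),
                "delta_g": getattr(p, "delta_g", np.nan),
            }
        )
    truth = pd.DataFrame(
        rows, columns=["snp_id", "snp_index", "model_tag", "alpha", "alpha_s", "alpha_d", "alpha_g", "delta_g"]
    )
    return TrioPanel(trios=build_trios(g), truth=truth, config=cfg)


def write_fixture(panel: TrioPanel, path_prefix, dialect: str = "binary") -> None:
    """Write a panel as PLINK files plus a ``<prefix>.truth.tsv`` sidecar."""
    prefix = Path(path_prefix)
    write_plink(panel.trios.genotypes, prefix, dialect=dialect)
    panel.truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
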