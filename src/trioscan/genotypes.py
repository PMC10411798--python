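"""Genotype containers, marker QC, and trio assembly.

Genotype calls are coded as the number of copies of ``allele_b``:
``AA=0`` (homozygous for ``allele_a``), ``AB=1``, ``BB=2``, ``MISSING=-1``.
``allele_a`` is the A1 allele of the source file as read; no re-polarisation
to the minor allele is performed, so all downstream distortion signs are
reported relative to ``allele_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

_NON_AUTOSOMAL = {"X", "Y", "XY", "MT", "M", "0"}


class PedigreeError(ValueError):
    """Raised for impossible pedigree structures (e.g. self-parenting)."""


class QCError(ValueError):
    """Raised when quality control leaves no usable variants."""


def is_autosome(chrom: str) -> bool:
    """True for numeric chromosome labels >= 1 (optionally 'chr'-prefixed)."""
    label = str(chrom)
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() in _NON_AUTOSOMAL:
        return False
    try:
        return int(label) >= 1
    except ValueError:
        return False


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic marker with 1-based physical coordinates."""

    id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.id}: alleles must differ, got {self.allele_a!r} twice")


@dataclass
class GenotypeMatrix:
    """Samples x variants genotype calls.

    Parameters
    ----------
    samples
        Ordered sample identifiers (unique).
    variants
        Ordered :class:`VariantRecord` list.
    calls
        ``int8`` array of shape ``(n_samples, n_variants)`` holding
        ``AA/AB/BB/MISSING`` codes.
    pedigree
        Optional ``(offspring, sire, dam)`` string triples recorded from the
        family file; used by :func:`build_trios`.
    """

    samples: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return (self.calls != MISSING).mean(axis=0)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def variant_index(self) -> dict[str, int]:
        return {v.id: j for j, v in enumerate(self.variants)}

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in keep],
            calls=self.calls[:, keep].copy(),
            pedigree=list(self.pedigree),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = self.sample_index()
        rows = [idx[s] for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            variants=list(self.variants),
            calls=self.calls[rows, :].copy(),
            pedigree=list(self.pedigree),
        )


@dataclass
class QCReport:
    n_input: int
    n_non_autosomal: int
    n_low_call_rate: int
    n_pass: int
    min_call_rate: float
    autosomes_only: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["input", "non_autosomal", "low_call_rate", "pass"],
                "count": [self.n_input, self.n_non_autosomal, self.n_low_call_rate, self.n_pass],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_marker_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.95,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop non-autosomal markers and markers with call rate below threshold.

    A marker failing both criteria is counted under each. Raises
    :class:`QCError` if no variant survives.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError(f"min_call_rate must be in [0, 1], got {min_call_rate}")
    autosomal = np.array([is_autosome(v.chrom) for v in g.variants], dtype=bool)
    cr_ok = g.call_rate() >= min_call_rate
    keep = cr_ok & (autosomal if autosomes_only else True)
    report = QCReport(
        n_input=g.n_variants,
        n_non_autosomal=int((~autosomal).sum()) if autosomes_only else 0,
        n_low_call_rate=int((~cr_ok).sum()),
        n_pass=int(keep.sum()),
        min_call_rate=min_call_rate,
        autosomes_only=autosomes_only,
    )
    if report.n_pass == 0:
        raise QCError("no variants pass QC")
    return g.subset_variants(keep), report


@dataclass
class TrioSet:
    """Complete (sire, dam, offspring) triplets over a shared variant index."""

    trios: list[tuple[str, str, str]]  # (sire, dam, offspring)
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        idx = self.genotypes.sample_index()
        offspring = [o for _, _, o in self.trios]
        if len(set(offspring)) != len(offspring):
            raise PedigreeError("an offspring appears in more than one trio")
        for s, d, o in self.trios:
            for member in (s, d, o):
                if member not in idx:
                    raise ValueError(f"trio member {member!r} not genotyped")
        self.sire_idx = np.array([idx[s] for s, _, _ in self.trios], dtype=np.intp)
        self.dam_idx = np.array([idx[d] for _, d, _ in self.trios], dtype=np.intp)
        self.off_idx = np.array([idx[o] for _, _, o in self.trios], dtype=np.intp)

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    def counts(self) -> dict[str, int]:
        return {
            "n_trios": self.n_trios,
            "n_sires": len({s for s, _, _ in self.trios}),
            "n_dams": len({d for _, d, _ in self.trios}),
            "n_offspring": len({o for _, _, o in self.trios}),
        }


def build_trios(
    g: GenotypeMatrix,
    pedigree: list[tuple[str, str, str]] | None = None,
) -> TrioSet:
    """Assemble complete trios from ``(offspring, sire, dam)`` triples.

    Triples with any ungenotyped member are dropped; an offspring listed as
    its own parent raises :class:`PedigreeError`.
    """
    if pedigree is None:
        pedigree = g.pedigree
    idx = g.sample_index()
    kept: list[tuple[str, str, str]] = []
    seen_offspring: set[str] = set()
    for off, sire, dam in pedigree:
        if off in (sire, dam):
            raise PedigreeError(f"offspring {off!r} listed as its own parent")
        if off in seen_offspring:
            raise PedigreeError(f"offspring {off!r} appears in multiple pedigree records")
        seen_offspring.add(off)
        if sire in idx and dam in idx and off in idx:
            kept.append((sire, dam, off))
    members: list[str] = []
    seen: set[str] = set()
    for s, d, o in kept:
        for m in (s, d, o):
            if m not in seen:
                seen.add(m)
                members.append(m)
    sub = g.subset_samples(members) if members else GenotypeMatrix([], g.variants, np.empty((0, g.n_variants), dtype=np.int8))
    return TrioSet(trios=kept, genotypes=sub)
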