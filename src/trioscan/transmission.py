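"""Mendelian trio classification and per-SNP transmission summaries.

For each trio x SNP the transmitted allele of every heterozygous parent is
resolved, where possible, by subtracting the obligate contribution of the
other parent. A het x het mating producing an AB offspring cannot be resolved
without phase and is recorded as AMBIGUOUS; the offspring genotype is still
tallied in the het x het cells used by the genotypic model. Trio genotype
combinations impossible under biparental inheritance are flagged as Mendelian
errors and excluded from all counts except the error tally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AB, MISSING, TrioSet

# transmission codes
TRANS_A = 0
TRANS_B = 1
AMBIGUOUS = 2
NOT_INFORMATIVE = 3

_TRANS_LABEL = {TRANS_A: "A", TRANS_B: "B", AMBIGUOUS: "AMBIGUOUS", NOT_INFORMATIVE: "NOT_INFORMATIVE"}

# mating-type codes (unordered with respect to parent sex for the genotypic cells)
M_HETHET = 0
M_HETHOM_AA = 1  # het x hom-AA, either orientation
M_HETHOM_BB = 2
M_HOMHOM = 3

_GT_LABEL = {0: "homAA", 1: "het", 2: "homBB"}


def _allele_sets(gt: int) -> tuple[int, ...]:
    # transmissible allele codes (0=A, 1=B)
    return {0: (0,), 1: (0, 1), 2: (1,)}[gt]


def _build_tables():
    """Enumerate all 27 non-missing trio genotype combinations once."""
    mendel = np.zeros(27, dtype=bool)
    sire_t = np.full(27, NOT_INFORMATIVE, dtype=np.int8)
    dam_t = np.full(27, NOT_INFORMATIVE, dtype=np.int8)
    mating = np.empty(27, dtype=np.int8)
    for s in range(3):
        for d in range(3):
            for o in range(3):
                idx = s * 9 + d * 3 + o
                if s == 1 and d == 1:
                    mating[idx] = M_HETHET
                elif (s, d) in ((1, 0), (0, 1)):
                    mating[idx] = M_HETHOM_AA
                elif (s, d) in ((1, 2), (2, 1)):
                    mating[idx] = M_HETHOM_BB
                else:
                    mating[idx] = M_HOMHOM
                # which (sire allele, dam allele) pairs reproduce the offspring
                pairs = [
                    (bs, bd)
                    for bs in _allele_sets(s)
                    for bd in _allele_sets(d)
                    if bs + bd == o
                ]
                mendel[idx] = bool(pairs)
                if not pairs:
                    continue
                if s == 1:
                    from_sire = {bs for bs, _ in pairs}
                    sire_t[idx] = AMBIGUOUS if len(from_sire) > 1 else from_sire.pop()
                if d == 1:
                    from_dam = {bd for _, bd in pairs}
                    dam_t[idx] = AMBIGUOUS if len(from_dam) > 1 else from_dam.pop()
    return mendel, sire_t, dam_t, mating


_MENDEL, _SIRE_T, _DAM_T, _MATING = _build_tables()


@dataclass(frozen=True)
class TrioClassification:
    mating_type: str
    sire_transmitted: str
    dam_transmitted: str
    mendel_consistent: bool


def classify_trio(sire_gt: int, dam_gt: int, off_gt: int) -> TrioClassification:
    """Classify one trio at one SNP. All genotypes must be non-missing."""
    for name, gt in (("sire", sire_gt), ("dam", dam_gt), ("offspring", off_gt)):
        if gt == MISSING or gt not in (0, 1, 2):
            raise ValueError(f"{name} genotype must be a non-missing code in {{0,1,2}}, got {gt}")
    idx = sire_gt * 9 + dam_gt * 3 + off_gt
    ok = bool(_MENDEL[idx])
    return TrioClassification(
        mating_type=f"{_GT_LABEL[sire_gt]}x{_GT_LABEL[dam_gt]}",
        sire_transmitted=_TRANS_LABEL[_SIRE_T[idx] if ok else NOT_INFORMATIVE],
        dam_transmitted=_TRANS_LABEL[_DAM_T[idx] if ok else NOT_INFORMATIVE],
        mendel_consistent=ok,
    )


@dataclass
class TransmissionSummary:
    """Per-SNP tallies of resolved transmissions and offspring genotype cells.

    ``sire_counts``/``dam_counts`` are ``(n_A, n_B)`` resolved transmissions
    from heterozygous parents. ``hethet_cells`` are offspring genotype counts
    ``(n_AA, n_AB, n_BB)`` from het x het matings; ``hethom_aa_cells`` are
    ``(n_AA, n_AB)`` from het x hom-AA matings and ``hethom_bb_cells`` are
    ``(n_AB, n_BB)`` from het x hom-BB matings (both orientations pooled).
    """

    snp_id: str
    sire_counts: tuple[int, int] = (0, 0)
    dam_counts: tuple[int, int] = (0, 0)
    hethet_cells: tuple[int, int, int] = (0, 0, 0)
    hethom_aa_cells: tuple[int, int] = (0, 0)
    hethom_bb_cells: tuple[int, int] = (0, 0)
    n_informative_offspring: int = 0
    n_informative_sires: int = 0
    n_informative_dams: int = 0
    n_mendel_errors: int = 0
    n_ambiguous: int = 0

    @property
    def hethom_cells(self) -> dict[str, tuple[int, int]]:
        return {"homAA": self.hethom_aa_cells, "homBB": self.hethom_bb_cells}

    @property
    def n_resolved(self) -> int:
        return sum(self.sire_counts) + sum(self.dam_counts)

    @property
    def n_hethet_ab(self) -> int:
        return self.hethet_cells[1]

    def has_data(self) -> bool:
        return self.n_resolved + sum(self.hethet_cells) + sum(self.hethom_aa_cells) + sum(self.hethom_bb_cells) > 0


def summarize_all(
    trios: TrioSet,
    snp_indices: np.ndarray | None = None,
    informative_mode: str = "inclusive",
) -> list[TransmissionSummary]:
    """Vectorised :func:`summarize_snp` over many SNPs.

    ``informative_mode="inclusive"`` (default) counts AB offspring of het x het
    matings as informative; ``"strict"`` requires at least one resolved
    transmission.
    """
    if informative_mode not in ("inclusive", "strict"):
        raise ValueError(f"informative_mode must be 'inclusive' or 'strict', got {informative_mode!r}")
    calls = trios.genotypes.calls
    if snp_indices is None:
        snp_indices = np.arange(trios.genotypes.n_variants)
    out = []
    for j in snp_indices:
        sgt = calls[trios.sire_idx, j]
        dgt = calls[trios.dam_idx, j]
        ogt = calls[trios.off_idx, j]
        complete = (sgt != MISSING) & (dgt != MISSING) & (ogt != MISSING)
        s, d, o = sgt[complete], dgt[complete], ogt[complete]
        idx = (s * 9 + d * 3 + o).astype(np.intp)
        ok = _MENDEL[idx]
        n_mendel_errors = int((~ok).sum())
        idx_ok = idx[ok]
        st, dt = _SIRE_T[idx_ok], _DAM_T[idx_ok]
        mat = _MATING[idx_ok]
        o_ok = o[ok]
        sire_counts = (int((st == TRANS_A).sum()), int((st == TRANS_B).sum()))
        dam_counts = (int((dt == TRANS_A).sum()), int((dt == TRANS_B).sum()))
        hh = mat == M_HETHET
        hethet = tuple(int(((o_ok == g) & hh).sum()) for g in (0, 1, 2))
        haa = mat == M_HETHOM_AA
        hethom_aa = (int(((o_ok == 0) & haa).sum()), int(((o_ok == 1) & haa).sum()))
        hbb = mat == M_HETHOM_BB
        hethom_bb = (int(((o_ok == 1) & hbb).sum()), int(((o_ok == 2) & hbb).sum()))
        n_ambiguous = int(((st == AMBIGUOUS) | (dt == AMBIGUOUS)).sum())
        has_het_parent = (s[ok] == AB) | (d[ok] == AB)
        if informative_mode == "inclusive":
            informative = has_het_parent
        else:
            informative = (st == TRANS_A) | (st == TRANS_B) | (dt == TRANS_A) | (dt == TRANS_B)
        n_informative = int(informative.sum())
        sires_ok = trios.sire_idx[complete][ok]
        dams_ok = trios.dam_idx[complete][ok]
        n_inf_sires = len(np.unique(sires_ok[s[ok] == AB]))
        n_inf_dams = len(np.unique(dams_ok[d[ok] == AB]))
        out.append(
            TransmissionSummary(
                snp_id=trios.genotypes.variants[j].id,
                sire_counts=sire_counts,
                dam_counts=dam_counts,
                hethet_cells=hethet,
                hethom_aa_cells=hethom_aa,
                hethom_bb_cells=hethom_bb,
                n_informative_offspring=n_informative,
                n_informative_sires=n_inf_sires,
                n_informative_dams=n_inf_dams,
                n_mendel_errors=n_mendel_errors,
                n_ambiguous=n_ambiguous,
            )
        )
    return out


def summarize_snp(trios: TrioSet, snp_id: str, informative_mode: str = "inclusive") -> TransmissionSummary:
    """Aggregate trio classifications for a single SNP."""
    vidx = trios.genotypes.variant_index()
    if snp_id not in vidx:
        raise KeyError(f"unknown SNP id {snp_id!r}")
    return summarize_all(trios, np.array([vidx[snp_id]]), informative_mode)[0]


def passes_informativeness(
    s: TransmissionSummary,
    min_offspring: int = 10,
    min_parents: int = 2,
    parent_rule: str = "or",
) -> bool:
    """Minimum-data filter: enough informative offspring and parents.

    ``parent_rule="or"`` (default) requires at least one parental sex to reach
    ``min_parents`` informative heterozygous parents; ``"and"`` requires both.
    """
    if min_offspring < 0 or min_parents < 0:
        raise ValueError("thresholds must be non-negative")
    if s.n_informative_offspring < min_offspring:
        return False
    if parent_rule == "or":
        return s.n_informative_sires >= min_parents or s.n_informative_dams >= min_parents
    if parent_rule == "and":
        return s.n_informative_sires >= min_parents and s.n_informative_dams >= min_parents
    raise ValueError(f"parent_rule must be 'or' or 'and', got {parent_rule!r}")


def summaries_table(summaries: list[TransmissionSummary]) -> pd.DataFrame:
    """One row per SNP with all count fields, exportable as TSV."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "snp_id": s.snp_id,
                "sire_A": s.sire_counts[0],
                "sire_B": s.sire_counts[1],
                "dam_A": s.dam_counts[0],
                "dam_B": s.dam_counts[1],
                "hethet_AA": s.hethet_cells[0],
                "hethet_AB": s.hethet_cells[1],
                "hethet_BB": s.hethet_cells[2],
                "hethomAA_AA": s.hethom_aa_cells[0],
                "hethomAA_AB": s.hethom_aa_cells[1],
                "hethomBB_AB": s.hethom_bb_cells[0],
                "hethomBB_BB": s.hethom_bb_cells[1],
                "n_informative_offspring": s.n_informative_offspring,
                "n_informative_sires": s.n_informative_sires,
                "n_informative_dams": s.n_informative_dams,
                "n_mendel_errors": s.n_mendel_errors,
                "n_ambiguous": s.n_ambiguous,
            }
        )
    return pd.DataFrame(rows)
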