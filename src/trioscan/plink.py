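"""PLINK genotype file input/output.

Supports the PLINK 1 binary triplet (.bed SNP-major with the v1 magic bytes,
.bim, .fam) and the text pair (.ped/.map). Sire and dam columns of the family
file are recorded on the returned :class:`~trioscan.genotypes.GenotypeMatrix`
for trio assembly.

Text-dialect allele coding: a .ped file declares no reference allele, so
``allele_a`` is defined as the first non-missing allele symbol encountered in
file order for each marker. This rule is stable under read -> write -> re-read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genotypes import AA, AB, BB, MISSING, GenotypeMatrix, VariantRecord

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 .bed 2-bit codes: 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_TO_CODE = np.array([AA, MISSING, AB, BB], dtype=np.int8)
_CODE_TO_BED = {AA: 0b00, MISSING: 0b01, AB: 0b10, BB: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or mutually inconsistent PLINK files."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required PLINK file not found: {path}")
    return path


def _read_fam(path: Path) -> tuple[list[str], list[tuple[str, str, str]]]:
    samples: list[str] = []
    pedigree: list[tuple[str, str, str]] = []
    for line in _require(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PlinkFormatError(f"{path}: expected 6 columns, got {len(parts)}")
        _, iid, father, mother, _, _ = parts[:6]
        samples.append(iid)
        if father != "0" or mother != "0":
            pedigree.append((iid, father, mother))
    if len(set(samples)) != len(samples):
        raise PlinkFormatError(f"{path}: duplicate sample IDs")
    return samples, pedigree


def _read_bim(path: Path) -> list[VariantRecord]:
    variants = []
    for line in _require(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError(f"{path}: expected 6 columns, got {len(parts)}")
        chrom, snp, _cm, pos, a1, a2 = parts
        variants.append(VariantRecord(id=snp, chrom=chrom, pos_bp=int(pos), allele_a=a1, allele_b=a2))
    return variants


def _read_map(path: Path) -> list[tuple[str, str, int]]:
    rows = []
    for line in _require(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise PlinkFormatError(f"{path}: expected 3 or 4 columns, got {len(parts)}")
        chrom, snp, pos = parts[0], parts[1], parts[-1]
        rows.append((chrom, snp, int(pos)))
    return rows


def _read_binary(prefix: Path) -> GenotypeMatrix:
    samples, pedigree = _read_fam(prefix.with_suffix(".fam"))
    variants = _read_bim(prefix.with_suffix(".bim"))
    data = _require(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK v1)")
    n, m = len(samples), len(variants)
    nb = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != m * nb:
        raise PlinkFormatError(
            f"{prefix}.bed: size {body.size} bytes does not match "
            f"{m} variants x {n} samples ({m * nb} expected)"
        )
    packed = body.reshape(m, nb)
    # unpack 2-bit fields, low-order bits first
    codes = np.empty((m, nb * 4), dtype=np.int8)
    for k in range(4):
        codes[:, k::4] = _BED_TO_CODE[(packed >> (2 * k)) & 0b11]
    calls = codes[:, :n].T  # samples x variants
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls, pedigree=pedigree)


def _read_text(prefix: Path) -> GenotypeMatrix:
    map_rows = _read_map(prefix.with_suffix(".map"))
    m = len(map_rows)
    samples: list[str] = []
    pedigree: list[tuple[str, str, str]] = []
    # per-marker allele registry in order of first appearance
    alleles: list[list[str]] = [[] for _ in range(m)]
    raw_rows: list[list[tuple[str, str]]] = []
    for line in _require(prefix.with_suffix(".ped")).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise PlinkFormatError(
                f"{prefix}.ped: sample {parts[1] if len(parts) > 1 else '?'} has "
                f"{len(parts) - 6} allele columns, expected {2 * m}"
            )
        _, iid, father, mother, _, _ = parts[:6]
        samples.append(iid)
        if father != "0" or mother != "0":
            pedigree.append((iid, father, mother))
        pairs = []
        for j in range(m):
            a, b = parts[6 + 2 * j], parts[7 + 2 * j]
            if (a == "0") != (b == "0"):
                raise PlinkFormatError(f"{prefix}.ped: half-missing genotype at marker {map_rows[j][1]}")
            pairs.append((a, b))
            for al in (a, b):
                if al != "0" and al not in alleles[j]:
                    alleles[j].append(al)
                    if len(alleles[j]) > 2:
                        raise PlinkFormatError(
                            f"{prefix}.ped: marker {map_rows[j][1]} has more than two alleles"
                        )
        raw_rows.append(pairs)
    if len(set(samples)) != len(samples):
        raise PlinkFormatError(f"{prefix}.ped: duplicate sample IDs")
    variants = []
    for (chrom, snp, pos), obs in zip(map_rows, alleles):
        a1 = obs[0] if len(obs) >= 1 else "N"
        a2 = obs[1] if len(obs) >= 2 else "0"
        variants.append(VariantRecord(id=snp, chrom=chrom, pos_bp=pos, allele_a=a1, allele_b=a2))
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw_rows):
        for j, (a, b) in enumerate(pairs):
            if a == "0":
                continue
            calls[i, j] = (a != variants[j].allele_a) + (b != variants[j].allele_a)
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls, pedigree=pedigree)


def read_plink(path_prefix, dialect: str | None = None) -> GenotypeMatrix:
    """Read a PLINK fileset given its path stem.

    ``dialect`` is ``"binary"`` (.bed/.bim/.fam), ``"text"`` (.ped/.map), or
    ``None`` to autodetect by file presence (binary preferred).
    """
    prefix = Path(path_prefix)
    if dialect is None:
        dialect = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if dialect == "binary":
        return _read_binary(prefix)
    if dialect == "text":
        return _read_text(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fam_lines(g: GenotypeMatrix) -> list[str]:
    parents = {o: (s, d) for o, s, d in g.pedigree}
    lines = []
    for iid in g.samples:
        father, mother = parents.get(iid, ("0", "0"))
        lines.append(f"FAM {iid} {father} {mother} 0 -9")
    return lines


def write_plink(g: GenotypeMatrix, path_prefix, dialect: str = "binary") -> None:
    """Write a genotype matrix as a PLINK fileset (binary or text)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        prefix.with_suffix(".fam").write_text("\n".join(_fam_lines(g)) + "\n")
        bim = [
            f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\t{v.allele_a}\t{v.allele_b}"
            for v in g.variants
        ]
        prefix.with_suffix(".bim").write_text("\n".join(bim) + "\n")
        n, m = g.n_samples, g.n_variants
        nb = (n + 3) // 4
        packed = np.zeros((m, nb), dtype=np.uint8)
        codes = g.calls.T  # variants x samples
        bed_codes = np.empty_like(codes, dtype=np.uint8)
        for code, bits in _CODE_TO_BED.items():
            bed_codes[codes == code] = bits
        for k in range(4):
            cols = bed_codes[:, k::4]
            packed[:, : cols.shape[1]] |= (cols << (2 * k)).astype(np.uint8)
        prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())
    elif dialect == "text":
        mp = [f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}" for v in g.variants]
        prefix.with_suffix(".map").write_text("\n".join(mp) + "\n")
        parents = {o: (s, d) for o, s, d in g.pedigree}
        lines = []
        for i, iid in enumerate(g.samples):
            father, mother = parents.get(iid, ("0", "0"))
            toks = ["FAM", iid, father, mother, "0", "-9"]
            for j, v in enumerate(g.variants):
                c = g.calls[i, j]
                if c == MISSING:
                    toks += ["0", "0"]
                elif c == AA:
                    toks += [v.allele_a, v.allele_a]
                elif c == AB:
                    toks += [v.allele_a, v.allele_b]
                else:
                    toks += [v.allele_b, v.allele_b]
            lines.append(" ".join(toks))
        prefix.with_suffix(".ped").write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
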