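"""Candidate-gene annotation of a distorted SNP with a +/- 250 kb window.

Uses published equine fertility genes (EquCab3.0 coordinates) around a
chromosome-20 signal to show the positional window lookup: genes containing
the SNP position are flagged "overlapping", other genes inside the window
are "proximal".
"""

from trioscan import VariantRecord
from trioscan.annotate import GeneInterval, annotate_snp

genes = [
    GeneInterval("BAG6", "BAG6", "20", 32_273_066, 32_283_378),
    GeneInterval("MSH5", "MSH5", "20", 32_366_937, 32_382_268),
    GeneInterval("HSPA1L", "HSPA1L", "20", 32_415_042, 32_416_967),
    GeneInterval("EHMT2", "EHMT2", "20", 32_472_911, 32_485_948),
    GeneInterval("SPIRE1", "SPIRE1", "8", 40_539_360, 40_796_466),
]

snp = VariantRecord("Affx-102696704", "20", 32_414_941, "A", "B")
print(f"SNP {snp.id} at {snp.chrom}:{snp.pos_bp:,}, window +/- 250 kb\n")
for gene, cls in annotate_snp(snp, genes, window_bp=250_000):
    print(f"  {gene.name:8s} {gene.chrom}:{gene.start_bp:,}-{gene.end_bp:,}  {cls}")
print(
    "\nThe four chromosome-20 fertility genes fall inside the window; SPIRE1 on\n"
    "chromosome 8 does not. HSPA1L starts 101 bp downstream of the SNP, so it is\n"
    "proximal rather than overlapping."
)
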