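import numpy as np
import pytest

from trioscan.genotypes import GenotypeMatrix, TrioSet, VariantRecord


def make_trioset(sire_gts, dam_gts, off_gts, variants=None) -> TrioSet:
    """Build a TrioSet from explicit genotype arrays.

    Each *_gts argument is (n_trios,) for a single SNP or (n_trios, n_snps);
    codes are 0=AA, 1=AB, 2=BB, -1=missing. Each trio gets its own sire and
    dam unless the same parent index is desired via duplicated rows upstream.
    """
    sire = np.atleast_2d(np.asarray(sire_gts, dtype=np.int8).T).T
    dam = np.atleast_2d(np.asarray(dam_gts, dtype=np.int8).T).T
    off = np.atleast_2d(np.asarray(off_gts, dtype=np.int8).T).T
    if sire.ndim == 1:
        sire, dam, off = sire[:, None], dam[:, None], off[:, None]
    n, m = sire.shape
    if variants is None:
        variants = [
            VariantRecord(f"snp{j}", "1", 1000 * (j + 1), "A", "B") for j in range(m)
        ]
    samples = (
        [f"S{i}" for i in range(n)] + [f"D{i}" for i in range(n)] + [f"O{i}" for i in range(n)]
    )
    calls = np.vstack([sire, dam, off])
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    trios = [(f"S{i}", f"D{i}", f"O{i}") for i in range(n)]
    return TrioSet(trios=trios, genotypes=g)


def brute_force_summary(sire_gts, dam_gts, off_gts):
    """Independent re-enumeration of one SNP's transmission summary.

    Works directly from Mendelian first principles (explicit allele-pair
    enumeration), sharing no code with the package's lookup tables. Parent
    identity is positional: trio i has sire i and dam i (as in make_trioset).
    Returns a dict of the count fields.
    """
    def allele_pairs(gt):
        return {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[gt]

    counts = dict(
        sire=[0, 0], dam=[0, 0], hethet=[0, 0, 0], haa=[0, 0], hbb=[0, 0],
        n_inf=0, inf_sires=set(), inf_dams=set(), mendel=0, ambiguous=0,
    )
    for i, (s, d, o) in enumerate(zip(sire_gts, dam_gts, off_gts)):
        if -1 in (s, d, o):
            continue
        transmissions = set()
        for sa in set(allele_pairs(s)):
            for da in set(allele_pairs(d)):
                for bs in set(sa):
                    for bd in set(da):
                        if bs + bd == o:
                            transmissions.add((bs, bd))
        if not transmissions:
            counts["mendel"] += 1
            continue
        if s == 1 or d == 1:
            counts["n_inf"] += 1
        if s == 1:
            counts["inf_sires"].add(i)
            from_s = {bs for bs, _ in transmissions}
            if len(from_s) == 1:
                counts["sire"][from_s.pop()] += 1
            else:
                counts["ambiguous"] += 1
        if d == 1:
            counts["inf_dams"].add(i)
            from_d = {bd for _, bd in transmissions}
            if len(from_d) == 1:
                counts["dam"][from_d.pop()] += 1
        if s == 1 and d == 1:
            counts["hethet"][o] += 1
        elif (s, d) in ((1, 0), (0, 1)):
            counts["haa"][o] += 1
        elif (s, d) in ((1, 2), (2, 1)):
            counts["hbb"][o - 1] += 1
    return counts


@pytest.fixture(scope="session")
def null_panel():
    """A small all-null simulated panel shared across tests."""
    from trioscan.simulate import SimConfig, simulate_panel

    return simulate_panel(SimConfig(n_trios=60, n_sires=15, n_dams=30, n_snps=25, seed=42))
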