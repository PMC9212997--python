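"""Independent brute-force oracles used to check the implementation.

Deliberately naive: dict-based triplet scans, O(m^2) step-up, per-gene
region assignment. The genetic code used here is built by translating
each codon with Biopython's Seq machinery, independently of the
package's table construction.
"""

from itertools import product

from Bio.Seq import Seq

BASES = "ACGT"
ORACLE_CODE = {
    "".join(c): str(Seq("".join(c)).translate()) for c in product(BASES, repeat=3)
}
ORACLE_FAMILIES: dict[str, list[str]] = {}
for codon, aa in ORACLE_CODE.items():
    if aa != "*":
        ORACLE_FAMILIES.setdefault(aa, []).append(codon)


def oracle_count(nucleotides: str) -> dict[str, int]:
    """Left-to-right non-overlapping triplet scan; skips N-codons."""
    counts: dict[str, int] = {}
    for i in range(0, len(nucleotides) - len(nucleotides) % 3, 3):
        codon = nucleotides[i : i + 3]
        if set(codon) <= set(BASES):
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def oracle_usage(counts: dict[str, int]) -> dict[str, float]:
    sense = {c: n for c, n in counts.items() if ORACLE_CODE[c] != "*"}
    total = sum(sense.values())
    return {c: n / total for c, n in sense.items()} if total else {}


def oracle_selection(counts: dict[str, int]) -> dict[str, float]:
    """codon count / family total, for every sense codon of an observed family."""
    out: dict[str, float] = {}
    for aa, family in ORACLE_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        if total:
            for c in family:
                out[c] = counts.get(c, 0) / total
    return out


def oracle_bh(p_values: list[float]) -> list[float]:
    """O(m^2) step-up: q_i = min over p_j >= p_i of p_j * m / rank(p_j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(
            min(p_values[order[k]] * m / (k + 1) for k in range(pos, m)), 1.0
        )
    return q


def oracle_regions(named_sets: dict[str, set[str]]) -> dict[str, int]:
    """Assign every gene of the union to its +/- region, one at a time."""
    names = list(named_sets)
    union = set().union(*named_sets.values())
    regions: dict[str, int] = {}
    for gene in union:
        pattern = "".join("+" if gene in named_sets[n] else "-" for n in names)
        regions[pattern] = regions.get(pattern, 0) + 1
    return regions


def oracle_filter(rows, padj_max: float, lfc_min: float, direction: str) -> set[str]:
    """Row-by-row scan of (gene_id, log2fc, padj) triples."""
    keep = set()
    for gene_id, lfc, padj in rows:
        if padj is None or padj != padj or not padj < padj_max:
            continue
        if direction == "up" and lfc > lfc_min:
            keep.add(gene_id)
        elif direction == "down" and lfc < -lfc_min:
            keep.add(gene_id)
        elif direction == "both" and abs(lfc) > lfc_min:
            keep.add(gene_id)
    return keep


def random_cds(rng, n_codons: int) -> str:
    return "".join(
        BASES[b] for b in rng.integers(0, 4, size=3 * n_codons)
    )
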