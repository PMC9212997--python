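"""Genetic code tables and synonymous-codon families.

A :class:`GeneticCode` maps each of the 64 trinucleotide codons to an
amino-acid symbol (one-letter code) or ``"*"`` for stop, and derives the
synonymous families that codon selection rates are normalized within.
The default is the standard code, built from Biopython's NCBI table 1.
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"

#: All 64 codons in lexicographic order; the index of codon ``b0 b1 b2`` is
#: ``16*i(b0) + 4*i(b1) + i(b2)`` with A,C,G,T -> 0..3.
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

CODON_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}


class GeneticCode:
    """A codon -> amino-acid map plus its derived synonymous families.

    Parameters
    ----------
    table:
        Mapping from each of the 64 codons to a one-letter amino-acid
        symbol, with stop codons mapped to ``"*"``.
    name:
        Label used in logs and manifests.
    """

    def __init__(self, table: dict[str, str], name: str = "custom"):
        if set(table) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(table)
            extra = set(table) - set(ALL_CODONS)
            raise ValueError(
                f"genetic code must cover exactly the 64 codons; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        self.table: dict[str, str] = {c: table[c] for c in ALL_CODONS}
        self.name = name
        if not self.stop_codons:
            raise ValueError("genetic code defines no stop codon")

    @cached_property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] == STOP)

    @cached_property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> its synonymous codons (sorted), stops excluded."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.table[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}

    @cached_property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    @cached_property
    def sense_codons(self) -> tuple[str, ...]:
        """Sense codons ordered by (amino acid, codon) — the canonical
        column order of every matrix this package emits."""
        return tuple(c for aa in self.amino_acids for c in self.families[aa])

    @cached_property
    def sense_index(self) -> np.ndarray:
        """Positions of :attr:`sense_codons` within :data:`ALL_CODONS`."""
        return np.array([CODON_TO_INDEX[c] for c in self.sense_codons])

    @cached_property
    def family_slices(self) -> dict[str, np.ndarray]:
        """Amino acid -> positions of its codons within :data:`ALL_CODONS`."""
        return {
            aa: np.array([CODON_TO_INDEX[c] for c in codons])
            for aa, codons in self.families.items()
        }

    def amino_acid(self, codon: str) -> str:
        return self.table[codon]

    def family_of(self, codon: str) -> tuple[str, ...]:
        """The synonymous family the codon belongs to."""
        aa = self.table[codon]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon and has no family")
        return self.families[aa]

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "GeneticCode":
        """Load a code from a 64-line TSV of ``codon<TAB>amino_acid``."""
        table: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'codon<TAB>amino_acid'")
            codon, aa = parts[0].upper().replace("U", "T"), parts[1].strip()
            table[codon] = aa
        return cls(table, name=name or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{self.table[c]}\n" for c in ALL_CODONS)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneticCode({self.name!r}, {len(self.sense_codons)} sense codons, "
            f"{len(self.stop_codons)} stops)"
        )


def standard_code() -> GeneticCode:
    """The standard genetic code (61 sense codons, 3 stops)."""
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = STOP
    return GeneticCode(table, name="standard")


STANDARD_CODE = standard_code()
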