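"""Read, validate, and deduplicate coding sequences from FASTA.

Downstream codon statistics want exactly one representative CDS per gene,
uppercase DNA, and a clean reading frame. This module supplies that:
:func:`read_cds_fasta` parses GENCODE-style or plain headers and normalizes
nucleotides (uppercase, U->T, anything else -> N), :func:`validate_cds`
enforces frame/ambiguity rules in a strict or lenient mode, and
:func:`select_representative` collapses multiple transcripts per gene.

Rejections are data, not exceptions: validation returns
:class:`Rejection` records with a reason code, writable as a TSV report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .errors import FastaParseError, HeaderError

__all__ = [
    "CodingSequence",
    "HeaderDialect",
    "Rejection",
    "PLAIN",
    "GENCODE",
    "GENCODE_PC_TRANSCRIPTS",
    "read_cds_fasta",
    "write_cds_fasta",
    "validate_cds",
    "validate_many",
    "select_representative",
    "write_rejection_report",
]

# Uppercase, map U->T; applied before the catch-all N substitution.
_CANONICAL = str.maketrans("acgtunU", "ACGTTNT")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence: gene id, transcript id, normalized nucleotides."""

    gene_id: str
    transcript_id: str
    nucleotides: str

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class Rejection:
    """A validation rejection with a machine-readable reason code."""

    gene_id: str
    transcript_id: str
    reason: str


@dataclass(frozen=True)
class HeaderDialect:
    """How to pull gene and transcript ids out of a FASTA header.

    ``plain`` uses the whole first whitespace-delimited token as both ids.
    ``gencode`` splits the token on ``|`` and picks fields by position.
    Note that GENCODE's own ``pc_transcripts`` FASTA puts the transcript id
    first and the gene id second; use :data:`GENCODE_PC_TRANSCRIPTS` for
    those files.
    """

    name: Literal["plain", "gencode"]
    field_index_gene: int = 0
    field_index_transcript: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("plain", "gencode"):
            raise ValueError(f"unknown header dialect {self.name!r}")
        if self.field_index_gene < 0 or self.field_index_transcript < 0:
            raise ValueError("header field indices must be non-negative")
        if self.name == "gencode" and self.field_index_gene == self.field_index_transcript:
            raise ValueError("gencode dialect needs distinct gene/transcript fields")


PLAIN = HeaderDialect("plain")
GENCODE = HeaderDialect("gencode", field_index_gene=0, field_index_transcript=1)
#: Field order of GENCODE pc_transcripts releases (transcript|gene|...).
GENCODE_PC_TRANSCRIPTS = HeaderDialect(
    "gencode", field_index_gene=1, field_index_transcript=0
)


def dialect_by_name(name: str) -> HeaderDialect:
    presets = {
        "plain": PLAIN,
        "gencode": GENCODE,
        "gencode-pc-transcripts": GENCODE_PC_TRANSCRIPTS,
    }
    try:
        return presets[name]
    except KeyError:
        raise ValueError(
            f"unknown dialect {name!r}; choose from {sorted(presets)}"
        ) from None


def _normalize(raw: str) -> str:
    seq = raw.translate(_CANONICAL)
    if set(seq) <= _VALID:
        return seq
    return "".join(ch if ch in _VALID else "N" for ch in seq)


def _parse_header(token: str, dialect: HeaderDialect) -> tuple[str, str]:
    if dialect.name == "plain":
        if not token:
            raise HeaderError("empty FASTA header")
        return token, token
    parts = token.split("|")
    needed = max(dialect.field_index_gene, dialect.field_index_transcript)
    if needed >= len(parts):
        raise HeaderError(
            f"header {token!r} has {len(parts)} pipe-delimited field(s); "
            f"dialect {dialect.name!r} needs index {needed}"
        )
    gene = parts[dialect.field_index_gene]
    transcript = parts[dialect.field_index_transcript]
    if not gene:
        raise HeaderError(f"header {token!r} has an empty gene id field")
    return gene, transcript


def read_cds_fasta(
    path: str | Path, dialect: HeaderDialect = PLAIN
) -> list[CodingSequence]:
    """Parse a CDS FASTA into normalized :class:`CodingSequence` records.

    Record order is preserved. Lowercase is uppercased, U is mapped to T,
    and any other character becomes N (strict validation later rejects it).

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header, naming the line.
    HeaderError
        If a header lacks the fields the dialect requires.
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, transcript = _parse_header(rec.id, dialect)
        records.append(CodingSequence(gene, transcript, _normalize(str(rec.seq))))
    return records


def write_cds_fasta(
    seqs: Iterable[CodingSequence],
    path: str | Path,
    dialect: HeaderDialect = GENCODE,
    width: int = 60,
) -> None:
    """Write sequences with headers the same dialect can read back."""
    with Path(path).open("w") as out:
        for seq in seqs:
            if dialect.name == "plain":
                header = seq.gene_id
            else:
                fields = ["", ""]
                fields[dialect.field_index_gene] = seq.gene_id
                fields[dialect.field_index_transcript] = seq.transcript_id
                header = "|".join(fields)
            out.write(f">{header}\n")
            for i in range(0, len(seq.nucleotides), width):
                out.write(seq.nucleotides[i : i + width] + "\n")


def validate_cds(
    seq: CodingSequence, mode: Literal["strict", "lenient"] = "strict"
) -> CodingSequence | Rejection:
    """Validate one CDS for codon counting.

    Strict mode rejects any sequence whose length is not a multiple of 3,
    that contains N, or that is shorter than one codon. Lenient mode
    truncates a trailing partial codon and drops codons containing N,
    rejecting only when no complete informative codon remains. The
    lenient-accepted sequence is the concatenation of the kept codons, so
    its length is always a multiple of 3.
    """
    n = len(seq.nucleotides)
    if mode == "strict":
        if n < 3:
            return Rejection(seq.gene_id, seq.transcript_id, "too_short")
        if n % 3 != 0:
            return Rejection(seq.gene_id, seq.transcript_id, "length_not_multiple_of_3")
        if "N" in seq.nucleotides:
            return Rejection(seq.gene_id, seq.transcript_id, "contains_N")
        return seq
    if mode != "lenient":
        raise ValueError(f"unknown validation mode {mode!r}")
    trimmed = seq.nucleotides[: n - n % 3]
    kept = [
        trimmed[i : i + 3] for i in range(0, len(trimmed), 3) if "N" not in trimmed[i : i + 3]
    ]
    if not kept:
        return Rejection(seq.gene_id, seq.transcript_id, "no_informative_codons")
    return replace(seq, nucleotides="".join(kept))


def validate_many(
    seqs: Iterable[CodingSequence], mode: Literal["strict", "lenient"] = "strict"
) -> tuple[list[CodingSequence], list[Rejection]]:
    accepted: list[CodingSequence] = []
    rejected: list[Rejection] = []
    for seq in seqs:
        out = validate_cds(seq, mode)
        (rejected if isinstance(out, Rejection) else accepted).append(out)
    return accepted, rejected


def write_rejection_report(rejections: Sequence[Rejection], path: str | Path) -> None:
    with Path(path).open("w") as out:
        out.write("gene_id\ttranscript_id\treason\n")
        for r in rejections:
            out.write(f"{r.gene_id}\t{r.transcript_id}\t{r.reason}\n")


def select_representative(
    seqs: Sequence[CodingSequence], policy: Literal["longest", "first"] = "longest"
) -> list[CodingSequence]:
    """Keep one CDS per gene id.

    ``longest`` keeps the maximal-length CDS per gene, breaking ties by
    lexicographically smallest transcript id; ``first`` keeps the first
    occurrence in input order. Output follows first-occurrence gene order.
    """
    if policy not in ("longest", "first"):
        raise ValueError(f"unknown representative policy {policy!r}")
    chosen: dict[str, CodingSequence] = {}
    for seq in seqs:
        held = chosen.get(seq.gene_id)
        if held is None:
            chosen[seq.gene_id] = seq
        elif policy == "longest" and (
            (len(seq), _neg_lex(seq.transcript_id))
            > (len(held), _neg_lex(held.transcript_id))
        ):
            chosen[seq.gene_id] = seq
    return list(chosen.values())


class _neg_lex(str):
    """Reversed lexicographic ordering, so max() prefers the smaller id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)
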