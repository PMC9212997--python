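"""Per-gene codon counts, usage rates, and within-family selection rates.

The central statistic is the *selection rate*: for a sense codon ``c``
encoding amino acid ``a`` in a given gene,

    selection(c) = count(c) / sum over c' in family(a) of count(c'),

i.e. the fraction of the gene's uses of amino acid ``a`` that chose codon
``c`` over its synonymous alternatives (an RSCU-style quantity normalized
to sum to 1 within each family). Families the gene never uses yield
MISSING (NaN), never 0, so short genes do not drag group means toward zero.
The *usage rate* is the simpler count(c)/total over included codons.

Counting reads non-overlapping triplets left to right from position 0 of
a validated CDS; there is no ORF search. Stop codons are kept in raw
counts and excluded from usage/selection statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetic_code import ALL_CODONS, STANDARD_CODE, GeneticCode
from .sequence_io import CodingSequence

__all__ = [
    "CodonCountTable",
    "UsageProfile",
    "SelectionRateProfile",
    "ProfileMatrix",
    "count_codons",
    "count_matrix",
    "usage_rates",
    "selection_rates",
    "usage_matrix",
    "selection_matrix",
    "profile_matrix",
    "pooled_selection_rates",
]

# ASCII byte -> base index (A,C,G,T -> 0..3), 255 for anything else.
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _codon_index_array(nucleotides: str) -> np.ndarray:
    """Non-overlapping triplets -> codon indices; -1 for triplets with
    any non-ACGT character (those are dropped by the caller)."""
    n = len(nucleotides) - len(nucleotides) % 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    raw = np.frombuffer(nucleotides[:n].encode("ascii"), dtype=np.uint8)
    bases = _BASE_LUT[raw].reshape(-1, 3).astype(np.int64)
    idx = bases[:, 0] * 16 + bases[:, 1] * 4 + bases[:, 2]
    idx[(bases >= 4).any(axis=1)] = -1
    return idx


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of each of the 64 codons observed in one gene's CDS."""

    gene_id: str
    counts: np.ndarray  # shape (64,), int64, indexed like ALL_CODONS

    def __post_init__(self) -> None:
        if self.counts.shape != (64,):
            raise ValueError("counts must be a length-64 vector")

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[ALL_CODONS.index(codon)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(ALL_CODONS), name=self.gene_id)


@dataclass(frozen=True)
class UsageProfile:
    """Per-gene codon usage rates over the included codon set."""

    gene_id: str
    rates: pd.Series  # index: included codons; NaN when profile is MISSING
    missing_reason: str | None = None


@dataclass(frozen=True)
class SelectionRateProfile:
    """Per-gene within-family selection rates; NaN marks unobserved families."""

    gene_id: str
    selection: pd.Series  # index: sense codons in the code's canonical order


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Count non-overlapping triplets of a validated CDS.

    The total equals floor(length/3) minus codons containing N (which a
    strict pipeline has already rejected and a lenient one has dropped).
    """
    idx = _codon_index_array(seq.nucleotides)
    counts = np.bincount(idx[idx >= 0], minlength=64).astype(np.int64)
    return CodonCountTable(seq.gene_id, counts)


def count_matrix(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Stack per-gene codon counts into a genes x 64 DataFrame."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for seq in seqs:
        idx = _codon_index_array(seq.nucleotides)
        rows.append(np.bincount(idx[idx >= 0], minlength=64))
        ids.append(seq.gene_id)
    data = np.vstack(rows) if rows else np.empty((0, 64), dtype=np.int64)
    return pd.DataFrame(data, index=ids, columns=list(ALL_CODONS), dtype=np.int64)


def usage_rates(
    counts: CodonCountTable,
    include_stops: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> UsageProfile:
    """count(c)/total over the included codon set (stops excluded by default)."""
    if include_stops:
        included = list(ALL_CODONS)
        vec = counts.counts.astype(float)
    else:
        included = list(code.sense_codons)
        vec = counts.counts[code.sense_index].astype(float)
    total = vec.sum()
    if total == 0:
        return UsageProfile(
            counts.gene_id,
            pd.Series(np.nan, index=included),
            missing_reason="no_included_codons",
        )
    return UsageProfile(counts.gene_id, pd.Series(vec / total, index=included))


def selection_rates(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> SelectionRateProfile:
    """Within-family selection rate per sense codon; NaN for families with
    zero observed codons. Single-codon families (Met, Trp) are 1 whenever
    observed."""
    sel = np.full(len(code.sense_codons), np.nan)
    pos = 0
    for aa in code.amino_acids:
        fam = code.family_slices[aa]
        fam_counts = counts.counts[fam].astype(float)
        total = fam_counts.sum()
        if total > 0:
            sel[pos : pos + len(fam)] = fam_counts / total
        pos += len(fam)
    return SelectionRateProfile(
        counts.gene_id, pd.Series(sel, index=list(code.sense_codons))
    )


def _family_normalize(sense: np.ndarray, code: GeneticCode) -> np.ndarray:
    """Row-wise family normalization of a genes x 61 sense-count array."""
    out = np.full(sense.shape, np.nan)
    pos = 0
    for aa in code.amino_acids:
        k = len(code.families[aa])
        block = sense[:, pos : pos + k].astype(float)
        totals = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = block / totals
        norm[np.broadcast_to(totals == 0, norm.shape)] = np.nan
        out[:, pos : pos + k] = norm
        pos += k
    return out


def usage_matrix(
    counts: pd.DataFrame, code: GeneticCode = STANDARD_CODE, include_stops: bool = False
) -> pd.DataFrame:
    cols = list(ALL_CODONS) if include_stops else list(code.sense_codons)
    block = counts[cols].to_numpy(dtype=float)
    totals = block.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = block / totals
    rates[np.broadcast_to(totals == 0, rates.shape)] = np.nan
    return pd.DataFrame(rates, index=counts.index, columns=cols)


def selection_matrix(
    counts: pd.DataFrame, code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Genes x 61 within-family selection rates from a genes x 64 count table."""
    sense = counts[list(code.sense_codons)].to_numpy()
    return pd.DataFrame(
        _family_normalize(sense, code), index=counts.index, columns=list(code.sense_codons)
    )


@dataclass(frozen=True)
class ProfileMatrix:
    """Per-gene codon statistics: raw counts, usage rates, selection rates.

    Rows follow input gene order; columns are the code's canonical
    (amino acid, codon) ordering. MISSING cells are NaN, never imputed 0.
    """

    counts: pd.DataFrame  # genes x 64
    usage: pd.DataFrame  # genes x 61
    selection: pd.DataFrame  # genes x 61
    code: GeneticCode = field(repr=False, default=STANDARD_CODE)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


def profile_matrix(
    genes: Sequence[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> ProfileMatrix:
    """Assemble counts/usage/selection matrices for deduplicated genes."""
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in profile input: {dupes[:5]}")
    counts = count_matrix(genes)
    return ProfileMatrix(
        counts=counts,
        usage=usage_matrix(counts, code),
        selection=selection_matrix(counts, code),
        code=code,
    )


def pooled_selection_rates(
    counts: pd.DataFrame, gene_ids: Iterable[str], code: GeneticCode = STANDARD_CODE
) -> pd.Series:
    """Selection rates of the pooled codon counts of a gene set.

    Sums counts over the genes first, then normalizes within families, so
    long genes weigh more — the subset-level companion to the per-gene
    statistics used for testing.
    """
    ids = [g for g in gene_ids if g in counts.index]
    pooled = counts.loc[ids].sum(axis=0).to_numpy()[None, :]
    sense = pooled[:, [list(ALL_CODONS).index(c) for c in code.sense_codons]]
    return pd.Series(
        _family_normalize(sense, code)[0], index=list(code.sense_codons)
    )
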