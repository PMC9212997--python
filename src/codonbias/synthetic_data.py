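"""Synthetic coding sequences, DE tables, and membership files with known truth.

The generator emulates the three inputs the analysis consumes:

* a genome-wide background of CDS drawn from a per-amino-acid codon
  preference model (per-family weights drawn from a symmetric Dirichlet),
* a "biased" gene subset whose weights are shifted for designated codons
  (multiplied by a factor, then renormalized within each affected family),
* DE results tables planted with a known number of rows passing the
  strict thresholds, plus boundary and missing-padj rows.

Each gene is an ATG start, a negative-binomial number of body codons
(floored so per-gene selection rates are estimable), amino acids drawn
i.i.d. from a frequency vector, synonymous codons drawn from the weight
model, and a uniformly chosen stop codon; internal stops never occur.
Everything is deterministic given its seed, and every generator returns a
truth object sufficient to predict downstream results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import selection_matrix
from .errors import DataError
from .genetic_code import ALL_CODONS, CODON_TO_INDEX, STANDARD_CODE, GeneticCode
from .sequence_io import CodingSequence, write_cds_fasta

__all__ = [
    "CodonWeightModel",
    "BiasSpec",
    "LengthModel",
    "SimulationTruth",
    "simulate_weight_model",
    "apply_bias",
    "simulate_cds_set",
    "simulate_codon_counts",
    "simulate_de_table",
    "simulate_membership_file",
    "MOUSE_LIKE_AA_FREQS",
]


@dataclass(frozen=True)
class CodonWeightModel:
    """Per-family synonymous-codon weights (each family sums to 1)."""

    weights: pd.Series  # index: sense codons in the code's canonical order
    concentration: float | None = None  # Dirichlet concentration used to draw it
    seed: int | None = None
    code: GeneticCode = field(repr=False, default=STANDARD_CODE)

    def __post_init__(self) -> None:
        for aa in self.code.amino_acids:
            fam = list(self.code.families[aa])
            total = float(self.weights[fam].sum())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"family {aa} weights sum to {total}, not 1")

    def family_weights(self, aa: str) -> pd.Series:
        return self.weights[list(self.code.families[aa])]


@dataclass(frozen=True)
class BiasSpec:
    """Codons to favour and the multiplicative shift applied to their weights."""

    target_codons: frozenset[str]
    shift: float

    def __post_init__(self) -> None:
        if self.shift <= 0:
            raise DataError("bias shift must be > 0")

    def affected_families(self, code: GeneticCode = STANDARD_CODE) -> frozenset[str]:
        return frozenset(code.amino_acid(c) for c in self.target_codons)

    def changed_codons(self, code: GeneticCode = STANDARD_CODE) -> frozenset[str]:
        """All codons whose expected selection rate the bias moves — the
        targets and, through renormalization, their family siblings."""
        out: set[str] = set()
        for aa in self.affected_families(code):
            out.update(code.families[aa])
        return frozenset(out)


@dataclass(frozen=True)
class LengthModel:
    """Negative-binomial body length in codons (mean/dispersion), floored."""

    mean_codons: float = 400.0
    dispersion: float = 5.0
    min_codons: int = 30

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r, mu = self.dispersion, self.mean_codons
        lengths = rng.negative_binomial(r, r / (r + mu), size=n)
        return np.maximum(lengths, self.min_codons)


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to predict what the pipeline should recover."""

    base_model: CodonWeightModel
    biased_model: CodonWeightModel | None
    bias: BiasSpec | None
    biased_gene_ids: frozenset[str]
    seed: int
    de_truth: pd.DataFrame | None = None  # per-gene intended pass/fail


#: Approximate average mammalian protein amino-acid composition (fractions,
#: normalized); a realism preset — tests default to uniform frequencies.
MOUSE_LIKE_AA_FREQS: Mapping[str, float] = {
    "A": 0.070, "C": 0.022, "D": 0.048, "E": 0.070, "F": 0.036,
    "G": 0.065, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.022, "N": 0.036, "P": 0.063, "Q": 0.044, "R": 0.056,
    "S": 0.081, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def _aa_freq_vector(
    amino_acid_freqs: Mapping[str, float] | Sequence[float] | None,
    code: GeneticCode,
) -> np.ndarray:
    aas = code.amino_acids
    if amino_acid_freqs is None:
        f = np.full(len(aas), 1.0 / len(aas))
    elif isinstance(amino_acid_freqs, Mapping):
        f = np.array([amino_acid_freqs[a] for a in aas], dtype=float)
    else:
        f = np.asarray(amino_acid_freqs, dtype=float)
        if f.shape != (len(aas),):
            raise DataError(f"amino-acid frequency vector must have {len(aas)} entries")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        f = f / f.sum()
    return f


def simulate_weight_model(
    concentration: float,
    seed: int,
    code: GeneticCode = STANDARD_CODE,
    uniform: bool = False,
) -> CodonWeightModel:
    """Draw each family's weights from a symmetric Dirichlet.

    ``uniform=True`` is the concentration -> infinity limit: every family
    gets equal weights (1/family size).
    """
    if concentration <= 0:
        raise DataError("Dirichlet concentration must be > 0")
    rng = np.random.default_rng(seed)
    w = np.empty(len(code.sense_codons))
    pos = 0
    for aa in code.amino_acids:  # family blocks are contiguous in sense order
        k = len(code.families[aa])
        if uniform or k == 1:
            w[pos : pos + k] = 1.0 / k
        else:
            w[pos : pos + k] = rng.dirichlet(np.full(k, concentration))
        pos += k
    weights = pd.Series(w, index=list(code.sense_codons))
    return CodonWeightModel(weights, concentration=concentration, seed=seed, code=code)


def apply_bias(model: CodonWeightModel, spec: BiasSpec) -> CodonWeightModel:
    """Multiply targeted codon weights by the shift; renormalize each
    affected family so weights sum to 1 again. Untouched families are
    returned unchanged."""
    code = model.code
    for codon in spec.target_codons:
        if code.table[codon] == "*" or codon not in model.weights.index:
            raise DataError(f"bias target {codon} is not a sense codon of the model")
    weights = model.weights.copy()
    for aa in spec.affected_families(code):
        fam = list(code.families[aa])
        w = weights[fam].to_numpy(dtype=float)
        targets = np.array([c in spec.target_codons for c in fam])
        w = np.where(targets, w * spec.shift, w)
        weights[fam] = w / w.sum()
    return CodonWeightModel(
        weights, concentration=model.concentration, seed=model.seed, code=code
    )


def _codon_probabilities(
    model: CodonWeightModel, aa_freqs: np.ndarray
) -> np.ndarray:
    """Unconditional sense-codon probabilities p(c) = f(aa) * w(c|aa),
    in the code's canonical sense order."""
    code = model.code
    p = np.empty(len(code.sense_codons))
    pos = 0
    for f_aa, aa in zip(aa_freqs, code.amino_acids):
        fam = list(code.families[aa])
        p[pos : pos + len(fam)] = f_aa * model.weights[fam].to_numpy()
        pos += len(fam)
    return p


# (64, 3) uint8 lookup: codon index -> its three ASCII bytes.
_CODON_BYTES = np.frombuffer("".join(ALL_CODONS).encode("ascii"), dtype=np.uint8).reshape(64, 3)


def simulate_cds_set(
    n_genes: int,
    length_model: LengthModel = LengthModel(),
    model: CodonWeightModel | None = None,
    amino_acid_freqs: Mapping[str, float] | Sequence[float] | None = None,
    seed: int = 0,
    gene_prefix: str = "GSYN",
    transcripts_per_gene: int = 1,
) -> tuple[list[CodingSequence], SimulationTruth]:
    """Simulate a set of coding sequences from a codon weight model.

    Each gene is ``ATG`` + body codons + one uniformly chosen stop; every
    body position draws an amino acid from ``amino_acid_freqs`` (uniform
    by default) and then a synonymous codon from the model weights.
    ``transcripts_per_gene > 1`` duplicates each gene with progressively
    truncated CDS (distinct transcript ids) to exercise representative
    selection. Deterministic given the seed.
    """
    if n_genes < 1:
        raise DataError("n_genes must be >= 1")
    code = model.code if model is not None else STANDARD_CODE
    if model is None:
        model = simulate_weight_model(1.0, seed=seed, code=code, uniform=True)
    rng = np.random.default_rng(seed)
    aa_freqs = _aa_freq_vector(amino_acid_freqs, code)
    p = _codon_probabilities(model, aa_freqs)
    sense_global = model.code.sense_index  # sense order -> 0..63 index
    stops = np.array([CODON_TO_INDEX[s] for s in code.stop_codons])

    lengths = length_model.draw(n_genes, rng)
    total = int(lengths.sum())
    body = sense_global[rng.choice(len(p), size=total, p=p)]
    stop_choice = stops[rng.integers(0, len(stops), size=n_genes)]
    atg = CODON_TO_INDEX["ATG"]

    seqs: list[CodingSequence] = []
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    width = len(str(n_genes))
    for i in range(n_genes):
        idx = np.concatenate(
            [[atg], body[offsets[i] : offsets[i + 1]], [stop_choice[i]]]
        )
        nt = _CODON_BYTES[idx].tobytes().decode("ascii")
        gid = f"{gene_prefix}{i + 1:0{width}d}"
        seqs.append(CodingSequence(gid, f"{gid}.T1", nt))
        for t in range(2, transcripts_per_gene + 1):
            # truncated isoform: drop codons from the tail, keep the frame
            cut = max(2, len(idx) - 5 * (t - 1))
            nt_t = _CODON_BYTES[idx[:cut]].tobytes().decode("ascii")
            seqs.append(CodingSequence(gid, f"{gid}.T{t}", nt_t))
    truth = SimulationTruth(
        base_model=model,
        biased_model=None,
        bias=None,
        biased_gene_ids=frozenset(),
        seed=seed,
    )
    return seqs, truth


def simulate_codon_counts(
    n_genes: int,
    length_model: LengthModel = LengthModel(),
    model: CodonWeightModel | None = None,
    amino_acid_freqs: Mapping[str, float] | Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    gene_prefix: str = "GSYN",
) -> pd.DataFrame:
    """Draw per-gene codon count tables directly (genes x 64).

    Position-wise categorical draws aggregate to a multinomial, so this
    is distribution-identical to counting the codons of
    :func:`simulate_cds_set` output (including the fixed ATG start and
    one uniform stop), but orders of magnitude faster for the replicated
    calibration and power studies.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    code = model.code if model is not None else STANDARD_CODE
    if model is None:
        model = simulate_weight_model(1.0, seed=0, code=code, uniform=True)
    aa_freqs = _aa_freq_vector(amino_acid_freqs, code)
    p = _codon_probabilities(model, aa_freqs)
    lengths = length_model.draw(n_genes, rng)
    body = rng.multinomial(lengths, p)  # (n_genes, 61) in sense order
    counts = np.zeros((n_genes, 64), dtype=np.int64)
    counts[:, code.sense_index] = body
    counts[:, CODON_TO_INDEX["ATG"]] += 1
    stops = np.array([CODON_TO_INDEX[s] for s in code.stop_codons])
    counts[np.arange(n_genes), stops[rng.integers(0, len(stops), size=n_genes)]] += 1
    width = len(str(n_genes))
    ids = [f"{gene_prefix}{i + 1:0{width}d}" for i in range(n_genes)]
    return pd.DataFrame(counts, index=ids, columns=list(ALL_CODONS))


def simulate_two_group_selection(
    n_subset: int,
    n_background: int,
    base_model: CodonWeightModel,
    bias: BiasSpec | None = None,
    length_model: LengthModel = LengthModel(),
    amino_acid_freqs: Mapping[str, float] | Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, frozenset[str], frozenset[str], SimulationTruth]:
    """Fast two-group study: subset genes drawn from the (optionally
    biased) model, background genes from the base model; returns the
    combined selection-rate matrix, both id sets, and the truth."""
    rng = np.random.default_rng(seed)
    subset_model = apply_bias(base_model, bias) if bias is not None else base_model
    sub = simulate_codon_counts(
        n_subset, length_model, subset_model, amino_acid_freqs, rng, gene_prefix="SUB"
    )
    bg = simulate_codon_counts(
        n_background, length_model, base_model, amino_acid_freqs, rng, gene_prefix="BG"
    )
    counts = pd.concat([sub, bg])
    truth = SimulationTruth(
        base_model=base_model,
        biased_model=subset_model if bias is not None else None,
        bias=bias,
        biased_gene_ids=frozenset(sub.index),
        seed=seed,
    )
    return (
        selection_matrix(counts, base_model.code),
        frozenset(sub.index),
        frozenset(bg.index),
        truth,
    )


def simulate_de_table(
    n_genes: int,
    n_pass: int,
    padj_max: float = 0.05,
    lfc_min: float = 0.7,
    missing_frac: float = 0.05,
    seed: int = 0,
    gene_prefix: str = "GDE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A DE results table with exactly ``n_pass`` rows strictly passing
    padj < padj_max AND log2fc > lfc_min.

    Failing rows cycle through the ways to fail: padj at or above the
    threshold, |log2fc| at or below the threshold, both, exact boundary
    rows (padj == padj_max with a large fold change; log2fc == lfc_min
    with a small padj), and a ``missing_frac`` fraction with missing padj.
    Passing rows have positive log2fc, so the planted count holds for
    direction "up" and "both" alike. Returns (table, truth) where truth
    has columns gene_id and passes.
    """
    if not 0 <= n_pass <= n_genes:
        raise DataError("need 0 <= n_pass <= n_genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    ids = [f"{gene_prefix}{i + 1:0{width}d}" for i in range(n_genes)]
    lfc = np.empty(n_genes)
    padj = np.empty(n_genes)
    passes = np.zeros(n_genes, dtype=bool)

    lfc[:n_pass] = lfc_min + 0.05 + rng.exponential(1.0, size=n_pass)
    padj[:n_pass] = rng.uniform(0.0, padj_max * 0.98, size=n_pass)
    passes[:n_pass] = True

    n_fail = n_genes - n_pass
    n_missing = int(round(missing_frac * n_fail))
    for j in range(n_fail):
        i = n_pass + j
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if j < n_missing:  # significant-looking fold change, padj missing
            lfc[i] = sign * (lfc_min + rng.exponential(1.0))
            padj[i] = np.nan
        elif j == n_missing and n_fail > n_missing:  # padj exactly at threshold
            lfc[i] = sign * (lfc_min + rng.exponential(1.0))
            padj[i] = padj_max
        elif j == n_missing + 1 and n_fail > n_missing + 1:  # lfc exactly at threshold
            lfc[i] = sign * lfc_min
            padj[i] = rng.uniform(0.0, padj_max * 0.98)
        elif j % 3 == 0:  # padj fails
            lfc[i] = sign * (lfc_min + rng.exponential(1.0))
            padj[i] = rng.uniform(padj_max, 1.0)
        elif j % 3 == 1:  # fold change fails
            lfc[i] = sign * rng.uniform(0.0, lfc_min)
            padj[i] = rng.uniform(0.0, padj_max * 0.98)
        else:  # both fail
            lfc[i] = sign * rng.uniform(0.0, lfc_min)
            padj[i] = rng.uniform(padj_max, 1.0)

    order = rng.permutation(n_genes)
    table = pd.DataFrame(
        {"gene_id": np.array(ids), "log2fc": lfc, "padj": padj}
    ).iloc[order].reset_index(drop=True)
    truth = pd.DataFrame({"gene_id": ids, "passes": passes})
    return table, truth


def simulate_membership_file(
    path: str | Path,
    n_terms: int = 10,
    genes_per_term: tuple[int, int] = (5, 40),
    gene_pool: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Write a synthetic GMT membership file; returns term -> gene truth."""
    rng = np.random.default_rng(seed)
    pool = list(gene_pool) if gene_pool is not None else [f"G{i:05d}" for i in range(2000)]
    truth: dict[str, set[str]] = {}
    with Path(path).open("w") as out:
        for t in range(1, n_terms + 1):
            k = int(rng.integers(genes_per_term[0], genes_per_term[1] + 1))
            genes = sorted(rng.choice(pool, size=min(k, len(pool)), replace=False))
            term = f"TERM:{t:07d}"
            truth[term] = set(genes)
            out.write("\t".join([term, f"synthetic term {t}"] + genes) + "\n")
    return truth


def write_simulation_fasta(
    seqs: Sequence[CodingSequence], path: str | Path
) -> None:
    """Convenience wrapper writing generator output as gene|transcript FASTA."""
    write_cds_fasta(seqs, path)
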