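"""Gene subsets and per-codon subset-vs-background comparisons.

Subsets come from a differential-expression results table (strict
thresholds: padj < 0.05 AND |log2 fold change| > 0.7 by default, in a
chosen direction) or from a membership file (GMT or two-column TSV, e.g.
standing in for the "osteoblast differentiation" GO term). A subset is
compared against the exhaustive background — all profiled genes minus the
subset, so the groups are disjoint — one sense codon at a time: group
means of the per-gene selection rates, a two-tailed Student's t-test
(Welch optional), and Benjamini-Hochberg correction over the full set of
codons tested in the invocation. Multi-set Venn region counts round out
the comparison toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .genetic_code import STANDARD_CODE, GeneticCode

__all__ = [
    "DERecord",
    "GeneSubset",
    "read_de_table",
    "filter_de",
    "membership_subset",
    "bh_adjust",
    "compare_codon_usage",
    "write_comparison",
    "OverlapResult",
    "overlap_counts",
    "write_overlap",
]

RESULT_COLUMNS = [
    "codon",
    "amino_acid",
    "mean_subset",
    "mean_background",
    "relative_change",
    "log2_ratio",
    "t_stat",
    "p_value",
    "q_value",
    "n_subset",
    "n_background",
    "note",
]


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression results table."""

    gene_id: str
    log2fc: float
    padj: float  # NaN when the DE tool reported no adjusted p-value


@dataclass(frozen=True)
class GeneSubset:
    """A named gene set with a provenance tag."""

    name: str
    members: frozenset[str]
    provenance: Literal["de_up", "de_down", "de_both", "membership_list", "explicit"]

    def __len__(self) -> int:
        return len(self.members)


def read_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a DE results TSV into the canonical gene_id/log2fc/padj frame."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (gene_col, lfc_col, padj_col) if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    out = df[[gene_col, lfc_col, padj_col]].copy()
    out.columns = ["gene_id", "log2fc", "padj"]
    out["gene_id"] = out["gene_id"].astype(str)
    return out


def _as_frame(records: pd.DataFrame | Iterable[DERecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
        required = {"gene_id", "log2fc", "padj"}
        if not required <= set(df.columns):
            raise DataError(
                f"DE frame needs columns {sorted(required)}; found {list(df.columns)}"
            )
        return df
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.padj) for r in records],
        columns=["gene_id", "log2fc", "padj"],
    )


def filter_de(
    records: pd.DataFrame | Iterable[DERecord],
    padj_max: float = 0.05,
    lfc_min: float = 0.7,
    direction: Literal["up", "down", "both"] = "both",
    name: str | None = None,
) -> GeneSubset:
    """Apply strict DE thresholds: padj < padj_max AND |log2fc| > lfc_min.

    Both inequalities are strict, so boundary rows (padj exactly at the
    threshold, |log2fc| exactly at the threshold) are excluded, as is any
    row with a missing padj. ``direction`` restricts the fold-change sign.

    Raises
    ------
    DataError
        If thresholds are non-positive, the direction is unknown, or a
        gene id appears in more than one row with conflicting values.
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise DataError("padj_max and lfc_min must be positive")
    if direction not in ("up", "down", "both"):
        raise DataError(f"unknown direction {direction!r}")
    df = _as_frame(records)
    dup = df[df.duplicated("gene_id", keep=False)]
    if not dup.empty:
        conflicting = [
            gid
            for gid, grp in dup.groupby("gene_id")
            if len(grp[["log2fc", "padj"]].drop_duplicates()) > 1
        ]
        if conflicting:
            raise DataError(
                f"conflicting duplicate DE records for gene(s): {conflicting[:5]}"
            )
        df = df.drop_duplicates("gene_id")
    lfc = df["log2fc"].to_numpy(dtype=float)
    padj = df["padj"].to_numpy(dtype=float)
    if direction == "up":
        fc_ok = lfc > lfc_min
    elif direction == "down":
        fc_ok = lfc < -lfc_min
    else:
        fc_ok = np.abs(lfc) > lfc_min
    keep = (padj < padj_max) & fc_ok & ~np.isnan(padj)
    return GeneSubset(
        name=name or f"de_{direction}",
        members=frozenset(df.loc[keep, "gene_id"]),
        provenance=f"de_{direction}",  # type: ignore[arg-type]
    )


def _parse_membership(path: str | Path) -> dict[str, set[str]]:
    """Parse GMT (term<TAB>description<TAB>gene...) or two-column
    (term<TAB>gene) membership files; repeated terms union their genes."""
    terms: dict[str, set[str]] = {}
    is_gmt = str(path).endswith(".gmt")
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if is_gmt or len(parts) > 2:
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, genes = parts[0], parts[2:]
        else:
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 'term<TAB>gene'")
            term, genes = parts[0], [parts[1]]
        terms.setdefault(term, set()).update(g for g in genes if g)
    return terms


def membership_subset(path: str | Path, term_name: str) -> GeneSubset:
    """The gene set annotated to ``term_name`` in a GMT/TSV membership file."""
    terms = _parse_membership(path)
    if term_name not in terms:
        raise DataError(
            f"term {term_name!r} not found in {path}; available: {sorted(terms)}"
        )
    return GeneSubset(term_name, frozenset(terms[term_name]), "membership_list")


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    NaN entries are excluded from the hypothesis count m and returned as
    NaN; any finite value outside [0, 1] is an error.
    """
    p = np.asarray(p_values, dtype=float)
    present = ~np.isnan(p)
    if ((p[present] < 0) | (p[present] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if present.any():
        q[present] = multipletests(p[present], method="fdr_bh")[1]
    return q


def compare_codon_usage(
    selection: pd.DataFrame,
    subset: GeneSubset,
    background: GeneSubset | None = None,
    min_n: int = 10,
    equal_var: bool = True,
    code: GeneticCode = STANDARD_CODE,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-codon comparison of subset vs background selection rates.

    Parameters
    ----------
    selection:
        Genes x sense-codons selection-rate matrix (NaN = family unseen).
    subset, background:
        Background defaults to every profiled gene; subset genes are
        removed from the background so the groups are disjoint.
    min_n:
        Codons with fewer non-missing values in either group are reported
        untested (MISSING statistics, note ``min_n_not_met``), never
        silently dropped.
    equal_var:
        True for Student's equal-variance t-test (the default), False
        for Welch.
    adjust:
        Apply BH over the codons tested in this invocation. Disable when
        pooling several comparisons into one correction family.

    Returns one row per sense codon, in the code's canonical order.
    """
    subset_ids = [g for g in selection.index if g in subset.members]
    if not subset_ids:
        raise DataError(
            f"subset {subset.name!r} shares no genes with the profile matrix"
        )
    if background is None:
        bg_members = set(selection.index) - subset.members
    else:
        bg_members = set(background.members) - subset.members
    bg_ids = [g for g in selection.index if g in bg_members]
    if not bg_ids:
        raise DataError(
            f"background for subset {subset.name!r} is empty after removing "
            "subset genes (disjoint-groups rule)"
        )

    cols = list(code.sense_codons)
    a = selection.loc[subset_ids, cols].to_numpy(dtype=float)
    b = selection.loc[bg_ids, cols].to_numpy(dtype=float)
    n_a = (~np.isnan(a)).sum(axis=0)
    n_b = (~np.isnan(b)).sum(axis=0)
    tested = (n_a >= min_n) & (n_b >= min_n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=0)
        mean_b = np.nanmean(b, axis=0)
        var_a = _nanvar_safe(a, n_a)
        var_b = _nanvar_safe(b, n_b)
        t_stat, p_value = stats.ttest_ind(
            a, b, axis=0, equal_var=equal_var, nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)

    # Degenerate codons: zero variance in both groups. Equal means (e.g.
    # single-codon families, constantly 1) -> t=0, p=1; unequal -> p=0.
    note = np.array([""] * len(cols), dtype=object)
    degenerate = tested & (var_a == 0) & (var_b == 0)
    same = degenerate & np.isclose(mean_a, mean_b, rtol=0, atol=1e-15)
    t_stat[same], p_value[same] = 0.0, 1.0
    diff = degenerate & ~same
    t_stat[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
    p_value[diff] = 0.0
    note[degenerate] = "degenerate_constant"

    t_stat[~tested] = np.nan
    p_value[~tested] = np.nan
    note[~tested] = "min_n_not_met"

    with np.errstate(invalid="ignore", divide="ignore"):
        relative_change = (mean_a - mean_b) / mean_b
        log2_ratio = np.log2(mean_a / mean_b)
    bg_zero = tested & (mean_b == 0)
    relative_change[bg_zero] = np.nan
    log2_ratio[bg_zero] = np.nan
    note[bg_zero] = np.where(
        note[bg_zero] == "", "background_mean_zero", note[bg_zero] + ";background_mean_zero"
    )
    mean_a[~tested] = np.nan
    mean_b[~tested] = np.nan
    relative_change[~tested] = np.nan
    log2_ratio[~tested] = np.nan

    q_value = bh_adjust(p_value) if adjust else np.full(len(cols), np.nan)

    return pd.DataFrame(
        {
            "codon": cols,
            "amino_acid": [code.amino_acid(c) for c in cols],
            "mean_subset": mean_a,
            "mean_background": mean_b,
            "relative_change": relative_change,
            "log2_ratio": log2_ratio,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "n_subset": n_a,
            "n_background": n_b,
            "note": note,
        },
        columns=RESULT_COLUMNS,
    )


def _nanvar_safe(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Column-wise sample variance ignoring NaN; 0 where n < 2."""
    out = np.zeros(x.shape[1])
    ok = n >= 2
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanvar(x[:, ok], axis=0, ddof=1)
        out[ok] = v
    return out


def write_comparison(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


@dataclass(frozen=True)
class OverlapResult:
    """Venn region counts for 2-4 named gene sets.

    Region keys are +/- patterns over the set names in order, e.g. for
    sets (A, B, C) the key "++-" is genes in A and B but not C. The
    2^k - 1 non-empty-pattern regions partition the union of the sets.
    """

    names: tuple[str, ...]
    regions: Mapping[str, int]
    core_genes: tuple[str, ...]  # genes present in every set, sorted

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def overlap_counts(subsets: Sequence[GeneSubset]) -> OverlapResult:
    """Exact set-algebra Venn region counts for 2-4 subsets."""
    if not 2 <= len(subsets) <= 4:
        raise DataError("overlap_counts takes between 2 and 4 subsets")
    names = tuple(s.name for s in subsets)
    if len(set(names)) != len(names):
        raise DataError(f"duplicate subset names: {names}")
    k = len(subsets)
    patterns = [
        "".join("+" if (mask >> i) & 1 else "-" for i in range(k))
        for mask in range(1, 2**k)
    ]
    regions = {pat: 0 for pat in patterns}
    union: set[str] = set()
    for s in subsets:
        union |= s.members
    core = []
    for gene in union:
        mask = sum(1 << i for i, s in enumerate(subsets) if gene in s.members)
        pat = "".join("+" if (mask >> i) & 1 else "-" for i in range(k))
        regions[pat] += 1
        if mask == 2**k - 1:
            core.append(gene)
    return OverlapResult(names, regions, tuple(sorted(core)))


def write_overlap(result: OverlapResult, path: str | Path) -> None:
    with Path(path).open("w") as out:
        out.write("region\t" + "\t".join(result.names) + "\tcount\n")
        for pat, count in result.regions.items():
            flags = "\t".join(pat)
            out.write(f"{pat}\t{flags}\t{count}\n")
        out.write(f"# core_genes\t{','.join(result.core_genes)}\n")
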