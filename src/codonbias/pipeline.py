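"""End-to-end orchestration: FASTA -> profiles -> subsets -> comparisons.

``run_codon_bias`` executes the stages read -> validate -> representative
-> profiles -> subsets -> compare -> write, producing per-subset codon
comparison TSVs, a pooled selection-rate / relative-change matrix (the
heatmap-style output), Venn overlap counts when at least two DE tables
are given, a rejection report, and a JSON run manifest.

Determinism: for a fixed config and seed the data outputs are
byte-identical across runs; the manifest records wall-clock timestamps
and is the one file excluded from that guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_core import pooled_selection_rates, profile_matrix
from .errors import DataError
from .genetic_code import STANDARD_CODE, GeneticCode
from .sequence_io import (
    dialect_by_name,
    read_cds_fasta,
    select_representative,
    validate_many,
    write_rejection_report,
)
from .subset_compare import (
    GeneSubset,
    bh_adjust,
    compare_codon_usage,
    filter_de,
    membership_subset,
    overlap_counts,
    read_de_table,
    write_comparison,
    write_overlap,
)

log = logging.getLogger("codonbias")

__all__ = ["PipelineConfig", "RunResult", "run_codon_bias"]


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    fasta: str
    out_dir: str
    de_tables: dict[str, str] = field(default_factory=dict)  # subset name -> TSV path
    membership_file: str | None = None
    membership_terms: list[str] = field(default_factory=list)
    genetic_code_tsv: str | None = None

    dialect: str = "gencode"
    validation: str = "lenient"
    representative: str = "longest"

    padj_max: float = 0.05
    lfc_min: float = 0.7
    direction: str = "both"
    min_n: int = 10

    t_test: str = "student"  # or "welch"
    bh_scope: str = "per_comparison"  # or "pooled"
    background: str = "exhaustive"  # or "de_genes"

    de_gene_col: str = "gene_id"
    de_lfc_col: str = "log2FoldChange"
    de_padj_col: str = "padj"

    seed: int = 0
    heatmap: bool = False

    def validate(self) -> None:
        if self.padj_max <= 0 or self.lfc_min <= 0:
            raise DataError("padj_max and lfc_min must be positive")
        if self.min_n < 1:
            raise DataError("min_n must be >= 1")
        for name, allowed in [
            ("validation", {"strict", "lenient"}),
            ("representative", {"longest", "first"}),
            ("direction", {"up", "down", "both"}),
            ("t_test", {"student", "welch"}),
            ("bh_scope", {"per_comparison", "pooled"}),
            ("background", {"exhaustive", "de_genes"}),
        ]:
            value = getattr(self, name)
            if value not in allowed:
                raise DataError(f"{name} must be one of {sorted(allowed)}, got {value!r}")
        paths = [self.fasta, *self.de_tables.values()]
        if self.membership_file:
            paths.append(self.membership_file)
        if self.genetic_code_tsv:
            paths.append(self.genetic_code_tsv)
        for p in paths:
            if not Path(p).exists():
                raise DataError(f"input path does not exist: {p}")
        if not self.de_tables and not (self.membership_file and self.membership_terms):
            raise DataError("config defines no gene subset (DE table or membership term)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunResult:
    """Paths of the emitted output bundle plus the in-memory tables."""

    out_dir: Path
    comparisons: dict[str, pd.DataFrame]
    pooled: pd.DataFrame
    overlap_path: Path | None
    manifest_path: Path

    def comparison_path(self, subset: str) -> Path:
        return self.out_dir / f"comparison_{subset}.tsv"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_code(config: PipelineConfig) -> GeneticCode:
    if config.genetic_code_tsv:
        return GeneticCode.from_tsv(config.genetic_code_tsv)
    return STANDARD_CODE


def run_codon_bias(config: PipelineConfig) -> RunResult:
    """Run the whole analysis described by ``config``; see module docs."""
    t0 = time.time()
    started = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code = _load_code(config)
    counts: dict[str, object] = {}

    def stage(name: str, value: int) -> None:
        counts[name] = value
        log.info("%s: %d (%.2fs elapsed)", name, value, time.time() - t0)

    seqs = read_cds_fasta(config.fasta, dialect_by_name(config.dialect))
    stage("parsed_records", len(seqs))
    accepted, rejected = validate_many(seqs, config.validation)  # type: ignore[arg-type]
    stage("validated_records", len(accepted))
    stage("rejected_records", len(rejected))
    write_rejection_report(rejected, out_dir / "rejections.tsv")
    genes = select_representative(accepted, config.representative)  # type: ignore[arg-type]
    stage("representative_genes", len(genes))

    profiles = profile_matrix(genes, code)

    subsets: list[GeneSubset] = []
    de_subsets: list[GeneSubset] = []
    de_gene_universe: dict[str, set[str]] = {}
    for name, path in config.de_tables.items():
        table = read_de_table(
            path, config.de_gene_col, config.de_lfc_col, config.de_padj_col
        )
        sub = filter_de(
            table, config.padj_max, config.lfc_min, config.direction, name=name  # type: ignore[arg-type]
        )
        if not sub.members:
            raise DataError(
                f"DE subset {name!r} is empty under padj<{config.padj_max}, "
                f"|log2fc|>{config.lfc_min}, direction={config.direction}"
            )
        de_gene_universe[name] = set(table["gene_id"])
        subsets.append(sub)
        de_subsets.append(sub)
        stage(f"subset_{name}_size", len(sub))
    for term in config.membership_terms:
        sub = membership_subset(config.membership_file, term)
        subsets.append(sub)
        stage(f"subset_{term}_size", len(sub))

    matrix_genes = set(profiles.selection.index)
    for sub in subsets:
        overlap = len(sub.members & matrix_genes)
        if overlap < len(sub.members):
            log.warning(
                "subset %s: %d of %d genes absent from the profile matrix",
                sub.name, len(sub.members) - overlap, len(sub.members),
            )

    comparisons: dict[str, pd.DataFrame] = {}
    for sub in subsets:
        background = None
        if config.background == "de_genes" and sub.name in de_gene_universe:
            background = GeneSubset(
                f"{sub.name}_universe",
                frozenset(de_gene_universe[sub.name]),
                "explicit",
            )
        comparisons[sub.name] = compare_codon_usage(
            profiles.selection,
            sub,
            background=background,
            min_n=config.min_n,
            equal_var=config.t_test == "student",
            code=code,
            adjust=config.bh_scope == "per_comparison",
        )
    if config.bh_scope == "pooled" and comparisons:
        pooled_p = pd.concat([c["p_value"] for c in comparisons.values()])
        pooled_q = bh_adjust(pooled_p.to_numpy())
        offset = 0
        for c in comparisons.values():
            c["q_value"] = pooled_q[offset : offset + len(c)]
            offset += len(c)

    for name, result in comparisons.items():
        write_comparison(result, out_dir / f"comparison_{name}.tsv")
        stage(f"tested_codons_{name}", int(result["p_value"].notna().sum()))

    pooled = _pooled_matrix(profiles, subsets, code)
    pooled.to_csv(
        out_dir / "pooled_selection.tsv", sep="\t", na_rep="NA", float_format="%.10g"
    )

    overlap_path = None
    if len(de_subsets) >= 2:
        overlap_path = out_dir / "overlap.tsv"
        write_overlap(overlap_counts(de_subsets[:4]), overlap_path)

    if config.heatmap:
        _render_heatmap(comparisons, out_dir / "relative_change_heatmap.png")

    manifest_path = out_dir / "manifest.json"
    manifest = {
        "software": {"name": "codonbias", "version": __version__},
        "config": dataclasses.asdict(config),
        "inputs": {
            str(p): _sha256(p)
            for p in [config.fasta, *config.de_tables.values()]
            + ([config.membership_file] if config.membership_file else [])
        },
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "elapsed_seconds": round(time.time() - t0, 3),
        "stage_counts": counts,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete in %.2fs; outputs in %s", time.time() - t0, out_dir)
    return RunResult(out_dir, comparisons, pooled, overlap_path, manifest_path)


def _pooled_matrix(profiles, subsets, code: GeneticCode) -> pd.DataFrame:
    """Codon x group pooled selection rates and relative changes — the
    subset-level matrix behind the heatmap-style figure."""
    all_genes = list(profiles.counts.index)
    bg = pooled_selection_rates(profiles.counts, all_genes, code)
    out = pd.DataFrame(
        {
            "amino_acid": [code.amino_acid(c) for c in code.sense_codons],
            "background_pooled": bg,
        },
        index=list(code.sense_codons),
    )
    out.index.name = "codon"
    for sub in subsets:
        pooled = pooled_selection_rates(profiles.counts, sub.members, code)
        out[f"{sub.name}_pooled"] = pooled
        out[f"{sub.name}_relative_change"] = (pooled - bg) / bg
    return out


def _render_heatmap(comparisons: dict[str, pd.DataFrame], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = pd.DataFrame(
        {name: c.set_index("codon")["relative_change"] for name, c in comparisons.items()}
    )
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(mat.columns) + 2), 12))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-0.5, vmax=0.5)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=5)
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
    fig.colorbar(im, ax=ax, label="relative change in selection rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
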