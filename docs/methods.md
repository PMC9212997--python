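# Methods

## Scope and model

`codonbias` asks whether a set of genes — defined by differential
expression or by pathway/GO membership — uses synonymous codons
differently from a genome-wide background of coding sequences. The unit
of observation is the gene; the per-gene statistic for sense codon `c`
with amino acid `a` is the **selection rate**, the codon's count divided
by the summed counts of its synonymous family in that gene. "Isodecoder"
competition is interpreted on the codon side: the alternatives a codon
is selected against are the other synonymous codons for the same amino
acid, so the statistic normalizes within codon families. (In the tRNA
literature *isodecoder* strictly means tRNA genes sharing an anticodon;
that quantity is not computable from CDS alone, which is why the
codon-family reading is used and documented here.)

Selection rates rather than raw usage rates make genes with different
amino-acid compositions comparable: a gene rich in leucine does not
automatically appear biased toward leucine codons. Within every observed
family the rates sum to 1 by construction; a family the gene never uses
is reported as missing (NA), never as 0, so short genes cannot drag
group means toward zero. Per-gene statistics (not pooled counts) are
primary because the group comparison is a t-test, which needs one
observation per gene; pooled subset-level rates are additionally emitted
for the heatmap-style relative-change matrix, where long genes
legitimately weigh more.

Counting reads non-overlapping triplets from position 0 of the provided
CDS — the inputs are assumed to be annotated coding sequences already in
frame; there is no ORF search. Stop codons are retained in raw counts
(I/O is lossless) and excluded from usage and selection statistics.

## Input handling

- **FASTA dialects.** `plain` (whole first header token = gene id =
  transcript id) and `gencode` (pipe-delimited token, configurable field
  positions). The default `gencode` dialect reads gene id from field 0
  and transcript id from field 1; the `gencode-pc-transcripts` preset
  swaps them to match GENCODE's own pc_transcripts releases
  (transcript|gene|...). Anything else must be pre-converted.
- **Normalization.** Uppercasing and U→T happen silently at parse time;
  any other character becomes N. Strict validation then rejects
  sequences containing N or whose length is not a multiple of 3; lenient
  validation truncates a trailing partial codon and drops N-containing
  codons, rejecting only when no informative codon remains. Rejections
  are data (TSV report with reason codes), not exceptions.
- **One CDS per gene.** The default policy keeps the longest CDS per
  gene (ties broken by lexicographically smallest transcript id), the
  common convention for gene-level codon statistics; `first` keeps input
  order. Whether a published "exhaustive list" used one or all
  transcripts per gene is generally unstated, so both are supported and
  the default is documented.

## The comparison

- **Thresholds.** DE subset membership requires `padj < 0.05` AND
  `|log2FC| > 0.7` (defaults), both inequalities strict, so boundary
  rows are excluded; missing `padj` excludes the gene. Direction `up`,
  `down`, or `both`.
- **Groups.** Background defaults to all profiled genes; subset genes
  are removed from it so the two groups are disjoint and the t-test's
  independence assumption is not violated by shared observations. A
  `de_genes` background mode restricts the background to the genes
  present in the subset's own DE table (the "expressed" universe)
  instead of the exhaustive list; both are supported because either
  choice is defensible and they answer slightly different questions.
- **Test.** Equal-variance Student's t-test by default (Welch behind a
  switch). Codons with fewer than `min_n = 10` non-missing values in
  either group are reported untested rather than dropped, keeping the
  output schema fixed at 61 rows. Single-codon families (ATG, TGG) have
  selection rate constantly 1 wherever observed; they fall under the
  zero-variance rule — both groups constant and equal means t = 0,
  p = 1 — and are flagged `degenerate_constant` rather than excluded.
  Zero variance with unequal means (possible only in pathological
  inputs) yields p = 0 with an infinite t of the appropriate sign.
- **Effect size.** `relative_change = (mean_subset − mean_background) /
  mean_background`. No standard definition exists for "relative change
  in codon usage", so this ratio-style formula is the package's own
  choice; a log2 ratio column is emitted alongside for users who prefer
  symmetric effects. When the background mean is 0 the relative change
  is missing (reason-coded) but the test is still performed.
- **Multiplicity.** Benjamini–Hochberg step-up over the full set of
  codons tested in one invocation — one family of hypotheses per
  comparison. When several comparisons run in one pipeline invocation a
  `pooled` scope concatenates their p-values into a single BH family
  instead (default `per_comparison`). The BH computation is delegated to
  statsmodels' `fdr_bh` behind the `bh_adjust` surface, which adds
  missing-value handling and range validation; tests verify it against
  an independent O(m²) step-up oracle.
- **Overlaps.** Venn region counts for 2–4 sets use exact set algebra;
  the 2^k − 1 regions partition the union by construction, and the
  all-sets intersection gene list is reported.

## Synthetic data

The generator provides truth-bearing substrates for every stage:

- **Codon weight model.** Per-family weights drawn from a symmetric
  Dirichlet. Default concentration 2.0: moderately skewed preferences —
  typical family weights spread over roughly 0.05–0.6 — resembling the
  moderate genome-wide codon bias of mammalian genomes, without the
  frequent near-zero weights of concentration ≤ 1. A `uniform` mode is
  the concentration→∞ limit.
- **Bias injection.** Target codon weights are multiplied by a shift
  (> 0) and each affected family renormalized. Note the renormalization
  necessarily *lowers* the expected selection rates of the targets'
  family siblings: those codons are genuinely changed under the
  generative model, so recovery tests score false positives only over
  codons in untouched families.
- **Sequences.** Each gene: ATG, a negative-binomial number of body
  codons (default mean 400 — the scale of a typical mammalian CDS —
  dispersion 5, floor 30 so per-gene selection rates are estimable),
  amino acids i.i.d. (uniform over 20 by default; a mammalian-like
  composition preset exists but no test depends on it), synonymous
  codons per the weight model, and a uniform stop. Internal stops never
  occur; generated sequences always pass strict validation.
- **Fast count path.** `simulate_codon_counts` draws per-gene codon
  count vectors directly from the equivalent multinomial (position-wise
  categorical draws aggregate to a multinomial, so the distribution is
  identical to counting simulated sequences, including the fixed ATG
  and one stop). The replicated calibration and power studies use it;
  sequence-level simulation is used wherever I/O or the end-to-end
  pipeline is exercised, and a test checks the two paths agree.
- **DE tables.** Exactly `n_pass` rows strictly pass the thresholds
  (positive log2FC, so the planted count holds for directions `up` and
  `both`); the failing rows cycle through every failure mode and always
  include exact boundary rows (`padj == padj_max`, `|log2fc| == lfc_min`)
  plus a configurable fraction (default 5%) with missing padj.

What the generator does *not* emulate: expression-level weighting,
GC/isochore structure, amino-acid composition differences between
subsets, phylogenetic correlation among genes, and DE effect sizes
coupled to codon content. Passing tests therefore demonstrate that the
statistics are computed correctly and calibrated under the stated
sampling model — not that any particular real dataset will show bias.

## Verification

The acceptance suite (also recomputed by `scripts/acceptance.py`) checks:
exact equality of counts/usage/selection with brute-force oracles on 100
random CDS (family sums within 1e-12); exact BH agreement on 1,000
random p-values; type-I error of the null comparison in [0.03, 0.075]
at p < 0.05 (300 genes/group, 200 replicates — the per-codon rejection
rate pooled over replicates and codons); ≥ 90% q < 0.05 detection of a
3-fold shift injected into six codons in six different families
(pooled over 20 replicates), with the injected sign for every detected
codon and ≤ 5% false positives among untouched-family codons; exact
recovery of a planted 137-gene DE subset from a 1,000-row table with
boundary rows; exact Venn partitioning of four 300-gene sets; and
byte-identical data outputs across two identical pipeline runs.

Replicate counts and gene numbers above are the package's chosen study
sizes: large enough that the binomial noise of the rejection-rate
estimate (~±0.004 at 200×59 tests) sits well inside the asserted bands.

## Numerical and reproducibility notes

- All randomness flows from integer seeds through
  `numpy.random.default_rng`; replicate seeds are spawned via
  `SeedSequence` so studies are reproducible and independent.
- Family sums and usage sums are exact up to float rounding (asserted at
  1e-12); comparisons of implementation vs oracle are exact because both
  perform the same IEEE division.
- TSV is the only tabular output dialect (header row, `NA` for missing,
  `%.10g` floats); the manifest is JSON. Outputs are byte-deterministic
  for a fixed config except the manifest, which records wall-clock
  timestamps, and the log.
- The genetic code defaults to the standard table (61 sense, 3 stops,
  built from Biopython's NCBI table 1) and can be replaced by a 64-line
  TSV; families, column order, and stop handling all derive from it.

## Known limitations

- Genes are treated as independent observations; shared evolutionary
  history or shared GC pressure among subset genes would inflate the
  t-test's effective significance on real data.
- The t-test operates on bounded fractions; for very small families in
  very short genes normal approximation is rough — `min_n` guards the
  worst cases but does not model the discreteness.
- No expression weighting: a gene counts once regardless of abundance,
  so the statistic describes the gene program's coding preferences, not
  the transcriptome-weighted codon demand.
- GO enrichment, DE model fitting, and tRNA abundance estimation are out
  of scope; the package consumes their outputs.
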