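# codonbias

Codon-usage-bias analysis of gene programs — for transcriptomics
researchers who want to ask whether the genes switched on by a biological
program (a differentiation time course, a perturbation response) favour
particular synonymous codons relative to the genome-wide background.

The motivating use case is osteoblast differentiation, where genes
upregulated during differentiation show a bias toward specific codons,
consistent with tRNA-supply-driven translational regulation downstream of
RNA polymerase III activity. The package makes that kind of analysis
reusable: it takes any coding-sequence FASTA, any differential-expression
(DE) results table, and/or any gene-membership list (e.g. the GO term
*osteoblast differentiation*, GO:0001649), and reports per-codon
statistics with multiplicity control.

## The statistic

For gene $g$ and sense codon $c$ encoding amino acid $a$, let $n_g(c)$ be
the number of times $c$ appears when the CDS is read as consecutive
triplets. The **selection rate** of $c$ in $g$ is its share within the
synonymous family:

$$s_g(c) = \frac{n_g(c)}{\sum_{c' : \,\mathrm{aa}(c') = a} n_g(c')}$$

Within each family the rates sum to 1; families the gene never uses are
*missing* (not zero). A gene subset $S$ (e.g. genes with adjusted
$p < 0.05$ and $|\log_2 \mathrm{FC}| > 0.7$) is compared against the
disjoint background $B$ (all other profiled genes): per codon, a
two-tailed Student's *t*-test on $\{s_g(c)\}_{g\in S}$ vs
$\{s_g(c)\}_{g\in B}$, the relative change
$(\bar{s}_S - \bar{s}_B)/\bar{s}_B$, and Benjamini–Hochberg *q*-values
over the full set of codons tested. Simple codon *usage rates*
($n_g(c)/\sum_{c'} n_g(c')$ over sense codons), pooled subset-level
rates, and multi-set Venn overlap counts are also produced.

## Worked example

Simulate a background genome and a subset with a known codon bias, then
run the comparison:

```python
from codonbias import (
    BiasSpec, GeneSubset, LengthModel, apply_bias, compare_codon_usage,
    simulate_two_group_selection, simulate_weight_model,
)

model = simulate_weight_model(concentration=2.0, seed=3)
bias = BiasSpec(frozenset({"AAA"}), shift=3.0)   # favour AAA (Lys) 3-fold
sel, sub, bg, truth = simulate_two_group_selection(
    50, 50, model, bias=bias, length_model=LengthModel(100, 5.0), seed=4
)
res = compare_codon_usage(sel, GeneSubset("up", sub, "explicit"),
                          GeneSubset("bg", bg, "explicit"))
print(res[res.codon == "AAA"][["mean_subset", "mean_background", "p_value", "q_value"]])
```

```
    mean_subset  mean_background   p_value   q_value
21      0.58388         0.338647  0.000041  0.001248
```

The subset uses AAA for 58% of its lysines versus 34% in the background;
the weight model drew 0.287 for AAA and the 3-fold shift moves its
expected share to $3 \cdot 0.287 / (1 + 2 \cdot 0.287) \approx 0.55$ —
recovered, and significant after BH correction (q = 0.0012).

The same analysis runs from the shell on files:

```bash
codonbias simulate cds --n-genes 200 --out-fasta cds.fa --seed 1
codonbias simulate de-table --n-genes 1000 --n-pass 137 --out de.tsv --seed 1
codonbias profile --fasta cds.fa --out-prefix prof
codonbias filter-de --de de.tsv --out up.txt
codonbias compare --selection-matrix prof.selection.tsv --subset up.txt --out cmp.tsv
```

or end-to-end from a YAML config (`codonbias run --config run.yaml`),
which also writes the pooled relative-change matrix, Venn overlap counts
for multiple DE tables, a rejection report, and a JSON run manifest.

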