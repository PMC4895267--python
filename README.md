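# epom

Compare tissues and cell types by where their chromatin is distinctively
active.

Hierarchical clustering and correlation matrices of epigenomic signal
give notoriously noisy pictures of how biological samples group.
`epom` implements the **Epigenome Overlap Measure (EPOM)**: instead of
correlating whole-genome tracks, it first finds the 200 bp
enhancer/promoter windows whose histone-mark signal is *specifically*
high in each tissue/cell-type group, then scores every pair of groups by
the statistical significance of the overlap of their associated region
sets. The result is a sharp correspondence map — similar groups share
associated regions far beyond chance, unrelated groups score zero.

## The method

Inputs: per-sample chromatin-state segmentations (25-state vocabulary,
200 bp bins), per-sample −log10 p-value signal tracks for one or more
histone marks (25 bp, averaged 8× onto the 200 bp grid), and a
sample→group design. Windows in enhancer states (10–18) or promoter
states (1–4, 22, 23) form the candidate lists. Then, per mark and
region class:

1. **ANOVA filter** — per window k, test H₀: μ₁ₖ = … = μ_Gₖ across the
   G groups; keep windows with Bonferroni-corrected p < α₁ (10⁻¹⁰).
2. **Pairwise one-sided t-tests** — window k is *associated* with group
   i when H₀: μᵢₖ ≤ μⱼₖ is rejected (Welch, raw p < α₂ = 0.01) against
   more than m of the other groups. Marks combine by per-group union.
3. **Overlap test** — with the union of all associated windows as the
   population (size n), each group pair (A, B) gets the exact tail
   probability

   p = Σ_{i=|A∩B|}^{min(|A|,|B|)} C(|A|,i) C(n−|A|,|B|−i) ⁄ C(n,|B|),

   the hypergeometric upper tail, evaluated entirely in log space so it
   never underflows. **EPOM score = −log10(Bonferroni-corrected p)**,
   corrected over the G(G−1)/2 pairs.

Downstream, associated regions are merged, assigned nearest-TSS target
genes within 200 kb (promoters only accept genes transcribed away from
them), and tested for gene-set (GO/DO) and trait-SNP enrichment with
the same overlap-test engine. See `docs/methods.md` for assumptions,
parameter semantics and design choices.

## Worked example

`examples/02_epom_matrix.py` plants four groups of four epigenomes over
2,000 windows, with 50% of the high-signal windows of groups 1 and 2
shared between them, and runs the full procedure:

```
population: union of all associated windows (311 regions)
Bonferroni factor: 6 group pairs

        group1  group2  group3  group4
group1   79.56    7.87    0.00    0.00
group2    7.87   81.09    0.00    0.00
group3    0.00    0.00   79.56    0.00
group4    0.00    0.00    0.00   79.56
```

The diagonal holds each group's (uncorrected) self-overlap score —
roughly the number of digits in 1/p for drawing its own region set
twice. The only non-zero off-diagonal entry is the planted pair:
score(1,2) = 7.87 means the corrected probability of groups 1 and 2
sharing that many associated windows by chance is about 10⁻⁷·⁹. The
other examples cover association counts (`01`), the raw overlap test
(`03`), target genes + gene-set enrichment and specificity (`04`), and
SNP/trait enrichment (`05`); each prints its numbers with a line on how
to read them.

A thin CLI wraps the same library for file-based runs:

```bash
epom simulate --seed 3 --out data/
epom associate --data data/ --region-class enhancer --outdir assoc/
epom epom --regions assoc/ --out matrix.tsv --heatmap matrix.png
```

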