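# Methods

## The measure

EPOM (Epigenome Overlap Measure) compares biological groups — tissues or
cell types profiled by several epigenomes each — through the regions of
the genome where their histone-modification signals are distinctively
high. The genome is divided into 200 bp windows; windows carrying an
enhancer-related chromatin state (states 10–18 of the 25-state
vocabulary) or a promoter-related state (1–4, 22, 23) in at least one
input segmentation form the candidate enhancer and candidate promoter
lists. Signals are per-window means of −log10 enrichment p-values for a
histone mark (e.g. H3K4me1, H3K27ac), compressed from 25 bp tracks by
averaging blocks of eight bins.

Three testing steps follow, per mark and region class:

1. **ANOVA filter.** For each candidate window k, a one-way
   fixed-effects ANOVA tests H₀: μ₁ₖ = … = μ_Gₖ across the G groups.
   Raw p-values are Bonferroni-corrected by the number of windows in the
   matrix; windows with corrected p < α₁ (default 10⁻¹⁰) survive as
   *candidate associated* regions. This removes windows whose signal is
   flat across groups — including housekeeping promoters that are high
   everywhere.
2. **Pairwise one-sided t-tests.** For each surviving window and each
   ordered group pair (i, j), a one-sided Welch t-test of
   H₀: μᵢₖ ≤ μⱼₖ is rejected when its raw p < α₂ (default 0.01). Window
   k is *associated* with group i when the rejection count over the
   G − 1 other groups is strictly greater than m (default 14; with 16
   groups this demands rejection against all 15). Marks are then
   combined per group by set union (default) or intersection.
3. **Overlap test.** With the union of all groups' associated windows as
   the population (size n), each unordered group pair (A, B) is scored
   by the exact tail probability that independent draws of |A| and |B|
   regions share at least |A∩B|:

       p = Σ_{i=|A∩B|}^{min(|A|,|B|)} C(|A|,i)·C(n−|A|,|B|−i) / C(n,|B|)

   — the hypergeometric upper tail. The **EPOM score** is
   −log10(Bonferroni-corrected p), corrected by the G(G−1)/2 pairs.
   Larger scores mean more shared epigenomic character; for display the
   matrix is conventionally saturated at 20.

### Numerical evaluation of the overlap test

On realistic inputs (tens of thousands of associated regions out of
millions of candidates) the tail probability underflows double
precision by hundreds to thousands of orders of magnitude. The tail is
therefore evaluated entirely in log space: log-binomial coefficients
from `gammaln`, accumulated with `logsumexp`, returning log10 p
directly. Raw binomial coefficients are never multiplied. An exhaustive
sweep over all 3,875 feasible (n ≤ 15, |A|, |B|, overlap) inputs agrees
with exact rational-arithmetic enumeration to better than 10⁻¹⁴ in
log10 space, and the scipy hypergeometric survival function provides an
independent cross-check in the moderate regime.

### Degenerate inputs and conventions

* ANOVA with zero within- and between-group variance (a constant
  window): p = 1, filtered out. Zero within-group variance with unequal
  means: p = 0, kept. These are the limits of the F statistic.
* Welch t-test with both variances zero: p = 0 if μᵢ > μⱼ, 1 if
  μᵢ < μⱼ, 0.5 if equal (the limit of t → ±∞ or 0).
* The minimal feasible overlap (including 0) gives p = 1 exactly — the
  tail covers the whole support.
* A group with an empty associated set scores 0 against every other
  group, with a logged warning, rather than erroring; near-empty groups
  occur in real data.
* Diagonal entries of the EPOM matrix are each group's full
  self-overlap, reported uncorrected: a self-comparison is not one of
  the G(G−1)/2 pair hypotheses.
* Nearest-TSS ties (two genes equidistant from a region midpoint)
  resolve to the lexicographically smallest gene id, deterministically.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha1` | 10⁻¹⁰ | level for Bonferroni-corrected ANOVA p (step 1) |
| `alpha2` | 0.01 | level for raw one-sided t-test p (step 2) |
| `m` | 14 | association needs rejection against > m other groups |
| `window_size` | 200 bp | unit of the candidate grid |
| compression factor | 8 | 25 bp bins per 200 bp window |
| `min_samples` | 1 | segmentations that must label a window a candidate |
| `combine_mode` | union | across-mark combination of associated sets |
| `cap` | 20 | display saturation of the score matrix |
| `max_distance` | 200 kb | nearest-TSS search radius for target genes |
| specificity p | 10⁻³ | raw-p threshold defining an "enriched" term |

Lowering m (e.g. to G − 3 instead of G − 2 others) lets a window stay
unrejected against one partner group, so regions shared by a *pair* of
similar groups remain associated with both — the setting that reveals
group-level similarity rather than strict identity. `m` must be smaller
than the number of groups.

## Design choices where the procedure is under-determined

* **t-test variant:** Welch (unequal variances). Group sizes in real
  designs range from 2 to ~20 samples; pooling variances across such
  unbalanced groups is the riskier default. Configurable only through
  the code, not a flag — the choice is structural.
* **Step-2 multiplicity:** raw p-values against α₂. Step 1 already
  pays a Bonferroni factor over windows; step 2's role is per-condition
  ranking among pre-filtered windows. A `correct_step2` switch applies
  Bonferroni over all (window, pair) tests for the conservative
  reading.
* **"More than m times"** is read as strictly greater than m
  (`strict=True`); a `strict=False` switch gives ≥ m.
* **Candidate definition across samples:** union (min_samples = 1). How
  per-sample state labels combine into one genome-wide candidate list
  is not pinned down by the procedure; union is the most inclusive
  reading and is exposed as `min_samples`.
* **Step-1 Bonferroni factor** = number of windows in the matrix at
  hand (per mark, per region class), matching separately reported
  per-mark candidate counts.
* **Matrix Bonferroni factor** = G(G−1)/2 unordered pairs (120 for 16
  groups), configurable; whether region classes should multiply the
  factor is left to the caller.
* **Target-gene anchor:** region midpoint to TSS. Midpoint is symmetric
  for merged regions of varying length; edge-anchored distance would
  depend on merge order.
* **Promoter directionality:** a promoter region only takes a gene
  transcribed away from it — TSS ≥ midpoint for '+' genes, TSS ≤
  midpoint for '−' genes, within the search radius. This places the
  region where a promoter sits, 5′ of its gene. Enhancers take the
  nearest TSS in either direction.
* **Enrichment populations:** gene-set enrichment defaults to the union
  of all groups' target genes; SNP enrichment uses the candidate-window
  background. Both mirror the step-3 population convention and accept a
  user-supplied universe.
* **Global SNP enrichment statistic:** the same overlap test at window
  level (population = candidate windows, B = windows containing ≥ 1
  SNP). No specific test is mandated by the analysis being reproduced;
  reusing the one engine keeps every p-value in the package comparable.

## The synthetic-data generator

`epom.synthetic` emulates the full input stack on a toy genome: one
chromosome of contiguous 200 bp windows, each labelled with one
enhancer state (13) or one promoter state (1) per a configurable split;
per-sample, per-mark signal tracks; a design table; a TSS table; gene
sets; and a SNP catalog. Ground truth (planted windows per group,
pair-shared windows, enriched terms, SNP-bearing windows) is recorded
alongside.

Background signal is Normal(baseline_mean, noise_sd) truncated at 0 —
the −log10 p-value scale is non-negative. Planted (group, window) pairs
add `effect_size` to that group's samples in every mark; a sharing
matrix plants windows common to group pairs (each group's planted count
stays exactly `round(fraction × n_windows)`, with the shared quota
drawn from it). Defaults — 6 groups × 6 samples, 10,000 windows, 5%
planted per group, effect 10, sd 1, baseline 1 — represent a strong
mark under clean conditions. Each planted window gets one gene with its
TSS 50–100 bp downstream (the window's own gene is therefore always its
nearest TSS), one planted gene-set term per group, and one
trait-labelled SNP per planted window, so downstream analyses have
recoverable truth. All randomness derives from one seed through named
`SeedSequence` spawns; identical configs yield byte-identical emitted
files.

What the generator does *not* emulate: spatial autocorrelation of real
chromatin (planted windows are scattered uniformly, real associated
regions cluster), heavy-tailed and heteroscedastic signal (a lognormal
noise mode exists as a robustness hook), correlated marks (marks are
independent draws sharing the same planted windows), realistic
gene density and distances, linkage structure among SNPs, and
genome-scale volumes. Passing recovery tests therefore demonstrate the
statistical machinery under its own assumptions, not performance on
Roadmap-scale data.

A note on error-control simulations: the family-wise error check of the
ANOVA filter is run at baseline 5 sd, where the truncation at 0 is
inactive and null values are genuinely i.i.d. normal. At the default
baseline (1 sd), truncation clips ~16% of the noise mass, and the
resulting skew inflates the far-tail false-positive rate of the F test
(measured FWER ≈ 0.10 at nominal 0.05 over 200 replicates of 5,000
windows) — a real robustness caveat for signals that hug zero, noted
here rather than hidden by the test conditions.

## Problem sizes used by the test suite

The suite favours conditions large enough to measure rates yet quick to
simulate: error control uses 200 null replicates of 6 groups × 5
samples × 5,000 windows; recovery uses one dataset of 6 groups × 6
samples × 10,000 windows at 5% planting (α₁ = 10⁻⁴, α₂ = 0.01,
m = G − 2), measuring sensitivity ≥ 0.90 and precision ≥ 0.95;
sharing-structure recovery uses 50 replicates of 4 groups × 4 samples ×
2,000 windows with 50% sharing between one pair and m = G − 3. The
exhaustive overlap-test sweep covers every feasible input with n ≤ 15.

## Known limitations

* Bonferroni is the only multiplicity correction offered, by design; no
  FDR variants.
* The ANOVA/t machinery assumes approximate normality of per-window
  signals; rank-based or permutation alternatives are out of scope.
* Target-gene assignment is purely distance-based; 3D-contact
  (Hi-C-informed) assignment is not attempted.
* bigWig input is not parsed; signal tracks are text (bedGraph or
  fixedStep wiggle).
* Candidate state sets are fixed to the 25-state vocabulary's enhancer
  and promoter groups unless overridden via `RegionClass`.
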