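# haloseq

Downstream analysis for RNA proximity-labeling experiments of the
Halo-seq family, in which a localized labeling agent biotinylates nearby
RNA so that a streptavidin **pulldown** sample can be compared against its
**input** (total RNA) sample. The ratio of pulldown to input abundance per
gene is a quantitative readout of how strongly an RNA is localized to the
labeled compartment (nucleus, nucleolus, cytoplasm, ...).

The package is for computational biologists who have transcript- or
gene-level count tables from such an experiment (e.g. Salmon + tximport
output) and want the standard downstream battery:

* **enrichment** — per-gene negative-binomial Wald test of
  pulldown vs input (median-of-ratios normalization, `log2FC`, BH-adjusted
  p-values, `enriched`/`depleted`/`ns` calls at padj < 0.05 and
  |log2FC| ≥ 0.5, genes required to have ≥ 5 counts in every sample);
* **reference_builder** — a dual transcriptome with two entries per
  transcript (`|spliced`: introns removed; `|unspliced`: introns retained),
  promoter-proximal upstream antisense windows, and per-gene 3′ UTRs;
* **ratio_metrics** — per-gene unspliced/spliced and antisense/sense
  ratios with Wilcoxon rank-sum comparisons between fractions or gene
  groups (gene classes, ARE presence, HuR-site bins), with the usual
  star notation (* < 0.05 ... **** < 0.0001);
* **localization_shift** — genes whose enrichment changes between two
  conditions (e.g. ± leptomycin B export block), tested through the
  fraction × condition interaction of an NB GLM, plus a decomposition into
  input-only and pulldown-only condition contrasts;
* **seq_features** — kmer, RBP-motif (PWM) and AU-rich-element enrichment
  in 3′ UTRs of a target gene set versus a background set (presence 2×2
  tables, two-sided Fisher exact, Haldane-corrected odds ratios, BH over
  the full kmer universe);
* **synthetic_data** — a generator that emulates the full experiment
  (gene classes, NB input/pulldown count pairs, spliced/unspliced mixtures,
  upstream antisense companions, condition shifts, planted UTR features)
  with a truth table whose flags are re-derivable from the emitted FASTA.

## The model in brief

Counts are modeled per gene as `y_gj ~ NB(mu_gj, alpha_g)` with
`Var = mu + alpha mu^2` and log link
`log mu_gj = log s_j + x_j' beta_g`, where `s_j` are median-of-ratios size
factors. The pulldown coefficient gives `log2FC`; the fraction × condition
interaction gives the localization shift
`delta_g = log2FC_B − log2FC_A`. Gene-wise dispersions are Cox–Reid
adjusted profile-likelihood estimates squeezed toward their across-gene
median (limma-style moderation, prior df 4), and Wald statistics are
referred to a t distribution with `n − p + 4` degrees of freedom — at 3–4
replicates per group this keeps the test calibrated without collapsing
power. See `docs/methods.md` for the full account.

## Worked example

One command simulates an experiment with planted truth, runs every stage,
and reports recovered vs planted:

```bash
haloseq demo --seed 7 -o demo_out
```

which prints (stderr logs elided):

```
demo summary: enrichment recall=1.000, null type-I=0.127, shift recall=0.126 (observed FDR=0.074), planted kmer rank=1
```

and writes `demo_out/summary.json`, including:

```json
{
  "planted_enrichment_recall": 1.0,
  "null_simulation_type_i_error": 0.0603,
  "ratio_tests": {"unspliced_spliced": {"pvalue": 0.0, "median_diff": 0.327, "stars": "****"}},
  "shift_recall": 0.126,
  "shift_observed_fdr": 0.074,
  "planted_kmer_rank_truth_sets": 1
}
```

Reading: every gene planted with a ±2 log2 pulldown effect was recovered
with the correct call (`recall = 1.0`); on a same-scale null simulation the
raw p < 0.05 rate is 0.06 (`null_simulation_type_i_error`), while
`null type-I = 0.127` measured on null genes *inside* the effect-laden
experiment reflects the composition bias that median-of-ratios
normalization inherits when a large gene fraction is truly enriched. The
unspliced/spliced ratio is higher in the pulldown (median shift +0.33,
Wilcoxon ****), as expected for a nuclear marker. The planted AU-rich
6-mer ranks first of 4096 in the UTRs of shift-target genes. Shift recall
is low by design size: detecting a 1-log2 enrichment change at FDR 0.05
with three replicates per cell is power-limited (see `docs/methods.md`),
although the discoveries that are made are clean (observed FDR 0.07).

Individual stages run as `haloseq simulate | build-ref | enrich | ratios |
shift | features`; all I/O is plain TSV/FASTA/GTF/BED/MEME.

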