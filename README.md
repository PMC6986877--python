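# glireg

Classification and enrichment analysis of GLI-bound enhancers that respond to
Hedgehog (HH) signaling.

## The problem

GLI transcription factors act as activators where HH ligand is present and as
truncated repressors where it is absent. At a subset of GLI binding regions
(GBRs), GLI repression removes histone H3K27 acetylation — the mark of active
enhancers — so comparing H3K27ac ChIP-seq between HH-active tissue (e.g.
wild-type limb bud) and HH-deficient tissue (e.g. *Shh* null) splits GBRs into
three biologically distinct classes:

* **stable** — H3K27ac retained without HH signaling;
* **HH-sensitive** — H3K27ac significantly reduced but still detectable;
* **HH-dependent** — H3K27ac enrichment absent without HH signaling.

HH-sensitive and HH-dependent GBRs together ("HH-responsive") are the
enhancers through which GLI repression regulates target genes: they
concentrate near HH target-gene promoters, carry more and better GLI motifs,
and lose chromatin accessibility under constitutive repression. `glireg`
implements this analysis end to end for anyone who has region-level ChIP/ATAC
count data and wants the same classification and its companion statistics.

## What is computed

Given per-condition peak calls and per-region read counts
(two replicates per condition), the pipeline:

1. normalizes counts by library size, `log2(count · N_ref / N_s + 1)`;
2. tests wild-type vs mutant signal per merged acetylation region with the
   empirical-Bayes **moderated t**: shrunken variance
   `s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g)`, `t̃_g = Δȳ_g / (s̃_g √(1/n₁+1/n₂))`
   on `d₀ + d_g` df, with the prior `(d₀, s₀²)` estimated by closed-form
   moment matching of log sample variances (digamma/trigamma equations);
3. converts p-values to q-values with Benjamini–Hochberg and classifies each
   GBR from its overlapping acetylation regions: no acetylated region →
   `non_acetylated`; every region's peak absent in the mutant →
   `hh_dependent`; any region with q < 0.05 and positive log2FC →
   `hh_sensitive`; otherwise `stable`;
4. tests positional enrichment of each class near target-gene TSS windows
   (2 kb upstream – 1 kb downstream) with a permutation null over random gene
   sets, promoter proximity of stable vs responsive GBRs with Fisher's exact
   test, accessibility differences with one-sided Wilcoxon rank-sum tests, and
   GLI-motif presence / quantity / quality with one-sided proportion and
   Wilcoxon tests after log-odds PWM scanning of both strands.

A simplified fixed-window Poisson peak caller (200 bp windows, BH-corrected
against a robust genome-wide background rate) stands in for a full peak
caller; externally called peaks can be supplied as BED instead.

Because real limb-bud data are not bundled, a seeded synthetic generator
(`glireg.simulate`) produces a complete toy dataset — genome FASTA, genes,
CpG islands, planted GBRs of all four classes with negative-binomial count
signal, library-size differences and class-dependent planted GLI motifs —
together with a ground-truth table, so every stage is testable and the whole
pipeline's recovery of planted truth is measurable.

## Worked example

```sh
glireg simulate --seed 11 --out bundle       # toy dataset + ground truth
glireg all --bundle bundle --out results --seed 11
```

`results/report.json` from this exact run (abridged):

```json
"summary":   {"counts": {"stable": 300, "hh_sensitive": 61,
                         "hh_dependent": 60, "non_acetylated": 29}},
"recovery":  {"hh_dependent":  {"n_planted": 60,  "n_recovered": 59},
              "hh_sensitive":  {"n_planted": 60,  "n_recovered": 60},
              "stable":        {"n_planted": 300, "n_recovered": 300}},
"enrichment": {"hh_dependent": {"observed": 15, "p_plain": 0.0,
                                "p_plus_one": 0.000999, "n_perm": 1000}},
"motifs":    {"classes": {"hh_dependent": {"presence_fraction": 0.667,
                                           "mean_quantity": 1.57},
                          "stable":       {"presence_fraction": 0.427,
                                           "mean_quantity": 1.25}}}
```

Reading: of 450 planted GBRs the pipeline recovered 59/60 HH-dependent,
60/60 HH-sensitive and 300/300 stable labels from the raw simulated reads; 15
of the classified HH-dependent GBRs fall in target-gene promoter windows
versus a permutation null with median 5 (`p_plus_one ≈ 1e-3`, 1000
permutations); and motif presence is higher in the dependent class (67%) than
the stable class (43%), mirroring the planted rates (69.7% / 39.5%).

`results/` also contains the peak calls (BED), the per-region differential
table, the classification table with co-mark and promoter annotations, the
accessibility comparisons and per-region motif statistics (all TSV).

## Layout

```
src/glireg/intervals.py    BED I/O, 0-based half-open interval arithmetic
src/glireg/stats.py        Fisher, proportion z, Wilcoxon, BH, moderated t, ΔΔCt
src/glireg/diff.py         counting, normalization, peak calling, differential
src/glireg/classify.py     GBR classification + TSS/accessibility/summary tests
src/glireg/permutation.py  TSS and neighbor permutation enrichment
src/glireg/motifs.py       PWM loading, both-strand log-odds scanning, stats
src/glireg/simulate.py     seeded synthetic bundle with planted ground truth
src/glireg/pipeline.py     stage orchestration; cli.py: the `glireg` command
docs/methods.md            model assumptions, defaults, limitations
```
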