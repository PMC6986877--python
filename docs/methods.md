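# Methods

This note records the models, defaults and numerical choices behind
`glireg`, and what the synthetic data do and do not establish.

## Coordinates and interval semantics

All coordinates are 0-based half-open (`[start, end)`), the BED convention
of the formats the package reads and writes. Overlap means at least one
shared base; adjacent intervals (`end == start`) neither overlap nor merge.
Promoter windows are strand-aware: 2 kb upstream to 1 kb downstream of the
TSS on the plus strand and the coordinate mirror on the minus strand (the
single-base asymmetry of the TSS base is immaterial at kilobase scale). A
strand-ignorant mode exists for annotations of unknown orientation. The
CpG-promoter rule flags a gene when any CpG island overlaps the window 5 kb
upstream to 2.5 kb downstream of its TSS.

## Differential acetylation model

Counts per merged acetylation region are normalized as
`log2(count · N_ref / N_s + 1)` where `N_s` is the sample's library size
(total reads) and `N_ref` defaults to the median library size. The
pseudo-count of 1 keeps zero counts at zero and stabilizes low counts.

The two-condition test is the empirical-Bayes moderated t. Per region the
pooled within-group variance `s²_g` on `d_g = n₁ + n₂ − 2` df is shrunk
toward a prior: `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, and
`t̃ = Δmean / (s̃ √(1/n₁ + 1/n₂))` is referred to a t distribution on
`d₀ + d_g` df. The prior is estimated by moment matching of
`log s²_g`: with `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, the excess of
`Var(e)` over `ψ′(d_g/2)` determines `d₀` through a trigamma inversion
(Newton iteration) and `s₀²` follows from the mean. When the spread of log
variances does not exceed sampling noise, `d₀ = ∞` and every region shrinks
fully to the pooled mean variance. The implementation agrees with the
reference empirical-Bayes implementation in R (limma) to at least five
significant figures on both the prior and the per-region t and p values;
the test suite performs that cross-check live.

With only two replicates per condition — the design this analysis targets —
the shrinkage is what makes region-level testing workable at all; classical
per-region t-tests on 2 vs 2 replicates are hopelessly underpowered.

q-values are Benjamini–Hochberg; the differential threshold defaults to
q < 0.05.

## Peak calling stand-in

`call_peaks_fixed_windows` is a deliberately simple caller: tile the genome
with fixed windows (default 200 bp), test each window's count against a
genome-wide uniform Poisson background, BH-correct across all windows
(q < 0.05), and merge runs of adjacent significant windows. The background
rate is estimated robustly as the median full-window count plus 1/3 (the
Poisson median-to-mean correction): the plain mean is inflated by the
signal windows themselves and would mask retained-but-reduced peaks in the
condition with more signal. `background="mean"` and a fixed rate are
available. The caller has no fragment model, duplicate handling or local
background — users with real data should supply peaks from a production
caller as BED, which bypasses it.

## GBR classification

Classification consumes the differential table over merged acetylation
regions and the per-condition peak-presence flags, with precedence:

1. no overlapping region acetylated in the HH-active condition →
   `non_acetylated`;
2. every overlapping acetylated region's peak absent in the HH-deficient
   condition → `hh_dependent` (complete absence);
3. any overlapping region with q < FDR and positive log2FC →
   `hh_sensitive` (significant reduction);
4. otherwise `stable`.

Where a GBR overlaps several regions with conflicting evidence the rules
are conservative about "complete absence": a single retained region
prevents the dependent label. "HH-responsive" always means sensitive ∪
dependent. Co-marks (H3K4me1/2, ATAC, H3K27me3) are plain any-overlap
booleans. The accessibility comparisons are one-sided Wilcoxon rank-sum
tests (stable > other for the HH-active signal; stable < other for the
log2 condition ratio, i.e. responsive classes lose more accessibility),
reported for sensitive, dependent and pooled responsive groups.

## Statistical kernel choices

* **Fisher's exact test** computes the two-sided p as the sum of
  hypergeometric point probabilities not exceeding the observed one
  (relative tolerance 1e-7), in log space so extreme tables (p ~ 1e-40)
  remain exact; the doubling rule is available as an option.
* **Two-proportion test** is the pooled z with Yates continuity correction
  on by default; the correction is required to reproduce the published
  motif-presence p of 8.00e-06 from the printed percentages, which is how
  the original software's convention was inferred.
* **Wilcoxon rank-sum** uses exact enumeration (dynamic programming over
  rank subsets) for combined n ≤ 12 without ties, and otherwise a midrank
  normal approximation with tie-corrected variance and a continuity
  correction that shrinks the deviation toward zero — so identical samples
  give exactly p = 0.5 one-sided.
* **Permutation enrichment** reports both `p_plain = #{null ≥ obs}/B` and
  the bias-corrected `p_plus_one = (1 + #{null ≥ obs})/(1 + B)`.
  `p_plain` can be zero and matches the "p = 0" convention of
  permutation-test reports; `p_plus_one` is the recommended value. Null
  gene sets are sampled uniformly without replacement; the neighbor-
  enrichment null repositions each query uniformly on its own chromosome,
  length preserved.
* **Motif scanning** scores every window on both strands as the log2
  likelihood ratio against the background (uniform by default); windows
  containing N are skipped. Presence/quantity/quality summaries use the
  mean hit score per motif-containing region by default ("max" optional).
  The bundled GLI-like matrix is a synthetic stand-in built from the
  canonical GACCACCCA consensus (count 10 per consensus base, pseudocount
  0.25, max score 17.1 bits); real scans should use a curated database
  matrix. The general-purpose scan threshold default is 7 bits.

## The synthetic data generator

The generator emulates the structure of the study design at desk scale:
two conditions (HH-active "a", HH-deficient "b"), two replicates each plus
inputs, planted GBR classes with condition-dependent signal, library-size
differences, class-dependent motif planting and ATAC-like accessibility
signal. Defaults, chosen once as plausible desk-scale study conditions:

* genome: 3 chromosomes totalling 3.5 Mb of i.i.d. uniform ACGT;
  300 genes, 15% of them "target genes".
* GBRs: 300 stable / 60 sensitive / 60 dependent / 30 silent, 1 kb each,
  pairwise separated by ≥ 1 kb. Responsive GBRs are placed inside
  target-gene promoter windows with probability 0.26, stable GBRs inside
  non-target promoter windows with probability 0.62 (the observed
  promoter-proximal fractions of the two classes); placement order is
  dependent → sensitive → stable → silent so the small responsive classes
  are not crowded out of the limited promoter-window space.
* signal: baseline 500 reads/region in the active condition; sensitive
  regions drop 1.5 log2 units in condition b; dependent regions drop to
  background; silent regions are background in both. Counts are
  negative-binomial (gamma-Poisson, shared dispersion 0.02) and reads are
  placed uniformly within their region over a uniform genomic background
  of 300,000 reads per unit scale (≈ 30% of reads in peaks, a realistic
  ChIP fraction). Per-sample scale factors (1.0/1.25 vs 0.85/1.10)
  exercise library-size normalization.
* calibration of baseline and dispersion: background reads landing inside
  a 1–1.4 kb merged region (~90–120) dilute the observed log2 contrast of
  sensitive regions from 1.5 to ~1.0–1.2; with two replicates the
  per-region log-scale sd is ≈ √(2.08·(1/mean + dispersion)), so mean 500
  with dispersion 0.02 puts the planted sensitive effect at ≈ 5σ — clearly
  detectable but dependent on the moderated-t shrinkage actually working.
* motifs: consensus GLI sites are embedded in place (no indels) with
  class rates 0.697 / 0.574 / 0.395 (dependent/sensitive/stable) and
  1 + Poisson(0.51/0.47/0.27) sites per motif-positive region, mirroring
  the observed per-class presence and density. The simulation-level scan
  threshold is 12 bits: planted sites are exact consensus (17.1 bits)
  while the best one-mismatch background words score 11.7 bits, so this
  threshold cleanly separates planting from the background hit rate of an
  i.i.d. genome. (At the 7-bit general default, ~2000 scanned windows per
  1 kb region would produce chance hits in ~20% of regions — a property of
  region length, not of planting.)
* accessibility: per-class ATAC means (a: 250/110/90/60,
  b: 250/75/45/60) reproduce the ordering stable > sensitive > dependent
  and the responsive-specific loss without signaling.

`regenerate_counts` redraws counts for fixed geometry (optionally forcing
condition b to equal condition a), enabling cheap null-calibration and
power sweeps.

### What the synthetic data do not emulate

No fragment-level reads, GC or mappability bias, diploidy, non-GBR
acetylation peaks, or realistic gene density: promoter windows cover ~26%
of the toy genome (vs ~2% of a mammalian genome), so promoter-proximity
contrasts are compressed relative to real data, and uniformly placed GBRs
are "promoter proximal" far more often than real distal enhancers. Stable
GBRs are planted at non-target promoters, so — unlike the original study,
which found weak but significant stable enrichment near target genes —
the synthetic stable class is depleted near target genes; only the
responsive classes carry planted TSS enrichment. Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is correct
and calibrated under the generative model, not that any particular
biological dataset will separate as cleanly.

## Problem sizes

Default analyses run in seconds on one core: the bundle is ~3.5 Mb of
genome and ~4M simulated reads; calibration suites use 500 permutation
replicates of a 100-region × 300-gene geometry and 100 count
regenerations of a 150-region matrix. These sizes were chosen so the whole
test suite and the acceptance script complete in well under a minute while
every statistical check retains non-trivial resolution.

## Known limitations

* The moderated-t prior estimation requires at least two regions with
  positive variance; degenerate all-constant matrices are rejected.
* The peak caller's robust background assumes most windows are background;
  datasets where signal covers a large genome fraction need an explicit
  background rate.
* One published figure cannot be reproduced from its printed inputs: the
  exact two-sided Fisher p for the 3,544/5,715 vs 91/349 promoter table is
  9.09e-40 (scipy and R agree), not the printed 2.55e-40; a chi-square
  without continuity correction (2.28e-40) comes closest, suggesting an
  approximate test or slightly different counts behind the printed value.
* The tissues-per-enhancer summary (`mean_tissues_per_class`) is exercised
  on synthetic stand-in tables only; the published reporter-assay table is
  external supplementary data and is not bundled.
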