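"""Classification of GLI binding regions (GBRs) by their H3K27ac response.

A GBR is classified from the differential-acetylation results of the
H3K27ac regions overlapping it:

* ``non_acetylated`` — no overlapping region carries acetylation in the
  HH-active condition;
* ``hh_dependent``  — acetylation is present with signaling but every
  overlapping acetylated region loses its peak entirely without it
  ("complete absence");
* ``hh_sensitive``  — acetylation is retained without signaling but at
  least one overlapping region is significantly reduced (q < fdr with
  positive log2 fold change);
* ``stable``        — acetylation retained with no significant reduction.

``hh_sensitive`` and ``hh_dependent`` together form the HH-responsive
class. The module also houses the TSS-proximity contingency test, the
accessibility comparisons and the tissues-per-enhancer summary.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    RegionSet,
    assign_cpg_promoters,
    intersect_any,
    promoter_windows,
)
from .stats import Table2x2, fisher_exact_2x2, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

LABELS = ("stable", "hh_sensitive", "hh_dependent", "non_acetylated")
RESPONSIVE = ("hh_sensitive", "hh_dependent")

CLASSIFICATION_COLUMNS = [
    "gbr_id", "chrom", "start", "end", "label",
    "n_overlapping", "min_q", "max_log2fc",
]


def classify_gbrs(
    gbrs: RegionSet,
    diff: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Label each GBR from the differential table over acetylation regions.

    ``diff`` must be a differential-result table (see
    :func:`glireg.diff.differential_regions`) computed on the merged union
    of condition_a and condition_b acetylation peaks; ``presence_a`` marks
    regions acetylated in the HH-active condition.
    """
    if len(gbrs) == 0:
        raise ValueError("GBR set is empty")
    diff_regions = RegionSet(
        (  # rebuild intervals from the table so diff can come from TSV
            _row_interval(row) for row in diff.itertuples(index=False)
        ),
        name="diff_regions",
    )
    by_id = diff.set_index("region_id")
    overlaps = intersect_any(gbrs, diff_regions)

    rows = []
    for iv in gbrs:
        hits = by_id.loc[overlaps[iv.id]] if overlaps[iv.id] else by_id.iloc[0:0]
        present = hits[hits["presence_a"]]
        if len(present) == 0:
            label = "non_acetylated"
            min_q = np.nan
            max_fc = np.nan
        else:
            min_q = float(present["q"].min())
            max_fc = float(present["log2fc"].max())
            if (present["peak_type"] == "a_only").all():
                label = "hh_dependent"
            elif ((present["q"] < fdr) & (present["log2fc"] > 0)).any():
                label = "hh_sensitive"
            else:
                label = "stable"
        rows.append(
            (iv.id, iv.chrom, iv.start, iv.end, label, len(present), min_q, max_fc)
        )
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)


def _row_interval(row):
    from .intervals import GenomicInterval

    return GenomicInterval(row.chrom, int(row.start), int(row.end), id=row.region_id)


def annotate_comarks(
    classes: pd.DataFrame,
    gbrs: RegionSet,
    marks: Mapping[str, RegionSet],
) -> pd.DataFrame:
    """Add a boolean any-overlap column per co-mark (e.g. H3K4me1, ATAC)."""
    out = classes.copy()
    for name, regions in marks.items():
        ov = intersect_any(gbrs, regions)
        out[name] = out["gbr_id"].map(lambda g: bool(ov[g]))
    return out


def annotate_promoters(
    classes: pd.DataFrame,
    gbrs: RegionSet,
    genes: Sequence[GeneAnnotation],
    cpg_islands: RegionSet | None = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Add ``promoter_proximal`` (overlap with any 2 kb/1 kb TSS window) and,
    when CpG islands are given, ``cpg_promoter`` (proximal to a CpG-island
    promoter under the 5 kb/2.5 kb rule)."""
    out = classes.copy()
    windows = promoter_windows(genes, upstream, downstream)
    ov = intersect_any(gbrs, windows)
    out["promoter_proximal"] = out["gbr_id"].map(lambda g: bool(ov[g]))
    if cpg_islands is not None:
        cpg_by_gene = assign_cpg_promoters(genes, cpg_islands)
        cpg_windows = promoter_windows(
            [g for g in genes if cpg_by_gene[g.gene_id]], upstream, downstream
        )
        ov_cpg = intersect_any(gbrs, cpg_windows)
        out["cpg_promoter"] = out["gbr_id"].map(lambda g: bool(ov_cpg[g]))
    return out


def tss_distribution_test(
    classes: pd.DataFrame,
    gbrs: RegionSet,
    genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 1000,
) -> tuple[Table2x2, float]:
    """Fisher's exact test for promoter proximity of stable vs HH-responsive
    GBRs.

    Builds the 2x2 table (stable vs responsive) x (proximal vs distal)
    with proximity defined by overlap with any gene's promoter window,
    and returns the table with the two-sided Fisher p-value.
    """
    ann = annotate_promoters(classes, gbrs, genes, upstream=upstream, downstream=downstream)
    stable = ann[ann["label"] == "stable"]
    responsive = ann[ann["label"].isin(RESPONSIVE)]
    for name, grp in (("stable", stable), ("responsive", responsive)):
        if len(grp) == 0:
            raise ValueError(f"class {name!r} is empty; cannot form the table")
    table = Table2x2(
        a=int(stable["promoter_proximal"].sum()),
        b=int((~stable["promoter_proximal"]).sum()),
        c=int(responsive["promoter_proximal"].sum()),
        d=int((~responsive["promoter_proximal"]).sum()),
    )
    return table, fisher_exact_2x2(table, "two_sided")


def accessibility_compare(
    signal: pd.DataFrame,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided Wilcoxon comparisons of accessibility between GBR classes.

    ``signal`` is indexed by gbr_id with columns ``condition_a`` and
    ``condition_b`` holding normalized log2 accessibility. Two measures
    are compared, each with the alternative "stable > other":

    * ``signal_a``   — the condition_a (HH-active) signal;
    * ``log2_ratio`` — the per-GBR condition_a - condition_b difference,
      i.e. how much accessibility is lost without signaling (compared
      with alternative "stable < other", responsive GBRs losing more).

    The stable class is tested against hh_sensitive, hh_dependent and
    their union (``responsive``). GBRs missing from ``signal`` are
    dropped with a warning; empty groups yield NaN p-values.
    """
    merged = classes.merge(
        signal, left_on="gbr_id", right_index=True, how="left", validate="1:1"
    )
    missing = merged["condition_a"].isna()
    if missing.any():
        logger.warning("%d classified GBRs missing accessibility signal", missing.sum())
        merged = merged[~missing]
    merged = merged.assign(log2_ratio=merged["condition_a"] - merged["condition_b"])

    stable = merged[merged["label"] == "stable"]
    groups = {
        "hh_sensitive": merged[merged["label"] == "hh_sensitive"],
        "hh_dependent": merged[merged["label"] == "hh_dependent"],
        "responsive": merged[merged["label"].isin(RESPONSIVE)],
    }
    rows = []
    for name, grp in groups.items():
        if len(grp) == 0 or len(stable) == 0:
            rows.append((name, len(stable), len(grp), np.nan, np.nan))
            continue
        p_sig = wilcoxon_rank_sum(
            stable["condition_a"], grp["condition_a"], sided="greater"
        )
        p_ratio = wilcoxon_rank_sum(
            stable["log2_ratio"], grp["log2_ratio"], sided="less"
        )
        rows.append((name, len(stable), len(grp), p_sig, p_ratio))
    return pd.DataFrame(
        rows, columns=["versus", "n_stable", "n_other", "p_signal_a", "p_log2_ratio"]
    )


def summarize_classes(classes: pd.DataFrame) -> dict:
    """Headline counts and fractions per label (JSON-serializable)."""
    counts = {label: int((classes["label"] == label).sum()) for label in LABELS}
    acetylated = sum(counts[l] for l in ("stable", "hh_sensitive", "hh_dependent"))
    out = {
        "n_gbrs": int(len(classes)),
        "n_acetylated": acetylated,
        "counts": counts,
        "n_responsive": counts["hh_sensitive"] + counts["hh_dependent"],
    }
    if acetylated:
        out["fraction_stable_of_acetylated"] = counts["stable"] / acetylated
        out["fraction_responsive_of_acetylated"] = out["n_responsive"] / acetylated
    return out


def mean_tissues_per_class(
    enhancers: pd.DataFrame,
    class_column: str = "gbr_class",
    tissues_column: str = "n_tissues",
) -> dict[str, float]:
    """Mean number of tissues with reporter activity per enhancer class.

    ``enhancers`` is a table of transgenic-reporter assays (one row per
    tested enhancer) with its GBR class and the number of tissues in
    which it drives expression. Returns class -> mean tissue count —
    the breadth-of-activity summary used to contrast tissue-specific
    (HH-responsive) with broadly active (stable) enhancers.
    """
    if enhancers.empty:
        return {}
    grouped = enhancers.groupby(class_column)[tissues_column].mean()
    return {str(k): float(v) for k, v in grouped.items()}
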