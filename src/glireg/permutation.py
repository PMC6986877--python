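"""Permutation nulls for positional enrichment of region sets.

Two tests: enrichment of regions in promoter windows of a target-gene
set against random gene sets of the same size, and enrichment of query
regions within a distance band of anchor regions against random
repositioning of the queries on their own chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneAnnotation, RegionSet, promoter_windows

__all__ = ["EnrichmentResult", "tss_enrichment_test", "neighbor_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic, its permutation null, and both p-value flavors.

    ``p_plain`` is ``#{null >= observed} / n_perm`` (can be 0);
    ``p_plus_one`` is the bias-corrected ``(1 + #{null >= observed}) /
    (1 + n_perm)`` and is the recommended p-value.
    """

    observed: int
    null: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.null.size != self.n_perm:
            raise ValueError("null vector length must equal n_perm")

    @property
    def p_plain(self) -> float:
        return float((self.null >= self.observed).sum()) / self.n_perm

    @property
    def p_plus_one(self) -> float:
        return (1.0 + float((self.null >= self.observed).sum())) / (1.0 + self.n_perm)

    def to_dict(self) -> dict:
        q = np.quantile(self.null, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "observed": int(self.observed),
            "null_quantiles": {k: float(v) for k, v in zip(("min", "q25", "median", "q75", "max"), q)},
            "p_plain": self.p_plain,
            "p_plus_one": self.p_plus_one,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _overlap_matrix(regions: RegionSet, windows: RegionSet, gene_order: list[str]) -> np.ndarray:
    """Boolean (regions x genes) matrix: region overlaps gene's window."""
    mat = np.zeros((len(regions), len(gene_order)), dtype=bool)
    col = {gid: j for j, gid in enumerate(gene_order)}
    win_by_chrom: dict[str, list] = windows.by_chrom()
    region_ids = regions.ids
    row = {rid: i for i, rid in enumerate(region_ids)}
    trees = windows.trees()
    for iv in regions:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            gid = hit.data.removesuffix("_prom")
            mat[row[iv.id], col[gid]] = True
    return mat


def tss_enrichment_test(
    regions: RegionSet,
    target_genes: Sequence[str],
    all_genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    count: str = "regions",
) -> EnrichmentResult:
    """Are ``regions`` enriched in the promoter windows of ``target_genes``?

    The statistic counts regions overlapping at least one promoter window
    (2 kb upstream to 1 kb downstream of the TSS by default) of the gene
    set; with ``count="genes"`` it counts genes instead. The null draws
    ``n_perm`` gene sets of the same size uniformly without replacement
    from ``all_genes``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gene_ids = [g.gene_id for g in all_genes]
    unknown = set(target_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"target genes absent from annotation: {sorted(unknown)[:5]}")
    k = len(target_genes)
    if k > len(gene_ids):
        raise ValueError("more target genes than genes in the annotation")
    if count not in ("regions", "genes"):
        raise ValueError("count must be 'regions' or 'genes'")

    windows = promoter_windows(all_genes, upstream, downstream)
    mat = _overlap_matrix(regions, windows, gene_ids)  # regions x genes

    col = {gid: j for j, gid in enumerate(gene_ids)}
    target_cols = np.array([col[g] for g in target_genes], dtype=int)

    def statistic(cols: np.ndarray) -> int:
        sub = mat[:, cols]
        if count == "regions":
            return int(sub.any(axis=1).sum())
        return int(sub.any(axis=0).sum())

    observed = statistic(target_cols)
    rng = np.random.default_rng(seed)
    g = len(gene_ids)
    null = np.empty(n_perm, dtype=np.int64)
    # vectorized sampling without replacement: argpartition of random keys
    keys = rng.random((n_perm, g))
    picks = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < g else np.tile(
        np.arange(g), (n_perm, 1)
    )
    for i in range(n_perm):
        null[i] = statistic(picks[i])
    return EnrichmentResult(observed=observed, null=null, n_perm=n_perm, seed=seed)


def neighbor_enrichment(
    query: RegionSet,
    anchors: RegionSet,
    chrom_sizes: Mapping[str, int],
    max_distance: int = 100_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Are query regions enriched within ``max_distance`` of anchors?

    The statistic counts query regions whose nearest anchor on the same
    chromosome lies within ``max_distance`` bp (overlap = distance 0).
    The null repositions each query uniformly on its own chromosome
    (length preserved) ``n_perm`` times.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for iv in query:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {iv.chrom!r} absent from chrom_sizes")
        if len(iv) > chrom_sizes[iv.chrom]:
            raise ValueError(f"region {iv.id} longer than its chromosome")

    # per-chromosome merged anchor boundaries for vectorized distance
    anchor_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    from .intervals import merge_overlapping

    if len(anchors):
        for chrom, ivs in merge_overlapping(anchors).by_chrom().items():
            anchor_by_chrom[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )

    def count_near(starts: np.ndarray, ends: np.ndarray, chrom: str) -> np.ndarray:
        """Boolean per query-on-chrom: nearest anchor within max_distance."""
        if chrom not in anchor_by_chrom:
            return np.zeros(starts.size, dtype=bool)
        a_start, a_end = anchor_by_chrom[chrom]
        i = np.searchsorted(a_start, ends)  # first anchor fully right
        right = np.where(i < a_start.size, a_start[np.minimum(i, a_start.size - 1)] - ends, np.iinfo(np.int64).max)
        j = np.searchsorted(a_end, starts, side="right") - 1  # last fully left
        left = np.where(j >= 0, starts - a_end[np.maximum(j, 0)], np.iinfo(np.int64).max)
        dist = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
        overlap = i - (j + 1) > 0
        dist = np.where(overlap, 0, dist)
        return dist <= max_distance

    by_chrom = query.by_chrom()
    observed = 0
    for chrom, ivs in by_chrom.items():
        s = np.array([iv.start for iv in ivs], dtype=np.int64)
        e = np.array([iv.end for iv in ivs], dtype=np.int64)
        observed += int(count_near(s, e, chrom).sum())

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    for chrom, ivs in by_chrom.items():
        lengths = np.array([len(iv) for iv in ivs], dtype=np.int64)
        size = chrom_sizes[chrom]
        max_start = size - lengths  # inclusive upper bound for start
        starts = rng.integers(0, max_start + 1, size=(n_perm, lengths.size))
        ends = starts + lengths
        for p in range(n_perm):
            null[p] += int(count_near(starts[p], ends[p], chrom).sum())
    return EnrichmentResult(observed=observed, null=null, n_perm=n_perm, seed=seed)
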