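"""Genomic interval model and arithmetic.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Intervals are the common currency of the pipeline — GLI binding regions,
histone-mark peaks, ATAC peaks, CpG islands and promoter windows are all
:class:`GenomicInterval` collected into :class:`RegionSet` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

UNSTRANDED = "."


class BedParseError(ValueError):
    """Raised for malformed BED / annotation lines (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    id : str
        Unique label within a :class:`RegionSet`.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (half-open arithmetic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` with unique ids."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        self._intervals: list[GenomicInterval] = []
        self._by_id: dict[str, GenomicInterval] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        if not iv.id:
            iv = replace(iv, id=f"region_{len(self._intervals) + 1}")
        if iv.id in self._by_id:
            raise ValueError(f"duplicate interval id {iv.id!r} in set {self.name!r}")
        self._intervals.append(iv)
        self._by_id[iv.id] = iv

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, region_id: str) -> GenomicInterval:
        return self._by_id[region_id]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self._intervals]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (data = interval id)."""
        out: dict[str, IntervalTree] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.id)
        return out

    def total_span(self) -> int:
        """Total number of bases covered by the union of the set."""
        return sum(len(iv) for iv in merge_overlapping(self))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site.

    ``tss`` is the 0-based coordinate of the first transcribed base;
    strand is required because promoter windows are strand-aware.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")


# ---------------------------------------------------------------------------
# BED / annotation I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> RegionSet:
    """Read a BED3/BED6 file into a :class:`RegionSet`.

    Missing name fields get sequential ids; duplicate names are de-duplicated
    with ``.2``, ``.3`` ... suffixes (a warning is logged). Malformed lines
    raise :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else UNSTRANDED
            if not name:
                name = f"region_{lineno}"
            if name in seen:
                seen[name] += 1
                new = f"{name}.{seen[name]}"
                logger.warning("%s:%d: duplicate name %r renamed to %r", path, lineno, name, new)
                name = new
            else:
                seen[name] = 1
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return RegionSet(intervals, name=str(path))


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read genes from a 4-column TSV (gene_id, chrom, strand, tss).

    A header line starting with ``gene_id`` is permitted and skipped.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                tss = int(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer tss") from exc
            genes.append(GeneAnnotation(fields[0], fields[1], fields[2], tss))
    return genes


def genes_from_bed(regions: RegionSet) -> list[GeneAnnotation]:
    """Interpret a BED6 RegionSet as genes: TSS = start on +, end-1 on -."""
    genes = []
    for iv in regions:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"gene {iv.id}: strand required in BED6 gene annotation")
        tss = iv.start if iv.strand == "+" else iv.end - 1
        genes.append(GeneAnnotation(iv.id, iv.chrom, iv.strand, tss))
    return genes


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def intersect_any(query: RegionSet, subject: RegionSet) -> dict[str, list[str]]:
    """Map every query id to the ids of overlapping subject intervals.

    Overlap means >= 1 shared base under half-open arithmetic. Every query id
    appears in the result, possibly with an empty list.
    """
    trees = subject.trees()
    out: dict[str, list[str]] = {}
    for iv in query:
        tree = trees.get(iv.chrom)
        if tree is None:
            out[iv.id] = []
        else:
            out[iv.id] = sorted(hit.data for hit in tree.overlap(iv.start, iv.end))
    return out


def merge_overlapping(regions: RegionSet | Iterable[GenomicInterval]) -> RegionSet:
    """Merge overlapping intervals into a sorted, disjoint RegionSet.

    Adjacent intervals (``end == start``) are NOT merged, consistent with
    half-open semantics. Merged ids are ``merged_1 .. merged_k`` in
    (chrom, start) order; strand information is dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict: adjacency does not merge
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return RegionSet(
        (replace(iv, id=f"merged_{i+1}") for i, iv in enumerate(merged)),
        name="merged",
    )


def promoter_window(
    gene: GeneAnnotation,
    upstream: int = 2000,
    downstream: int = 1000,
    strand_aware: bool = True,
) -> GenomicInterval:
    """The promoter window around a gene's TSS.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand is the
    coordinate mirror ``[tss - downstream, tss + upstream)``. Coordinates are
    clipped at 0 (so windows near chromosome starts are shorter). With
    ``strand_aware=False`` every gene is treated as plus-strand.
    """
    if upstream < 0 or downstream < 0 or (upstream == 0 and downstream == 0):
        raise ValueError("window sizes must be >= 0 and not both 0")
    plus = gene.strand == "+" or not strand_aware
    if plus:
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand, f"{gene.gene_id}_prom")


def promoter_windows(
    genes: Iterable[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 1000,
    strand_aware: bool = True,
) -> RegionSet:
    return RegionSet(
        (promoter_window(g, upstream, downstream, strand_aware) for g in genes),
        name="promoters",
    )


def assign_cpg_promoters(
    genes: Iterable[GeneAnnotation],
    cpg_islands: RegionSet,
    upstream: int = 5000,
    downstream: int = 2500,
) -> dict[str, bool]:
    """Flag genes whose CpG window (5 kb upstream to 2.5 kb downstream of the
    TSS by default) overlaps any CpG island."""
    trees = cpg_islands.trees()
    out: dict[str, bool] = {}
    for gene in genes:
        win = promoter_window(gene, upstream, downstream)
        tree = trees.get(win.chrom)
        out[gene.gene_id] = bool(tree is not None and tree.overlap(win.start, win.end))
    return out


def nearest_distance(query: GenomicInterval, subjects: RegionSet) -> int | None:
    """Distance in bp from ``query`` to the nearest subject on the same
    chromosome (0 if overlapping); ``None`` if that chromosome has no subject.

    The gap between half-open ``[100,200)`` and ``[300,400)`` is 100 bp
    (bases 200..299).
    """
    best: int | None = None
    for iv in subjects:
        if iv.chrom != query.chrom:
            continue
        dist = max(0, iv.start - query.end, query.start - iv.end)
        if best is None or dist < best:
            best = dist
    return best


def nearest_distances(
    query: RegionSet, subjects: RegionSet | Iterable[GenomicInterval]
) -> dict[str, int | None]:
    """:func:`nearest_distance` for every query interval, against the *merged*
    subject set (merging makes sorted-array gap arithmetic exact)."""
    merged = merge_overlapping(subjects)
    subj = merged.by_chrom()
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in subj.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in subj.items()}
    out: dict[str, int | None] = {}
    for iv in query:
        if iv.chrom not in starts:
            out[iv.id] = None
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]  # parallel, sorted, disjoint
        i = np.searchsorted(s, iv.end)  # first subject fully right of query
        right = int(s[i] - iv.end) if i < len(s) else None
        j = np.searchsorted(e, iv.start, side="right") - 1  # last fully left
        left = int(iv.start - e[j]) if j >= 0 else None
        if i - (j + 1) > 0:  # at least one subject neither left nor right
            out[iv.id] = 0
        else:
            candidates = [d for d in (right, left) if d is not None]
            out[iv.id] = min(candidates) if candidates else None
    return out


def read_chrom_sizes(path) -> Mapping[str, int]:
    """Read a 2-column (chrom, size) TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes
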