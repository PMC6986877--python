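"""From read positions to differential regions.

Reads are simplified to single 5' genomic positions (chrom, pos). The
module counts reads per region per sample, normalizes counts by library
size on a log2 scale with a pseudo-count of 1, calls peaks with a
fixed-window Poisson caller (a documented simplified stand-in for
MACS2/CisGenome — real peak calls may be supplied as BED and the caller
bypassed), and tests wild-type vs mutant signal with the empirical-Bayes
moderated t, flagging per-condition peak presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, RegionSet, intersect_any
from .stats import ModeratedTPrior, bh_fdr, moderated_t

logger = logging.getLogger(__name__)

CONDITIONS = ("condition_a", "condition_b", "input_a", "input_b")

#: Columns of the differential-result table.
DIFF_COLUMNS = [
    "region_id", "chrom", "start", "end",
    "mean_a", "mean_b", "log2fc", "t", "df", "p", "q",
    "presence_a", "presence_b", "peak_type",
]


@dataclass
class CountMatrix:
    """Per-region, per-sample read counts with sample metadata.

    ``counts`` is a DataFrame indexed by region id with one column per
    sample; ``samples`` maps sample id -> (condition, library_size).
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    library_sizes: dict[str, int]
    regions: RegionSet | None = None

    def __post_init__(self) -> None:
        for sample in self.counts.columns:
            if sample not in self.conditions:
                raise ValueError(f"sample {sample!r} has no condition label")
            if self.conditions[sample] not in CONDITIONS:
                raise ValueError(
                    f"sample {sample!r}: condition must be one of {CONDITIONS}"
                )
            lib = self.library_sizes.get(sample)
            if lib is None or lib <= 0:
                raise ValueError(f"sample {sample!r}: positive library_size required")
            if len(self.counts) and lib < int(self.counts[sample].max()):
                raise ValueError(f"sample {sample!r}: library_size below counts")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="region_id")
        meta = pd.DataFrame(
            {
                "sample_id": list(self.counts.columns),
                "condition": [self.conditions[s] for s in self.counts.columns],
                "library_size": [self.library_sizes[s] for s in self.counts.columns],
            }
        )
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path, regions: RegionSet | None = None):
        counts = pd.read_csv(counts_path, sep="\t", index_col="region_id")
        meta = pd.read_csv(samples_path, sep="\t")
        return cls(
            counts=counts,
            conditions=dict(zip(meta["sample_id"], meta["condition"])),
            library_sizes=dict(zip(meta["sample_id"], meta["library_size"].astype(int))),
            regions=regions,
        )


@dataclass(frozen=True)
class PeakCall:
    """A called peak: interval, log2 enrichment over background, q-value."""

    interval: GenomicInterval
    log2_enrichment: float
    q: float

    def __post_init__(self) -> None:
        if not (0 <= self.q <= 1):
            raise ValueError("q must lie in [0, 1]")


ReadPositions = Mapping[str, np.ndarray]  # chrom -> sorted-able positions


def read_positions_from_tsv(path) -> dict[str, np.ndarray]:
    """Read a 2-column (chrom, position) TSV of simplified reads."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"])
    return {
        chrom: grp["pos"].to_numpy(dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=True)
    }


def count_reads_in_regions(
    read_positions: Mapping[str, ReadPositions],
    regions: RegionSet,
    conditions: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Count, per sample, the reads whose position falls in each region.

    A read at position p is counted for region [start, end) iff
    start <= p < end; overlapping regions each count the read. Library
    size is the total number of reads in the sample.
    """
    by_chrom = regions.by_chrom()
    region_ids = regions.ids
    data: dict[str, np.ndarray] = {}
    library_sizes: dict[str, int] = {}
    for sample, reads in read_positions.items():
        col = pd.Series(0, index=region_ids, dtype=np.int64)
        total = 0
        known = set(by_chrom)
        for chrom, pos in reads.items():
            pos = np.sort(np.asarray(pos, dtype=np.int64))
            if np.any(pos < 0):
                raise ValueError(f"sample {sample!r}: negative read position")
            total += pos.size
            if chrom not in known:
                logger.warning(
                    "sample %s: chromosome %s absent from region set", sample, chrom
                )
                continue
            ivs = by_chrom[chrom]
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            hits = np.searchsorted(pos, ends, side="left") - np.searchsorted(
                pos, starts, side="left"
            )
            col[[iv.id for iv in ivs]] += hits
        data[sample] = col.to_numpy()
        library_sizes[sample] = max(1, int(total))  # keep library sizes positive
    counts = pd.DataFrame(data, index=pd.Index(region_ids, name="region_id"))
    if conditions is None:
        conditions = {s: "condition_a" for s in counts.columns}
    return CountMatrix(
        counts=counts,
        conditions=dict(conditions),
        library_sizes=library_sizes,
        regions=regions,
    )


def normalize_log2(
    counts: CountMatrix, reference_depth: int | None = None
) -> pd.DataFrame:
    """Library-size-adjusted log2 counts with a pseudo-count of 1:
    ``log2(count * reference_depth / library_size + 1)``.

    ``reference_depth`` defaults to the median library size.
    """
    libs = np.array([counts.library_sizes[s] for s in counts.counts.columns], dtype=float)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    if reference_depth is None:
        reference_depth = float(np.median(libs))
    scaled = counts.counts.to_numpy(dtype=float) * (reference_depth / libs)
    return pd.DataFrame(
        np.log2(scaled + 1.0), index=counts.counts.index, columns=counts.counts.columns
    )


def call_peaks_fixed_windows(
    read_positions: ReadPositions,
    chrom_sizes: Mapping[str, int],
    window: int = 200,
    q_cutoff: float = 0.05,
    background: str | float = "median",
) -> list[PeakCall]:
    """Simplified fixed-window peak caller.

    Tiles each chromosome with non-overlapping windows of ``window`` bp,
    tests each window's read count against a genome-wide uniform
    background rate with a one-sided Poisson test, corrects across all
    windows with Benjamini-Hochberg, and merges runs of adjacent
    significant windows. Merged peaks carry the minimum q and the
    length-weighted mean log2 enrichment of their windows.

    ``background`` selects the background-rate estimate:

    * ``"median"`` (default) — median full-width window count plus 1/3
      (the Poisson median-to-mean correction), which is robust to the
      minority of signal-carrying windows;
    * ``"mean"``   — total reads / genome size;
    * a float      — a fixed rate in reads per bp.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    for chrom in read_positions:
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} absent from chrom_sizes")
    genome = float(sum(chrom_sizes.values()))
    if genome <= 0:
        raise ValueError("chromosome sizes must be positive")
    total_reads = int(sum(len(p) for p in read_positions.values()))
    if total_reads == 0:
        logger.warning("no reads supplied; returning no peaks")
        return []

    chrom_windows: list[tuple[str, np.ndarray, np.ndarray]] = []  # chrom, counts, widths
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_win = -(-size // window)
        counts = np.zeros(n_win, dtype=np.int64)
        pos = np.asarray(read_positions.get(chrom, np.array([], dtype=np.int64)))
        if pos.size:
            if np.any((pos < 0) | (pos >= size)):
                raise ValueError(f"read position outside chromosome {chrom}")
            np.add.at(counts, pos // window, 1)
        widths = np.full(n_win, window, dtype=np.int64)
        widths[-1] = size - (n_win - 1) * window
        chrom_windows.append((chrom, counts, widths))

    if background == "mean":
        rate = total_reads / genome
    elif background == "median":
        full = np.concatenate(
            [c[w == window] for _, c, w in chrom_windows]
        )
        med = float(np.median(full)) if full.size else 0.0
        rate = max((med + 1.0 / 3.0) / window, total_reads / genome / 100.0)
    else:
        rate = float(background)
        if rate <= 0:
            raise ValueError("fixed background rate must be positive")

    pvals: list[np.ndarray] = []
    for _, counts, widths in chrom_windows:
        lam = rate * widths
        # P(X >= count) under Poisson background
        pvals.append(sps.poisson.sf(counts - 1, lam))

    q = bh_fdr(np.concatenate(pvals))
    peaks: list[PeakCall] = []
    offset = 0
    idx = 1
    for chrom, counts, widths in chrom_windows:
        n_win = counts.size
        qc = q[offset : offset + n_win]
        offset += n_win
        sig = qc < q_cutoff
        lam = rate * widths
        i = 0
        while i < n_win:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_win and sig[j + 1]:
                j += 1
            start = i * window
            end = min(j * window + int(widths[j]), int(chrom_sizes[chrom]))
            w = widths[i : j + 1].astype(float)
            enr = np.log2(counts[i : j + 1] / lam[i : j + 1])
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(chrom, start, end, id=f"peak_{idx}"),
                    log2_enrichment=float(np.average(enr, weights=w)),
                    q=float(qc[i : j + 1].min()),
                )
            )
            idx += 1
            i = j + 1
    return peaks


def peaks_to_regionset(peaks: Sequence[PeakCall], name: str = "peaks") -> RegionSet:
    return RegionSet((p.interval for p in peaks), name=name)


def differential_regions(
    counts: CountMatrix,
    peaks_a: RegionSet,
    peaks_b: RegionSet,
    fdr: float = 0.05,
    reference_depth: int | None = None,
    prior: ModeratedTPrior | str = "estimate",
) -> pd.DataFrame:
    """Test condition_a vs condition_b signal over the count-matrix regions.

    The count matrix is expected to cover the merged union of the two
    peak sets. Counts are normalized with :func:`normalize_log2`, tested
    per region with the moderated t, and BH-corrected. Peak presence per
    condition comes from overlap with ``peaks_a`` / ``peaks_b`` and is
    summarized as ``peak_type`` in {shared, a_only, b_only, neither}.

    Returns a DataFrame with :data:`DIFF_COLUMNS`.
    """
    if counts.regions is None:
        raise ValueError("CountMatrix must carry its RegionSet for overlap flags")
    sa = counts.samples_for("condition_a")
    sb = counts.samples_for("condition_b")
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition")
    norm = normalize_log2(counts, reference_depth)
    g1 = norm[sa].to_numpy().T  # replicates x regions
    g2 = norm[sb].to_numpy().T
    t, df, p = moderated_t(g1, g2, prior=prior)
    q = bh_fdr(p)

    ov_a = intersect_any(counts.regions, peaks_a)
    ov_b = intersect_any(counts.regions, peaks_b)
    if not any(ov_a.values()) and not any(ov_b.values()):
        logger.warning("count-matrix regions overlap no peaks in either condition")

    rows = []
    mean_a = g1.mean(axis=0)
    mean_b = g2.mean(axis=0)
    for i, iv in enumerate(counts.regions):
        pa = bool(ov_a[iv.id])
        pb = bool(ov_b[iv.id])
        peak_type = {
            (True, True): "shared",
            (True, False): "a_only",
            (False, True): "b_only",
            (False, False): "neither",
        }[(pa, pb)]
        rows.append(
            (
                iv.id, iv.chrom, iv.start, iv.end,
                mean_a[i], mean_b[i], mean_a[i] - mean_b[i],
                t[i], df[i], p[i], q[i], pa, pb, peak_type,
            )
        )
    out = pd.DataFrame(rows, columns=DIFF_COLUMNS)
    out.attrs["fdr"] = fdr
    return out
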