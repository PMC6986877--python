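"""End-to-end orchestration of the GBR analysis stages.

The pipeline mirrors the study design: call acetylation peaks per
condition, merge them, count reads, test differential signal, classify
GBRs by response, test positional enrichment near target-gene TSSs,
compare accessibility between classes and score GLI motifs. Every stage
is a pure function over in-memory objects; file I/O lives at the edges
so the CLI stays thin and the stages stay testable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import diff as _diff
from . import motifs as _motifs
from . import permutation as _perm
from .intervals import (
    GeneAnnotation,
    RegionSet,
    merge_overlapping,
    read_bed,
    read_chrom_sizes,
    read_gene_table,
    write_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Thresholds and sizes used across stages."""

    seed: int = 0
    fdr: float = 0.05
    peak_window: int = 200
    peak_q: float = 0.05
    motif_bits: float = 12.0
    n_perm: int = 1000
    promoter_upstream: int = 2000
    promoter_downstream: int = 1000
    max_neighbor_distance: int = 100_000

    def validate(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")
        if not (0 < self.peak_q <= 1):
            raise ValueError("peak q cutoff must lie in (0, 1]")
        if self.peak_window <= 0:
            raise ValueError("peak window must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class BundlePaths:
    """Input files of an analysis bundle (as produced by the simulator)."""

    directory: Path

    def __post_init__(self) -> None:
        self.directory = Path(self.directory)

    def file(self, name: str) -> Path:
        p = self.directory / name
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        return p

    def read_samples(self, prefix: str) -> dict[str, dict[str, np.ndarray]]:
        reads_dir = self.file("reads")
        out = {}
        for p in sorted(reads_dir.glob(f"{prefix}*.tsv")):
            out[p.stem] = _diff.read_positions_from_tsv(p)
        if not out:
            raise FileNotFoundError(f"no {prefix}* read files under {reads_dir}")
        return out


def pooled_reads(samples: dict[str, dict[str, np.ndarray]], names: list[str]):
    """Concatenate read positions of several samples per chromosome."""
    pooled: dict[str, list[np.ndarray]] = {}
    for name in names:
        for chrom, pos in samples[name].items():
            pooled.setdefault(chrom, []).append(np.asarray(pos))
    return {c: np.sort(np.concatenate(parts)) for c, parts in pooled.items()}


def diffpeaks_stage(
    chip_reads: dict,
    conditions: dict,
    chrom_sizes: dict,
    params: PipelineParams,
) -> tuple[RegionSet, RegionSet, pd.DataFrame]:
    """Peak calling per condition, merge, count, differential test."""
    names_a = [s for s in chip_reads if conditions[s] == "condition_a"]
    names_b = [s for s in chip_reads if conditions[s] == "condition_b"]
    peaks_a = _diff.peaks_to_regionset(
        _diff.call_peaks_fixed_windows(
            pooled_reads(chip_reads, names_a), chrom_sizes,
            window=params.peak_window, q_cutoff=params.peak_q,
        ),
        name="peaks_a",
    )
    peaks_b = _diff.peaks_to_regionset(
        _diff.call_peaks_fixed_windows(
            pooled_reads(chip_reads, names_b), chrom_sizes,
            window=params.peak_window, q_cutoff=params.peak_q,
        ),
        name="peaks_b",
    )
    merged = merge_overlapping(list(peaks_a) + list(peaks_b))
    counts = _diff.count_reads_in_regions(chip_reads, merged, conditions)
    diff = _diff.differential_regions(counts, peaks_a, peaks_b, fdr=params.fdr)
    return peaks_a, peaks_b, diff


def classify_stage(
    gbrs: RegionSet,
    diff: pd.DataFrame,
    genes: list[GeneAnnotation],
    cpg_islands: RegionSet | None,
    params: PipelineParams,
    comarks: dict[str, RegionSet] | None = None,
) -> pd.DataFrame:
    classes = _classify.classify_gbrs(gbrs, diff, fdr=params.fdr)
    classes = _classify.annotate_promoters(
        classes, gbrs, genes, cpg_islands,
        upstream=params.promoter_upstream, downstream=params.promoter_downstream,
    )
    if comarks:
        classes = _classify.annotate_comarks(classes, gbrs, comarks)
    return classes


def enrichment_stage(
    classes: pd.DataFrame,
    gbrs: RegionSet,
    target_genes: list[str],
    genes: list[GeneAnnotation],
    params: PipelineParams,
) -> dict:
    """Permutation enrichment of each GBR class near target-gene TSSs."""
    results = {}
    subsets = {
        "hh_dependent": classes[classes["label"] == "hh_dependent"],
        "hh_responsive": classes[classes["label"].isin(_classify.RESPONSIVE)],
        "stable": classes[classes["label"] == "stable"],
    }
    for name, sub in subsets.items():
        if sub.empty:
            results[name] = None
            continue
        regions = RegionSet((gbrs[g] for g in sub["gbr_id"]), name=name)
        res = _perm.tss_enrichment_test(
            regions, target_genes, genes,
            upstream=params.promoter_upstream,
            downstream=params.promoter_downstream,
            n_perm=params.n_perm,
            seed=params.seed,
        )
        results[name] = res.to_dict()
    return results


def accessibility_stage(
    atac_counts: _diff.CountMatrix, classes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized per-GBR accessibility per condition + class comparisons."""
    norm = _diff.normalize_log2(atac_counts)
    sa = atac_counts.samples_for("condition_a")
    sb = atac_counts.samples_for("condition_b")
    signal = pd.DataFrame(
        {"condition_a": norm[sa].mean(axis=1), "condition_b": norm[sb].mean(axis=1)}
    )
    return signal, _classify.accessibility_compare(signal, classes)


def motif_stage(
    classes: pd.DataFrame,
    gbrs: RegionSet,
    fasta,
    params: PipelineParams,
    pwm: _motifs.Pwm | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scan classified (acetylated) GBRs and compare per-class statistics."""
    if pwm is None:
        pwm = _motifs.default_gli_pwm()
    acetylated = classes[classes["label"].isin(("stable",) + _classify.RESPONSIVE)]
    stats_by_class: dict[str, pd.DataFrame] = {}
    all_stats = []
    for label, grp in acetylated.groupby("label"):
        regions = RegionSet((gbrs[g] for g in grp["gbr_id"]), name=label)
        df = _motifs.scan_regions_fasta(pwm, fasta, regions, threshold=params.motif_bits)
        stats_by_class[label] = df
        all_stats.append(df.assign(label=label))
    report = (
        _motifs.compare_motif_stats(stats_by_class, reference="stable")
        if "stable" in stats_by_class and len(stats_by_class) >= 2
        else {"classes": {}, "tests": {}}
    )
    stats = pd.concat(all_stats, ignore_index=True) if all_stats else pd.DataFrame(
        columns=["region_id", "has_motif", "quantity", "quality", "label"]
    )
    return stats, report


def recovery_report(classes: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Planted-label recovery per class (synthetic bundles only)."""
    merged = truth.merge(
        classes[["gbr_id", "label"]], on="gbr_id", how="left", validate="1:1"
    )
    out = {}
    for cls, grp in merged.groupby("true_class"):
        out[cls] = {
            "n_planted": int(len(grp)),
            "n_recovered": int((grp["label"] == cls).sum()),
            "recovery": float((grp["label"] == cls).mean()),
        }
    return out


@dataclass
class PipelineResult:
    peaks_a: RegionSet
    peaks_b: RegionSet
    diff: pd.DataFrame
    classes: pd.DataFrame
    summary: dict
    enrichment: dict
    accessibility_signal: pd.DataFrame
    accessibility: pd.DataFrame
    motif_stats: pd.DataFrame
    motif_report: dict
    tss_table: tuple
    recovery: dict | None = None


def run_all(bundle_dir, params: PipelineParams) -> PipelineResult:
    """Run every stage on a bundle directory (simulator layout)."""
    params.validate()
    paths = BundlePaths(bundle_dir)
    chrom_sizes = dict(read_chrom_sizes(paths.file("chrom_sizes.tsv")))
    genes = read_gene_table(paths.file("genes.tsv"))
    target_genes = [
        line.strip() for line in open(paths.file("target_genes.txt")) if line.strip()
    ]
    gbrs = read_bed(paths.file("gbrs.bed"))
    cpg = read_bed(paths.file("cpg_islands.bed"))
    chip_reads = paths.read_samples("chip_")
    chip_reads.update(paths.read_samples("input_"))
    atac_reads = paths.read_samples("atac_")
    conditions = {}
    for s in list(chip_reads) + list(atac_reads):
        if s.startswith(("chip_a", "atac_a")):
            conditions[s] = "condition_a"
        elif s.startswith(("chip_b", "atac_b")):
            conditions[s] = "condition_b"
        else:
            conditions[s] = "input_a" if "a" in s.split("_") else "input_b"

    peaks_a, peaks_b, diff = diffpeaks_stage(chip_reads, conditions, chrom_sizes, params)

    # WT ATAC peaks provide the accessibility co-mark flag
    atac_names = [s for s in atac_reads if conditions[s] == "condition_a"]
    atac_peaks = _diff.peaks_to_regionset(
        _diff.call_peaks_fixed_windows(
            pooled_reads(atac_reads, atac_names), chrom_sizes,
            window=params.peak_window, q_cutoff=params.peak_q,
        ),
        name="atac_a",
    )
    classes = classify_stage(
        gbrs, diff, genes, cpg, params, comarks={"atac": atac_peaks}
    )
    summary = _classify.summarize_classes(classes)
    tss_table = _classify.tss_distribution_test(
        classes, gbrs, genes,
        upstream=params.promoter_upstream, downstream=params.promoter_downstream,
    )
    enrichment = enrichment_stage(classes, gbrs, target_genes, genes, params)

    atac_counts = _diff.count_reads_in_regions(atac_reads, gbrs, conditions)
    signal, accessibility = accessibility_stage(atac_counts, classes)

    import pyfaidx

    fasta = pyfaidx.Fasta(str(paths.file("genome.fa")))
    motif_stats, motif_report = motif_stage(classes, gbrs, fasta, params)

    recovery = None
    truth_path = paths.directory / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        if len(truth):
            recovery = recovery_report(classes, truth)

    return PipelineResult(
        peaks_a=peaks_a, peaks_b=peaks_b, diff=diff, classes=classes,
        summary=summary, enrichment=enrichment,
        accessibility_signal=signal, accessibility=accessibility,
        motif_stats=motif_stats, motif_report=motif_report,
        tss_table=tss_table, recovery=recovery,
    )


def write_outputs(result: PipelineResult, outdir, params: PipelineParams) -> dict:
    """Write every stage's outputs under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(result.peaks_a, outdir / "peaks_a.bed")
    write_bed(result.peaks_b, outdir / "peaks_b.bed")
    result.diff.to_csv(outdir / "differential.tsv", sep="\t", index=False, float_format="%.6g")
    result.classes.to_csv(outdir / "classification.tsv", sep="\t", index=False, float_format="%.6g")
    result.accessibility_signal.to_csv(
        outdir / "accessibility_signal.tsv", sep="\t", index_label="gbr_id", float_format="%.6g"
    )
    result.accessibility.to_csv(outdir / "accessibility_tests.tsv", sep="\t", index=False, float_format="%.6g")
    result.motif_stats.to_csv(outdir / "motif_stats.tsv", sep="\t", index=False, float_format="%.6g")
    table, p = result.tss_table
    report = {
        "summary": result.summary,
        "tss_distribution": {
            "table": {"stable_proximal": table.a, "stable_distal": table.b,
                      "responsive_proximal": table.c, "responsive_distal": table.d},
            "fisher_p_two_sided": p,
        },
        "enrichment": result.enrichment,
        "motifs": result.motif_report,
    }
    if result.recovery is not None:
        report["recovery"] = result.recovery
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "params": dataclasses.asdict(params),
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.glob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
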