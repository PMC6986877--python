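"""Seeded synthetic dataset with planted ground truth.

The generator builds a toy genome with annotated genes and CpG islands,
plants GLI binding regions (GBRs) of four response classes, embeds GLI
motif instances at class-dependent rates, and simulates simplified
ChIP/ATAC reads for two conditions with replicates:

* ``stable``         — equal acetylation signal in both conditions;
* ``hh_sensitive``   — signal reduced by a configurable log2 drop in
  condition_b (mutant / no signaling);
* ``hh_dependent``   — condition_b signal is pure background;
* ``non_acetylated`` — background only in both conditions.

Counts are negative-binomial (gamma-Poisson) with shared dispersion, on
top of a uniform genomic background; samples carry different library
sizes. Identical seed + config produce a byte-identical file bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diff import CountMatrix, count_reads_in_regions
from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    RegionSet,
    intersect_any,
    promoter_windows,
    write_bed,
)
from .motifs import GLI_CONSENSUS

logger = logging.getLogger(__name__)

CLASSES = ("stable", "hh_sensitive", "hh_dependent", "non_acetylated")

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset. ``seed`` is mandatory.

    Defaults are desk-scale study conditions: a 3.5 Mb genome, 300 genes
    (10% signaling targets), 300/60/60/30 planted GBRs per class, 1 kb
    regions with a baseline of 300 signal reads, a 1.5 log2 sensitive
    drop, motif planting rates mirroring the observed per-class motif
    presence (69.7% / 57.4% / 39.5%) and extra-motif rates mirroring the
    observed motif densities (1.51 / 1.47 / 1.27 per motif-positive
    region).
    """

    seed: int
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_200_000, "chr3": 800_000}
    )
    n_genes: int = 300
    fraction_target_genes: float = 0.15
    n_gbr: dict = field(
        default_factory=lambda: {
            "stable": 300, "hh_sensitive": 60, "hh_dependent": 60, "non_acetylated": 30,
        }
    )
    gbr_length: int = 1000
    min_gbr_gap: int = 1000
    promoter_bias: dict = field(
        default_factory=lambda: {
            "stable": 0.62, "hh_sensitive": 0.26, "hh_dependent": 0.26,
            "non_acetylated": 0.20,
        }
    )
    baseline_mean: float = 500.0
    sensitive_drop_log2: float = 1.5
    nb_dispersion: float = 0.02
    n_replicates: int = 2
    background_reads: int = 300_000
    chip_scales_a: tuple = (1.0, 1.25)
    chip_scales_b: tuple = (0.85, 1.10)
    input_scales: tuple = (1.0, 1.0)
    atac_background_reads: int = 30_000
    atac_scales_a: tuple = (1.0, 1.15)
    atac_scales_b: tuple = (0.90, 1.05)
    atac_mean_a: dict = field(
        default_factory=lambda: {
            "stable": 250.0, "hh_sensitive": 110.0, "hh_dependent": 90.0,
            "non_acetylated": 60.0,
        }
    )
    atac_mean_b: dict = field(
        default_factory=lambda: {
            "stable": 250.0, "hh_sensitive": 75.0, "hh_dependent": 45.0,
            "non_acetylated": 60.0,
        }
    )
    cpg_fraction: float = 0.5
    cpg_length: int = 500
    motif_rates: dict = field(
        default_factory=lambda: {
            "stable": 0.395, "hh_sensitive": 0.574, "hh_dependent": 0.697,
            "non_acetylated": 0.395,
        }
    )
    extra_motif_poisson: dict = field(
        default_factory=lambda: {
            "stable": 0.27, "hh_sensitive": 0.47, "hh_dependent": 0.51,
            "non_acetylated": 0.27,
        }
    )
    motif_scan_bits: float = 12.0
    promoter_upstream: int = 2000
    promoter_downstream: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, rate in self.motif_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"motif rate for {name} outside [0, 1]")
        for name, bias in self.promoter_bias.items():
            if not 0 <= bias <= 1:
                raise ValueError(f"promoter bias for {name} outside [0, 1]")
        if any(v < 0 for v in self.n_gbr.values()):
            raise ValueError("n_gbr values must be >= 0")
        for scales in (self.chip_scales_a, self.chip_scales_b, self.input_scales,
                       self.atac_scales_a, self.atac_scales_b):
            if len(scales) != self.n_replicates:
                raise ValueError("per-replicate scale tuples must match n_replicates")

    def mean_for(self, cls: str, condition: str) -> float:
        """Expected acetylation signal reads per region (unscaled)."""
        if cls == "stable":
            return self.baseline_mean
        if cls == "hh_sensitive":
            return (
                self.baseline_mean
                if condition == "a"
                else self.baseline_mean / 2.0**self.sensitive_drop_log2
            )
        if cls == "hh_dependent":
            return self.baseline_mean if condition == "a" else 0.0
        return 0.0  # non_acetylated

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticBundle:
    """File bundle plus in-memory handles to the generated objects."""

    directory: Path
    config: SimulationConfig
    gbrs: RegionSet
    genes: list
    target_genes: list
    cpg_islands: RegionSet
    truth: pd.DataFrame
    chip_reads: dict  # sample -> {chrom: positions}
    atac_reads: dict
    counts: CountMatrix
    atac_counts: CountMatrix
    sequences: dict  # chrom -> str

    @property
    def chip_conditions(self) -> dict:
        return {s: _condition_of(s) for s in self.chip_reads}

    def path(self, name: str) -> Path:
        return self.directory / name


def _condition_of(sample: str) -> str:
    if sample.startswith(("chip_a", "atac_a")):
        return "condition_a"
    if sample.startswith(("chip_b", "atac_b")):
        return "condition_b"
    if sample.startswith("input_a"):
        return "input_a"
    return "input_b"


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draw as gamma-Poisson; Poisson when dispersion ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * np.maximum(mean, 0.0))
    return rng.poisson(lam)


def _place_genes(rng, config) -> tuple[list, list]:
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    margin = 12_000
    genes = []
    for i in range(config.n_genes):
        chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        tss = int(rng.integers(margin, config.chrom_sizes[chrom] - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"gene_{i+1:04d}", chrom, strand, tss))
    n_targets = int(round(config.n_genes * config.fraction_target_genes))
    target_idx = rng.choice(config.n_genes, size=n_targets, replace=False)
    targets = sorted(genes[i].gene_id for i in target_idx)
    return genes, targets


def _place_cpg(rng, config, genes) -> RegionSet:
    islands = []
    for gene in genes:
        if rng.random() >= config.cpg_fraction:
            continue
        lo, hi = -5000, 2500 - config.cpg_length
        off = int(rng.integers(lo, hi + 1))
        if gene.strand == "+":
            start = gene.tss + off
        else:
            start = gene.tss - off - config.cpg_length
        start = max(0, start)
        islands.append(
            GenomicInterval(gene.chrom, start, start + config.cpg_length,
                            id=f"cpg_{gene.gene_id}")
        )
    return RegionSet(islands, name="cpg_islands")


def _place_gbrs(rng, config, genes, targets) -> tuple[RegionSet, pd.DataFrame]:
    target_set = set(targets)
    target_genes = [g for g in genes if g.gene_id in target_set]
    other_genes = [g for g in genes if g.gene_id not in target_set]
    occupied: dict[str, list] = {c: [] for c in config.chrom_sizes}
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    up, down, L = config.promoter_upstream, config.promoter_downstream, config.gbr_length

    def free(chrom: str, start: int, end: int) -> bool:
        gap = config.min_gbr_gap
        return all(
            not (start - gap < e and s < end + gap) for s, e in occupied[chrom]
        )

    intervals, rows = [], []
    idx = 0
    # responsive classes claim target-gene promoter windows first; the much
    # larger stable class would otherwise saturate shared genomic space and
    # silently erode the planted placement bias
    for cls in ("hh_dependent", "hh_sensitive", "stable", "non_acetylated"):
        for _ in range(config.n_gbr.get(cls, 0)):
            idx += 1
            gbr_id = f"gbr_{idx:04d}"
            placed = False
            for _attempt in range(2000):
                if rng.random() < config.promoter_bias[cls]:
                    pool = (
                        target_genes if cls in ("hh_sensitive", "hh_dependent")
                        else other_genes
                    )
                    if not pool:
                        continue
                    gene = pool[int(rng.integers(len(pool)))]
                    window = up + down - L
                    off = int(rng.integers(0, max(window, 1)))
                    win_start = gene.tss - (up if gene.strand == "+" else down)
                    start = max(0, win_start + off)
                    chrom = gene.chrom
                else:
                    chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
                    start = int(rng.integers(0, config.chrom_sizes[chrom] - L))
                end = start + L
                if end > config.chrom_sizes[chrom]:
                    continue
                if free(chrom, start, end):
                    occupied[chrom].append((start, end))
                    intervals.append(GenomicInterval(chrom, start, end, id=gbr_id))
                    rows.append((gbr_id, chrom, start, end, cls))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "could not place all GBRs without overlap; "
                    "use a larger genome or fewer/shorter regions"
                )
    gbrs = RegionSet(intervals, name="gbrs")
    truth = pd.DataFrame(rows, columns=["gbr_id", "chrom", "start", "end", "true_class"])
    return gbrs, truth


def _build_sequences(rng, config, gbrs, truth) -> tuple[dict, pd.Series]:
    """Uniform ACGT background with consensus motif instances planted in
    GBRs at class-dependent rates. Returns sequences and planted counts."""
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom in sorted(config.chrom_sizes):
        codes = rng.integers(0, 4, size=config.chrom_sizes[chrom])
        seqs[chrom] = bytearray(letters[codes].tobytes())
    motif = GLI_CONSENSUS
    w = len(motif)
    planted = pd.Series(0, index=truth["gbr_id"], dtype=int)
    cls_of = dict(zip(truth["gbr_id"], truth["true_class"]))
    for iv in gbrs:
        cls = cls_of[iv.id]
        if rng.random() >= config.motif_rates[cls]:
            continue
        k = 1 + int(rng.poisson(config.extra_motif_poisson[cls]))
        taken: list[tuple[int, int]] = []
        n_placed = 0
        for _ in range(50 * k):
            if n_placed == k:
                break
            off = int(rng.integers(0, len(iv) - w))
            if any(o < off + w and off < o + lw for o, lw in taken):
                continue
            site = motif if rng.random() < 0.5 else _revcomp(motif)
            pos = iv.start + off
            seqs[iv.chrom][pos : pos + w] = site.encode()
            taken.append((off, w))
            n_placed += 1
        planted[iv.id] = n_placed
    return {c: bytes(s).decode() for c, s in seqs.items()}, planted


def _simulate_sample_reads(
    rng, config, gbrs, truth, means: pd.Series, background_mean: float
) -> dict:
    """Reads for one sample: NB signal per region + uniform background."""
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    positions: dict[str, list] = {c: [] for c in chroms}
    counts = _nb_draw(rng, means.to_numpy(), config.nb_dispersion)
    for iv, n in zip(gbrs, counts):
        if n > 0:
            positions[iv.chrom].append(
                rng.integers(iv.start, iv.end, size=int(n))
            )
    n_bg = int(rng.poisson(background_mean))
    bg_chrom = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
    bg_pos = rng.integers(0, sizes[bg_chrom].astype(np.int64))
    for ci, c in enumerate(chroms):
        positions[c].append(bg_pos[bg_chrom == ci])
    return {
        c: np.sort(np.concatenate(parts)).astype(np.int64) if parts else
        np.array([], dtype=np.int64)
        for c, parts in positions.items()
    }


def _chip_sample_plan(config) -> list[tuple[str, str, float]]:
    """(sample, condition letter or 'input', scale) for chip samples."""
    plan = []
    for r in range(config.n_replicates):
        plan.append((f"chip_a_{r+1}", "a", config.chip_scales_a[r]))
    for r in range(config.n_replicates):
        plan.append((f"chip_b_{r+1}", "b", config.chip_scales_b[r]))
    plan.append(("input_a_1", "input", config.input_scales[0]))
    plan.append(("input_b_1", "input", config.input_scales[1 % len(config.input_scales)]))
    return plan


def _atac_sample_plan(config) -> list[tuple[str, str, float]]:
    plan = []
    for r in range(config.n_replicates):
        plan.append((f"atac_a_{r+1}", "a", config.atac_scales_a[r]))
    for r in range(config.n_replicates):
        plan.append((f"atac_b_{r+1}", "b", config.atac_scales_b[r]))
    return plan


def generate_dataset(config: SimulationConfig, outdir) -> SyntheticBundle:
    """Generate the complete bundle under ``outdir`` and return handles.

    Identical seed + config yield byte-identical files. The bundle
    contains genome FASTA, chrom sizes, gene/TSS table, target-gene
    list, CpG-island BED, GBR BED, per-sample simplified read TSVs
    (ChIP and ATAC), count matrices with sample metadata, the ground
    truth table and a manifest with per-file checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes, targets = _place_genes(rng, config)
    cpg = _place_cpg(rng, config, genes)
    gbrs, truth = _place_gbrs(rng, config, genes, targets)
    sequences, planted = _build_sequences(rng, config, gbrs, truth)

    truth = truth.assign(
        planted_motifs=truth["gbr_id"].map(planted).fillna(0).astype(int)
        if len(truth) else pd.Series(dtype=int),
        mean_a=truth["true_class"].map(lambda c: config.mean_for(c, "a")),
        mean_b=truth["true_class"].map(lambda c: config.mean_for(c, "b")),
    )
    if len(truth):
        windows = promoter_windows(genes, config.promoter_upstream, config.promoter_downstream)
        prox = intersect_any(gbrs, windows)
        truth["promoter_proximal"] = truth["gbr_id"].map(lambda g: bool(prox[g]))
    else:
        truth["promoter_proximal"] = pd.Series(dtype=bool)

    mean_a = pd.Series(truth["mean_a"].to_numpy(), index=truth["gbr_id"]) if len(truth) else pd.Series(dtype=float)
    mean_b = pd.Series(truth["mean_b"].to_numpy(), index=truth["gbr_id"]) if len(truth) else pd.Series(dtype=float)
    zero = mean_a * 0.0

    chip_reads: dict[str, dict] = {}
    for sample, cond, scale in _chip_sample_plan(config):
        means = {"a": mean_a, "b": mean_b, "input": zero}[cond] * scale
        chip_reads[sample] = _simulate_sample_reads(
            rng, config, gbrs, truth, means, config.background_reads * scale
        )
    atac_reads: dict[str, dict] = {}
    atac_a = pd.Series(
        truth["true_class"].map(config.atac_mean_a).to_numpy(), index=truth["gbr_id"]
    ) if len(truth) else pd.Series(dtype=float)
    atac_b = pd.Series(
        truth["true_class"].map(config.atac_mean_b).to_numpy(), index=truth["gbr_id"]
    ) if len(truth) else pd.Series(dtype=float)
    for sample, cond, scale in _atac_sample_plan(config):
        means = (atac_a if cond == "a" else atac_b) * scale
        atac_reads[sample] = _simulate_sample_reads(
            rng, config, gbrs, truth, means, config.atac_background_reads * scale
        )

    conditions = {s: _condition_of(s) for s in list(chip_reads) + list(atac_reads)}
    if len(gbrs):
        counts = count_reads_in_regions(chip_reads, gbrs, conditions)
        atac_counts = count_reads_in_regions(atac_reads, gbrs, conditions)
    else:
        empty = pd.DataFrame(
            {s: pd.Series(dtype=np.int64) for s in chip_reads},
        )
        empty.index.name = "region_id"
        counts = CountMatrix(empty, {s: conditions[s] for s in chip_reads},
                             {s: 1 for s in chip_reads}, regions=gbrs)
        empty_a = pd.DataFrame({s: pd.Series(dtype=np.int64) for s in atac_reads})
        empty_a.index.name = "region_id"
        atac_counts = CountMatrix(empty_a, {s: conditions[s] for s in atac_reads},
                                  {s: 1 for s in atac_reads}, regions=gbrs)

    # ---- write the bundle -------------------------------------------------
    _write_fasta(sequences, outdir / "genome.fa")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(config.chrom_sizes):
            fh.write(f"{chrom}\t{config.chrom_sizes[chrom]}\n")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")
    with open(outdir / "target_genes.txt", "w") as fh:
        for gid in targets:
            fh.write(gid + "\n")
    write_bed(cpg, outdir / "cpg_islands.bed")
    write_bed(gbrs, outdir / "gbrs.bed")
    for sample, reads in {**chip_reads, **atac_reads}.items():
        with open(outdir / "reads" / f"{sample}.tsv", "w") as fh:
            for chrom in sorted(reads):
                for pos in reads[chrom]:
                    fh.write(f"{chrom}\t{pos}\n")
    counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    atac_counts.to_tsv(outdir / "atac_counts.tsv", outdir / "atac_samples.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SyntheticBundle(
        directory=outdir, config=config, gbrs=gbrs, genes=genes,
        target_genes=targets, cpg_islands=cpg, truth=truth,
        chip_reads=chip_reads, atac_reads=atac_reads,
        counts=counts, atac_counts=atac_counts, sequences=sequences,
    )


def regenerate_counts(
    bundle: SyntheticBundle, seed_override: int, condition_b_equals_a: bool = False
) -> CountMatrix:
    """Fresh negative-binomial count draws for the fixed geometry.

    Counts are drawn directly per region and sample (class signal mean x
    sample scale + expected uniform background within the region), which
    enables cheap calibration and power sweeps without re-planting the
    genome. ``condition_b_equals_a`` forces a pure-null draw in which
    condition_b uses the condition_a means.
    """
    config = bundle.config
    truth = bundle.truth
    if truth.empty:
        raise ValueError("bundle has no planted regions; geometry missing")
    rng = np.random.default_rng(seed_override)
    genome = float(sum(config.chrom_sizes.values()))
    bg_per_region = config.background_reads * config.gbr_length / genome
    mean_a = truth["mean_a"].to_numpy()
    mean_b = mean_a if condition_b_equals_a else truth["mean_b"].to_numpy()
    data = {}
    libs = {}
    for sample, cond, scale in _chip_sample_plan(config):
        base = {"a": mean_a, "b": mean_b}.get(cond, np.zeros_like(mean_a))
        means = (base + bg_per_region) * scale
        data[sample] = _nb_draw(rng, means, config.nb_dispersion)
        libs[sample] = int(round((config.background_reads + base.sum()) * scale))
    counts = pd.DataFrame(data, index=pd.Index(truth["gbr_id"], name="region_id"))
    return CountMatrix(
        counts=counts,
        conditions={s: _condition_of(s) for s in counts.columns},
        library_sizes=libs,
        regions=bundle.gbrs,
    )


def _write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
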