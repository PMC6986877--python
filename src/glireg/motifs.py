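"""Position-weight-matrix motif scanning and per-class motif statistics.

A PWM is stored as per-position probabilities over ACGT; scanning scores
every window of a sequence on both strands as the log2 likelihood ratio
(bits) against the background. Per-region summaries are motif presence,
quantity (hit count) and quality (mean hit score over motif-containing
regions); classes of regions are compared with a one-sided proportion
test (presence) and one-sided Wilcoxon rank-sum tests (quantity and
quality over motif-containing regions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import two_proportion_test, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

#: Consensus of the canonical 9-bp GLI binding site.
GLI_CONSENSUS = "GACCACCCA"


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix over ACGT with a background model.

    ``matrix`` has shape (L, 4); rows sum to 1. ``log_odds`` is in bits.
    """

    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0
    name: str = "pwm"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position's probabilities must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=f"{self.name}_rc",
        )


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence; ``offset`` is 0-based on the forward strand."""

    region_id: str
    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class RegionMotifStats:
    """Per-region motif summary: presence, hit count, mean hit score (bits)."""

    region_id: str
    has_motif: bool
    quantity: int
    quality: float  # NaN when has_motif is False

    def __post_init__(self) -> None:
        if self.has_motif != (self.quantity >= 1):
            raise ValueError("has_motif must equal quantity >= 1")


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> Pwm:
    """Build a Pwm from an L x 4 count (or frequency) matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be L x 4")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if background is None:
        background = np.full(4, 0.25)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return Pwm(matrix=probs, background=np.asarray(background, float), pseudocount=pseudocount, name=name)


def load_pwm(path, pseudocount: float = 0.25, background: np.ndarray | None = None) -> Pwm:
    """Load a JASPAR-style text matrix.

    Accepts the bracketed JASPAR layout (four rows ``A [ ... ]`` etc.,
    optionally preceded by a ``>`` header) or a plain whitespace-separated
    4-row numeric matrix in ACGT row order. Counts are converted to
    probabilities with the pseudocount.
    """
    name = "pwm"
    rows: dict[str, list[float]] = {}
    plain: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else name
                continue
            m = re.match(r"^([ACGTacgt])\s*\[?\s*([-\d.\s]+?)\s*\]?$", line)
            if m:
                values = [float(v) for v in m.group(2).split()]
                rows[m.group(1).upper()] = values
            else:
                try:
                    plain.append([float(v) for v in line.replace("[", " ").replace("]", " ").split()])
                except ValueError as exc:
                    raise ValueError(f"{path}: unparseable matrix line {line!r}") from exc
    if rows:
        if set(rows) != set(ALPHABET):
            raise ValueError(f"{path}: need one row per nucleotide ACGT")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{path}: ragged rows")
        counts = np.array([rows[c] for c in ALPHABET]).T
    elif len(plain) == 4:
        lengths = {len(v) for v in plain}
        if len(lengths) != 1:
            raise ValueError(f"{path}: ragged rows")
        counts = np.array(plain).T
    else:
        raise ValueError(f"{path}: expected a 4-row matrix")
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative matrix entries")
    return pwm_from_counts(counts, pseudocount=pseudocount, background=background, name=name)


def default_gli_pwm(pseudocount: float = 0.25, counts_per_site: int = 10) -> Pwm:
    """A GLI-like PWM built from the canonical GACCACCCA consensus.

    This is a documented synthetic stand-in sharp enough for testing and
    simulation; supply a curated database matrix for production scans.
    """
    L = len(GLI_CONSENSUS)
    counts = np.zeros((L, 4))
    for i, base in enumerate(GLI_CONSENSUS):
        counts[i, _CODE[base]] = counts_per_site
    return pwm_from_counts(counts, pseudocount=pseudocount, name="GLI_consensus")


def encode_sequence(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (incl. N) -> -1."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _scan_one_strand(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window; windows containing non-ACGT return -inf."""
    L = log_odds.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(L):
        window_codes = safe[j : j + n]
        scores += log_odds[j, window_codes]
        valid &= codes[j : j + n] >= 0
    scores[~valid] = -np.inf
    return scores


def scan_region(
    pwm: Pwm,
    sequence: str,
    threshold: float = 7.0,
    region_id: str = "",
) -> list[MotifHit]:
    """Exhaustive log-odds scan of a sequence on both strands.

    Every window of the motif width is scored in bits; windows containing
    N are skipped; hits are windows scoring >= ``threshold``. Reverse-
    strand hits report the forward-strand offset of the window.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    codes = encode_sequence(sequence)
    if codes.size < pwm.width:
        return []
    fwd = _scan_one_strand(pwm.log_odds, codes)
    rev = _scan_one_strand(pwm.reverse_complement().log_odds, codes)
    hits: list[MotifHit] = []
    for offset in range(fwd.size):
        if fwd[offset] >= threshold:
            hits.append(MotifHit(region_id, offset, "+", float(fwd[offset])))
        if rev[offset] >= threshold:
            hits.append(MotifHit(region_id, offset, "-", float(rev[offset])))
    return hits


def region_stats(
    hits: Sequence[MotifHit], region_id: str, quality: str = "mean"
) -> RegionMotifStats:
    """Summarize hits for one region; quality is the mean (or max) hit score."""
    if quality not in ("mean", "max"):
        raise ValueError("quality must be 'mean' or 'max'")
    scores = [h.score for h in hits]
    if not scores:
        return RegionMotifStats(region_id, False, 0, float("nan"))
    agg = np.mean(scores) if quality == "mean" else np.max(scores)
    return RegionMotifStats(region_id, True, len(scores), float(agg))


def scan_regions_fasta(
    pwm: Pwm,
    fasta,
    regions,
    threshold: float = 7.0,
    quality: str = "mean",
) -> pd.DataFrame:
    """Scan every region's sequence from an indexed FASTA.

    ``fasta`` is a :class:`pyfaidx.Fasta` (or any mapping of chromosome
    name to sliceable sequence). Returns one row per region with columns
    region_id, has_motif, quantity, quality.
    """
    rows = []
    for iv in regions:
        seq = str(fasta[iv.chrom][iv.start : iv.end])
        st = region_stats(scan_region(pwm, seq, threshold, iv.id), iv.id, quality)
        rows.append((st.region_id, st.has_motif, st.quantity, st.quality))
    return pd.DataFrame(rows, columns=["region_id", "has_motif", "quantity", "quality"])


def compare_motif_stats(
    stats_by_class: Mapping[str, pd.DataFrame],
    reference: str = "stable",
) -> dict:
    """Per-class motif summaries with tests against a reference class.

    For each class: n, fraction of regions with >= 1 motif, and mean
    quantity/quality over motif-containing regions. Each non-reference
    class is tested against the reference with a one-sided two-proportion
    test (presence, with continuity correction) and one-sided Wilcoxon
    rank-sum tests (quantity and quality, restricted to motif-containing
    regions; marked None when a class has no motif-containing regions).
    """
    if len(stats_by_class) < 2:
        raise ValueError("need >= 2 classes to compare")
    if reference not in stats_by_class:
        raise ValueError(f"reference class {reference!r} missing")
    summary: dict[str, dict] = {}
    for name, df in stats_by_class.items():
        if len(df) == 0:
            raise ValueError(f"class {name!r} is empty")
        with_motif = df[df["has_motif"]]
        summary[name] = {
            "n": int(len(df)),
            "n_with_motif": int(len(with_motif)),
            "presence_fraction": float(df["has_motif"].mean()),
            "mean_quantity": float(with_motif["quantity"].mean()) if len(with_motif) else None,
            "mean_quality": float(with_motif["quality"].mean()) if len(with_motif) else None,
        }
    tests: dict[str, dict] = {}
    ref = stats_by_class[reference]
    ref_motif = ref[ref["has_motif"]]
    for name, df in stats_by_class.items():
        if name == reference:
            continue
        cls_motif = df[df["has_motif"]]
        entry: dict = {
            "presence_p": two_proportion_test(
                int(df["has_motif"].sum()), len(df),
                int(ref["has_motif"].sum()), len(ref),
                sided="greater", continuity=True,
            )
        }
        if len(cls_motif) and len(ref_motif):
            entry["quantity_p"] = wilcoxon_rank_sum(
                cls_motif["quantity"], ref_motif["quantity"], sided="greater"
            )
            entry["quality_p"] = wilcoxon_rank_sum(
                cls_motif["quality"], ref_motif["quality"], sided="greater"
            )
        else:
            entry["quantity_p"] = None
            entry["quality_p"] = None
        tests[f"{name}_vs_{reference}"] = entry
    return {"classes": summary, "tests": tests}
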