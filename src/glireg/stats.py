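"""Self-contained statistical kernel for the pipeline.

Implements the tests the analysis relies on: Fisher's exact test on 2x2
tables, the pooled one-/two-sided two-proportion z-test with Yates
continuity correction, the Wilcoxon rank-sum test (exact for small
untied samples, tie-corrected normal approximation otherwise),
Benjamini-Hochberg FDR, the empirical-Bayes moderated t-statistic with
closed-form prior estimation, and qPCR ddCt fold enrichment.

scipy supplies only distribution tails and special functions; the test
logic itself lives here so it can be validated against independent
enumeration oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats as sps

logger = logging.getLogger(__name__)

Sided = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table [[a, b], [c, d]] of non-negative counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("at least one margin must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(
    table: Table2x2,
    sided: Sided = "two_sided",
    two_sided_rule: Literal["point_prob", "double"] = "point_prob",
) -> float:
    """Fisher's exact test with margins fixed.

    The two-sided p is the sum of hypergeometric point probabilities no
    larger than the observed one (within relative tolerance 1e-7); the
    doubling rule (2x the smaller tail, capped at 1) is available as an
    option. Computation runs in log space so large counts stay exact.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = sps.hypergeom.logpmf(ks, n, r1, c1)
    obs = logp[a - lo]
    if sided == "greater":
        sel = ks >= a
    elif sided == "less":
        sel = ks <= a
    elif sided == "two_sided":
        if two_sided_rule == "double":
            upper = float(np.exp(special.logsumexp(logp[ks >= a])))
            lower = float(np.exp(special.logsumexp(logp[ks <= a])))
            return min(1.0, 2.0 * min(upper, lower))
        sel = logp <= obs + math.log1p(1e-7)
    else:
        raise ValueError(f"unknown sided {sided!r}")
    return min(1.0, float(np.exp(special.logsumexp(logp[sel]))))


def two_proportion_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    sided: Sided = "greater",
    continuity: bool = True,
) -> float:
    """Pooled two-proportion z-test (optionally Yates-corrected).

    With ``continuity=True`` the absolute difference of proportions is
    reduced by ``0.5 * (1/n1 + 1/n2)`` (floored at 0) before standardizing.
    ``sided="greater"`` tests p1 > p2.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("require 0 <= x <= n for both samples")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = math.copysign(max(0.0, abs(diff) - cc), diff)
    if se == 0.0:
        z = 0.0
    else:
        z = diff / se
    if sided == "greater":
        return float(sps.norm.sf(z))
    if sided == "less":
        return float(sps.norm.cdf(z))
    if sided == "two_sided":
        return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    raise ValueError(f"unknown sided {sided!r}")


def _rank_sum_exact_cdf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the rank-sum of the first sample over ranks 1..n1+n2
    (no ties), by dynamic programming over subsets."""
    n = n1 + n2
    max_sum = n1 * n + 1
    # counts[k, s] = number of k-subsets of {1..j} with sum s
    counts = np.zeros((n1 + 1, max_sum), dtype=float)
    counts[0, 0] = 1.0
    for j in range(1, n + 1):
        for k in range(min(j, n1), 0, -1):
            counts[k, j:] += counts[k - 1, : max_sum - j]
    pmf = counts[n1] / math.comb(n, n1)
    return pmf


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    sided: Sided = "two_sided",
    exact_max_n: int = 12,
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is <= ``exact_max_n``
    and there are no ties; otherwise a normal approximation with midranks,
    tie-corrected variance and a continuity correction shrinking the
    deviation toward zero (so identical samples give one-sided p = 0.5).
    ``sided="greater"`` tests whether x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = np.unique(combined).size < n

    if n <= exact_max_n and not has_ties:
        pmf = _rank_sum_exact_cdf(n1, n2)
        sums = np.arange(pmf.size)
        wi = int(round(w))
        p_greater = float(pmf[sums >= wi].sum())
        p_less = float(pmf[sums <= wi].sum())
    else:
        mean = n1 * (n + 1) / 2.0
        _, t = np.unique(combined, return_counts=True)
        tie_term = float(((t**3 - t).sum()) / (n * (n - 1))) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p_greater = p_less = 0.5
        else:
            dev = w - mean
            dev = math.copysign(max(0.0, abs(dev) - 0.5), dev)
            z = dev / math.sqrt(var)
            p_greater = float(sps.norm.sf(z))
            p_less = float(sps.norm.cdf(z))

    if sided == "greater":
        return p_greater
    if sided == "less":
        return p_less
    if sided == "two_sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown sided {sided!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values, order-preserving relative to the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeratedTPrior:
    """Prior for the moderated t: d0 prior degrees of freedom (may be
    ``inf``) and s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s_sq: np.ndarray, df: float) -> ModeratedTPrior:
    """Estimate (d0, s0_sq) by moment matching of log sample variances.

    Under the hierarchical model, log(s_g^2/s0^2) is distributed as the
    difference of log chi-squares; matching the mean and variance of
    log s_g^2 via digamma/trigamma gives the closed-form estimates. When
    the observed spread of log variances does not exceed what df alone
    explains, d0 is infinite (all variances shrink fully to s0_sq).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive sample variances to estimate a prior")
    z = np.log(s_sq[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var <= 0:
        # spread of log variances is fully explained by sampling noise:
        # complete shrinkage to the pooled (arithmetic mean) variance
        logger.info("log-variance spread within sampling noise; using d0 = inf")
        return ModeratedTPrior(math.inf, float(s_sq[ok].mean()))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return ModeratedTPrior(d0, s0_sq)


def moderated_t(
    group1: np.ndarray,
    group2: np.ndarray,
    prior: ModeratedTPrior | Literal["estimate"] = "estimate",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated two-sample t-test per region.

    Parameters
    ----------
    group1, group2 : arrays of shape (replicates, regions)
        At least two replicates per group.
    prior : ModeratedTPrior or "estimate"
        Fixed prior, or estimate (d0, s0_sq) from the data by moment
        matching of log variances.

    Returns
    -------
    (t, df, p) arrays over regions. The shrunken variance is
    ``s~^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and
    ``t = (mean1 - mean2) / (s~ * sqrt(1/n1 + 1/n2))`` on d0 + d_g
    degrees of freedom (normal tail when d0 is infinite).
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group for variance estimation")
    if g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must cover the same regions")
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    d_g = n1 + n2 - 2
    s_sq = ss / d_g
    if prior == "estimate":
        prior = estimate_prior(s_sq, d_g)
    if math.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df = np.full_like(s_sq, math.inf)
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s_sq) / (prior.d0 + d_g)
        df = np.full_like(s_sq, prior.d0 + d_g)
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    if math.isinf(prior.d0):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, np.minimum(p, 1.0)


def ddct_enrichment(
    ct_ip_target: float,
    ct_input_target: float,
    ct_ip_control: float,
    ct_input_control: float,
) -> float:
    """qPCR fold enrichment by the delta-delta-Ct method:
    ``2 ** -[(ct_ip_target - ct_input_target) - (ct_ip_control - ct_input_control)]``.
    """
    for ct in (ct_ip_target, ct_input_target, ct_ip_control, ct_input_control):
        if not math.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_ip_target - ct_input_target) - (ct_ip_control - ct_input_control)
    return 2.0 ** (-ddct)


def fisher_exact_bruteforce(table: Table2x2, sided: Sided = "two_sided") -> float:
    """Reference Fisher p by explicit enumeration of all tables with the
    observed margins (factorial arithmetic; intended for small N in tests)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c

    def point_prob(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    obs = point_prob(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = point_prob(k)
        if sided == "two_sided" and pk <= obs * (1 + 1e-7):
            total += pk
        elif sided == "greater" and k >= a:
            total += pk
        elif sided == "less" and k <= a:
            total += pk
    return min(1.0, total)
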