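"""Tag-frequency differential expression tests.

Two tests over per-group EST counts with known group totals:

* a chi-squared goodness-of-fit test across g >= 2 groups with expected
  counts proportional to group sizes (df = g - 1), for multigroup
  comparisons; and
* the exact conditional test for a pair of libraries, based on the
  distribution of the second count given the first,

      p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

  evaluated in log space.  Given x, the count y follows a negative
  binomial; the two-sided significance doubles the smaller tail and is
  capped at 1.

Filters (minimum total ESTs for the multigroup test, singleton removal
for the pairwise test) and Bonferroni control are applied by the runner
helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist


class EnrichmentDirection(str, Enum):
    GROUP_A_ENRICHED = "GROUP_A_ENRICHED"
    GROUP_B_ENRICHED = "GROUP_B_ENRICHED"
    NA = "NA"


@dataclass
class DETestResult:
    gene_id: str
    counts: tuple[int, ...]
    totals: tuple[int, ...]
    test: str  # "CHI2" or "AC"
    p_value: float
    statistic: Optional[float] = None
    significant: bool = False
    direction: EnrichmentDirection = EnrichmentDirection.NA
    cutoff: Optional[float] = None


@dataclass
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    min_total_ests: int = 4  # chi-squared filter
    min_per_side: int = 2  # pairwise singleton filter
    alpha: float = 0.01
    multiple_testing: str = "BONFERRONI"  # or "NONE"
    m: Optional[int] = None  # number of tests; default = genes actually tested

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")


def chi2_multigroup(
    counts: Sequence[int], totals: Sequence[int]
) -> tuple[float, float]:
    """Goodness-of-fit statistic and p-value for one gene across g groups.

    Expected counts are proportional to group totals; df = g - 1.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.shape != totals.shape or counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need aligned count/total vectors for >= 2 groups")
    if np.any(totals <= 0):
        raise ValueError("all group totals must be positive")
    c_sum = counts.sum()
    if c_sum == 0:
        return 0.0, 1.0
    expected = c_sum * totals / totals.sum()
    stat = float(np.sum((counts - expected) ** 2 / expected))
    p = float(chi2_dist.sf(stat, df=len(counts) - 1))
    return stat, p


def _log_cond_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    """log p(k | x) with r = N2/N1; the negative-binomial conditional law."""
    return (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pr
    )


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Exact two-sided p-value for counts x (library size n1) vs y (size n2).

    Both tails are accumulated by direct summation in log space; the
    two-sided value doubles the smaller tail and is capped at 1.
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)

    # lower tail: k = 0..y (finite)
    ks = np.arange(0, y + 1)
    log_lower = logsumexp(_log_cond_pmf(ks, x, log_r, log_1pr))
    lower = math.exp(min(log_lower, 0.0))

    # upper tail: k = y..inf; sum until the geometric remainder is negligible
    mode = r * (x + 1) / (1.0 + r)  # approximate location of the pmf peak
    upper = _upper_tail(x, y, log_r, log_1pr, mode)

    return min(1.0, 2.0 * min(lower, upper))


def _upper_tail(x: int, y: int, log_r: float, log_1pr: float, mode: float) -> float:
    """Sum of p(k|x) for k >= y, in chunks, until convergence."""
    chunk = 512
    start = y
    total_log = -np.inf
    # sum at least past the mode before testing convergence
    while True:
        ks = np.arange(start, start + chunk)
        block = logsumexp(_log_cond_pmf(ks, x, log_r, log_1pr))
        total_log = np.logaddexp(total_log, block)
        start += chunk
        if start > mode and block < total_log + math.log(1e-16):
            break
        if start > mode + 400 * math.sqrt(mode + 10) + 10_000:  # pragma: no cover
            break
    return math.exp(min(float(total_log), 0.0))


def run_chi2(
    counts_by_gene: dict[str, Sequence[int]],
    totals: Sequence[int],
    config: TestConfig = TestConfig(min_total_ests=4, alpha=0.001, multiple_testing="NONE"),
) -> tuple[list[DETestResult], dict[str, str]]:
    """Run the multigroup test over all genes; returns results and the map of
    excluded genes to exclusion reasons."""
    results: list[DETestResult] = []
    excluded: dict[str, str] = {}
    totals_t = tuple(int(t) for t in totals)
    for gene in sorted(counts_by_gene):
        counts = tuple(int(c) for c in counts_by_gene[gene])
        if sum(counts) < config.min_total_ests:
            excluded[gene] = f"fewer than {config.min_total_ests} ESTs in dataset"
            continue
        stat, p = chi2_multigroup(counts, totals_t)
        results.append(DETestResult(
            gene_id=gene, counts=counts, totals=totals_t, test="CHI2",
            statistic=stat, p_value=p,
        ))
    apply_multiple_testing(results, config)
    return results, excluded


def run_audic_claverie(
    counts_by_gene: dict[str, tuple[int, int]],
    n1: int,
    n2: int,
    config: TestConfig = TestConfig(),
) -> tuple[list[DETestResult], dict[str, str]]:
    """Run the pairwise exact test over all genes, removing genes with fewer
    than ``min_per_side`` ESTs on both sides (singleton removal)."""
    results: list[DETestResult] = []
    excluded: dict[str, str] = {}
    for gene in sorted(counts_by_gene):
        x, y = counts_by_gene[gene]
        if max(x, y) < config.min_per_side:
            excluded[gene] = f"fewer than {config.min_per_side} ESTs on both sides"
            continue
        p = audic_claverie_p(x, y, n1, n2)
        results.append(DETestResult(
            gene_id=gene, counts=(int(x), int(y)), totals=(int(n1), int(n2)),
            test="AC", p_value=p,
        ))
    apply_multiple_testing(results, config)
    return results, excluded


def apply_multiple_testing(
    results: list[DETestResult], config: TestConfig
) -> list[DETestResult]:
    """Set significance flags in place; returns the results for chaining.

    BONFERRONI: significant iff raw p < alpha / m, with m defaulting to the
    number of genes actually tested.  The effective cutoff is recorded on
    every result.
    """
    if config.multiple_testing == "BONFERRONI":
        m = config.m if config.m is not None else max(1, len(results))
        cutoff = config.alpha / m
    elif config.multiple_testing == "NONE":
        cutoff = config.alpha
    else:
        raise ValueError(f"unknown multiple_testing {config.multiple_testing!r}")
    for r in results:
        r.cutoff = cutoff
        r.significant = r.p_value < cutoff
        if not r.significant:
            r.direction = EnrichmentDirection.NA
    return results


def call_pairwise_enrichment(
    results: list[DETestResult],
) -> dict[EnrichmentDirection, list[DETestResult]]:
    """Partition significant pairwise results by which side is enriched.

    Direction compares per-10k frequencies between the two sides.
    """
    partition: dict[EnrichmentDirection, list[DETestResult]] = {
        EnrichmentDirection.GROUP_A_ENRICHED: [],
        EnrichmentDirection.GROUP_B_ENRICHED: [],
    }
    for r in results:
        if not r.significant:
            continue
        if r.test != "AC" or len(r.counts) != 2:
            raise ValueError("enrichment direction applies to pairwise results")
        (x, y), (n1, n2) = r.counts, r.totals
        fa, fb = x / n1, y / n2
        if fa == fb:  # unreachable for a significant exact test
            raise AssertionError(
                f"gene {r.gene_id}: equal frequencies with significant p"
            )
        r.direction = (
            EnrichmentDirection.GROUP_A_ENRICHED
            if fa > fb
            else EnrichmentDirection.GROUP_B_ENRICHED
        )
        partition[r.direction].append(r)
    return partition
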