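"""The balancing-selection test battery.

Heterozygote-excess rank test with its power analysis, the Hudson F_ST
estimator and its frequency-matched rank test, the recombination-rate
contrast between fixed and segregating sites, the per-chromosome SNP
density dispersion test, and the beta-score comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import matched_ranks
from .io_formats import GeneticMap
from .synthetic_data import het_count_distribution

logger = logging.getLogger(__name__)

DEFAULT_MIN_K_HET = 100
DEFAULT_MIN_POOLED_K_FST = 10
DEFAULT_DISPERSION_REPLICATES = 200
DEFAULT_POWER_REPLICATES = 1000
DEFAULT_POWER_ALPHA = 0.05
EXACT_MW_MAX_TOTAL = 12


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact enumeration for small samples)
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test (U of x against y).

    Exact p by permutation enumeration of the pooled sample when
    len(x) + len(y) <= 12 (valid with ties); otherwise the normal
    approximation with tie and continuity corrections.  ``alternative``
    'greater' means x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if n + m <= EXACT_MW_MAX_TOTAL:
        pooled = np.concatenate([x, y])
        total = 0
        ge = le = 0
        for idx in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            up = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if up >= u - 1e-9:
                ge += 1
            if up <= u + 1e-9:
                le += 1
        if alternative == "greater":
            p = ge / total
        elif alternative == "less":
            p = le / total
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(ge, le) / total)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return u, float(p)
    # asymptotic with tie correction
    pooled = np.concatenate([x, y])
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (N * (N - 1.0))
    sigma2 = n * m / 12.0 * (N + 1.0 - tie)
    mu = n * m / 2.0
    if sigma2 <= 0:
        return u, 1.0
    sigma = np.sqrt(sigma2)
    # continuity correction shifts toward the tail being integrated
    if alternative == "greater":
        p = float(stats.norm.sf((u - mu - 0.5) / sigma))
    elif alternative == "less":
        p = float(stats.norm.cdf((u - mu + 0.5) / sigma))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf((abs(u - mu) - 0.5) / sigma))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return u, min(1.0, p)


# ---------------------------------------------------------------------------
# heterozygote excess
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HetTestResult:
    mean_rank: float
    z: float
    p: float
    n_used: int


def het_excess_test(
    focal: Sequence[tuple[int, int]],
    null_bins: matched_ranks.FrequencyBinSet,
    rng: np.random.Generator,
    min_k: int = DEFAULT_MIN_K_HET,
) -> HetTestResult:
    """Test whether focal sites carry more heterozygotes than matched controls.

    ``focal`` holds (k, het_count) pairs; sites with k < min_k are
    excluded; ranks use randomized tie-breaking and the test is a
    one-sided z-test in the 'greater' direction.
    """
    arr = np.asarray(focal, dtype=np.int64).reshape(-1, 2)
    arr = arr[arr[:, 0] >= min_k]
    if arr.shape[0] == 0:
        raise ValueError(f"no focal sites with k >= {min_k}")
    df, n_unmatched = matched_ranks.rank_sites(arr[:, 0], arr[:, 1].astype(float),
                                               null_bins, rng)
    if n_unmatched:
        logger.info("het_excess_test: %d focal sites unmatched by any bin", n_unmatched)
    if len(df) == 0:
        raise ValueError("no focal sites matched a frequency bin")
    mean, z, p = matched_ranks.mean_rank_ztest(df["rank"].to_numpy(), "greater")
    return HetTestResult(mean_rank=mean, z=z, p=p, n_used=len(df))


@dataclass(frozen=True)
class PowerResult:
    s: float
    replicates: int
    rejections: int
    alpha: float

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.rejections <= self.replicates:
            raise ValueError("rejections outside [0, replicates]")

    @property
    def power(self) -> float:
        return self.rejections / self.replicates


def build_het_null_bins(
    spectrum: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    null_draws_per_k: int = 1000,
) -> matched_ranks.FrequencyBinSet:
    """Simulated s = 0 heterozygote-count null, one single-k bin per observed k."""
    bins = []
    for k in sorted({k for k, _ in spectrum}):
        n = next(nn for kk, nn in spectrum if kk == k)
        h, prob = het_count_distribution(k, n, 0.0)
        draws = rng.choice(h, size=null_draws_per_k, p=prob)
        bins.append(matched_ranks.FrequencyBin(k, k, draws.astype(float)))
    return matched_ranks.FrequencyBinSet(bins=tuple(bins))


def het_power_analysis(
    freq_spectrum: Sequence[tuple[int, int]],
    s_grid: Sequence[float],
    rng: np.random.Generator,
    replicates: int = DEFAULT_POWER_REPLICATES,
    alpha: float = DEFAULT_POWER_ALPHA,
    null_draws_per_k: int = 1000,
    min_k: int = 0,
) -> list[PowerResult]:
    """Power of the heterozygote-excess z-test across selection coefficients.

    For each s, ``replicates`` datasets matching the observed frequency
    spectrum are simulated under heterozygote fitness 1+s and tested
    against an s = 0 simulated null; the rejection fraction at ``alpha``
    is the power.  The whole computation is vectorized over replicates.
    """
    spectrum = [(k, n) for k, n in freq_spectrum if k >= min_k]
    if not spectrum:
        raise ValueError("empty frequency spectrum after min_k filter")
    null_bins = build_het_null_bins(spectrum, rng, null_draws_per_k)
    nulls_by_k = {b.k_lo: b.values for b in null_bins.bins}
    m = len(spectrum)
    results = []
    for s in s_grid:
        ranks = np.empty((m, replicates))
        for i, (k, n) in enumerate(spectrum):
            h, prob = het_count_distribution(k, n, s)
            draws = rng.choice(h, size=replicates, p=prob).astype(float)
            null = nulls_by_k[k]
            lo = np.searchsorted(null, draws, side="left")
            hi = np.searchsorted(null, draws, side="right")
            pos = rng.integers(lo, hi + 1)
            ranks[i] = pos / null.size
        means = ranks.mean(axis=0)
        z = (means - 0.5) * np.sqrt(12.0 * m)
        pvals = stats.norm.sf(z)
        results.append(PowerResult(s=float(s), replicates=replicates,
                                   rejections=int((pvals < alpha).sum()), alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def hudson_fst(k1: int, n1: int, k2: int, n2: int) -> float:
    """Hudson two-population F_ST with finite-sample correction.

    With p_i = k_i / n_i (allele counts over chromosome counts):
    numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), denominator
    p1(1-p2) + p2(1-p1).  A zero denominator returns NaN.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    p1, p2 = k1 / n1, k2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        return float("nan")
    return num / den


@dataclass(frozen=True)
class FstRecord:
    key: object
    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("allele counts outside sample sizes")

    @property
    def pooled_k(self) -> int:
        return self.k1 + self.k2

    @property
    def fst(self) -> float:
        return hudson_fst(self.k1, self.n1, self.k2, self.n2)


def fst_rank_test(
    focal: Sequence[tuple[int, float]],
    null_bins: matched_ranks.FrequencyBinSet,
    rng: np.random.Generator,
    min_pooled_k: int = DEFAULT_MIN_POOLED_K_FST,
) -> tuple[float, float, float, int]:
    """Rank focal F_ST values in frequency-matched null F_ST distributions.

    ``focal`` holds (pooled derived count, fst) pairs for sites already
    pre-filtered to age rank > 0.5; sites with pooled k < min_pooled_k are
    excluded.  Returns (mean rank, Wilcoxon W, one-sided p, n used) testing
    for an excess of ranks above 0.5.
    """
    arr = [(k, f) for k, f in focal if k >= min_pooled_k and np.isfinite(f)]
    if not arr:
        raise ValueError(f"no focal sites with pooled k >= {min_pooled_k}")
    ks = np.array([k for k, _ in arr])
    fsts = np.array([f for _, f in arr])
    df, n_unmatched = matched_ranks.rank_sites(ks, fsts, null_bins, rng)
    if n_unmatched:
        logger.info("fst_rank_test: %d focal sites unmatched by any bin", n_unmatched)
    if len(df) == 0:
        raise ValueError("no focal sites matched a frequency bin")
    ranks = df["rank"].to_numpy()
    W, p = matched_ranks.wilcoxon_signed_vs_half(ranks, alternative="greater")
    return float(ranks.mean()), W, p, len(df)


# ---------------------------------------------------------------------------
# recombination contrast
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombContrast:
    median_fixed: float
    median_segregating: float
    U: float
    p: float


def recomb_contrast(fixed_positions: Sequence[int], segregating_positions: Sequence[int],
                    gmap: GeneticMap, alternative: str = "greater") -> RecombContrast:
    """Compare local recombination rates at fixed vs segregating sites.

    Per-site rates come from the genetic map's piecewise-constant lookup;
    the default alternative 'greater' tests the staggered-sweep prediction
    that fixed sites sit in higher-recombination regions.
    """
    fixed_positions = np.asarray(fixed_positions)
    segregating_positions = np.asarray(segregating_positions)
    if fixed_positions.size == 0 or segregating_positions.size == 0:
        raise ValueError("both site groups must be non-empty")
    rf = gmap.rate_at(fixed_positions)
    rs = gmap.rate_at(segregating_positions)
    U, p = mann_whitney_u(rf, rs, alternative=alternative)
    return RecombContrast(median_fixed=float(np.median(rf)),
                          median_segregating=float(np.median(rs)), U=U, p=p)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionResult:
    chrom: str
    observed_variance: float
    simulated_variances: np.ndarray
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("empirical p must lie in (0, 1]")


def _density_variance(counts: np.ndarray, lengths: np.ndarray) -> float:
    # variance of per-gene density normalized by its mean, so the statistic
    # is invariant to uniform rescaling of lengths and counts
    dens = counts / lengths
    mean = dens.mean()
    if mean == 0.0:
        return 0.0
    return float(np.var(dens / mean, ddof=1))


def dispersion_test(
    gene_table: pd.DataFrame,
    rng: np.random.Generator,
    replicates: int = DEFAULT_DISPERSION_REPLICATES,
    null_counts: pd.DataFrame | None = None,
) -> list[DispersionResult]:
    """Per-chromosome test for overdispersion of SNP counts across genes.

    The observed statistic is the variance of relative per-gene SNP
    density; the null places each chromosome's total count multinomially
    across its genes with probability proportional to gene length.
    Externally simulated per-gene counts (columns gene, replicate, count)
    can replace the multinomial null.  The empirical p-value is
    (1 + #{sim >= obs}) / (1 + #sims).  Single-gene chromosomes are
    skipped with a warning.
    """
    required = {"gene", "chrom", "length", "count"}
    if not required <= set(gene_table.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    if (gene_table["length"] <= 0).any():
        raise ValueError("gene lengths must be > 0")
    results = []
    for chrom, sub in gene_table.groupby("chrom", sort=True):
        if len(sub) < 2:
            warnings.warn(f"chromosome {chrom}: single gene, dispersion undefined; skipped",
                          stacklevel=2)
            continue
        lengths = sub["length"].to_numpy(dtype=float)
        counts = sub["count"].to_numpy(dtype=float)
        observed = _density_variance(counts, lengths)
        if null_counts is not None:
            sims = []
            nc = null_counts[null_counts["gene"].isin(sub["gene"])]
            for _, rep in nc.groupby("replicate"):
                merged = sub[["gene", "length"]].merge(rep[["gene", "count"]], on="gene")
                sims.append(_density_variance(merged["count"].to_numpy(dtype=float),
                                              merged["length"].to_numpy(dtype=float)))
            sims = np.asarray(sims)
        else:
            total = int(counts.sum())
            prob = lengths / lengths.sum()
            draws = rng.multinomial(total, prob, size=replicates).astype(float)
            dens = draws / lengths[None, :]
            means = dens.mean(axis=1)
            means[means == 0.0] = 1.0
            sims = np.var(dens / means[:, None], axis=1, ddof=1)
        b = int((sims >= observed - 1e-12).sum())
        p = (1.0 + b) / (1.0 + sims.size)
        results.append(DispersionResult(chrom=str(chrom), observed_variance=observed,
                                        simulated_variances=sims, p=p))
    return results


# ---------------------------------------------------------------------------
# beta-score comparison
# ---------------------------------------------------------------------------

def beta_compare(beta_scores_pos: Sequence[float], beta_scores_neg: Sequence[float]
                 ) -> tuple[float, float, float, float]:
    """Compare balancing-selection beta scores of positive vs negative delta-EP sites.

    Returns (mean positive, mean negative, U, two-sided p).
    """
    pos = np.asarray(beta_scores_pos, dtype=float)
    neg = np.asarray(beta_scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    U, p = mann_whitney_u(pos, neg, alternative="two-sided")
    return float(pos.mean()), float(neg.mean()), U, p
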