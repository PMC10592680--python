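"""Frequency-matched null distributions and normalized rank statistics.

The central statistic of the pipeline: a focal value (an allele age, an
F_ST, a heterozygote count) is placed into the sorted null distribution of
the same quantity for neutral control variants of the same derived allele
count k, and its position divided by the null size gives a rank in [0, 1]
that is uniform under the null.  Low-k controls (k <= singleton_k_max,
default 8) stay in single-k bins; higher k values are pooled greedily in
ascending order until each bin reaches the target size.

Tie handling is randomized: a focal value equal to e null values lands
uniformly on any of the e + 1 admissible positions.  The rank of the
minimum (no ties) is 0 and of a value above every null is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SINGLETON_K_MAX = 8
DEFAULT_TARGET_BIN_SIZE = 500


@dataclass(frozen=True)
class FrequencyBin:
    k_lo: int
    k_hi: int
    values: np.ndarray  # sorted ascending

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if self.k_lo > self.k_hi:
            raise ValueError("bin k-range inverted")
        if v.size == 0:
            raise ValueError("empty frequency bin")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FrequencyBinSet:
    bins: tuple

    def __post_init__(self) -> None:
        for a, b in zip(self.bins[:-1], self.bins[1:]):
            if b.k_lo <= a.k_hi:
                raise ValueError("frequency bins overlap or are unordered")

    def bin_index(self, k) -> np.ndarray:
        """Index of the bin containing each k, or -1 when unmatched."""
        k = np.atleast_1d(np.asarray(k, dtype=np.int64))
        los = np.array([b.k_lo for b in self.bins])
        his = np.array([b.k_hi for b in self.bins])
        idx = np.searchsorted(los, k, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.bins) - 1)
        ok = (idx >= 0) & (k <= his[idx_c])
        return np.where(ok, idx_c, -1)

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class RankResult:
    key: object
    rank: float
    bin_id: int
    null_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rank <= 1.0:
            raise ValueError("rank outside [0, 1]")


def build_frequency_bins(
    ks: Sequence[int],
    values: Sequence[float],
    target_bin_size: int = DEFAULT_TARGET_BIN_SIZE,
    singleton_k_max: int = DEFAULT_SINGLETON_K_MAX,
) -> FrequencyBinSet:
    """Partition null (k, value) pairs into frequency bins.

    Every observed k <= singleton_k_max gets its own bin even when larger
    than the target; higher k values are pooled in ascending order until
    the accumulated count reaches target_bin_size.  Pooled bins cover
    contiguous k ranges so any focal k between the pooled minimum and
    maximum maps to exactly one bin.
    """
    ks = np.asarray(ks, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if ks.size == 0:
        raise ValueError("empty null set")
    if ks.size != values.size:
        raise ValueError("ks and values have different lengths")
    if target_bin_size < 1:
        raise ValueError("target_bin_size must be >= 1")
    order = np.argsort(ks, kind="mergesort")
    ks, values = ks[order], values[order]
    uniq, starts = np.unique(ks, return_index=True)
    ends = np.append(starts[1:], ks.size)

    bins: list[FrequencyBin] = []
    pool_vals: list[np.ndarray] = []
    pool_lo: int | None = None
    prev_pooled_hi: int | None = None
    pool_count = 0
    for u, s, e in zip(uniq, starts, ends):
        if u <= singleton_k_max:
            bins.append(FrequencyBin(int(u), int(u), values[s:e]))
            continue
        if pool_lo is None:
            # consecutive pooled bins cover contiguous k ranges
            pool_lo = int(u) if prev_pooled_hi is None else prev_pooled_hi + 1
        pool_vals.append(values[s:e])
        pool_count += e - s
        if pool_count >= target_bin_size:
            bins.append(FrequencyBin(pool_lo, int(u), np.concatenate(pool_vals)))
            prev_pooled_hi = int(u)
            pool_lo, pool_vals, pool_count = None, [], 0
    if pool_count:
        # trailing partial pool keeps its own bin
        bins.append(FrequencyBin(pool_lo, int(uniq[-1]), np.concatenate(pool_vals)))
    return FrequencyBinSet(bins=tuple(bins))


def rank_in_null(value: float, bin: FrequencyBin | np.ndarray,
                 rng: np.random.Generator) -> float:
    """Normalized rank of one value in a sorted null distribution."""
    null = bin.values if isinstance(bin, FrequencyBin) else np.asarray(bin, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    lo = int(np.searchsorted(null, value, side="left"))
    hi = int(np.searchsorted(null, value, side="right"))
    pos = lo + int(rng.integers(0, hi - lo + 1))
    return pos / null.size


def _rank_batch(values: np.ndarray, null_sorted: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    lo = np.searchsorted(null_sorted, values, side="left")
    hi = np.searchsorted(null_sorted, values, side="right")
    pos = rng.integers(lo, hi + 1)
    return pos / null_sorted.size


def rank_sites(
    ks: Sequence[int],
    values: Sequence[float],
    bins: FrequencyBinSet,
    rng: np.random.Generator,
    keys: Sequence | None = None,
) -> tuple[pd.DataFrame, int]:
    """Rank each focal (k, value) pair within its frequency-matched bin.

    Returns a table (key, k, value, bin_id, null_size, rank) for matched
    sites, plus the count of focal sites whose k fell outside every bin.
    """
    ks = np.asarray(ks, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if keys is None:
        keys = np.arange(ks.size)
    key_arr = np.empty(ks.size, dtype=object)
    key_arr[:] = list(keys)
    keys = key_arr
    idx = bins.bin_index(ks)
    matched = idx >= 0
    n_unmatched = int((~matched).sum())
    ranks = np.full(ks.size, np.nan)
    sizes = np.zeros(ks.size, dtype=np.int64)
    for b in np.unique(idx[matched]):
        sel = idx == b
        ranks[sel] = _rank_batch(values[sel], bins.bins[b].values, rng)
        sizes[sel] = bins.bins[b].size
    df = pd.DataFrame({
        "key": keys[matched],
        "k": ks[matched],
        "value": values[matched],
        "bin_id": idx[matched],
        "null_size": sizes[matched],
        "rank": ranks[matched],
    })
    return df, n_unmatched


def mean_rank_ztest(ranks: Sequence[float], direction: str = "greater"
                    ) -> tuple[float, float, float]:
    """One-sample z-test of mean rank against 0.5 under the uniform null.

    The null fully specifies the rank distribution (uniform on [0, 1]), so
    the variance is 1/12 and z = (mean - 0.5) * sqrt(12 m).
    """
    ranks = np.asarray(ranks, dtype=float)
    m = ranks.size
    if m < 1:
        raise ValueError("need at least one rank")
    mean = float(ranks.mean())
    z = (mean - 0.5) * np.sqrt(12.0 * m)
    if direction == "greater":
        p = float(stats.norm.sf(z))
    elif direction == "less":
        p = float(stats.norm.cdf(z))
    elif direction == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return mean, float(z), p


def wilcoxon_signed_vs_half(ranks: Sequence[float], alternative: str = "two-sided",
                            exact_max_m: int = 15) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of median 0.5.

    Zero differences are dropped (all-zero input returns p = 1 with a
    warning).  For m <= exact_max_m the null distribution of W+ is
    enumerated over all 2^m sign patterns given the observed midranks of
    |rank - 0.5|; larger samples use the normal approximation with tie and
    continuity corrections.
    """
    d = np.asarray(ranks, dtype=float) - 0.5
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        warnings.warn("all ranks equal 0.5; Wilcoxon test degenerate", stacklevel=2)
        return 0.0, 1.0
    r = stats.rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    if m <= exact_max_m:
        bits = (np.arange(2 ** m)[:, None] >> np.arange(m)) & 1
        dist = bits @ r
        p_ge = np.mean(dist >= w_plus - 1e-9)
        p_le = np.mean(dist <= w_plus + 1e-9)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return w_plus, float(p)
    mu = m * (m + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(r, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0 - tie_term)
    if sigma == 0:
        return w_plus, 1.0
    # continuity correction shifts toward the tail being integrated
    if alternative == "greater":
        p = float(stats.norm.sf((w_plus - mu - 0.5) / sigma))
    elif alternative == "less":
        p = float(stats.norm.cdf((w_plus - mu + 0.5) / sigma))
    else:
        p = float(2.0 * stats.norm.sf((abs(w_plus - mu) - 0.5) / sigma))
    return w_plus, min(1.0, p)
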