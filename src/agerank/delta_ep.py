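"""Rooting, delta-EP computation, and class summaries with bootstrap CIs.

A biallelic SNP is oriented into ancestral/derived space either by
parsimony against a supplied ancestral state (optionally requiring the
ancestral state to equal the reference allele, the filter used for all
age analyses) or from maximum-likelihood posterior probabilities with a
0.9 certainty threshold.  delta EP is the derived-allele evolutionary
probability minus the ancestral-allele one, so positive values mark
candidate beneficial changes and negative values candidate deleterious
ones.

Confidence intervals on class means use the bias-corrected bootstrap
(acceleration optional via jackknife, off by default).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io_formats import SiteRecord

DEFAULT_BOOTSTRAP_B = 2000
ML_POSTERIOR_THRESHOLD = 0.9


@dataclass(frozen=True)
class RootedSite:
    """A site plus its ancestral/derived orientation and delta EP."""

    site: SiteRecord
    ancestral_allele: str
    derived_allele: str
    derived_k: int
    ep_ancestral: float | None
    ep_derived: float | None

    def __post_init__(self) -> None:
        alleles = {self.site.ref_allele, self.site.alt_allele}
        if {self.ancestral_allele, self.derived_allele} != alleles:
            raise ValueError("derived/ancestral alleles must be the site's two alleles")
        if not 0 <= self.derived_k <= self.site.n2:
            raise ValueError("derived_k outside [0, n2]")

    @property
    def delta_ep(self) -> float | None:
        if self.ep_ancestral is None or self.ep_derived is None:
            return None
        return self.ep_derived - self.ep_ancestral

    @property
    def derived_freq(self) -> float:
        return self.derived_k / self.site.n2

    @property
    def fixed_flag(self) -> bool:
        return self.derived_k == self.site.n2

    # convenience passthroughs used all over the downstream analyses
    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def is_cpg(self) -> bool | None:
        return self.site.is_cpg


def _orient(site: SiteRecord, ancestral: str) -> RootedSite:
    if ancestral == site.ref_allele:
        derived, derived_k = site.alt_allele, site.k
        ep_anc, ep_der = site.ep_ref, site.ep_alt
    else:
        derived, derived_k = site.ref_allele, site.n2 - site.k
        ep_anc, ep_der = site.ep_alt, site.ep_ref
    return RootedSite(site=site, ancestral_allele=ancestral, derived_allele=derived,
                      derived_k=derived_k, ep_ancestral=ep_anc, ep_derived=ep_der)


def root_by_parsimony(site: SiteRecord | RootedSite,
                      require_anc_equals_ref: bool = False) -> RootedSite | None:
    """Orient a site by its ancestral state; None means a tallied rejection.

    Rejections: missing ancestral state, ancestral state matching neither
    allele, or (when the flag is on, as for all age analyses) ancestral
    state differing from the reference allele.  Re-rooting an already
    rooted site is a no-op.
    """
    if isinstance(site, RootedSite):
        return site
    anc = site.anc_state
    if anc is None:
        return None
    if anc not in (site.ref_allele, site.alt_allele):
        return None
    if require_anc_equals_ref and anc != site.ref_allele:
        return None
    return _orient(site, anc)


def root_by_ml_posteriors(site: SiteRecord | RootedSite,
                          posteriors: Mapping[str, float],
                          threshold: float = ML_POSTERIOR_THRESHOLD) -> RootedSite | None:
    """Orient a site from ML ancestral-state posteriors (argmax > threshold)."""
    if isinstance(site, RootedSite):
        return site
    total = float(sum(posteriors.values()))
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"posteriors sum to {total}, not 1")
    anc = max(posteriors, key=posteriors.get)
    if posteriors[anc] <= threshold:
        return None
    if anc not in (site.ref_allele, site.alt_allele):
        return None
    return _orient(site, anc)


def root_sites(sites: Iterable[SiteRecord], require_anc_equals_ref: bool = False
               ) -> tuple[list[RootedSite], Counter]:
    """Parsimony-root a collection, tallying rejection reasons."""
    rooted: list[RootedSite] = []
    tally: Counter = Counter()
    for site in sites:
        if site.anc_state is None:
            tally["missing_ancestral"] += 1
            continue
        if site.anc_state not in (site.ref_allele, site.alt_allele):
            tally["ancestral_matches_neither"] += 1
            continue
        if require_anc_equals_ref and site.anc_state != site.ref_allele:
            tally["ancestral_not_reference"] += 1
            continue
        rooted.append(_orient(site, site.anc_state))
        tally["rooted"] += 1
    return rooted, tally


def compute_delta_ep(rooted: RootedSite) -> float | None:
    """Derived EP minus ancestral EP; None (a tallied rejection) when an EP is missing."""
    return rooted.delta_ep


# ---------------------------------------------------------------------------
# bias-corrected bootstrap
# ---------------------------------------------------------------------------

def bca_bootstrap_ci(
    values: Sequence[float],
    statistic: Callable = np.mean,
    B: int = DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    acceleration: bool = False,
) -> tuple[float, float]:
    """Bias-corrected (optionally accelerated) bootstrap percentile interval.

    z0 comes from the fraction of bootstrap statistics below the point
    estimate; interval endpoints sit at the Phi(2 z0 +/- z_{alpha/2})
    percentiles of the bootstrap distribution (with the usual BCa
    adjustment when jackknife acceleration is enabled).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    theta = float(statistic(values))
    if np.ptp(values) == 0.0:
        return theta, theta
    idx = rng.integers(0, n, size=(B, n))
    try:
        boot = np.asarray(statistic(values[idx], axis=1), dtype=float)
    except TypeError:
        boot = np.array([statistic(values[row]) for row in idx], dtype=float)
    if np.ptp(boot) == 0.0 and boot[0] == theta:
        return theta, theta
    prop = np.clip(np.mean(boot < theta), 1.0 / (B + 1), B / (B + 1))
    z0 = ndtri(prop)
    a = 0.0
    if acceleration:
        jack = np.array([statistic(np.delete(values, i)) for i in range(n)])
        d = jack.mean() - jack
        denom = 6.0 * (d ** 2).sum() ** 1.5
        a = (d ** 3).sum() / denom if denom > 0 else 0.0
    z_alpha = ndtri([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
    lo_q, hi_q = ndtr(adj)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# class summaries
# ---------------------------------------------------------------------------

def _mean_ci(values: np.ndarray, B: int, alpha: float, rng) -> tuple[float, float, float]:
    if values.size == 0:
        return np.nan, np.nan, np.nan
    lo, hi = bca_bootstrap_ci(values, np.mean, B=B, alpha=alpha, rng=rng)
    return float(values.mean()), lo, hi


def summarize_classes(
    rooted_sites: Iterable[RootedSite],
    B: int = DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Summary table of delta-EP sign classes split by fixed vs polymorphic.

    For each of {negative, positive} x {fixed, polymorphic}: count, share
    of the sign class, mean derived frequency (polymorphic only), mean
    ancestral/derived EP and mean delta EP, each with bias-corrected
    bootstrap CIs.  Sites with delta EP exactly 0 (or missing) are
    excluded from both sign classes and tallied in a separate row.
    """
    if rng is None:
        rng = np.random.default_rng()
    groups: dict[tuple[str, str], list[RootedSite]] = {
        (sign, state): []
        for sign in ("negative", "positive") for state in ("fixed", "polymorphic")
    }
    n_zero_or_missing = 0
    for r in rooted_sites:
        dep = r.delta_ep
        if dep is None or dep == 0.0:
            n_zero_or_missing += 1
            continue
        sign = "positive" if dep > 0 else "negative"
        state = "fixed" if r.fixed_flag else "polymorphic"
        groups[(sign, state)].append(r)
    sign_totals = {
        sign: len(groups[(sign, "fixed")]) + len(groups[(sign, "polymorphic")])
        for sign in ("negative", "positive")
    }
    rows = []
    for (sign, state), members in groups.items():
        dep = np.array([r.delta_ep for r in members], dtype=float)
        anc = np.array([r.ep_ancestral for r in members], dtype=float)
        der = np.array([r.ep_derived for r in members], dtype=float)
        freq = np.array([r.derived_freq for r in members], dtype=float)
        n = len(members)
        row = {
            "sign": sign,
            "state": state,
            "n": n,
            "pct_of_sign_class": 100.0 * n / sign_totals[sign] if sign_totals[sign] else np.nan,
        }
        if state == "polymorphic":
            m, lo, hi = _mean_ci(freq, B, alpha, rng)
            row |= {"mean_derived_freq": m, "derived_freq_lo": lo, "derived_freq_hi": hi}
        else:
            row |= {"mean_derived_freq": 1.0 if n else np.nan,
                    "derived_freq_lo": np.nan, "derived_freq_hi": np.nan}
        for name, arr in (("ancestral_ep", anc), ("derived_ep", der), ("delta_ep", dep)):
            m, lo, hi = _mean_ci(arr, B, alpha, rng)
            row |= {f"mean_{name}": m, f"{name}_lo": lo, f"{name}_hi": hi}
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_zero_or_missing_delta_ep"] = n_zero_or_missing
    return df


def binned_mean(
    values: Sequence[float],
    by: Sequence[float],
    bin_edges: Sequence[float],
    B: int = DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-bin mean and bias-corrected bootstrap CI of ``values`` binned by ``by``.

    Bins are half-open [lo, hi) with the last bin closed on the right;
    points outside [first, last] are dropped; an empty bin yields NaN.
    """
    values = np.asarray(values, dtype=float)
    by = np.asarray(by, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    if rng is None:
        rng = np.random.default_rng()
    idx = np.searchsorted(edges, by, side="right") - 1
    idx[by == edges[-1]] = edges.size - 2  # last bin closed
    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        vals = values[sel & (by >= edges[0]) & (by <= edges[-1])]
        m, lo, hi = _mean_ci(vals, B, alpha, rng)
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                     "n": int(vals.size), "mean": m, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def delta_ep_bin_edges(width: float = 0.1) -> np.ndarray:
    """Default delta-EP binning: width-0.1 bins over [-1, 1]."""
    n = int(round(2.0 / width))
    return np.linspace(-1.0, 1.0, n + 1)
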