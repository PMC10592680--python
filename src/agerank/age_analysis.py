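"""Allele-age analyses: Box-Cox + two-way ANOVA, rank curves, archaic sharing.

The ANOVA asks whether selected derived alleles have the same mean
(Box-Cox-transformed) age as frequency-matched neutral controls, with
selected-vs-control as one main effect and allele frequency bin as the
second.  The model has no interaction term and uses Type-II sums of
squares, so each effect is tested adjusting for the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .delta_ep import RootedSite, binned_mean, delta_ep_bin_edges
from .io_formats import ArchaicTable

OLD_AGE_THRESHOLD_GENS = 200_000.0  # approx human-chimp divergence at 29 yr/gen
BOXCOX_LAMBDA_BOUNDS = (-3.0, 3.0)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox_loglik(lam: float, values: np.ndarray) -> float:
    """Profile log-likelihood of the Box-Cox parameter for a normal model."""
    y = boxcox_transform(values, lam)
    n = values.size
    var = y.var()
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lam - 1.0) * np.log(values).sum()


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if lam == 0.0:
        return np.log(values)
    return (values ** lam - 1.0) / lam


def boxcox_mle(values: Sequence[float],
               bounds: tuple[float, float] = BOXCOX_LAMBDA_BOUNDS,
               tol: float = 1e-5) -> tuple[float, np.ndarray]:
    """Maximum-likelihood Box-Cox transform on a bounded lambda search.

    All values must be strictly positive (fatal otherwise, reporting the
    offending count).  Returns (lambda, transformed values).
    """
    values = np.asarray(values, dtype=float)
    n_bad = int((values <= 0).sum())
    if n_bad:
        raise ValueError(f"Box-Cox requires positive values; {n_bad} are <= 0")
    if values.size < 2 or np.ptp(values) == 0.0:
        raise ValueError("Box-Cox needs at least two distinct values")
    res = optimize.minimize_scalar(
        lambda lam: -boxcox_loglik(lam, values),
        bounds=bounds, method="bounded", options={"xatol": tol},
    )
    lam = float(res.x)
    return lam, boxcox_transform(values, lam)


# ---------------------------------------------------------------------------
# two-way ANOVA (main effects, Type-II SS)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame  # rows: effects + residual; columns: ss, df, F, p
    boxcox_lambda: float | None = None

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def _dummies(levels: np.ndarray) -> np.ndarray:
    # treatment coding: drop the first level
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, 1:]).astype(float)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(values: Sequence[float], factor_a: Sequence, factor_b: Sequence,
                  names: tuple[str, str] = ("class", "freq_bin"),
                  boxcox_lambda: float | None = None) -> AnovaResult:
    """Main-effects two-way ANOVA with Type-II sums of squares.

    ``factor_a`` is the selected-vs-control label, ``factor_b`` the allele
    frequency bin.  Each factor needs >= 2 observed levels.  When every
    cell holds identical values the F statistics are reported as 0 with
    p = 1 (a perfectly fitting non-degenerate model instead yields p -> 0).
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("values and factors must have equal lengths")
    da, db = _dummies(a), _dummies(b)
    if da.shape[1] < 1 or db.shape[1] < 1:
        raise ValueError("each factor needs at least 2 levels")
    ones = np.ones((y.size, 1))
    X_full = np.hstack([ones, da, db])
    df_res = y.size - X_full.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    rss_full = _rss(X_full, y)
    rows = {}
    for name, dm, other in ((names[0], da, db), (names[1], db, da)):
        ss = _rss(np.hstack([ones, other]), y) - rss_full
        ss = max(ss, 0.0)
        df_eff = dm.shape[1]
        if rss_full <= 1e-12 * max(1.0, float(y @ y)):
            if ss <= 1e-12 * max(1.0, float(y @ y)):
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
        else:
            F = (ss / df_eff) / (rss_full / df_res)
            p = float(stats.f.sf(F, df_eff, df_res))
        rows[name] = {"ss": ss, "df": df_eff, "F": F, "p": p}
    rows["residual"] = {"ss": rss_full, "df": df_res, "F": np.nan, "p": np.nan}
    table = pd.DataFrame(rows).T
    return AnovaResult(table=table, boxcox_lambda=boxcox_lambda)


def anova_age_vs_control(ages: Sequence[float], is_selected: Sequence[bool],
                         freq_bins: Sequence) -> AnovaResult:
    """Box-Cox the ages (single pooled lambda), then run the two-way ANOVA."""
    lam, transformed = boxcox_mle(np.asarray(ages, dtype=float))
    labels = np.where(np.asarray(is_selected, dtype=bool), "selected", "control")
    res = two_way_anova(transformed, labels, freq_bins, boxcox_lambda=lam)
    return res


# ---------------------------------------------------------------------------
# rank curves and tabulations
# ---------------------------------------------------------------------------

def age_rank_curve(
    rooted_sites: Iterable[RootedSite],
    ranks: pd.DataFrame,
    dep_bin_edges: Sequence[float] | None = None,
    B: int = 500,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean age rank per delta-EP bin (CpG-flagged sites excluded).

    ``ranks`` must carry (chrom, pos, rank); sites are joined by position
    key.  Returns the binned_mean table with delta-EP bin edges.
    """
    if dep_bin_edges is None:
        dep_bin_edges = delta_ep_bin_edges()
    by_key = {}
    for r in rooted_sites:
        if r.is_cpg:
            continue
        if r.delta_ep is None:
            continue
        by_key[(r.chrom, r.pos)] = r.delta_ep
    deps, rank_vals = [], []
    for row in ranks.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key in by_key:
            deps.append(by_key[key])
            rank_vals.append(float(row.rank))
    return binned_mean(rank_vals, deps, dep_bin_edges, B=B, rng=rng)


def fraction_above_half(ranks: Sequence[float]) -> tuple[int, int, float]:
    """(count strictly above 0.5, total, fraction); fraction is NaN when empty."""
    ranks = np.asarray(ranks, dtype=float)
    total = int(ranks.size)
    if total == 0:
        return 0, 0, float("nan")
    above = int((ranks > 0.5).sum())
    return above, total, above / total


def old_age_fraction(ages: Sequence[float],
                     generation_threshold: float = OLD_AGE_THRESHOLD_GENS) -> float:
    """Fraction of ages strictly exceeding the threshold (NaN when empty)."""
    if generation_threshold <= 0:
        raise ValueError("threshold must be > 0")
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return float("nan")
    return float((ages > generation_threshold).mean())


def archaic_sharing(rooted_sites: Iterable[RootedSite],
                    archaic: ArchaicTable) -> pd.DataFrame:
    """Shared-with-archaic and introgression tabulation per delta-EP class.

    A site is shared iff its (chrom, pos, derived allele) appears in the
    archaic allele set, and introgressed iff its position falls inside an
    introgression interval.  Classes: positive / negative delta EP for
    nonsynonymous sites, plus noncoding controls.
    """
    classes = {"positive": [], "negative": [], "noncoding": []}
    for r in rooted_sites:
        if r.site.site_class == "noncoding_nonregulatory":
            classes["noncoding"].append(r)
        elif r.delta_ep is not None and r.delta_ep > 0:
            classes["positive"].append(r)
        elif r.delta_ep is not None and r.delta_ep < 0:
            classes["negative"].append(r)
    rows = []
    for name, members in classes.items():
        n = len(members)
        shared = sum(archaic.has_allele(r.chrom, r.pos, r.derived_allele) for r in members)
        intro = sum(archaic.in_introgression(r.chrom, r.pos) for r in members)
        rows.append({
            "class": name,
            "n": n,
            "shared_count": shared,
            "shared_pct": 100.0 * shared / n if n else np.nan,
            "introgressed_count": intro,
            "introgressed_pct": 100.0 * intro / n if n else np.nan,
        })
    return pd.DataFrame(rows)
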