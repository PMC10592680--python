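"""Forward Wright-Fisher simulation and genotype samplers.

The generator produces cohorts with the statistical structure the analysis
assumes: segregating biallelic sites with known ("true") ages, derived
allele counts from a sample of 2n chromosomes, EP annotations whose sign
correlates with the selection regime, and heterozygote counts drawn from
the post-selection conditional distribution given the observed allele
count.

The population model is a haploid-size-2N Wright-Fisher recursion with
viability selection.  Each generation the derived-allele frequency p maps
deterministically to

    p* = (p^2 w_DD + p(1-p) w_H) / (p^2 w_DD + 2 p(1-p) w_H + (1-p)^2 w_AA)

and the next generation is a binomial(2N, p*)/2N draw.  Frequencies 0 and
1 are absorbing.

A sampled site's "true age" is the number of generations between the
mutation's origin and the sampling time.  Cohorts are generated by pairing
a uniform origin time on [1, max_gens] with a forward trajectory and
rejecting pairs that are not segregating at sampling; under a stationary
origination process this is exactly the age distribution of segregating
variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import SiteRecord

MODEL_LABELS = ("neutral", "additive_positive", "additive_negative", "overdominant", "staggered")
_BASES = "ACGT"


@dataclass(frozen=True)
class SelectionModel:
    """A diploid fitness scheme (w_anc_hom, w_het, w_der_hom) for the derived allele.

    ``s`` is the selection coefficient parameterizing the scheme.  The
    staggered-sweep model additionally carries ``r``, the per-generation
    probability of recombining away from the linked recessive deleterious
    background, and ``s_del``, the recessive cost of that background.
    """

    label: str
    s: float = 0.0
    w_anc_hom: float = 1.0
    w_het: float = 1.0
    w_der_hom: float = 1.0
    r: float = 0.0
    s_del: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in MODEL_LABELS:
            raise ValueError(f"unknown selection model label {self.label!r}")
        if min(self.w_anc_hom, self.w_het, self.w_der_hom) <= 0:
            raise ValueError("all fitnesses must be > 0")
        if self.label == "neutral" and self.triple != (1.0, 1.0, 1.0):
            raise ValueError("neutral model must have fitness triple (1, 1, 1)")
        if self.label == "overdominant" and not self.w_het > max(self.w_anc_hom, self.w_der_hom):
            raise ValueError("overdominant model requires w_het > both homozygote fitnesses")
        if self.label.startswith("additive"):
            mid = 0.5 * (self.w_anc_hom + self.w_der_hom)
            if not math.isclose(self.w_het, mid, rel_tol=1e-9):
                raise ValueError("additive model requires w_het midway between homozygotes")

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.w_anc_hom, self.w_het, self.w_der_hom)

    # -- constructors ------------------------------------------------------
    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls(label="neutral")

    @classmethod
    def additive(cls, s: float) -> "SelectionModel":
        label = "additive_positive" if s >= 0 else "additive_negative"
        return cls(label=label, s=s, w_anc_hom=1.0, w_het=1.0 + s, w_der_hom=1.0 + 2.0 * s)

    @classmethod
    def overdominant(cls, s: float) -> "SelectionModel":
        if s <= 0:
            raise ValueError("overdominance requires s > 0")
        return cls(label="overdominant", s=s, w_anc_hom=1.0, w_het=1.0 + s, w_der_hom=1.0)

    @classmethod
    def staggered(cls, s: float, r: float, s_del: float) -> "SelectionModel":
        # pre-escape scheme: beneficial allele rides a recessive deleterious background
        if not 0 < r <= 1:
            raise ValueError("escape probability r must be in (0, 1]")
        if not 0 <= s_del < 1:
            raise ValueError("recessive cost s_del must be in [0, 1)")
        return cls(label="staggered", s=s, r=r, s_del=s_del,
                   w_anc_hom=1.0, w_het=1.0 + s,
                   w_der_hom=(1.0 + s) ** 2 * (1.0 - s_del))

    def escaped(self) -> "SelectionModel":
        """Post-recombination scheme of the staggered sweep: additive in s alone."""
        return SelectionModel.additive(self.s)


@dataclass(frozen=True)
class TrajectoryRecord:
    """One simulated frequency path.

    ``freqs`` includes the initial frequency 1/(2N) at index 0; ``fate`` is
    the state at the end of the simulated window; ``true_age`` counts
    generations from origin to sampling and is None for lost alleles.
    """

    origin_gen: int
    freqs: np.ndarray
    fate: str
    true_age: int | None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies outside [0, 1]")
        if self.fate not in ("fixed", "lost", "segregating"):
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.true_age is not None and self.true_age < 1:
            raise ValueError("true_age must be >= 1")
        object.__setattr__(self, "freqs", f)


def expected_freq(p, model: SelectionModel, escaped=None):
    """Deterministic post-selection frequency p*; vectorized over p.

    For the staggered model, ``escaped`` (bool or bool array) selects the
    post-recombination additive scheme per element.
    """
    p = np.asarray(p, dtype=float)
    wAA, wH, wDD = model.triple
    if model.label == "staggered" and escaped is not None:
        eAA, eH, eDD = model.escaped().triple
        esc = np.asarray(escaped, dtype=bool)
        wAA = np.where(esc, eAA, wAA)
        wH = np.where(esc, eH, wH)
        wDD = np.where(esc, eDD, wDD)
    q = 1.0 - p
    num = p * p * wDD + p * q * wH
    den = p * p * wDD + 2.0 * p * q * wH + q * q * wAA
    out = num / den
    return float(out) if out.ndim == 0 else out


def wf_step(p: float, model: SelectionModel, N: int, rng: np.random.Generator,
            escaped=None) -> float:
    """One Wright-Fisher generation: binomial(2N, p*)/2N."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if N < 2:
        raise ValueError("N must be >= 2")
    pstar = expected_freq(p, model, escaped=escaped)
    return rng.binomial(2 * N, pstar) / (2 * N)


def simulate_trajectory(model: SelectionModel, N: int, max_gens: int,
                        rng: np.random.Generator) -> TrajectoryRecord:
    """Run one trajectory from frequency 1/(2N) until absorption or max_gens."""
    p = 1.0 / (2 * N)
    freqs = [p]
    escaped = model.label != "staggered"
    fate = "segregating"
    gens = 0
    for _ in range(max_gens):
        if not escaped and rng.random() < model.r:
            escaped = True
        p = wf_step(p, model, N, rng, escaped=escaped)
        freqs.append(p)
        gens += 1
        if p == 0.0:
            fate = "lost"
            break
        if p == 1.0:
            fate = "fixed"
            break
    true_age = None if fate == "lost" else gens
    return TrajectoryRecord(origin_gen=-gens, freqs=np.asarray(freqs), fate=fate,
                            true_age=true_age)


# ---------------------------------------------------------------------------
# vectorized batch engines
# ---------------------------------------------------------------------------

def _step_batch(p: np.ndarray, model: SelectionModel, N: int,
                rng: np.random.Generator, escaped: np.ndarray | None) -> np.ndarray:
    pstar = expected_freq(p, model, escaped=escaped)
    return rng.binomial(2 * N, pstar).astype(float) / (2 * N)


def simulate_fates(model: SelectionModel, N: int, n_traj: int, max_gens: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Fates and sojourn times for ``n_traj`` trajectories (vectorized).

    Sojourn is the number of generations spent segregating (capped at
    max_gens for trajectories still segregating at the end).
    """
    p = np.full(n_traj, 1.0 / (2 * N))
    sojourn = np.zeros(n_traj, dtype=np.int64)
    escaped = None
    if model.label == "staggered":
        escaped = np.zeros(n_traj, dtype=bool)
    active = np.arange(n_traj)
    for _ in range(max_gens):
        if active.size == 0:
            break
        if escaped is not None:
            flip = ~escaped[active] & (rng.random(active.size) < model.r)
            escaped[active[flip]] = True
        p[active] = _step_batch(p[active], model, N, rng,
                                None if escaped is None else escaped[active])
        sojourn[active] += 1
        still = (p[active] > 0.0) & (p[active] < 1.0)
        active = active[still]
    fate = np.where(p == 0.0, "lost", np.where(p == 1.0, "fixed", "segregating"))
    return pd.DataFrame({"fate": fate, "sojourn": sojourn, "final_freq": p})


def sample_segregating_sites(model: SelectionModel, N: int, count: int, max_gens: int,
                             rng: np.random.Generator,
                             max_batches: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """(final population frequency, true age) for ``count`` segregating variants.

    Rejection scheme: draw an origin time T uniform on [1, max_gens], run
    the trajectory forward T generations, accept iff still segregating.
    """
    freqs: list[np.ndarray] = []
    ages: list[np.ndarray] = []
    got = 0
    batch = max(4 * count, 4000)
    for _ in range(max_batches):
        if got >= count:
            break
        T = rng.integers(1, max_gens, size=batch, endpoint=True)
        p = np.full(batch, 1.0 / (2 * N))
        escaped = np.zeros(batch, dtype=bool) if model.label == "staggered" else None
        active = np.arange(batch)
        g = 0
        while active.size:
            g += 1
            if escaped is not None:
                flip = ~escaped[active] & (rng.random(active.size) < model.r)
                escaped[active[flip]] = True
            p[active] = _step_batch(p[active], model, N, rng,
                                    None if escaped is None else escaped[active])
            still = (p[active] > 0.0) & (p[active] < 1.0) & (T[active] > g)
            active = active[still]
        ok = (p > 0.0) & (p < 1.0)
        freqs.append(p[ok])
        ages.append(T[ok])
        accepted = int(ok.sum())
        got += accepted
        rate = max(accepted / batch, 1.0 / batch)
        batch = int(np.clip((count - got + 1) / rate * 1.5, 2000, 200_000))
    if got < count:
        raise RuntimeError(
            f"could not draw {count} segregating {model.label} sites in {max_batches} batches")
    return np.concatenate(freqs)[:count], np.concatenate(ages)[:count]


def sample_fixed_sites(model: SelectionModel, N: int, count: int, max_gens: int,
                       rng: np.random.Generator,
                       max_batches: int = 200) -> np.ndarray:
    """Fixation (sojourn) times for ``count`` trajectories conditioned on fixation."""
    ages: list[np.ndarray] = []
    got = 0
    # neutral fixation probability is 1/(2N); size batches accordingly
    expect = max(2.0 * model.s, 1.0 / (2 * N)) if model.s > 0 else 1.0 / (2 * N)
    batch = int(np.clip(count / expect * 1.5, 2000, 200_000))
    for _ in range(max_batches):
        if got >= count:
            break
        fates = simulate_fates(model, N, batch, max_gens, rng)
        fixed = fates.loc[fates["fate"] == "fixed", "sojourn"].to_numpy()
        ages.append(fixed)
        got += fixed.size
        rate = max(fixed.size / batch, 1.0 / batch)
        batch = int(np.clip((count - got + 1) / rate * 1.5, 2000, 200_000))
    if got < count:
        raise RuntimeError(
            f"could not draw {count} fixed {model.label} sites in {max_batches} batches")
    return np.concatenate(ages)[:count].astype(float)


# ---------------------------------------------------------------------------
# conditional heterozygote sampler
# ---------------------------------------------------------------------------

def het_count_distribution(k: int, n: int, s: float = 0.0,
                           triple: tuple[float, float, float] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count h given k of 2n.

    Genotype configurations with n_het = h, n_derhom = (k-h)/2 and
    n_anchom = n - h - (k-h)/2 are weighted by the multinomial coefficient
    times post-selection Hardy-Weinberg genotype weights at p = k/(2n):
    (q^2 w_AA, 2pq w_H, p^2 w_DD); the mean-fitness normalizer cancels.
    Default fitnesses are (1, 1+s, 1) — pure heterozygote advantage.
    """
    if triple is None:
        triple = (1.0, 1.0 + s, 1.0)
    wAA, wH, wDD = triple
    if not 0 <= k <= 2 * n:
        raise ValueError(f"k={k} outside [0, {2 * n}]")
    if k == 0 or k == 2 * n:
        return np.array([0]), np.array([1.0])
    h = np.arange(k % 2, min(k, 2 * n - k) + 1, 2)
    n_dd = (k - h) // 2
    n_aa = n - h - n_dd
    p = k / (2 * n)
    q = 1.0 - p
    logw = (
        gammaln(n + 1) - gammaln(n_dd + 1) - gammaln(h + 1) - gammaln(n_aa + 1)
        + n_dd * np.log(p * p * wDD)
        + h * np.log(2.0 * p * q * wH)
        + n_aa * np.log(q * q * wAA)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return h, w / w.sum()


def sample_het_count_conditional(k: int, n: int, s: float,
                                 rng: np.random.Generator) -> int:
    """Draw a heterozygote count from :func:`het_count_distribution`."""
    h, prob = het_count_distribution(k, n, s)
    return int(rng.choice(h, p=prob))


def simulate_het_dataset(freq_spectrum: Sequence[tuple[int, int]], s: float,
                         rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """One conditional heterozygote count per (k, n) spectrum entry."""
    if len(freq_spectrum) == 0:
        raise ValueError("empty frequency spectrum")
    cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    out = []
    for k, n in freq_spectrum:
        key = (k, n)
        if key not in cache:
            cache[key] = het_count_distribution(k, n, s)
        h, prob = cache[key]
        out.append((k, n, int(rng.choice(h, p=prob))))
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """One site class in a synthetic cohort.

    EP values are Beta-distributed with the stated means and a shared
    concentration, ordered so that E[delta EP] has the sign matching the
    selection regime (equal means for the neutral control class).
    """

    model: SelectionModel
    count: int
    site_class: str = "nonsynonymous"
    ep_mean_ancestral: float = 0.4
    ep_mean_derived: float = 0.4
    ep_concentration: float = 8.0
    fixed: bool = False  # condition on fixation instead of segregation

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("class count must be >= 1")
        for m in (self.ep_mean_ancestral, self.ep_mean_derived):
            if not 0 < m < 1:
                raise ValueError("EP means must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    N is the diploid population size; n2 the number of sampled chromosomes;
    max_gens the origination window (default 20N generations, wide enough
    to cover the stationary neutral age distribution).
    """

    N: int = 1000
    n2: int = 1000
    classes: dict = field(default_factory=dict)
    max_gens: int | None = None
    n_genes: int = 60
    mean_gene_length: int = 3000

    def __post_init__(self) -> None:
        if self.N < 2 or self.n2 < 2 or self.n2 % 2:
            raise ValueError("need N >= 2 and even n2 >= 2")
        if not self.classes:
            raise ValueError("cohort config names no site classes")
        if self.max_gens is not None and self.max_gens < 1:
            raise ValueError("max_gens must be >= 1")

    @property
    def window(self) -> int:
        return self.max_gens if self.max_gens is not None else 20 * self.N


def default_cohort_config(N: int = 1000, n2: int = 1000, sites_per_class: int = 2000,
                          s_negative: float = -0.01, s_overdominant: float = 0.05,
                          ) -> CohortConfig:
    """The standard three-class study design.

    A neutral noncoding control class, an additively deleterious
    nonsynonymous class (negative delta EP) and an overdominant
    nonsynonymous class (positive delta EP).
    """
    classes = {
        "neutral": ClassSpec(model=SelectionModel.neutral(), count=sites_per_class,
                             site_class="noncoding_nonregulatory",
                             ep_mean_ancestral=0.4, ep_mean_derived=0.4),
        "deleterious": ClassSpec(model=SelectionModel.additive(s_negative),
                                 count=sites_per_class,
                                 ep_mean_ancestral=0.8, ep_mean_derived=0.15),
        "balanced": ClassSpec(model=SelectionModel.overdominant(s_overdominant),
                              count=sites_per_class,
                              ep_mean_ancestral=0.2, ep_mean_derived=0.55),
    }
    return CohortConfig(N=N, n2=n2, classes=classes)


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def simulate_cohort(config: CohortConfig, rng: np.random.Generator
                    ) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Generate a site table and its true-age table under the configured regimes.

    Sites are laid out on synthetic genes along one chromosome; the
    reference allele is the ancestral state, so parsimony rooting retains
    every site.  Sampled counts k ~ binomial(n2, p_final); k = 0 draws are
    replaced (unobservable), k = n2 sites are fixed in the sample.
    """
    N, n2 = config.N, config.n2
    gene_lengths = np.maximum(
        rng.poisson(config.mean_gene_length, size=config.n_genes), 200)
    gene_starts = np.concatenate([[1], 1 + np.cumsum(gene_lengths + 1000)[:-1]])
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    genome_len = int(gene_starts[-1] + gene_lengths[-1] + 1000)

    sites: list[SiteRecord] = []
    age_rows = []
    used_positions: set[int] = set()

    for name in sorted(config.classes):
        spec = config.classes[name]
        a_anc, b_anc = _beta_params(spec.ep_mean_ancestral, spec.ep_concentration)
        a_der, b_der = _beta_params(spec.ep_mean_derived, spec.ep_concentration)
        need = spec.count
        while need > 0:
            if spec.fixed:
                ages = sample_fixed_sites(spec.model, N, need, config.window, rng)
                ks = np.full(ages.size, n2, dtype=np.int64)
            else:
                pfin, ages = sample_segregating_sites(spec.model, N, int(need * 1.5) + 8,
                                                      config.window, rng)
                ks = rng.binomial(n2, pfin)
                keep = ks > 0
                ages, ks = ages[keep], ks[keep]
            take = min(need, ks.size)
            for i in range(take):
                pos = _draw_position(spec.site_class, gene_starts, gene_lengths,
                                     genome_len, used_positions, rng)
                gene = None
                if spec.site_class == "nonsynonymous":
                    g = int(np.searchsorted(gene_starts, pos, side="right") - 1)
                    gene = gene_ids[g]
                anc = _BASES[rng.integers(4)]
                der = _BASES[(int(_BASES.index(anc)) + 1 + int(rng.integers(3))) % 4]
                ep_anc = float(rng.beta(a_anc, b_anc))
                ep_der = float(rng.beta(a_der, b_der))
                sites.append(SiteRecord(
                    chrom="1", pos=pos, ref_allele=anc, alt_allele=der,
                    anc_state=anc, k=int(ks[i]), n2=n2,
                    ep_ref=ep_anc, ep_alt=ep_der,
                    site_class=spec.site_class, is_cpg=False, gene_id=gene,
                ))
                age_rows.append(("1", pos, "true", float(ages[i])))
            need -= take
    sites.sort(key=lambda s: s.pos)
    ages_df = pd.DataFrame(age_rows, columns=["chrom", "pos", "estimator", "age_gens"])
    ages_df = ages_df.sort_values("pos", kind="mergesort").reset_index(drop=True)
    return sites, ages_df


def _draw_position(site_class: str, gene_starts, gene_lengths, genome_len,
                   used: set[int], rng: np.random.Generator) -> int:
    for _ in range(10_000):
        if site_class == "nonsynonymous":
            g = int(rng.integers(len(gene_starts)))
            pos = int(gene_starts[g] + rng.integers(gene_lengths[g]))
        else:
            pos = int(1 + rng.integers(genome_len))
        if pos not in used:
            used.add(pos)
            return pos
    raise RuntimeError("could not place a unique site position")


def cohort_gene_table(sites: Iterable[SiteRecord], gene_lengths: Mapping | None = None
                      ) -> pd.DataFrame:
    """Per-gene positive-delta-EP-style SNP counts for the dispersion test.

    Counts nonsynonymous sites per gene_id; lengths default to the span of
    observed positions + 1 unless supplied.
    """
    rows = {}
    for s in sites:
        if s.gene_id is None:
            continue
        lo, hi, cnt = rows.get(s.gene_id, (s.pos, s.pos, 0))
        rows[s.gene_id] = (min(lo, s.pos), max(hi, s.pos), cnt + 1)
    df = pd.DataFrame(
        [(g, "1", (hi - lo + 1) if gene_lengths is None else gene_lengths[g], cnt)
         for g, (lo, hi, cnt) in sorted(rows.items())],
        columns=["gene", "chrom", "length", "count"],
    )
    return df
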