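# Methods

This note documents the models, estimators and numerical conventions the
package implements, the study conditions its synthetic-data generator
defines, and the design choices made where the design was genuinely open.

## The rank statistic

Each focal allele carries a value (an age in generations, an F_ST, a
heterozygote count) and a derived allele count k out of n2 sampled
chromosomes. Controls — noncoding sites outside every supplied regulatory
interval set — are partitioned into frequency bins: every k up to
`singleton_k_max` (default 8) forms its own bin regardless of size, and
larger k are pooled in ascending order until each bin reaches
`target_bin_size` (default 500 at desk scale; the binning is the same
construction used at cohort scale with ~75,000-variant bins). Consecutive
pooled bins cover contiguous k ranges, so every focal k between the pooled
minimum and maximum maps to exactly one bin; a trailing partial pool keeps
its own (smaller) bin rather than contaminating the previous bin's
k range. Focal k outside all bins is tallied as unmatched, never silently
dropped.

The rank of a value v in a sorted null of length L is
(#{null < v} + U)/L with U uniform on {0, …, #{null = v}}: the minimum
(untied) value gets rank 0, a value above every null gets 1, and ties are
randomized — the tie rule is applied uniformly to all value types, not
only to the discrete heterozygote counts where it is indispensable.

Under the null the rank is uniform on [0, 1], which fully specifies its
variance; the mean-rank z-test therefore uses 1/12 rather than the sample
variance: z = (mean − 0.5)·√(12 m). The one-sample Wilcoxon test against
0.5 drops exact-0.5 ranks, uses midranks of |rank − 0.5|, enumerates all
2^m sign patterns for m ≤ 15 and otherwise applies the normal
approximation with tie and continuity corrections (the correction shifts
toward the tail being integrated).

## Rooting and ΔEP

Parsimony rooting assigns the derived allele as the one differing from the
supplied ancestral state; sites whose ancestral state matches neither
allele are rejected (tallied, not errors). For age analyses the stricter
filter requiring ancestral = reference is available and is the pipeline
default. ML rooting takes a 4-vector of posterior probabilities (must sum
to 1 within 1e−6), accepts the argmax base only above 0.9, and does not
require a reference match. ΔEP is the exact difference of derived and
ancestral EP. Sites with ΔEP exactly 0 or with a missing EP belong to
neither sign class; they are tallied separately in the class summary.

Class summaries report counts, within-sign-class percentages (fixed +
polymorphic = 100% per sign), mean derived frequency (polymorphic only)
and EP/ΔEP means. Confidence intervals use the bias-corrected bootstrap:
z0 = Φ⁻¹(fraction of bootstrap statistics below the point estimate),
endpoints at the Φ(2z0 ± z_{α/2}) percentiles; jackknife acceleration is
available behind a flag and off by default, matching the cited method's
name ("bias-corrected"). The empirical fraction is clipped to
[1/(B+1), B/(B+1)] so z0 stays finite; an all-equal sample returns the
degenerate interval (θ̂, θ̂). Default B = 2000 for summaries, 1000 for the
coverage experiment.

## ANOVA with Box-Cox

The age comparison fits a main-effects linear model
age^(λ) ~ class + frequency_bin with treatment coding and Type-II sums of
squares (each effect adjusted for the other, no interaction term — the
class main effect is the hypothesis of interest). λ maximizes the Box-Cox
profile log-likelihood on a bounded search over [−3, 3] (scipy's bounded
scalar minimizer, tolerance 1e−5); one pooled λ is fitted per contrast, a
per-stratum option being deliberately out of scope for the default path.
Degenerate inputs: a factor with one observed level is fatal; identical
values in all cells return F = 0, p = 1; a perfectly fitting
non-degenerate model returns p = 0.

A numerical caveat verified during development: λ is only identifiable
when the coefficient of variation is appreciable. For data with CV ≈ 0.01
(e.g. normal with mean 100, sd 1) the profile likelihood is flat over the
whole search interval and the MLE is arbitrary — our implementation and
scipy's `boxcox_normmax` agree to 4 decimals on such samples, both far
from λ = 1. Calibration checks of "λ recovery on normal data" therefore
use CV ≈ 0.25, where the MLE concentrates tightly around 1.

## Balancing-selection tests

**Heterozygote excess.** For each focal site with at least `min_k`
(default 100) derived copies, the observed heterozygote count is ranked in
the frequency-matched null of control heterozygote counts, with randomized
ties, followed by the one-sided ('greater') mean-rank z-test. The power
analysis simulates replicate datasets over the observed frequency
spectrum: given k derived alleles among n diploids, genotype
configurations (n_DD, n_het, n_AA) are weighted by the multinomial
coefficient times post-selection Hardy–Weinberg weights at p = k/(2n)
under fitnesses (1, 1+s, 1) — both homozygote fitnesses fixed at 1, since
pure heterozygote advantage is the hypothesis under test; the mean-fitness
normalizer cancels. The conditional distribution is enumerated exactly
over the ≤ k/2 + 1 admissible heterozygote counts (log-space weights via
gammaln). Per selection coefficient, 1000 replicate datasets are tested at
α = 0.05 against an s = 0 simulated null; the desk-scale study conditions
are 200 focal sites with k drawn uniformly in [100, 900] at n2 = 1000.

**F_ST.** The two-population Hudson estimator with finite-sample
correction: with p_i = k_i/n_i,
F_ST = [(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)],
returning missing on a zero denominator. The estimator slot accepts any
callable with the same signature should a different estimator be wanted.
Focal sites (pre-filtered to age rank > 0.5, pooled derived count ≥ 10)
are ranked in frequency-matched null F_ST distributions and tested with
the one-sided Wilcoxon against 0.5.

**Recombination contrast.** Per-site cM/Mb rates come from a
piecewise-constant genetic-map lookup (row i's rate applies on
[pos_i, pos_{i+1}); left queries take the first rate, right queries the
last). Fixed vs segregating rates are compared by Mann–Whitney U, default
one-sided with fixed greater — the staggered-sweep prediction. The U test
enumerates the full permutation distribution when the pooled size is ≤ 12
(valid under ties) and otherwise uses the tie-corrected normal
approximation with continuity correction; the approximation is accurate to
a few thousandths once both samples exceed ~12.

**Dispersion.** Per chromosome, the observed statistic is the variance
across genes of relative SNP density (per-gene count/length divided by
the mean density — the normalization makes the statistic invariant to
uniform rescalings and leaves the p-value unchanged). The null places the
chromosome total multinomially across genes with probability proportional
to gene length, 200 replicates by default; p = (1 + #{sim ≥ obs})/(1 + B),
one-sided on variance excess. This length-proportional null carries no
linkage clustering, so against a clustered mutational process the test is
anti-conservative; externally simulated per-gene counts (e.g. from a
demographic tree-sequence simulation) can be supplied via `null_counts` to
recover a fully structured null.

**β scores.** Published per-site balancing-selection scores are consumed
as a (position, score) table and compared between positive- and
negative-ΔEP classes with the two-sided Mann–Whitney U.

## The synthetic-data generator

The generator defines the study conditions; it emulates the statistical
structure the analysis assumes, not any particular cohort.

*Population model.* A Wright–Fisher population of N diploids with
viability selection: p* = (p²w_DD + pq·w_H)/(p²w_DD + 2pq·w_H + q²w_AA),
next generation binomial(2N, p*)/2N; 0 and 1 absorbing. Fitness schemes:
neutral (1,1,1); additive (1, 1+s, 1+2s); overdominant (1, 1+s, 1);
staggered sweep (1, 1+s, (1+s)²(1−s_del)) until a geometric(r)
recombination "escape" event, after which the scheme becomes additive in s
alone — a single-parameter stand-in for explicit two-locus dynamics that
reproduces the rise → plateau → fixation trajectory shape.

*Ages.* A site is generated by pairing an origin time T uniform on
[1, max_gens] with a forward trajectory and rejecting pairs not
segregating at sampling (or not fixed, for fixed-derived classes); under a
stationary origination process this rejection scheme yields exactly the
age distribution of segregating variants, and the accepted T is the true
age. The origination window defaults to 20N generations — wide enough to
cover the stationary neutral age distribution, so that long-persisting
balanced alleles can actually be old. Sampled counts are
k ~ binomial(n2, p_final); k = 0 draws are rejected as unobservable and
k = n2 sites are flagged fixed-in-sample.

*Study conditions.* The default cohort: N = 1000, n2 = 1000 chromosomes,
2000 sites per class; a neutral noncoding control class; an additively
deleterious class at s = −0.01 (2Ns = −20, unambiguously selected yet
segregating at observable frequencies); an overdominant class at s = 0.05
(2Ns = 100, strong enough to hold survivors near the p = 0.5
equilibrium). EP pairs are Beta-distributed with concentration 8 and means
ordered by class (0.8/0.15 deleterious, 0.2/0.55 beneficial, 0.4/0.4
neutral), so the ΔEP sign correlates with — but does not perfectly
determine — the regime, as in real EP annotations.

*What it does not emulate.* No linkage or haplotype structure (sites are
exchangeable given their class), no demography (constant N), no mutation
rate heterogeneity (CpG flags are generated unset), and a genetic map
drawn independently of selection. Consequently: passing tests show the
statistics are calibrated and detect the encoded regimes; they cannot show
robustness to background selection, population growth, or map error, and
the pipeline's recombination contrast on purely synthetic data is a
calibration (null) check, not a signal check.

*Determinism.* All randomness flows through one `numpy` Generator; the
pipeline derives per-stage generators from the master seed keyed by stage
name (CRC32), so stages are independently re-runnable and a repeated run
is byte-identical (verified by manifest content hashes).

## Numerical conventions and edge cases

- Coordinates: 1-based site positions; BED 0-based half-open; a site at
  1-based p overlaps [s, e) iff s ≤ p−1 < e.
- Missing genotypes reduce the site's n2 (a sample with any missing allele
  contributes nothing), keeping k/n2 unbiased without imputation; the VCF
  reader never invents calls.
- CpG status: an explicit input flag wins over reference-derived
  trinucleotide context; age analyses exclude CpG-flagged sites.
- Empirical p-values use (1 + b)/(1 + B), never zero.
- ΔEP bins are width-0.1 half-open over [−1, 1] with the last bin closed.
- Bootstrap, binning and ranking treat empty cells as missing (NaN), not
  errors; empty focal sets after a hard filter are errors.

## Problem sizes used in the checks

Calibration and power experiments run at: 10,000 focal / 50,000 null sites
(rank calibration); 2000 sites per class at N = 1000 (sign patterns);
100,000 draws (sampler total-variation); 1000 replicates per selection
coefficient (power); 2000 × B = 1000 (bootstrap coverage); 20,000
trajectories at N = 100 (fixation probability). These sizes give
Monte-Carlo standard errors a factor ≥ 3 below every margin they are
tested against.

## Known limitations

- The heterozygote-advantage power model conditions on the observed allele
  count with both homozygote fitnesses at 1; other dominance schemes are
  expressible through the general fitness-triple sampler but are not part
  of the default analysis.
- The dispersion null ignores linkage (see above).
- Only two-population F_ST contrasts are supported; no global estimator.
- The Wilcoxon/Mann–Whitney normal approximations are accurate to ~0.005
  in their regimes but are not exact just past the enumeration cutoffs;
  the cutoffs (15 and 12) were chosen so enumeration covers the sizes
  where the approximation is weakest.
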