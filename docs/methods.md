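# Methods

This note documents the models, conventions and numerical choices behind
`fulmargsi`, in the order the pipeline runs.

## The assignment model

The package implements conditional GSI with a Dirichlet–multinomial
baseline. For colony k and locus l with observed allele counts
y<sub>kla</sub> (n<sub>kl</sub> = Σ<sub>a</sub> y<sub>kla</sub>) and prior
α<sub>la</sub> = 1/A<sub>l</sub> (A<sub>l</sub> = number of alleles at the
locus across baseline and mixture jointly), the probability of an unordered
genotype is the posterior predictive of two draws without replacement from
the Dirichlet-updated frequency:

- P(a,a) = (y<sub>a</sub>+α<sub>a</sub>)(y<sub>a</sub>+α<sub>a</sub>+1) / ((n+θ)(n+1+θ))
- P(a,b) = 2(y<sub>a</sub>+α<sub>a</sub>)(y<sub>b</sub>+α<sub>b</sub>) / ((n+θ)(n+1+θ)), a ≠ b

with θ = Σ<sub>a</sub>α<sub>a</sub>. These sum to exactly 1 over unordered
genotypes (property-tested). Multilocus log-likelihoods sum over non-missing
loci; missing loci contribute nothing (no imputation). Fixing the allele
universe from baseline + mixture before computing α guarantees novel
mixture alleles receive prior mass rather than zero probability.

**Self-assignment** is leave-one-out: the focal bird's two allele copies
per locus are subtracted from its own colony's counts before scoring, which
equals (exactly, tested) scoring against a baseline built without the bird.
The colony prior is flat 1/K and a bird counts as assigned when its
normalized likelihood reaches the 0.9 threshold.

**Mixture inference** is the conditional Gibbs sampler: baseline counts are
fixed (not updated by the mixture); each sweep draws allocations
z<sub>i</sub> | π ∝ π<sub>k</sub>L<sub>ik</sub> and
π | z ~ Dirichlet(1/K + n<sub>k</sub>). Defaults are 2000 sweeps with 100
burn-in; per-bird posteriors are post-burn-in indicator means. On tiny
instances the sampler agrees with exact Dirichlet-multinomial enumeration
to < 0.02, so results do not hinge on MCMC settings. The fully Bayesian
variant (baseline updated by the mixture) is intentionally out of scope;
the conditional model is standard at these reference sizes.

**z-scores.** For a bird assigned to colony k, z = (logL − μ)/σ where μ
and σ² sum the per-locus mean and variance of log P(g) under colony k's own
posterior-predictive genotype distribution, over the bird's non-missing
loci. Birds from the baseline population calibrate to approximately
standard normal (tested: |mean| < 0.15, sd ∈ [0.8, 1.2]); birds from a
strongly diverged unsampled population score well below −3. σ = 0 (all loci
monomorphic) or no scorable loci yields NaN, reported as undefined.

## QC cascade

Order is fixed and logged: depth/ratio genotype calling → duplicate-sample
removal → per-sample missingness filter → per-locus HWE screen. Each later
stage's denominators depend on earlier removals; re-running the cascade on
its own output removes nothing (tested). Conventions:

- A call needs ≥ 20 reads over its two deepest haplotypes; the second
  haplotype is kept iff depth₂/depth₁ ≥ 0.4; deeper-ranked ties break by
  allele string; haplotypes beyond the top two are treated as sequencing
  error and dropped.
- Missingness is strict: a sample is removed when missing_loci/total_loci
  > 0.2 (29 of 141 loci removes a sample; 28 does not).
- Duplicates: pairs sharing ≥ 30 called loci that match at ≥ 95% of them;
  the member with more missing data is removed. The thresholds are package
  conventions (near-identity rather than exact identity, to tolerate a few
  discordant calls from genotyping error).
- HWE: Monte-Carlo exact test (default 10,000 permutations of the allele
  pool into diploids) rather than an asymptotic chi-square, because
  microhaplotypes are multiallelic with sparse genotype classes. The
  screening p-value is the standard conservative (1 + #{T ≥ T_obs})/(R+1).
  Because the statistic is discrete, that p-value cannot be exactly uniform
  under the null; `hwe_mc_pvalue(randomized=True)` breaks ties uniformly,
  which is exactly uniform for any discrete statistic and is what the
  calibration diagnostics use. Screening decisions always use the
  conservative version. Monomorphic locus-population cells get p = 1 by
  convention. A locus is removed when p < 0.05 in ≥ 3 colonies.

## F_ST

Weir & Cockerham (1984) θ, summing the variance components a (among
populations), b (among individuals within populations) and c (within
individuals) over alleles and loci, with θ = Σa/Σ(a+b+c) (ratio of sums).
Per-locus sample sizes count non-missing calls only; samples with > 20%
missing data are excluded before estimation. Loci with zero total variance
contribute nothing. A delete-one-locus jackknife provides the standard
error used by the recovery checks. The estimator is verified against a
brute-force implementation of the published formulas on random small tables
and against a hand-computed two-colony example.

Divergent-SNP ranking scores each SNP by the maximum absolute per-allele
frequency difference between a colony pair (not heterozygosity-weighted —
the simplest faithful reading of "greatest allele frequency differences"),
sorts descending with positional tie-breaks, takes the top 40 per pair, and
de-duplicates the union. Microhaplotype grouping is greedy by leftmost SNP
with a strict < 150 bp span window; no optimal interval packing, matching
the exploratory character of panel design. BED export is 0-based half-open.

## Impact tests

The per-colony statistic is a 1-df Pearson goodness-of-fit on rounded
integer percentages treated as counts out of 100:
χ² = (o−e)²/e + (o−e)²/(100−e). This percent-as-count form is the package
default because it reproduces the published per-colony statistics exactly
from the printed observed/expected percentages; it deliberately ignores the
real sample size, so a conventional mode on true assigned counts
(`mode="counts"`) is provided and clearly labelled. Rounding to integers
happens before testing (13.7 → 14). Family-wise error across the colony set
is controlled by Holm's sequential Bonferroni (via statsmodels), at
α = 0.05. Note the statistic is asymmetric in (o, e) except when o = e or
o + e = 100.

## Utilization distributions and overlap

UDs are Gaussian kernel densities on a shared lat/lon grid (default 0.25°,
finer than the 0.5° effort grid), with the ad-hoc normal reference
bandwidth per marginal (h = σ·n^(−1/6), the `href` convention) and a
cos(latitude) equal-area weight instead of a named projection — adequate at
the tested extents, with a projection hook left open. Strata need ≥ 5
points; coincident points are an error unless the single-cell delta
fallback is enabled. Longitudes are unwrapped across the antimeridian so
Bering Sea grids stay contiguous, and each stratum's points are placed on
the shared grid's axis.

The q-isopleth is the greedy highest-density cell set: cells sorted by
density (ties broken deterministically by cell index) accumulate until mass
reaches q. For Bhattacharyya's affinity each UD is truncated outside its
own 50% isopleth and **not** renormalized — the only convention consistent
with the stated 0–0.5 range — and the crossing cell is included
fractionally so retained mass is exactly q. This realizes the
continuous-isopleth limit on a finite grid: identical UDs give BA = q
exactly, disjoint cores give 0, and BA ≤ q by Cauchy–Schwarz. An inclusive
tie rule was rejected because it can retain arbitrarily more than q of the
mass (a uniform grid would give BA = 1).

Effort aggregation floors coordinates to 0.5° cells on the unwrapped
longitude axis and sums hooks per cell per season; totals are conserved
exactly. The seasonal effort ratio is per-month:
(hooks_a/months_a)/(hooks_b/months_b), with the 7-month nonbreeding season
(Oct–April) against the 5-month breeding season (May–Sept).

## Synthetic data

The generator's defaults are the study conditions: K = 4 colonies at
F_ST = 0.005 (the middle of the observed 0.003–0.01 range), 140
microhaplotype loci, alleles per locus 1 + min(Poisson(2.9), 9) giving mean
≈ 3.9 and range 1–10 (monomorphic loci allowed), ancestral frequencies
symmetric Dirichlet(1), a 517-bird reference split evenly across colonies
(the per-colony composition of the real reference is unpublished, so an
even split is used), and a 1000-bird mixture with proportions
(0.36, 0.23, 0.27, 0.14) in colony order (Semidis, Pribilofs, St. Matthew,
Chagulak), matching the observed bycatch split.

Colony frequencies follow the Balding–Nichols model,
Dirichlet(p·(1−F)/F), whose single parameter maps directly onto the
Weir–Cockerham F_ST scale (recovery verified at F ∈ {0.003, 0.005, 0.01});
F = 0 is the exact no-drift limit. Genotypes are two independent HWE draws.

Read depths are negative binomial (mean 80, size 5 — chosen so ~2% of
calls fall under the 20-read threshold, matching the high pass rate of real
amplicon data); heterozygote reads split beta-binomially (Beta(40, 40), so
the allelic ratio occasionally fails 0.4); homozygotes gain 1–few stray
reads on another allele with probability 0.05. These settings exercise
every QC filter without overwhelming the data.

Space: breeding-season birds are bivariate normal around their own colony
(σ = 250 km, inside the ~500 km central-place foraging radius);
nonbreeding birds come from a shared wintering field on the Bering Shelf
(σ = 600 km) with probability 1−γ and from a colony-centred cloud with
probability γ = 0.3. γ reproduces the qualitative seasonal ordering
(between-colony overlap higher in the nonbreeding season) without asserting
unmeasured biology. Colony centroids are the approximate real colony
locations; effort is a log-normal field per 0.5° cell per month with a 1.4×
nonbreeding per-month multiplier. No per-colony spatial density parameters
are published, so all spatial defaults are package conventions.

What the generator does **not** emulate: oceanographic structure, vessel
behaviour, movement models, genotyping batch effects, null alleles, or
family structure in the reference. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling models, not
robustness to those real-data complications.

## Problem sizes and determinism

The test suite and acceptance script run the recovery experiments at the
study scale (140 loci, 517 + 1000 birds) with 3 generator replicates for
the mixing-proportion check — a single replicate's error is dominated by
the multinomial draw of the realized labels (sd ≈ 0.013 per colony), so
the replicate mean is the meaningful measure of estimator recovery — and
at 500 loci × 200 birds for F_ST recovery. All randomness flows from
explicit seeds through `numpy.random.SeedSequence`; identical config +
seed gives byte-identical outputs (tested). MCMC checks against exact
enumeration use small instances (K = 2, n ≤ 5) where all K^n allocations
are summed analytically over π.

## Known limitations

- The percent-as-count impact test inherits the original convention's
  insensitivity to sample size; use `mode="counts"` for inference that
  respects n.
- The conditional GSI model slightly shrinks extreme mixing proportions
  toward uniform when the baseline is noisy relative to among-colony
  differentiation (reference ~130 birds/colony at F_ST = 0.005); at the
  study conditions the residual bias is ≲ 0.03 per colony.
- KDE bandwidth, grid resolution and the equal-area approximation all
  influence BA values; comparisons should hold them fixed (the pipeline
  computes all strata on one shared grid for this reason).
- Pairwise F_ST re-estimates components per colony pair; with few loci the
  jackknife SE should be consulted before interpreting small differences.
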