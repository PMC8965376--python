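# fulmargsi

Genetic stock identification (GSI) of seabird fisheries bycatch, built
around the Northern Fulmar metapopulation in Alaska: four large breeding
colonies (Semidi Islands, Pribilof Islands, St. Matthew/Hall Islands,
Chagulak Island) whose birds are caught incidentally by North Pacific
groundfish longline fisheries. The package is for population geneticists
and fisheries scientists who want to assign mixed bycatch samples to source
colonies from a microhaplotype amplicon panel, test whether colonies suffer
disproportionate mortality, and relate colony-specific bycatch
distributions to seasonal fishing effort.

## What it does

1. **Panel design** (`marker_panel`) — from dense SNP genotypes (VCF):
   positional LD pruning (one SNP per scaffold or >100 kb apart), per-colony
   allele frequencies, Weir–Cockerham F_ST (per-locus variance components
   *a*, *b*, *c*; multi-locus θ = Σa / Σ(a+b+c); pairwise colony matrix),
   ranking of divergent SNPs by max |Δp| per colony pair (top 40 per pair),
   and greedy grouping of SNPs within <150 bp into candidate microhaplotype
   amplicons, exported as BED/FASTA.
2. **Genotype QC** (`genotype_qc`) — read-depth genotype calling (≥20
   reads; heterozygote iff allelic ratio ≥ 0.4), duplicate-sample
   detection, per-sample missingness filter (>20% removed), and a
   Monte-Carlo exact Hardy–Weinberg screen (locus removed when p < 0.05 in
   ≥3 colonies), plus observed/expected heterozygosity.
3. **Assignment** (`gsi_core`) — the conditional Bayesian GSI model: colony
   allele counts y with a Dirichlet prior α = 1/A give the
   posterior-predictive probability of an unordered genotype (a, b),

       P(a,a) = (y_a + α_a)(y_a + α_a + 1) / ((n + θ)(n + 1 + θ))
       P(a,b) = 2 (y_a + α_a)(y_b + α_b) / ((n + θ)(n + 1 + θ)),   θ = Σα,

   multiplied over loci. Leave-one-out self-assignment measures panel
   power; bycatch is assigned by a Gibbs sampler over mixing proportions
   π ~ Dirichlet(1/K) and per-bird allocations z; birds count as assigned
   at ≥90% posterior; z-scores flag birds from unsampled populations.
4. **Colony impact** (`colony_impact`) — per-colony 1-df Pearson tests of
   observed vs census-expected bycatch percentages with Holm's sequential
   Bonferroni adjustment.
5. **Spatial overlap** (`spatial_overlap`) — seasonal (May–Sept breeding /
   Oct–April nonbreeding) kernel utilization distributions per colony, 50%
   highest-density isopleths, Bhattacharyya's affinity BA = Σ√(f₁f₂) on
   truncated UDs (0 = disjoint cores, 0.5 = identical), and 0.5°-grid
   longline-effort aggregation with per-month seasonal effort ratios.
6. **Synthetic data** (`synthetic_data`) — a Balding–Nichols generator that
   emulates the study system with known truth (colony frequencies, labels,
   mixing proportions, spatial fields, effort grids), so every stage is
   testable end to end without restricted observer data.

## Worked example

```python
import fulmargsi as fg
from fulmargsi.synthetic_data import SimulationConfig, simulate_bundle

cfg = SimulationConfig(seed=42)      # K=4 colonies, F_ST=0.005, 140 loci,
bundle = simulate_bundle(cfg)        # 517 reference birds, 1000 bycatch
baseline = fg.build_baseline(bundle.reference, bundle.reference_labels,
                             mixture=bundle.mixture)
self_res = fg.self_assign_loo(baseline)
mix = fg.infer_mixture(baseline, bundle.mixture, sweeps=2000, burn_in=100,
                       seed=43)
print(mix.pi_summary.round(3).to_string(index=False))
```

prints

```
   colony  pi_mean  ci_5  ci_95
 Chagulak    0.165 0.142  0.189
Pribilofs    0.280 0.252  0.307
  Semidis    0.321 0.292  0.351
StMatthew    0.234 0.207  0.261
```

i.e. the posterior mean mixing proportions (with 90% credible intervals)
recover the generator's true mixture (0.14, 0.23, 0.36, 0.27) to within a
few percent at this differentiation level, and leave-one-out
self-assignment reports 90.2% accuracy among the 47.2% of reference birds
that pass the 0.9 criterion. Feeding the assignments and a colony census
into `fg.impact_report` then flags the colonies whose bycatch share departs
from their population share:

```
   colony  observed_pct  expected_pct    chi2  p_adjusted  significant
 Chagulak            15            34 16.0873      0.0002         True
Pribilofs            28             6 85.8156      0.0000         True
  Semidis            36            30  1.7143      0.1904        False
StMatthew            22            30  3.0476      0.1617        False
```

Here the smallest colony (Pribilofs) is over-represented in bycatch and the
largest (Chagulak) under-represented — the disproportionate-mortality
signal the pipeline is designed to detect.

A thin CLI chains the stages on disk:

```bash
fulmargsi run-all workdir/          # simulate -> qc -> assign -> impact -> overlap
fulmargsi panel --vcf snps.vcf --labels colonies.csv --out panel/
```

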