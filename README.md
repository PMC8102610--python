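# conigen

Post-genotyping conservation population genomics for hierarchically
structured, drift-dominated species — built for reduced-representation
(e.g. ddRAD) SNP panels from declining mammals sampled across isolated
remnant populations, where the questions are *how is genomic diversity
distributed across the landscape* and *which populations must be
conserved to retain it*.

The package covers the full analysis chain downstream of genotype
calling:

1. **SNP/sample filtering** — locus call rate, minor allele count,
   observed-heterozygosity ceiling, within-window LD pruning, sample
   missingness, in a fixed audited order with a per-stage report.
2. **Diversity and differentiation** — per-population A, A_E, H_O, H_E
   (small-sample corrected), F_IS and P_E; pairwise Nei F_ST (Nei–Chesser
   corrected components, deme-number-corrected among-population term) and
   Hedrick's standardised G″_ST with permutation p-values; dosage-based
   kinship screening with a robustness-rerun sample list; PCoA on Nei
   (population) or Prevosti (individual) genetic distances.
3. **Spatial autocorrelation** — Smouse–Peakall multilocus correlograms
   with permutation null envelopes.
4. **Hierarchical diversity cascade** — Rao's Quadratic Entropy converted
   to effective diversities and partitioned multiplicatively into
   grand-total (γ), among-region (δ), within-region (σ),
   among-population-within-region (β) and within-population (α)
   components, with a Bartlett (or permutation) homogeneity test.
5. **Conservation prioritisation** — hypergeometric rarefied allelic
   richness, leave-one-out population contributions
   C_i = (AR(t) − AR(−i)) / (AR(t) − 1), and a resampled maximum-coverage
   reserve-selection analysis solved exactly by subset enumeration.
6. **Niche hypervolumes** — one-class-SVM environmental occupancy models
   per lineage with Monte-Carlo volume estimates and Jaccard/Sørensen
   overlap.
7. **Synthetic data** — a hierarchical Balding–Nichols generator (regions
   drift from an ancestral pool, populations drift within regions) with
   planted kin pairs, missing data, region-specific environmental niches
   and geographic layouts, so the entire chain is testable without any
   external dataset.

## The model in brief

Allele frequencies follow a two-level Balding–Nichols hierarchy: for each
locus with ancestral frequency p₀, region frequencies are drawn
p_r ~ Beta(p₀(1−F_R)/F_R, (1−p₀)(1−F_R)/F_R) and population frequencies
analogously from p_r with F_P; genotypes are Binomial(2, p_rp) under
Hardy–Weinberg. Expected pairwise differentiation is F_P within a region
and 1 − (1−F_R)(1−F_P) between regions, and the Nei F_ST estimator used
here recovers those values (see `conigen.simdata.expected_fst`).

Diversity partitioning works in effective-number space: per locus
D = 1/(1−Q) with Q = 1 − Σp² , stratum D is the arithmetic mean over
loci, and the hierarchy satisfies exactly

    D_GT = D_AR × mean_r D_WR(r)        D_WR(r) = D_AP(r) × mean_p D_α(p)

with sample-size-weighted (or unweighted) stratum means, so the reported
δ and β are exact multiplicative complements of the within-stratum terms.

## Worked example

```python
from conigen import (SimulationConfig, simulate_dataset, filter_snps,
                     pairwise_fst, cascade, loo_contributions, max_coverage)

cfg = SimulationConfig(n_loci=10_000, seed=42)   # 2 lineages x 2 populations
g, popmap, env = simulate_dataset(cfg)
panel, report = filter_snps(g)
print(f"retained {report.n_loci_out} loci x {report.n_samples_out} samples "
      f"({report.missing_fraction:.1%} missing)")
# retained 3462 loci x 42 samples (1.5% missing)

print(pairwise_fst(panel, popmap, n_perm=0).fst.round(2))
#       pop1  pop2  pop3  pop4
# pop1  0.00  0.19  0.35  0.33
# pop2  0.19  0.00  0.37  0.35
# pop3  0.35  0.37  0.00  0.19
# pop4  0.33  0.35  0.19  0.00

casc = cascade(panel, popmap)
print(f"gamma={casc.gamma:.3f} delta={casc.delta:.3f}")
# gamma=0.344 delta=0.073

sel = max_coverage(panel, popmap, budgets=(1, 2, 3, 4), n_iter=100, seed=1)
print(sel.coverage.round(3))
# budget 1: 0.798   2: 0.933   3: 0.974   4: 1.000
```

Reading the output: populations within a lineage (pop1/pop2 and
pop3/pop4) are moderately differentiated (F_ST ≈ 0.19) while every
between-lineage pair is far more isolated (≈ 0.33–0.37), exactly the
structure the generator plants. The cascade attributes the largest
between-stratum share of effective diversity to the lineage split
(δ = 0.073 against β ≈ 0.03–0.04 within lineages), and the
maximum-coverage analysis shows the diminishing-returns curve typical of
allele coverage: one well-chosen population already covers ~80% of
alleles, two populations — always one from each lineage — cover ~93%.

The same pipeline runs from the shell:

```
conigen simulate --out data --seed 42
conigen run --config pipeline.yaml
```

where `pipeline.yaml` points at a VCF (or dosage CSV), a population map
CSV (`sample,population,region,lat,lon`) and an environment CSV, and
every stage writes one labelled CSV.

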