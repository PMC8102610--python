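# Methods

This note records the statistical definitions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Synthetic data: hierarchical Balding–Nichols generator

`simdata` draws, per locus, an ancestral frequency p₀ uniform on a folded
minor-allele range (default 0.1–0.5, avoiding reference/alternate
asymmetry), then region frequencies p_r ~ Beta(p₀(1−F_R)/F_R,
(1−p₀)(1−F_R)/F_R) and population frequencies from p_r with F_P; the
F = 0 limit copies frequencies exactly rather than degenerating the Beta.
Genotypes are Binomial(2, p) under Hardy–Weinberg; missingness is
completely at random; planted kin replace an existing individual with a
Mendelian offspring of two others in the same population, keeping the
configured sample sizes. Defaults emulate a two-lineage island/mainland
system: 2 regions × 2 populations with n = (15, 10, 6, 11), 10⁴ loci,
F_R = 0.5 and F_P = 0.2 (expected between-lineage F_ST
1 − (1−F_R)(1−F_P) = 0.6, within-lineage 0.2 — the drift-dominated scale
of strongly fragmented small mammals), 2% missing calls, region-specific
environmental Gaussians separated by many pooled SD in the rainfall
dimension (disjoint niches), and population centroids placing the two
mainland sites ~800 km apart and the two island sites adjacent, with 2 km
within-population scatter (the within-site sampling scale is a free
choice; 2 km matches trapping-grid extents).

The generator contains no migration, selection, linkage or coalescent
machinery: every downstream statistic consumes allele-frequency structure
only, and the Beta hierarchy controls that directly. Consequences worth
knowing when interpreting green tests: simulated loci are physically
unlinked, so LD pruning on *unstructured* simulations removes only
chance-correlated pairs (duplicated loci can be planted to exercise the
pruner deterministically), while on *structured* simulations pooled-sample
dosage correlation between divergent loci is real and pruning removes
many of the most differentiated loci — the same behaviour pooled-sample
pruning has on real structured data, and the reason post-filter
differentiation is attenuated relative to the generator's expectation.
Passing tests demonstrate correctness of the statistics under
drift-dominated equilibrium structure; they do not probe admixture
clines, isolation-by-distance gradients within populations, null alleles
or genotyping error.

## Filter cascade

Five stages in a fixed order: locus call rate ≥ 0.80 → minor allele
count ≥ 3 → observed heterozygosity ≤ 0.5 (paralog screen) → LD pruning →
sample missingness ≤ 0.25. Stage counts depend on the order; the report
records each stage so reruns are auditable. LD pruning compares the
dosage correlation of locus pairs closer than 100 kb within a scaffold
against a threshold of 0.5 on |r| (the r² convention is a config switch),
using pairwise-complete observations and skipping pairs sharing fewer
than 10 samples. Which member of a correlated pair is dropped is
deterministic: the locus with more missing data, then the later position.
Comparisons use a 10⁻⁹ guard above the threshold so correlations exactly
at the boundary (rational values are common in dosage data) are
consistently *not* pruned regardless of floating-point path.

## Differentiation

Per-locus H_S and H_T for a population pair use the Nei–Chesser
small-sample corrections (harmonic-mean sample size, observed-
heterozygosity terms). Multi-locus aggregation is a ratio of sums:
per-locus ratios are unstable when H_T is small. The among-population
component carries the deme-number correction for k = 2 sampled demes:
D′_ST = k/(k−1)(H_T − H_S), H′_T = H_S + D′_ST, F_ST = D′_ST/H′_T. This
form reaches exactly 1 for fixed differences and is unbiased for the
drift coefficient of a Balding–Nichols pair (the uncorrected ratio
1 − H_S/H_T has expectation f/(2−f), i.e. 0.11 at f = 0.2 — a property of
the estimator, not of the data). G″_ST applies the Meirmans–Hedrick
standardisation to the same components:
G″_ST = k(H′_T − H_S)/((kH′_T − H_S)(1 − H_S)); it equals 1 whenever the
pair shares no alleles and is ≥ F_ST when H_S > 0. Significance is a
one-sided permutation test (individuals reshuffled between the pair, 1000
permutations by default so the smallest attainable p is 1/1001); negative
point estimates are reported as computed, never clamped — clamping is a
display choice.

## Kinship screening

One dosage-based estimator is implemented: pairwise allele matching
M = mean over loci of (x_i x_j + (2−x_i)(2−x_j))/4, centred by the mean
matching M₀ over all within-population pairs, β = (M − M₀)/(1 − M₀)
(Weir–Goudet-style). Under this scaling unrelated pairs sit near zero,
parent–offspring pairs near the pedigree kinship 0.25 and duplicated
samples near 0.5. Flag thresholds of 0.125 (half-sib/PO boundary) and
0.25 are retained as configuration; the default screen flags > 0.125.
The "pruned" list removes the higher-missingness member of each flagged
pair greedily, and the pipeline reruns diversity/differentiation on that
list to report paired differences (a robustness check, not a correction).

## Ordination and distances

Population-level distance is Nei's (1972) standard distance
D = −ln(J_xy/√(J_x J_y)); individual-level distance is the Prevosti
distance (mean |dosage difference|/2 over shared loci). PCoA is classical
metric scaling: double-centre the squared distances, eigendecompose,
order axes by eigenvalue; percent variance uses only positive eigenvalues
and negative ones are logged and excluded from the denominator.

## Spatial autocorrelation

Smouse–Peakall multivariate r: squared Prevosti distances are
double-centred to a covariance matrix C; for distance class k,
r_k = Σ c_ij over unordered pairs in the class / Σ c_ii over the
individuals those pairs involve. The null reshuffles whole genotypes
across the fixed geographic locations (999 permutations by default),
giving a two-tailed 95% envelope and rank-based p per class. Default
class edges {0, 1, 5, 10, 50, 100, 500, 1000} km are log-spaced to
resolve both fine-scale decay (< 5 km) and long-range persistence
(> 100 km); empty classes report NaN rather than erroring. Geographic
distances are haversine with Earth radius 6371 km.

## Diversity cascade

With unit mismatch distance between distinct alleles Rao's quadratic
entropy collapses to Q = 1 − Σp² per locus. Aggregation across loci
happens in effective-number space (D = 1/(1−Q), arithmetic mean over
loci, back-transform), and the hierarchy is partitioned multiplicatively:
D_AR = D_GT / mean_r D_WR(r) and D_AP(r) = D_WR(r) / mean_p D_α(p), with
sample-size-weighted means by default and an unweighted switch. This
locus-aggregation/weighting combination is the single largest
reconstruction risk in the module — the family of Q-partition methods
does not pin it down uniquely — which is why both weighting modes are
exposed and the partition identities are asserted to 10⁻⁹ on every run
rather than assumed. Homogeneity of within-region diversity is tested by
Bartlett's variance test on the per-locus D values grouped by region
(degenerate zero-variance groups report NaN); because per-locus D values
are far from Gaussian a permutation alternative (population labels
permuted between regions, statistic = range of region σ values) is
provided. The cascade operates on the complete-case panel (loci with any
missing genotype dropped), as the metric is undefined under missingness.

## Rarefaction and prioritisation

Per locus with allele counts N_a summing to N, rarefied allelic richness
at g copies is AR = Σ_a [1 − C(N−N_a, g)/C(N, g)] (expected distinct
alleles in a hypergeometric subsample; computed via log-gamma for
stability and verified against exhaustive enumeration). The default
g = 8 copies suits minimum group sizes of 4 diploids. Loci where *any*
group has fewer than g genotyped copies are excluded listwise (a
per-locus skipping alternative is available), so group values are
computed on a common panel. Leave-one-out contributions
C_i = (AR(t) − AR(−i))/(AR(t) − 1) may be negative — a depauperate group
can raise pooled richness when removed; note the parenthesisation: it is
the only reading that yields a bounded proportional loss. Count-based
rarefaction depends weakly on total N, so an exact duplicate of a group
has a small non-zero contribution that vanishes as groups grow large
relative to g.

Reserve selection: each of 100 iterations draws 4 individuals per group
without replacement, marks an allele present in a group iff observed in
the subsample, and solves maximum coverage exactly for each budget by
enumerating all C(G, b) subsets (feasible for the ≤ ~10 groups this
analysis targets; unit cost per group, so budget = number of groups).
Ties on covered alleles are broken by the larger rarefied AR of the
selected union, then lexicographically — deterministically, because
selection-frequency splits across iterations must reflect resampling
variation, never randomised tie-splitting.

## Niche hypervolumes

Points are pooled-z-standardised (zero-variance dimensions dropped with a
warning), a one-class SVM (RBF) is fitted per group, and volume is
estimated by uniform Monte-Carlo sampling over the group's bounding box
inflated by 0.5 standardised units per side: volume = box volume ×
inclusion fraction, with a binomial standard error reported. Defaults:
nu = 0.1; RBF bandwidth = (median pairwise distance)/(2√2), i.e.
gamma = 4/h². The raw median heuristic describes the scale of the whole
cloud and lets the boundary balloon roughly one cloud-scale outward —
a ~70% volume overestimate in five dimensions — so the bandwidth is
scaled down, calibrated once against uniform samples of known volume;
both parameters remain configurable and are recorded on the result.
Overlap classifies a single uniform sample drawn over the *intersection*
of the two bounding boxes with both boundaries (sampling the union box
instead starves the estimate when one volume is tiny, e.g. nested
niches); the union volume is V₁ + V₂ − V∩, and disjoint boxes or zero
joint-inclusion points give exactly zero Jaccard and Sørensen. Absolute
volumes depend on boundary-model internals and are not comparable across
estimators — volume ratios and the zero/non-zero overlap distinction are
the robust outputs.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed and is bit-reproducible
given one. The test-suite and acceptance-script simulations use 2–5 × 10³
loci and 10–20 individuals per population — at these sizes the
frequency-level statistics are already within a few percent of their
large-panel values, and the full suite plus acceptance run complete in
well under a minute of compute on one core. The acceptance script scales
the end-to-end run to the generator's full default (10⁴ loci).

## Known limitations

- Only biallelic loci are supported end to end; multi-allelic VCF records
  are counted and skipped at import.
- The kinship screen is a flagging tool, not a relatedness estimator for
  downstream quantitative use; its centring assumes most within-
  population pairs are unrelated.
- The cascade's locus aggregation and stratum weighting follow one
  defensible convention (documented above); other Q-partition software
  may aggregate differently, so cross-package numeric comparisons should
  be made at matched settings.
- Hypervolume estimates inherit one-class-SVM boundary bias; with ≲ d+5
  points per group the fitted volume is dominated by the kernel
  bandwidth, and only presence/absence of overlap should be interpreted.
- The maximum-coverage solver enumerates subsets; beyond ~15 groups an
  integer-programming formulation would be needed.
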