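# Methods

## The measurement model

Monosynaptic retrograde rabies tracing labels two cell populations in each
animal: **starter neurons** (co-infected by helper AAV and rabies,
double-labeled; confined to the dorsal subiculum injection target) and
**presynaptic input neurons** (rabies-only, single-labeled) distributed
across the brain. Every labeled cell is assigned to one of 21 named input
regions — hippocampal CA1/CA2/CA3 sublayers, subiculum (SUB) and
postsubiculum, medial septum–diagonal band (MS-DB), thalamus,
retrosplenial, visual, auditory, somatosensory, temporal-association,
perirhinal, ectorhinal, and lateral/medial entorhinal cortices — or to an
`OTHER_SPARSE` sink pooling sparsely labeled out-of-vocabulary structures
(contralateral CA1, hypothalamus, dentate gyrus, cingulate, midbrain).

For an animal with starter count S and per-region input counts N_r:

- **CSI** (connectivity strength index): `CSI_r = N_r / S`
- **PI** (proportion of input): `PI_r = 100 · N_r / Σ_r N_r` (percent; the
  total includes `OTHER_SPARSE`, so named-region PIs sum to slightly under
  100)
- **overall connectivity**: `Σ_r N_r / S`

These satisfy `CSI_r = (PI_r/100) · overall` identically; the test suite
asserts this to 1e−12 per animal. Aggregation is per-animal-first: group
tables report the mean ± SEM (n−1 denominator, missing at n = 1) of the
per-animal ratios, never ratios of pooled counts — the two differ
substantially when starter counts vary across animals.

Counts are per sampled section (30 µm sections, one of every three
quantified). No sampling-fraction correction is applied anywhere: every
index is a ratio of counts collected under the same scheme, so the factor
cancels.

### Inclusion rules

An animal is excluded when (a) any starter cell lies outside SUB
("starter leakage" — the tracing origin is then ambiguous) or (b) it has
zero starters (indices are undefined). `OTHER_SPARSE` records are retained
in whole-brain totals (hence in PI denominators and overall connectivity)
but never appear in per-region outputs or comparisons. Filtering is
idempotent and reported in a JSON QC ledger.

## AP-axis profiles

Each section carries an anteroposterior (AP) coordinate in mm relative to
bregma (negative = posterior; the injection target sits at −3.52 mm).
Binning a region's input counts by AP at Δ = 0.1 mm and dividing by S
gives a curve whose bin values sum exactly to the region CSI. Δ = 0.1 mm
is the finest honest registration grid given the ~0.09 mm sampling pitch;
it is configurable. Inside an animal's sampled span, empty bins are
genuine zeros; outside it they are censored (missing), not zero. Group
curves average bin-wise over the animals whose span covers the bin, with
per-bin SEM and a low-support flag below two animals.

Two group curves are compared by pairing the group means at every shared
bin and applying the exact two-sided Wilcoxon signed-rank test to the
per-bin differences; the bin is the pairing unit because group sizes
differ, ruling out animal-level pairing. The area under a curve uses the
trapezoidal rule over its support (a single-bin curve has zero area).

## Statistical battery

**Exact rank tests.** Cohorts are small (8–12 animals per group, 3–7 per
sex-stratified subgroup), so both Wilcoxon tests use exact null
distributions: midranks for ties, doubled to integers, and a subset-sum
dynamic program that reproduces complete enumeration of all
C(n1+n2, n1) group assignments (rank-sum) or 2^n sign patterns
(signed-rank) in polynomial time. Two-sided p = 2·min(lower tail, upper
tail), capped at 1. The exact path is taken whenever C(n1+n2, n1) ≤
700,000 — which covers the largest cohort comparison, 10 vs 12 animals
(C(22,10) = 646,646) — and for signed-rank n ≤ 30; beyond that, a tie- and
continuity-corrected normal approximation is used and the method is
recorded in the result. Signed-rank zeros are dropped (Wilcoxon
convention); all-zero differences return p = 1 with a degenerate flag.
Consequences worth knowing: the smallest attainable p is a combinatorial
floor (2/252 ≈ 0.0079 at 5 vs 5; 2/126 ≈ 0.0159 at 4 vs 5; 2/792 ≈ 0.0025
at 5 vs 7), and the test is conservative — its null rejection rate at
nominal 0.05 equals the largest attainable level (0.0426 for 10 vs 12
continuous data, lower still under ties), which the acceptance suite
verifies against the exactly computed attained level rather than assuming
a uniform p-value distribution.

**Multiple comparisons.** Within each (group-pair × metric) family of 21
regions, Benjamini–Hochberg step-up adjustment controls the FDR at
q = 0.05. The genotype/age battery (four pairs × CSI/PI) is adjusted; the
sex battery (male vs female within each genotype × age group) is
unadjusted by default, with a switch, mirroring the original analyses
where FDR control is documented only for the genotype/age families.
Whether CSI and PI should share one family is undecidable from the source;
per-metric families were chosen and are fixed here. Significance stars
follow the conventional ladder (≤0.05 *, ≤0.01 **, ≤0.001 ***,
≤0.0001 ****). Reported direction is the sign of the group-mean
difference.

**Mixed-effects model.** Plaque size and intensity are measured once per
plaque — hundreds per animal — so two-group contrasts use
`value_ij = β₀ + β₁·[group=B] + u_i + ε_ij` with a per-animal random
intercept `u_i ~ N(0, σ²_u)`, fit by REML (statsmodels MixedLM), with a
Wald z test on β₁. Wald z is the simplest defensible default; with ~20
animals it is mildly anti-conservative relative to a
degrees-of-freedom-corrected test (null rejection rates a few points above
5% are expected and visible in the calibration outputs). The pooled
alternative — treating plaques as independent — pseudo-replicates the
animal and shows an order-of-magnitude inflated false-positive rate under
between-animal variance; the acceptance suite demonstrates the contrast
quantitatively. Gradient optimizers can diverge when σ²_u sits on its zero
boundary; the fit retries with a derivative-free optimizer and keeps the
best converged solution, which at the boundary coincides with pooled OLS.
Pairwise group contrasts refit the two groups involved rather than using
one omnibus model. Density metrics (plaques/mm², intraneuronal cells/mm²)
are one value per animal and use the exact rank-sum test.

Plaque intensities are taken as provided (no background subtraction —
the upstream measurement protocol does not specify one).

## The synthetic cohort generator

No per-animal counts were released with the published cohort summaries, so
the generator emulates the hierarchical structure the analysis assumes,
parameterized from those summaries; it is first-class, tested code and the
pipeline's fixture factory.

Tracing arm, per animal of group g: starter count
`S = max(5, round(LogNormal))` with group means 95 / 101 / 65 / 132 (WT
young, WT middle, 5xFAD young, 5xFAD middle) and log-SD 0.5; per region
`N_r ~ NegBin(mean = κ_{g,r}·S, dispersion θ)` with κ defaulting to the
published group-mean CSI values and θ = 5 — the published between-animal
SEMs imply overdispersion well beyond Poisson, and θ = 5 reproduces the
SEM magnitudes of the large regions within a factor of ~2 (a stated
assumption, not an estimate; tunable). `OTHER_SPARSE` receives 4% of
expected inputs, consistent with named-region PI totals of ≈95–96%.
Counts are allocated multinomially over sections on a 0.09 mm AP grid
using truncated-Gaussian region kernels at anatomically plausible centers
(MS-DB anterior at +0.9 mm, entorhinal cortex posterior at −4.6 mm; the
kernels are synthetic conveniences — the source does not parameterize its
curves). Starters are spread over dorsal-SUB sections. Sex composition
defaults to the study's rosters (3M/5F, 5M/5F, 6M/4F, 5M/7F).

Plaque arm, per animal of a genotype × age × sex subgroup: plaque count
~ Poisson(density × field area) with the published sex-specific densities
and a 0.02 mm² field; log-normal sizes (within-animal log-SD 0.5,
between-animal intercept log-SD 0.1) whose means match the published
68.7–150 µm² range; normal intensities truncated at zero (within-SD 600,
between-SD 150 AU); Poisson intraneuronal counts. All wild-type rates are
zero. Five animals per subgroup by default.

What the generator does **not** emulate: spatial correlation of cells
within sections, per-animal AP-kernel variability, counting error,
atlas-assignment ambiguity, left–right asymmetries, or any
viral-efficiency biology. Passing tests therefore certify the arithmetic,
the exactness and calibration of the statistics, and detection power under
the assumed hierarchical count model — not robustness to those real-data
features.

## Problem sizes and numerical choices

Monte-Carlo experiments use sizes chosen as standard desk-scale designs:
power of the middle-age genotype contrast over 200 replicate 10-vs-12
cohorts (≥80% required for CA1_py with the correct direction); null
calibration over 150 replicate families; mixed-model null calibration over
500 replicates of 10+10 animals × 20 measurements and effect detection
over 100 replicates of 5 animals × ~300 plaques per group (≥95%
required); generator-mean recovery at 400 animals (within 5%). The
rank-sum implementation is verified against literal brute-force
enumeration on 1,000 randomized tied datasets to 1e−12, and BH against the
definitional step-up on 1,000 random vectors. All simulations are seeded;
identical seeds give byte-identical outputs end to end, including the CLI.

Tie-breaking and degenerate inputs: midranks everywhere; two-sided
doubling capped at 1; 1-vs-1 comparisons give p = 1; empty samples raise;
animals with zero plaques contribute zero density and missing mean
size/intensity; a mouse's AP curve requires at least one section; group
curves require ≥5 shared bins for comparison.

## Known limitations

- The published per-animal data are unavailable, so published table values
  serve as generative parameters, not as reproduction targets; only
  self-contained arithmetic (combinatorial p-value floors, index
  identities) is checked against printed numbers.
- The Wald-z mixed-model p-value is mildly anti-conservative at small
  animal counts (no Satterthwaite correction).
- The random-intercept model is the only mixed structure supported (no
  random slopes or crossed effects) — sufficient for two-group repeated
  measurements, by design.
- "Paired" curve comparison assumes bin-level pairing of group means; with
  equal group sizes an animal-level pairing would be possible and would
  differ.
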