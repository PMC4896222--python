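# Methods

`ssrmap` implements an association-mapping workflow for diversity panels
of inbred crop accessions genotyped at multi-allelic SSR
(microsatellite) loci: diversity statistics, population structure and
kinship, linkage disequilibrium, a Q+K mixed-model genome scan,
allele-effect estimation against the null-allele reference, elite-allele
mining and cross design.  This note records the models, the defaults and
the genuinely open design choices.

## Data model

Inbred accessions are effectively homozygous, and SSR genotyping scores
one amplified fragment per accession and locus, so genotypes are
haploid-coded: one allele label (fragment size, bp) per cell, or a
*null allele* when the primer pair fails to amplify.  The null allele is
modelled as a missing-at-random amplification failure, independent of
the underlying genotype — the simplest model consistent with scoring it
as "non-amplified".  Files use the literal token `NA`; in memory the
cell is a missing value in a nullable-integer matrix, never conflated
with an absent record.

## Synthetic panels

The generator draws, per locus, ancestral allele frequencies from a
symmetric Dirichlet over the locus's allele count (3–25 by default),
then subpopulation frequencies from a Balding–Nichols-style Dirichlet
`Dir(p · (1−F_ST)/F_ST)` — the standard drift model for structured
frequencies.  Accessions receive admixture proportions
`Dir(α, …, α)` over `K` subpopulations and sample one allele per locus
from their personal mixture frequency.  Defaults emulate a
628-accession, 262-locus rice panel with `K = 7`, `F_ST = 0.15` and
`α = 0.2` (appreciable admixture), two years × two replicates, and a 3%
null-allele rate.

Phenotypes come from a handful of planted QTL with additive per-allele
effects (null allele contributes 0), an optional subpopulation-level
confounding term `Q · shifts` (used to build structured null traits for
calibration), per-year additive shifts, and replicate noise with
variance chosen so that line-mean heritability
`Var(g) / (Var(g) + σ²_e/n_reps)` hits the per-trait target (0.92–0.98
by default, matching highly heritable grain-size traits).  Trait means
and effect scales are set to grain-trait magnitudes (e.g. grain length
≈ 7.8 mm, SD contributions of a few tenths of a millimetre).

What the generator does **not** emulate: map-aware gametic LD (linkage
disequilibrium in simulated panels arises only from structure and
drift, so simulated decay curves are qualitative), stepwise mutation,
pedigree or selection.  Passing tests therefore demonstrate the
estimators' correctness and calibration under a standard structured
model, not the historical LD architecture of any real panel.

## Diversity statistics

Allele frequencies exclude null calls from the denominator (the panel
summary counts amplified alleles).  Gene diversity is `1 − Σp²`; PIC is
Botstein's `1 − Σp² − 2·Σ_{i<j} p²_i p²_j`; loci are classed highly
(PIC > 0.5), moderately (0.25 < PIC ≤ 0.5) or slightly (PIC ≤ 0.25)
informative.  Summaries round as conventionally printed: allele means
to 1 decimal, diversity/PIC to 4 decimals.

"Nei's distance" between single inbred individuals is ambiguous among
the 1972/1978/1983 variants, but for one haploid profile per
"population" they all reduce to allele sharing; the implemented
distance is `1 − (shared alleles)/(co-amplified loci)`.  The
neighbor-joining tree uses the Saitou–Nei algorithm via scikit-bio with
negative branch lengths clamped at zero; it is exact on additive
matrices, which is the tested contract.

## Population structure and kinship

The admixture model is fitted by EM on the haploid multi-allelic
likelihood `P(x_i) = Π_l Σ_k q_ik f_kl(x_il)`.  This is a deliberate,
deterministic-given-seed surrogate for Bayesian MCMC clustering: same
Q-matrix contract, no correlated-frequency prior, restarts controlled
by a seed.  The log-likelihood is monotone over iterations; stopping is
`|Δloglik| < tol` or an iteration cap.  Model selection uses Evanno's
`ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K))` over restarts with an
sd floor of 1e-6 and ties resolved toward the smaller (more
parsimonious) K.

Kinship is background-corrected allele sharing,
`k_ij = (s_ij − s̄)/(1 − s̄)` with `s̄` the mean off-diagonal sharing —
a natural relatedness estimator for haploid SSR profiles.  The model
copy is clamped at zero, given a unit diagonal, and repaired to
positive semidefiniteness by flooring eigenvalues at zero so it can
serve as a covariance matrix.  The reported histogram uses the
conventional <0.05 / 0.05–0.10 / >0.10 bins.

## Linkage disequilibrium

For two multi-allelic loci, two-locus haplotypes are directly observable
in inbreds.  `D′` is the frequency-weighted mean `ΣΣ p_i q_j |D′_ij|`
with the standard `D_max` normalisation; on biallelic pairs it equals
classical `|D′|` (tested against the direct 2×2 formula).  Significance
is by permutation of one locus's calls across accessions,
`p = (#{D′_perm ≥ D′_obs} + 1)/(n_perm + 1)`; 1,000 permutations is the
test-scale default and 100,000 is available by flag.  Null-allele
accessions are dropped pairwise.  Subpopulation membership is the hard
argmax of the Q row; groups under 10 accessions are skipped.  The
scan's "ratio" column normalises each subpopulation's significant-pair
count by the total across subpopulations.  Significance is raw
`p < 0.05`, deliberately without multiple-testing correction, matching
the reporting convention for this kind of panel summary.

Decay is summarised by least squares on `D′ = b·ln(x) + c` over
syntenic significant pairs.  "Decay distance" has no canonical
definition; here it is the distance at which the fitted curve falls to
a critical background D′, by default the 95th percentile of
non-syntenic (inter-chromosomal) D′ in the same subpopulation — the
usual background-threshold practice — and the threshold is exposed as a
flag.

## Quantitative genetics

Descriptives (mean, sample SD, CV%, Fisher excess kurtosis, adjusted
skewness — conventions chosen and documented since several exist) are
computed on accession means per year.  Variance components come from a
one-way genotype ANOVA on replicate-level data within a year:
`σ²_e = MSE`, `σ²_g = (MSG − MSE)/n̄` with `n̄` the harmonic-mean
replicate count; negative moment estimates are truncated at zero and
flagged.  Broad-sense heritability of line means is
`H² = σ²_g / (σ²_g + σ²_e/n)` with `n` the replicates within a year
(2 by default), reported per year in percent.  Trait correlations are
Pearson on accession means per year with t-test stars at 0.05/0.01.

## Q+K association scan

The mixed model `y = Xβ + u + e`, `u ~ N(0, σ²_g K)`,
`e ~ N(0, σ²_e I)`, carries an intercept and the first K−1 admixture
columns (dropping one avoids collinearity with the intercept).  REML is
a one-dimensional profile over the variance ratio on the eigenbasis of
the kinship matrix (EMMA-style): a coarse grid over log-ratio in
[−12, 12] followed by bounded scalar minimisation, deterministic given
inputs.  Variance components are estimated once per trait-year on the
covariate-only model and re-used for every marker (P3D), which keeps a
628 × 262 scan in seconds without materially changing p-values.

Each marker enters as an allele-class factor.  Rare classes (fewer than
5 carriers by default, always including singletons) are collapsed into
one "rare" class for F-test stability at up-to-25-allele loci;
accessions with a null call at the marker are excluded from its test
(but participate in allele-effect estimation, where null is the
reference class).  The marker test is a GLS F-test computed on the
whitened scale (inverse Cholesky of `σ²_g K + σ²_e I` on the marker's
accession subset).  PVE is `(RSS_null − RSS_marker)/TSS × 100`, with
TSS the whitened intercept-only residual sum of squares.  A trait-locus
pair is retained when `p < 0.05` (strict) in **both** years and PVE
exceeds 5% in at least one year; both choices are flags.  No
multiple-testing correction is applied by default (matching the
scan's reporting convention); a Benjamini–Hochberg variant can be
applied downstream by the user.

Calibration under a structured null (trait driven by subpopulation
shifts, no marker effects) is part of the acceptance suite: the Q+K
scan's type-I error stays near nominal 5% while a naive one-way ANOVA
rejects a large fraction of null markers — the rationale for the mixed
model.

## Allele mining and cross design

The effect of allele i at an associated locus is
`a_i = Σx_ij/n_i − ΣN_k/n_k`: mean phenotype of its carriers minus the
mean of null-allele accessions at that locus.  Phenotypes are
per-accession means across both years and replicates (a per-year
variant is available).  If a locus has no null-allele accession the
reference falls back to the population mean with an explicit flag.
Alleles with favourable effects (positive for traits to increase; a
direction flag covers the converse) are elite; singleton carriers are
never marked elite (minimum 2 carriers, a flag).  The "typical carrier"
is the highest-phenotype carrier among the trait's top-30 accessions,
falling back (flagged) to the best carrier overall.

Cross prediction assumes a derived inbred line fixes one allele per
locus: per associated locus the elite alleles carried by either parent
are pooled and the largest-effect one retained; the predicted effect is
the sum over loci.  All unordered pairs are scored exhaustively
(desk-scale for panels up to ~1,000 accessions) and ranked by elite
count, then predicted effect, with lexicographic tie-breaks for a total
order.

## Pipeline and reproducibility

The pipeline runs simulate → diversity → tree → structure → kinship →
ld → qstats → assoc → mine → cross from a single YAML config.  A
manifest records SHA-256 hashes of each stage's inputs and outputs;
stages whose outputs exist with unchanged input hashes are skipped, so
corrupting one intermediate reruns only its downstream stages.  Every
stochastic stage derives its randomness from the single pipeline seed,
and two runs with the same config and seed produce byte-identical
outputs.

## Problem sizes in the test and acceptance runs

Unit and property tests use panels of 60–200 accessions and 10–40 loci.
Parameter-recovery suites use the sizes the estimators were designed
for: heritability recovery and scan calibration at n = 600 accessions
(20 and 10 phenotype draws respectively, ~250+ null tests), ΔK recovery
at 150 accessions × 40 loci with K ∈ 2…6 and 5 restarts, and the
acceptance script exercises the full study-scale 628 × 262 panel for
diversity, structure (K ∈ 5…9), kinship, a 30-locus LD subset with 200
permutations, the complete five-trait two-year scan, mining and cross
design.  These sizes were chosen so the entire workflow remains a
desk-scale computation while leaving the statistical behaviour of every
estimator observable.

## Known limitations

- The admixture EM is a point-estimate surrogate; it reports no
  credible intervals and can converge to local optima (mitigated by
  restarts, which ΔK consumes anyway).
- Allele-sharing kinship is unbiased only relative to the panel's own
  background; it is a relative, not absolute, relatedness scale.
- The LD decay distance depends on the chosen critical D′; with few
  syntenic significant pairs the log-linear fit is fragile, and the
  pipeline skips subpopulations where it is undefined.
- REML assumes a single polygenic variance component; no marker-by-year
  interaction or spatial field effects are modelled.
- Simulated LD decays with map distance only insofar as structure
  induces it; decay-curve parameters are not calibrated to any real
  panel.
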