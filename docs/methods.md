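# Methods

`rcscan` implements the statistical machinery of a strain-panel genome scan
for a quantitative immune trait (plasma IgE) measured in a panel of
recombinant congenic strains (RCS) derived from A/J and C57BL/6J mice, plus
a generative simulator of such panels so that every stage of the pipeline is
testable without access to the original animal data.

## The genetic material: RCS panels and how we simulate them

An RCS is produced by crossing two inbred strains, backcrossing the F1 twice
to one parent (the recurrent or *major donor*), and then brother–sister
mating until the line is fully inbred. Each backcross halves the expected
contribution of the other parent (the *minor donor*), so after two
backcrosses (the N3 generation) a fixed line carries on average
(1/2)^3 = 12.5% minor-donor genome, in a mosaic of chromosomal blocks.
AcB strains have A/J as the recurrent parent (carrying C57BL/6J segments);
BcA strains are the reciprocal. The default panel is 10 AcB + 21 BcA
strains, the composition of the classical AcB/BcA set.

The simulator (`rcscan.simulate`) makes this breeding scheme explicit:

- **Meiosis.** Crossovers per chromosome are Poisson with mean equal to the
  chromosome's genetic length in Morgans, positions uniform on the cM axis
  (no interference). Adjacent-marker recombination therefore follows
  Haldane's map function, c = (1 − e^(−2d))/2, which the tests verify
  against the closed form.
- **Backcrossing.** The final backcross litter provides the two sibs that
  found the inbreeding line; earlier backcrosses are single offspring.
- **Inbreeding.** Sib-mating proceeds until all four line haplotypes agree
  at every marker, with a cap (default 20 generations; per-locus
  heterozygosity decays by a factor ≈ 0.809 per generation, so residual
  heterozygosity after 20 generations is ~1% of segregating loci). Residual
  heterozygous segments are then fixed by adopting one of the four line
  haplotypes, chosen uniformly per contiguous segment — this guarantees
  termination while preserving both the expected donor fraction and local
  block structure.
- **Consomics.** `make_css_strain` builds chromosome substitution strains
  (one whole donor chromosome on an otherwise pure background), used for
  the three-group follow-up comparisons.

The default marker map places 1215 markers (the density of the classical
mouse SNP/microsatellite marker lists) over chromosomes 1–19 and X,
proportionally to mm10 physical lengths and evenly spaced within a
chromosome. Genetic positions use a uniform 0.5 cM/Mbp, giving a ~13 Morgan
genome close to the mouse consensus map. Real maps can be supplied as TSV.
The X chromosome is simulated and scanned like an autosome: the study design
uses inbred male animals, so parental-origin coding is well defined either
way.

## Phenotype model

Animal-level log2(IgE) is

    log2(IgE) = m_c + Σ_q β_q · 1[allele at q = A/J] + u_s + ε

with condition baseline means m_c (defaults 7.0 / 9.0 / 10.0 log2 ng/ml for
baseline / OVA-PBS / OVA-OVA, reflecting the rise of IgE with allergen
sensitization and challenge), additive QTL effects β_q in log2 units,
a strain random effect u_s ~ N(0, 0.25) shared across conditions, and an
animal residual ε ~ N(0, 0.5). Group sizes are drawn uniformly from 5–20
animals per strain and condition. Reported IgE is 2^(log2 value), so it is
strictly positive and the log2 transform used throughout the analysis is
exactly invertible. The default planted QTL effect is 1.5 log2 units on
chromosome 4.

What the generator does *not* emulate: dominance and epistasis (lines are
fully inbred and effects are additive), sex and litter effects, assay
(ELISA) measurement error beyond the lognormal residual, and the real
panel's pedigree idiosyncrasies (exact inbreeding depth, per-strain residual
heterozygosity). Passing tests therefore demonstrate correctness of the
statistical machinery under a clean additive lognormal architecture, not
robustness to those real-data features. One real-data feature the generator
*does* reproduce is family structure: because AcB strains are ~87.5% A/J and
BcA strains ~87.5% C57BL/6J, genotypes are correlated genome-wide through
family membership, and a strong QTL produces associated markers on other
chromosomes. This is a property of RCS panels themselves, not an artifact.

## Strain-level statistics

All statistics operate on log2-transformed IgE. `summarize_strains` gives
mean ± SEM per strain and condition. `parental_contrast` is a two-sided
pooled-variance two-sample t-test (Welch available by flag); the pooled
flavour matches the one-way ANOVA framework used for the other comparisons.
"Informative" strains — RCS whose phenotype differs from their major
parental strain — are flagged by `dunnett_many_to_one`: t statistics on the
ANOVA-pooled error against the familywise null distribution of max |T_i|,
where the T_i are equicorrelated multivariate-t with ρ_ij = λ_i λ_j and
λ_i = sqrt(n_i / (n_i + n_0)) (or the balanced λ = 1/√2 by flag, since
software implementations differ for unbalanced designs; both are exposed).
The adjusted p-value is evaluated by deterministic quadrature —
Gauss–Hermite over the shared normal factor × Gauss–Legendre on the
probability scale of the pooled-error chi factor, 64 nodes each, accurate to
~1e-6 — with a seeded Monte-Carlo alternative (`method="mc"`). At k = 1 the
adjusted p equals the two-sample pooled t-test p, a reduction the tests
check to 1e-3 and that holds to quadrature accuracy. Three-group consomic
comparisons use pairwise contrasts on the pooled ANOVA error with Bonferroni
adjustment (p × 3, capped at 1).

## The genome scan

The unit of analysis is the **strain mean** of log2 IgE (the ~31 strain
means are exchangeable under the null, which is what makes the permutation
construction valid; permuting animal-level data within a strain structure
would not be). Parental and consomic strains are excluded from the response
by default: their genotypes are constant genome-wide, so any marker would
absorb their whole-genome background difference.

Per marker, genotype is coded 0 = C57BL/6J allele, 1 = A/J allele (positive
slope means the A/J allele raises IgE); heterozygous and missing calls are
dropped per marker, and markers with fewer than 3 strains in the minor
allele class are skipped (`monomorphic` or `class_size<3`), keeping the
slope test non-degenerate. The per-marker test is the OLS slope t-test,
which for a binary regressor is algebraically the pooled two-sample t-test
between allele classes — a duality the tests enforce to machine precision.
The scan is vectorised (centered cross-products across all markers at once),
which is what makes 10,000-permutation thresholds and simulation studies
cheap.

Genome-wide significance uses the familywise permutation construction:
shuffle the strain labels of the response, re-run the full scan, record the
genome-wide maximum −log10(p); the threshold is the empirical (1 − α)
quantile of those maxima (default α = 0.05, 10,000 permutations). The
quantile is the ceiling-rule order statistic (k = ⌈q·n⌉), so the threshold
is always an actually observed permutation value; `threshold_p` is exactly
10^(−threshold_neg_log10). Permutations are applied to the sorted response
values, so for a fixed seed the threshold depends only on the multiset of
strain means and the genotypes — exactly invariant to strain relabeling.
Skipping decisions depend on genotypes only, so the same marker set is
tested in every permutation.

Significant regions are maximal runs of contiguous significant markers
(p ≤ threshold_p) on one chromosome, reported as the closed physical
interval between the outermost significant markers in Mbp (2 decimals), with
the run's smallest p as the peak. Skipped markers are transparent; a
non-significant tested marker splits a run (a configurable `max_gap` relaxes
this); peak ties break to the lowest position. Single-marker regions are
allowed (start = end). Regions never span chromosomes.

## Problem sizes and numerical choices

Simulation studies in the test suite and the acceptance script use the
design-scale panel — 31 strains × 1215 markers — with 1000-permutation
thresholds and 100–200 replicates; these sizes give Monte-Carlo standard
errors comfortably below the effects being measured (e.g. ±1.5 percentage
points on a 5% familywise rate at 200 panels). Breeding-composition checks
use 200 strains. All stochastic stages draw from `numpy` `SeedSequence`
spawns of a single master seed, so every run is byte-reproducible; the CLI
refuses to run stochastic stages without a seed.

Degenerate inputs are handled explicitly: constant responses give t = 0 and
p = 1 rather than NaN; two identical constant groups in a t-test return
p = 1 (a null by construction) and zero pooled variance with unequal means
returns p = 0; a zero pooled ANOVA variance flags the Dunnett comparison as
degenerate rather than emitting p-values.

## Known limitations

- The simulator matches the published panel only in its stated composition
  (~12.5/87.5) and dimensions; the true pedigrees differ.
- Permutation of strain means treats them as exchangeable; unequal group
  sizes make their variances mildly unequal (residual/n on top of the strain
  variance), which is the usual, slightly imperfect, approximation.
- No interval mapping, kinship/mixed-model correction, multi-QTL selection
  or epistasis scans — the method is a single-marker scan by design.
- The Dunnett quadrature assumes the one-factor (product-correlation)
  structure of many-to-one contrasts; it is not a general multivariate-t
  integrator.
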