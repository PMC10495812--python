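# Methods

`consgen` implements the quantitative workflow used to delimit conservation
units in a narrowly distributed plant from two marker systems: diploid
nuclear microsatellites (nSSRs) and haploid, non-recombining chloroplast
sequence (cpDNA).  This note documents the models, estimators, numerical
choices and limitations; the package README shows the user-facing workflow.

## Differentiation statistics

**AMOVA.** All differentiation measures derive from the analysis of
molecular variance: squared genetic distances between units are partitioned
into hierarchical variance components via sums of squares, degrees of
freedom and the unequal-sample-size coefficients of the classical
random-effects scheme.  Two decompositions are available: two-level
(among/within strata, index F_ST or φ_ST) and three-level
(groups / populations within groups / within populations, indices F_CT,
F_SC, F_ST).  Significance comes from label permutations: units among
strata for the two-level index; whole populations among groups (F_CT),
individuals among populations within groups (F_SC) and individuals among
populations (F_ST) for the three-level case.  p-values use the
(hits + 1)/(n_perm + 1) estimator, so a reported p is never 0.

**Distances.**  For genotypes the codominant squared distance is half the
squared Euclidean distance between allele-count vectors summed over loci
(0 identical genotype, 1 one shared allele, 2 heterozygotes with no shared
allele, 3 AA–BC, 4 AA–BB); missing genotypes are dropped pairwise.  For
sequences the distance is the count of differing sites after
complete-deletion filtering (below).

**Wright's F_ST vs. the genotype-level φ.**  The genotype-level AMOVA index
(individuals as units) is not Wright's F: under Hardy–Weinberg its
expectation is ≈ 2F/(1+F), because the between-individual variance of a
genotype doubles the allele-level deme effect while the within-deme
genotype variance does not.  `wright_fst` therefore decomposes variance at
the allele-copy level (gene copies as units, allele identity as distance),
summing per-locus components across loci; this estimator is calibrated —
on F-model data its replicate mean recovers the target F (checked to
within 2 Monte-Carlo standard errors in the tests).  The package reports
both: `wright_fst` as "F_ST" and the genotype-level AMOVA percentages as
the variance table, which is also how the two numbers coexist in the
literature this workflow serves (an F_ST near 0.11 beside an among-group
variance fraction near 18%).

**F′_ST.**  Standardized differentiation is F_ST/F_ST(max), with
F_ST(max) computed on a recoded table in which each group's alleles are
made private (allele `a` in group `g` becomes the pair `(g, a)`), which
preserves within-group frequencies while removing all between-group
identity.  The same construction on collapsed haplotypes (with 0/1
identity distance) gives φ′_ST for sequences.

**R_ST and the allele-size permutation test.**  R_ST uses allele sizes in
repeat units: per-locus among/within variance components of size, summed
across loci (this equals an AMOVA with squared size differences as
distances).  The null hypothesis "mutation contributes nothing to
differentiation" is tested by permuting the sizes assigned to the allelic
states within each locus (10,000 permutations by default), giving the
permutation mean pR_ST and a one-sided p.  R_ST ≫ pR_ST indicates
phylogeographic structure — stepwise-similar alleles co-occurring within
groups.  Monomorphic loci are excluded with a warning.  Sizes must be on
the repeat scale; `MsatGenotypeTable.to_repeat_scale()` divides by the
declared repeat unit.

**Diversity.**  Per locus and stratum: Na (allele count),
Ne = 1/Σp², Ho (observed heterozygote fraction), He = 1 − Σp² (a
2n/(2n−1) unbiased switch is available but off by default) and
F_IS = (He − Ho)/He, which is NaN — never a silent 0 — when He = 0.
The Hardy–Weinberg test is Monte-Carlo: the 2n allele copies are shuffled
into random diploids and the heterozygote count's absolute deviation from
its permutation mean is the statistic.  This replaces the exact enumeration
test of the GENEPOP family; for the sample sizes this package targets
(tens to hundreds of diploids) the Monte-Carlo null is indistinguishable
from exact in the calibration tests.

## Sequence statistics

Sites containing a gap or an ambiguous base in any sequence are excluded
alignment-wide (complete deletion) for all SNP-based statistics; haplotype
collapse compares full sequences including indels (ambiguous columns
masked), since indels are real, heritable variation in non-recombining
plastid DNA but are not modelled by the neutrality-test theory.
Haplotype diversity uses Nei's unbiased form h = n/(n−1)(1 − Σ(f/n)²).
π is the mean pairwise proportion of differing usable sites.  Tajima's D
uses the standard constants with π on the per-alignment scale; Fu & Li's
D* and F* (no outgroup) use total mutations η and singletons η_s with the
corrected variance constants of the DnaSP lineage of implementations.
All three are NaN when S = 0.

## Coalescent simulator

Demographies (diploid sizes, times in generations): SNM (constant N), PGM
(exponential growth at forward rate G since t generations ago, ancestral
size N·exp(−G·t) — the equivalent backward-time rate convention writes
this ancestral size as N·exp(G·t) with G the backward rate), SRM
(instantaneous decline at t1 from Nb > N), and DVM (two demes split from
an ancestor of size N_anc at T, migration active from T to the present).
Migration rates are per gene copy per generation; `m21` is the fraction of
deme-1 copies that are immigrants from deme 2, so N_cur1·m21 is the
expected migrant count per generation.

The event-driven structured coalescent (a numba-compiled kernel) races
exponential waiting times for within-deme coalescence (rate k(k−1)/(4N))
and per-lineage migration; exponential size trajectories are integrated in
closed form (time-rescaled waiting times); demes merge at the split time.
Verified against closed forms (E[T2] = 2N, E[TMRCA] = 4N(1−1/n), stepwise
equilibrium He = 1 − 1/√(1+8Nμ), all within 3 SE at 2,000 replicates) and
cross-checked against msprime on a divergence model.

**GSM mutation.**  Mutations are Poisson on branches; each moves the
allele size by ±k with geometric k (parameter P_GSM; P_GSM = 0 is the
strict stepwise model, mean step 1/(1−P_GSM)).  No size boundaries are
imposed (sizes are identifiable only up to translation in every statistic
the package computes; a per-locus shift keeps stored sizes positive).
Per-locus rates are Gamma(shape, shape) multiples of the mean rate
μ = 5×10⁻⁴ per generation, rescaled so the across-locus mean equals μ
exactly (`normalize_mu`, on by default — the rescaling is the documented
interpretation of "gamma heterogeneity around a fixed mean").

## ABC

Summary statistics follow the ARLSUMSTAT set: mean and SD across loci of
allele number, He and allele-size range; two-group mode adds the pooled
size range and Nei's G_ST.  Reference tables allocate simulations equally
across candidate models.

**Model choice** uses a 1000-tree classification random forest; the
selected model is the majority vote at the observed vector, the prior
error rate is the out-of-bag (OOB) misclassification rate, and the
posterior probability of the selection is a regression-forest estimate of
P(correct | summaries) fit to the OOB outcomes.

**Parameter estimation**: retain the nearest ceil(tolerance·n) rows by
Euclidean distance in SD-normalized summary space, then adjust draws by
weighted local-linear regression (Epanechnikov weights; a
single-hidden-layer neural-network adjustment is available).  Parameters
with bounded uniform priors are logit-transformed to their bounds before
regression — this keeps adjusted draws inside the prior support, which
plain log-scale adjustment does not; strictly positive unbounded
parameters are log-transformed.  The posterior mode is the maximizer of a
Gaussian KDE (Silverman bandwidth) on a 512-point grid; the 95% HPD is the
narrowest contiguous window holding 95% of the draws.  Goodness of fit
simulates pseudo-observed datasets from the joint posterior and locates
each observed summary in its predictive distribution (two-sided doubled
tail p with the +1 estimator).

**Priors.**  The divergence-model priors are T ~ U(1, 10⁴) generations,
N_anc ~ U(10², 10⁴) truncated below at the fixed current sizes (the
divergence analysis assumes N_cur < N_anc), m ~ U(10⁻⁵, 0.3); current
sizes are fixed-value entries carried over from the single-population
stage.  The size-change priors (SNM/PGM/SRM) and the mutation hyperpriors
(shape ~ U(0.5, 5), P_GSM ~ U(0, 1), one value shared across loci whose
posterior is reported as the per-locus mean) are this package's defaults,
chosen as weakly informative ranges around plausible microsatellite
values; they are exposed in `snm_spec`/`pgm_spec`/`srm_spec`/`dvm_spec`
and any OOB error rate naturally depends on them.

## Synthetic data

`balding_nichols_table` is the F-model: group allele frequencies are
Dirichlet(p_anc·(1−F)/F) draws, genotypes Hardy–Weinberg within groups.
It gives direct control of the expected F_ST, separating statistic
calibration from simulator testing; defaults emulate the motivating
design (two groups totalling 467 diploids, 8 loci, F ≈ 0.11, allele sizes
on a 10–40 repeat support).  `two_clade_cpdna` builds two star-like
haplotype clusters separated by fixed differences, clade labels attached
and order randomized — two old organelle lineages admixed in space.
What the generators do **not** emulate: genotyping error, null alleles,
linkage, isolation-by-distance within groups, recombination and rate
variation along the chloroplast, and real spatial coordinates.  Passing
tests therefore demonstrate correctness of the estimators and decision
rule under the stated models, not robustness to those artefacts.

## Unit delimitation

Two groups are distinct **management units** iff the nuclear
differentiation permutation p < α (default 0.05) *and* every directional
dispersal rate is below 10% per generation (the threshold is applied per
direction; the rule's source phrasing does not say whether the 10% is per
direction or summed, and per-direction is the stricter reading under
asymmetric flow).  Distinct **evolutionarily significant units**
additionally require organelle clades that are reciprocally monophyletic
and spatially segregated; the pipeline operationalizes "spatially
segregated" as φ_ST between spatial strata exceeding a configurable
threshold (default 0.2) with permutation p < α, replacing a visual
judgement with an explicit criterion.  Missing plastid evidence marks the
ESU decision indeterminate (reported as one ESU with a flag).  Migration
input comes from the package's own divergence-model posterior or from
externally supplied per-generation rates.  The decision is monotone:
lowering p or m never decreases the number of units.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed; identical config + seed
reproduce byte-identical pipeline reports.  The test suite and the
acceptance script use scaled designs chosen to estimate each quantity to
useful precision: 2,000 replicates for coalescent closed forms, 200
datasets × 199 permutations for null-calibration (a design with ≥8 alleles
and 8 loci keeps permutation ties — which make discrete permutation tests
conservative — negligible), a 20,000-row reference table for the HPD
coverage experiment (20 repeated observations against one table), and
4,500–6,000-row tables for the model-choice runs.

## Known limitations

* The HWE test is Monte-Carlo, not exact enumeration.
* Genotype-level AMOVA percentages and allele-level F_ST answer different
  questions (see above); users comparing against frequency-based software
  should use `wright_fst`.
* The coalescent kernel supports at most two contemporary demes (the
  models above); no recombination, selection or SNP ascertainment.
* Local-linear adjustment can concentrate posterior mass near a prior
  bound when the observed summaries sit at the edge of the simulated
  cloud; the rejection posterior is always available for comparison and
  the recovery test asserts the two agree within an HPD width.
* GenePop export requires allele sizes ≤ 3 digits; convert to repeat
  scale first for base-pair-scaled tables.
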