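# Methods

This note documents the models, estimators and numerical choices behind
`paleotempo`, and what the synthetic-data experiments do and do not
demonstrate about real ancient-DNA panels.

## Data model

A `GenotypeDataset` is a sites × samples matrix of alt-allele dosages
(diploid 0/1/2, pseudohaploid 0/2, −1 missing) with a site table
(chromosome, 1-based position, ref/alt, transversion flag) and per-sample
metadata (group, age in years BP, ancient flag, coverage). Pseudohaploid
samples can never hold dosage 1; this invariant is enforced at construction.
I/O covers EIGENSTRAT (geno/snp/ind; geno counts *reference* alleles, 9 =
missing) and VCFv4.2 (pseudohaploid samples written as haploid GT), with a
TSV metadata sidecar. Coordinates are 1-based inclusive everywhere except
exported BED (0-based half-open).

## Pseudohaploid calling and filters

`pseudohaploid_call` reproduces the conventional ancient-DNA pileup caller:
discard reads shorter than 35 bp or below mapping quality 20 / base quality
30, draw one retained read uniformly at random (seeded), return its allele
as a homozygous dosage, and return missing if the base matches neither
dataset allele. A random draw (rather than majority vote) is the standard
convention and keeps the expected allele frequency unbiased; the marginal
frequency equals the retained-read fraction, which is under test.

`filter_sites` applies, in order: excess-heterozygosity removal (one-sided
Levene exact test of the heterozygote count against Hardy–Weinberg given the
allele counts, among diploid samples only; threshold P < 1e-6 — the
probability of *at least* the observed heterozygotes), indel-carrier
masking, depth masking (below mean/3, above 2×mean, or below 5 reads),
third-allele masking, removal of sites with ≥130 missing genotypes, and an
optional transversion-only restriction (transversion = ref/alt pair not in
{A↔G, C↔T}). Filters are idempotent by construction and tested as such.

Jackknife blocks are consecutive 10-Mb windows per chromosome (trailing
partial windows are their own block; a canFam3.1-like 2.2-Gb genome yields
~225 blocks). On reduced simulated genomes smaller blocks — or one block per
chromosome — are used instead; block size is a parameter everywhere.

## f-statistics

Frequencies are alt-allele fractions per group; a pseudohaploid individual
contributes one allele, a diploid two. Each statistic uses every site at
which its own groups are all non-missing ("allsnps" semantics); a global
site mask can impose an intersection or an ascertainment (e.g. sites
heterozygous in an external outgroup individual, used for the outgroup-f3
matrix and conditional heterozygosity).

Standard errors are weighted delete-one-block jackknives (Busing, Meijer &
van der Leeden 1999) with per-block usable-site counts as weights, since
block occupancy is unequal after filtering. The corrected f3 subtracts the
sampling-noise term p(1−p)/(n−1) of the first population. For joint
covariance matrices of several f4-statistics (qpWave/qpAdm) the classic
unweighted delete-one formula is used: no standard weighted cross-covariance
form exists, and the choice is validated empirically by the null-calibration
experiment below.

Estimates are exactly reproducible by naive per-site evaluation (asserted to
1e-12), and the jackknife SE is compared against the spread of estimates
across independent simulation replicates.

**Finite-block reference distribution.** The qpWave statistic minimises
(x − x̂)ᵀΩ⁻¹(x − x̂) over rank-r x̂ (alternating generalised least squares on
the A·Bᵀ factorisation; rank 0 is the closed-form quadratic form). Because Ω
is estimated from B jackknife blocks, the statistic is referred by default to
the Hotelling-type reference q·(B−dof)/(dof·(B−1)) ~ F(dof, B−dof) rather
than χ²(dof); the two coincide as B grows (at 225 blocks the difference is
negligible) but the χ² reference is visibly anticonservative when a reduced
genome provides only a few dozen blocks. Simulation of 200 panmictic null
replicates shows the F reference restores uniform P-values. Two practical
lessons from that calibration are baked into the default designs: blocks
must be much longer than the local LD scale (or chromosomes used as blocks)
for the independence assumption to hold, and near-singular Ω (small right
sets) is ridge-regularised with λ = 1e-5·trace/dim when the condition number
exceeds 1e12, flagged in the output.

## qpAdm

For target T and sources s₁…sₙ with Σw = 1, linearity of f4 in the target
frequency gives f4(T, r₀; rⱼ, r₀) = Σᵢ wᵢ f4(sᵢ, r₀; rⱼ, r₀) in expectation.
Weights solve this system by constrained GLS: the residual covariance is the
block-jackknife covariance of the residual statistic itself, iterated twice
from an identity-weighted start. Computing each j-statistic on the sites
shared by the target, all sources and both right populations makes the
sampling-noise bias of the shared basis population r₀ cancel under the
sum-to-one constraint. Weight SEs come from a delete-one-block jackknife of
the entire fit with the weighting matrix held fixed. The model P-value is
the rank-(n−1) qpWave test on left = {T, s₁…sₙ}; models with any weight
outside [−0.1, 1.1] are failed regardless of P.

The rotating search enumerates all 1–3-source subsets of a candidate set,
with unused candidates as the right set. Ranking is parsimony-first: any
simpler model with P above the threshold (0.01 by default) outranks every
more complex model; within a source count, models rank by P descending, with
lexicographic source labels as the deterministic tie-break.

## Temporal selection scan

Each site is tested by OLS with sample age (years BP; modern = 0) as the
response and dosage as the predictor. The two orientations give the same
two-sided t-test P; the age-on-dosage orientation is used. χ² is the squared
t-statistic, matching the 1-dof assumption of genomic control
(λ = median(χ²)/0.4549; adjusted χ² = χ²/λ; λ < 1 is retained rather than
clipped, with a clip option, so calibration experiments see the raw value).

Neutral drift makes allele frequencies autocorrelated in time, so the raw
regression χ² is genuinely inflated genome-wide — this is the reason genomic
control is part of the method, not a defect of it. Under the emulated study
conditions (Ne = 50,000, samples spanning ~33,000 generations, 72
pseudohaploid ancient + 68 modern genomes) both a direct Wright–Fisher
calculation and the coalescent pipeline put λ around 4–5. After GC, a ~200-Mb
neutral genome yields zero significant regions at 5×10⁻⁸, and an injected
co-selected cluster (10 sites within 24 kb, logistic trajectory from ~1% at
40 ka to ~99% at 30 ka, s = 0.05) is recovered as a region at the injected
locus.

Filters: ≥40 ancient calls and ancient minor-allele frequency ≥5%
(inclusive thresholds) on ancient samples only; then the neighbourhood
filter retains a site iff ≥7 other sites within a 50-kb window (read as
±25 kb around the focal site; a ±50-kb mode is provided) have
−log₁₀P ≥ 0.9 × −log₁₀P(site), using GC-adjusted P (both raw- and
adjusted-P modes exist). The production implementation is windowed and
sorted but required to agree exactly with an O(n²) oracle; by default it is
evaluated only for sites significant at the region threshold, which leaves
the region list identical while avoiding a full-genome quadratic pass.
Significant retained sites within 50 kb merge into regions (the merge
distance matches the neighbourhood window and is a parameter); regions with
a single significant variant are dropped.

## Summary statistics

*Conditional heterozygosity*: at sites ascertained heterozygous in an
external individual, two reads carrying allowed alleles are sampled without
replacement (seeded); the mismatch fraction estimates half the true
heterozygous fraction (two independent reads from a heterozygote differ with
probability 1/2). SEs by delete-one-chromosome jackknife.

*FST*: Hudson estimator as a ratio of sums,
numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator
p₁(1−p₂) + p₂(1−p₁), with negative per-site numerators retained. In
pseudohaploid-aware mode every individual is reduced to one allele per site
(diploid heterozygotes by fair coin, seeded) so mixed-ploidy pools carry no
spurious within-individual heterozygosity — the pseudohaploid-data analogue
of treating all genomes as inbred. Pools need ≥2 genomes; pair lists can be
restricted by age-midpoint gap (e.g. ≤12,500 years for temporal series).

*Sexing*: X/autosome coverage ratio below 0.75 (midway between the
hemizygous 0.5 and diploid 1.0 expectations) calls a male; the cohort male
fraction gets a Clopper–Pearson 95% CI and an exact two-sided binomial test
against 1:1.

## Synthetic data

The generator is backward-in-time (msprime Hudson coalescent with
recombination), with chromosomes simulated independently — exact for
unlinked chromosomes and the main cost lever. Ancient samples are serial
lineages at round(age/3 years) generations. Mutations use a binary 0/1
model; sites are biallelic, flagged transversion (damage modelling is out of
scope), with strictly increasing integer positions.

The default study design mirrors the emulated panel: 72 ancient samples with
ages uniform on [1, 100] kyr BP plus 68 modern, panmictic Ne = 50,000,
μ = 0.4×10⁻⁸ per site per generation, r = 10⁻⁸, 3-year generations, ancient
coverage 1× (the panel's median; `P(missing) = e^(−cov)` then gives ~46
ancient calls per site, comfortably above the ≥40 filter) and 20×10 Mb
chromosomes (~200 Mb; a genome-wide run only changes the constant in front
of the runtime).

Sweeps are imposed, not forward-simulated: the selected site's genotypes are
redrawn as Binomial(2, p(age)) from the deterministic logistic
p(Δt) = p₀ / (p₀ + (1−p₀)e^(−sΔt)). Linked hitchhiking is emulated by
rewriting a cluster of 8–12 existing nearby sites with the same trajectory
(independent binomial draws per site), which is what the scan's
neighbourhood filter actually consumes; sites on other chromosomes are
untouched, byte for byte.

The admixture-recovery design (`dual_ancestry_design`) is a 20-population
tree: western and eastern clades splitting 1,500 generations ago (Ne =
10,000 per branch), each with a true progenitor, a sampled proxy source
(splitting from the progenitor 250 generations ago) and two sampled
references; a mid-depth reference and a deep outgroup complete the right
set; the target is a single pulse at generation 100. Per-branch drift at
these depths gives qpAdm both the power to reject single-source models and
essentially unbiased weights (verified over replicates).

What the synthetic experiments do *not* show: post-mortem damage and
sequencing error (all reads are error-free; transversion flags make damage
filters vacuous by design), reference bias, real LD structure of a specific
genome build, non-equilibrium demography beyond the configured events, and
hitchhiking haplotype structure. Passing tests demonstrate the estimators
and their calibration under the stated models, not robustness to these
artefacts.

## Problem sizes in the test suite

Simulation scales were chosen once, as the package's own study conditions:
the scan calibration uses the full ~200-Mb design; sweep power re-uses one
neutral background with 10 independent injection/degradation replicates;
admixture recovery uses 20 replicates of ~15 Mb (~58k SNPs) in the test
suite and ~54 Mb (≥200k SNPs) in `scripts/acceptance.py`; qpWave null
calibration uses 200 replicates of 24 short chromosomes (one jackknife block
each). Monte-Carlo tolerances are stated in each test (2–3 SE).

## Known limitations

* The excess-heterozygosity exact test loops per site in Python; it is meant
  for datasets up to a few hundred thousand sites, not 67.8M.
* qpAdm's GLS treats source f4-statistics as fixed regressors; with very
  noisy sources (tiny groups, few SNPs) weights can show attenuation bias.
* The EM low-rank completion for f4-profile PCAs assumes entries are missing
  at random; systematically missing ancient individuals violate this.
* Multi-allelic VCF records are rejected rather than decomposed.
* Block-jackknife SEs are modestly anticonservative (~20-35% in simulation)
  when blocks are not much longer than the local LD scale, as on strongly
  reduced genomes; the F-corrected rank test absorbs this for model
  P-values, but weight SEs inherit it. At genome scale with 10-Mb blocks
  the effect is small.
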