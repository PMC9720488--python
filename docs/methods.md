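# Methods

`resgwas` reimplements, on synthetic data, the full quantitative-genetic
analysis of a single layer-hen production batch: resilience indicators from
longitudinal egg records, heritability of natural-antibody (NAb) titers and
of the indicators with an animal model, and a single-SNP mixed-model GWAS
with genomic-relationship correction and FDR control. The real batch this
emulates (a purebred Rhode Island line, 2,494 hens, 1,221 genotyped) is
proprietary, so a first-class generator reproduces its stated statistical
structure and every stage is exercised against that.

## Synthetic batch generator

**Pedigree.** Two generations: unrelated founder sires and dams, and one
generation of hens partitioned into ~500 maternal families (one dam each,
default 5 hens per family) mated to 50 sires, giving full-sib families
nested in paternal half-sib groups. Hens hatch in 3 fortnightly hatch weeks
(assigned per family, roughly equal thirds) and are housed in 12 barn rows.

**Genotypes.** A configurable SNP map spans five macro-chromosomes, a block
of micro-chromosomes and Z (default 5% of SNPs), with founder allele
frequencies ~ U(0.05, 0.95). Founders draw Hardy–Weinberg genotypes;
offspring genotypes arise by Mendelian gene dropping, one independently
transmitted allele per parent per SNP (loci unlinked — LD decay is out of
scope). Females are hemizygous on Z: dams and hens carry a single Z allele
coded 0/2 (a hen's Z allele is the transmitted paternal one), so true Z
heterozygotes never occur in females and any heterozygous Z call in real
data is an artefact — the motivation for the QC masking rule.

**Breeding values.** Founders ~ N(0, σ²ₐ); a non-founder is the parent
average plus a Mendelian-sampling deviate with variance σ²ₐ/2. The
non-inbred approximation is exact here because pedigree depth is 2 and
founders are unrelated; the implied covariance is A·σ²ₐ (checked
empirically against the tabular A-matrix in the tests).

**NAb titers.** titer = μ + plate + age-class + breeding value + residual.
Defaults: IgM μ = 6.85, σ²ₐ+σ²ₑ = 1.35 at h² = 0.39; IgG μ = 6.03,
σ²ₐ+σ²ₑ = 1.65 at h² = 0.20; 146 ELISA plates filled in hen order with
plate effects ~ N(0, 0.10); age at sampling is confounded with hatch week
(week 1 → 112 d, week 2 → 123/124 d, week 3 → 138 d) with small fixed
effects summing to ~0. These reproduce the published sample means and SDs
(≈6.85 ± 1.21 IgM, ≈6.03 ± 1.33 IgG). The two isotypes are generated as
independent polygenic traits; their genetic correlation is not modelled.

**Egg production.** The batch-mean anchor curve rises linearly from 0 at
week 18 of age to 6.8 eggs/week at week 29 and declines linearly to 4.9 at
week 92 (the two published anchors; the published curve gives no more
shape information, so the simplest curve through them is used). Each hen's
weekly potential is the anchor curve divided by the expected disturbance
loss (see below), plus an additive production level (SD 0.15 eggs/wk) and
a persistency slope deviation (SD 0.01 eggs/wk²) applied post-peak, capped
at 7. Disturbance episodes arrive as Poisson onsets (0.015 per hen-week)
with multiplicative depth ~ U(0.1, 0.8) recovering exponentially
(half-life 1.5 weeks); because laying is sampled weekly, the expected loss
uses the discrete geometric sum rate·E[depth]/(1 − 2^(−1/half-life)), and
dividing the anchor curve by the resulting multiplier makes the realized
batch mean track the anchors within the Monte-Carlo noise of 2,494 hens.
Daily laying is Bernoulli(potential·disturbance/7); hens face a weekly
culling hazard of 0.0025 from week 25 (≈15% lost before the end of lay,
matching the published share of hens excluded from the late period).
Survivors are followed to week 92.

**Registration.** Eggs are recorded on a farm-wide schedule with 1–4-day
gaps. By default a collection is forced on the last day of every age week,
so no interval straddles a week boundary and weekly registered counts stay
in [0, 7]. The real data's rare ">7 eggs in a week" registrations — a
collection-timing artefact — are reproduced only under the
`boundary_overlap_quirk` flag (pure random-walk schedule).

What the generator does **not** emulate: linkage and LD structure,
selection history, genotype-by-environment interaction, maternal effects,
genetic correlations between traits, seasonal/calendar effects, and
production-dependent culling. Tests passing on this generator therefore
show the *estimators* behave correctly under the assumed model, not that
the model captures every feature of commercial data.

## Resilience indicators

Weekly counts assign each collection record to the age week containing its
collection day (week w = days 7(w−1)..7w−1, anchored at hatch; no
proration — with ≤4-day intervals the error is small and the rule is
deterministic). Partially covered edge weeks are dropped. Deviations are
observed minus the batch mean of hens observed that week. Per hen and
period — weeks [25, 83) and week 83 to last observed week; the boundary
week 83 is assigned to the late period —

* **LNvar** = ln of the sample variance (n−1 denominator),
* **Skew** = m₃/m₂^{3/2}, central moments with denominator n (unadjusted
  Fisher–Pearson),
* **Rauto** = lag-one serial autocorrelation
  r₁ = Σ(dₜ−d̄)(dₜ₊₁−d̄) / Σ(dₜ−d̄)², which is bounded in [−1, 1]; a
  Pearson-of-lagged-pairs variant is available behind `method="pearson"`.

The exact denominator conventions are not fixed by the source analysis;
these are the common defaults and are pinned by oracle tests. With week
gaps (possible in real data, not in the generator), non-adjacent pairs are
excluded from the Rauto numerator while the variance and skewness use all
present values. All three indicators are set to missing for hens laying
fewer than 20 eggs in a period, and the filter counts are reported. A
zero-variance deviation series yields missing indicators.

Because the reference curve is the batch mean, a perfectly steady hen
(constant 7 eggs/week) has deviations that grow as the batch declines and
an Rauto above 0.95 — the worked interpretation caveat, reproduced as an
acceptance check. Individual quantile-regression reference curves are a
recognised alternative; a config hook is reserved but not implemented.

## Genotype QC

Three steps in narrative order: (1) drop SNPs with >10% missing calls
(strict); (2) per SNP, set genotype classes with <10 hens to missing, and
mask all heterozygous Z calls; (3) drop SNPs with fewer than two genotype
classes of ≥10 hens (for Z-SNPs only two classes exist; the same ≥2-class
criterion applies). Missingness is computed before masking. The cascade is
idempotent, order-preserving, and its report closes exactly. After QC
every retained SNP has at least two analysable classes — the precondition
the categorical SNP test relies on.

## Relationship matrices

The pedigree A-matrix uses the tabular method. The genomic matrix is
VanRaden method 1, G = WW′/(2Σpⱼ(1−pⱼ)) with W the 0/1/2 calls centred at
observed sample frequencies (base-population frequencies are unknown);
missing calls are mean-imputed (zero contribution) and monomorphic SNPs
excluded from numerator and denominator. Z-SNP calls (0/2 in hens) enter
like autosomal calls. For mixed-model equations G is blended with 1%
identity, which bounds its eigenvalues away from zero without materially
changing relationships.

## Variance components (REML)

The animal model y = Xb + a + e, a ~ N(0, Kσ²ₐ), e ~ N(0, Iσ²ₑ), with one
record per animal (as in this study; the implementation enforces it). The
implementation eigendecomposes K once, rotates the data, profiles σ²ₑ
analytically and maximises the restricted likelihood over the ratio
γ = σ²ₐ/σ²ₑ by a coarse log-grid plus bounded Brent refinement. This was
chosen over an iterative AI-REML update loop because the 1-D profiled
search is globally convergent with no step-control heuristics, and the
eigendecomposition is reused across the eight traits and across simulation
replicates sharing the same relationship matrix, which is what keeps the
parameter-recovery study (60 fits at n = 2,494) in seconds rather than
hours. Fixed effects enter as treatment-coded categorical factors;
linearly dependent columns (e.g. the hatch-week/age confounding) are
dropped deterministically in first-occurrence order with a warning.

Standard errors come from the inverse average-information matrix evaluated
at the optimum, with the delta method for h² = σ²ₐ/(σ²ₐ+σ²ₑ). A flat
profile (e.g. K = I with one record per animal, where only the total
variance is identified) or a singular information matrix flags the fit as
non-identifiable rather than raising. The additive-variance LRT compares
against the γ = 0 model; since the null is on the boundary, the default
reference distribution is the mixture ½χ²₀ + ½χ²₁ (p = ½P(χ²₁ ≥ Λ)); the
plain χ²₁ convention is available via `boundary_mixture=False`.

Numerical choices: γ searched on [0, 10³] (41-point grid, Brent to
xatol 10⁻⁹ on log γ); σ²ₑ floored at 10⁻⁸·var(y); eigenvalues clipped at 0.

## GWAS

Per SNP, the trait model gains the SNP as a categorical factor (one level
per genotype class, most frequent class as reference). The
polygenic-to-residual ratio is fixed at the batch-level REML estimate, so
each SNP model is a GLS fit under V₀ = ratio·G + I; after whitening, the
conditional (incremental) Wald F for the SNP given all other fixed effects
is the ordinary incremental F on the whitened data, with denominator df =
n − rank of the full fixed design (no Kenward–Roger/Satterthwaite
adjustment; at n > 1,000 the difference is negligible). Hens with a
missing call are excluded for that SNP (n varies per SNP); SNP dummy
columns collinear with the base design are dropped by rank-revealing QR,
and a SNP with no surviving contrast is flagged untestable. Complete-call
SNPs share one rotation of the base model; SNPs with missing calls take a
per-SNP Cholesky path.

The inflation factor converts every p-value to a 1-df χ² quantile —
regardless of the test's numerator df, matching the stated convention —
and divides the observed median by 0.45494. In the scaled-down null
experiment (5,000 SNPs, h² = 0.2 family structure) the corrected scan
gives λ ≈ 1.02–1.04: the fixed-ratio approximation and the sampling noise
of a 5,000-SNP GRM leave a small residue, within the ≤1.05 behaviour the
analysis reports, while the uncorrected scan inflates well beyond it.

Q-values follow Storey: π̂₀ from the share of p-values above λ on the grid
0.05–0.95, smoothed by a cubic smoothing spline (GCV-chosen smoothness)
and evaluated at λ = 0.95, clipped to (0, 1]; with fewer than 100 tests
π̂₀ = 1, which makes the q-values exactly Benjamini–Hochberg. Calls use
FDR < 0.10 (suggestive) and < 0.05 (significant).

## Problem sizes in the shipped checks

The acceptance script and end-to-end tests use the batch's stated sizes
where the quantity depends on them (2,494 hens for the lay curve, 1,221
for NAb titers and the null GWAS) and a 5,000-SNP panel — the package's
scaled-down default for a desk-scale scan; unit tests run on far smaller
batches. The pipeline driver accepts any configured scale.

## Known limitations

* One observation per animal (no repeated records, no permanent
  environment effect) and single-trait models only.
* Maternal effects are not modelled (the source analysis discarded them on
  AIC grounds); no multi-trait or genetic-correlation machinery.
* Denominator-df and π̂₀ conventions are decisions where the source is
  silent; both are isolated behind flags or single functions and pinned by
  tests.
* The generator's disturbance and curve models are deliberately simple;
  indicator *values* on synthetic data should not be read as predictions
  for commercial batches.
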