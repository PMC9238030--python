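# Methods

This note documents the statistical procedures implemented in `extremeprs`,
the defaults and numerical choices behind them, and what the synthetic cohort
generator does and does not emulate.

## Study design

The package implements a case-only, extreme-phenotype association analysis in
female *BRCA1/2* pathogenic-variant carriers. The outcome contrasts two
extremes of age at onset: primary breast-cancer diagnosis before age 35
(ED, coded 1) versus cancer-free survival to age 60 (LD, coded 0). The design
deliberately enriches the phenotypic tails, so effect estimates are odds
ratios for tail membership, not hazard ratios for onset age; no survival
model is fitted.

## Quality control

QC runs in a fixed order, each step on the previous step's output:

1. **Call rate.** SNPs with a call rate below `min_call_rate` (default 0.95)
   are dropped first, computed over all samples; sample call rates are then
   computed over the retained SNPs only, and low-rate samples dropped. The
   SNP-first order matters when missingness is concentrated; it is
   configurable in `QcConfig`.
2. **Heterozygosity.** Per-sample heterozygosity rates (heterozygous /
   non-missing calls) are fitted by a normal distribution using the sample
   mean and sample sd (n−1 denominator). Samples outside the α/n and 1−α/n
   quantiles are removed, with α = 0.05 and n the number of samples tested —
   i.e. a Bonferroni correction over samples, applied per tail. Zero
   dispersion yields a warning and no flags. Both the α and the Bonferroni
   family are configurable because reasonable alternatives (correcting over
   tails as well) exist.
3. **Ancestry.** Identity-by-state distances, d(a,b) = 1 − shared/(2·loci),
   are computed over the SNPs shared between the study and a labelled
   reference panel, using for each pair only loci observed in both samples.
   Classical (Torgerson) MDS embeds the joint sample set; each study sample
   takes the population label of the nearest reference centroid in the first
   `mds_dims` (default 3) dimensions, and samples not assigned to the
   retained population (default EUR) are excluded. Nearest-centroid was
   chosen because it is threshold-free; an optional maximum centroid
   distance marks samples "unassignable" instead of silently forcing a
   label.

MDS numerical conventions: the doubly-centered −D²/2 matrix is symmetrized
before `eigh`; eigenvalues are sorted descending; axes with negative
eigenvalues among the top k are zeroed with a warning (IBS distances are not
exactly Euclidean); each axis' sign is fixed by making its first nonzero
loading positive so embeddings are reproducible across runs.

## PRS computation

Scoring is strictly ordered: **harmonize → impute → score → standardize**.

* **Harmonization** resolves allele orientation by allele identity, never by
  file column order. Palindromic (A/T, C/G) SNPs are excluded outright as
  strand-ambiguous. For the remaining SNPs, calls matching the weight
  alleles are counted directly; calls matching only the base-complemented
  alleles are counted on the flipped strand and flagged `flipped`; calls
  with alleles fitting neither strand are excluded as `allele-mismatch`,
  and weight SNPs absent from the genotype panel as `unmatched`. Nothing in
  harmonization is fatal — every dropped SNP is listed with one reason.
* **Imputation** replaces a missing dosage with the mean observed dosage at
  that SNP, computed over the whole cohort being scored (not per subgroup).
  Imputed values are left fractional to preserve the expectation. A SNP
  missing in all samples is excluded with a warning.
* **Scoring** is the dot product of the set's β vector with the sample's
  dosages; the effective set size (retained SNPs) is recorded per set.
* **Standardization** z-scores each set's raw PRS with the sample sd (n−1)
  over all scored samples of the run — both genes together; per-gene
  standardization is available by scoring per-gene inputs. A zero-variance
  PRS is fatal.

## Cluster-region annotation

BRCA1/2 breast- and ovarian-cancer cluster regions are carried as 1-based
inclusive c.-coordinate intervals (BRCA1 on NM_007294.4: BCCR 179–505,
4328–4945, 5261–5563; OCCR 1380–4062. BRCA2 on NM_000059.4: BCCR 1–596,
772–1806, 7394–8904; OCCR 3249–5681, 6645–7471). A variant's extent is the
altered reference nucleotides only — a nonsense SNV is a 1-bp interval, a
deletion spans its deleted bases; the truncated downstream sequence does not
count. A variant is "inside" a region iff the closed intervals overlap. Note
the BRCA2 BCCR and OCCR genuinely overlap (c.7394–7471), so both flags can be
true even for a point variant; the two indicators enter the regression as
separate covariates, so no precedence rule is needed.

## Association

The logistic model is fitted by iteratively reweighted least squares
(convergence when the largest coefficient change < 1e-8, at most 100
iterations; weights clipped below at 1e-10). Rank deficiency is fatal and
names the collinear columns; (quasi-)perfect separation — every fitted
probability within 1e-6 of its outcome — is flagged with a warning, never
silently ignored.

The covariance is the cluster-robust sandwich V = A⁻¹ B A⁻¹, with A the
observed information and B the sum over family clusters of outer products of
within-cluster summed score vectors, scaled by m/(m−1) for m clusters. With
singleton clusters this reduces exactly to the HC-type heteroskedasticity-
robust estimator with factor n/(n−1). The m/(m−1) correction is one of
several in use; it is the package's documented choice and is configurable in
the sense that alternative scalings are a one-line transformation of the
returned covariance. Confidence intervals are Wald on the log-odds scale,
exponentiated with the conventional 1.96 quantile; p-values are two-sided
normal z-tests.

Models are stratified by gene with one PRS term per model (2 genes × 3 PRS
sets = 6 models), each adjusted for the two cluster-region indicators and
the ascertainment flag.

Supporting statistics: Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom (ED vs LD standardized PRS per gene
and set); Spearman's ρ via mid-ranks with a Fisher-z 95% CI
(atanh ρ ± 1.96/√(n−3), clipped to [−1, 1]); and a per-SNP two-sided Fisher
exact comparison of effect-allele counts between recruitment sources,
computed by hypergeometric point-mass summation (tables with point
probability ≤ the observed, with a 1+1e-7 relative tolerance) and
Bonferroni-corrected over the SNPs tested. The screen requires
pre-imputation integer dosages by construction.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes, with
defaults fixed at the study conditions: 295 carriers in 293 families (two
sibling pairs), 183/295 BRCA1, ascertainment-flag prevalence 188/295,
carrier-level cluster-region prevalences 45/295 (BCCR) and 37/295 (OCCR),
four divergent-ancestry outliers at Fst = 0.1, 2% missing calls, and true
coefficients ln 1.62 per PRS standard deviation, ln 3.45 (sICGT), ln 0.65
(BCCR) and ln 0.32 (OCCR). The intercept default −0.4 solves for a marginal
ED fraction near 162/295 under those prevalences.

* Unrelated individuals draw Hardy–Weinberg genotypes at per-SNP effect-
  allele frequencies (default Uniform(0.05, 0.5)); sibling pairs are built
  by simulating two parental genotypes and Mendelian transmission; divergent
  samples draw from Balding–Nichols frequencies
  p′ ~ Beta(p(1−F)/F, (1−p)(1−F)/F). Missingness is MCAR. In addition to
  the PRS loci, 244 extra panel SNPs are simulated so the ancestry MDS runs
  on ~342 overlapping SNPs, matching the panel size the design assumes; they
  are ignored by scoring.
* The synthetic weight table mirrors the published set-size structure:
  88 overall / 87 ER+ / 53 ER− loci with palindromic SNPs planted exactly
  where the ambiguity exclusion must act, leaving effective sizes 77/77/50,
  86 unique retained loci, and 76 of 77 retained SNPs shared between the
  overall and ER+ sets (including rs11571833 as an A/T locus). Alleles and
  βs (N(0, 0.05²), a magnitude typical of published PRS loci) are synthetic;
  only this bookkeeping structure is meaningful.
* Covariates (gene, sICGT, region flags) are drawn once per family —
  relatives share the pathogenic variant and recruitment route — and the
  variant c.-interval is synthesised to realise the drawn region flags. The
  ED indicator is Bernoulli under the logistic model; ED samples get an
  integer age at diagnosis in [20, 34]. Outcomes are simulated directly as
  group membership through the analysis model, not via an onset-age hazard;
  an age-at-onset model is out of scope.
* One global seed drives a named sub-stream per component (weights,
  genotypes, divergence, missingness, reference, phenotypes), so components
  are independently reproducible and every manifest records the seed.

What the generator does **not** emulate: linkage disequilibrium between loci
(SNPs are independent), realistic site-frequency spectra, ascertainment
beyond a binary covariate, genotyping error (only MCAR missingness), and
admixed or continuously structured ancestry. Passing tests therefore
demonstrate correctness of the pipeline's computations under its assumed
model, not robustness of the scientific conclusions to real-data violations
of those assumptions.

## Problem sizes in tests and acceptance runs

Parameter recovery uses 200 replicate cohorts of n = 20,000 under model-exact
conditions (no missingness or outliers, so the estimand equals the configured
ln 1.62); type-I calibration uses 100 study-sized (n = 295) null cohorts;
the Fisher-screen null calibration uses 1000 replicate 86-SNP screens with 30
samples per source; the sandwich-vs-bootstrap comparison uses a 500-family
sibling-pair cohort with a 2000-replicate cluster bootstrap; QC sensitivity
uses 50 replicate heterozygosity cohorts (two gross outliers each) and 20
replicate ancestry cohorts (five Fst = 0.1 divergent samples each, 342-SNP
panels). These sizes were chosen so each check's Monte-Carlo error is small
relative to its acceptance band.

## Known limitations

* The heterozygosity rule assumes approximately normal rates; with very few
  SNPs the normal fit is coarse.
* Nearest-centroid ancestry assignment has no "none of the above" region
  unless `max_centroid_distance` is set; a sample from an unrepresented
  population is assigned to the closest available centroid.
* IBS/MDS is a joint embedding, so adding study samples can shift reference
  coordinates slightly; projection-based MDS is out of scope.
* The Fisher screen treats alleles within genotypes as independent counts,
  as is conventional; family structure is not accounted for there.
* With small per-gene strata and rare covariate patterns, quasi-separation
  of the logistic model is possible; it is flagged, and results for flagged
  models should not be interpreted.
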