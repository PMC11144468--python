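# Methods

This note documents the statistical model the package implements, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical and design decisions a maintainer should
know about.

## Phenotype preparation

Continuous biomarkers are residualized on a covariate design (intercept
always added) by ordinary least squares and the residuals are mapped to
normal quantiles by the rank inverse-normal transform (RINT): the value
with tie-averaged rank *r* among *n* maps to Φ⁻¹((r − c)/(n − 2c + 1)).
The offset is Blom's c = 3/8, the standard choice in human-genetics
pipelines; it is configurable in `TransformSpec`. Both steps run
independently within each stratum (recruitment region), so the transformed
variable has mean ≈ 0, SD ≈ 1 per stratum and between-region location or
scale differences cannot masquerade as genetic signal. Ties get average
ranks (deterministic and symmetric); missing rows are deleted listwise
with counts logged; strata below `min_stratum_size` (default 30) are
dropped with a warning. A rank-deficient design raises an error naming the
collinear columns rather than silently pseudo-inverting.

## Locus weights and the internal-weight jackknife

The locus score weights are the mutually-adjusted per-allele effects of
the locus SNPs on RINT LDL-C: a joint regression on all SNP dosages plus
covariates within each region, with each SNP's coefficient pooled across
regions by inverse-variance-weighted fixed-effect (IVW-FE) meta-analysis —
the same pooling operator used everywhere else in the package. Fits are
computed from per-(stratum, block) cross-products, so the B
leave-one-block-out refits of the jackknife cost B small linear solves,
not B passes over the data; each refit is verified in the tests against a
brute-force refit on the complementary rows.

Participants contributing LDL-C data receive weights from the refit that
excluded their own block (B = 100 near-equal random blocks, seeded);
participants without LDL-C receive full-sample weights. The bias this
removes is first-moment: with naive internal weights the score's sample
covariance with the phenotype equals (number of SNPs)·σ² under a **null**
locus — equivalently the score–phenotype calibration slope is ≈ 1 even
when there is no signal. With jackknifed weights that covariance is zero
in expectation (verified by simulation in the test suite).

A known property worth stating plainly: cross-fitting does **not** make
the same-sample score–exposure F-statistic average 1 under the null. The
per-block weight vectors share a common noise direction, and block b's
residuals enter block k's weights and vice versa, so the global F of a
jackknifed null score still averages ≈ (number of SNPs), about the same as
the naive score's. The F-statistic the package reports
(`instrument_strength`, F = r²/(1 − r²)·(n − 2) for the 1-df score term)
is therefore meaningful for strong instruments — where the overfit
component is negligible against a true F in the hundreds — and the
jackknife's value lies in unbiased *downstream* association estimates,
not in deflating this diagnostic.

## Polygenic comparator score

The polygenic LDL-C score uses externally estimated weights for an
independent SNP panel. Monomorphic SNPs are dropped; a SNP is retained if
its internal effect is directionally consistent with the external one or
if a two-sample heterogeneity z-test between the two is not significant at
0.05/m, m = number of polymorphic candidates. Effect alleles must already
be aligned between sources; the package records allele labels in the
dosage manifest and never strand-flips automatically.

## Association engine

Binary endpoints: maximum-likelihood logistic regression of case/control
labels on the score plus covariates within each region (Newton, tolerance
1e-10, 100 iterations), pooled by IVW-FE. Strata with fewer than
`min_cases` (default 5) cases or controls, separated strata, and
non-converged or Wald-degenerate fits are dropped from pooling with a
logged warning — a deliberate, transparent alternative to penalized
regression. Continuous traits use least squares in the same scaffold.
Estimates are produced per unit score (one unit = one predicted SD of
LDL-C, higher = more LDL-raising) and re-oriented by an explicit involution
to the per-1-SD-*lower*-LDL-C scale; orientation is metadata, never
inferred from signs.

Small-cell behaviour, documented because it is easy to mistake for a bug:
IVW-FE pooling of per-stratum MLEs with a *rare-variant* score is slightly
anti-conservative when the expected number of carrier-cases per stratum is
small. Strata in which carriers happen to yield few cases produce large
negative estimates with large estimated SEs and are down-weighted, so the
pooled null z-score acquires a positive mean of roughly 0.1–0.3 for
carrier-case counts below ~50 per stratum (a joint model with region
indicator covariates — available as the sensitivity mode — does not show
this). The null-calibration experiment therefore runs at the pipeline's
target scale (cohort 100,000, common outcome) where the effect is within
Monte-Carlo noise; analyses of very rare outcomes should prefer the
joint-model sensitivity mode or merge strata.

Endpoint construction follows biobank practice: cases are participants
with any qualifying ICD-10 event (codes, prefixes, or ranges like
"J40-J44"); control pools exclude baseline self-reports of the disease
(disease-specific mode) or prior CHD/stroke-TIA self-report plus any major
vascular event during follow-up (common-vascular mode); participants
genotyped for a different disease's case-control panel are removed from
both groups; URTI-style endpoints can drop case events before a calendar
year, with a spike-detection report flagging regions holding more than 10%
of all cases inside a window. Case + control + excluded counts always
reconcile with cohort size and are written to the run log.

The phenome-wide scan applies the same machinery to disjoint ICD-10
code-range groups spanning A00–N99 with no prevalent-disease exclusions,
flagged at 0.05/(number of groups + prior tests); the default 41 groups
are contiguous equal-width ranges, a stand-in for curated clinical
groupings supplied via YAML.

## Summary-statistic layer

Standard errors are back-calculated from printed ORs and 95% CIs with the
exact normal quantile 1.959964 (not 1.96); printed rounding means a point
estimate may sit slightly outside its own CI, so a 2% relative tolerance
is allowed before erroring. Per-allele external estimates are rescaled to
per-SD-of-LDL-C by dividing beta and SE by the variant's per-allele LDL-C
effect (default 0.497 SD). Cochran's Q uses the IVW-FE pooled mean and is
χ²(k−1) under homogeneity. Benjamini-Hochberg FDR delegates to
statsmodels and is tested against an exhaustive brute-force step-up
oracle. Bonferroni thresholds are reported at two significant figures
(0.05/7 → 0.0071) to match reporting convention; exact values are
available.

## Synthetic cohort

What it emulates: 10 recruitment regions with sum-to-zero LDL-C
intercepts; three locus SNPs sampled as two haplotypes per individual from
an 8-haplotype frequency table (Hardy-Weinberg at the haplotype level;
"independent" builds the product table), so LD among the mutually-adjusted
SNPs is exact and simple; 64 independent polygenic LDL-C SNPs; LDL-C
2.36 (SD 0.69) mmol/L with age/sex/fasting-time effects, measured in a
random 25% subset (missing completely at random — the real measured subset
was assay-driven, not outcome-driven); binary outcomes from logistic
models with an LDL-C-mediated path and/or a score-direct (pleiotropic)
path, both parameterized per 1 SD *lower* exposure; uniform event years
over 10 years of follow-up from a 2004–2008 baseline with configurable
fatal fractions; spirometry from a log-scale height/age/sex FVC model with
the FEV₁/FVC ratio drawn through the LMS reference at z ~ N(0,1) plus a
COPD liability shift (default −1.5 SD in 10% of the cohort), and 2 of 10
regions flagged spirometry-unusable.

Chosen constants: the loss-of-function variant's MAF is 0.013 (pinned by
the reference cohort's carrier counts, 1826/70,914 ≈ 1 − (1−p)²); the two
companion SNPs' frequencies are not published for this population and are
free parameters — the defaults (0.025, 0.013) were set so the analytic
locus variance Σ2p(1−p)β² with the per-allele effects (0.65, 0.10, 0.16)
SD equals the reported ≈1.2% of LDL-C variance. Polygenic panel
frequencies and effects are drawn once per seed (MAF U(0.05, 0.5),
|β| U(0.02, 0.08) SD with random signs), giving ~7% of LDL-C variance,
typical of a genome-wide significant lipid panel. All randomness flows
from one config seed through named substreams, so cohorts are
bit-reproducible and components can be regenerated independently.

What it does not emulate (so passing tests do not speak to these):
genotyping error, imputation uncertainty, ancestry structure beyond region
intercepts, assay batch effects, informative missingness, competing risks
or time-varying hazards (the analysis is cumulative logistic, as in the
design it mirrors), and real ICD-10 coding noise.

## Simulation-study design (problem sizes)

Weight recovery: 100 cohorts of 100,000 (LDL-C in the 25% subset,
region-stratified fits) — the target scale of the pipeline. Jackknife
contrast: 200 replicates of 20,000 with all effects null and LDL-C fully
measured, the regime where internal-weight overfitting is visible. Null
calibration: one cohort of 100,000, 200 independent null outcomes at risk
0.2 through the full stratified engine. Heterogeneity-p uniformity: 1,000
summary-level replicates with a shared true effect. These sizes keep the
complete suite within a few minutes on one core while leaving each
experiment in its asymptotic regime.

## Numerical choices and degenerate inputs

OLS via cross-products with explicit rank handling; saturated leave-out
fits (n = p) return coefficients with infinite SEs rather than failing;
Wald p-values are clamped at the smallest positive float so perfect fits
stay in (0, 1]; the LMS z-score switches to the log-limit form for
|L| < 1e-7; the lower limit of normal uses strict inequality (z < Φ⁻¹(c));
"fatal" classification means any qualifying event was fatal, regardless of
event order; jackknife blocks differ in size by at most one. Monomorphic
SNPs, collinear dosages, dosages outside [0, 2], missing dosages (no
imputation), events before baseline, empty case sets and mixed-scale
meta-analysis inputs are all hard errors naming the offending item.

## Known limitations

The LMS reference shipped is a self-consistent synthetic table (constant
Box-Cox λ = 1, mild age decline, no height term) for exercising the
framework; published reference-equation coefficient tables should be
supplied via YAML for real data, including the ancestry key. The
instrument F caveat and the sparse-stratum pooling bias are described
above. The phenome-scan groups are illustrative, not clinical groupings.
VCF support is read-only (per-sample DS field); TSV is canonical.
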