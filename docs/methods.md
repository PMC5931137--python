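# Methods

## The analysis model

Disease risk is modelled log-additively in allele dosage.  Within each
case-control stratum s the per-variant model is

    logit P(case) = β₀ + β·g + γ₁·age + γ₂·sex + γ₃·BMI + Σₖ δₖ·PCₖ

with g the effect-allele dosage in [0, 2] (hard calls or imputed
expectations) and PC₁..PC₁₀ the within-population genotype principal
components.  Fitting is maximum likelihood by iteratively reweighted
least squares; iteration stops when the largest coefficient change
falls below 1e-8 or after 50 iterations, and fits that fail to converge
or show effectively infinite coefficients (quasi-separation) are
flagged unusable and excluded downstream with a logged reason.  The
reported p-value is the two-sided Wald test on β.  Missing dosages are
handled per SNP as complete-case analysis; no mean imputation.

Stratum estimates are pooled by fixed-effects inverse-variance
weighting on the log-odds scale (weights 1/SE²), first over a
population's strata, then across populations for variants observed in
at least two populations.  Fixed-effects pooling is associative, so the
two-stage estimate equals a direct pool over all 18 strata; the test
suite asserts this to 1e-10.  A sample-size-weighted z-score scheme is
available but not the default, because odds ratios from the
meta-analysis require effect-scale pooling.  Cochran's Q and I² are
computed for every pool and reported, never used to filter.

### Filters

Variants enter a population's analysis at MAF ≥ 1%, evaluated on the
population's pooled cases and controls, and enter a stratum at
imputation INFO > 0.8.  PCs are computed per population from a random
subset of up to 10,000 variants with MAF > 5% and call rate > 95%
(all eligible variants, with a warning, when fewer exist), by SVD of
the column-standardized dosage matrix.

### Allele alignment

Effects are oriented to each catalog entry's reported risk allele:
+1 when the effect allele is the risk allele, −1 when it is the other
allele, with strand-complement matching for non-palindromic pairs.
Palindromic (A/T, C/G) pairs are resolved by frequency only when both
the observed and the reported frequencies are folded below 0.40;
otherwise the SNP is ambiguous and excluded from directional counts
with a log entry.  The 0.40 bound is the conventional safeguard; it is
configurable in `transrep.io.AMBIGUOUS_FREQ_THRESHOLD`.

### Directional consistency

With n evaluable index SNPs (passing filters, unambiguous orientation)
and k of them showing oriented β > 0, the evidence that loci generalize
is the exact one-sided upper tail P(X ≥ k), X ~ Binomial(n, ½).  A β of
exactly 0 counts as inconsistent — the conservative choice, and a
probability-zero event for continuous estimates.  The one-sided tail is
used because generalization is a directional hypothesis.

### Regional replication

A region's proxy set is every region variant with r² ≥ 0.4 (inclusive)
to the index SNP in the designated proxy panel; r² is the squared
Pearson correlation of dosages, which equals haplotype r² on phased
indicators.  The effective number of tests is the number of greedy
pairwise tag bins at r² ≥ 0.8 among MAF > 1% variants in the tag panel:
repeatedly pick the variant covering the most untagged variants
(itself included), ties broken by higher MAF then lower position, until
every eligible variant is binned.  Bins partition the eligible set by
construction and the implementation asserts it.  A region replicates in
a scope when the smallest proxy p-value there beats 0.05 / n_tags;
when every proxy has been removed by the INFO filter the call is
"untestable", not a failure.  Proxy and tag panels are separate handles
(the original design used different reference ancestries for the two
roles) and may point at the same genotype panel.

### Genetic risk scores

The base score is the unweighted risk-allele count over the catalog
SNPs; scores therefore live in [0, 2m].  Modified score I substitutes,
for each region replicated in a given population, the index SNP with
that population's best proxy; modified score II substitutes the
cross-ethnic best proxy under the same rule.  "Region-wide
significance" is exactly the regional threshold 0.05 / n_tags.  A
substituted SNP's risk allele is the allele with positive observed
effect in the same scope.  Samples missing a chip-level block of score
SNPs are excluded (with the threshold derived from the chip plan, e.g.
20 of 71 in the full design); remaining sporadic missingness is imputed
at twice the population risk-allele frequency, standard allele-score
practice.  Quartile cut-points come from the full analyzed
within-population sample (cases + controls); a controls-only option
exists.  Distribution comparisons use Welch's t-test.

### Power

For population allele frequency p and per-allele odds ratio R, the
expected case allele frequency is p₁ = Rp/(Rp + 1 − p) and controls
stay at p₀ = p.  The allele-based estimate of log R has variance
1/(2n₁p₁q₁) + 1/(2n₀p₀q₀) over 2n alleles per group, giving two-sided
power Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂).  A protective allele
(R < 1) is relabeled to its risk counterpart (1/R at frequency 1 − p)
before evaluation: the Wald test is identical under allele relabeling,
so this is the statistically correct convention — note that power is
*not* symmetric in R ↔ 1/R at a fixed allele frequency, because the
case-group variance term differs; the Monte-Carlo oracle (binomial
allele counts, 2×2 allelic Wald test with Haldane-Anscombe correction
for empty cells) confirms the asymmetry and agrees with the analytic
value within 2 percentage points across the tested grid.

## The synthetic cohort

The generator produces data with the statistical structure the
analysis assumes, not a population-genetic simulation of real history:

- **Allele frequencies.**  Each variant has an ancestral frequency;
  population frequencies are Balding-Nichols draws,
  Beta(p(1−F)/F, (1−p)(1−F)/F), mean p and variance F·p(1−p).
  Default Fst values (0.10, 0.06, 0.12) give frequency spreads of the
  size seen across the three study populations.  The designated
  index and functional variants share one draw per population —
  tightly linked alleles drift together, and this keeps the target r²
  attainable.
- **LD.**  Within a region, haplotypes are thresholded multivariate
  normals with latent correlation exp(−distance/L), L = 100 kb by
  default.  Thresholding attenuates correlation, so the latent
  correlation of the index-functional pair is calibrated by a Brent
  root search on the closed-form thresholded r² (Drezner-Wesolowsky
  quadrature for the bivariate normal orthant probability); the
  functional latent is constructed as ρ·(index latent) + noise so the
  correlation matrix stays positive semi-definite.  Infeasible targets
  (frequency mismatch caps attainable r²) warn and report the achieved
  value.  This model gives controllable pairwise r² at desk scale; it
  does not reproduce recombination maps, admixture LD or haplotype
  block structure, so passing tests say nothing about those features
  of real data.
- **Phenotypes.**  A source population ~2.5× the target size receives
  case labels from the logistic model (baseline −3.0 plus age, sex,
  BMI effects of 0.03/0.4/0.03 per unit, echoing the case/control
  contrasts of the study's descriptive table); exact per-stratum
  case/control counts are then subsampled, mimicking the cohort-nested
  design.  Unreachable targets raise with the achieved counts.
- **Genotyping artifacts.**  A chip plan marks a sample subset (30% of
  two populations by default) missing a fixed block of score SNPs;
  INFO scores are drawn per variant × stratum, mostly in (0.85, 1.0)
  with a configured fraction in (0.5, 0.8) so the quality filter is
  exercised.  Imputation itself is not simulated.
- **Catalog.**  Each region contributes one index-SNP entry whose
  "reported" OR is the functional effect attenuated through the target
  LD (exp(log R·√r²)); null regions still claim OR 1.12, so a null
  cohort exercises the false-discovery side of the directional test.

The default configuration mirrors the study design: 3 populations with
case/control totals 2,376/4,139, 2,291/3,818 and 1,368/3,294, six
nested strata each (18 in all), 65 regions × 30 variants, and a chip
block removing 20 index variants from 30% of two populations.  The
analysis scripts and calibration experiments use structurally identical
reduced designs (documented per script) chosen once for desk-scale
runtimes: 20 regions × 12 variants at 400/700 per population for the
worked example; 8 × 8 at 150/250 with two strata per population for
the 50-replicate null calibration.

## Numerical choices

- Missing dosage sentinel is NaN, never a numeric code.
- Logistic linear predictors are clipped at ±30 before the inverse
  logit; IRLS weights are floored at 1e-12.
- p-values are floored at the smallest positive double and capped at 1.
- Greedy-binning ties break by higher MAF, then lower position, making
  bins deterministic.
- Thresholds at r² 0.4 and 0.8 and MAF 1% are inclusive (≥) /
  exclusive (>) exactly as stated for each filter; INFO uses strict >.
- All randomness flows from a single integer seed through spawned
  generator streams; identical seeds give byte-identical artifacts.

## Known limitations

- The latent-Gaussian LD model cannot represent multi-locus haplotype
  effects or allelic heterogeneity; regional replication power under
  realistic LD decay will differ.
- The power formula is asymptotic; at very rare alleles or small
  strata it can drift more than the oracle tolerance from the exact
  rejection rate.
- Case-control misclassification, relatedness and fine-scale
  stratification within populations are not simulated; the PCs in the
  synthetic cohort mostly absorb noise.
- Heterogeneity statistics are descriptive only; no random-effects or
  Bayesian trans-ethnic model is provided.
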