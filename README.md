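# transrep

Do risk loci discovered by GWAS in one ancestry group carry over to
others?  `transrep` implements the complete analytic chain used to
answer that question in a multi-population case-control cohort, for
coronary heart disease-style designs with a catalog of known index
SNPs:

- **Stratified association scan** — the log-additive effect of each
  variant, `logit P(case) = β₀ + β·dosage + γ·(age, sex, BMI, PC1..PC10)`,
  fit by unconditional logistic regression within each case-control
  stratum; variants filtered to population MAF ≥ 1% and imputation
  INFO > 0.8.
- **Fixed-effects meta-analysis** — inverse-variance pooling
  (`β̂ = Σwᵢβᵢ/Σwᵢ`, `wᵢ = 1/SEᵢ²`) of stratum results within each
  population and then across populations for variants observed in at
  least two of them, with Cochran's Q and I² reported.
- **Directional consistency** — the count k of index SNPs whose
  risk-allele-oriented effect agrees in sign with the reported OR,
  tested against Binomial(n, ½) with an exact one-sided upper tail.
- **Regional replication** — proxies of each index SNP at r² ≥ 0.4 in a
  reference panel; the effective number of tests per region from greedy
  pairwise tag-SNP binning at r² ≥ 0.8 (MAF > 1%); a region replicates
  when any proxy's p-value beats 0.05 / n_tags.
- **Genetic risk scores** — three unweighted allele-count scores (base;
  region-wide-significant ethnic-specific lead substitutions; cross-
  ethnic lead substitutions), their case/control and cross-population
  distributions, and continuous plus quartile logistic associations.
- **Analytic power** — the per-allele test's power from the allele-based
  non-centrality `log OR / √(1/(2n₁p₁q₁) + 1/(2n₀p₀q₀))`, with a
  Monte-Carlo oracle for verification.

Because the real cohort genotypes are access-controlled, the package
ships a first-class synthetic-cohort generator (Balding-Nichols allele
frequency divergence, latent-Gaussian block LD with calibrated
index-functional r², a logistic disease model, chip-style block
missingness, and imputation INFO scores) so the entire pipeline is
reproducible and testable end-to-end.

## Worked example

The numbered scripts under `analysis/` run the chain on a simulated
three-population cohort (400 cases / 700 controls per population in 6
strata each, 20 regions × 12 variants, 8 regions carrying a true
functional effect of OR 1.12 tagged at r² 0.8):

```bash
python analysis/01_simulate_cohort.py --seed 2024
python analysis/02_association_scan.py
python analysis/03_meta_analysis.py
python analysis/04_directional_consistency.py
python analysis/05_regional_replication.py
python analysis/06_risk_scores.py
python analysis/07_power.py
```

The consistency stage prints, for this seed:

```
       scope  n  k  fraction  binomial_p  n_nominal
      AFR_AM 20 14      0.70    0.057659          0
         LAT 20 15      0.75    0.020695          0
      JPN_AM 20 12      0.60    0.251722          4
cross_ethnic 20 16      0.80    0.005909          1
```

With 8 of 20 regions carrying a true shared effect, 70–80% of index
SNPs point the reported way — an excess over the 50% chance expectation
that reaches p = 0.006 in the pooled cross-ethnic analysis even though
almost no single SNP is individually significant; exactly the situation
the directional test is designed for.  The regional stage then finds
one region (`r16`) replicating after its tag-count multiplicity
correction, and the power stage explains why so few do: at these sample
sizes no catalog SNP reaches 80% power for its reported effect
(`n_powered = 0` in every scope), e.g.

```
  African Americans, MAF 0.05, 2376/4139: 28.8%
  African Americans, MAF 0.20, 2376/4139: 72.0%
```

— the per-allele power for OR 1.12 at the full study's case/control
totals, rare vs common allele.

The same chain is available as a console tool (`transrep simulate`,
`scan`, `run`, `power`, …); `transrep run --small --seed 1 --out out/`
executes every stage and writes all tables, the run log and a JSON
report.

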