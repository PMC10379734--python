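# Methods

## The model

The outcome is a bounded integer depression score `y ∈ [0, 63]` (BDI-II
total). The analysis treats it as quantitative and fits ordinary least
squares throughout. The polygenic score for individual `j` is

    PGS_j = Σ_i w_i · d_ij

where `d_ij` is the dosage (0/1/2) of variant `i`'s *scoring allele* and the
weights `w_i ≥ 0` come from per-SNP additive regressions of `y` on the
effect-allele dosage adjusted for sex, age and ethnicity. A per-SNP
coefficient `β_i < 0` is recoded onto the other allele — the term `β x`
becomes `|β| (2 − x)` — so every weight is non-negative and the score counts
risk-increasing alleles. The recoding shifts every individual's score by the
same constant `Σ_{β<0} 2|β|`; regression fits on the score are invariant to
it (asserted numerically in the tests to 1e-10). Weights are raw per-allele
coefficients in score points per allele, matching the scale on which they
are reported; z-standardization of dosages is available as an option but is
not the default.

The four nested models are (1) PGS; (2) sex + ethnicity + age; (3) PGS +
demographics; (4) model 3 plus social predictors surviving backward
elimination. Adjusted r², `1 − (1 − R²)(n − 1)/(n − k − 1)` with `k` the
number of non-intercept design columns, is the variance-decomposition
metric reported across models.

## Quality control

Filters run strictly in the order call rate → MAF → HWE → LD proxies, so
frequency and equilibrium statistics use post-call-rate samples. Defaults:
call rate > 0.98, MAF > 0.05 (inclusion rules), HWE α = 0.05. The HWE test
is the exact conditional test: given the observed allele counts, all
compatible heterozygote counts are enumerated under the random-union-of-
gametes distribution and every configuration with probability ≤ that of the
observed one (within a 1e-12 relative guard against floating-point
inequality at symmetric configurations) contributes to the two-sided p. A
chi-square variant is provided; exact is the default because it is valid at
the small expected counts a 30-variant panel can produce.

LD between variants annotated to the same locus is the haplotype-frequency
r² = D²/(p_A q_A p_B q_B), with haplotype frequencies estimated from
unphased genotypes by EM (only the double heterozygote is phase-ambiguous).
This matches the estimand of standard pruning tools; the squared genotype
correlation is available as `method="corr"`. Pairs with r² ≥ 0.2 lose one
member: an explicit keep-list wins, otherwise the member with the larger
preliminary association p is dropped, otherwise the later variant in panel
order. The keep-list override exists because curated panels sometimes fix
the kept proxy by criteria (prior literature, assay quality) that no
in-sample rule reproduces. Monomorphic input defines r² = 0 with a warning
rather than NaN, so pruning decisions stay total.

## Association and the social screen

Per-SNP regressions delete individuals listwise per variant (missing
genotype, outcome or covariate); the used n is reported per variant, and a
dosage with zero variance after deletion is flagged with undefined β rather
than silently zero. Sex is coded man = 0 / woman = 1; ethnicity is one-hot
with "mixed" as reference. Covariate columns that become constant within an
analysis subset are dropped from that fit only.

The social screen uses the Mann–Whitney U test: exact when both groups have
≤ 8 observations and no ties, otherwise the normal approximation with tie
and continuity corrections (the scipy implementation supplies both paths).
The multiple-testing bound is α/m over the m = 8 screened factors —
0.00625, displayed as 0.0063 at two significant figures (half-up rounding).
Although sometimes labelled an FDR threshold in applied reports, α/m is a
Bonferroni-type familywise bound and is named accordingly here;
Benjamini–Hochberg is provided separately.

Parental Bonding Instrument scales are dichotomized at cut-offs 27.0
(maternal care), 13.5 (maternal protection), 24.0 (paternal care), 12.5
(paternal protection); a score exactly at the cut-off is "high". The
boundary rule is a fixed convention chosen for determinism.

## Model 4 selection

Backward elimination is pure AIC: at each step the removable term whose
removal most decreases AIC is dropped; elimination stops when no removal
decreases AIC; ties break toward the earlier term in the declared order.
PGS, sex, age and ethnicity are forced (sex is dropped as constant in the
women-only subgroup); candidates are income, full-family rearing,
maltreatment and the four PBI categories. Ethnicity is removed or retained
as a block. The AIC convention is `n·log(RSS/n) + 2(k + 2)` (Gaussian
likelihood, error variance counted); only differences within a dataset
matter, and per-step p-values are retained in the elimination log for
inspection.

## The synthetic cohort generator

`default_study_config()` encodes the emulated study conditions: n = 1065;
32 biallelic SNPs at the published effect-allele frequencies (0.079–0.473);
per-allele effects from the published per-SNP scan (range −0.73 to +0.67
score points per allele; the two out-of-equilibrium variants carry no
effect); three intra-locus LD pairs at r² 0.44/0.23/0.55; inbreeding
coefficients F = 0.205 and 0.091 for the two HWE violators, back-computed
from their reported exclusion statistics via X² ≈ nF²; covariate
prevalences at the study margins (79.25% women; ethnicity 357/340/234/134;
10.6% lower income; 83.7% full family; 9.8% maltreatment; PBI high-category
counts 728/575/564/500 of 1065 — the count-based maternal-protection
proportion is used, the published percentage being a typo); age uniform on
18–25 years; conditional covariate effects from the published full model
(e.g. +1.50 for women, −0.27/year of age, −2.65 for high maternal care);
phenotype noise SD 6.6 so the latent score SD is ≈ 7 points, matching the
reported subgroup SDs of 6–8.7. The latent mean is centered at 8.36, the
study sample mean. The two extra panel variants' coordinates and alleles
are synthetic stand-ins, as only their identifiers and test statistics are
characterized in the source.

Genotypes: unlinked variants are drawn from (p² + Fpq, 2pq(1−F), q² + Fpq);
LD pairs are drawn as 2n haplotypes from the two-locus distribution with
D = sqrt(r² p_A q_A p_B q_B) (positive D; an infeasible target reports the
maximum attainable r²) and paired at random, so the target r² is exactly
the haplotype-frequency r² that QC estimates. Missingness is independent at
rate 0.005. Everything is reproducible from a single integer seed.

**Exact-frequency mode.** `make_study_cohort` defaults to a
conditional-on-summary construction: genotype and haplotype class counts
are largest-remainder-rounded to their target proportions and randomly
assigned to individuals. This pins realized frequencies, r² and HWE
statistics to their targets up to integer rounding — appropriate because
the bundle's purpose is to recreate an *observed* panel, in which the
frequencies and test statistics are data, not estimands. Under iid
multinomial sampling (the default for `simulate_genotypes`, used in all
statistical property tests), the r² = 0.23 pair would fall below the 0.2
pruning threshold in roughly 9% of draws at n = 1065 and the weaker HWE
violator would escape detection in ~15%, making the 27-variant filter
ledger a sampling event rather than a property of the study conditions.

**Phenotype discretization.** The latent Gaussian score is rounded and
clipped to [0, 63]. With mean ≈ 8.4 and SD ≈ 7, about 11% of latent mass
lies below zero, so clipping compresses the left tail: the realized SD is
≈ 6.4 and, by Stein's lemma, per-allele regression slopes on the clipped
scale attenuate by roughly the factor P(latent > 0) ≈ 0.89. R² is far less
affected because the outcome variance shrinks in near proportion. The
parameter-recovery validation therefore runs with `discretize=False`
(OLS is only unbiased under its own generative law; the attenuation is a
property of the bounded scale, not of the estimator), while the
variance-share validation keeps the default bounded scale and absorbs the
residual ~2% relative attenuation inside its tolerance. Recovery truths for
variants in LD pairs are the analytic *marginal* slopes
`β_a + β_b·D/(p_a q_a)`, since single-SNP regression estimates the marginal
projection.

What the generator does **not** emulate: population structure and cryptic
relatedness, genotyping error beyond random missingness, LD with unobserved
causal variants, non-Gaussian (right-skewed, zero-inflated) depression-score
shapes, covariate–genotype correlation, and PGS-by-environment interaction.
Passing tests therefore validate the estimation machinery under the stated
additive model, not the substantive findings on real cohorts.

## Validation problem sizes

The statistical suite uses 200 cohorts of n = 2000 for effect recovery
(bias within Monte-Carlo error; 95% CI coverage in [0.92, 0.98]), 100
cohorts of n = 5000 for variance-share recovery (mean Model 1 R² within
±0.005 of the configured 2.4% share), 50 randomized cohorts of n = 400 for
the nesting/AIC contracts, and 100 replicates at the study n = 1065 for the
in-sample-optimism property (in-sample adjusted r² exceeds split-half
out-of-sample r² in ≥ 90%). Exhaustive oracles cover all HWE genotype
triples with total ≤ 10 (exact rational enumeration) and all tie-free
Mann–Whitney group sizes up to 6×6 (full label permutation).

## Known limitations

- In-sample weighting is circular by design; Model 1's adjusted r² is
  optimistic by roughly m/n (number of scored variants over cohort size).
  The split-half diagnostic quantifies, but does not remove, this optimism.
- The bounded outcome attenuates per-allele effects (~11% at the default
  configuration); analyses of real BDI data share this property.
- OLS inference assumes homoscedastic Gaussian errors; the bounded,
  right-skewed score violates this mildly, and no robust-SE option is
  currently exposed.
- The EM r² assumes random mating within the sample when resolving double
  heterozygotes; strong substructure would bias it.
- External-weight harmonization drops strand-ambiguous (A/T, C/G) variants
  rather than resolving them by frequency, a deliberately conservative
  choice on a small panel with frequencies near 0.5.
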