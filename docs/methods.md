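# Methods

## The estimation problem

Carriers of a high-risk mutation are recruited through clinics conditional
on phenotype: stage 1 of a typical two-stage modifier GWAS takes young
affected women and older unaffected women; stage 2 broadens the age rules.
Genotype–phenotype association must therefore condition on the phenotype.
All estimation in this package is built on the retrospective likelihood of
the observed genotypes given the observed survival phenotype (t, δ), with
disease risk entering through a proportional-hazards model on a **known,
externally supplied** carrier baseline hazard λ0(t):

    l_i(β, q) = δ_i β x(g_i) − Λ0(t_i) e^{β x(g_i)} + log p_s(g_i)
                − log Σ_g p_s(g) exp(δ_i β x(g) − Λ0(t_i) e^{β x(g)}).

The λ0(t_i)^δ_i factor cancels between numerator and denominator, so only
the cumulative hazard Λ0 is needed.  Genotype priors p_s(g) are HWE
functions of per-stratum allele frequencies q_s; strata are country ×
founder-mutation (optionally × stage).  The likelihood is per individual,
conditional on that individual's own phenotype; familial dependence is
handled in the variance, not the mean (see below).  This is the
single-individual analogue of maximising the same retrospective likelihood
in pedigree software, and is exact when relatives' phenotypes are
conditionally independent given their own genotypes.

### Time at risk

Censoring occurs at the first of: breast cancer (case), ovarian cancer
(censored unaffected), bilateral prophylactic mastectomy (censored
unaffected), last observation, or age 80 (no reliable carrier incidence
rates beyond 80).  A BPM recorded more than one year before a cancer
overrides that cancer; within a year it is treated as diagnosis-related
(ages in these data are often rounded, so a strict `cancer − bpm > 1.0`
rule is used; fractional and integer ages are both accepted).  Event ages
after the recorded last observation are rejected as data errors; male
carriers are rejected at table validation.

### The score test and its kinship-adjusted variance

Differentiating the total log-likelihood at β = 0, with q_s profiled at
its null MLE (the stratum sample frequency), gives

    U = Σ_i c_i (g_i − ḡ_s(i)),   c_i = δ_i − Λ0(t_i).

Because Σ_{i∈s}(g_i − ḡ_s) = 0, U is identically Σ_i a_i g_i with
**centred weights** a_i = c_i − (Σ_{j∈s(i)} c_j)/n_s(i).  The null
variance over the genotype distribution is then

    V = Σ_{i,j same family} a_i a_j · 2φ_ij · σ_s(i) σ_s(j),

with φ the pedigree kinship coefficient (2φ_ii = 1 for non-inbred
carriers, so unrelated carriers contribute a_i² σ²_s) and σ²_s = 2q_s(1−q_s)
the HWE genotype variance.  The centring in a_i matters: under
ascertainment the residuals c_i do not sum to zero within a stratum, and a
variance built on raw c_i would overstate V substantially.  χ² = U²/V is
referred to a 1-df chi-square.

Two estimator details:

- **Finite-sample variance correction (default).**  The plugin
  2q̂(1−q̂) is biased low: E[2q̂(1−q̂)] = σ²(1 − K_s/(2n_s²)), where
  K_s = Σ_{i,j∈s, same family} 2φ_ij.  With ~28 strata over ~1,700
  carriers the aggregate bias is ~1.5%, enough to inflate λ visibly and to
  break null-uniformity of the p-values at genome scale.  The default
  `variance="hwe"` divides by (1 − K_s/(2n_s²)) (clamped at 3×);
  `variance="hwe_plugin"` gives the uncorrected estimator and
  `variance="empirical"` the within-stratum sample variance.
- **Centering choice.**  With q̂_s equal to the stratum sample frequency,
  stratum-mean centring and HWE-expected centring (2q̂_s) coincide, so a
  single implementation serves both.

Missing genotypes are handled per SNP by complete-case analysis (the
stratum means, frequencies and kinship pair sums are all recomputed on the
observed subset).  A genome scan uses a vectorised path when the matrix has
no missing calls and every family lies within one stratum; otherwise it
falls back to the per-SNP routine.

Genomic control is λ = median(χ²)/0.4549364.  Diagnostic mode
`adjusted=False` zeroes the off-diagonal kinship terms; on
family-structured fixtures with phenotype-concordant families this naive
variance rejects at ~3× the nominal level while the adjusted test holds
0.05, which is the operational argument for the adjustment.

### Hazard-ratio estimation

`fit_hr` maximises Σ l_i jointly over β (per-allele, or het/hom indicators
for the 2-df model) and the per-stratum frequencies, using bounded
L-BFGS-B (|β| ≤ 5 guards separation; frequencies on the logit scale;
ftol 1e-8; finite-difference gradients).  Standard errors are robust
sandwich A⁻¹BA⁻¹ with B the sum over family clusters of score outer
products (central finite differences of per-individual contributions,
step 1e-5).  95% CIs are exp(β̂ ± 1.959964·SE).  On synthetic ascertained
cohorts (n ≈ 2,000, MAF 0.3, HR 1.3, 200 replicates) the log-scale bias is
< 0.01 and CI coverage ≈ 0.94; a naive prospective Cox fit on the same
data is more biased (both asserted in the test suite).

The age-varying model multiplies the hazard by exp((β0 + β1(t − t_ref))·g)
with t_ref = 50 years (the centring age is a package choice; it shifts β0
but not the β1 test).  The cumulative hazard ∫λ0(u)e^{(β0+β1(u−t_ref))g}du
is evaluated in closed form per piecewise-constant band, and β1 = 0 is
tested by a 1-df likelihood ratio against the age-constant fit.

Two-stage analyses: `combined_stage_fit` pools carriers with stage appended
to the stratum key (frequencies re-profiled per stage-stratum; carriers
appearing in both stages are an error, since cross-stage duplicates are a
QC responsibility), and `meta_fixed_effect` combines (HR, 95% CI) pairs by
inverse-variance weighting on the log scale, recovering SEs from CI widths.

## Quality control

Filters are pure functions logging (threshold, n_removed, n_remaining,
removed ids) into a report whose telescoping consistency is validated.
Fixed order — samples: call rate → heterozygosity FDR → IBS duplicates;
SNPs: monomorphic/gross-missing → call rate → MAF → exact HWE →
differential missingness (phenotype, batch, neighbour genotype) — and an
iterative loop alternating the two until a full pass removes nothing.
Specifics:

- **HWE**: the conditional exact test (standard tail definition, not
  mid-p), summing Pr(h | n, allele count) over heterozygote counts no more
  probable than observed; verified against an exact-fraction enumeration
  oracle for every table with n ≤ 60.
- **Heterozygosity outliers**: two-sided normal p-values of per-sample
  heterozygosity z-scores, Benjamini–Hochberg at FDR 0.1%.
- **Duplicates**: pairwise IBS (mean allele-sharing over shared calls)
  ≥ 0.95; the member with the lower call rate is dropped (tie →
  lexicographic id).
- **Ancestry outliers**: classical MDS of the standardized-genotype
  kinship matrix; a sample is flagged when its distance from the robust
  main-cluster centre on the first two coordinates exceeds `cutoff`
  (default 0.11) times the overall coordinate span *and* it is a robust
  outlier (MAD z > 6).  The published ">11%" rule has no recoverable
  metric, so this is a documented heuristic, not a reproduction: the
  two-part rule keeps homogeneous cohorts from flagging boundary samples
  while recovering strongly shifted ancestries (≥18/20 planted at
  Fst 0.15 in the tests).
- **LD pruning**: squared Pearson correlation of dosages; greedy
  best-p-first selection keeping SNPs with r² < 0.80 against everything
  already kept (undefined r² counts as independent).

## Gene-set enrichment

A gene's raw score is the minimum p over SNPs in a strand-aware window
(110 kb beyond the 5′ transcript boundary, 40 kb beyond the 3′).  Scores
are adjusted for confounders — log window length, log SNP count, and an LD
proxy (SNP count after r² ≥ 0.8 pruning) — by OLS on −log10 p with the
residual ranks mapped back to (0, 1].  The set statistic is the fraction
of set genes beating the genome-wide 95th-percentile cutoff, after
retaining only the best-scoring gene among any subset sharing a best SNP;
the p-value compares against 10,000 random same-size sets with the +1
correction, deduplicated the same way.  The permutation p is discrete: for
small sets (tens of genes) its null distribution is sub-uniform
(conservative), approaching exact uniformity as the set grows — both
regimes are asserted in the tests.

## IBD sharing

Segments are found GERMLINE-style: exact allele words of 64 markers
(windows slide by half a window, so a shared run 1.5 windows long is
guaranteed a hash hit) nominate candidate pairs, whose mismatch profiles
are merged into maximal runs under a budget of 1 mismatch per 100 markers
(haplotype mode; genotype mode treats opposite homozygotes as hard breaks
and defaults the budget to 0).  Lengths come from piecewise-linear
interpolation of a user genetic map (clamped outside anchors, with a
warning).  Sharing profiles count spanning pairs at grid sites every
2.5 cM, excluding user-supplied mask intervals (telomeres/centromeres);
group contrasts use pair-label permutation p-values and report a target
locus's mid-tie percentile within the genome-wide profile.

## The synthetic cohort generator

The generator is the package's test bed and defines the conditions under
which the statistical guarantees are demonstrated:

- **Families**: sizes 1–3 (probabilities 0.45/0.35/0.20); larger families
  are a typed mother, a latent untyped father and typed children, so every
  typed pair is first-degree (2φ = 0.5).  Families are assigned to 14
  countries with stage-1-like weights and a founder-mutation flag with
  probability 0.2.
- **Genotypes**: founders Binomial(2, p) under HWE (per-stratum p for the
  causal SNP; null MAFs uniform on [0.05, 0.5]); children by Mendelian
  gamete transmission, which induces exactly the 2φσ² covariance the score
  test models.
- **Phenotypes**: onset solves Λ0(T)·e^{βg} = −log U by inverting the
  piecewise-linear cumulative hazard.  The default baseline rises by age
  decade to a cumulative risk of ~50% by age 70 — a plausible synthetic
  default, deliberately *not* a published carrier rate table (users supply
  their own rates via config).  Independent constant-hazard ovarian cancer
  and BPM events (0.002/year from age 30) exercise the censoring rules;
  interview ages are uniform on [25, 80].
- **Ascertainment** is individual-level and phenotype-only: eligible cases
  have diagnosis ≤ 50 (subsampling weighted 3:1 toward diagnosis < 40),
  eligible controls are unaffected past 40.  Because the likelihood
  conditions on phenotype, only phenotype-based selection matters for
  validity; clinic-referral dynamics are out of scope.
- **Artifacts**: ledgered injections of background and differential
  (phenotype/batch) missingness, exact duplicates, heterozygosity-inflated
  samples, HWE-violating SNPs (het deficit), and Balding–Nichols
  frequency-shifted ancestry outliers, used to measure QC recovery.

What the generator does not emulate: chromosome-scale LD (the causal SNP
is unlinked to the null SNPs; a two-SNP copy suffices for pruning
fixtures), imputation uncertainty, genotype-calling intensity artifacts,
X-chromosome inheritance, or competing-risk correlation between breast and
ovarian disease.  Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to LD
confounding or calling artifacts in real intensity data.

## Problem sizes and numerical choices

The calibration study behind the headline λ uses ~1,703 ascertained
carriers (899 affected / 804 unaffected) from 2,600 simulated families and
150,000 null SNPs; the Monte-Carlo standard error of λ at that size is
about 0.006.  Parameter-recovery suites use 200 replicates at n ≈ 2,000.
Degenerate inputs are explicit: constant genotypes give U = 0 and p = 1
(flagged monomorphic when the stratum frequency is 0 or 1), non-positive
variances are flagged rather than silently dropped, strata below 2
carriers are pooled into a per-country rest stratum, and empty matrices or
empty ascertainment pools raise.  PLINK text round-trips are lossless
except for markers monomorphic in the file, where the unseen allele is
unrecoverable (the binary format, which records both alleles, has no such
caveat).

## Known limitations

- The per-individual retrospective likelihood ignores residual phenotype
  correlation within families beyond what conditioning on own phenotype
  captures; the sandwich variance absorbs this for inference but point
  estimates are not a full pedigree-likelihood MLE.
- The MDS ancestry cutoff is a heuristic (above).
- Hard-call genotypes only; no dosage input.
- The IBD detector's window/budget defaults assume marker densities of
  roughly 10+ markers/cM; sparser maps need a smaller window.
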