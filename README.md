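# carriermod

Association testing and effect estimation for **penetrance-modifier GWAS in
mutation carriers** — cohorts of women carrying a high-risk mutation (e.g.
*BRCA2*) recruited through cancer-genetics clinics, where the question is
whether common SNPs shift the carrier's breast-cancer hazard.

Such cohorts break standard GWAS tooling in two ways:

1. **Non-random ascertainment.** Carriers enter the study *because of* their
   phenotype (young affected cases, older unaffected controls), so a
   prospective Cox regression of disease on genotype is biased.  carriermod
   instead maximises the **retrospective likelihood** of the genotypes given
   the phenotypes,

   ```
   L_i(β, q) = P(t_i, δ_i | g_i) p_s(g_i) / Σ_g P(t_i, δ_i | g) p_s(g),
   P(t, δ | g) ∝ [λ0(t) e^{βx(g)}]^δ exp(−Λ0(t) e^{βx(g)}),
   ```

   where Λ0 is a known (external) carrier baseline cumulative hazard,
   x(g) the per-allele or 2-df genotype coding, and p_s(g) HWE genotype
   priors with per-stratum allele frequencies q_s (country × founder-mutation
   strata) profiled jointly with β.

2. **Familial correlation.** Relatives share genotypes.  The 1-df score test
   at β = 0, U = Σ_i (δ_i − Λ0(t_i)) (g_i − ḡ_s(i)), uses a variance that
   sums c_i c_j · 2φ_ij σ²_s over within-family pairs (φ = pedigree kinship),
   and hazard-ratio fits use a Huber/Lin–Wei sandwich variance clustered on
   family.

Around this core the package provides the full machinery of a two-stage
modifier GWAS: time-at-risk/censoring derivation, pedigree kinship, a
genotype/sample QC cascade with exact ledger bookkeeping (call rate, MAF,
exact Hardy–Weinberg, differential missingness, heterozygosity FDR, IBS
duplicates, iterative loop, MDS ancestry outliers, LD pruning), genomic
control (λ), fixed-effect stage combination, MAGENTA-style gene-set
enrichment, GERMLINE-style IBD segment sharing, and a synthetic-cohort
generator that emulates the study design end to end (Mendelian families,
proportional-hazards onset ages on a piecewise-constant baseline, two-stage
ascertainment, planted genotyping artifacts).

## Worked example

```python
import numpy as np
from carriermod import (SimConfig, AscertainmentScheme, simulate_cohort,
                        fit_hr, meta_fixed_effect)
from carriermod.assoc import prepare_scan_inputs, genome_scan

cfg = SimConfig(
    n_families=1500,
    beta=float(np.log(1.4)),      # planted per-allele HR 1.4
    causal_maf=0.3,
    n_null_snps=2000,
    seed=7,
    ascertainment=AscertainmentScheme(n_cases=600, n_controls=600),
)
data = simulate_cohort(cfg)
gm = data.selected_genotypes()
inputs = prepare_scan_inputs(data.selected, cfg.incidence)

scan = genome_scan(gm, inputs)
print(f"carriers analysed : {gm.n_samples}")
print(f"genomic inflation : lambda = {scan.lambda_gc:.3f}")
print(scan.results.nsmallest(3, "p")[["snp", "chisq", "p"]].to_string(index=False))

fit = fit_hr(gm.calls[:, 0], inputs)
print(f"per-allele HR     : {fit.hr[0]:.2f} "
      f"(95% CI {fit.ci_low[0]:.2f}-{fit.ci_high[0]:.2f})")

hr, (lo, hi) = meta_fixed_effect(1.30, (1.16, 1.45), 1.26, (1.11, 1.43))
print(f"combined HR       : {hr:.2f} (95% CI {lo:.2f}-{hi:.2f})")
```

prints

```
carriers analysed : 1200
genomic inflation : lambda = 1.021
    snp     chisq        p
 causal 17.298899 0.000032
snp1695 12.004802 0.000531
snp1219  9.469889 0.002089
per-allele HR     : 1.31 (95% CI 1.17-1.47)
combined HR       : 1.28 (95% CI 1.18-1.39)
```

Reading the output: λ ≈ 1.02 says the stratified, kinship-adjusted scan is
not inflated by the family structure or the strata; the planted modifier is
the top hit by orders of magnitude while the best null SNPs sit where the
multiplicity of 2,000 tests puts them; the retrospective fit recovers the
simulated HR of 1.4 within its confidence interval; and the last line
combines two stage-specific estimates on the log scale by inverse-variance
weighting.

## Command line

```bash
carriermod simulate --n-families 500 --beta 0.26 --seed 1 --out sim/cohort
carriermod qc    --genotypes sim/cohort --out sim/clean
carriermod assoc --genotypes sim/clean --phenotypes sim/cohort.pheno.tsv \
                 --incidence incidence.yaml --out assoc.tsv
carriermod fit   --genotypes sim/clean --phenotypes sim/cohort.pheno.tsv \
                 --incidence incidence.yaml --snp causal
carriermod meta  1.30 1.16 1.45  1.26 1.11 1.43
carriermod run   --config run.yaml --seed 1 --out results/
```

All QC/association thresholds default to conventional array-GWAS values
(SNP and sample call rate 0.95, MAF 0.01, HWE p 1e-6, IBS duplicate 0.95,
heterozygosity FDR 0.001, LD pruning r² 0.80, gene windows 110 kb/40 kb,
IBD minimum 5 cM) and are overridable by flags or the YAML config.

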