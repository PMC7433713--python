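# tacpgx

Pharmacogenomic–pharmacokinetic analysis of tacrolimus in renal-transplant
cohorts: CYP3A5 *3/*6/*7 metabolic-composite phenotyping, ABCB1 haplotype
estimation and haplotype–phenotype association, non-compartmental
pharmacokinetics over a 12-h dosing interval, ordered-trend statistics, and
a synthetic-cohort generator that emulates trough-targeted therapeutic drug
monitoring so the entire chain runs without patient data.

## The problem

Tacrolimus exposure varies widely between patients. Two gene products drive
much of that variability: the CYP3A5 isoenzyme that metabolizes the drug,
and the P-glycoprotein efflux transporter encoded by *ABCB1*. Three CYP3A5
variants — \*3 (rs776746), \*6 (rs10264272) and \*7 (rs41303343) — each
independently abolish protein expression, so single-SNP analyses mislabel
enzyme status. This package implements a **metabolic composite** over all
three loci:

* **Poor** metabolizer — homozygous variant at ≥ 1 locus (both chromosomes
  certainly carry a loss-of-function allele);
* **Extensive** — homozygous wild-type at all three loci;
* **Intermediate** — heterozygous otherwise; double heterozygotes are
  phase-ambiguous (the variants may lie in *cis* or in *trans*) and are
  conservatively called Intermediate with a `phase_ambiguous` flag.

The three *ABCB1* SNPs (1236C>T, 2677G>T/A, 3435C>T) are inherited as
haplotypes. With unphased genotypes the haplotype pair is latent, so
frequencies are estimated by EM under Hardy–Weinberg random pairing
(maximizing `L(f) = Π_i Σ_{(h,k)∼g_i} c·f_h·f_k`, where the sum runs over
diplotypes compatible with subject *i*'s genotype and `c = 2` for
heterozygous pairs), and haplotype–phenotype association uses a joint
maximum-likelihood normal model whose mean is additive in haplotype copy
number plus covariates, with phase marginalized over compatible diplotypes —
the approach popularized by THESIAS. Exact Hardy–Weinberg tests and pairwise
D′/r² linkage disequilibrium round out the population-genetic layer.

Pharmacokinetics are non-compartmental over one steady-state 12-h interval
sampled at 0, 1, 2, 3, 4, 6, 8, 10, 12 h: linear-trapezoid AUC₀₋₁₂ and
AUC₀₋₄, trough C₁₂, peak C_max/T_max, apparent oral clearance
CL/F = dose·1000/AUC₀₋₁₂ (L/h), and normalizations to a 1 mg dose and to
total and lean body weight (Janmahasatian). Group contrasts across the
ordered composite (Poor < Intermediate < Extensive) use a two-sided,
tie-corrected Jonckheere–Terpstra trend test (exact permutation p at small
n), Holm–Bonferroni-adjusted pairwise Wilcoxon rank-sum tests, and a
two-factor (composite × ABCB1 3435 T-carrier) Type-II ANOVA.

The simulator captures the study mechanism that makes these cohorts
statistically distinctive: clinicians titrate each dose in 0.5 mg steps to
a 4–9 ng/ml trough window, so **troughs are equalized across genotypes
while doses track clearance**. Clearance is drawn lognormally per composite
class; concentrations follow a one-compartment oral steady-state model with
multiplicative assay noise.

## Worked example

```python
from tacpgx import SimConfig, simulate_cohort, run_full_analysis

records, profiles, truth = simulate_cohort(SimConfig(n_subjects=65), seed=7)
report = run_full_analysis(records, profiles)

t2 = report.table2.set_index("parameter")
for p in ("dose", "cl_f", "auc_star", "c12"):
    row = t2.loc[p]
    print(f"{p:10s} Poor {row['Poor_mean']:6.2f}  Int {row['Intermediate_mean']:6.2f}  "
          f"Ext {row['Extensive_mean']:6.2f}  JT p = {row['jt_trend_p']:.2g}")
```

prints

```
dose       Poor   2.05  Int   2.65  Ext   5.62  JT p = 0.0037
cl_f       Poor  18.78  Int  24.74  Ext  51.71  JT p = 0.0019
auc_star   Poor  59.05  Int  50.30  Ext  21.23  JT p = 0.0019
c12        Poor   6.51  Int   6.33  Ext   6.54  JT p = 0.34
```

Read it as the therapeutic-drug-monitoring signature: Extensive
metabolizers clear the drug ~2.5× faster (51.7 vs 18.8 L/h) and therefore
need ~2.7× the dose (5.62 vs 2.05 mg) and show half the dose-normalized
exposure AUC\* — yet troughs (`c12`) are indistinguishable (p = 0.34),
because every subject was titrated into the same 4–9 ng/ml window. The
monotone dose/clearance/AUC\* gradients across the ordered classes are what
the Jonckheere–Terpstra p-values quantify. `report.table3` holds the
haplotype association (phenotypic mean of each haplotype's homozygote with
Wald 95% CI and likelihood-ratio p vs the CGC reference), `report.table4`
the composite × 3435-carrier grid, and `report.haplotype_frequencies` the
EM estimates by race.

The same chain is scriptable from a shell:

```bash
tacpgx simulate --seed 7 --out-dir cohort
tacpgx report --genotypes cohort/genotypes.csv \
              --concentrations cohort/concentrations.csv \
              --doses cohort/doses.csv --out-dir report
```

Real cohorts enter through the same readers: genotypes as a subject × locus
CSV or a VCF (loci matched by rsID, unphased GT), concentrations as a
long-format CSV plus a covariate table.

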