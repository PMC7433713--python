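# Methods

This note records the models, conventions, and numerical choices behind
`tacpgx`, and what the synthetic cohorts do and do not establish about real
data.

## Metabolic-composite phenotyping

The classifier operates on unphased calls at rs776746 (\*3), rs10264272
(\*6) and rs41303343 (\*7), each variant independently abolishing CYP3A5
expression. Rules, in precedence order: homozygous-variant at any locus ⇒
Poor (loss on both chromosomes is certain regardless of the other loci);
homozygous wild-type at all three ⇒ Extensive; otherwise Intermediate.
Subjects heterozygous at two or more loci could be Poor (variants in
*trans*) or Intermediate (in *cis*); they are assigned Intermediate — the
conservative choice when phase is unobserved — and flagged
`phase_ambiguous` in the result's `basis`. The classifier is verified
against an independent phase-enumeration oracle over all 27 unphased
three-locus combinations (19 Poor, 7 Intermediate, 1 Extensive) and is
monotone: raising variant dosage at any locus never moves the call toward
Extensive.

Missing genotypes are never imputed; subjects with incomplete CYP3A5 calls
are excluded from composite analyses and itemized in the log. The
wild-type/variant orientation of each locus is fixed by a built-in allele
map (overridable via `make_locus_map`) because REF/ALT orientation differs
across builds and assay strands.

## EM haplotype estimation

For the three ABCB1 loci the diplotype is latent: a subject heterozygous at
k loci is compatible with 2^(k−1) unordered haplotype pairs (the tri-allelic
2677 site expands like any heterozygote). Frequencies maximize the
Hardy–Weinberg multinomial likelihood via EM (Excoffier–Slatkin gene
counting): E-step, posterior weights over each subject's compatible pairs at
the current frequencies; M-step, weighted haplotype counting. Unique
genotype patterns are collapsed before iteration, so cost is independent of
cohort size beyond the pattern tally.

Defaults: tolerance 1e-8 on the log-likelihood, 5,000 iterations maximum,
10 restarts (one near-uniform start with a small seeded perturbation, the
rest Dirichlet-random), all driven by one seed. The log-likelihood is
non-decreasing by construction and this is asserted in tests; ties between
equal-likelihood modes (e.g. a single double-heterozygote, where coupling
and repulsion solutions both attain likelihood ½) are broken by whichever
restart wins — an arbitrary but reproducible choice. Non-convergence
returns `converged=False` with a warning, never silently.

HWE uses the exact conditional test (probability of heterozygote counts as
or less probable than observed given the allele counts), stratified by
race; LD (D, D′, r²) is computed from the estimated haplotype table on
major-allele coding. For HWE and LD the 2677 T and A alleles are collapsed
into one non-G class: A is rare and the haplotype labels of interest
(TTT/CGC) are bi-allelic per locus. A monomorphic locus yields D = 0 with
D′ and r² reported as NaN rather than 0/0.

## Haplotype–phenotype association

The joint model treats the phenotype as normal with mean additive in
haplotype copy number plus covariate terms, and marginalizes phase:

L_i = Σ_{(h,k) compatible with g_i} P(h,k | f) · N(y_i; β₀ + β_h + β_k + γ'x_i, σ²)

with P(h,k|f) = 2 f_h f_k (h≠k) or f_h². Frequencies and effects are
maximized jointly by EM (E-step: diplotype posteriors informed by both the
genotype and the phenotype; M-step: weighted counting for f, weighted least
squares for the mean model, weighted residual variance for σ²). On
phase-unambiguous data the model reduces exactly to ordinary least squares
on allele dosage, which tests assert to 1e-8.

Reporting conventions: the reference haplotype is CGC by default; each
haplotype's "phenotypic mean" is the expected phenotype of its homozygote
at reference covariate levels (intercept + 2 × per-copy effect) — the
homozygote convention rather than the single-copy one, chosen so the
reference row equals the model intercept. 95% CIs are Wald intervals from
the observed information (numerical Hessian over the full parameter vector,
frequencies on a multinomial-logit scale; delta method for the means).
P-values are likelihood-ratio tests refitting with the haplotype's effect
pinned at zero. Haplotypes below a frequency floor (default 0.03,
configurable) share one pooled "rare" effect; the pooling is decided on the
genotype-only EM frequencies, so a haplotype whose joint-model frequency
drifts below the floor afterwards keeps its own effect. In small cohorts,
low-frequency haplotypes can produce unstable effect estimates with wide
CIs — visible in 65-subject demos and intrinsic to the method, which is why
the pooling floor exists.

Null calibration is tested by simulation: with zero haplotype effect the
likelihood-ratio p is uniform (type-I error at 0.05 within Monte-Carlo
error over 500 replicates).

## Non-compartmental pharmacokinetics

AUC is the exact integral of the piecewise-linear interpolant (linear
trapezoid; off-grid boundaries interpolated), so AUC(0,4) + AUC(4,12) =
AUC(0,12) identically. C₁₂ is the observed sample within ±15 min of 12 h —
never an extrapolation; T_max ties break to the earliest time; there is no
terminal-slope extrapolation because the analysis is confined to one dosing
interval. CL/F = dose(mg)·10⁶/AUC(ng·h/ml)/1000 = dose·1000/AUC in L/h, and
CL/F × AUC = dose·1000 holds per subject to machine precision. Lean body
weight uses Janmahasatian (2005) — pinned because the source analysis named
no formula — with Hume (1966) available as an alternative; the LBW < TBW
bound holds over the physiological BMI range (the male denominator crosses
TBW only below BMI ≈ 12, which triggers the non-physiological-input
warning). Renal function uses the four-variable MDRD equation. Besides the
reported dose/TBW and CL/LBW columns, CL/TBW is emitted as an extra column
since "adjusted for TBW and LBW" is ambiguous about which quantity was
TBW-scaled.

## Trend and group statistics

The Jonckheere–Terpstra statistic sums between-group Mann–Whitney counts
over ordered group pairs with ties counting ½ (doses rounded to 0.5 mg
guarantee ties). The asymptotic p uses the tie-corrected null variance and
a 0.5 continuity correction; the exact p enumerates all splits of the
pooled sample into the observed group sizes (used when total n ≤ 12 or on
request) with the two-sided value 2·min(lower tail, upper tail) capped at
1\. Exhaustive enumeration at group sizes (4,4,4) puts the maximum
exact-vs-asymptotic gap at ≈ 0.011 with the continuity correction (≈ 0.06
without), which motivated including it. Pairwise comparisons are two-sided
Wilcoxon rank-sum tests (exact when both groups are ≤ 25 with no ties,
continuity-corrected normal otherwise) with Holm step-down adjustment. No
additional multiplicity control is applied across PK parameters.

The combined analysis fits, per PK parameter, a main-effects linear model
over the unbalanced 3×2 composite × 3435-carrier grid with Type-II sums of
squares (matching a report of two main-effect p-values without
interaction); cell means carry both sample and pooled-variance model SEs
because either convention is defensible. A factor observed at a single
level is dropped and its p reported as NaN; an optional Wilks-lambda
multivariate test across a parameter set is available. On balanced designs
the Type-II p-values equal textbook two-way ANOVA closed forms to 1e-8.

## Synthetic cohorts

The generator emulates the study conditions: 65 subjects by default, race
mix 33:32 Black:White, CYP3A5 haplotype frequencies per race (defaults
Black {\*1 .45, \*3 .32, \*6 .12, \*7 .11}, White {\*1 .05, \*3 .95} —
qualitative defaults, not estimates), ABCB1 haplotype frequencies with the
TTT entries fixed to the reported 39.8% (White) and 8.9% (Black) and the
remainder spread over CGC and minor haplotypes. Loss-of-function CYP3A5
variants never co-occur on one simulated haplotype, matching star-allele
definitions, so double-heterozygote ambiguity is a property of observation,
not of the truth. Haplotypes are drawn independently per subject, giving
Hardy–Weinberg genotypes by construction.

Clearance is lognormal per composite class with arithmetic mean/SD
calibrated to the reported group summaries (21.14/8.02, 30.79/12.19,
47.43/17.30 L/h), multiplied by 0.85 for ABCB1 3435 T-carriers (direction
from the combined analysis; the magnitude is a free default). The PK shape
is ka = 2 h⁻¹ and t½ = 12 h, putting C₁₂/C_avg ≈ 0.71; V/F follows from
CL/F and the half-life. Doses are titrated in 0.5 mg steps to a 6.5 ng/ml
trough target inside the 4–9 ng/ml window (the clinical target point within
the window is not documented; 6.5 is this package's choice), and observed
concentrations apply multiplicative lognormal assay noise (CV 5% by
default, consistent with an immunoassay). With zero assay noise, ≥ 99% of
subjects with feasible doses land in the window, and per-subject NCA
recovers the true clearance within trapezoid discretization error (< 5% on
the study grid).

What the simulator does **not** reproduce: with this shape and target,
titrated exposures sit near AUC₀₋₁₂ ≈ 110 ng·h/ml, so most simulated
subjects fall below the 120–200 ng·h/ml therapeutic band — a higher
below-band fraction than the ~40% seen clinically, where troughs averaged
nearer 7 ng/ml. It also omits visit-to-visit titration dynamics, adherence,
food effects, intra-subject PK variability, genotyping error, and any
CYP3A4 or mycophenolate pharmacology. Passing tests therefore demonstrate
estimator correctness and the TDM mechanism (equalized troughs, doses
tracking clearance), not clinical dosing guidance.

## Problem sizes and determinism

Default verification sizes were chosen to make sampling error negligible
relative to the assertions: EM frequency recovery at 1,000 subjects × 10
seeds (binomial SE ≈ 1.1% at 39.8%, so a ±2-point check on the 10-seed mean
is comfortably powered), trend-test power at the reported group sizes
(35/23/7) × 200 replicates, and dose reconstruction at 200 subjects per
composite class. All randomness flows through `numpy.random.default_rng`
seeded explicitly; every simulation, report and script output is
reproducible from (config, seed).
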