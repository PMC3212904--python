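# Methods

## Data model and allele orientation

Genotypes are risk-allele dosages c ∈ {0, 1, 2} with a missing mask. Every
variant is *risk-oriented*: the declared risk allele is the one whose count
increases modelled risk. For protective variants (here the two *IL23R* SNPs,
rs11209026 and rs7517847, with published multivariate ORs 0.43 and 0.59) the
major allele is declared the risk allele (`is_flipped`), the frequency
becomes 1 − f and the weight the reciprocal OR (2.33, 1.69). This makes both
risk scores monotone in risk and matches the control score distribution of
the reference threshold table (control mean count score ≈ 2·Σp ≈ 4.8, so
most controls sit below the ≥7 cutoff). The flip is an involution and is
applied on VCF ingestion (ALT count c ↦ 2 − c when the risk allele is REF).

Missing genotypes are handled pairwise in frequencies, 2×2 tables and LD
(only jointly observed samples enter); risk scores mean-impute a missing
dosage as twice the pooled risk-allele frequency so the cohort size stays
fixed, flagging affected samples; the multivariate regression uses
complete-case rows. These are documented defaults, not inferences — the
reference analysis is silent on missingness.

## QC statistics

**HWE.** Pearson χ² with 1 df of observed genotype counts against
(np̂², 2np̂q̂, nq̂²) with p̂ from the allele counts. Monomorphic input returns
χ² = 0, p = 1. Computed among controls by default (the source-population
stratum); pooled or case strata are options.

**LD.** Two-locus haplotype frequencies are maximised by EM from unphased
genotypes: all cells of the 3×3 genotype table except the double
heterozygote contribute fixed haplotype counts; the double heterozygote's
cis/trans split is re-weighted each E-step by the current estimate
h_AB·h_ab/(h_AB·h_ab + h_Ab·h_aB). Initialisation is linkage equilibrium;
convergence is max frequency change < 1e-10 or 1000 iterations; the
observed-data log-likelihood is non-decreasing (asserted in tests). Then
D = p_AB − p_A·p_B, D′ = D/Dmax with Dmax = min(p_A·q_B, q_A·p_B) for D > 0
and min(p_A·p_B, q_A·q_B) for D < 0, and r² = D²/(p_A q_A p_B q_B). If
Dmax = 0 (boundary frequencies) D′ is defined as 0 with a warning flag to
avoid 0/0. The 1-D grid search over p_AB (marginals are phase-free and fixed
at their MLEs) serves as an independent oracle in the tests, never as the
implementation.

## Association

All 2×2 effects use OR = ad/bc, SE(ln OR) = √(1/a+1/b+1/c+1/d), 95% CI
exp(ln OR ± z·SE), two-sided normal p. If any cell is zero, 0.5 is added to
all four cells (Haldane-Anscombe) and the result flagged — the analogue of a
"not determinable" cell left blank in sparse genotype strata. Allelic tests
treat the 2n alleles as independent observations; this convention is pinned
down exactly by the extreme-cutoff reference row (27, 342, 3, 500) → CI
3.96–43.72. Carriage and compound tests are carrier-level tables with
exposure ≥1 and ≥2 risk alleles respectively across a SNP set.

The logistic model is maximised by Newton-Raphson/IRLS with step-halving
(halve until the log-likelihood does not decrease), convergence at max score
residual < 1e-8, SEs from the inverse observed information. Perfect
separation is detected as a coefficient passing |β| > 15 while the
likelihood still climbs; the fit is flagged, not silently reported. Rank
deficiency raises an error naming the collinear columns. Codings:
log-additive (per-SNP linear dosage) and genotype (per-SNP 1-copy/2-copy
indicator pair). A backward-elimination helper (drop the least significant
term while p ≥ α) is provided for convenience and labelled non-canonical —
there is no single canonical selection path for "SNPs that sustain
significance", so the full joint fit is the primary interface.

**Power.** Analytic power of the two-sided allelic test uses the normal
approximation on allele frequencies: p₁ from the control frequency and OR on
the odds scale, SE_alt = √(p₁q₁/2n_case + p₀q₀/2n_control), power =
Φ(|p₁−p₀|/SE_alt − z_{1−α/2}) plus the opposite-tail term (negligible except
near the null, where it makes the null value exactly α). The Monte-Carlo
mode draws case/control genotype counts from the analytic stratum
distribution (below), which for a single SNP is exactly the conditional law
the rejection simulator induces, and reports the empirical rejection rate
with its binomial SE. With the study geometry (369/503, control RAF 0.59,
α = 0.05) the detectable OR at 80% power is ≈ 1.32; the assumed frequency
behind that published remark is not stated anywhere, and 0.59 — the
*ATG16L1* risk-allele control frequency under discussion there — reproduces
it; it is a documented assumption, not an assertion about the authors'
input.

## Risk scores and classification

Count score: Σ cᵢ over the seven-SNP panel (*NOD2* rs2066844/rs2066845/
rs2066847, *IL23R* rs11209026/rs7517847 flipped, *IRGM* rs13361189, *PTGER4*
rs1373692), range 0–14. Weighted score: Σ wᵢcᵢ with wᵢ the multivariate
log-additive OR by default ("multiply the OR by 0, 1 or 2"); log-OR or fully
user-supplied weights are accepted, because the published weight set and
protective-allele convention cannot be uniquely reconstructed — under the
reciprocal-OR flip the control weighted-score distribution sits higher than
a minor-allele-coded one, so no bin-for-bin distribution reproduction is
claimed.

Cutoffs are inclusive ("score ≥ t"). For each cutoff: sensitivity
= 100·a/n_cases, specificity = 100·(n_controls−c)/n_controls, accuracy their
prevalence-weighted mean, PPV/NPV conditioned on the predicted class, OR/CI/p
from the 2×2 Wald machinery. The ROC walks all distinct cutoffs in
descending order; trapezoidal integration makes the AUC equal to the
Mann-Whitney probability with ties counted ½ (verified against exhaustive
pairwise counting and scikit-learn).

**Reference-table remark.** Recomputing the published per-cutoff table from
its own counts reproduces every metric of the count rows ≥3…≥8 and weighted
rows ≥2…≥8 to 0.1 (OR to 0.01), with two documented exceptions: (i) the
printed ORs of the weighted ≥9/≥10/≥11 rows are not the cross-products of
their printed counts (7.30/5.96/6.32 recomputed vs 7.69/9.45/14.2 printed) —
`recompute_threshold_table` flags such rows rather than reproducing them;
(ii) the count ≥6 accuracy prints 64.5 where its own counts imply
(214+351)/872 = 64.8 via the accuracy identity that all other rows obey — a
single-cell typo, excluded from exact reproduction.

## Synthetic cohort generator

The generator emulates the study conditions: 369 cases / 503 controls, 22
SNPs at the reference control risk-allele frequencies (used as population
frequencies), per-allele ORs, disease prevalence 0.005 (a CD-like rare
disease; no prevalence is stated in the reference analysis, so it is an
exposed parameter whose rare-disease default keeps OR ≈ RR), and the
reported strong LD pairs (D′ 0.86–1.0 among the *NOD2*, *IL23R*, *IRGM*,
*PTGER4*, *ATG16L1* clusters).

Sampling is honestly retrospective: genotypes drawn prospectively (two
haplotypes per LD block; a block is a tree of pairwise D′ constraints —
chains are allowed, cycles rejected — sampled root-first with per-edge
conditionals from the pair's haplotype table), disease assigned
Bernoulli(σ(β₀ + Σ ln ORᵢ·cᵢ)), individuals retained in draw order until
both quotas fill. A configurable cap errors out on infeasible quotas. One
master seed drives a single generator; per-experiment replicate seeds are
spawned via `SeedSequence`. Bit-exact reproducibility is promised within
this implementation only.

**Intercept calibration.** β₀ solves E[σ(β₀+S)] = prevalence over the exact
distribution of S = Σ ln ORᵢ·cᵢ: per-block genotype score PMFs are
enumerated exactly (haplotype trees have ≤ 2³ states here) and convolved;
if the global support would exceed 2×10⁵ atoms it is snapped to a uniform
grid, introducing error ≪ 1e-6 in the prevalence equation, then Brent's
method solves to xtol 1e-12 on a guaranteed bracket
[logit(π) − max S − 1, logit(π) − min S + 1].

**What it does and does not emulate.** It reproduces HWE in the source
population, stratum-specific allele frequency shifts, retrospective
ascertainment, and pairwise LD. It does not model population structure,
relatedness, genotyping error, non-MCAR missingness, or full multi-locus
haplotypes beyond chained pairs (the 3-SNP *IRGM* block is a chain, which
matches pairwise D′/r² but not necessarily three-locus frequencies). Passing
tests therefore validate the estimators under the stated generative model,
not robustness to those real-data complications. Quantities that depend on
the unavailable raw genotypes (univariate OR table values, per-SNP
multivariate coefficients on real data, the published AUCs and score
histograms) are checked distributionally — parameter recovery, coverage,
calibration — not cell-for-cell.

## Validation experiments (problem sizes)

- Parameter recovery: 200 replicates of the 7-SNP cohort at 369/503,
  prevalence 0.005; median joint log-additive OR per SNP within 15% of truth
  and aggregate 95% Wald-CI coverage within [0.93, 0.97] (observed ≈ 0.95).
- Null calibration: 1000 replicates of a single-SNP cohort (100/100, RAF
  0.3, prevalence 0.1) with OR = 1; allelic-test type-I error within
  [0.04, 0.06] and control HWE p-values uniform (KS at the 0.01 level).
- Power cross-check: 2000 Monte-Carlo replicates agree with the analytic
  formula within two binomial SEs.
- Oracle equivalences: EM LD vs a 1e-5-resolution likelihood grid (≤ 1e-4),
  AUC vs exhaustive pairwise counting (exact), single-binary-covariate
  logistic vs the closed-form 2×2 OR (1e-8), IRLS vs statsmodels
  (coefficients to 1e-6).

These sizes were chosen to give stable Monte-Carlo tolerances at interactive
runtimes; all experiments are reproducible from one integer seed
(`scripts/acceptance.py --seed N`).

## Known limitations

- Wald intervals and the Haldane correction are asymptotic conveniences;
  exact (Fisher/Wigginton) tests are out of scope by design.
- The backward-pruning selection path is one of many; published "surviving
  SNP" sets need not be recoverable by it.
- The score is developed and evaluated on the same data by construction
  (no cross-validation), mirroring the reference design; AUCs are
  in-sample.
- rs1373692 is carried purely as an identifier with a declared risk allele;
  its printed gene/annotation pairing is not adjudicated here.
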