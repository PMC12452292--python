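# Methods

## Scope and design

The package implements a two-arm safety analysis. The first arm is
classical pharmacovigilance disproportionality on spontaneous-report
data: does a target drug family co-occur with a target set of adverse
event preferred terms (PTs) more often than independence would predict?
The second arm is two-sample drug-target Mendelian randomization: using
cis-region variants as proxies for pharmacological modulation of the
target, does genetically proxied exposure shift the outcome? Both arms
are driven by synthetic-data generators whose parameters are the ground
truth the tests check against.

The public surface follows the model/results convention: a
`DisproportionalityModel` is built from one or more contingency tables
and `fit()` returns a `DisproportionalityResults` with estimates,
interval bounds, criterion flags and a `summary()`; an `MRModel` is built
from a harmonized `InstrumentSet` (directly or via
`MRModel.from_summary_stats`, which runs selection and harmonization) and
`fit()` returns `MRResults` with the five estimates. The stateless
per-statistic functions underneath are public too.

## Spontaneous-report model

### Generator

Each synthetic report is one case: a primary (drug, event) cell drawn
from a multinomial over the joint law q(d,e) ∝ p_d · p_e · lift(d,e),
where `lift` is the configured reporting-rate ratio relative to
independence (1 everywhere by default). Extra co-reported drugs (0–2,
mean 0.5) are drawn within the primary drug's class (target family /
other lipid-lowering / other), and extra reactions (0–3, mean 0.7) from
non-memory PTs only. Those two restrictions are deliberate: they make a
report's 2×2 membership — target-drug status, class membership, and
target-event occurrence count — a function of the primary draw alone, so
the expected cells, and hence the true ROR, are available in closed form
(`expected_cells`). The closed form holds for the target *family*; a
single brand can ride along as an extra on a family report, so
brand-level cohorts have no ledger truth (they remain supported in the
ETL).

Default conditions: 2% of primary reactions are memory-loss PTs spread
over the nine terms, 3% of primary drugs are the target family, 17%
other lipid-lowering agents; ~30% of ages and 5% of genders missing;
5% duplicated CASEIDs. Duplicates clone a case with a receipt date 1–90
days later and a higher report version number, optionally mutating one
demographic field — exercising every branch of the deduplication rule
(latest FDA_DT, ties to highest PRIMARYID). Files are written in the
'$'-delimited quarterly ASCII dialect (DEMO/DRUG/REAC, plus an OUTC
table carrying serious-outcome codes), byte-for-byte fixed by the seed.

What the generator does **not** emulate: realistic co-prescription
structure, MedDRA hierarchy above flat PTs, reporting-rate drift over
time, free-text drug-name noise, and probabilistic (non-CASEID)
duplicates. Passing tests therefore demonstrate correctness of the
counting and inference machinery under the stated sampling model, not
robustness to real FAERS messiness.

### Statistics

* **ROR** with the Woolf log-scale Wald interval. Zero cells are an
  error by default; an explicit Haldane +0.5-to-every-cell option exists
  and is flagged in results, never applied silently.
* **PRR / χ²** with the Yates continuity correction by default
  (uncorrected available), matching the usual MHRA-criterion practice.
* **EBGM** via the two-gamma-mixture gamma-Poisson shrinker. The five
  hyperparameters (α₁, β₁, α₂, β₂, π) are fitted by maximizing the
  negative-binomial mixture marginal likelihood over the drug–event
  matrix with L-BFGS-B on log/logit-transformed parameters, starting
  from (0.2, 0.1, 2, 4, 1/3), box constraints (10⁻⁶, 10⁶), ftol 10⁻⁸;
  non-convergence raises with the optimizer trace attached. The
  posterior is the two-component gamma mixture with weights given by the
  component marginals; EBGM05 is found by Brent root-finding on the
  mixture CDF (residual < 10⁻⁸, verified against brute-force quadrature
  to 10⁻⁶ in tests). Fewer than ~100 pairs triggers a warning; a single
  table falls back to the canonical starting prior and says so in the
  results (`prior_source`).
* **IC** in the observed-vs-expected +½-offset form with the exact
  gamma-quantile credibility bound — chosen because it is closed-form
  and testable; which exact BCPNN variant the field's SAS tooling uses
  is not standardized.

Signal criteria as printed in results: ROR lower CI > 1 with a ≥ 3;
PRR ≥ 2 with χ² ≥ 4; EBGM05 ≥ 2; IC025 > 0; overall = all four.

### ETL choices

Drug matching is case-insensitive substring over drug name and active
ingredient, all role codes by default (suspect-only restriction
available) — the least-surprise default where practice varies. Event
matching is exact case-insensitive PT comparison, counted per
occurrence: the default counting unit is event-level (a report with two
matched PTs contributes 2), with a report-level switch. The
lipid-lowering background is a packaged editable generic-name list
standing in for ATC class C10; spontaneous-report data carry no ATC
codes, so no lookup is attempted. Age strata are 18–64 and ≥65; missing
ages form their own stratum and under-18 reports get a separate `<18`
stratum so the adult bands stay clean while strata still partition the
universe. Dates compare as integer YYYYMMDD.

Percentages in rendered tables use round-half-up to two decimals.
Percentages are always computed from counts; published characteristic
tables occasionally contain percentage cells inconsistent with their own
counts, and the renderer makes no attempt to reproduce such cells.

## GWAS generator and MR

### Generator

`n_snps` variants (default 100) at distinct positions in a configurable
cis region (default chr1:55,505,221–55,530,525, ~25 kb). True per-allele
exposure effects have magnitude uniform in [0.5, 1.5] × scale (default
scale 0.05 phenotype SD) with a configurable fraction of
exposure-lowering effect alleles (default 30%), forcing the orientation
step. Standard errors follow the per-allele approximation
se = scale/√(2·MAF·(1−MAF)·n) with n = 500,000 (exposure) and 50,000
(outcome) by default; observed betas add N(0, se²) noise. Outcome
effects are β_Y = θ·β_X(true) + α + noise with α ~ N(pleiotropy_mean,
pleiotropy_sd²). LD is block-diagonal with constant within-block
correlation (positive semi-definite by construction); estimation noise
is drawn independently across SNPs, so LD affects clumping but not the
sampling correlation of effect estimates — a simplification that keeps
estimator calibration exact at the cost of not stress-testing residual-LD
bias. The outcome table re-encodes configurable fractions of SNPs with
swapped alleles (sign and frequency flipped) and strand complements, and
makes ~10% of variants palindromic.

### Pipeline

Selection: region + p < 5×10⁻⁸ filter, then greedy clumping — sort by
p, accept the best, discard SNPs with r² > 0.3 within 100 kb of *any*
accepted SNP (distance-to-any semantics; ties in p broken by SNP id for
determinism). Harmonization resolves the four allele encodings,
aligns palindromic SNPs by allele frequency when both EAFs are outside
(0.42, 0.58) and drops them otherwise, drops irreconcilable pairs with a
logged reason, and finally orients every instrument to the
exposure-increasing allele (flipping both betas), the convention Egger
regression needs. Instruments are kept in canonical SNP order so seeded
bootstrap SEs are invariant to input order.

Estimators: IVW as zero-intercept weighted regression with weights
1/se_Y², SE scaled by max(1, √(Q/(L−1))) (multiplicative random effects,
never deflating); Egger as weighted regression with intercept, residual
scale floored at 1, p-values from t with L−2 df; weighted median by
cumulative-weight interpolation at 50% with parametric-bootstrap SE
(default 1000 draws, mandatory seed); simple and weighted mode as the
argmax of a Gaussian KDE over the Wald ratios (512-point grid spanning
the ratios ± 3 bandwidths), bandwidth φ × 0.9·min(sd, mad/0.6745)·L^(−1/5)
(φ = 1 default), degenerate all-equal ratios returned directly. CIs are
exp(β ± 1.96·se) throughout; p-values two-sided normal except Egger.
The positive-control runner executes the full battery and raises a
dedicated error (CLI exit code 3) when the IVW direction contradicts the
configured truth; a control with no configured direction warns instead.

## Problem sizes

The shipped checks run at desk scale, chosen to hold Monte-Carlo error
well below the margins being asserted: 200,000 reports for lift
recovery (expected a ≈ 1000, binomial CV ≈ 3.5%), 500 tables for
null-calibration, 50,000 pairs for MGPS weight recovery (±0.05 band
≈ 10 MC SDs), 300–500 replicates of 50–60 instruments for IVW coverage
and estimator recovery.

## Known limitations

Two-way MGPS only (no multi-item sets, no time-scan statistics);
deduplication is exactly the CASEID rule, not probabilistic linkage; no
reference-panel LD (the LD matrix is an input); no colocalization,
Steiger filtering or multivariable MR. The IC and χ² variants are one
reasonable convention each; printed values from other toolchains may
differ at the margins without the underlying counts.
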