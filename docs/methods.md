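# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the
simulation-based tests do and do not establish.

## Cohort definitions and filtering

A sample enters the **metastatic** cohort if it is metastasis tissue
*or* a stage-IV primary (a stage-IV metastasis sample counts once, in
the metastatic cohort), and the **early-primary** cohort if it is a
primary of stage I–III. Everything else is excluded with a recorded
reason, checked in this order:

1. `msi_h` — samples *known* to be MSI-H. Their globally inflated
   mutation load would confound frequency comparisons. Samples of
   unknown MSI status are kept: the exclusion targets known MSI-H only.
2. `unknown_origin` — sample type not identifiable as primary or
   metastasis.
3. `assay_filtered` — panel not on the configured allow-list (the
   allow-list is off by default; it exists to reproduce restrictions
   such as "MSK-IMPACT panels only").
4. `unknown_stage_primary` — primaries whose stage is not recorded.
   Cohort membership cannot be decided for them, so they are excluded
   rather than guessed.

Multiple samples from one patient are *not* collapsed; the unit of
analysis is the sample. This matches registry-style counting and is a
documented choice, not an oversight.

"Nonsilent" means missense, frameshift (ins/del), nonsense, nonstop,
splice-site or translation-start-site. The synonym table lives in
`data/variant_classes.yaml` and is matched case- and
punctuation-insensitively; unknown tokens count as silent and are
tallied in the log rather than raising, because registry MAF dialects
drift.

## The enrichment statistic

For a module M (a set of 1–3 driver genes; a sample carries M iff every
gene of M is nonsilently mutated in it — AND semantics) the 2×2 table
(a, b; c, d) counts carriers/non-carriers in the metastatic and
early-primary cohorts.

**Two-sided Fisher exact test, minimum-likelihood definition.** With
N = a+b+c+d, K = a+c, n = a+b, the hypergeometric pmf is
Pr(k) = C(K,k)·C(N−K,n−k)/C(N,n); the two-sided P sums Pr(k) over all k
in the support with Pr(k) ≤ Pr(a)·(1 + 1e-7). The 1e-7 relative slack
treats floating-point near-ties as ties, matching standard statistical
software. "Two-sided Fisher" has competing definitions (doubling the
one-sided tail is the main alternative); the minimum-likelihood
convention is stated explicitly for that reason. Probabilities are
computed via `gammaln` in log space and accumulated with `logsumexp`,
so deep tails (P ~ 1e-300) remain accurate. Degenerate margins leave a
single admissible table and give P = 1. The implementation is verified
against an exact rational brute-force enumeration for *every* table
with N ≤ 30 (max |ΔP| observed ≈ 2e-14) and against
`scipy.stats.fisher_exact` property-wise; scipy is never the
implementation.

**Odds ratio.** Reported as the sample cross-product (a·d)/(b·c), with
0.5 added to every cell when any cell is zero (Haldane). The exact
test's P never uses the correction. The enrichment direction is the
sign of log OR.

**Multiple testing.** Bonferroni per cancer type: q = min(1, P·m) with
m = the number of modules actually tested in that cancer type.
Single-gene and multi-gene modules share one family — the alternative
(separate families) has no principled boundary once modules overlap.
Results are ordered by (q, P, module size, gene list) for deterministic
output. Significance flags: `*` at q < 0.05, `**` at q < 0.01.

**Driver selection and enumeration.** Per cancer type, a user-supplied
driver list is filtered to genes with ≥ `min_met_samples` (default 5)
metastatic carriers; modules are all subsets of size 1..`max_module_size`
(default 3 — the largest module size of practical interest here; the
count grows as Σ C(g,k), so a guard rail refuses > 10⁶ modules unless
forced).

## Survival analysis

Kaplan–Meier: S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) over distinct event times;
subjects censored at an event time are still in the risk set at that
time (events precede censorings at ties — the standard convention).
Log-rank: at each distinct event time, E₁ accumulates d·n₁/n and the
hypergeometric variance accumulates d·(n₁/n)(n₂/n)(n−d)/(n−1); the
statistic (O₁−E₁)²/V is referred to χ²(1). Zero total events returns
P = 1 with a warning. The module is endpoint-agnostic
(progression-free vs overall survival is a column-selection concern)
and both estimators are cross-checked against `lifelines` in the tests.
The altered group is defined by *nonsilent* mutations, consistent with
the rest of the pipeline. No Cox regression or confidence bands are
provided; the scope is the two-group contrast.

## The synthetic cohort generator

The generator defines the study conditions for every calibration claim:

- **Scale.** Defaults mimic a non-small-cell lung cancer registry
  cohort (3298 metastatic / 4012 early-primary) at quarter scale
  (824/1003) so tests run in seconds.
- **Gene frequencies.** No public per-gene table is bundled, so the
  default panel spans 0.5–15% (TP53 0.15 down to MET 0.005), the range
  typical of targeted panel sequencing; these are assumptions, flagged
  as such.
- **Enrichment injection.** A latent "module-active" Bernoulli in MSS
  metastatic samples forces all module genes mutated with probability
  π = (q − p₀)/(1 − p₀), where p₀ = Π p_g is the baseline carrier
  probability and q solves odds(q) = OR·odds(p₀). This calibrates the
  *module-level* marginal odds ratio exactly; per-gene independent
  inflation was rejected because it under-delivers module-level OR.
  Odds ratios < 1 use the dual thinning construction. A side effect:
  modules *overlapping* an injected module are genuinely enriched too
  (their genes' marginal rates rise), so the recovery report tallies
  false positives among gene-disjoint modules separately from
  overlapping ones — only the former indicate a miscalibrated test.
  Injecting several modules that share genes compounds their effects;
  calibration is exact only for non-overlapping injections.
- **MSI-H contamination.** Each sample is independently MSI-H with
  probability 0.04 (registry-plausible), with carrier probabilities
  inflated ×5 (capped at 0.95). Ground truth labels these samples
  excluded; the end-to-end tests require the filters to remove exactly
  them.
- **Mutation rows.** Each carrier emits 1–3 rows (uniform), the first
  always nonsilent (so carrier status is guaranteed by construction),
  the rest silent with probability 0.25 — this exercises the
  indicator's idempotence and silent-blindness, not mutational realism.
- **Survival.** Event time ~ Exponential(0.02/month ×
  2.0^altered), censoring ~ Uniform(0, 120 months); "altered" means
  carrying every gene of at least one injected module.
- **Randomness.** One root seed spawns five named `SeedSequence`
  streams (clinical, carriers, modules, mutations, survival), so
  changing a knob of one table never perturbs the draws of another.

What the generator does **not** emulate: mutational signatures, tumour
mutation burden beyond the MSI-H flag, panel footprints, copy-number or
fusion events, co-mutation dependence beyond the injected modules, or
non-exponential hazards. Passing tests therefore demonstrate the
*statistical machinery* is correct and calibrated under these idealised
conditions, not that any particular real-cohort finding reproduces.

## Study sizes used in tests and the acceptance script

- Exact-test oracle sweep: all 46,376 tables with N ≤ 30, tolerance
  1e-12.
- Null calibration: 20 genes (frequencies geometric from 0.005 to
  0.15), 1000 samples per cohort, modules up to size 2, 200 replicates;
  the per-module rejection rate at P < 0.05 must not exceed the upper
  99% binomial bound around 0.05 (the exact test's discreteness makes
  it conservative, so observed ≪ nominal is expected and acceptable).
- Recovery/power: a single-gene module at frequency 0.05 injected at
  OR = 3, 2000 samples per cohort, 100 replicates; median estimated OR
  within [2.4, 3.6], Bonferroni detection ≥ 90%, gene-disjoint
  family-wise false positives in ≤ 5 runs. The injected module is a
  single gene because at 2×2000 a two-gene module at baseline 0.0025
  carries ~5 early-primary samples — no test has meaningful power
  there, and the property under test is estimator calibration, not
  small-count heroics.
- Survival: KM vs empirical survivor function exactly (no censoring);
  log-rank type-I error over 1000 equal-hazard replicates (100/arm)
  within the 99% binomial band; power ≥ 95% at hazard ratio 2.5 with
  200/arm over 200 replicates, 0.02/month baseline, 120-month uniform
  censoring (~20% censored in the control arm).

These sizes were chosen so each property is decided with comfortable
statistical margin while the whole suite stays interactive.

## Worked-example counts

The melanoma-scale worked example (14/1148 metastatic vs 0/669
early-primary carriers) is checked against the brute-force oracle, not
against any published P: the minimum-likelihood two-sided P for those
exact counts is 0.0033 (and q at a 161-test family ≈ 0.53). Published
figures for similar tables differ depending on the carrier count and
sidedness convention used; the package's contract is agreement with its
own exact enumeration oracle, which the acceptance script re-verifies
exhaustively.

## Known limitations

- Bonferroni is deliberately conservative; no FDR alternative is
  offered because the family sizes here are small.
- The odds-ratio estimator is the raw cross-product ratio; no
  confidence interval is reported (the exact P carries the inference).
- Carrier AND-semantics means large modules are sparse; module sizes
  beyond 3 are configurable but rarely informative at registry scale.
- The readers accept one mutation/clinical dialect at a time; multi-file
  merging is the caller's job.
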