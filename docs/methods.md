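# Methods

## Problem and scope

Seed amplification assays (SAA) for α-synuclein are read out as Thioflavin-T
(ThT) fluorescence kinetics and reported qualitatively per sample: positive,
negative, or inconclusive.  When several laboratories assay aliquots of the
same CSF under different protocols and decision rules, their calls disagree,
and the cost of that disagreement must be quantified.  The package models the
reference design — 20 DLB patients (10 amyloid-β-positive, 10 negative) and
10 controls, assayed blind by four laboratories (A–D) — and separates three
concerns: the kinetics of the signal (simulated), the decision rules that
turn kinetics into calls, and the evaluation statistics computed from calls.

## Kinetics model

Each well is either aggregating or not.  A non-aggregating well is flat at a
per-well baseline F₀ ~ N(f0_mean, f0_sd²).  An aggregating well follows a
logistic curve

    F(t) = F₀ + (Fmax − F₀) / (1 + exp(−rate · (t − t½)))

with additive N(0, noise_sd²) read noise, clipped at zero.  A logistic was
chosen over Gompertz or mechanistic nucleation–polymerisation models because
the downstream analysis uses only threshold crossing and maxima, and the
logistic midpoint has a closed form used as a test oracle (F(t½) =
(F₀+Fmax)/2).

Lag midpoints t½ are log-normal (lag times in amplification assays are
right-skewed).  Whether a well aggregates is Bernoulli:

* a patient well seeds with probability `p_detect` depending on the sample's
  amyloid status;
* any well (patient or control) can aggregate spontaneously with probability
  `p_spont`, with its midpoint delayed by `spont_tmid_shift` (spontaneous,
  unseeded nucleation is slower than seeded amplification).

A sample's seeding propensity — its amyloid-dependent `p_detect` and its
seeded log-midpoint — is drawn once per sample and shared across
laboratories (the laboratories assay aliquots of the same CSF); well-level
outcomes are independent draws per laboratory.  All randomness flows from a
single `numpy.random.Generator` in documented order (per-sample midpoints
first, then per-lab, per-sample, per-well: seeding draw, spontaneous draw,
midpoint if needed, baseline, noise).

### Defaults and rationale

| parameter | default | why |
|---|---|---|
| `duration_h`, `dt_h` | 100 h, 0.5 h | typical multi-day shaking-incubation assay; read interval unspecified in the reference protocols, declared not inferred |
| `f0_mean`, `f0_sd`, `fmax` | 100, 5, 5000 RFU | arbitrary RFU scale; plateau ~50× baseline so crossings are unambiguous |
| `rate` | 0.5 /h | full rise over ~1 day |
| `tmid_log_mean`, `tmid_log_sd` | log 68 h, 0.12 | typical threshold crossing at ~55–65 h, i.e. after the 48-h minimum valid time of the median-trace rule set, so early-aggregation flags are tail events (3 of 120 samples in the reference data) |
| `p_detect_abeta_neg`, `p_detect_abeta_pos` | 0.78, 0.65 | under the 2-of-3 rule these give sample-level sensitivity ≈ 0.88 / 0.70, matching the reported Aβ⁻ 87.5% vs Aβ⁺ 70% pattern |
| `p_spont` | 0.05 /well | occasional control positives and single-replicate inconclusives |
| `spont_tmid_shift` | +25 h | spontaneous events land near the end of the assay window, where a maximum-assay-time rule can clip them |

Laboratory protocol metadata (substrate concentration 0.07–0.3 mg/mL, CSF
volume 15/40 µL, 37/42 °C, pH 5.5–8, NaCl 0–500 mM, 3–4 replicates) are
carried as covariates only; no mechanistic protocol→kinetics model is
published, so by default protocols differ only in replicate count, with an
optional `detect_multiplier` hook for emulating protocol-driven sensitivity
differences.

### What the generator does not emulate

Plate-edge and drift artifacts, vendor-specific RFU scales, read-interval
differences between laboratories, and correlated (sample-level) spontaneous
aggregation.  The last matters: real control positives cluster within
samples (one control was 3/3 positive in one laboratory), whereas the
generator draws spontaneous events independently per well, so simulated
specificity under default parameters runs higher than the reference study's.
Passing end-to-end tests therefore demonstrate correctness of the decision
and evaluation machinery under the stated model, not real-world assay
performance.

## Decision rules (call engine)

* **Cutoff fluorescence**: mean of all readings in the first 10 h plus 30
  standard deviations, pooled per plate by default (the per-plate cutoff was
  decisive in the reference analysis; per-experiment pooling is a config
  option).  The SD is the sample (n−1) SD; the source rule says only "SD".
* **Replicate call**: crossed iff any reading ≥ cutoff, with the crossing
  time taken as the first grid time at or above the cutoff (no
  interpolation; the 0.5-h grid is dense enough).  Crossings after
  `max_assay_h` do not count; crossings before `min_valid_crossing_h` are
  flagged *early*.
* **Sample call**: count-based (Labs A–C style): ≥2 crossings → positive,
  exactly 1 → inconclusive, 0 → negative; median-trace (Lab D style): the
  pointwise median of the (odd number of) replicate traces is called like a
  replicate.  In either mode any early crossing overrides the category to
  inconclusive (48-h rule).  On strictly nondecreasing noise-free traces the
  median-trace rule is provably equivalent to ≥⌈n/2⌉ replicates crossing,
  which for n = 3 is the 2-of-3 rule (tested exhaustively).
* **Repeat pooling**: laboratories that repeat inconclusive samples pool
  replicate counts across the two runs and apply the ≥2 rule to the pooled
  counts.  A pooled count of exactly 1 resolves to *negative*, not
  inconclusive: the repeat exhausts the repeat policy, so a final call is
  always conclusive.  This reproduces every published pooled outcome
  (4/6 → positive, 2/6 → positive, 1/6 and 1/8 → negative).
* **Lab B's time cutoff** is published without a number; it is modelled as
  `max_assay_h = 90 h` in the packaged Lab B rule set (crossings in the last
  10 h of the 100-h window don't count).  The field is generic and
  configurable.

The packaged reference rule sets reproduce every published call for Labs A,
B and C from the replicate counts.  Lab D's published calls are *not* a pure
function of counts (two samples with 1/3 crossings received different
calls), consistent with a continuous median-fluorescence criterion applied
to raw traces that are not published; the package therefore treats the
published Lab D calls as authoritative in reproduce mode and exercises the
median-trace rule on synthetic data only.

## Evaluation statistics

**Tiers.** *Initial*: first-run calls, inconclusive samples excluded from
denominators.  *Actual*: first-run calls, inconclusives kept in denominators
as failures.  *Final*: calls after repeats (equal to actual for
laboratories that could not repeat).  The reference standard is the clinical
group (DLB = condition-positive).

**Metrics.** Sensitivity = patients called positive / patient denominator;
specificity = controls called negative / control denominator; accuracy =
(both numerators) / (both denominators); PPV = TP/(TP+FP) and NPV =
TN/(TN+FN) over conclusive calls (an inconclusive sample is neither a
positive nor a negative call, so it never enters PPV/NPV).  Metrics with a
zero denominator are reported as an explicit undefined marker (`None`), not
zero and not an exception, so degenerate designs (e.g. no controls) don't
crash summaries.

**Intervals.** 95% Wilson score intervals throughout, clipped to [0, 1].
Wilson was verified against 28 published (k, n, CI) triples at
integer-percent rounding: it reproduces 23 exactly; the remaining five
(8/10, 28/30, 30/30, 9/10, 6/7) appear to reflect boundary-adjusted hybrid
intervals from the original analysis software and are reproduced by no
single documented method — the plain Wilson score is used consistently.

**Rounding.** Half-up, integer percent for metrics and CI bounds; cross-lab
means average the rounded integer percentages and round half-up to one
decimal (this printed-integer convention is what makes the published
cross-lab means, e.g. 78.8 from {100, 85, 55, 75}, exact).

**Agreement.** Unweighted Cohen's κ per laboratory pair over the categories
positive/negative/inconclusive, with inconclusive as a first-class category
by default; `drop` (remove samples inconclusive in either laboratory) and
`negative` (recode) modes are provided because the published pairwise
summaries beyond κ(A,B) don't state their convention and are not
reproducible from the published table (they are excluded from regression
targets).  When chance agreement pₑ = 1 the statistic is undefined and a
flagged sentinel is reported (1 if observed agreement is also 1, else 0).
Interpretation uses Landis–Koch bands with closed upper ends: ≤0 poor…,
(0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80]
substantial, (0.80, 1] almost perfect.

## Numerical and design choices

* Blank clinical-feature cells in the cohort table are stored as `unknown`,
  never imputed; frequency denominators shrink accordingly.
* Published calls are validated against structural invariants at load time
  (group sizes, replicate-total ranges per laboratory, n_pos ≤ n_total,
  early flags only where the 48-h rule applies); violations are data, not
  exceptions, except for the packaged fixture, where any violation is an
  integrity error.
* Tabular interfaces are UTF-8 TSV/CSV with headers; rule sets are JSON.
* Test problem sizes: the binomial-oracle Monte-Carlo check uses ~10,000
  wells (3 standard errors); the effect-direction check uses 100 replicate
  single-laboratory studies with a one-sided sign test.

## Known limitations

* The simulator's well-level independence understates correlated
  false-positive structure seen in real plates (see above).
* Protocol covariates have no mechanistic effect on kinetics; inter-lab
  kinetic differences must be injected via per-lab parameters or the
  detection multiplier.
* No quantification of seeding activity (SD50, AUC, lag-time modelling):
  the assay outcome modelled here is deliberately qualitative.
* Published pairwise κ values other than κ(A,B), and the published average
  κ, are not recomputable from the published per-sample table under any
  inconclusive-handling mode; the package reports its own full pairwise
  matrix instead.
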