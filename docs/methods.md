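# Methods

## Response frameworks

All classification operates on lesion tables: per lesion, a volume (cm³),
body-weight SUVmean/SUVmax, an anatomical site class (`local`,
`pelvic_node`, `extrapelvic_node`, `bone`, `organ`), and — on follow-up
scans — a `match_id` naming the baseline lesion it corresponds to. Matching
is expert input, never computed: a follow-up lesion without a valid
`match_id` *is* a new lesion. Lesions present only at baseline (resolved
disease) contribute nothing to any progression clause.

**Liver normalisation.** SUV-based criteria divide each lesion SUV by the
mean SUV of a right-liver reference volume of the same scan (baseline
reference for baseline, follow-up for follow-up). The ratio makes SUV-based
calls invariant to any per-scan global SUV rescaling — the property that
motivates the normalisation, and the property the tests assert. No rescaling
back to a typical liver magnitude is applied: classification uses relative
change only, so the choice is inconsequential. Volume-based criteria never
see normalised values.

**PPP.** Progression iff ≥ 1 new lesion, or some matched lesion satisfies
`(followup − baseline)/baseline ≥ 0.30` in the variant's metric. The
threshold is inclusive (exactly +30 % progresses). When both clauses hold
the reported trigger is `new_lesion` (reporting only; the boolean is
unaffected).

**RECIP 1.0.** Decision order on whole-body tumour volume TV and
new-lesion count:

1. follow-up TV = 0 and no new lesions → **CR** (if baseline TV was also 0
   there is no natural category; reported **SD** with `degenerate=True`);
2. ≥ 1 new lesion and ΔTV ≥ +20 % → **PD**;
3. no new lesions and ΔTV < −30 % → **PR** (strict: exactly −30 % is SD,
   honouring the asymmetric ≥ / > conventions of the published definitions);
4. otherwise **SD**.

Zero-baseline patients (lesion-free at baseline, a real feature of early
biochemical recurrence) make ΔTV undefined; growth from nothing is treated
as an unbounded increase, so any new lesion puts them in PD. A lesion
shrinking to absence can never trigger progression.

These conventions imply a theorem the tests exercise: RECIP-PD requires a
new lesion, and a new lesion progresses every PPP variant, so RECIP-PD ⇒
PPP-PD for all three metrics.

**Nomograms.** `promise_nomogram` is a generic additive-points engine:
boolean features contribute fixed points, continuous features pass through
user-defined piecewise-linear knot tables (clamped outside the knot range),
and `total ≥ cutoff` means high risk. The published visual/quantitative
point tables live in their source appendices and are deliberately not
reproduced; the YAML files under `src/psmaresp/data/` are synthetic
placeholders (labelled as such) that only exercise the machinery. Nomograms
are applied to the follow-up scan and analysed for overall survival only.

## Endpoints

Overall survival is clocked from the follow-up scan. The PCWG3 PSA rule uses
the post-scan series only: the first value initialises the nadir; a
candidate progression at index *i* must exceed the nadir of all earlier
post-scan values by ≥ 25 % relative *and* ≥ 2 ng/mL absolute, and (by
default) be confirmed by a later value above the same bounds ≥ 3 weeks
after. All four constants are configurable because published
operationalisations differ on the confirmation requirement; disabling
confirmation can only move the event earlier. Death before confirmed
progression is an event with cause `death`. Fewer than three post-scan
measurements → ineligible, excluded from PSA-PFS rather than censored.
Durations are days / 30.44 months throughout.

## Survival statistics

Kaplan–Meier, log-rank, Cox and concordance computations are delegated to
lifelines; this layer fixes the conventions and the failure modes:

- Cox fits use Efron tie handling (month-scale data are tie-heavy), Wald
  95 % CIs and p-values, α = 0.05, and a tightened convergence precision
  (1e−9) so small-sample estimates agree with direct exact
  partial-likelihood maximisation to ~1e−4.
- Quasi-complete separation is detected up front (observed events confined
  to one covariate group) and, as a backstop, by a monotone-likelihood bound
  (|β̂| > 10). Either way the row is returned non-converged with
  diagnostics, no numeric HR — the behaviour clinical tables render as
  `NA`.
- Medians never reached by the curve are a distinguished `NR` value, never a
  number.
- Harrell's C counts a pair usable when the earlier time is an event, scores
  tied pairs 0.5, and reads higher score as higher risk.

Pairwise four-category log-rank tests are reported unadjusted (matching
standard practice for exploratory pairwise curves); a Holm-adjusted column
is emitted alongside, clearly an extension.

## Synthetic cohort

The generator emulates the structure of a ~154-patient biochemical
recurrence cohort, with each patient drawn from an independent substream of
one global seed (cohorts are prefix-stable in n):

- **Lesion counts**: zero-inflated negative binomial, shifted NB(r = 1.2,
  p = 0.4) + 1 with zero mass 21/92 among the profiles that permit an empty
  baseline, clipped at 34 — realised cohort-wide: median 2, ~13.6 %
  lesion-free, matching the published moments. Volumes and SUVs are
  log-normal (median 1.5 cm³ / SUV 6); liver references are normal around
  6.2.
- **Response profiles** resolver/responder/stable/grower with default
  weights 23 : 43 : 69 : 19 (the published CR/PR/SD/PD mixture). Change
  multipliers are drawn with a safety margin around the ±30 %/+20 %
  thresholds (e.g. stable volumes ∈ [0.85, 1.10]× per lesion, grower
  ∈ [1.35, 1.70]× plus ≥ 1 new lesion), so the intended class is unambiguous
  and the ledger is an exact oracle. A consequence: on synthetic data PPP
  and RECIP progression calls coincide (only growers progress, always via a
  new lesion), unlike real cohorts where lesion-level and whole-body
  criteria dissociate. Tests of framework *disagreement* therefore use
  hand-constructed patients, not the generator.
- **Scan interval**: normal(6.2, 1.1) clipped to [3.2, 8.8] months.
- **Survival**: exponential; the planted PD group has median OS 53.2 months
  and hazard ratio 4.62 over the rest; administrative censoring uniform on
  [55, 90] months.
- **PSA**: 10 monthly values from the follow-up scan, truncated at death.
  Planted progressors (default rate 64/98) decline to a nadir by month 2
  then regrow exponentially with an amplitude guaranteeing the +2 ng/mL and
  +25 % bounds plus a confirming value; non-progressors decline with 3 %
  noise at levels that cannot meet the absolute bound. Because nearly every
  simulated patient has ≥ 3 post-scan values, PSA-PFS eligibility is
  near-universal here, unlike real cohorts where missing lab data shrink the
  eligible subset.
- **Treatments**: ADT-only / radiotherapy-only / both / other at
  65 : 36 : 34 : 19.

`simulate_survival` is the bare parameter-recovery harness: two-group
exponential event times with a specified true hazard ratio, plus independent
exponential censoring whose rate is solved numerically so the expected
censored fraction matches the request.

What passing tests show, and don't: the generator validates classification
logic, endpoint derivation and estimator calibration under clean,
well-separated conditions. It does not model measurement noise near decision
thresholds, scanner harmonisation, informative censoring, correlated
lesion growth, or PSA assay variability — conclusions about real-data
robustness near the ±30 %/+20 % boundaries do not follow from these tests.

## Numerical and design choices

- Percent changes use the baseline as denominator; a zero baseline with
  positive follow-up is an explicit "undefined" handled by new-disease
  logic, never an infinity.
- Subgroup membership is exact-set equality by default (ADT-only means ADT
  and nothing else); superset semantics are a flag. Subgroups below 7
  patients are skipped with a log entry rather than fitted.
- The analysis pipeline is a pure function of (patients, config); reports
  carry a config hash for provenance.
- Problem sizes in the test suite (cohorts of 40–2000 for behaviour, 10 000
  for simulator calibration, n = 5000 × 20 seeds for hazard-ratio recovery)
  were chosen to keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

Single scan pair per patient (no multi-timepoint trajectories); univariate
Cox only (no adjustment, time-varying covariates or competing risks);
nomogram point tables must be supplied by the user; PCWG3 radiographic and
testosterone criteria out of scope; the simulator does not attempt the real
cohort's joint distribution beyond published moments.
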