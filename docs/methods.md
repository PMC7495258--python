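# Methods

## Scope and model

`pumplink` reconciles three event streams for continuous intravenous
infusions — medication orders with dated dose/rate changes, clinician
MAR entries, and pump-logged SPRs — and detects administration
discrepancies. The analysis is per (patient, medication): there is no
cross-medication inference, and one consistent dose unit is assumed per
medication (e.g. mcg/kg/min for vasopressors), so no unit-conversion
layer exists. Timestamps are timezone-naive at one-minute resolution;
the 30-minute and 24-hour rules are minute-granular.

### Validity screening

An SPR is usable for linkage only when its raw patient-ID string is in
the registry's active set *and* a drug-library medication name is
present (pumps programmed as generic "basic" infusions have none).
Invalid IDs are assigned to exactly one of nine failure modes through a
fixed specific-before-generic precedence chain:

empty → patient-name match → encounter-ID match → expired/merged-chart
ID → date-like with out-of-range year → contains letters → too few
digits → too many digits → one substituted digit from a valid ID →
random number.

The category set is mutually exclusive in reports but the patterns
overlap on raw strings; the chain is a declared convention that makes
classification deterministic. Two operational choices:

* **Date-of-birth detection** accepts exactly 8-digit strings parsing
  as YYYYMMDD or MMDDYYYY on the real calendar with a year outside
  1965–2014 (the plausible-DOB range for the studied population).
  Shorter digit strings are never treated as dates: 6–7-digit strings
  routinely parse as zero-stripped dates, which would swallow the
  length-deficit and typographical categories and break the guaranteed
  round-trip with the corruption generator.
* **Typographical error** means Levenshtein distance 1 by substitution
  only, keeping it disjoint from the length-based categories.

Invalid records are excluded from all downstream analysis, not rescued
by fuzzy matching; they are tallied in the validity quadrants.

### Alignment

Only `started`/`restarted` pump states enter the analysis — they mark
initiation of drug delivery, the moment an erroneous infusion could be
intercepted. Each such SPR links to the order minimizing the absolute
gap between the SPR timestamp and the order's nearest *activity* event
(placement, modification, audit, free-text communication, or MAR),
subject to a 24-hour window. The window is symmetric around the SPR by
default (`symmetric_window=False` gives look-back only; the choice is
exposed because either reading is defensible). Ties break by earlier
order initiation, then lexicographic order id, making linkage a total
deterministic order. Free-text communications count as activity but
carry no numeric dose. SPRs with no candidate stay unlinked and are
excluded from discrepancy denominators (reported separately in the
stage log). MARs are attributed to the most recently initiated order at
or before their timestamp.

### Discrepancy rule

Each MAR and each linked SPR is evaluated once (per-source counting: a
MAR and an SPR documenting the same physical administration yield one
evaluation each, matching how the per-source summary tables count).
For an administration of value *v* at time *t*:

1. if *v* matches the latest order value at or before *t* → clean;
2. else if *v* matches an order event in (*t*, *t* + 30 min] → clean
   (anticipated verbal order within the grace window);
3. else if *v* matches an order event later than *t* + 30 min →
   discrepancy with MoD = 0 %, `documentation_only=True`, reference =
   the late order's value;
4. else → discrepancy with MoD = (v − prescribed)/prescribed × 100
   against the prescription active at *t* (an administration preceding
   every order event is referenced to the first order value and flagged
   `pre_order`).

Dose equality uses relative tolerance 1e-6: values are machine-entered,
not measured; the tolerance is configurable for data with rounding
dialects. Enlarging the grace window can only move records from
branches 3–4 into branch 2, so the discrepancy count is monotonically
non-increasing in the grace parameter (property-tested).

MoD bins follow the report convention `<−50%`, `[−50%,−20%)`,
`[−20%,−10%)`, `[−10%,0%)`, `0%`, `(0%,10%]`, `(10%,20%]`, `(20%,50%]`,
`(50%,100%]`, `>100%` — a partition of the line; "substantial overdose"
is the `>100%` bin. Rates are rounded half-up to 1 decimal and
validity percentages to 2 decimals; ratios with zero denominators are
reported as undefined (`None`), never as 0.

### Concordance

Each timeline is segmented at boundary order events (initiations,
modifications, audits when present). An interval becomes an event block
only if it contains at least one administration: categories are defined
by member discrepancies, so an empty interval has nothing to
categorize. Administrations at exactly a boundary minute open the new
block, consistent with the rule that a simultaneous order event
legitimizes the administration (order event < MAR < SPR at equal
timestamps everywhere). The tail interval extends from the last event
onward; a leading interval collects any pre-order administrations.

Orders enter the concordance assessment only when they carry both MAR
and SPR members. Blocks are classified none / MAR-only / SPR-only /
both, and Cohen's kappa is computed from the 2×2 counts:
p_o = (both + none)/N, p_e from the marginal products,
κ = (p_o − p_e)/(1 − p_e); degenerate marginals (p_e = 1) yield an
explicit undefined result rather than a number. Kappa is kept at full
precision internally and rounded to 2 decimals for reporting. Both
block-level category counts and raw per-record discrepancy counts are
emitted, since summary tables can reasonably be built from either.

## Synthetic cohorts

The generator emulates the study conditions rather than clinical
physiology. Per patient it draws orders (Poisson, mean 3, min 1 per
patient), each with Poisson(1) dose modifications; multiplicative
titration steps (×1.15–1.6 up or ×0.6–0.85 down) guarantee consecutive
prescribed values differ. Event blocks last 6–10 h; MARs are documented
5 min after each order event and then every 240 min, pump
starts/restarts 2 min after each event and then every 120 min (so every
block carries both sources, matching the roughly 4.6 MARs and 10 SPRs
per order of the studied cohort); occasional paused/stopped/delayed and
completed pump events exercise the state filter. Orders for the same
patient-medication are separated by > 48 h, which makes the 24-hour
linkage window provably unambiguous — the suite verifies every SPR
links to its generating order.

Corruption channels, with defaults emulating the observed rates:

* invalid patient IDs on 22 % of SPRs, category drawn from weights
  shaped like the observed 2014 tally; corruptions are rejection-sampled
  until they classify back to their generating category, so the
  screen↔generator round-trip holds by construction;
* missing medication names on 10 % of SPRs (basic infusions),
  independent of ID corruption;
* dose misprogramming per event block — MAR-only (p = 0.017), SPR-only
  (p = 0.075), joint (p = 0.025, same wrong value in both sources) —
  chosen so the block-level MAR/SPR/both marginals match the published
  concordance table; each selected block has exactly one record of the
  source corrupted by a signed relative error drawn from a mixture over
  the report bins (0 % excluded; open bins bounded at −90 % and
  +300 %), rejection-sampled away from all order values of the group so
  detection can never be masked by coincidence;
* late orders (p = 0.005 per block): a modification is delayed to
  45–180 min after its first administration while administered values
  stay equal, producing pure 0 %-magnitude documentation discrepancies.
  Administrations within 30 min before the delayed order are *not*
  ledgered — they are legitimately grace-matched.

Records screened out by ID/name corruption are never dose-corrupted, so
every ledgered dose/late entry is detectable downstream and sensitivity
and precision have exact expected values of 1.0 under clean identifier
channels. Ledger magnitudes are recomputed from the stored floats, so
detected magnitudes match to machine precision.

Because the per-block probabilities govern blocks, detected rates are
compared to their binomial bands at block level (share of blocks with a
detected discrepancy of that source), not at record level, where the
rate is diluted by records-per-block.

What passing tests do **not** show about real data: the generator has
regular cadences and a single timezone, no concurrent duplicate orders,
no free-text dose changes, no unit heterogeneity, and titration
trajectories with no pharmacokinetic meaning. Real extracts exercise
messier timestamp ties, rounding dialects (tune `dose_rtol`), and
medication-name variants the drug library must normalize.

## Problem sizes and runtime

The suite runs cohorts of 10–330 patients (up to ~1,050 orders, ~24,000
pump records) and a ~10,000-block cohort for the kappa-independence
property; everything completes in well under a minute on one CPU. The
kappa implementation is verified against a label-expansion oracle
exhaustively for all 2×2 tables with N ≤ 36 and on a seeded sample of
tables up to N = 200, and against scikit-learn's
`cohen_kappa_score`.

## Known limitations

* Free-text communication orders count as linkage activity but their
  dose content is not parsed.
* Root causes (misprogramming vs misunderstanding) and non-dose error
  types (e.g. premature stops) are out of scope; only dose/rate
  mismatches at delivery starts are detected.
* The nine-category ID precedence is a convention; other orderings are
  defensible and would shuffle counts among overlapping categories.
* Published summary shares are reproduced to within half a printed
  unit; two printed values (58.2 % and 21.7 %) appear floor-rounded
  relative to their exact cell ratios (58.26 %, 21.75 %), and tests
  compare at ±0.06 percentage points accordingly.
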