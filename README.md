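# pumplink

Reconcile **smart infusion pump records (SPRs)** with **EHR medication
orders and administration records (MARs)** to detect medication
administration discrepancies for continuous intravenous infusions.

## The problem

Smart pumps log every programmed infusion — dose/rate, pump state, and a
hand-typed patient ID — but in most hospitals they are not integrated
with the EHR ("closed loop"), so there is no key joining a pump record
to the order it executed. Clinician-entered MARs, the EHR's own account
of administration, are prone to documentation slips. Linking the two
sources post hoc makes both ends of the medication-use process visible
and lets dosing errors be separated from documentation problems.

`pumplink` implements that reconciliation as a tested pipeline:

1. **Validity screening** — classify every SPR by whether its raw
   patient-ID string maps to the registry and whether a drug-library
   medication name is present (2×2 quadrants), and categorize each
   invalid ID into nine failure modes (date-of-birth entered, patient
   name entered, missing digits, random number, encounter ID, invalid
   letters, expired/merged-chart ID, extra digits, typographical error)
   via a deterministic precedence chain.
2. **Alignment** — keep only `started`/`restarted` pump events, group
   records by (patient, medication), and link each SPR to the *closest*
   order having any activity (placement, modification, or MAR) within
   24 h of the pump event.
3. **Discrepancy detection** — an administration is discrepant when its
   value disagrees with the active prescription and is not legitimized
   by an order arriving within a 30-minute grace window (verbal-order
   transcription). An order arriving *later* than 30 minutes still
   counts as a discrepancy, at 0 % magnitude (documentation-only). The
   **magnitude of discrepancy** is

   `MoD = (administered − prescribed) / prescribed × 100 %`

   (overdoses positive), summarized in ten bins from `<−50%` to `>100%`.
4. **Concordance** — each order's timeline is cut into **event blocks**
   at order initiations/modifications; blocks are categorized
   none / MAR-only / SPR-only / both, and **Cohen's κ** on the 2×2
   agreement table, `κ = (p_o − p_e)/(1 − p_e)`, quantifies how much
   the two sources agree on where problems occur.

Because institutional EHR/pump extracts cannot be shared, the package
ships a first-class **synthetic cohort generator** that emulates the
study conditions (titrated infusion orders, MAR/SPR cadences, the nine
ID-corruption modes, dose misprogramming, late orders) and records
every injected error in a ground-truth ledger, so detection
sensitivity, precision and magnitude recovery are scored exactly.

## Worked example

```python
from pumplink import (CohortConfig, ErrorMixture, generate_cohort,
                      run_streams, evaluate_against_ledger)

cohort = generate_cohort(CohortConfig(n_patients=60, seed=1))  # study-shaped errors
bundle = run_streams(cohort.orders, cohort.order_events, cohort.mars,
                     cohort.sprs, cohort.registry, cohort.drug_library)

q = bundle.quadrants
print(q.percentages())          # (71.24, 18.77, 7.43, 2.55)
overall = bundle.concordance[-1]
print(overall.n_blocks, dict(overall.counts), round(overall.kappa, 2))
# 355 {'none': 314, 'MAR_only': 4, 'SPR_only': 22, 'both': 15} 0.5
ev = evaluate_against_ledger(bundle, cohort.ledger)
print(ev.sensitivity, ev.precision, ev.max_mod_error)  # 1.0 1.0 0.0
```

Reading the output: 71.24 % of the generated pump records carry both a
valid patient ID and a medication name (the only records usable for
linkage); the cohort's 355 analysis blocks split into the four
concordance categories with κ = 0.50; and every injected error was
recovered with the exact injected magnitude (sensitivity and precision
1.0, zero magnitude-recovery error).

The per-medication discrepancy table is in `bundle.table3`
(`Overall` row for this run: MAR rate 2.3 %, SPR rate 3.4 %), the MoD
bin tallies in `bundle.table4`.

## Command line

```bash
pumplink simulate --config config.yaml --seed 7 --out data/
pumplink report --in data/ --out report/       # full chain, CSV tables
pumplink all --config config.yaml --seed 7 --out run/   # simulate+analyze+manifest
```

Stage-wise subcommands `screen`, `align`, `detect`, `concord` operate
on files for pipeline debugging; see `pumplink --help`.

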