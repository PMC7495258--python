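"""Discrepancy rules: grace window, late documentation, MoD arithmetic
and binning."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pumplink import (
    MOD_BIN_LABELS,
    bin_mod,
    detect_discrepancies,
    discrepancy_rate,
    magnitude_of_discrepancy,
    mod_bin_counts,
    overdose_summary,
    prescribed_value_at,
)

from helpers import make_timeline, ts


class TestMagnitude:
    @pytest.mark.parametrize(
        "administered,prescribed,expected",
        [(2.0, 1.0, 100.0), (0.5, 1.0, -50.0), (1.0, 1.0, 0.0), (1.1, 1.0, 10.0)],
    )
    def test_arithmetic(self, administered, prescribed, expected):
        assert magnitude_of_discrepancy(administered, prescribed) == pytest.approx(expected)

    def test_nonpositive_prescribed_rejected(self):
        with pytest.raises(ValueError):
            magnitude_of_discrepancy(1.0, 0.0)

    @given(
        p=st.floats(0.01, 100, allow_nan=False),
        d=st.floats(0, 50, allow_nan=False),
    )
    def test_sign_symmetry(self, p, d):
        """mod(p + d, p) = -mod(p - d, p): over- and under-doses of the
        same absolute size have opposite signed magnitudes."""
        assert magnitude_of_discrepancy(p + d, p) == pytest.approx(
            -magnitude_of_discrepancy(p - d, p), abs=1e-9
        )


class TestBinning:
    @pytest.mark.parametrize(
        "mod,label",
        [
            (-60, "<-50%"), (-50, "[-50%,-20%)"), (-20, "[-20%,-10%)"),
            (-10, "[-10%,0%)"), (0, "0%"), (0.5, "(0%,10%]"), (10, "(0%,10%]"),
            (10.1, "(10%,20%]"), (20, "(10%,20%]"), (50, "(20%,50%]"),
            (100, "(50%,100%]"), (100.1, ">100%"), (1000, ">100%"),
        ],
    )
    def test_bracket_conventions(self, mod, label):
        assert bin_mod(mod) == label

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_bins_partition_the_line(self, mod):
        assert bin_mod(mod) in MOD_BIN_LABELS

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bin_mod(math.inf)


class TestRatesAndOverdoses:
    @pytest.mark.parametrize(
        "num,den,expected", [(321, 10575, 3.0), (682, 23397, 2.9), (0, 100, 0.0),
                             (233, 1937, 12.0)]
    )
    def test_rate_rounding(self, num, den, expected):
        assert discrepancy_rate(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            discrepancy_rate(1, 0)

    @pytest.mark.parametrize(
        "counts,total,overdose,substantial",
        [
            # MAR and SPR MoD rows of the study's bin table
            ((19, 61, 38, 12, 4, 20, 36, 44, 46, 41), 321, 58.2, 21.9),
            ((43, 104, 66, 12, 1, 15, 88, 98, 129, 126), 682, 66.9, 27.6),
        ],
    )
    def test_overdose_shares(self, counts, total, overdose, substantial):
        binned = dict(zip(MOD_BIN_LABELS, counts))
        s = overdose_summary(binned)
        assert s.n_total == total
        # printed values are at 1-decimal precision
        assert s.overdose_pct == pytest.approx(overdose, abs=0.06)
        assert s.substantial_pct == pytest.approx(substantial, abs=0.06)

    def test_all_zero_bins_undefined(self):
        s = overdose_summary({b: 0 for b in MOD_BIN_LABELS})
        assert s.overdose_pct is None and s.substantial_pct is None


class TestPrescribedValueAt:
    def test_plain_lookup(self):
        tl = make_timeline([(0, 0.5)])
        assert prescribed_value_at(tl, ts(60)) == (0.5, False)

    def test_grace_match_within_30min(self):
        # order 0.5 at 09:00, modification to 1.0 at 10:10; an
        # administration of 1.0 at 10:00 anticipates it by 10 min
        tl = make_timeline([(0, 0.5), (70, 1.0)])
        assert prescribed_value_at(tl, ts(60), admin_value=1.0) == (1.0, True)

    def test_no_grace_match_beyond_30min(self):
        tl = make_timeline([(0, 0.5), (105, 1.0)])  # modification at +45 min
        assert prescribed_value_at(tl, ts(60), admin_value=1.0) == (0.5, False)

    def test_none_before_all_orders(self):
        tl = make_timeline([(100, 0.5)])
        assert prescribed_value_at(tl, ts(0)) is None


class TestDetect:
    def test_matching_values_are_clean(self):
        tl = make_timeline([(0, 0.5)], mars=[(30, 0.5)], sprs=[(40, 0.5)])
        assert detect_discrepancies(tl) == []

    def test_mismatch_yields_signed_mod(self):
        tl = make_timeline([(0, 0.1)], sprs=[(30, 0.2)])
        (d,) = detect_discrepancies(tl)
        assert d.source == "SPR"
        assert d.mod_percent == pytest.approx(100.0)
        assert d.mod_bin == "(50%,100%]"
        assert not d.documentation_only

    def test_late_order_is_documentation_discrepancy(self):
        # administration of 1.0 at +60; matching modification only at
        # +105 (45 min later); active order was 0.5
        tl = make_timeline([(0, 0.5), (105, 1.0)], sprs=[(60, 1.0)])
        (d,) = detect_discrepancies(tl)
        assert d.documentation_only
        assert d.mod_percent == 0.0
        assert d.mod_bin == "0%"
        assert d.reference == 1.0

    def test_grace_legitimizes_anticipated_dose(self):
        tl = make_timeline([(0, 0.5), (80, 1.0)], sprs=[(60, 1.0)])
        assert detect_discrepancies(tl) == []

    def test_record_before_all_orders_flagged(self):
        tl = make_timeline([(100, 0.5)], mars=[(0, 1.0)])
        (d,) = detect_discrepancies(tl)
        assert d.pre_order
        assert d.reference == 0.5

    def test_grace_monotonicity(self):
        """Enlarging the grace window never creates new discrepancies."""
        tl = make_timeline(
            [(0, 0.5), (100, 1.0), (400, 0.7)],
            mars=[(60, 1.0), (90, 1.0), (150, 1.0), (390, 0.7), (500, 0.9)],
            sprs=[(80, 1.0), (120, 0.5), (395, 0.7)],
        )
        counts = [len(detect_discrepancies(tl, grace_minutes=g)) for g in (0, 10, 30, 60, 240)]
        assert counts == sorted(counts, reverse=True)

    def test_per_source_counting(self):
        # a MAR and an SPR documenting the same wrong administration
        # are counted once per source
        tl = make_timeline([(0, 1.0)], mars=[(30, 2.0)], sprs=[(31, 2.0)])
        found = detect_discrepancies(tl)
        assert sorted(d.source for d in found) == ["MAR", "SPR"]

    def test_bin_totals_conserve_discrepancy_totals(self, default_bundle):
        for source in ("MAR", "SPR"):
            discs = [d for d in default_bundle.discrepancies if d.source == source]
            assert sum(mod_bin_counts(discs).values()) == len(discs)


class TestLedgerRecovery:
    def test_exact_recovery_with_clean_channels(self):
        from pumplink import (
            CohortConfig,
            ErrorMixture,
            evaluate_against_ledger,
            generate_cohort,
            run_streams,
        )

        mix = ErrorMixture(
            p_invalid_id=0, p_missing_med_name=0,
            p_mar_discrepancy=0.05, p_spr_discrepancy=0.08,
            p_joint_discrepancy=0.02, p_late_order=0,
        )
        c = generate_cohort(CohortConfig(n_patients=30, seed=17), mix)
        b = run_streams(c.orders, c.order_events, c.mars, c.sprs, c.registry,
                        c.drug_library)
        ev = evaluate_against_ledger(b, c.ledger)
        assert ev.sensitivity == 1.0
        assert ev.precision == 1.0
        assert ev.max_mod_error is not None and ev.max_mod_error < 1e-9

    def test_late_order_only_run_all_documentation_flagged(self):
        from pumplink import (
            CohortConfig,
            ErrorMixture,
            evaluate_against_ledger,
            generate_cohort,
            run_streams,
        )

        mix = ErrorMixture(
            p_invalid_id=0, p_missing_med_name=0, p_mar_discrepancy=0,
            p_spr_discrepancy=0, p_joint_discrepancy=0, p_late_order=0.5,
        )
        c = generate_cohort(CohortConfig(n_patients=20, seed=3), mix)
        b = run_streams(c.orders, c.order_events, c.mars, c.sprs, c.registry,
                        c.drug_library)
        ev = evaluate_against_ledger(b, c.ledger)
        assert ev.n_injected > 0
        assert ev.sensitivity == 1.0 and ev.precision == 1.0
        assert ev.all_late_documentation_only is True
        assert all(d.documentation_only for d in b.discrepancies)
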