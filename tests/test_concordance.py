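"""Event-block segmentation, block categories and Cohen's kappa."""

import numpy as np
import pytest

from pumplink import (
    CohortConfig,
    ErrorMixture,
    classify_block,
    cohen_kappa,
    concordance_summary,
    detect_discrepancies,
    generate_cohort,
    include_order,
    run_streams,
    segment_event_blocks,
)

from helpers import make_timeline


def kappa_bruteforce(both, mar_only, spr_only, none):
    """Independent oracle: expand the counts into per-block label pairs
    and compute agreement directly."""
    mar = [1] * both + [1] * mar_only + [0] * spr_only + [0] * none
    spr = [1] * both + [0] * mar_only + [1] * spr_only + [0] * none
    n = len(mar)
    po = sum(m == s for m, s in zip(mar, spr)) / n
    pm, ps = sum(mar) / n, sum(spr) / n
    pe = pm * ps + (1 - pm) * (1 - ps)
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


class TestSegmentation:
    def test_three_blocks_for_two_modifications(self):
        tl = make_timeline(
            [(0, 1.0), (300, 2.0), (600, 3.0)],
            mars=[(60, 1.0), (360, 2.0), (660, 3.0)],
            sprs=[(90, 1.0), (390, 2.0), (690, 3.0)],
        )
        blocks = segment_event_blocks(tl)
        assert len(blocks) == 3
        assert [b.index for b in blocks] == [0, 1, 2]
        assert all(b.n_members == 2 for b in blocks)

    def test_order_without_modifications_has_one_block(self):
        tl = make_timeline([(0, 1.0)], mars=[(60, 1.0)], sprs=[(90, 1.0)])
        assert len(segment_event_blocks(tl)) == 1

    def test_empty_interval_emits_no_block(self):
        # no administrations between the two modifications
        tl = make_timeline(
            [(0, 1.0), (300, 2.0), (600, 3.0)],
            mars=[(60, 1.0)],
            sprs=[(660, 3.0)],
        )
        blocks = segment_event_blocks(tl)
        assert len(blocks) == 2
        assert [(len(b.mars), len(b.sprs)) for b in blocks] == [(1, 0), (0, 1)]

    def test_blocks_cover_all_administrations(self, default_bundle):
        for tl in default_bundle.timelines:
            blocks = segment_event_blocks(tl)
            n = sum(b.n_members for b in blocks)
            assert n == len(tl.mars) + len(tl.sprs)


class TestClassification:
    def test_spr_only_block(self):
        tl = make_timeline([(0, 1.0)], sprs=[(30, 2.0), (60, 3.0)])
        discs = detect_discrepancies(tl)
        (block,) = segment_event_blocks(tl)
        assert classify_block(block, discs) == "SPR_only"
        assert block.n_spr_discrepant == 2 and block.n_mar_discrepant == 0

    def test_clean_block(self):
        tl = make_timeline([(0, 1.0)], mars=[(30, 1.0)], sprs=[(40, 1.0)])
        (block,) = segment_event_blocks(tl)
        assert classify_block(block, detect_discrepancies(tl)) == "none"

    def test_mixed_order_like_worked_example(self):
        """Order with three blocks: one SPR-only discrepancy, then two
        blocks where both sources disagree with the prescription."""
        tl = make_timeline(
            [(0, 10.0), (300, 12.0), (600, 8.0)],
            mars=[(60, 10.0), (360, 14.0), (660, 9.0)],
            sprs=[(90, 11.0), (390, 14.0), (690, 9.0)],
        )
        discs = detect_discrepancies(tl)
        blocks = segment_event_blocks(tl)
        cats = [classify_block(b, discs) for b in blocks]
        assert cats == ["SPR_only", "both", "both"]


class TestIncludeOrder:
    def test_mar_only_order_excluded(self):
        tl = make_timeline([(0, 1.0)], mars=[(30, 1.0)])
        assert include_order(segment_event_blocks(tl)) is False

    def test_order_with_both_included(self):
        tl = make_timeline([(0, 1.0)], mars=[(30, 1.0)], sprs=[(40, 1.0)])
        assert include_order(segment_event_blocks(tl)) is True


class TestCohenKappa:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((67, 44, 197, 2330), 0.32),  # the concordance table's totals
            ((5, 0, 0, 5), 1.00),
            ((25, 25, 25, 25), 0.00),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert round(cohen_kappa(counts), 2) == expected

    def test_degenerate_marginals_undefined(self):
        assert cohen_kappa((0, 0, 0, 10)) is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa((0, 0, 0, 0))

    def test_oracle_equivalence_exhaustive_small(self):
        """Implementation vs label-expansion oracle on every table with
        N <= 24."""
        for total in range(1, 25):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        ours = cohen_kappa((a, b, c, d))
                        ref = kappa_bruteforce(a, b, c, d)
                        if ref is None:
                            assert ours is None
                        else:
                            assert abs(ours - ref) < 1e-12

    def test_oracle_equivalence_sampled_to_200(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(1, 201))
            cut = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c, d = cut[0], cut[1] - cut[0], cut[2] - cut[1], n - cut[2]
            ours = cohen_kappa((int(a), int(b), int(c), int(d)))
            ref = kappa_bruteforce(int(a), int(b), int(c), int(d))
            if ref is None:
                assert ours is None
            else:
                assert abs(ours - ref) < 1e-12

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = tuple(int(x) for x in rng.integers(1, 50, size=4))
            a, b, c, d = counts
            mar = [1] * a + [1] * b + [0] * c + [0] * d
            spr = [1] * a + [0] * b + [1] * c + [0] * d
            assert cohen_kappa(counts) == pytest.approx(
                cohen_kappa_score(mar, spr), abs=1e-12
            )


class TestSummary:
    def test_block_shares_match_printed_table(self):
        from pumplink.concordance import ConcordanceResult

        row = ConcordanceResult(
            "Overall", 2306, 1397, 2638, 250, 665,
            {"none": 2330, "MAR_only": 44, "SPR_only": 197, "both": 67},
        )
        assert row.n_discrepancy_blocks == 308
        shares = row.discrepancy_block_shares()
        assert shares["SPR_only"] == 64.0
        assert shares["MAR_only"] == 14.3
        assert shares["both"] == 21.8  # 67/308 = 21.75 rounds half-up
        assert shares["spr_capture"] >= 85.0

    def test_counts_sum_to_blocks_everywhere(self, default_bundle):
        for row in default_bundle.concordance:
            assert sum(row.counts.values()) == row.n_blocks

    def test_no_discrepancy_shares_undefined(self):
        from pumplink.concordance import ConcordanceResult

        row = ConcordanceResult("x", 1, 1, 1, 0, 0,
                                {"none": 1, "MAR_only": 0, "SPR_only": 0, "both": 0})
        assert row.discrepancy_block_shares() is None


class TestKappaOnSyntheticCohorts:
    def test_independent_errors_give_near_zero_kappa(self):
        """MAR and SPR corruption injected independently: block labels
        are independent Bernoulli pairs, so kappa -> 0 for many blocks."""
        mix = ErrorMixture(
            p_invalid_id=0, p_missing_med_name=0,
            p_mar_discrepancy=0.2, p_spr_discrepancy=0.2,
            p_joint_discrepancy=0, p_late_order=0,
        )
        c = generate_cohort(CohortConfig(n_patients=1600, seed=101), mix)
        b = run_streams(c.orders, c.order_events, c.mars, c.sprs, c.registry,
                        c.drug_library)
        overall = b.concordance[-1]
        assert overall.n_blocks >= 9000
        assert abs(overall.kappa) < 0.05

    def test_joint_errors_give_kappa_one(self):
        mix = ErrorMixture(
            p_invalid_id=0, p_missing_med_name=0,
            p_mar_discrepancy=0, p_spr_discrepancy=0,
            p_joint_discrepancy=0.3, p_late_order=0,
        )
        c = generate_cohort(CohortConfig(n_patients=40, seed=23), mix)
        b = run_streams(c.orders, c.order_events, c.mars, c.sprs, c.registry,
                        c.drug_library)
        overall = b.concordance[-1]
        assert overall.counts["MAR_only"] == 0 and overall.counts["SPR_only"] == 0
        assert overall.counts["both"] > 0
        assert overall.kappa == 1.0
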