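"""CNA-region restriction, lead-SNP clumping, known-locus flagging and the
gain-vs-loss Fisher test (with an independent scipy oracle)."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from gsassoc.cna_gwas import (
    fisher_exact_two_sided, flag_known, gain_loss_test, lead_snps,
    restrict_to_regions, significant_variants,
)
from gsassoc.multiple_testing import significance_threshold


def _stats(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "p"])
    df["ref"], df["alt"], df["eaf"] = "A", "G", 0.3
    df["se"] = 0.05
    df["beta"] = 0.1
    return df


def _regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "direction"])


class TestRestrict:
    def test_boundary_positions_included(self):
        regions = _regions([("1", 100, 200, "R", "gain")])
        stats = _stats([("1", 99, "a", 0.5), ("1", 100, "b", 0.5),
                        ("1", 200, "c", 0.5), ("1", 201, "d", 0.5),
                        ("2", 150, "e", 0.5)])
        out = restrict_to_regions(stats, regions)
        assert list(out["id"]) == ["b", "c"]
        assert set(out["region_label"]) == {"R"}

    def test_engineered_in_region_count(self):
        regions = _regions([("1", 1000, 2000, "R", "loss")])
        inside = [("1", 1000 + i, f"in{i}", 0.5) for i in range(37)]
        outside = [("2", 1500, "out0", 0.5), ("1", 5000, "out1", 0.5)]
        out = restrict_to_regions(_stats(inside + outside), regions)
        assert len(out) == 37


class TestSignificant:
    def test_strict_inequality(self):
        thr = significance_threshold(0.05, 1, 19659)
        cut = thr.threshold
        stats = _stats([("1", 1, "below", cut * 0.99),
                        ("1", 2, "exact", cut),
                        ("1", 3, "above", cut * 1.01)])
        assert list(significant_variants(stats, thr)["id"]) == ["below"]

    def test_empty_result_is_valid(self):
        out = significant_variants(_stats([("1", 1, "a", 0.5)]), 1e-6)
        assert len(out) == 0


class TestLeadSnps:
    def test_hand_traced_greedy_example(self):
        stats = _stats([("1", 1_000_000, "a", 1e-9),
                        ("1", 1_400_000, "b", 1e-7),
                        ("1", 3_000_000, "c", 1e-8)])
        leads = lead_snps(stats)
        assert list(leads["id"]) == ["a", "c"]

    def test_single_variant_is_its_own_lead(self):
        leads = lead_snps(_stats([("5", 10, "solo", 1e-8)]))
        assert list(leads["id"]) == ["solo"]

    def test_input_order_invariance(self, rng):
        rows = [(str(c), int(p), f"v{c}_{p}", float(pv))
                for c in (1, 2)
                for p, pv in zip(rng.integers(1, 10_000_000, 30),
                                 rng.uniform(1e-12, 1e-6, 30))]
        a = lead_snps(_stats(rows))
        shuffled = list(rows)
        rng.shuffle(shuffled)
        b = lead_snps(_stats(shuffled))
        pd.testing.assert_frame_equal(a, b)

    def test_no_two_leads_within_half_window(self):
        rows = [("1", int(p), f"v{p}", 1e-8 * (1 + p % 7))
                for p in range(1_000_000, 3_000_000, 100_000)]
        leads = lead_snps(_stats(rows))
        pos = np.sort(leads["pos"].to_numpy())
        assert (np.diff(pos) > 500_000).all()

    def test_six_planted_loci_resolve_to_six_leads(self, small_cohort):
        in_region = restrict_to_regions(small_cohort.summary_stats,
                                        small_cohort.annotations.cna_regions)
        signif = significant_variants(in_region, 2.54e-6)
        leads = lead_snps(signif)
        assert len(leads) == 6
        flagged = flag_known(leads, small_cohort.truth.known_loci)
        assert int(flagged["known"].sum()) == 5
        assert int((~flagged["known"]).sum()) == 1


class TestFlagKnown:
    def test_nearby_locus_flags_known(self):
        leads = lead_snps(_stats([("1", 2_000_000, "a", 1e-9)]))
        known = pd.DataFrame({"chrom": ["1"], "pos": [1_500_000],
                              "id": ["k"]})
        assert flag_known(leads, known)["known"].iloc[0]

    def test_absent_chromosome_is_novel(self):
        leads = lead_snps(_stats([("9", 2_000_000, "a", 1e-9)]))
        known = pd.DataFrame({"chrom": ["1"], "pos": [2_000_000], "id": ["k"]})
        assert not flag_known(leads, known)["known"].iloc[0]


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_two_sided([[2, 8], [2, 8]]) == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # C(10,5) = 252 tables; the two extreme tables each carry 1/252
        assert fisher_exact_two_sided([[5, 0], [0, 5]]) == pytest.approx(
            2 / 252, rel=1e-9)

    def test_row_swap_symmetry(self):
        p1 = fisher_exact_two_sided([[7, 2], [3, 8]])
        p2 = fisher_exact_two_sided([[3, 8], [7, 2]])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_scipy_oracle_on_all_small_tables(self):
        for n in range(1, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                    continue
                table = [[a, b], [c, d]]
                ours = fisher_exact_two_sided(table)
                ref = fisher_exact(table, alternative="two-sided")[1]
                assert ours == pytest.approx(ref, abs=1e-10), table


class TestGainLoss:
    def test_counts_regions_with_any_lead(self):
        regions = _regions([("1", 0, 10, "g1", "gain"),
                            ("1", 20, 30, "g2", "gain"),
                            ("2", 0, 10, "l1", "loss"),
                            ("2", 20, 30, "l2", "loss")])
        leads = _stats([("1", 5, "a", 1e-9), ("1", 6, "b", 1e-8)])
        p, table = gain_loss_test(regions, leads)
        assert table.loc["gain", "hit"] == 1  # both leads in the same region
        assert table.loc["loss", "hit"] == 0
        assert 0 < p <= 1

    def test_degenerate_margins_rejected(self):
        regions = _regions([("1", 0, 10, "g1", "gain"),
                            ("1", 20, 30, "g2", "gain")])
        with pytest.raises(ValueError, match="degenerate"):
            gain_loss_test(regions, _stats([("1", 5, "a", 1e-9)]))
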