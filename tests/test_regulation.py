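"""Regulation classes, dynamics labels, rank-sum test and replicate correlation."""

import math

import numpy as np
import pytest
from scipy import stats

from silacsig.errors import ConfigurationError, InsufficientDataError, ValidationError
from silacsig.regulation import (
    RegulationThresholds,
    assign_dynamics_class,
    classify_regulation,
    classify_sites,
    ranksum_test,
    regulation_counts,
    replicate_correlation,
    residue_class_summary,
)
from conftest import make_protein, make_site


class TestClassification:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(2.0, "up"), (2.5, "up"), (0.5, "down"), (0.4, "down"),
         (1.0, "unchanged"), (1.99, "unchanged"), (0.51, "unchanged")],
    )
    def test_thresholds_with_inclusive_boundaries(self, ratio, expected):
        call = classify_regulation(make_site(ml={1: ratio}))
        assert call.class_5min == expected

    def test_median_over_replicates(self):
        # Replicates 1.0, 2.2, 3.0: median 2.2 -> up even though one rep is flat.
        call = classify_regulation(make_site(ml={1: 1.0, 2: 2.2, 3: 3.0}))
        assert call.ratio_5min == pytest.approx(2.2)
        assert call.class_5min == "up"

    def test_unquantified_channel_is_missing(self):
        call = classify_regulation(make_site(ml={1: 2.0}))
        assert call.class_15min == "missing"
        assert call.ratio_15min is None

    def test_rapid_transient_site_is_up_at_both_points(self):
        call = classify_regulation(make_site(ml={1: 19.5}, hl={1: 2.0}))
        assert (call.class_5min, call.class_15min) == ("up", "up")

    def test_inverting_ratios_swaps_up_and_down(self):
        rng = np.random.default_rng(3)
        sites = [
            make_site(f"P{i}", position=i + 1,
                      ml={1: float(2.0 ** rng.normal(0, 1.5))},
                      hl={1: float(2.0 ** rng.normal(0, 1.5))})
            for i in range(50)
        ]
        inverted = [
            make_site(s.protein_id, position=s.position,
                      ml={k: 1.0 / v for k, v in s.ratios_ml.items()},
                      hl={k: 1.0 / v for k, v in s.ratios_hl.items()})
            for s in sites
        ]
        fwd = regulation_counts(classify_sites(sites))
        rev = regulation_counts(classify_sites(inverted))
        for tp in ("5min", "15min"):
            assert fwd[tp]["n_up"] == rev[tp]["n_down"]
            assert fwd[tp]["n_down"] == rev[tp]["n_up"]

    def test_invalid_thresholds(self):
        with pytest.raises(ConfigurationError):
            RegulationThresholds(up_fold=0.9)


class TestDynamics:
    def test_transient_spike_is_early_transient(self):
        # 19.5-fold at 5 min collapsing to 2-fold at 15 min.
        call = classify_regulation(make_site(ml={1: 19.5}, hl={1: 2.0}))
        assert call.dynamics == "early-transient"

    def test_persistent_high_ratio_is_sustained(self):
        call = classify_regulation(make_site(ml={1: 20.5}, hl={1: 22.0}))
        assert call.dynamics == "sustained"

    def test_flat_site_is_unregulated(self):
        call = classify_regulation(make_site(ml={1: 1.0}, hl={1: 1.1}))
        assert call.dynamics == "unregulated"

    @pytest.mark.parametrize(
        "c5, c15, r5, r15, expected",
        [
            ("up", "unchanged", 4.0, 1.2, "early-transient"),
            ("up", "missing", 4.0, None, "early-transient"),
            ("up", "up", 4.0, 3.5, "sustained"),
            ("unchanged", "up", 1.2, 4.0, "late"),
            ("missing", "up", None, 4.0, "late"),
            ("down", "unchanged", 0.3, 1.0, "down-regulated"),
            ("unchanged", "down", 1.0, 0.3, "down-regulated"),
            ("down", "up", 0.3, 4.0, "mixed"),
            ("missing", "missing", None, None, "unregulated"),
        ],
    )
    def test_rule_table(self, c5, c15, r5, r15, expected):
        assert assign_dynamics_class(c5, c15, r5, r15) == expected


class TestResidueSummary:
    def test_toy_means_for_tyr_and_st(self):
        sites = [
            make_site("P1", residue="Y", position=1, ml={1: 4.0}),
            make_site("P2", residue="Y", position=2, ml={1: 5.0}),
            make_site("P3", residue="Y", position=3, ml={1: 3.0}),
            make_site("P4", residue="S", position=4, ml={1: 1.5}),
            make_site("P5", residue="T", position=5, ml={1: 1.7}),
        ]
        summary = residue_class_summary(classify_sites(sites), up_only=False)
        assert summary["Tyr"]["5min"]["mean_fold"] == pytest.approx(4.0)
        assert summary["Ser/Thr"]["5min"]["mean_fold"] == pytest.approx(1.6)
        assert summary["Tyr"]["5min"]["n_sites"] == 3

    def test_default_restricts_mean_to_upregulated_sites(self):
        sites = [
            make_site("P1", residue="Y", position=1, ml={1: 4.0}),
            make_site("P2", residue="Y", position=2, ml={1: 1.0}),
        ]
        summary = residue_class_summary(classify_sites(sites))
        assert summary["Tyr"]["5min"]["mean_fold"] == pytest.approx(4.0)
        assert summary["Tyr"]["5min"]["n_sites"] == 2
        assert summary["Tyr"]["5min"]["n_up"] == 1

    def test_empty_class_flagged_as_missing_mean(self):
        sites = [make_site("P1", residue="S", ml={1: 3.0})]
        summary = residue_class_summary(classify_sites(sites))
        assert summary["Tyr"]["5min"]["n_sites"] == 0
        assert summary["Tyr"]["5min"]["mean_fold"] is None

    def test_digly_calls_are_rejected(self):
        calls = classify_sites([make_site(residue="K", modification="diGly",
                                          ml={1: 3.0})])
        with pytest.raises(ValidationError):
            residue_class_summary(calls)


class TestRanksum:
    def test_separated_groups_exact_two_sided(self):
        _, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        _, p = ranksum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_one_sided_tails(self):
        _, p_less = ranksum_test([1, 2, 3], [4, 5, 6], alternative="less")
        _, p_greater = ranksum_test([1, 2, 3], [4, 5, 6], alternative="greater")
        assert p_less == pytest.approx(1 / 20)
        assert p_greater == pytest.approx(1.0)

    def test_exact_path_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n, m = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = list(pooled[:n]), list(pooled[n:])
            _, p = ranksum_test(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_for_small_groups(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n, m = rng.integers(3, 9, size=2)
            pooled = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = list(pooled[:n]), list(pooled[n:])
            _, p_exact = ranksum_test(a, b)
            _, p_approx = ranksum_test(a, b, exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.05

    def test_empty_group_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            ranksum_test([], [1.0])


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self):
        records = [make_protein(f"P{i}", ml={1: v, 2: v})
                   for i, v in enumerate([1.5, 2.0, 0.5, 3.0])]
        assert replicate_correlation(records, "ML", 1, 2) == pytest.approx(1.0)

    def test_reciprocal_replicates_anticorrelate(self):
        records = [make_protein(f"P{i}", ml={1: v, 2: 1.0 / v})
                   for i, v in enumerate([1.5, 2.0, 0.5, 3.0])]
        assert replicate_correlation(records, "ML", 1, 2) == pytest.approx(-1.0)

    def test_ten_fixed_pairs_match_textbook_formula(self):
        rng = np.random.default_rng(21)
        xs = rng.normal(0, 1, 10)
        ys = 0.6 * xs + rng.normal(0, 0.5, 10)
        records = [
            make_protein(f"P{i}", ml={1: float(2.0 ** x), 2: float(2.0 ** y)})
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        # Hand Pearson on the log2 values.
        mx, my = xs.mean(), ys.mean()
        expected = (((xs - mx) * (ys - my)).sum()
                    / math.sqrt(((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum()))
        assert replicate_correlation(records, "ML", 1, 2) == pytest.approx(expected)

    def test_incomplete_pairs_are_skipped_and_counted(self):
        records = [make_protein("P1", ml={1: 2.0}), make_protein("P2", ml={2: 2.0}),
                   make_protein("P3", ml={1: 1.0, 2: 1.0})]
        with pytest.raises(InsufficientDataError):
            replicate_correlation(records, "ML", 1, 2)
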