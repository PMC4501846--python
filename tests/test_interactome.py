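"""Background model, cutoffs and interactor calling against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silacsig.errors import ConfigurationError, InsufficientDataError
from silacsig.interactome import (
    BackgroundModel,
    CutoffSet,
    call_interactors,
    derive_cutoffs,
    fit_background_model,
    partition_venn,
    venn_counts,
)
from conftest import make_protein, random_protein_table
import oracles


def model(median, sd, channel="ML"):
    return BackgroundModel(channel=channel, median_log2=median, sd_log2=sd,
                           n_background=9, n_quantified=10)


class TestBackgroundModel:
    def test_all_unit_ratios_give_zero_median_and_sd(self):
        records = [make_protein(f"P{i}", ml={1: 1.0, 2: 1.0}) for i in range(10)]
        fitted = fit_background_model(records, "ML")
        assert fitted.median_log2 == 0.0
        assert fitted.sd_log2 == 0.0
        assert fitted.n_background == 9

    def test_ten_protein_table_matches_brute_force(self):
        rng = np.random.default_rng(42)
        records = [
            make_protein(f"P{i}", ml={r: float(2.0 ** rng.normal(0, 1))
                                      for r in (1, 2, 3)})
            for i in range(10)
        ]
        fitted = fit_background_model(records, "ML")
        med, sd, n_bg = oracles.background_fit(records, "ML")
        assert fitted.median_log2 == pytest.approx(med, abs=1e-12)
        assert fitted.sd_log2 == pytest.approx(sd, abs=1e-12)
        assert fitted.n_background == n_bg == 9

    def test_too_few_quantified_proteins(self):
        records = [make_protein("P1", ml={1: 2.0}), make_protein("P2", ml={1: 2.0}),
                   make_protein("P3", hl={1: 2.0})]
        with pytest.raises(InsufficientDataError):
            fit_background_model(records, "ML")

    def test_unquantified_proteins_are_excluded(self):
        records = [make_protein(f"P{i}", ml={1: 1.0}) for i in range(9)]
        records.append(make_protein("P9", hl={1: 8.0}))  # no M/L data
        fitted = fit_background_model(records, "ML")
        assert fitted.n_quantified == 9


class TestCutoffs:
    def test_zero_background_gives_zero_cutoff(self):
        cutoffs = derive_cutoffs(model(0.0, 0.0), model(0.0, 0.0, "HL"))
        assert cutoffs.cutoff_log2_ml == 0.0

    def test_published_style_arithmetic(self):
        # median 0.20 plus two SDs of 0.58 lands on a 1.36 log2 cutoff.
        cutoffs = derive_cutoffs(model(0.20, 0.58), model(0.20, 0.58, "HL"))
        assert cutoffs.cutoff_log2_ml == pytest.approx(1.36)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        median=st.floats(-2, 2, allow_nan=False),
        sd_lo=st.floats(0, 3, allow_nan=False),
        delta=st.floats(0.01, 2, allow_nan=False),
    )
    def test_cutoff_strictly_increasing_in_sd(self, median, sd_lo, delta):
        lo = derive_cutoffs(model(median, sd_lo), model(0, 0, "HL"))
        hi = derive_cutoffs(model(median, sd_lo + delta), model(0, 0, "HL"))
        assert hi.cutoff_log2_ml > lo.cutoff_log2_ml


class TestCallInteractors:
    def test_two_of_four_replicates_at_twofold_is_enriched(self):
        cutoffs = CutoffSet(cutoff_log2_ml=0.5, cutoff_log2_hl=0.5)
        protein = make_protein(
            "P1",
            ml={1: 2.0, 2: 2.0, 3: 1.6, 4: 1.7},  # support 2, median log2 ~0.9
            hl={1: 1.0, 2: 1.0},
        )
        (call,) = call_interactors([protein], cutoffs)
        assert call.enriched_5min and not call.enriched_15min
        assert call.replicate_support_5 == 2
        assert call.is_interactor

    def test_replicate_support_alone_is_not_enough(self):
        # Two replicates above 2-fold but the median stays below the cutoff.
        cutoffs = CutoffSet(cutoff_log2_ml=1.5, cutoff_log2_hl=1.5)
        protein = make_protein("P1", ml={1: 2.1, 2: 2.1, 3: 1.0, 4: 1.0})
        (call,) = call_interactors([protein], cutoffs)
        assert not call.enriched_5min

    def test_empty_record_list(self):
        assert call_interactors([], CutoffSet(0.0, 0.0)) == []

    def test_min_replicates_beyond_data_is_a_configuration_error(self):
        records = [make_protein("P1", ml={1: 2.0})]
        with pytest.raises(ConfigurationError):
            call_interactors(records, CutoffSet(0.0, 0.0), min_replicates=5)

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            records = random_protein_table(rng, max_proteins=40)
            model_ml = fit_background_model(records, "ML")
            model_hl = fit_background_model(records, "HL")
            cutoffs = derive_cutoffs(model_ml, model_hl)
            calls = call_interactors(records, cutoffs)
            for rec, call in zip(records, calls):
                expected = oracles.call_one_protein(
                    rec, cutoffs.cutoff_log2_ml, cutoffs.cutoff_log2_hl, 2, 2.0
                )
                assert (call.enriched_5min, call.enriched_15min) == expected

    def test_scale_equivariance_of_criterion_ii(self):
        rng = np.random.default_rng(11)
        records = random_protein_table(rng, max_proteins=60)
        scale = 3.7
        scaled = [
            make_protein(r.protein_id,
                         ml={k: v * scale for k, v in r.ratios_ml.items()},
                         hl=r.ratios_hl)
            for r in records
        ]
        m1 = fit_background_model(records, "ML")
        m2 = fit_background_model(scaled, "ML")
        assert m2.median_log2 == pytest.approx(m1.median_log2 + math.log2(scale))
        assert m2.sd_log2 == pytest.approx(m1.sd_log2, abs=1e-9)
        c1 = derive_cutoffs(m1, fit_background_model(records, "HL"))
        c2 = derive_cutoffs(m2, fit_background_model(scaled, "HL"))
        passes_1 = {
            r.protein_id for r in records
            if oracles.protein_summary(r, "ML") > c1.cutoff_log2_ml
        }
        passes_2 = {
            r.protein_id for r in scaled
            if oracles.protein_summary(r, "ML") > c2.cutoff_log2_ml
        }
        assert passes_1 == passes_2


class TestMedianCentering:
    def test_centered_channel_has_unit_median(self):
        from silacsig.interactome import median_center

        rng = np.random.default_rng(31)
        records = random_protein_table(rng, max_proteins=40)
        centered = median_center(records)
        pooled = [v for r in centered for v in r.ratios_ml.values()]
        assert float(np.median(pooled)) == pytest.approx(1.0)

    def test_centering_preserves_cutoff_rule_passes(self):
        from silacsig.interactome import median_center

        rng = np.random.default_rng(37)
        records = random_protein_table(rng, max_proteins=60)
        sets = []
        for recs in (records, median_center(records)):
            cutoff = derive_cutoffs(fit_background_model(recs, "ML"),
                                    fit_background_model(recs, "HL")).cutoff_log2_ml
            sets.append({
                r.protein_id for r in recs
                if oracles.protein_summary(r, "ML") > cutoff
            })
        assert sets[0] == sets[1]


class TestVenn:
    def test_published_partition_sums_to_total(self):
        partition = venn_counts(
            [(True, True)] * 73 + [(True, False)] * 31 + [(False, True)] * 50
        )
        assert partition.n_both == 73
        assert partition.n_total == 154

    def test_no_enriched_proteins(self):
        assert partition_venn([]).n_total == 0
        partition = venn_counts([(False, False)] * 5)
        assert partition.as_dict() == {
            "n_both": 0, "n_only_t1": 0, "n_only_t2": 0, "n_total": 0,
        }

    def test_random_flags_match_set_arithmetic(self):
        rng = np.random.default_rng(5)
        pairs = [(bool(rng.integers(2)), bool(rng.integers(2))) for _ in range(20)]
        partition = venn_counts(pairs)
        set5 = {i for i, (a, _) in enumerate(pairs) if a}
        set15 = {i for i, (_, b) in enumerate(pairs) if b}
        assert partition.n_both == len(set5 & set15)
        assert partition.n_only_t1 == len(set5 - set15)
        assert partition.n_only_t2 == len(set15 - set5)
        assert partition.n_total == len(set5 | set15)
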