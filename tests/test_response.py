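import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilcd.config import PipelineConfig
from soilcd.diffabund import DiffAbundResult
from soilcd.io import CountTable
from soilcd.response import (
    assign_cd_category,
    classify_activity_responders,
    classify_composition_responders,
    core_taxa,
    summarize_response,
    timepoint_enrichment,
)
from soilcd.simulate import CommunitySimParams, simulate_timepoint_counts


def _da(taxon, lfc=0.0, q=1.0, structural=False):
    return DiffAbundResult(
        taxon_id=taxon, lfc=lfc, se=0.1, w=lfc / 0.1, p=q, q=q,
        structural_zero=structural, structural_zero_group=None,
        direction=("positive" if lfc > 0 else "negative") if q <= 0.05 and not structural else "none",
    )


class TestCdCategory:
    @pytest.mark.parametrize(
        "cd,expected",
        [(0.0, "low"), (0.5, "low"), (1.0, "medium"), (1.9, "medium"),
         (2.0, "high"), (3.0, "high"), (4.3, "high"), (100.0, "high")],
    )
    def test_assignment(self, cd, expected):
        assert assign_cd_category(cd) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_cd_category(-0.1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(min_value=0, max_value=1000, allow_nan=False))
    def test_total_and_single_valued(self, cd):
        assert assign_cd_category(cd) in ("low", "medium", "high")


class TestActivitySetLogic:
    def test_set_difference(self):
        calls = classify_activity_responders({"A": 1, "B": 1}, {"B"})
        assert [c.taxon_id for c in calls] == ["A"]

    def test_empty_spiked_set(self):
        assert classify_activity_responders({}, {"A", "B"}) == []

    def test_truth_table_exhaustive(self):
        # responsive iff enriched in the spiked arm AND not in the control arm
        for in_spiked, in_control in itertools.product([False, True], repeat=2):
            spiked = {"X": 1} if in_spiked else {}
            control = {"X"} if in_control else set()
            calls = classify_activity_responders(spiked, control)
            expected_responsive = in_spiked and not in_control
            assert (len(calls) == 1) == expected_responsive

    def test_direction_carried_from_spiked_sign(self):
        calls = classify_activity_responders({"A": -1, "B": 1}, set())
        directions = {c.taxon_id: c.direction for c in calls}
        assert directions == {"A": "negative", "B": "positive"}


class TestCompositionClassification:
    def test_null_gives_zero_responsive(self):
        da = [_da(f"T{i}", lfc=0.1, q=0.9) for i in range(20)]
        calls, summary = classify_composition_responders(da)
        assert calls == []
        assert summary.fraction_responsive == 0.0
        assert summary.fraction_stable == 1.0

    def test_six_positive_seven_negative_phyla_give_thirteen(self):
        # the accounting the field survey reports at the phylum level
        da = (
            [_da(f"P{i}", lfc=1.0, q=0.01) for i in range(6)]
            + [_da(f"N{i}", lfc=-1.0, q=0.01) for i in range(7)]
            + [_da(f"S{i}", lfc=0.0, q=0.8) for i in range(33)]
        )
        calls, summary = classify_composition_responders(da)
        assert summary.n_responsive == 13
        assert summary.n_positive == 6
        assert summary.n_negative == 7
        assert summary.n_taxa_total == 46

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_composition_responders([])


class TestSummarize:
    def test_sixteen_up_eleven_down_of_hundred(self):
        calls = classify_activity_responders(
            {f"U{i}": 1 for i in range(16)} | {f"D{i}": -1 for i in range(11)}, set()
        )
        universe = [f"U{i}" for i in range(16)] + [f"D{i}" for i in range(11)] + [
            f"Z{i}" for i in range(73)
        ]
        s = summarize_response(calls, universe)
        assert s.fraction_responsive == pytest.approx(0.27)
        assert s.fraction_stable == pytest.approx(0.73)
        assert s.fraction_positive == pytest.approx(0.16)
        assert s.fraction_negative == pytest.approx(0.11)

    def test_zero_calls(self):
        s = summarize_response([], [f"T{i}" for i in range(100)])
        assert s.fraction_responsive == 0.0
        assert s.fraction_stable == 1.0

    def test_fractions_sum_to_one(self, rng):
        universe = [f"T{i}" for i in range(57)]
        picks = rng.choice(57, size=13, replace=False)
        calls = classify_activity_responders(
            {universe[i]: int(rng.choice([-1, 1])) for i in picks}, set()
        )
        s = summarize_response(calls, universe)
        assert s.fraction_positive + s.fraction_negative == pytest.approx(s.fraction_responsive, abs=1e-12)
        assert s.fraction_responsive + s.fraction_stable == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            summarize_response([], [])


class TestCoreTaxa:
    def _table(self):
        # 5 taxa x 4 samples, abundances set around the detection threshold
        counts = np.array(
            [
                [500, 500, 500, 500],   # everywhere
                [500, 500, 0, 0],       # group a only
                [0, 0, 500, 500],       # group b only
                [2, 2, 2, 2],           # everywhere but below 1% detection
                [500, 500, 500, 0],     # a, and half of b
            ]
        )
        return CountTable([f"T{i}" for i in range(5)], [""] * 5,
                          ["a1", "a2", "b1", "b2"], counts)

    def test_partition_matches_hand_enumeration(self):
        cfg = PipelineConfig(prevalence_threshold=0.6, detection_threshold=0.01)
        regions = core_taxa(self._table(), ["a", "a", "b", "b"], cfg)
        assert regions[frozenset({"a", "b"})] == 1   # T0
        assert regions[frozenset({"a"})] == 2        # T1, T4 (b prevalence 0.5 < 0.6)
        assert regions[frozenset({"b"})] == 1        # T2
        # T3 occurs nowhere at 1% detection
        assert sum(regions.values()) == 4

    def test_single_group_all_unique(self):
        regions = core_taxa(self._table(), ["a", "a", "a", "a"])
        assert set(regions) == {frozenset({"a"})}

    def test_regions_partition_occurring_taxa(self):
        t = self._table()
        regions = core_taxa(t, ["a", "a", "b", "b"])
        assert sum(regions.values()) <= t.n_taxa


class TestTimepointEnrichment:
    def test_planted_spiked_only_taxon_called(self):
        params = CommunitySimParams(n_taxa=100, seed=7, responder_lfc=np.log(4))
        table, meta, _ = simulate_timepoint_counts(
            params, enriched_taxa={"ASV0005": 1},
            non_response_taxa=["ASV0010"], n_replicates=8,
        )
        enriched = timepoint_enrichment(table, meta)
        assert "ASV0005" in enriched["spiked"]
        assert "ASV0010" in enriched["control"] and "ASV0010" in enriched["spiked"]
        calls = classify_activity_responders(enriched["spiked"], enriched["control"])
        assert [c.taxon_id for c in calls] == ["ASV0005"]

    def test_null_arms_empty_at_calibrated_rate(self):
        # identical S/P/E compositions: enrichment in either arm is a false
        # call. Four BH families at alpha=0.05 (positive side only) allow a
        # ~10% any-call rate; the observed count must sit inside the exact
        # binomial band for that rate.
        from scipy.stats import binom

        nonempty = 0
        n_reps = 40
        for seed in range(n_reps):
            params = CommunitySimParams(n_taxa=60, seed=100 + seed)
            table, meta, _ = simulate_timepoint_counts(params, n_replicates=10)
            enriched = timepoint_enrichment(table, meta)
            nonempty += bool(enriched["control"] or enriched["spiked"])
        assert nonempty <= binom.ppf(0.975, n_reps, 0.10)

    def test_intersection_subset_of_union(self):
        params = CommunitySimParams(n_taxa=80, seed=42, responder_lfc=np.log(3))
        table, meta, _ = simulate_timepoint_counts(
            params, enriched_taxa={"ASV0001": 1, "ASV0002": 1}, n_replicates=8
        )
        union = timepoint_enrichment(table, meta, rule="union")
        inter = timepoint_enrichment(table, meta, rule="intersection")
        for arm in ("control", "spiked"):
            assert set(inter[arm]) <= set(union[arm])

    def test_missing_timepoint_rejected(self):
        params = CommunitySimParams(n_taxa=50, seed=3)
        table, meta, _ = simulate_timepoint_counts(params, n_replicates=4)
        keep = [s for s in table.samples if not s.startswith("control_S")]
        sub = table.select_samples(keep)
        meta_sub = meta[meta["sample_id"].isin(keep)]
        with pytest.raises(ValueError, match="control"):
            timepoint_enrichment(sub, meta_sub)
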