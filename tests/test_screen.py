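"""Tests for percentile classification, Venn overlaps and region tests."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustscreen.core import RobustnessRecord
from robustscreen.screen import (
    VENN_CATEGORIES,
    AnnotationTable,
    ClassificationSets,
    attach_regions,
    classify_percentiles,
    region_deviation_test,
    top_regions,
    venn_overlaps,
)

from conftest import make_records


class TestClassifyPercentiles:
    def test_tail_sets_on_1_to_100(self):
        recs = make_records(list(range(1, 101)), [-0.001 * i for i in range(100)])
        cs = classify_percentiles(recs)
        assert cs.q_low_fitness == pytest.approx(10.9)
        assert cs.q_high_fitness == pytest.approx(90.1)
        assert cs.LF == frozenset(f"s{i:04d}" for i in range(10))      # values 1..10
        assert cs.HF == frozenset(f"s{i:04d}" for i in range(90, 100))  # values 91..100

    def test_equal_tail_sizes_when_n_divisible_by_10(self, rng):
        vals = rng.permutation(np.arange(1.0, 201.0))
        recs = make_records(vals, -vals / 100.0)
        cs = classify_percentiles(recs)
        assert len(cs.LF) == len(cs.HF) == 20
        assert len(cs.LR) == len(cs.HR) == 20

    def test_degenerate_distribution_flagged(self):
        recs = make_records([1.0] * 20, [-0.5] * 20)
        with pytest.warns(UserWarning, match="degenerate"):
            cs = classify_percentiles(recs)
        assert cs.degenerate_fitness and cs.degenerate_robustness
        assert cs.HF == cs.LF == frozenset(r.strain_id for r in recs)

    def test_tie_block_at_maximal_robustness_fully_included(self):
        # 67 strains at R = 0 and 33 below: the 90th-percentile threshold
        # falls on the tie block and every tied strain is kept
        robs = [0.0] * 67 + [-0.01 * (i + 1) for i in range(33)]
        recs = make_records([1.0 + 0.001 * i for i in range(100)], robs)
        cs = classify_percentiles(recs)
        assert cs.q_high_robustness == 0.0
        assert len(cs.HR) == 67

    def test_missing_metric_excluded(self):
        recs = make_records(
            list(range(1, 21)), [-0.01 * i for i in range(19)] + [math.nan],
            status=["ok"] * 19 + ["too_few_obs"],
        )
        cs = classify_percentiles(recs)
        assert recs[19].strain_id not in (cs.HR | cs.LR)

    def test_too_few_records_raises(self):
        recs = make_records([1, 2, 3], [-0.1, -0.2, -0.3])
        with pytest.raises(ValueError, match=">= 10"):
            classify_percentiles(recs)


def brute_force_venn(HF, LF, HR, LR):
    """Enumeration oracle: category per strain from its membership pattern."""
    counts = dict.fromkeys(VENN_CATEGORIES, 0)
    for s in HF | LF | HR | LR:
        pat = (s in HF, s in LF, s in HR, s in LR)
        key = {
            (True, False, False, False): "HF_only",
            (False, True, False, False): "LF_only",
            (False, False, True, False): "HR_only",
            (False, False, False, True): "LR_only",
            (True, False, True, False): "HF_HR",
            (True, False, False, True): "HF_LR",
            (False, True, True, False): "LF_HR",
            (False, True, False, True): "LF_LR",
        }[pat]
        counts[key] += 1
    return counts


def sets_from(HF, LF, HR, LR):
    return ClassificationSets(
        0.0, 0.0, 0.0, 0.0,
        frozenset(HF), frozenset(LF), frozenset(HR), frozenset(LR),
        10.0, 90.0,
    )


class TestVennOverlaps:
    def test_spec_example(self):
        vs = venn_overlaps(sets_from({"a", "b"}, {"c"}, {"b"}, {"c", "d"}))
        assert vs.universe_size == 4
        assert vs.counts["HF_only"] == 1 and vs.percentages["HF_only"] == 25.0
        assert vs.counts["HF_HR"] == 1
        assert vs.counts["LF_LR"] == 1
        assert vs.counts["LR_only"] == 1
        assert sum(vs.counts.values()) == 4

    def test_disjoint_singletons(self):
        vs = venn_overlaps(sets_from({"a"}, {"b"}, {"c"}, {"d"}))
        assert all(vs.percentages[f"{k}_only"] == 25.0 for k in ("HF", "LF", "HR", "LR"))

    def test_full_overlap(self):
        vs = venn_overlaps(sets_from({"a"}, set(), {"a"}, set()))
        assert vs.counts["HF_HR"] == 1 and vs.percentages["HF_HR"] == 100.0

    def test_empty_universe_flagged(self):
        vs = venn_overlaps(sets_from(set(), set(), set(), set()))
        assert vs.empty and vs.universe_size == 0
        assert all(v == 0 for v in vs.counts.values())

    def test_overlapping_hf_lf_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            venn_overlaps(sets_from({"a"}, {"a"}, set(), {"b"}))

    @given(data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_partition_matches_enumeration_oracle(self, data):
        universe = [f"s{i}" for i in range(30)]
        fit_label = data.draw(
            st.lists(st.sampled_from(["HF", "LF", "none"]), min_size=30, max_size=30)
        )
        rob_label = data.draw(
            st.lists(st.sampled_from(["HR", "LR", "none"]), min_size=30, max_size=30)
        )
        HF = {s for s, l in zip(universe, fit_label) if l == "HF"}
        LF = {s for s, l in zip(universe, fit_label) if l == "LF"}
        HR = {s for s, l in zip(universe, rob_label) if l == "HR"}
        LR = {s for s, l in zip(universe, rob_label) if l == "LR"}
        vs = venn_overlaps(sets_from(HF, LF, HR, LR))
        assert dict(vs.counts) == brute_force_venn(HF, LF, HR, LR)
        assert sum(vs.counts.values()) == vs.universe_size


class TestRegions:
    def annotated(self, fitness, robustness, regions):
        recs = make_records(fitness, robustness)
        table = AnnotationTable(
            {r.strain_id: reg for r, reg in zip(recs, regions)}
        )
        return attach_regions(recs, table)

    def test_attach_drops_unannotated(self):
        recs = make_records([1, 2, 3], [-0.1, -0.2, -0.3])
        table = AnnotationTable({recs[0].strain_id: "mitosis", recs[1].strain_id: "unknown"})
        ann = attach_regions(recs, table)
        assert len(ann) == 2
        assert {a.region for a in ann} == {"mitosis", "unknown"}

    def test_unknown_is_a_region_not_missing(self):
        ann = self.annotated([1, 2], [-0.1, -0.2], ["unknown", "unknown"])
        assert all(a.region == "unknown" for a in ann)

    def test_empty_annotation_warns(self):
        recs = make_records([1, 2], [-0.1, -0.2])
        with pytest.warns(UserWarning, match="empty annotation"):
            assert attach_regions(recs, AnnotationTable({})) == []

    def test_top_regions_ranking_and_ties(self):
        ann = self.annotated(
            [1] * 8, [-0.1] * 8,
            ["cellpolarity"] * 3 + ["mitosis"] + ["a"] * 2 + ["b"] * 2,
        )
        members = {a.strain_id for a in ann}
        assert top_regions(ann, members, k=1) == [("cellpolarity", 3)]
        assert top_regions(ann, members, k=3) == [("cellpolarity", 3), ("a", 2), ("b", 2)]
        assert len(top_regions(ann, members, k=99)) == 4
        assert top_regions(ann, set(), k=5) == []


class TestRegionDeviation:
    def test_region_equal_to_population_gives_p_one(self, rng):
        vals = rng.normal(1.0, 0.1, 40)
        # one region is the entire population bar two strains in a stub region
        regions = ["big"] * 38 + ["stub"] * 2
        recs = make_records(vals, -np.abs(rng.normal(0.1, 0.02, 40)))
        table = AnnotationTable({r.strain_id: g for r, g in zip(recs, regions)})
        ann = attach_regions(recs, table)
        res = {e.region: e for e in region_deviation_test(ann, "fitness", min_region_size=2)}
        # the big region nearly is the background: p must be ~1
        assert res["big"].p_value > 0.9

    def test_complete_separation_matches_exact_enumeration(self, rng):
        # 5 values strictly above the other 95, region vs complement:
        # two-sided exact Mann-Whitney p is 2 / C(100, 5)
        low = rng.uniform(0.0, 1.0, 95)
        high = rng.uniform(2.0, 3.0, 5)
        vals = np.concatenate([high, low])
        regions = ["top"] * 5 + ["rest"] * 95
        recs = make_records(vals, -np.linspace(0.01, 0.99, 100))
        table = AnnotationTable({r.strain_id: g for r, g in zip(recs, regions)})
        ann = attach_regions(recs, table)
        res = {
            e.region: e
            for e in region_deviation_test(
                ann, "fitness", include_region=False, method="exact"
            )
        }
        assert res["top"].p_value == pytest.approx(2 / comb(100, 5), rel=1e-9)

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        vals = rng.normal(1.0, 0.2, 200)
        vals[:20] += 0.5
        regions = [f"g{i % 10}" for i in range(200)]
        recs = make_records(vals, -np.abs(rng.normal(0.1, 0.02, 200)))
        table = AnnotationTable({r.strain_id: g for r, g in zip(recs, regions)})
        ann = attach_regions(recs, table)
        res = region_deviation_test(ann, "fitness")
        assert all(e.p_adjusted >= e.p_value for e in res)
        by_p = sorted(res, key=lambda e: e.p_value)
        adj = [e.p_adjusted for e in by_p]
        assert adj == sorted(adj)

    def test_small_regions_skipped(self, rng):
        vals = rng.normal(1.0, 0.1, 23)
        regions = ["a"] * 10 + ["b"] * 11 + ["tiny"] * 2
        recs = make_records(vals, -np.abs(rng.normal(0.1, 0.02, 23)))
        table = AnnotationTable({r.strain_id: g for r, g in zip(recs, regions)})
        ann = attach_regions(recs, table)
        res = region_deviation_test(ann, "fitness", min_region_size=3)
        assert {e.region for e in res} == {"a", "b"}

    def test_planted_shift_detected(self, rng):
        # one region shifted by 2 pooled sd must reach adjusted significance
        vals = rng.normal(1.0, 0.1, 300)
        vals[:30] += 0.2
        regions = ["shifted"] * 30 + [f"g{i % 9}" for i in range(270)]
        recs = make_records(vals, -np.abs(rng.normal(0.1, 0.02, 300)))
        table = AnnotationTable({r.strain_id: g for r, g in zip(recs, regions)})
        ann = attach_regions(recs, table)
        res = {e.region: e for e in region_deviation_test(ann, "fitness")}
        assert res["shifted"].p_adjusted < 0.05
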