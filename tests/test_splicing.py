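"""PSI arithmetic, the count filter, differential calling and set overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen import (
    JunctionCounts,
    compute_psi,
    differential_splicing,
    filter_events,
    psi_matrix,
    shared_event_overlap,
    tally_event_types,
)

from .oracles import fisher_one_sided_enrichment, fisher_two_sided


def make_counts(inc, skip, groups):
    samples = list(groups)
    index = pd.Index([f"e{i}" for i in range(len(inc))], name="event_id")
    return JunctionCounts(
        inclusion=pd.DataFrame(inc, index=index, columns=samples),
        skipping=pd.DataFrame(skip, index=index, columns=samples),
        groups=groups,
    )


class TestComputePsi:
    def test_length_normalized_worked_example(self):
        assert compute_psi(9, 1, 2, 1) == pytest.approx(4.5 / 5.5)

    def test_boundaries(self):
        assert compute_psi(0, 5) == 0.0
        assert compute_psi(5, 0) == 1.0

    def test_no_reads_is_missing(self):
        assert np.isnan(compute_psi(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 5)
        with pytest.raises(ValueError):
            compute_psi(1, 5, l_inc=0)

    @settings(deadline=None, max_examples=100)
    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(1, 10), st.integers(1, 10)
    )
    def test_bounds_and_swap_symmetry(self, ic, sc, li, ls):
        psi = compute_psi(ic, sc, li, ls)
        if ic + sc == 0:
            assert np.isnan(psi)
        else:
            assert 0.0 <= psi <= 1.0
            assert compute_psi(sc, ic, ls, li) == pytest.approx(1.0 - psi)

    def test_matrix_missing_where_no_coverage(self):
        counts = make_counts([[0, 10]], [[0, 10]], {"a": "group1", "b": "group2"})
        psi = psi_matrix(counts)
        assert np.isnan(psi.iloc[0, 0]) and psi.iloc[0, 1] == pytest.approx(10 / 2 / (5 + 10))


class TestFilterEvents:
    groups = {"a1": "group1", "a2": "group1", "b1": "group2"}

    def test_group_sum_boundary_inclusive(self):
        counts = make_counts([[4, 5, 50], [5, 5, 50]], [[0, 0, 0], [0, 0, 0]], self.groups)
        kept = filter_events(counts, "group1", "group2", min_total=10)
        assert list(kept) == ["e1"]  # group1 sums: 9 excluded, 10 kept

    def test_replicate_sums_pool_within_group(self):
        groups = {"a1": "group1", "a2": "group1", "a3": "group1",
                  "b1": "group2", "b2": "group2", "b3": "group2"}
        counts = make_counts([[4, 3, 3, 4, 3, 3]], [[0, 0, 0, 0, 0, 0]], groups)
        assert list(filter_events(counts, "group1", "group2")) == ["e0"]

    def test_sample_scope_stricter(self):
        counts = make_counts([[4, 20, 50]], [[0, 0, 0]], self.groups)
        assert len(filter_events(counts, "group1", "group2", scope="group")) == 1
        assert len(filter_events(counts, "group1", "group2", scope="sample")) == 0

    def test_raising_min_total_never_adds_events(self, small_junctions):
        _, counts, _ = small_junctions
        previous = None
        for min_total in (5, 10, 50, 200):
            kept = set(filter_events(counts, "group1", "group2", min_total))
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_unknown_group_rejected(self, small_junctions):
        _, counts, _ = small_junctions
        with pytest.raises(ValueError, match="no samples"):
            filter_events(counts, "group1", "groupX")


class TestDifferentialSplicing:
    def test_identical_groups_null(self, se_event):
        events = [se_event]
        counts = make_counts([[30, 30]], [[10, 10]], {"a": "group1", "b": "group2"})
        counts.inclusion.index = pd.Index(["ev1"], name="event_id")
        counts.skipping.index = pd.Index(["ev1"], name="event_id")
        result = differential_splicing(events, counts, "group1", "group2")
        assert result.loc["ev1", "delta_psi"] == 0.0
        assert result.loc["ev1", "p"] == pytest.approx(1.0)

    def test_fisher_p_matches_enumeration_oracle(self, small_junctions):
        events, counts, _ = small_junctions
        result = differential_splicing(events, counts, "group1", "group2")
        g1 = counts.samples_in_group("group1")
        g2 = counts.samples_in_group("group2")
        for eid in result.index[:40]:
            table = [
                [int(counts.inclusion.loc[eid, g1].sum()), int(counts.skipping.loc[eid, g1].sum())],
                [int(counts.inclusion.loc[eid, g2].sum()), int(counts.skipping.loc[eid, g2].sum())],
            ]
            assert result.loc[eid, "p"] == pytest.approx(fisher_two_sided(table), rel=1e-6)

    def test_direction_follows_delta_sign(self, small_junctions):
        events, counts, _ = small_junctions
        result = differential_splicing(events, counts, "group1", "group2")
        neg = result["delta_psi"] < 0
        assert (result.loc[neg, "direction"] == "exclusion").all()
        assert (result.loc[~neg, "direction"] == "inclusion").all()

    def test_bh_rejections_nested_in_alpha(self, small_junctions):
        events, counts, _ = small_junctions
        strict = differential_splicing(events, counts, "group1", "group2", alpha=0.01)
        loose = differential_splicing(events, counts, "group1", "group2", alpha=0.05)
        assert set(strict.index[strict["significant"]]) <= set(loose.index[loose["significant"]])

    def test_recovers_planted_events(self, small_junctions):
        events, counts, truth = small_junctions
        result = differential_splicing(events, counts, "group1", "group2")
        called = set(result.index[result["significant"]])
        tp = len(called & truth.true_delta_events)
        assert tp / len(truth.true_delta_events) >= 0.8
        assert (1 - tp / len(called)) <= 0.15 if called else True


class TestTally:
    def test_empty_input_all_zero(self):
        table = tally_event_types(pd.DataFrame(columns=["etype", "direction", "significant"]))
        assert table.to_numpy().sum() == 0
        assert table.shape == (5, 2)

    def test_counts_by_type_and_direction(self):
        results = pd.DataFrame(
            {
                "etype": ["SE", "SE", "SE", "RI"],
                "direction": ["exclusion"] * 3 + ["inclusion"],
                "significant": [True] * 4,
            }
        )
        table = tally_event_types(results)
        assert table.loc["SE", "exclusion"] == 3
        assert table.loc["RI", "inclusion"] == 1
        assert table.to_numpy().sum() == 4

    def test_total_equals_significant_count(self, small_junctions):
        events, counts, _ = small_junctions
        result = differential_splicing(events, counts, "group1", "group2")
        table = tally_event_types(result)
        assert table.to_numpy().sum() == int(result["significant"].sum())


class TestSharedEventOverlap:
    def test_disjoint_sets_p_one(self):
        k, p = shared_event_overlap({"a", "b"}, {"c", "d"}, 100)
        assert k == 0 and p == pytest.approx(1.0)

    def test_identical_sets_match_enumeration(self):
        ids = {f"e{i}" for i in range(10)}
        k, p = shared_event_overlap(ids, ids, 100)
        assert k == 10
        assert p == pytest.approx(fisher_one_sided_enrichment(10, 100, 10, 10), rel=1e-9)

    def test_partial_overlap_matches_enumeration(self):
        set_a = {f"e{i}" for i in range(10)}
        set_b = {f"e{i}" for i in range(5, 15)}
        k, p = shared_event_overlap(set_a, set_b, 100)
        assert k == 5
        assert p == pytest.approx(fisher_one_sided_enrichment(5, 100, 10, 10), rel=1e-9)

    def test_small_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            shared_event_overlap({"a", "b"}, {"c"}, 2)
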