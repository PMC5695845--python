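import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapart.commonness import (
    SpeciesRanking,
    detect_inflection,
    equalize_information,
    information_content,
    rank_species,
    split_common_rare,
    subset_matrix,
)


def ranking(totals, ids=None):
    ids = ids or [f"s{i}" for i in range(len(totals))]
    return SpeciesRanking(ids, np.asarray(totals, dtype=float), "abundance")


class TestRankSpecies:
    def test_descending_totals(self, matrix_factory):
        m = matrix_factory([[5, 9, 1]], species_ids=["A", "B", "C"])
        r = rank_species(m)
        assert r.species_ids == ["B", "A", "C"]
        assert r.totals.tolist() == [9, 5, 1]

    def test_ties_break_by_id_ascending(self, matrix_factory):
        m = matrix_factory([[3, 3]], species_ids=["B", "A"])
        assert rank_species(m).species_ids == ["A", "B"]

    def test_invariant_to_plot_permutation(self, matrix_factory):
        rows = [[1, 0, 4], [2, 5, 0], [0, 1, 1]]
        r1 = rank_species(matrix_factory(rows))
        r2 = rank_species(matrix_factory(rows[::-1], plot_ids=["P3", "P2", "P1"]))
        assert r1.species_ids == r2.species_ids

    def test_all_zero_matrix_rejected(self, matrix_factory):
        with pytest.raises(ValueError, match="rankable"):
            rank_species(matrix_factory([[0, 0]]))


def brute_force_knee(totals):
    """Independent distance-to-chord search over all positive ranks."""
    pos = [(k + 1, np.log10(t)) for k, t in enumerate(totals) if t > 0]
    (x0, y0), (x1, y1) = pos[0], pos[-1]
    best_k, best_d = None, -1.0
    for x, y in pos:
        d = abs((x - x0) * (y1 - y0) - (y - y0) * (x1 - x0)) / np.hypot(x1 - x0, y1 - y0)
        if d > best_d + 1e-15:
            best_k, best_d = x, d
    return best_k


class TestDetectInflection:
    def test_steep_then_flat_curve(self):
        totals = [1000, 10, 9, 8, 7, 6]
        res = detect_inflection(ranking(totals))
        assert res.cutoff_rank == 2 == brute_force_knee(totals)
        assert res.pronounced

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 10_000), min_size=3, max_size=40).map(
            lambda xs: sorted(xs, reverse=True)
        )
    )
    def test_matches_brute_force_oracle(self, totals):
        res = detect_inflection(ranking(totals))
        assert res.cutoff_rank == brute_force_knee(totals)

    def test_geometric_series_flags_no_knee(self):
        totals = [1000.0 * 0.5**k for k in range(10)]
        res = detect_inflection(ranking(totals))
        assert not res.pronounced

    def test_needs_three_positive_species(self):
        with pytest.raises(ValueError):
            detect_inflection(ranking([5, 3, 0, 0]))


class TestInformationContent:
    def test_ubiquitous_species_contributes_zero(self, matrix_factory):
        m = matrix_factory([[1], [2], [3], [1]], species_ids=["A"])
        assert information_content(m, ["A"]) == 0.0

    def test_half_occupancy(self, matrix_factory):
        m = matrix_factory([[1], [4], [0], [0]], species_ids=["A"])
        assert information_content(m, ["A"]) == pytest.approx(0.25)

    def test_hand_summed_pair(self, matrix_factory):
        # p = 0.25 and 0.5 -> 0.1875 + 0.25
        m = matrix_factory([[1, 1], [0, 2], [0, 0], [0, 0]], species_ids=["A", "B"])
        assert information_content(m, ["A", "B"]) == pytest.approx(0.4375)

    def test_additive_over_disjoint_subsets(self, matrix_factory):
        rng = np.random.default_rng(5)
        m = matrix_factory(rng.integers(0, 3, size=(6, 8)))
        ids = m.species_ids
        whole = information_content(m, ids)
        parts = information_content(m, ids[:3]) + information_content(m, ids[3:])
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_single_species_bounded_by_quarter(self, matrix_factory):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = matrix_factory(rng.integers(0, 2, size=(7, 1)), species_ids=["A"])
            if m.values.sum() == 0:
                continue
            assert 0.0 <= information_content(m, ["A"]) <= 0.25

    def test_unknown_species_rejected(self, matrix_factory):
        with pytest.raises(ValueError):
            information_content(matrix_factory([[1]]), ["nope"])


def occupancy_matrix(factory, occupied_counts, n_plots=4):
    """One column per species, occupying the requested number of plots."""
    cols = np.zeros((n_plots, len(occupied_counts)))
    for j, k in enumerate(occupied_counts):
        cols[:k, j] = 1
    return factory(cols)


class TestEqualizeInformation:
    def test_target_equal_to_current_means_no_removal(self, matrix_factory):
        m = occupancy_matrix(matrix_factory, [2, 2, 1])
        ids = m.species_ids
        r = ranking([10, 5, 1], ids)
        target = information_content(m, ids)
        trimmed, warned = equalize_information(r, ids, target, m)
        assert trimmed == ids and not warned

    def test_hand_worked_single_removal(self, matrix_factory):
        # contributions 0.25, 0.25, 0.1875 in rank order; target 0.4
        m = occupancy_matrix(matrix_factory, [2, 2, 1])
        ids = m.species_ids
        trimmed, warned = equalize_information(ranking([10, 5, 1], ids), ids, 0.4, m)
        assert trimmed == ids[1:] and not warned
        assert information_content(m, trimmed) == pytest.approx(0.4375)

    def test_low_information_rare_set_returned_unchanged_with_warning(
        self, matrix_factory
    ):
        m = occupancy_matrix(matrix_factory, [1, 1])
        ids = m.species_ids
        trimmed, warned = equalize_information(ranking([9, 1], ids), ids, 0.9, m)
        assert trimmed == ids and warned

    @settings(deadline=None, derandomize=True)
    @given(
        occ=st.lists(st.integers(1, 5), min_size=1, max_size=12),
        target=st.floats(0.0, 2.0),
    )
    def test_global_minimizer_against_exhaustive_oracle(self, occ, target):
        """The returned suffix beats every other removal count k."""
        m = occupancy_matrix(matrix_factory_local, occ, n_plots=6)
        ids = m.species_ids
        r = ranking(sorted(range(len(ids), 0, -1), reverse=True), ids)
        full_ic = information_content(m, ids)
        trimmed, warned = equalize_information(r, ids, target, m)
        if full_ic < target:
            assert warned and trimmed == ids
            return
        got = abs(information_content(m, trimmed) - target) if trimmed else abs(target)
        best = min(
            abs(sum_suffix(m, ids, k) - target) for k in range(len(ids) + 1)
        )
        assert got == pytest.approx(best, abs=1e-12)
        assert ids[len(ids) - len(trimmed):] == trimmed  # retained set is a suffix


def matrix_factory_local(rows, **kw):
    import pandas as pd

    from metapart.census import CommunityMatrix

    arr = np.asarray(rows, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"P{i + 1}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )
    return CommunityMatrix(df, basis="abundance")


def sum_suffix(m, ids, k):
    rest = ids[k:]
    return information_content(m, rest) if rest else 0.0


class TestSubsetMatrix:
    def test_identity_subset(self, matrix_factory):
        m = matrix_factory([[1, 2], [3, 0]])
        s = subset_matrix(m, m.species_ids)
        assert s.data.equals(m.data)

    def test_single_column_totals_match(self, matrix_factory):
        m = matrix_factory([[1, 2], [3, 0]])
        s = subset_matrix(m, ["A"])
        assert s.values.sum() == m.data["A"].sum()

    def test_consistent_with_information_content_subsetting(self, matrix_factory):
        m = matrix_factory([[1, 0, 2], [0, 1, 1], [1, 1, 0]])
        sub = subset_matrix(m, ["A", "C"])
        assert information_content(sub, ["A", "C"]) == pytest.approx(
            information_content(m, ["A", "C"])
        )

    def test_missing_id_rejected(self, matrix_factory):
        with pytest.raises(ValueError):
            subset_matrix(matrix_factory([[1]]), ["missing"])


class TestSplitCommonRare:
    def test_manual_cutoff_defines_common_ranks(self, sorting_scenario):
        m = sorting_scenario["community"]
        split = split_common_rare(m, cutoff_rank=22)
        assert split.cutoff_rank == 22
        assert len(split.common_ids) == 22
        ranks = rank_species(m).species_ids
        assert split.common_ids == ranks[:22]

    def test_trimmed_rare_is_a_ranking_suffix(self, sorting_scenario):
        m = sorting_scenario["community"]
        split = split_common_rare(m, cutoff_rank=22)
        ranks = rank_species(m).species_ids
        assert split.trimmed_rare_ids == ranks[len(ranks) - len(split.trimmed_rare_ids):]
        assert split.ic_rare_trimmed <= split.ic_rare_full

    def test_equalization_brings_ic_close_to_common(self, sorting_scenario):
        m = sorting_scenario["community"]
        split = split_common_rare(m, cutoff_rank=22)
        # no other removal count does better (contribution of the pivot species bounds the gap)
        gap = abs(split.ic_rare_trimmed - split.ic_common)
        assert gap <= 0.25  # one species contributes at most 1/4
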