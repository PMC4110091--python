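"""Clonality, rare-early, spatial and twin statistics."""

import itertools

import numpy as np
import pytest

import linrob as lr
from linrob import randomize as rz
from linrob.errors import DegenerateInputError
from linrob.features import rare_early_from_sizes
from .conftest import random_lineage


def oracle_pair_distances(lineage):
    """All-pairs lineal distances by direct path counting."""
    cells = lineage.leaves
    out = {}
    for a, b in itertools.combinations(cells, 2):
        out[(a, b)] = lr.lineal_distance(lineage, a, b)
    return out


class TestClonality:
    def test_clonal_fixture(self, tl1):
        res = lr.clonality(tl1)
        assert res.C == pytest.approx(5 / 3)
        assert res.T == 2

    def test_interleaved_fixture(self, tl2):
        assert lr.clonality(tl2).C == pytest.approx(5 / 6)

    def test_single_type_gives_one(self):
        lin = lr.parse_lineage("((a,b),(c,d));", {c: "A" for c in "abcd"})
        assert lr.clonality(lin).C == pytest.approx(1.0)

    def test_no_multi_member_type_rejected(self):
        lin = lr.parse_lineage("(a,b);", {"a": "A", "b": "B"})
        with pytest.raises(DegenerateInputError):
            lr.clonality(lin)

    def test_edge_decomposition_matches_direct_enumeration(self):
        for seed in range(4):
            lin = random_lineage(12, 3, seed)
            res = lr.clonality(lin)
            dists = oracle_pair_distances(lin)
            assert res.total_pair_sum == pytest.approx(sum(dists.values()))
            # within-type means recomputed directly
            for t, mean_t in res.within_type_means.items():
                members = [c for c in lin.leaves if lin.leaf_types[c] == t]
                pairs = list(itertools.combinations(sorted(members), 2))
                direct = np.mean([lr.lineal_distance(lin, a, b) for a, b in pairs])
                assert mean_t == pytest.approx(direct)

    def test_pair_sum_invariant_under_relabeling(self, lin64):
        """The all-pairs distance sum depends on topology alone."""
        base = lr.clonality(lin64).total_pair_sum
        rng = np.random.default_rng(0)
        for tag in (rz.RELABEL_ALL, rz.RELABEL_WITHIN_DEPTH):
            r = lr.randomize_lineage(lin64, rz.RandomizationMode(tag), rng)
            assert lr.clonality(r).total_pair_sum == pytest.approx(base)

    def test_child_swap_invariance(self, tl1):
        swapped = {n: (b, a) for n, (a, b) in tl1.children.items()}
        mirrored = lr.CellLineage(swapped, tl1.leaf_types, root=tl1.root)
        assert lr.clonality(mirrored).C == pytest.approx(lr.clonality(tl1).C)

    def test_ratio_of_sums_form(self, tl1):
        res = lr.clonality(tl1, form="ratio_of_sums")
        # all-pairs sum 20; within-type sums 2 and 2
        assert res.C == pytest.approx((20 / 2 + 20 / 2) / 2)


class TestRareEarly:
    def test_rare_shallow_gives_plus_one(self, rare3):
        assert lr.rare_early_correlation(rare3).rho == pytest.approx(1.0)

    def test_rare_deep_gives_minus_one(self):
        # rare type (2 cells) at depth 3, common type (3 cells) at depth 2:
        # depth and size ranks are perfectly anticoncordant
        lin = lr.parse_lineage(
            "(((r1,r2),c1),(c2,c3));",
            {"r1": "R", "r2": "R", "c1": "C", "c2": "C", "c3": "C"})
        assert lr.rare_early_correlation(lin).rho == pytest.approx(-1.0)

    def test_single_type_degenerate(self):
        lin = lr.parse_lineage("((a,b),(c,d));", {c: "A" for c in "abcd"})
        assert lr.rare_early_correlation(lin).degenerate

    def test_relabel_null_centered_near_zero(self, lin64):
        rng = np.random.default_rng(1)
        rhos = [
            lr.rare_early_correlation(
                lr.randomize_lineage(lin64, rz.RandomizationMode(rz.RELABEL_ALL),
                                     rng)).rho
            for _ in range(200)
        ]
        assert abs(np.mean(rhos)) < 3 * np.std(rhos) / np.sqrt(len(rhos)) + 0.02

    def test_tied_ranks_use_averages(self):
        res = rare_early_from_sizes([1, 2, 2], [1, 2, 2])
        assert res.rho == pytest.approx(1.0)


class TestSpatial:
    def test_monotone_coords_give_rho_one(self):
        # physical distance a monotone function of lineal distance across
        # the three same-type pairs (A3 equidistant from A1 and A2)
        lin = lr.parse_lineage("((A1,A2),(A3,B1));",
                               {"A1": "A", "A2": "A", "A3": "A", "B1": "B"})
        coords = {"A1": np.array([0.0, 0, 0]), "A2": np.array([0.5, 0, 0]),
                  "A3": np.array([0.25, 5.0, 0]), "B1": np.array([9.0, 9, 9])}
        res = lr.physical_lineal_correlation(lin, coords)
        assert res.rho == pytest.approx(1.0)

    def test_constant_distances_degenerate(self, tl1):
        coords = {c: np.zeros(3) for c in tl1.leaf_types}
        assert lr.physical_lineal_correlation(tl1, coords).degenerate

    def test_cells_without_coordinates_are_skipped(self, tl1):
        coords = {"A1": np.zeros(3), "A2": np.ones(3)}
        res = lr.physical_lineal_correlation(tl1, coords)
        assert res.n == 1 and res.degenerate  # one pair, zero spread

    def test_no_eligible_pair_rejected(self, tl2):
        with pytest.raises(DegenerateInputError):
            lr.physical_lineal_correlation(tl2, {"A1": np.zeros(3)})

    def test_null_coords_give_rho_near_zero(self, lin64):
        rhos = []
        for seed in range(30):
            coords = lr.synth_coords(lin64, clustering_strength=0.0, seed=seed)
            rhos.append(lr.physical_lineal_correlation(lin64, coords).rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_planted_link_gives_positive_rho(self, lin64):
        rhos = []
        for seed in range(20):
            coords = lr.synth_coords(lin64, clustering_strength=3.0, seed=seed)
            rhos.append(lr.physical_lineal_correlation(lin64, coords).rho)
        assert np.mean(rhos) > 0.1
        assert np.mean(np.array(rhos) > 0) >= 0.9


class TestTwins:
    def test_clonal_fixture_has_two(self, tl1):
        n, pairs = lr.count_twins(tl1)
        assert n == 2
        assert {frozenset(p) for p in pairs} == {frozenset({"A1", "A2"}),
                                                 frozenset({"B1", "B2"})}

    def test_interleaved_fixture_has_none(self, tl2):
        assert lr.count_twins(tl2)[0] == 0

    def test_single_division_mixed_types(self):
        lin = lr.parse_lineage("(A1,B1);", {"A1": "A", "B1": "B"})
        assert lr.count_twins(lin)[0] == 0

    def test_coincident_twins_give_negative_z(self, tl1):
        coords = {"A1": np.zeros(3), "A2": np.zeros(3),
                  "B1": np.array([9.0, 0, 0]), "B2": np.array([9.0, 0, 0])}
        # twins coincide; add same-type non-twin spread via extra cells
        lin = lr.parse_lineage("(((A1,A2),(A3,A4)),((B1,B2),(B3,B4)));",
                               {f"{t}{i}": t for t in "AB" for i in range(1, 5)})
        coords = {"A1": np.zeros(3), "A2": np.zeros(3),
                  "A3": np.array([8.0, 0, 0]), "A4": np.array([8.0, 0, 0]),
                  "B1": np.array([0, 7.0, 0]), "B2": np.array([0, 7.0, 0]),
                  "B3": np.array([0, 0, 6.0]), "B4": np.array([0, 0, 6.0])}
        z = lr.twin_spatial_zscore(lin, coords, reps=60, seed=1)
        assert z < -2

    def test_identical_coords_flagged(self, tl1):
        coords = {c: np.zeros(3) for c in tl1.leaf_types}
        with pytest.raises(DegenerateInputError):
            lr.twin_spatial_zscore(tl1, coords, reps=20, seed=1)

    def test_reproducible(self):
        lin = lr.parse_lineage("(((A1,A2),(A3,A4)),((B1,B2),(B3,B4)));",
                               {f"{t}{i}": t for t in "AB" for i in range(1, 5)})
        rng = np.random.default_rng(0)
        coords = {c: rng.normal(size=3) for c in sorted(lin.leaf_types)}
        a = lr.twin_spatial_zscore(lin, coords, reps=30, seed=5)
        b = lr.twin_spatial_zscore(lin, coords, reps=30, seed=5)
        assert a == b

    def test_twin_adjacency_drives_z_negative(self, lin64):
        coords = lr.synth_coords(lin64, clustering_strength=0.0,
                                 twin_adjacency=5.0, seed=3)
        assert lr.twin_spatial_zscore(lin64, coords, reps=80, seed=4) < 0


class TestHillClimb:
    def test_zero_rounds_is_identity(self, lin64):
        coords = lr.synth_coords(lin64, clustering_strength=0.0, seed=1)
        out, rho, trace = lr.hill_climb_rho(lin64, coords, rounds=0,
                                            candidates=10, seed=2)
        assert len(trace) == 1
        assert out.leaf_types == lin64.leaf_types

    def test_rho_never_decreases(self, lin64):
        coords = lr.synth_coords(lin64, clustering_strength=0.0, seed=5)
        _, rho, trace = lr.hill_climb_rho(lin64, coords, rounds=15,
                                          candidates=25, seed=6)
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        assert rho == trace[-1] >= trace[0]

    def test_random_start_improves(self, lin64):
        """From unstructured coordinates the greedy search finds a strictly
        higher physical-lineal correlation within the round budget."""
        coords = lr.synth_coords(lin64, clustering_strength=0.0, seed=7)
        out, rho, trace = lr.hill_climb_rho(lin64, coords, rounds=30,
                                            candidates=40, seed=8)
        assert rho > trace[0]
        # swaps preserve the census and every cell's depth
        assert out.census().counts == lin64.census().counts
        d0, d1 = lin64.depths(), out.depths()
        for cell in lin64.leaf_types:
            assert d0[cell] == d1[cell]
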