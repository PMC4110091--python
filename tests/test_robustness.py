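"""Robustness estimators checked against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

import linrob as lr
from linrob.errors import DegenerateInputError, MappingError
from .conftest import random_lineage


# ---------------------------------------------------------------------- #
# Independent oracles: plain-python recursion, no shared code path with
# the package's array engine.
# ---------------------------------------------------------------------- #
def oracle_f(census, survivors, excluded=(), a=None):
    f = 1.0
    for t, N in census.items():
        if t in excluded:
            continue
        f *= (survivors.get(t, N) / N) ** (a or {}).get(t, 1.0)
    return f


def oracle_descendant_leaves(lineage, node):
    if node in lineage.leaf_types:
        return [node]
    a, b = lineage.children[node]
    return oracle_descendant_leaves(lineage, a) + oracle_descendant_leaves(lineage, b)


def oracle_fn(lineage, excluded=()):
    census = {}
    for t in lineage.leaf_types.values():
        census[t] = census.get(t, 0) + 1
    values = []
    nodes = [n for n in list(lineage.children) + list(lineage.leaf_types)
             if n != lineage.root]
    for node in nodes:
        surv = dict(census)
        for leaf in oracle_descendant_leaves(lineage, node):
            surv[lineage.leaf_types[leaf]] -= 1
        values.append(oracle_f(census, surv, excluded))
    return sum(values) / len(values)


def oracle_programs(lineage):
    """Independent recursive canonicalization of division programs."""
    def fate(node):
        if node in lineage.leaf_types:
            return lineage.leaf_types[node]
        a, b = lineage.children[node]
        return tuple(sorted((fate(a), fate(b)), key=repr))
    return {n: fate(n) for n in lineage.children}


def oracle_fp_exact(lineage, p, excluded=()):
    """Exact E[f]: every program fails independently with probability p."""
    progs = oracle_programs(lineage)
    distinct = sorted(set(progs.values()), key=repr)
    census = {}
    for t in lineage.leaf_types.values():
        census[t] = census.get(t, 0) + 1
    total = 0.0
    for failed in itertools.product([False, True], repeat=len(distinct)):
        failed_set = {k for k, fl in zip(distinct, failed) if fl}
        prob = p ** len(failed_set) * (1 - p) ** (len(distinct) - len(failed_set))
        surv = dict(census)
        dead = set()
        for leaf in lineage.leaf_types:
            node = leaf
            while node != lineage.root:
                node = lineage.parent[node]
                if progs[node] in failed_set:
                    dead.add(leaf)
                    break
        for leaf in dead:
            surv[lineage.leaf_types[leaf]] -= 1
        total += prob * oracle_f(census, surv, excluded)
    return total


# ---------------------------------------------------------------------- #
class TestComputeF:
    def test_all_alive_gives_one(self):
        census = lr.CellTypeCensus({"A": 2, "B": 2})
        assert lr.compute_f(census, {"A": 2, "B": 2}) == 1.0

    def test_half_survival(self):
        census = lr.CellTypeCensus({"A": 2, "B": 2})
        assert lr.compute_f(census, {"A": 1}) == 0.5

    def test_exponent_weighting(self):
        census = lr.CellTypeCensus({"A": 2, "B": 2})
        spec = lr.RobustnessSpec(a={"A": 2.0})
        assert lr.compute_f(census, {"A": 1}, spec) == 0.25

    def test_extinct_type_zeroes_f(self):
        census = lr.CellTypeCensus({"A": 3, "B": 2})
        assert lr.compute_f(census, {"A": 0, "B": 2}) == 0.0

    def test_excluded_type_ignored(self):
        census = lr.CellTypeCensus({"A": 2, "death": 5}, excluded=frozenset({"death"}))
        assert lr.compute_f(census, {"death": 0}) == 1.0

    def test_oversurvival_rejected(self):
        census = lr.CellTypeCensus({"A": 2})
        with pytest.raises(MappingError):
            lr.compute_f(census, {"A": 3})

    def test_unknown_type_rejected(self):
        with pytest.raises(MappingError):
            lr.compute_f(lr.CellTypeCensus({"A": 2}), {"Z": 1})

    def test_monotone_in_survivors(self):
        census = lr.CellTypeCensus({"A": 4, "B": 3})
        fs = [lr.compute_f(census, {"A": n, "B": 2}) for n in range(5)]
        assert fs == sorted(fs)


class TestRemoveSubtree:
    def test_terminal_removal(self, tl1):
        assert lr.remove_subtree(tl1, "A1") == {"A": 1, "B": 2}

    def test_internal_removal(self, tl1):
        parent_a = tl1.parent["A1"]
        assert lr.remove_subtree(tl1, parent_a) == {"A": 0, "B": 2}

    def test_root_removal_kills_everything(self, tl1):
        assert lr.remove_subtree(tl1, tl1.root) == {"A": 0, "B": 0}

    def test_unknown_cell(self, tl1):
        with pytest.raises(MappingError):
            lr.remove_subtree(tl1, "ghost")


class TestNecrosisRobustness:
    def test_clonal_fixture(self, tl1):
        assert lr.necrosis_robustness(tl1) == pytest.approx(1 / 3)

    def test_interleaved_fixture(self, tl2):
        assert lr.necrosis_robustness(tl2) == pytest.approx(2.5 / 6)

    def test_all_distinct_types_gives_zero(self):
        lin = lr.parse_lineage("((a,b),(c,d));",
                               {"a": "A", "b": "B", "c": "C", "d": "D"})
        assert lr.necrosis_robustness(lin) == 0.0

    def test_matches_enumeration_oracle_on_random_lineages(self):
        for seed in range(6):
            lin = random_lineage(14, 3, seed)
            assert lr.necrosis_robustness(lin) == pytest.approx(oracle_fn(lin))

    def test_excluded_types_cost_nothing(self):
        lin = lr.parse_lineage("((a,x),(b,c));",
                               {"a": "A", "x": "death", "b": "A", "c": "A"})
        spec = lr.RobustnessSpec(excluded=frozenset({"death"}))
        assert lr.necrosis_robustness(lin, spec) == pytest.approx(
            oracle_fn(lin, excluded={"death"}))

    def test_deterministic(self, tl2):
        assert lr.necrosis_robustness(tl2) == lr.necrosis_robustness(tl2)

    def test_degenerate_single_cell(self):
        lin = lr.CellLineage({}, {"z": "A"})
        with pytest.raises(DegenerateInputError):
            lr.necrosis_robustness(lin)


class TestProgramFailure:
    def test_exact_clonal(self, tl1):
        spec = lr.RobustnessSpec(p=1 / 3)
        assert lr.exact_program_failure_expectation(tl1, spec) == pytest.approx(8 / 27)

    def test_exact_interleaved(self, tl2):
        spec = lr.RobustnessSpec(p=1 / 3)
        assert lr.exact_program_failure_expectation(tl2, spec) == pytest.approx(4 / 9)

    def test_exact_matches_independent_oracle(self):
        for seed in range(4):
            lin = random_lineage(10, 3, seed)
            p = 1.0 / lin.n_internal
            spec = lr.RobustnessSpec(p=p)
            assert lr.exact_program_failure_expectation(lin, spec) == pytest.approx(
                oracle_fp_exact(lin, p))

    def test_p_zero_gives_one(self, tl1):
        spec = lr.RobustnessSpec(p=0.0, replicates=10, seed=1)
        assert lr.exact_program_failure_expectation(tl1, spec) == 1.0
        assert lr.program_failure_robustness(tl1, spec) == 1.0

    def test_p_one_kills_single_division_lineage(self):
        lin = lr.parse_lineage("(A1,B1);", {"A1": "A", "B1": "B"})
        assert lr.exact_program_failure_expectation(
            lin, lr.RobustnessSpec(p=1.0)) == 0.0

    def test_monte_carlo_converges_to_exact(self, tl1):
        spec = lr.RobustnessSpec(p=1 / 3, replicates=40_000, seed=5)
        exact = 8 / 27
        se = math.sqrt(exact * (1 - exact) / spec.replicates)
        assert abs(lr.program_failure_robustness(tl1, spec) - exact) < 3 * se

    def test_seed_reproducibility(self, tl2):
        spec = lr.RobustnessSpec(p=1 / 3, replicates=500, seed=11)
        assert (lr.program_failure_robustness(tl2, spec)
                == lr.program_failure_robustness(tl2, spec))

    def test_default_p_expected_failures_is_one(self):
        """Sum over programs of usage x p equals exactly one internal cell."""
        for seed in range(5):
            lin = random_lineage(18, 4, seed)
            pa = lr.infer_programs(lin)
            p = 1.0 / pa.n_internal
            assert sum(pa.usage.values()) * p == pytest.approx(1.0, abs=1e-12)


class TestDistributedLoss:
    def test_concentrated_loss_is_worst(self):
        """Splitting h deaths across equal-sized types never lowers f below
        concentrating them in one type; brute force over all allocations."""
        for T in (2, 3, 4):
            for N in (2, 3, 4, 6):
                census = lr.CellTypeCensus({f"t{i}": N for i in range(T)})
                for h in range(1, N + 1):
                    allocations = [
                        alloc for alloc in itertools.product(range(N + 1), repeat=T)
                        if sum(alloc) == h
                    ]
                    fs = {
                        alloc: lr.compute_f(
                            census, {f"t{i}": N - a for i, a in enumerate(alloc)})
                        for alloc in allocations
                    }
                    concentrated = fs[tuple([h] + [0] * (T - 1))]
                    assert concentrated == min(fs.values())


class TestVariableRates:
    def test_constant_model_matches_fn(self, tl2):
        spec = lr.RobustnessSpec(p=1 / 3, replicates=2000, seed=3)
        fn, _ = lr.variable_rate_robustness(tl2, spec, draws=10)
        assert fn == pytest.approx(lr.necrosis_robustness(tl2))

    def test_exponential_rates_average_to_constant_fn(self, tl2):
        spec = lr.RobustnessSpec(p=1 / 3, rate_model="exponential")
        fn, fp = lr.variable_rate_robustness(tl2, spec, draws=6000, seed=4)
        # the rate-weighted mean is consistent in expectation with the
        # constant-rate value; wide MC band
        assert abs(fn - lr.necrosis_robustness(tl2)) < 0.02
        assert 0.0 <= fp <= 1.0

    def test_seed_reproducible(self, tl1):
        spec = lr.RobustnessSpec(p=1 / 3, rate_model="exponential")
        a = lr.variable_rate_robustness(tl1, spec, draws=200, seed=9)
        b = lr.variable_rate_robustness(tl1, spec, draws=200, seed=9)
        assert a == b

    def test_draws_domain_error(self, tl1):
        with pytest.raises(DegenerateInputError):
            lr.variable_rate_robustness(tl1, draws=0)


class TestStochasticDistribution:
    def test_program_mode_mean_near_exact(self, tl1):
        spec = lr.RobustnessSpec(p=1 / 3)
        s = lr.stochastic_f_distribution(tl1, spec, ndraws=30_000, seed=2,
                                         mode="program")
        exact = 8 / 27
        se = s.sd / math.sqrt(s.values.size)
        assert abs(s.mean - exact) < 3 * se

    def test_zero_death_probability(self):
        # a lineage large enough that 1/n_nonroot ~ 0 still yields f near 1;
        # the exact zero case is p=0 in program mode
        lin = lr.parse_lineage("(A1,B1);", {"A1": "A", "B1": "B"})
        s = lr.stochastic_f_distribution(lin, lr.RobustnessSpec(p=0.0),
                                         ndraws=50, seed=1, mode="program")
        assert s.mean == 1.0 and s.sd == 0.0

    def test_reproducible(self, tl2):
        spec = lr.RobustnessSpec(p=1 / 3)
        a = lr.stochastic_f_distribution(tl2, spec, ndraws=100, seed=7, mode="necrosis")
        b = lr.stochastic_f_distribution(tl2, spec, ndraws=100, seed=7, mode="necrosis")
        assert np.array_equal(a.values, b.values)
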