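"""Lineage robustness to necrosis and division-program failure.

The fitness proxy is

    f = prod over included types i of (n_i / N_i) ** a_i

where N_i is the unperturbed terminal count of type i, n_i the surviving
count, and a_i >= 1 a type-importance exponent (1 by default).  Apoptotic
("death") terminal cells are excluded from the product but still exist in the
tree, so losing one costs nothing while losing an internal ancestor of live
cells does.

Necrosis robustness f_n is the exact mean of f over the single removal of
every non-root cell.  Program-failure robustness f_p is the expectation of f
when the number of failed programs is Binomial(N_program, p) and failed
programs are drawn uniformly without replacement; with p = 1/N_internal the
expected number of internal cells whose program fails equals exactly 1 in
any lineage, making f_p comparable across lineages of the same terminals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from ._rng import as_rng
from .errors import DegenerateInputError, MappingError
from .lineage import CellLineage, CellTypeCensus, infer_programs

__all__ = [
    "RobustnessSpec",
    "PerturbationOutcome",
    "compute_f",
    "remove_subtree",
    "necrosis_robustness",
    "program_failure_robustness",
    "exact_program_failure_expectation",
    "variable_rate_robustness",
    "stochastic_f_distribution",
    "StochasticSample",
]


@dataclass(frozen=True)
class RobustnessSpec:
    """Parameters of the robustness calculation.

    p defaults to 1/N_internal (one expected program failure per lineage);
    replicates defaults to 10 * N_all, the number of cells in the lineage
    times ten.
    """

    a: Optional[Mapping[str, float]] = None      # per-type exponents, default 1
    excluded: frozenset = frozenset()
    p: Optional[float] = None
    replicates: Optional[int] = None
    rate_model: str = "constant"                 # "constant" | "exponential"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.a is not None:
            for t, ai in self.a.items():
                if ai < 1:
                    raise DegenerateInputError(f"a[{t!r}] = {ai} < 1")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise DegenerateInputError(f"p = {self.p} outside [0, 1]")
        if self.replicates is not None and self.replicates < 1:
            raise DegenerateInputError("replicate count must be >= 1")
        if self.rate_model not in ("constant", "exponential"):
            raise DegenerateInputError(f"unknown rate model {self.rate_model!r}")

    def exponent(self, cell_type: str) -> float:
        if self.a is None:
            return 1.0
        return float(self.a.get(cell_type, 1.0))

    def failure_p(self, lineage: CellLineage) -> float:
        if self.p is not None:
            return self.p
        if lineage.n_internal == 0:
            raise DegenerateInputError("lineage has no internal cells")
        return 1.0 / lineage.n_internal

    def n_replicates(self, lineage: CellLineage) -> int:
        return self.replicates if self.replicates is not None else 10 * lineage.n_all


@dataclass(frozen=True)
class PerturbationOutcome:
    """Surviving counts and the resulting f for one realized perturbation."""

    survivors: Dict[str, int]
    f: float


# ---------------------------------------------------------------------- #
# Array engine: shared by every estimator on one (lineage, spec) pair.
# ---------------------------------------------------------------------- #
class _Engine:
    def __init__(self, lineage: CellLineage, spec: RobustnessSpec):
        self.lineage = lineage
        self.spec = spec
        census = lineage.census(spec.excluded)
        self.types = sorted(census.included)
        self.t_index = {t: i for i, t in enumerate(self.types)}
        self.N = np.array([census.included[t] for t in self.types], dtype=float)
        self.a = np.array([spec.exponent(t) for t in self.types], dtype=float)

        order = lineage.postorder()
        self.node_index = {n: i for i, n in enumerate(order)}
        self.order = order
        T = len(self.types)
        counts = np.zeros((len(order), T), dtype=float)
        for i, n in enumerate(order):
            if n in lineage.leaf_types:
                t = lineage.leaf_types[n]
                if t in self.t_index:
                    counts[i, self.t_index[t]] = 1.0
            else:
                a, b = lineage.children[n]
                counts[i] = counts[self.node_index[a]] + counts[self.node_index[b]]
        self.counts = counts
        self.nonroot = np.array([n != lineage.root for n in order])

        self._programs = None
        self._leaf_prog = None

    # -- f for a batch of per-type survivor matrices ------------------- #
    def f_of_survivors(self, surv: np.ndarray) -> np.ndarray:
        frac = surv / self.N
        return np.prod(frac ** self.a, axis=-1)

    def single_removal_f(self) -> np.ndarray:
        """f after removing each non-root cell's subtree, in postorder order."""
        surv = self.N[None, :] - self.counts[self.nonroot]
        return self.f_of_survivors(surv)

    # -- program machinery --------------------------------------------- #
    @property
    def programs(self):
        if self._programs is None:
            self._programs = infer_programs(self.lineage)
        return self._programs

    def leaf_program_incidence(self) -> Tuple[np.ndarray, np.ndarray, list]:
        """(A, leaf_type_onehot, program list).

        A[l, j] = 1 iff program j is used by an internal cell on the path
        from the root to leaf l (the leaf dies when program j fails).
        """
        if self._leaf_prog is not None:
            return self._leaf_prog
        pa = self.programs
        prog_list = sorted(pa.usage, key=repr)
        p_index = {k: i for i, k in enumerate(prog_list)}
        lineage = self.lineage
        leaves = lineage.leaves
        L, P, T = len(leaves), len(prog_list), len(self.types)
        A = np.zeros((L, P), dtype=np.float32)
        onehot = np.zeros((L, T), dtype=np.float32)
        leaf_index = {c: i for i, c in enumerate(leaves)}
        # DFS accumulating the set of programs above each node
        stack = [(lineage.root, [])]
        while stack:
            node, progs = stack.pop()
            if node in lineage.children:
                progs = progs + [p_index[pa.programs[node]]]
                for c in lineage.children[node]:
                    stack.append((c, progs))
            else:
                li = leaf_index[node]
                A[li, progs] = 1.0
                t = lineage.leaf_types[node]
                if t in self.t_index:
                    onehot[li, self.t_index[t]] = 1.0
        self._leaf_prog = (A, onehot, prog_list)
        return self._leaf_prog

    def f_of_failed_masks(self, failed: np.ndarray) -> np.ndarray:
        """f for each row of a (reps x P) boolean failed-program matrix."""
        A, onehot, _ = self.leaf_program_incidence()
        dead_leaf = (failed.astype(np.float32) @ A.T) > 0          # reps x L
        dead_per_type = dead_leaf.astype(np.float32) @ onehot      # reps x T
        surv = self.N[None, :] - dead_per_type
        return self.f_of_survivors(surv)


# ---------------------------------------------------------------------- #
def compute_f(
    census: CellTypeCensus,
    survivors: Mapping[str, int],
    spec: Optional[RobustnessSpec] = None,
) -> float:
    """Product over included types of (n_i / N_i) ** a_i."""
    spec = spec or RobustnessSpec()
    excluded = census.excluded | spec.excluded
    unknown = set(survivors) - set(census.counts)
    if unknown:
        raise MappingError(f"unknown types in survivors: {sorted(unknown)}")
    f = 1.0
    for t, N in census.counts.items():
        if t in excluded:
            continue
        n = survivors.get(t, N)
        if n > N:
            raise MappingError(f"survivors[{t!r}] = {n} exceeds census {N}")
        f *= (n / N) ** spec.exponent(t)
    return f


def remove_subtree(lineage: CellLineage, cell: str) -> Dict[str, int]:
    """Per-type terminal counts surviving the death of ``cell``'s subtree."""
    lost = lineage.subtree_leaves(cell)
    counts = dict(lineage.census().counts)
    for leaf in lost:
        counts[lineage.leaf_types[leaf]] -= 1
    return counts


def necrosis_robustness(
    lineage: CellLineage, spec: Optional[RobustnessSpec] = None
) -> float:
    """Exact mean f over the single removal of every non-root cell."""
    spec = spec or RobustnessSpec()
    if lineage.n_all < 2:
        raise DegenerateInputError("necrosis robustness needs a non-root cell")
    eng = _Engine(lineage, spec)
    return float(eng.single_removal_f().mean())


def program_failure_robustness(
    lineage: CellLineage,
    spec: Optional[RobustnessSpec] = None,
    rng=None,
    chunk: int = 4096,
) -> float:
    """Monte-Carlo expectation of f under binomial program failure."""
    spec = spec or RobustnessSpec()
    eng = _Engine(lineage, spec)
    p = spec.failure_p(lineage)
    reps = spec.n_replicates(lineage)
    rng = as_rng(spec.seed if rng is None else rng)
    _, _, prog_list = eng.leaf_program_incidence()
    P = len(prog_list)
    total = 0.0
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        b = rng.binomial(P, p, size=r)
        scores = rng.random((r, P))
        ranks = scores.argsort(axis=1).argsort(axis=1)
        failed = ranks < b[:, None]
        total += float(eng.f_of_failed_masks(failed).sum())
        done += r
    return total / reps


def exact_program_failure_expectation(
    lineage: CellLineage,
    spec: Optional[RobustnessSpec] = None,
    max_programs: int = 18,
) -> float:
    """Exact E[f] by enumerating every subset of failed programs.

    Binomial-count sampling followed by a uniform without-replacement draw is
    equivalent to independent Bernoulli(p) failure per program, so subset S
    has probability p^|S| (1-p)^(P-|S|).
    """
    spec = spec or RobustnessSpec()
    eng = _Engine(lineage, spec)
    p = spec.failure_p(lineage)
    A, onehot, prog_list = eng.leaf_program_incidence()
    P = len(prog_list)
    if P > max_programs:
        raise DegenerateInputError(f"{P} programs exceed the enumeration cap")
    subsets = np.arange(1 << P, dtype=np.int64)
    k = np.bitwise_count(subsets).astype(float)
    if p == 0.0:
        prob = (k == 0).astype(float)
    elif p == 1.0:
        prob = (k == P).astype(float)
    else:
        prob = np.exp(k * math.log(p) + (P - k) * math.log1p(-p))
    # leaf masks as ints, grouped by (mask, type)
    leaf_masks = (A.astype(np.int64) * (1 << np.arange(P, dtype=np.int64))).sum(axis=1)
    T = len(eng.types)
    dead = np.zeros((len(subsets), T))
    groups: Dict[Tuple[int, int], int] = {}
    type_of_leaf = onehot.argmax(axis=1)
    counted = onehot.sum(axis=1) > 0   # excluded-type leaves never enter f
    for mask, t, c in zip(leaf_masks, type_of_leaf, counted):
        if c:
            groups[(int(mask), int(t))] = groups.get((int(mask), int(t)), 0) + 1
    for (mask, t), n in groups.items():
        dead[:, t] += n * ((subsets & mask) != 0)
    surv = eng.N[None, :] - dead
    f = eng.f_of_survivors(surv)
    return float(np.dot(f, prob))


def variable_rate_robustness(
    lineage: CellLineage,
    spec: Optional[RobustnessSpec] = None,
    draws: int = 1000,
    seed=None,
) -> Tuple[float, float]:
    """(f_n, f_p) when rates vary among cells / programs.

    Per draw, every non-root cell receives an exponential necrosis rate with
    mean equal to the constant rate, and f_n is the rate-weighted mean of the
    single-removal f values; every program receives an exponential failure
    probability (mean p, truncated at 1) and one Bernoulli failure
    realization is scored.  Returns means over draws.
    """
    spec = spec or RobustnessSpec()
    if draws < 1:
        raise DegenerateInputError("draws must be >= 1")
    rng = as_rng(seed if seed is not None else spec.seed)
    eng = _Engine(lineage, spec)
    f_single = eng.single_removal_f()
    n_nonroot = f_single.size
    p = spec.failure_p(lineage)
    _, _, prog_list = eng.leaf_program_incidence()
    P = len(prog_list)

    if spec.rate_model == "constant":
        fn = float(f_single.mean())
        fp = program_failure_robustness(lineage, spec, rng=rng)
        return fn, fp

    rates = rng.exponential(scale=1.0 / n_nonroot, size=(draws, n_nonroot))
    fn_draws = (rates * f_single[None, :]).sum(axis=1) / rates.sum(axis=1)

    q = np.minimum(rng.exponential(scale=p, size=(draws, P)), 1.0)
    failed = rng.random((draws, P)) < q
    fp_draws = eng.f_of_failed_masks(failed)
    return float(fn_draws.mean()), float(fp_draws.mean())


@dataclass(frozen=True)
class StochasticSample:
    """Individual-level f draws with summary statistics."""

    values: np.ndarray
    mode: str

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def stochastic_f_distribution(
    lineage: CellLineage,
    spec: Optional[RobustnessSpec] = None,
    ndraws: int = 1000,
    seed=None,
    mode: str = "necrosis",
) -> StochasticSample:
    """Distribution of f across individuals under stochastic perturbation.

    necrosis mode: every non-root cell dies independently with probability
    1/(number of non-root cells).  program mode: every program fails
    independently with probability p.
    """
    spec = spec or RobustnessSpec()
    if ndraws < 2:
        raise DegenerateInputError("ndraws must be >= 2")
    rng = as_rng(seed if seed is not None else spec.seed)
    eng = _Engine(lineage, spec)

    if mode == "necrosis":
        order = eng.order
        nonroot_nodes = [n for n in order if n != lineage.root]
        q = 1.0 / len(nonroot_nodes)
        # leaf x nonroot incidence: leaf dies if any non-root node on its
        # path (itself included) dies
        leaves = lineage.leaves
        leaf_index = {c: i for i, c in enumerate(leaves)}
        B = np.zeros((len(leaves), len(nonroot_nodes)), dtype=np.float32)
        nr_index = {n: i for i, n in enumerate(nonroot_nodes)}
        stack = [(lineage.root, [])]
        while stack:
            node, above = stack.pop()
            mine = above + [nr_index[node]] if node != lineage.root else above
            if node in lineage.children:
                for c in lineage.children[node]:
                    stack.append((c, mine))
            else:
                B[leaf_index[node], mine] = 1.0
        onehot = np.zeros((len(leaves), len(eng.types)), dtype=np.float32)
        for c, i in leaf_index.items():
            t = lineage.leaf_types[c]
            if t in eng.t_index:
                onehot[i, eng.t_index[t]] = 1.0
        values = np.empty(ndraws)
        chunk = max(1, int(4e6 // max(1, len(nonroot_nodes))))
        done = 0
        while done < ndraws:
            r = min(chunk, ndraws - done)
            dead_node = rng.random((r, len(nonroot_nodes))) < q
            dead_leaf = (dead_node.astype(np.float32) @ B.T) > 0
            dead_per_type = dead_leaf.astype(np.float32) @ onehot
            values[done:done + r] = eng.f_of_survivors(eng.N[None, :] - dead_per_type)
            done += r
        return StochasticSample(values=values, mode=mode)

    if mode == "program":
        p = spec.failure_p(lineage)
        _, _, prog_list = eng.leaf_program_incidence()
        failed = rng.random((ndraws, len(prog_list))) < p
        return StochasticSample(values=eng.f_of_failed_masks(failed), mode=mode)

    raise DegenerateInputError(f"unknown mode {mode!r}")
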