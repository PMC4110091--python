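"""Constrained lineage randomization and empirical P/Z null tests.

Eight null models, all conserving the terminal-cell census exactly:

COALESCENT                  free random coalescence of the terminal cells
COALESCENT_FIXED_MAXDEPTH   coalescence with max depth fixed at D
COALESCENT_BOOTSTRAP_DEPTHS terminal depths bootstrapped from the real
                            multiset, max depth held at the real value
FROM_DEPTH_MULTISET         terminal depth multiset exactly conserved,
                            topology rebuilt by deepest-first random pairing
RELABEL_ALL                 same topology, terminal cells permuted freely
RELABEL_WITHIN_DEPTH        permuted only within their depths
RELABEL_WITHIN_DEPTH_TWINS  within-depth permutation that keeps every twin
                            pair (same-type terminal siblings) together
CLONALITY_GRADIENT          within-depth reassignment with a fraction g of
                            each type sorted by a fixed type order, yielding
                            clonality that rises with g
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._rng import as_rng
from .errors import ConstraintError, DegenerateInputError
from .lineage import CellLineage, theoretical_min_max_depth

__all__ = [
    "RandomizationMode",
    "NullDistribution",
    "randomize_lineage",
    "null_distribution",
    "COALESCENT",
    "COALESCENT_FIXED_MAXDEPTH",
    "COALESCENT_BOOTSTRAP_DEPTHS",
    "FROM_DEPTH_MULTISET",
    "RELABEL_ALL",
    "RELABEL_WITHIN_DEPTH",
    "RELABEL_WITHIN_DEPTH_TWINS",
    "CLONALITY_GRADIENT",
]

COALESCENT = "coalescent"
COALESCENT_FIXED_MAXDEPTH = "coalescent_fixed_maxdepth"
COALESCENT_BOOTSTRAP_DEPTHS = "coalescent_bootstrap_depths"
FROM_DEPTH_MULTISET = "from_depth_multiset"
RELABEL_ALL = "relabel_all"
RELABEL_WITHIN_DEPTH = "relabel_within_depth"
RELABEL_WITHIN_DEPTH_TWINS = "relabel_within_depth_twins"
CLONALITY_GRADIENT = "clonality_gradient"

_TAGS = {
    COALESCENT, COALESCENT_FIXED_MAXDEPTH, COALESCENT_BOOTSTRAP_DEPTHS,
    FROM_DEPTH_MULTISET, RELABEL_ALL, RELABEL_WITHIN_DEPTH,
    RELABEL_WITHIN_DEPTH_TWINS, CLONALITY_GRADIENT,
}


@dataclass(frozen=True)
class RandomizationMode:
    """A null-model tag plus its parameters.

    max_depth (D) is required for the fixed-max-depth mode and may span
    D_min .. D_real + 2 (D_real - D_min + 1); g in [0, 1] is the sorted
    fraction of the clonality gradient.
    """

    tag: str
    max_depth: Optional[int] = None
    g: Optional[float] = None

    def __post_init__(self):
        if self.tag not in _TAGS:
            raise DegenerateInputError(f"unknown randomization mode {self.tag!r}")
        if self.tag == COALESCENT_FIXED_MAXDEPTH and self.max_depth is None:
            raise DegenerateInputError("fixed-max-depth mode needs max_depth")
        if self.tag == CLONALITY_GRADIENT:
            if self.g is None or not (0.0 <= self.g <= 1.0):
                raise DegenerateInputError("clonality gradient needs g in [0, 1]")


@dataclass(frozen=True)
class NullDistribution:
    """Null samples of a statistic with empirical P and Z."""

    statistic: str
    observed: float
    samples: np.ndarray
    direction: str
    p_value: float
    z: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return int(self.samples.size)


# ---------------------------------------------------------------------- #
# Coalescent constructions
# ---------------------------------------------------------------------- #
def _coalesce(cells: Sequence[str], rng, max_depth: Optional[int] = None
              ) -> Optional[Dict[str, Tuple[str, str]]]:
    """Random pairwise coalescence; returns children map or None on dead end.

    With max_depth set, merges that would force a terminal beyond max_depth
    are forbidden (a merged subtree must gain at least one more edge unless
    it is the final merge).
    """
    pool: List[str] = list(cells)
    heights: List[int] = [0] * len(pool)
    children: Dict[str, Tuple[str, str]] = {}
    serial = 0
    # Kraft budget: the current subtree heights {h_i} can still complete
    # inside depth D iff sum 2^h_i <= 2^D (each subtree needs a slot at
    # depth <= D - h_i in the remaining upper tree)
    S = len(pool) if max_depth is not None else 0
    cap = (1 << max_depth) if max_depth is not None else 0
    while len(pool) > 1:
        k = len(pool)
        if max_depth is None:
            i, j = rng.choice(k, size=2, replace=False)
        else:
            i, j = _pick_feasible_pair(heights, k, S, cap, rng)
        if i > j:
            i, j = j, i
        serial += 1
        node = f"_r{serial}"
        children[node] = (pool[i], pool[j])
        new_h = max(heights[i], heights[j]) + 1
        if max_depth is not None:
            S += (1 << new_h) - (1 << heights[i]) - (1 << heights[j])
        # replace slot i with the merged node, swap-pop slot j
        pool[i], heights[i] = node, new_h
        pool[j], heights[j] = pool[-1], heights[-1]
        pool.pop()
        heights.pop()
    return children


def _pick_feasible_pair(heights, k, S, cap, rng):
    """A uniform-ish merge pair that keeps the Kraft budget satisfiable.

    Random pairs are screened against the budget; when sampling fails, the
    two shallowest subtrees are merged, a move that provably preserves
    feasibility, so constrained coalescence never dead-ends.
    """
    for _ in range(40):
        i, j = rng.choice(k, size=2, replace=False)
        new_S = S + (1 << (max(heights[i], heights[j]) + 1)) \
            - (1 << heights[i]) - (1 << heights[j])
        if new_S <= cap:
            return i, j
    order = sorted(range(k), key=lambda t: heights[t])
    return order[0], order[1]


def _coalescent_lineage(lineage: CellLineage, rng) -> CellLineage:
    children = _coalesce(list(lineage.leaf_types), rng)
    return CellLineage(children, lineage.leaf_types)


def _fixed_maxdepth_lineage(lineage: CellLineage, D: int, rng,
                            max_attempts: int = 2000) -> CellLineage:
    cells = list(lineage.leaf_types)
    d_min = theoretical_min_max_depth(len(cells))
    if D < d_min:
        raise ConstraintError(f"max depth {D} below the theoretical minimum {d_min}")
    for _ in range(max_attempts):
        children = _coalesce(cells, rng, max_depth=D)
        if children is None:
            continue
        out = CellLineage(children, lineage.leaf_types, validate=False)
        if out.max_depth == D:
            return out
    raise ConstraintError(f"could not realize max depth {D} in {max_attempts} tries")


# ---------------------------------------------------------------------- #
# Depth-multiset constructions
# ---------------------------------------------------------------------- #
def _kraft_closes(depths: np.ndarray, max_d: int) -> bool:
    units = np.sum(np.int64(1) << (max_d - depths))
    return int(units) == (1 << max_d)


def _pairup_from_depths(cells: Sequence[str], depths: Sequence[int], rng,
                        types: Dict[str, str]) -> CellLineage:
    """Deepest-first random pairing of cells with assigned depths."""
    by_depth: Dict[int, List[str]] = {}
    for c, d in zip(cells, depths):
        by_depth.setdefault(int(d), []).append(c)
    max_d = max(by_depth)
    serial = 0
    children: Dict[str, Tuple[str, str]] = {}
    level = list(by_depth.get(max_d, []))
    for d in range(max_d, 0, -1):
        rng.shuffle(level)
        if len(level) % 2:
            raise ConstraintError(
                f"odd number of cells ({len(level)}) at depth {d}; the depth "
                "multiset does not close to a single root"
            )
        nxt: List[str] = []
        for i in range(0, len(level), 2):
            serial += 1
            node = f"_d{serial}"
            children[node] = (level[i], level[i + 1])
            nxt.append(node)
        level = nxt + list(by_depth.get(d - 1, []))
    if len(level) != 1:
        raise ConstraintError("depth multiset does not close to a single root")
    return CellLineage(children, types, root=level[0])


def _depth_multiset_lineage(lineage: CellLineage, rng) -> CellLineage:
    d = lineage.depths()
    depths = [d[c] for c in lineage.leaves]
    cells = list(lineage.leaves)
    rng.shuffle(cells)  # random depth assignment of the terminal identities
    return _pairup_from_depths(cells, depths, rng, lineage.leaf_types)


def _bootstrap_depths_lineage(lineage: CellLineage, rng,
                              max_attempts: int = 10000) -> CellLineage:
    d = lineage.depths()
    real = np.array([d[c] for c in lineage.leaves])
    D_real = int(real.max())
    L = real.size
    batch = 256
    tried = 0
    while tried < max_attempts:
        draws = rng.choice(real, size=(batch, L), replace=True)
        tried += batch
        maxes = draws.max(axis=1)
        for row in draws[maxes == D_real]:
            if _kraft_closes(row, D_real):
                cells = list(lineage.leaves)
                rng.shuffle(cells)
                return _pairup_from_depths(cells, row, rng, lineage.leaf_types)
    raise ConstraintError(
        f"no feasible bootstrap depth sample in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------- #
# Relabeling constructions (topology conserved)
# ---------------------------------------------------------------------- #
def _relabel_all(lineage: CellLineage, rng) -> CellLineage:
    positions = lineage.leaves
    cells = list(positions)
    rng.shuffle(cells)
    return lineage.relabel(dict(zip(positions, cells)))


def _relabel_within_depth(lineage: CellLineage, rng) -> CellLineage:
    d = lineage.depths()
    assignment: Dict[str, str] = {}
    by_depth: Dict[int, List[str]] = {}
    for leaf in lineage.leaves:
        by_depth.setdefault(d[leaf], []).append(leaf)
    for positions in by_depth.values():
        cells = list(positions)
        rng.shuffle(cells)
        assignment.update(zip(positions, cells))
    return lineage.relabel(assignment)


def _twin_pairs(lineage: CellLineage) -> List[Tuple[str, str]]:
    out = []
    for node, (a, b) in lineage.children.items():
        if (a in lineage.leaf_types and b in lineage.leaf_types
                and lineage.leaf_types[a] == lineage.leaf_types[b]):
            out.append((a, b))
    return out


def _relabel_within_depth_twins(lineage: CellLineage, rng) -> CellLineage:
    d = lineage.depths()
    twins = _twin_pairs(lineage)
    twin_cells = {c for pair in twins for c in pair}
    # sibling leaf-position pairs per depth (positions able to host a twin)
    sib_positions: Dict[int, List[Tuple[str, str]]] = {}
    for node, (a, b) in lineage.children.items():
        if a in lineage.leaf_types and b in lineage.leaf_types:
            sib_positions.setdefault(d[a], []).append((a, b))
    twin_by_depth: Dict[int, List[Tuple[str, str]]] = {}
    for pair in twins:
        twin_by_depth.setdefault(d[pair[0]], []).append(pair)

    assignment: Dict[str, str] = {}
    used_positions = set()
    for depth, pairs in twin_by_depth.items():
        slots = list(sib_positions[depth])
        rng.shuffle(slots)
        order = list(pairs)
        rng.shuffle(order)
        for (ca, cb), (pa, pb) in zip(order, slots):
            if rng.random() < 0.5:
                ca, cb = cb, ca
            assignment[pa], assignment[pb] = ca, cb
            used_positions.update((pa, pb))

    by_depth_pos: Dict[int, List[str]] = {}
    by_depth_cell: Dict[int, List[str]] = {}
    for leaf in lineage.leaves:
        if leaf not in used_positions:
            by_depth_pos.setdefault(d[leaf], []).append(leaf)
        if leaf not in twin_cells:
            by_depth_cell.setdefault(d[leaf], []).append(leaf)
    for depth, positions in by_depth_pos.items():
        cells = list(by_depth_cell.get(depth, []))
        rng.shuffle(cells)
        assignment.update(zip(positions, cells))
    return lineage.relabel(assignment)


def _clonality_gradient(lineage: CellLineage, g: float, rng) -> CellLineage:
    d = lineage.depths()
    types = lineage.leaf_types
    type_order = sorted(set(types.values()))
    rng.shuffle(type_order)
    rank = {t: i for i, t in enumerate(type_order)}

    by_depth: Dict[int, List[str]] = {}
    for leaf in lineage.leaves:  # left-to-right within each depth
        by_depth.setdefault(d[leaf], []).append(leaf)

    assignment: Dict[str, str] = {}
    for depth, positions in by_depth.items():
        cells = list(positions)
        by_type: Dict[str, List[str]] = {}
        for c in cells:
            by_type.setdefault(types[c], []).append(c)
        sorted_part: List[str] = []
        loose: List[str] = []
        for t in sorted(by_type, key=lambda t: rank[t]):
            members = by_type[t]
            rng.shuffle(members)
            n_pick = int(round(g * len(members)))
            sorted_part.extend(members[:n_pick])
            loose.extend(members[n_pick:])
        rng.shuffle(loose)
        ordered = list(sorted_part)
        for c in loose:
            ordered.insert(int(rng.integers(0, len(ordered) + 1)), c)
        assignment.update(zip(positions, ordered))
    return lineage.relabel(assignment)


# ---------------------------------------------------------------------- #
def randomize_lineage(lineage: CellLineage, mode: RandomizationMode, seed=None
                      ) -> CellLineage:
    """Draw one random lineage under the given constraint set."""
    rng = as_rng(seed)
    tag = mode.tag
    if tag == COALESCENT:
        return _coalescent_lineage(lineage, rng)
    if tag == COALESCENT_FIXED_MAXDEPTH:
        return _fixed_maxdepth_lineage(lineage, int(mode.max_depth), rng)
    if tag == COALESCENT_BOOTSTRAP_DEPTHS:
        return _bootstrap_depths_lineage(lineage, rng)
    if tag == FROM_DEPTH_MULTISET:
        return _depth_multiset_lineage(lineage, rng)
    if tag == RELABEL_ALL:
        return _relabel_all(lineage, rng)
    if tag == RELABEL_WITHIN_DEPTH:
        return _relabel_within_depth(lineage, rng)
    if tag == RELABEL_WITHIN_DEPTH_TWINS:
        return _relabel_within_depth_twins(lineage, rng)
    if tag == CLONALITY_GRADIENT:
        return _clonality_gradient(lineage, float(mode.g), rng)
    raise DegenerateInputError(f"unknown mode {tag!r}")


def null_distribution(
    lineage: CellLineage,
    statistic: Callable[[CellLineage], float],
    mode: RandomizationMode,
    n: int,
    direction: str = "greater",
    seed=None,
    name: Optional[str] = None,
) -> NullDistribution:
    """Empirical P and Z of a statistic against a constrained null.

    P is the fraction of null samples at least as extreme as the observed
    value in the given direction (ties count as extreme); Z is the observed
    value's deviation from the null mean in null standard deviations.
    """
    if n < 1:
        raise DegenerateInputError("n must be >= 1")
    if direction not in ("greater", "less"):
        raise DegenerateInputError("direction must be 'greater' or 'less'")
    rng = as_rng(seed)
    observed = float(statistic(lineage))
    samples = np.empty(n)
    for i in range(n):
        samples[i] = statistic(randomize_lineage(lineage, mode, rng))
    if direction == "greater":
        r = int(np.sum(samples >= observed))
    else:
        r = int(np.sum(samples <= observed))
    sd = samples.std(ddof=1) if n > 1 else 0.0
    degenerate = not (sd > 0)
    z = float("nan") if degenerate else (observed - samples.mean()) / sd
    return NullDistribution(
        statistic=name or getattr(statistic, "__name__", "statistic"),
        observed=observed, samples=samples, direction=direction,
        p_value=r / n, z=z, degenerate=degenerate,
    )
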