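"""Clonality, rare-early correlation, spatial statistics and twin analysis.

Clonality C measures how lineally clustered the terminal cells of each type
are.  With d the lineal distance (edges on the tree path), M the set of all
terminal pairs and M_i the pairs within type i,

    C = (1/T) * sum over types i of  mean_M(d) / mean_{M_i}(d)

The numerator is a property of the unlabeled topology alone (invariant under
any relabeling); the within-type mean shrinks as type members cluster, so a
larger C means stronger clonality.  The raw-sum form (ratio of sums instead
of means) is available via ``form="ratio_of_sums"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats

from ._rng import as_rng
from .errors import DegenerateInputError, MappingError
from .lineage import CellLineage, lineal_distance

__all__ = [
    "ClonalityResult",
    "CorrelationResult",
    "SpatialMap",
    "clonality",
    "rare_early_correlation",
    "rare_early_from_sizes",
    "physical_lineal_correlation",
    "count_twins",
    "twin_spatial_zscore",
    "hill_climb_rho",
    "read_coords",
    "write_coords",
]

SpatialMap = Dict[str, np.ndarray]   # cell id -> (x, y, z) nucleus center


@dataclass(frozen=True)
class ClonalityResult:
    C: float
    total_pair_sum: float          # sum of d over all terminal pairs M
    within_type_means: Dict[str, float]
    T: int
    form: str


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float = float("nan")
    degenerate: bool = False


# ---------------------------------------------------------------------- #
def _pair_distance_sums(lineage: CellLineage, excluded=frozenset()
                        ) -> Tuple[float, int, Dict[str, float], Dict[str, int]]:
    """Sum of lineal distances over all pairs and per-type pairs.

    Uses the edge decomposition sum_pairs d = sum_edges s_e * (L - s_e),
    where s_e counts terminals below the edge, applied per type as well.
    """
    types = sorted({t for t in lineage.leaf_types.values() if t not in excluded})
    t_index = {t: i for i, t in enumerate(types)}
    totals = np.zeros(len(types))
    order = lineage.postorder()
    idx = {n: i for i, n in enumerate(order)}
    counts = np.zeros((len(order), len(types)))
    for i, n in enumerate(order):
        if n in lineage.leaf_types:
            t = lineage.leaf_types[n]
            if t in t_index:
                counts[i, t_index[t]] = 1
        else:
            a, b = lineage.children[n]
            counts[i] = counts[idx[a]] + counts[idx[b]]
    N = counts[idx[lineage.root]]
    all_total = 0.0
    L = N.sum()
    for i, n in enumerate(order):
        if n == lineage.root:
            continue
        s = counts[i].sum()
        all_total += s * (L - s)
        totals += counts[i] * (N - counts[i])
    n_pairs = {t: int(N[t_index[t]] * (N[t_index[t]] - 1) // 2) for t in types}
    per_type = {t: float(totals[t_index[t]]) for t in types}
    return float(all_total), int(L * (L - 1) // 2), per_type, n_pairs


def clonality(lineage: CellLineage, excluded=frozenset(),
              form: str = "ratio_of_means") -> ClonalityResult:
    """Clonality index C; larger C means lineally more clustered types.

    Types with fewer than two terminal cells contribute no within-type pair
    and are skipped; T counts contributing types only.
    """
    if form not in ("ratio_of_means", "ratio_of_sums"):
        raise DegenerateInputError(f"unknown clonality form {form!r}")
    all_total, n_all_pairs, per_type, n_pairs = _pair_distance_sums(
        lineage, excluded)
    contributing = [t for t in per_type if n_pairs[t] >= 1]
    if not contributing:
        raise DegenerateInputError("no cell type has two or more terminal cells")
    mean_all = all_total / n_all_pairs
    within_means = {t: per_type[t] / n_pairs[t] for t in contributing}
    if form == "ratio_of_means":
        C = sum(mean_all / within_means[t] for t in contributing) / len(contributing)
    else:
        C = sum(all_total / per_type[t] for t in contributing) / len(contributing)
    return ClonalityResult(C=float(C), total_pair_sum=all_total,
                           within_type_means=within_means,
                           T=len(contributing), form=form)


# ---------------------------------------------------------------------- #
def rare_early_correlation(lineage: CellLineage, excluded=frozenset()
                           ) -> CorrelationResult:
    """Spearman correlation between terminal-cell depth and its type's size.

    Positive rho means rare types appear shallow (early) and common types
    deep.  Excluded (apoptotic) types are left out, matching the robustness
    denominator.
    """
    census = lineage.census(excluded).included
    d = lineage.depths()
    pts = [(d[c], census[t]) for c, t in lineage.leaf_types.items()
           if t in census]
    return rare_early_from_sizes([p[0] for p in pts], [p[1] for p in pts])


def rare_early_from_sizes(depths, sizes) -> CorrelationResult:
    depths = np.asarray(depths, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if depths.size < 2:
        raise DegenerateInputError("need at least two terminal cells")
    if np.ptp(depths) == 0 or np.ptp(sizes) == 0:
        return CorrelationResult(rho=float("nan"), n=depths.size, degenerate=True)
    rho, p = stats.spearmanr(depths, sizes)
    return CorrelationResult(rho=float(rho), n=depths.size, p_value=float(p))


# ---------------------------------------------------------------------- #
def _same_type_pairs_with_coords(lineage: CellLineage, coords: SpatialMap
                                 ) -> List[Tuple[str, str]]:
    by_type: Dict[str, List[str]] = {}
    for c, t in lineage.leaf_types.items():
        if c in coords:
            by_type.setdefault(t, []).append(c)
    pairs = []
    for cells in by_type.values():
        cells = sorted(cells)
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                pairs.append((cells[i], cells[j]))
    return pairs


def physical_lineal_correlation(lineage: CellLineage, coords: SpatialMap
                                ) -> CorrelationResult:
    """Spearman rho between physical and lineal distance of same-type pairs."""
    pairs = _same_type_pairs_with_coords(lineage, coords)
    if not pairs:
        raise DegenerateInputError("no same-type terminal pair has coordinates")
    phys = np.array([np.linalg.norm(coords[a] - coords[b]) for a, b in pairs])
    lin = np.array([lineal_distance(lineage, a, b) for a, b in pairs],
                   dtype=float)
    if np.ptp(phys) == 0 or np.ptp(lin) == 0:
        return CorrelationResult(rho=float("nan"), n=len(pairs), degenerate=True)
    rho, p = stats.spearmanr(phys, lin)
    return CorrelationResult(rho=float(rho), n=len(pairs), p_value=float(p))


# ---------------------------------------------------------------------- #
def count_twins(lineage: CellLineage) -> Tuple[int, List[Tuple[str, str]]]:
    """Terminal sibling pairs sharing their immediate progenitor and type."""
    pairs = []
    for node, (a, b) in lineage.children.items():
        if (a in lineage.leaf_types and b in lineage.leaf_types
                and lineage.leaf_types[a] == lineage.leaf_types[b]):
            pairs.append((a, b))
    return len(pairs), pairs


def twin_spatial_zscore(lineage: CellLineage, coords: SpatialMap,
                        reps: int = 100, seed=None) -> float:
    """Z of the mean twin physical distance against random same-type pairs.

    Negative Z means twins sit physically closer than random same-type
    pairs.  Per replicate, one random distinct same-type pair is drawn for
    every observed twin pair (matching the type composition), and the Z uses
    the mean and sd of the replicate-wise means.
    """
    _, twins = count_twins(lineage)
    twins = [(a, b) for a, b in twins if a in coords and b in coords]
    if not twins:
        raise DegenerateInputError("no twin pair has coordinates")
    rng = as_rng(seed)
    obs = float(np.mean([np.linalg.norm(coords[a] - coords[b])
                         for a, b in twins]))
    by_type: Dict[str, List[str]] = {}
    for c, t in lineage.leaf_types.items():
        if c in coords:
            by_type.setdefault(t, []).append(c)
    rep_means = np.empty(reps)
    for r in range(reps):
        ds = []
        for a, b in twins:
            cells = by_type[lineage.leaf_types[a]]
            i, j = rng.choice(len(cells), size=2, replace=False)
            ds.append(np.linalg.norm(coords[cells[i]] - coords[cells[j]]))
        rep_means[r] = np.mean(ds)
    sd = rep_means.std(ddof=1)
    if not sd > 0:
        raise DegenerateInputError("null distances have zero variance")
    return float((obs - rep_means.mean()) / sd)


# ---------------------------------------------------------------------- #
def hill_climb_rho(lineage: CellLineage, coords: SpatialMap,
                   rounds: int = 100, candidates: int = 100, seed=None
                   ) -> Tuple[CellLineage, float, List[float]]:
    """Greedy search for a higher physical-lineal correlation.

    Each round examines ``candidates`` lineages that differ from the current
    one by a single swap of two terminal cells of the same depth and the
    same type, and keeps the best if it improves rho; rho never decreases.
    Returns (lineage, final rho, per-round rho trace).
    """
    rng = as_rng(seed)
    d = lineage.depths()
    # swappable groups: same (depth, type), >= 2 members with coordinates
    groups: Dict[Tuple[int, str], List[str]] = {}
    for c, t in lineage.leaf_types.items():
        groups.setdefault((d[c], t), []).append(c)
    groups = {k: sorted(v) for k, v in groups.items() if len(v) >= 2}
    base = physical_lineal_correlation(lineage, coords)
    if not groups or base.degenerate:
        return lineage, base.rho, [base.rho]

    # cells permute within type; the position sets per type are fixed, so we
    # track cell -> position and recompute rho from per-type distance blocks
    pairs = _same_type_pairs_with_coords(lineage, coords)
    phys = np.array([np.linalg.norm(coords[a] - coords[b]) for a, b in pairs])
    pos_of = {c: c for c in lineage.leaf_types}   # identity at the start

    def rho_of(pos_map) -> float:
        lin = np.array([lineal_distance(lineage, pos_map[a], pos_map[b])
                        for a, b in pairs], dtype=float)
        return float(stats.spearmanr(phys, lin).statistic)

    current = rho_of(pos_of)
    trace = [current]
    keys = sorted(groups)
    for _ in range(int(rounds)):
        best_rho, best_swap = current, None
        for _ in range(int(candidates)):
            key = keys[int(rng.integers(0, len(keys)))]
            cells = groups[key]
            i, j = rng.choice(len(cells), size=2, replace=False)
            u, v = cells[i], cells[j]
            pos_of[u], pos_of[v] = pos_of[v], pos_of[u]
            r = rho_of(pos_of)
            pos_of[u], pos_of[v] = pos_of[v], pos_of[u]
            if r > best_rho:
                best_rho, best_swap = r, (u, v)
        if best_swap is None:
            trace.append(current)
            continue
        u, v = best_swap
        pos_of[u], pos_of[v] = pos_of[v], pos_of[u]
        current = best_rho
        trace.append(current)
    assignment = {pos: cell for cell, pos in pos_of.items()}
    return lineage.relabel(assignment), current, trace


# ---------------------------------------------------------------------- #
def read_coords(path) -> SpatialMap:
    """Coordinates TSV with header: cell <tab> x <tab> y <tab> z."""
    out: SpatialMap = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("cell"):
            raise MappingError(f"{path}: coordinate TSV requires a header row")
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise MappingError(f"{path}:{lineno}: expected 4 columns")
            out[parts[0]] = np.array([float(x) for x in parts[1:]])
            if not np.all(np.isfinite(out[parts[0]])):
                raise MappingError(f"{path}:{lineno}: non-finite coordinate")
    return out


def write_coords(path, coords: SpatialMap) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tx\ty\tz\n")
        for cell in sorted(coords):
            x, y, z = coords[cell]
            fh.write(f"{cell}\t{x:.6g}\t{y:.6g}\t{z:.6g}\n")
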