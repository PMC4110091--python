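"""Synthetic lineages, expression matrices and coordinates for every stage.

The packaged census files carry only the per-type terminal-cell counts of
the published lineages (embryonic and post-embryonic C. elegans, P. marina,
H. roretzi); no tree structure, coordinates or expression values are claimed
as real data — all of those are generated here with controllable structure:

* rare-early strength  — probability that the depth-sorted slot order is
  respected when rare types are placed shallow;
* twin enrichment      — factor (>= 1) inflating same-type sibling pairs;
* expression separation — gap between cluster means in within-cluster sds;
* clustering strength  — weight of a recursive tree embedding in the 3-D
  coordinates, linking physical to lineal proximity;
* twin adjacency       — contraction of twin pairs toward their midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._rng import as_rng
from .errors import ConstraintError, DegenerateInputError
from .features import SpatialMap, count_twins
from .lineage import CellLineage, CellTypeCensus, parse_lineage
from .randomize import COALESCENT, RandomizationMode, randomize_lineage
from .expression import Partition

__all__ = [
    "SyntheticSpec",
    "toy_lineages",
    "synth_lineage",
    "synth_expression",
    "synth_coords",
    "load_census",
    "CENSUS_NAMES",
]

CENSUS_NAMES = (
    "celegans_embryonic",
    "celegans_embryonic_neuron_subtypes",
    "celegans_postembryonic",
    "pmarina",
    "hroretzi",
)

_APOPTOTIC = {"death"}


def load_census(name: str) -> CellTypeCensus:
    """Packaged per-type terminal counts of the published lineages."""
    if name not in CENSUS_NAMES:
        raise DegenerateInputError(f"unknown census {name!r}; have {CENSUS_NAMES}")
    counts: Dict[str, int] = {}
    text = resources.files("linrob.data").joinpath(f"{name}.tsv").read_text()
    for line in text.splitlines():
        if not line.strip():
            continue
        t, n = line.split("\t")
        counts[t] = int(n)
    excluded = frozenset(_APOPTOTIC & set(counts))
    return CellTypeCensus(counts=counts, excluded=excluded)


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SyntheticSpec:
    census: CellTypeCensus
    mode: RandomizationMode = field(
        default_factory=lambda: RandomizationMode(COALESCENT))
    rare_early_strength: float = 0.0
    twin_enrichment: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.rare_early_strength < 0 or self.twin_enrichment < 0:
            raise DegenerateInputError("strengths must be >= 0")


@dataclass(frozen=True)
class ToyLineage:
    """A hand-sized fixture with its analytically known statistics."""

    lineage: CellLineage
    oracle: Dict[str, float]


def toy_lineages() -> Dict[str, ToyLineage]:
    """Canonical small fixtures with exhaustively verified statistics.

    The stored oracle values are cross-checks; tests recompute them with
    brute-force enumeration.
    """
    tl1 = parse_lineage("((A1,A2),(B1,B2));",
                        {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
    tl2 = parse_lineage("((A1,B1),(A2,B2));",
                        {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
    rare = parse_lineage("((B1,B2),A1);", {"A1": "A", "B1": "B", "B2": "B"})
    # 16-terminal, 4-type lineage with rare types shallow and one clonal and
    # one dispersed common type
    nwk = ("(((G1,G2),((M1,M2),(M3,M4))),"
           "(((N1,E1),(N2,E2)),((N3,E3),((N4,E4),(N5,N6)))));")
    tmap = {"G1": "G", "G2": "G"}
    tmap.update({f"M{i}": "M" for i in range(1, 5)})
    tmap.update({f"N{i}": "N" for i in range(1, 7)})
    tmap.update({f"E{i}": "E" for i in range(1, 5)})
    fig = parse_lineage(nwk, tmap)
    return {
        "TL1": ToyLineage(tl1, {"f_n": 1 / 3, "f_p_at_third": 8 / 27,
                                "complexity": 3, "C": 5 / 3, "twins": 2}),
        "TL2": ToyLineage(tl2, {"f_n": 2.5 / 6, "f_p_at_third": 4 / 9,
                                "complexity": 2, "C": 5 / 6, "twins": 0}),
        "RARE3": ToyLineage(rare, {"rho_rare_early": 1.0}),
        "FIG16": ToyLineage(fig, {"L": 16}),
    }


# ---------------------------------------------------------------------- #
def synth_lineage(spec: SyntheticSpec) -> CellLineage:
    """A lineage whose terminal census equals ``spec.census`` exactly.

    Topology comes from the requested randomization mode (free coalescence
    by default); terminal identities are then arranged so that rare types
    sit shallow with probability ``rare_early_strength`` and same-type twin
    pairs are enriched by ``twin_enrichment``.
    """
    rng = as_rng(spec.seed)
    cells = spec.census.cells()
    types = dict(cells)
    skeleton_children = _random_topology(list(types), rng)
    lineage = CellLineage(skeleton_children, types)
    if spec.mode.tag != COALESCENT:
        lineage = randomize_lineage(lineage, spec.mode, rng)

    s = min(spec.rare_early_strength, 1.0)
    if s > 0:
        lineage = _arrange_rare_early(lineage, s, rng)
    if spec.twin_enrichment > 1:
        lineage = _enrich_twins(lineage, spec.twin_enrichment, rng)
    if lineage.census().counts != spec.census.counts:
        raise ConstraintError("terminal census was not conserved")  # pragma: no cover
    return lineage


def _random_topology(cells: List[str], rng) -> Dict[str, Tuple[str, str]]:
    pool = list(cells)
    children: Dict[str, Tuple[str, str]] = {}
    serial = 0
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        if i > j:
            i, j = j, i
        serial += 1
        node = f"_s{serial}"
        children[node] = (pool[i], pool[j])
        pool[i] = node
        pool[j] = pool[-1]
        pool.pop()
    return children


def _arrange_rare_early(lineage: CellLineage, s: float, rng) -> CellLineage:
    census = lineage.census().counts
    d = lineage.depths()
    positions = sorted(lineage.leaves, key=lambda c: (d[c], rng.random()))
    cells = sorted(lineage.leaves,
                   key=lambda c: (census[lineage.leaf_types[c]], rng.random()))
    cells = np.array(cells, dtype=object)
    free = rng.random(len(cells)) >= s
    idx = np.flatnonzero(free)
    cells[idx] = cells[rng.permutation(idx)]
    return lineage.relabel(dict(zip(positions, cells)))


def _enrich_twins(lineage: CellLineage, factor: float, rng) -> CellLineage:
    """Convert mixed-type sibling pairs into twins via same-depth swaps."""
    d = lineage.depths()
    types = dict(lineage.leaf_types)
    children = lineage.children
    sib_pairs = [(a, b) for a, b in children.values()
                 if a in types and b in types]
    attempts = int((factor - 1) * max(1, len(sib_pairs)) / 2)
    assignment = {c: c for c in types}          # position -> cell
    cell_types = dict(types)                    # by cell id

    pos_type = dict(types)                      # type currently at a position
    by_depth: Dict[int, List[str]] = {}
    for leaf in types:
        by_depth.setdefault(d[leaf], []).append(leaf)
    for _ in range(attempts):
        mixed = [(a, b) for a, b in sib_pairs if pos_type[a] != pos_type[b]]
        if not mixed:
            break
        a, b = mixed[int(rng.integers(0, len(mixed)))]
        want = pos_type[a]
        options = [p for p in by_depth[d[b]]
                   if pos_type[p] == want and p not in (a, b)]
        if not options:
            continue
        c = options[int(rng.integers(0, len(options)))]
        pos_type[b], pos_type[c] = pos_type[c], pos_type[b]
        assignment[b], assignment[c] = assignment[c], assignment[b]
    return lineage.relabel(assignment, types=cell_types)


# ---------------------------------------------------------------------- #
def synth_expression(partition: Partition, separation: float, seed=None,
                     n_genes: int = 20) -> pd.DataFrame:
    """Gaussian expression with planted cluster structure.

    Cluster j's mean vector is ``separation`` (in units of the within-cluster
    standard deviation, which is 1) along gene axis j; independent unit
    Gaussian noise is added per cell and gene.
    """
    if separation < 0:
        raise DegenerateInputError("separation must be >= 0")
    rng = as_rng(seed)
    labels = sorted(set(partition.labels.values()))
    n_genes = max(n_genes, len(labels))
    centers = {lab: np.eye(n_genes)[i % n_genes] * separation
               for i, lab in enumerate(labels)}
    cells = partition.cells
    data = np.empty((len(cells), n_genes))
    for i, c in enumerate(cells):
        data[i] = centers[partition.labels[c]] + rng.normal(size=n_genes)
    return pd.DataFrame(data, index=cells,
                        columns=[f"g{j:03d}" for j in range(n_genes)])


def synth_coords(lineage: CellLineage, clustering_strength: float = 0.0,
                 twin_adjacency: float = 0.0, seed=None) -> SpatialMap:
    """3-D nucleus coordinates with controllable planted structure.

    Every cell sits near its type's center (uniform in a 10-unit box) with
    unit Gaussian spread.  ``clustering_strength`` adds a recursive tree
    embedding so that lineally close cells are physically close, planting a
    positive physical-lineal correlation; ``twin_adjacency`` pulls each twin
    pair toward its midpoint.
    """
    if clustering_strength < 0 or twin_adjacency < 0:
        raise DegenerateInputError("strengths must be >= 0")
    rng = as_rng(seed)
    types = sorted(set(lineage.leaf_types.values()))
    centers = {t: rng.uniform(0.0, 10.0, size=3) for t in types}

    embed: Dict[str, np.ndarray] = {lineage.root: np.zeros(3)}
    d = lineage.depths()
    for node in reversed(lineage.postorder()):   # parents before children
        if node in lineage.children:
            for c in lineage.children[node]:
                step = rng.normal(size=3)
                step *= (0.7 ** d[c]) * 2.0 / np.linalg.norm(step)
                embed[c] = embed[node] + step

    coords: SpatialMap = {}
    for c, t in lineage.leaf_types.items():
        coords[c] = (centers[t] + clustering_strength * embed[c]
                     + rng.normal(size=3))
    if twin_adjacency > 0:
        _, twins = count_twins(lineage)
        shrink = 1.0 / (1.0 + twin_adjacency)
        for a, b in twins:
            mid = (coords[a] + coords[b]) / 2
            coords[a] = mid + (coords[a] - mid) * shrink
            coords[b] = mid + (coords[b] - mid) * shrink
    return coords
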