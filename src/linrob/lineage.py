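"""Rooted binary cell-lineage trees: data model, I/O and core computations.

A developmental cell lineage is a rooted binary tree whose leaves are
terminal cells carrying a cell-type label and whose internal nodes are
progenitor cells.  The zygote (root) sits at depth 0 and every cell division
adds one to the depth.  Division *programs* are inferred recursively: the
program of an internal cell is the unordered pair of the fates of its two
daughters, where the fate of a terminal cell is its type and the fate of an
internal cell is its own program.  The number of distinct programs is the
lineage's complexity.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import dendropy

from .errors import (
    DegenerateInputError,
    MappingError,
    NewickParseError,
    StructureError,
)

__all__ = [
    "CellLineage",
    "CellTypeCensus",
    "ProgramAssignment",
    "parse_lineage",
    "node_depths",
    "theoretical_min_max_depth",
    "lineal_distance",
    "infer_programs",
    "read_type_map",
    "write_type_map",
]


class CellLineage:
    """A rooted binary tree with typed terminal cells.

    Parameters
    ----------
    children
        Map of internal-cell id -> (left child id, right child id).  Child
        order is preserved (it defines the left-to-right layout used by the
        clonality-gradient randomizer) but carries no semantics elsewhere.
    leaf_types
        Map of terminal-cell id -> cell-type name.
    root
        Root id; inferred when omitted.
    """

    __slots__ = ("children", "leaf_types", "root", "parent", "_depths", "_leaves")

    def __init__(
        self,
        children: Mapping[str, Tuple[str, str]],
        leaf_types: Mapping[str, str],
        root: Optional[str] = None,
        validate: bool = True,
    ):
        self.children: Dict[str, Tuple[str, str]] = dict(children)
        self.leaf_types: Dict[str, str] = dict(leaf_types)
        self.parent: Dict[str, str] = {}
        for node, (a, b) in self.children.items():
            if a == b:
                raise StructureError(f"node {node!r} has duplicated child {a!r}")
            for c in (a, b):
                if c in self.parent:
                    raise StructureError(f"node {c!r} has more than one parent")
                self.parent[c] = node
        if root is None:
            roots = [n for n in list(self.children) + list(self.leaf_types)
                     if n not in self.parent]
            roots = sorted(set(roots))
            if len(roots) != 1:
                raise StructureError(f"expected exactly one root, found {roots}")
            root = roots[0]
        self.root = root
        self._depths: Optional[Dict[str, int]] = None
        self._leaves: Optional[List[str]] = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        if self.root not in self.children and self.root not in self.leaf_types:
            raise StructureError(f"root {self.root!r} is not a node of the tree")
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise StructureError(f"cycle detected at {n!r}")
            seen.add(n)
            if n in self.children:
                if n in self.leaf_types:
                    raise StructureError(f"internal node {n!r} carries a type label")
                stack.extend(self.children[n])
            elif n not in self.leaf_types:
                raise MappingError(f"terminal cell {n!r} has no type label")
        extra = (set(self.children) | set(self.leaf_types)) - seen
        if extra:
            raise StructureError(f"nodes unreachable from root: {sorted(extra)[:5]}")
        if len(self.children) != len(self.leaf_types) - 1 and len(self.leaf_types) > 1:
            raise StructureError(
                f"{len(self.children)} internal nodes for {len(self.leaf_types)} "
                "terminals (binary tree requires L - 1)"
            )

    # ------------------------------------------------------------------ #
    @property
    def L(self) -> int:
        """Number of terminal cells."""
        return len(self.leaf_types)

    # Alias used in randomization / macroevolution contexts.
    m = L

    @property
    def n_internal(self) -> int:
        return len(self.children)

    @property
    def n_all(self) -> int:
        """Total number of cells (terminal + internal)."""
        return self.L + self.n_internal

    @property
    def leaves(self) -> List[str]:
        """Terminal cells in left-to-right (in-order DFS) order."""
        if self._leaves is None:
            out: List[str] = []
            stack = [self.root]
            while stack:
                n = stack.pop()
                if n in self.children:
                    a, b = self.children[n]
                    stack.append(b)
                    stack.append(a)
                else:
                    out.append(n)
            self._leaves = out  # right child pushed first, so pops are left-to-right
        return list(self._leaves)

    def postorder(self) -> List[str]:
        """All nodes, children before parents."""
        out: List[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            if n in self.children:
                stack.extend(self.children[n])
        out.reverse()
        return out

    def depths(self) -> Dict[str, int]:
        """Depth (division count from the zygote) of every cell; root = 0."""
        if self._depths is None:
            d = {self.root: 0}
            stack = [self.root]
            while stack:
                n = stack.pop()
                if n in self.children:
                    for c in self.children[n]:
                        d[c] = d[n] + 1
                        stack.append(c)
            self._depths = d
        return dict(self._depths)

    @property
    def max_depth(self) -> int:
        d = self.depths()
        return max(d[leaf] for leaf in self.leaf_types)

    @property
    def mean_depth(self) -> float:
        d = self.depths()
        return sum(d[leaf] for leaf in self.leaf_types) / self.L

    def census(self, excluded: Iterable[str] = ()) -> "CellTypeCensus":
        return CellTypeCensus(
            counts=dict(Counter(self.leaf_types.values())),
            excluded=frozenset(excluded),
        )

    def subtree_leaves(self, node: str) -> List[str]:
        """Terminal descendants of ``node`` (a terminal is its own descendant)."""
        if node not in self.children and node not in self.leaf_types:
            raise MappingError(f"unknown cell {node!r}")
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n in self.children:
                stack.extend(self.children[n])
            else:
                out.append(n)
        return out

    # ------------------------------------------------------------------ #
    def relabel(self, assignment: Mapping[str, str],
                types: Optional[Mapping[str, str]] = None) -> "CellLineage":
        """Re-assign terminal cells to leaf positions.

        ``assignment`` maps each current leaf position (old leaf id) to the
        cell id that should occupy it.  Cell types travel with the cell ids
        (from this lineage, or from ``types`` when given).
        """
        types = dict(types) if types is not None else dict(self.leaf_types)
        if set(assignment) != set(self.leaf_types):
            raise MappingError("assignment must cover every leaf position exactly")
        new_children = {}
        for node, (a, b) in self.children.items():
            new_children[node] = (assignment.get(a, a), assignment.get(b, b))
        new_types = {assignment[old]: types[assignment[old]] for old in assignment}
        root = assignment.get(self.root, self.root)
        return CellLineage(new_children, new_types, root=root)

    def with_leaf_types(self, type_map: Mapping[str, str]) -> "CellLineage":
        """Same tree, terminal types replaced (e.g. by a reclassification)."""
        missing = set(self.leaf_types) - set(type_map)
        if missing:
            raise MappingError(f"cells missing from type map: {sorted(missing)[:5]}")
        return CellLineage(self.children,
                           {c: type_map[c] for c in self.leaf_types},
                           root=self.root)

    def copy(self) -> "CellLineage":
        return CellLineage(self.children, self.leaf_types, root=self.root,
                           validate=False)

    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        def fmt(n: str) -> str:
            if n in self.children:
                a, b = self.children[n]
                return f"({fmt(a)},{fmt(b)})"
            return n
        return fmt(self.root) + ";"

    def to_json(self, coords: Optional[Mapping[str, Tuple[float, ...]]] = None) -> str:
        """Single-container round-trip format (tree + types + coordinates)."""
        payload = {"newick": self.to_newick(), "types": self.leaf_types}
        if coords is not None:
            payload["coords"] = {c: list(map(float, xyz)) for c, xyz in coords.items()}
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str):
        payload = json.loads(text)
        lineage = parse_lineage(payload["newick"], payload["types"])
        coords = payload.get("coords")
        if coords is not None:
            import numpy as np
            coords = {c: np.asarray(xyz, dtype=float) for c, xyz in coords.items()}
        return lineage, coords

    def __repr__(self) -> str:
        return f"<CellLineage L={self.L} types={len(set(self.leaf_types.values()))}>"


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class CellTypeCensus:
    """Per-type terminal-cell counts with an apoptotic-exclusion set.

    The excluded types (typically programmed-death cells) keep their counts
    but do not enter the robustness product; ``T`` counts included types only.
    """

    counts: Dict[str, int]
    excluded: frozenset = frozenset()

    def __post_init__(self):
        for t, n in self.counts.items():
            if n < 1 or n != int(n):
                raise MappingError(f"census count for {t!r} must be a positive int")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def included(self) -> Dict[str, int]:
        return {t: n for t, n in self.counts.items() if t not in self.excluded}

    @property
    def T(self) -> int:
        return len(self.included)

    def cells(self, prefix: str = "t") -> List[Tuple[str, str]]:
        """Expand to a deterministic list of (cell id, type) pairs."""
        out = []
        i = 0
        for t in sorted(self.counts):
            for _ in range(self.counts[t]):
                out.append((f"{prefix}{i:05d}", t))
                i += 1
        return out


@dataclass(frozen=True)
class ProgramAssignment:
    """Canonical division program of every internal cell.

    Two internal cells share a program iff the unordered pair of their
    daughters' fates is identical; ``complexity`` is the number of distinct
    programs.
    """

    programs: Dict[str, tuple]          # internal cell -> canonical key
    usage: Dict[tuple, int] = field(default_factory=dict)

    @property
    def n_internal(self) -> int:
        return len(self.programs)

    @property
    def n_program(self) -> int:
        return len(self.usage)

    complexity = n_program


# ---------------------------------------------------------------------- #
def parse_lineage(newick_text: str, type_map: Mapping[str, str]) -> CellLineage:
    """Parse a Newick tree plus a cell->type map into a validated lineage.

    Branch lengths and internal-node labels are accepted and ignored.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickParseError(f"could not parse Newick: {exc}") from exc

    children: Dict[str, Tuple[str, str]] = {}
    leaf_types: Dict[str, str] = {}
    counter = [0]

    def walk(node) -> str:
        kids = node.child_nodes()
        if not kids:
            if node.taxon is None or not node.taxon.label:
                raise MappingError("unlabeled terminal cell in Newick")
            name = node.taxon.label
            if name in leaf_types:
                raise MappingError(f"duplicated terminal cell {name!r}")
            if name not in type_map:
                raise MappingError(f"terminal cell {name!r} missing from type map")
            leaf_types[name] = type_map[name]
            return name
        if len(kids) != 2:
            raise StructureError(
                f"internal node with {len(kids)} children (binary tree required)"
            )
        counter[0] += 1
        me = f"_i{counter[0]}"
        children[me] = (walk(kids[0]), walk(kids[1]))
        return me

    root = walk(tree.seed_node)
    return CellLineage(children, leaf_types, root=root)


def node_depths(lineage: CellLineage) -> Dict[str, int]:
    """Depth of every cell; root at 0, one per cell division."""
    return lineage.depths()


def theoretical_min_max_depth(L: int) -> int:
    """Smallest achievable maximum depth of a binary lineage with L terminals.

    Equals the ceiling of log2(L), attained by (near-)balanced trees.
    """
    if L < 1 or L != int(L):
        raise DegenerateInputError(f"L must be a positive integer, got {L!r}")
    return int(L - 1).bit_length()


def lineal_distance(lineage: CellLineage, cell_a: str, cell_b: str) -> int:
    """Number of edges on the tree path between two cells."""
    lineage.depths()
    depths = lineage._depths
    for c in (cell_a, cell_b):
        if c not in depths:
            raise MappingError(f"unknown cell {c!r}")
    a, b = cell_a, cell_b
    da, db = depths[a], depths[b]
    dist = 0
    while da > db:
        a = lineage.parent[a]
        da -= 1
        dist += 1
    while db > da:
        b = lineage.parent[b]
        db -= 1
        dist += 1
    while a != b:
        a = lineage.parent[a]
        b = lineage.parent[b]
        dist += 2
    return dist


def infer_programs(lineage: CellLineage) -> ProgramAssignment:
    """Bottom-up canonicalization of division programs.

    fate(terminal) = its type name; fate(internal) = the unordered
    (sorted) pair of its daughters' fates.  Child order never matters.
    """
    fate: Dict[str, tuple] = {}
    programs: Dict[str, tuple] = {}
    usage: Counter = Counter()
    for node in lineage.postorder():
        if node in lineage.leaf_types:
            fate[node] = ("t", lineage.leaf_types[node])
        else:
            a, b = lineage.children[node]
            key = ("p",) + tuple(sorted((fate[a], fate[b])))
            fate[node] = key
            programs[node] = key
            usage[key] += 1
    return ProgramAssignment(programs=programs, usage=dict(usage))


# ---------------------------------------------------------------------- #
def read_type_map(path) -> Dict[str, str]:
    """Two-column headerless TSV: cell-id <tab> type-name."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MappingError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_type_map(path, type_map: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for cell in sorted(type_map):
            fh.write(f"{cell}\t{type_map[cell]}\n")
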