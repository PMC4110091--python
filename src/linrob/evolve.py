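"""Macroevolution: stepwise lineage expansion under truncation selection.

The simulator mimics the evolutionary growth of a cell lineage: starting
from a single founder cell, terminal cells are added one per round by
bifurcating an existing terminal; one daughter inherits the parental type,
the other takes the next type from a pre-shuffled terminal-cell sequence
drawn from the target census.  Each round examines a tournament of candidate
bifurcations, ranks them by fitness, and the winner is drawn uniformly from
the top k — k/candidates is the selection intensity (k = candidates is
neutral evolution).

Fitness is R (necrosis robustness f_n), f_p-mode R, S = 1/complexity, or
R**x * S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._rng import as_rng
from .errors import DegenerateInputError
from .lineage import CellLineage, CellTypeCensus, infer_programs
from .features import rare_early_correlation
from .robustness import (
    RobustnessSpec,
    exact_program_failure_expectation,
    necrosis_robustness,
    program_failure_robustness,
)

__all__ = ["EvolutionConfig", "evolve_lineage", "mirror_evolve",
           "lineage_fitness", "mirror_lineage"]

_FITNESS_MODES = ("fn", "fp", "S", "RxS")


@dataclass(frozen=True)
class EvolutionConfig:
    """Tournament size, truncation threshold and fitness definition.

    The necrosis rate is one expected death per lineage and the program
    failure rate 1/N_internal, both recomputed as the lineage grows.  f_p is
    evaluated exactly while the program count stays small and by reduced
    Monte Carlo beyond that.
    """

    candidates: int = 100
    k: int = 100
    fitness: str = "fn"
    x: float = 1.0
    robustness: RobustnessSpec = field(default_factory=RobustnessSpec)
    fp_exact_max_programs: int = 12
    fp_replicates: int = 300
    mirror: bool = False

    def __post_init__(self):
        if not (1 <= self.k <= self.candidates):
            raise DegenerateInputError("need 1 <= k <= candidates")
        if self.fitness not in _FITNESS_MODES:
            raise DegenerateInputError(f"unknown fitness {self.fitness!r}")
        if self.x < 0:
            raise DegenerateInputError("exponent x must be >= 0")

    @property
    def selection_intensity(self) -> float:
        return self.k / self.candidates


def _fp(lineage: CellLineage, config: EvolutionConfig, rng) -> float:
    pa = infer_programs(lineage)
    if pa.n_program <= config.fp_exact_max_programs:
        return exact_program_failure_expectation(lineage, config.robustness)
    spec = replace(config.robustness, replicates=config.fp_replicates)
    return program_failure_robustness(lineage, spec, rng=rng)


def lineage_fitness(lineage: CellLineage, config: EvolutionConfig,
                    rng=None) -> float:
    """Fitness of a lineage under the configured definition."""
    if lineage.n_internal == 0:
        raise DegenerateInputError("fitness undefined for a single-cell lineage")
    rng = as_rng(rng)
    if config.fitness == "S":
        return 1.0 / infer_programs(lineage).n_program
    if config.fitness == "fp":
        return _fp(lineage, config, rng)
    R = necrosis_robustness(lineage, config.robustness)
    if config.fitness == "fn":
        return R
    S = 1.0 / infer_programs(lineage).n_program
    return (R ** config.x) * S


# ---------------------------------------------------------------------- #
def mirror_lineage(half: CellLineage) -> CellLineage:
    """Join two copies of a half lineage at a new root (bilateral symmetry)."""
    def side(tag: str):
        children = {f"{n}{tag}": (f"{a}{tag}", f"{b}{tag}")
                    for n, (a, b) in half.children.items()}
        types = {f"{c}{tag}": t for c, t in half.leaf_types.items()}
        return children, types, f"{half.root}{tag}"

    cl, tl, rl = side(".L")
    cr, tr, rr = side(".R")
    children = {**cl, **cr, "_mroot": (rl, rr)}
    return CellLineage(children, {**tl, **tr}, root="_mroot")


# ---------------------------------------------------------------------- #
def evolve_lineage(target_census: CellTypeCensus, config: EvolutionConfig,
                   seed=None, type_sequence: Optional[List[str]] = None
                   ) -> Tuple[CellLineage, pd.DataFrame]:
    """Grow a lineage matching the target census under selection.

    ``type_sequence`` (a pre-shuffled list of the census's terminal types)
    may be supplied to share one sequence across selection intensities for
    paired comparisons; by default it is drawn from ``seed``.
    """
    return _evolve(target_census, config, seed, type_sequence, mirror=False)


def mirror_evolve(target_half_census: CellTypeCensus, config: EvolutionConfig,
                  seed=None, type_sequence: Optional[List[str]] = None
                  ) -> Tuple[CellLineage, pd.DataFrame]:
    """Evolve one half lineage, scoring fitness on the mirrored whole."""
    return _evolve(target_half_census, config, seed, type_sequence, mirror=True)


def _evolve(census: CellTypeCensus, config: EvolutionConfig, seed,
            type_sequence, mirror: bool) -> Tuple[CellLineage, pd.DataFrame]:
    if not census.counts:
        raise DegenerateInputError("empty target census")
    rng = as_rng(seed)
    if type_sequence is None:
        type_sequence = [t for _, t in census.cells()]
        rng.shuffle(type_sequence)
    else:
        type_sequence = list(type_sequence)
        if sorted(type_sequence) != sorted(t for _, t in census.cells()):
            raise DegenerateInputError("type sequence does not match the census")
    m = len(type_sequence)

    children: Dict[str, Tuple[str, str]] = {}
    types: Dict[str, str] = {"c0": type_sequence[0]}
    serial = [0]
    records = []

    def snapshot(round_no: int, fitness: float) -> None:
        lin = CellLineage(children, types, validate=False)
        scored = mirror_lineage(lin) if mirror else lin
        pa = infer_programs(scored)
        fn = necrosis_robustness(scored, config.robustness)
        fp = (exact_program_failure_expectation(scored, config.robustness)
              if pa.n_program <= config.fp_exact_max_programs else float("nan"))
        try:
            rho = rare_early_correlation(scored, config.robustness.excluded)
        except DegenerateInputError:
            rho = None
        records.append({
            "round": round_no, "n_terminals": len(types), "fitness": fitness,
            "f_n": fn, "f_p": fp, "complexity": pa.n_program,
            "max_depth": scored.max_depth, "mean_depth": scored.mean_depth,
            "rho_rare_early": rho.rho if rho is not None else float("nan"),
        })

    for round_no in range(1, m):
        new_type = type_sequence[round_no]
        terminals = sorted(types)
        picks = rng.integers(0, len(terminals), size=config.candidates)
        # deduplicate identical candidate bifurcations for scoring: both the
        # parent terminal and daughter order fully determine the candidate
        fitness_cache: Dict[str, float] = {}
        cand_fit = np.empty(config.candidates)
        for ci, pi in enumerate(picks):
            parent = terminals[pi]
            if parent not in fitness_cache:
                cand = _apply_bifurcation(children, types, parent, new_type,
                                          serial, preview=True)
                scored = (mirror_lineage(cand) if mirror else cand)
                fitness_cache[parent] = lineage_fitness(scored, config, rng)
                serial[0] -= 2  # preview ids are rolled back
            cand_fit[ci] = fitness_cache[parent]
        # rank candidates; ties keep generation order (stable sort)
        order = np.argsort(-cand_fit, kind="stable")
        winner_ci = order[int(rng.integers(0, config.k))]
        winner_parent = terminals[picks[winner_ci]]
        _apply_bifurcation(children, types, winner_parent, new_type, serial,
                           preview=False)
        snapshot(round_no, float(cand_fit[winner_ci]))

    final = CellLineage(children, types)
    traj = pd.DataFrame.from_records(records)
    return final, traj


def _apply_bifurcation(children, types, parent: str, new_type: str, serial,
                       preview: bool):
    """Split terminal ``parent`` into an inheriting and a new-type daughter."""
    serial[0] += 2
    a, b = f"c{serial[0] - 1}", f"c{serial[0]}"
    if preview:
        new_children = dict(children)
        new_children[parent] = (a, b)
        new_types = dict(types)
        del new_types[parent]
        new_types[a] = types[parent]
        new_types[b] = new_type
        return CellLineage(new_children, new_types, validate=False)
    children[parent] = (a, b)
    t = types.pop(parent)
    types[a] = t
    types[b] = new_type
    return None
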