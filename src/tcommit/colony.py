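"""Proliferation level: agent-based colony simulation over a 120 h horizon.

Each cell is an agent carrying its own GRN copy and regulatory region.  A
colony starts from a single generation-0 cell in the progenitor (ETP) state;
every cell draws a generation-dependent division time, evolves its
transcriptional level first and then its epigenetic level over its lifetime,
and either divides into two daughters or is censored at the 120 h horizon.
Divisions occurring exactly at the horizon still count; their daughters are
zero-lifetime censored leaves.

At division all gene counts are copied to both daughters.  The regulatory
sites follow a conditional rule: if the mother ended life with X > 0 the
site counts are copied verbatim; if X = 0 the opening rule applies
independently per daughter — every closed site first becomes intermediate,
then every intermediate site (including the freshly converted ones) opens
with probability 1/2, and open sites stay open, so O' = O + Bin(C + I, 1/2).
Each X = 0 division therefore at least halves the distance of the open
fraction to 1, and the complete loss of X is the strong driving force for
opening the region over the following one to two generations.

Reproducibility: each cell's random stream is derived deterministically from
(colony root seed, cell id), with ids assigned structurally (root 0,
children 2i+1 and 2i+2), so colony results do not depend on traversal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .epigenetics import (EpigeneticParameters, RegionTrajectory,
                          RegulatoryRegion, is_region_open)
from .grn import (GeneState, GRNParameters, GRNTrajectory, KD_GENES,
                  apply_knockdown)

__all__ = [
    "DivisionTimeModel",
    "KnockdownSpec",
    "Cell",
    "LineageTree",
    "SimulationConfig",
    "draw_division_time",
    "inherit_region",
    "divide",
    "simulate_cell_lifetime",
    "simulate_colony",
    "run_ensemble",
    "colony_summary",
]

#: colony time horizon in hours
DEFAULT_HORIZON = 120.0


@dataclass(frozen=True)
class DivisionTimeModel:
    """Per-generation Gaussian division-time parameters (mu_g, sigma_g) in hours.

    Generations beyond the table use its last row.  Draws are resampled
    until strictly positive.
    """

    table: Tuple[Tuple[float, float], ...] = (
        (34.0, 13.0),  # g = 0
        (15.0, 5.0),   # g = 1
        (13.0, 5.0),   # g = 2
        (12.0, 4.0),   # g = 3
        (12.0, 3.0),   # g >= 4
    )

    def __post_init__(self):
        if not self.table:
            raise ValueError("division-time table must not be empty")
        for mu, sigma in self.table:
            if mu <= 0 or sigma < 0:
                raise ValueError("division-time means must be positive, sd >= 0")

    def params_for(self, generation: int) -> Tuple[float, float]:
        if generation < 0:
            raise ValueError("generation must be >= 0")
        return self.table[min(generation, len(self.table) - 1)]

    def draw(self, generation: int, rng: np.random.Generator) -> float:
        mu, sigma = self.params_for(generation)
        t = rng.normal(mu, sigma)
        while t <= 0.0:
            t = rng.normal(mu, sigma)
        return float(t)


def draw_division_time(generation: int, model: DivisionTimeModel,
                       rng: np.random.Generator) -> float:
    return model.draw(generation, rng)


@dataclass(frozen=True)
class KnockdownSpec:
    """A single-gene knockdown: production scaled by ``factor`` from ``onset``.

    With onset 0 the gene's initial count is scaled too.  An onset equal to
    the horizon is a degenerate no-op (nothing remains to simulate).
    """

    gene: str
    factor: float = 0.2
    onset: float = 0.0

    def __post_init__(self):
        if self.gene not in KD_GENES:
            raise ValueError(f"unknown knockdown gene {self.gene!r}")
        if not (0.0 < self.factor <= 1.0):
            raise ValueError("knockdown factor must lie in (0, 1]")
        if self.onset < 0:
            raise ValueError("knockdown onset must be >= 0")


@dataclass
class Cell:
    """One agent of the lineage tree.

    ``final_state`` and ``final_region`` hold the end-of-life ("before
    division") values; full trajectories are retained only when the
    configuration asks for them.  ``end == birth`` occurs only for cells
    born exactly at the horizon.
    """

    id: int
    parent: Optional[int]
    generation: int
    birth: float
    end: Optional[float] = None
    end_cause: Optional[str] = None  # "divided" | "censored"
    final_state: Optional[GeneState] = None
    final_region: Optional[RegulatoryRegion] = None
    children: Tuple[int, ...] = ()
    grn_trajectory: Optional[GRNTrajectory] = None
    region_trajectory: Optional[RegionTrajectory] = None

    @property
    def lifetime(self) -> float:
        if self.end is None:
            raise ValueError("cell not yet simulated")
        return self.end - self.birth

    @property
    def divided(self) -> bool:
        return self.end_cause == "divided"


@dataclass
class LineageTree:
    """Strictly binary rooted tree of completed cells for one colony."""

    cells: Dict[int, Cell]
    root_id: int = 0
    horizon: float = DEFAULT_HORIZON
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def root(self) -> Cell:
        return self.cells[self.root_id]

    def children(self, cell_id: int) -> Tuple[int, ...]:
        return self.cells[cell_id].children

    def leaves(self) -> List[Cell]:
        return [c for c in self.cells.values() if not c.children]

    def max_generation(self) -> int:
        return max(c.generation for c in self.cells.values())

    @property
    def n_divisions(self) -> int:
        """The colony's division count: the modal leaf generation.

        Division draws are per cell, so lineages within one colony reach
        different depths by the horizon; the number of divisions a typical
        surviving cell has undergone (the most common leaf generation,
        smallest on ties) is the colony-size statistic.  The deepest lineage
        is available separately as ``max_generation``.
        """
        gens = np.array([c.generation for c in self.leaves()])
        vals, counts = np.unique(gens, return_counts=True)
        return int(vals[np.argmax(counts)])

    def validate(self) -> None:
        roots = [c for c in self.cells.values() if c.parent is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise ValueError("tree must have exactly one root")
        n_internal = 0
        seen = set()
        stack = [self.root_id]
        while stack:
            cid = stack.pop()
            seen.add(cid)
            cell = self.cells[cid]
            if cell.end is None or cell.end < cell.birth:
                raise ValueError(f"cell {cid}: invalid lifetime")
            if cell.end > self.horizon + 1e-9:
                raise ValueError(f"cell {cid}: activity beyond the horizon")
            if cell.children:
                if len(cell.children) != 2:
                    raise ValueError(f"cell {cid}: tree must be strictly binary")
                if cell.end_cause != "divided":
                    raise ValueError(f"cell {cid}: children on a non-divided cell")
                n_internal += 1
                for ch in cell.children:
                    child = self.cells[ch]
                    if child.parent != cid:
                        raise ValueError(f"cell {ch}: parent link mismatch")
                    if child.birth != cell.end:
                        raise ValueError(f"cell {ch}: birth != parent end")
                    if child.generation != cell.generation + 1:
                        raise ValueError(f"cell {ch}: generation mismatch")
                    stack.append(ch)
            elif cell.end_cause == "divided":
                raise ValueError(f"cell {cid}: divided but no children")
        if seen != set(self.cells):
            raise ValueError("cells unreachable from the root")
        if len(self.cells) - n_internal != n_internal + 1:
            raise ValueError("leaf/internal counting identity violated")


@dataclass
class SimulationConfig:
    """Everything needed to simulate one colony.

    Defaults reproduce the wild-type setup: progenitor initial counts
    (R=1, T=2, G=1, P=5, X=8, N=7), a fully closed 500-site region, the
    fitted division-time table and a 120 h horizon.
    """

    grn: GRNParameters = field(default_factory=GRNParameters)
    epigenetic: EpigeneticParameters = field(default_factory=EpigeneticParameters)
    division: DivisionTimeModel = field(default_factory=DivisionTimeModel)
    initial_state: GeneState = field(
        default_factory=lambda: GeneState(R=1, T=2, G=1, P=5, X=8, N=7))
    initial_region: RegulatoryRegion = field(
        default_factory=lambda: RegulatoryRegion(C=500, I=0, O=0))
    horizon: float = DEFAULT_HORIZON
    knockdown: Optional[KnockdownSpec] = None
    seed: Optional[int] = None
    record_trajectories: bool = False

    def __post_init__(self):
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.knockdown is not None and self.knockdown.onset > self.horizon:
            raise ValueError("knockdown onset must not exceed the horizon")


def inherit_region(region: RegulatoryRegion, mother_X: int,
                   rng: np.random.Generator) -> RegulatoryRegion:
    """Daughter region at division.

    Mother X > 0: counts copied verbatim.  Mother X = 0: all closed sites
    become intermediate first, then every intermediate site (old and new)
    opens independently with probability 1/2 and open sites stay open, so
    C' = 0 and O' = O + Binomial(C + I, 1/2).  The draw is independent per
    daughter; site conservation holds on both branches.
    """
    if mother_X > 0:
        return region
    n_int = region.C + region.I
    opened = int(rng.binomial(n_int, 0.5)) if n_int else 0
    o_new = region.O + opened
    return RegulatoryRegion(C=0, I=region.S - o_new, O=o_new, S=region.S)


def _cell_rng(root_seed: int, cell_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=root_seed, spawn_key=(cell_id,)))


def divide(mother: Cell, rng_left: np.random.Generator,
           rng_right: np.random.Generator) -> Tuple[Cell, Cell]:
    """Create the two newborn daughters of a divided cell.

    Gene counts are copied (time reset to birth); regions follow
    ``inherit_region`` independently per daughter using each daughter's own
    stream.  The daughters are returned unsimulated (no end-of-life state).
    """
    if mother.end_cause != "divided":
        raise ValueError("divide() requires a cell that ended by division")
    daughters = []
    for k, rng in ((1, rng_left), (2, rng_right)):
        region = inherit_region(mother.final_region, mother.final_state.X, rng)
        daughters.append(Cell(
            id=2 * mother.id + k,
            parent=mother.id,
            generation=mother.generation + 1,
            birth=mother.end,
            final_state=replace(mother.final_state, t=mother.end),
            final_region=region,
        ))
    return daughters[0], daughters[1]


def simulate_cell_lifetime(cell: Cell, state: GeneState,
                           region: RegulatoryRegion, config: SimulationConfig,
                           rng: np.random.Generator,
                           kd_switch: float = math.inf,
                           params_after: Optional[GRNParameters] = None) -> Cell:
    """Simulate one cell from birth to division or censoring.

    Draws the division time for the cell's generation, runs the GRN SSA over
    the lifetime (with an optional knockdown switch at ``kd_switch``), then
    drives the region SSA from the resulting trajectory.  The completed cell
    records its end-of-life state and cause.
    """
    t_div = config.division.draw(cell.generation, rng)
    end = cell.birth + t_div
    if end <= config.horizon:
        cause = "divided"
    else:
        end = config.horizon
        cause = "censored"
    grn_seed = int(rng.integers(2**31))
    epi_seed = int(rng.integers(2**31))

    kd0 = config.grn.kd_array()
    kd1 = kd0 if params_after is None else params_after.kd_array()
    times, states = _kernels.grn_ssa(
        state.as_array(), float(cell.birth), float(end),
        config.grn.p_array(), config.grn.gamma_array(), kd0, kd1,
        float(kd_switch), grn_seed)
    rtimes, rstates, c, i_, o = _kernels.epi_ssa(
        int(region.C), int(region.I), int(region.O), int(region.S),
        times, states[:, 4].astype(float), states[:, 0].astype(float),
        states[:, 5].astype(float), float(cell.birth), float(end),
        *config.epigenetic.rate_tuple(), epi_seed,
        config.record_trajectories)

    cell.end = end
    cell.end_cause = cause
    cell.final_state = GeneState.from_array(states[-1], t=end)
    cell.final_region = RegulatoryRegion(C=int(c), I=int(i_), O=int(o),
                                         S=region.S)
    if config.record_trajectories:
        cell.grn_trajectory = GRNTrajectory(times=times, states=states,
                                            t_end=end)
        cell.region_trajectory = RegionTrajectory(times=rtimes, states=rstates,
                                                  t_end=end, S=region.S)
    return cell


def simulate_colony(config: SimulationConfig,
                    seed: Optional[int] = None) -> LineageTree:
    """Event-driven expansion of one colony from a single generation-0 cell.

    Every cell is simulated to division or to the horizon; divisions at
    exactly the horizon produce zero-lifetime censored daughters.  The
    knockdown in the configuration is applied globally: at onset 0 it scales
    the initial count and production before simulation, otherwise production
    switches for all live cells (and their descendants) at the onset time.
    """
    root_seed = seed if seed is not None else config.seed
    if root_seed is None:
        raise ValueError("a colony seed is required (config.seed or seed=)")
    root_seed = int(root_seed)

    params = config.grn
    state0 = config.initial_state
    kd_switch = math.inf
    params_after = None
    kd = config.knockdown
    if kd is not None and kd.factor < 1.0:
        if kd.onset <= 0.0:
            params, state0 = apply_knockdown(params, state0, kd.gene,
                                             kd.factor, scale_initial=True)
        elif kd.onset < config.horizon:
            params_after, _ = apply_knockdown(params, None, kd.gene, kd.factor)
            kd_switch = kd.onset
    cfg = replace(config, grn=params)

    cells: Dict[int, Cell] = {}
    root = Cell(id=0, parent=None, generation=0, birth=0.0)
    # (cell, birth gene state, birth region)
    stack: List[Tuple[Cell, GeneState, RegulatoryRegion]] = [
        (root, replace(state0, t=0.0), config.initial_region)]
    while stack:
        cell, state, region = stack.pop()
        rng = _cell_rng(root_seed, cell.id)
        if cell.parent is not None:
            # region inheritance consumes the first draws of the cell stream
            region = inherit_region(region, state.X, rng)
        cell = simulate_cell_lifetime(cell, state, region, cfg, rng,
                                      kd_switch=kd_switch,
                                      params_after=params_after)
        cells[cell.id] = cell
        if cell.divided:
            kids = []
            for k in (1, 2):
                child = Cell(id=2 * cell.id + k, parent=cell.id,
                             generation=cell.generation + 1, birth=cell.end)
                stack.append((child,
                              replace(cell.final_state, t=cell.end),
                              cell.final_region))
                kids.append(child.id)
            cell.children = tuple(kids)
    return LineageTree(cells=cells, root_id=0, horizon=config.horizon,
                       seed=root_seed)


def colony_summary(tree: LineageTree,
                   params: Optional[EpigeneticParameters] = None) -> dict:
    """Per-colony statistics over the cells alive at the horizon (the leaves)."""
    leaves = tree.leaves()
    n_open = sum(is_region_open(c.final_region, params) for c in leaves)
    return {
        "n_cells": len(tree),
        "n_leaves": len(leaves),
        "divisions": tree.n_divisions,
        "n_open_leaves": n_open,
        "fraction_open": n_open / len(leaves) if leaves else 0.0,
        "mean_x_horizon": float(np.mean([c.final_state.X for c in leaves]))
        if leaves else math.nan,
        "mean_open_fraction": float(np.mean(
            [c.final_region.open_fraction for c in leaves])) if leaves else math.nan,
    }


def run_ensemble(n_colonies: int, config: SimulationConfig, base_seed: int,
                 return_trees: bool = True):
    """Simulate ``n_colonies`` independently seeded colonies.

    Colony k's root seed is derived from (base_seed, k) through a
    SeedSequence, so the ensemble is reproducible and colonies are
    independent.  Returns (trees, summary DataFrame); ``trees`` is empty
    when ``return_trees`` is false.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    trees: List[LineageTree] = []
    rows = []
    for k in range(n_colonies):
        colony_seed = int(np.random.SeedSequence(
            entropy=int(base_seed), spawn_key=(k,)).generate_state(1)[0])
        tree = simulate_colony(config, seed=colony_seed)
        row = {"colony": k, "seed": colony_seed}
        row.update(colony_summary(tree, config.epigenetic))
        rows.append(row)
        if return_trees:
            trees.append(tree)
    return trees, pd.DataFrame(rows)
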