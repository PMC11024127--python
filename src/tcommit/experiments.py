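"""In silico experiment drivers: wild-type ensembles, knockdowns, delays.

These reproduce the study protocols at configurable ensemble sizes:
wild-type colony statistics (division counts, per-colony open fractions,
per-category expression means), single-gene knockdowns at 20 % production
from t = 0 (with the initial count scaled too), delayed knockdowns applied
to all live cells at a chosen onset, and the commitment-delay statistic —
how many generations pass between the loss of the Bcl11b-opposing function
X in a lineage and the first open cell below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .colony import (KnockdownSpec, LineageTree, SimulationConfig,
                     run_ensemble)
from .epigenetics import EpigeneticParameters
from .lca import (KIND_LCA, LCACategory, STATUS_OPEN, category_statistics,
                  classify_tree, tree_statuses, _open_subtree_distance)

__all__ = [
    "KnockdownSpec",
    "ExperimentReport",
    "wt_report",
    "knockdown_experiment",
    "delayed_kd_series",
    "delay_statistics",
    "preparatory_switch_generation",
]


@dataclass
class ExperimentReport:
    """Per-colony summaries for one simulated condition.

    ``colonies`` has one row per colony with division count, leaf count,
    fraction of open cells at the horizon and mean X over the cells alive at
    the horizon.
    """

    label: str
    colonies: pd.DataFrame
    seed: int

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def total_open_cells(self) -> int:
        return int(self.colonies["n_open_leaves"].sum())

    @property
    def n_colonies_with_open_cells(self) -> int:
        return int((self.colonies["n_open_leaves"] > 0).sum())

    @property
    def median_fraction_open(self) -> float:
        return float(self.colonies["fraction_open"].median())

    @property
    def median_mean_x(self) -> float:
        return float(self.colonies["mean_x_horizon"].median())

    def mean_x_iqr(self) -> float:
        q1, q3 = self.colonies["mean_x_horizon"].quantile([0.25, 0.75])
        return float(q3 - q1)

    def division_histogram(self) -> pd.Series:
        return self.colonies["divisions"].value_counts().sort_index()

    @property
    def modal_divisions(self) -> int:
        hist = self.division_histogram()
        return int(hist.idxmax())


def _ensemble_report(label: str, n_colonies: int, config: SimulationConfig,
                     seed: int, return_trees: bool):
    trees, summary = run_ensemble(n_colonies, config, base_seed=seed,
                                  return_trees=return_trees)
    return trees, ExperimentReport(label=label, colonies=summary, seed=int(seed))


def wt_report(n_colonies: int, config: SimulationConfig, seed: int,
              return_trees: bool = False):
    """Wild-type ensemble: per-colony report plus the pooled category table.

    Returns (report, category_table) or (report, category_table, trees).
    """
    cfg = replace(config, knockdown=None)
    trees, report = _ensemble_report("WT", n_colonies, cfg, seed,
                                     return_trees=True)
    cats = category_statistics(trees, params=cfg.epigenetic)
    if return_trees:
        return report, cats, trees
    return report, cats


def knockdown_experiment(spec: KnockdownSpec, n_colonies: int,
                         config: SimulationConfig, seed: int,
                         return_trees: bool = False):
    """Ensemble under a single-gene knockdown.

    Onset 0 scales the production factor and the initial count before
    simulation; a later onset leaves everything untouched until the onset
    time, then scales production for every live cell and its descendants.
    A factor of 1 reproduces the wild-type ensemble bit for bit.
    """
    cfg = replace(config, knockdown=spec)
    label = f"{spec.gene} KD f={spec.factor} t0={spec.onset}"
    trees, report = _ensemble_report(label, n_colonies, cfg, seed,
                                     return_trees=return_trees)
    if return_trees:
        return report, trees
    return report


def delayed_kd_series(gene: str, onsets: Sequence[float], n_per_onset: int,
                      config: SimulationConfig, seed: int,
                      factor: float = 0.2) -> Dict[float, ExperimentReport]:
    """One knockdown ensemble per onset time (ascending onsets required).

    Each onset gets an independent seed stream derived from ``seed``; an
    entry with factor 1 would equal the plain wild-type report.
    """
    if list(onsets) != sorted(onsets):
        raise ValueError("onsets must be sorted ascending")
    reports: Dict[float, ExperimentReport] = {}
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(onsets))
    for onset, child in zip(onsets, children):
        sub_seed = int(child.generate_state(1)[0])
        spec = KnockdownSpec(gene=gene, factor=factor, onset=float(onset))
        reports[float(onset)] = knockdown_experiment(
            spec, n_per_onset, config, sub_seed)
    return reports


def _x_loss_candidates(tree: LineageTree, f: Dict[int, float]) -> Dict[int, bool]:
    """Cells whose end-of-life X hits zero freshly (mother ended with X > 0,
    or root) and whose subtree contains an open cell."""
    out = {}
    for cid, cell in tree.cells.items():
        if cell.final_state.X != 0 or not math.isfinite(f[cid]):
            continue
        parent = cell.parent
        if parent is None or tree.cells[parent].final_state.X > 0:
            out[cid] = True
    return out


def delay_statistics(trees: Sequence[LineageTree],
                     params: Optional[EpigeneticParameters] = None
                     ) -> pd.DataFrame:
    """Commitment-delay table: one row per X-loss cell over all trees.

    For every open cell, its X-loss cell is the earliest ancestor (or the
    cell itself) whose end-of-life X is zero while its mother's was positive
    (the root qualifies if it ends with X = 0).  Each loss cell is counted
    once per colony; ``delay`` is the generation distance from the loss cell
    to the first open cell at or below it, and ``lca_order`` the loss cell's
    LCA order when it is classified as an LCA (NaN otherwise).  Colonies
    without open cells contribute nothing.
    """
    rows = []
    for k, tree in enumerate(trees):
        st = tree_statuses(tree, params)
        open_map = {cid: s == STATUS_OPEN for cid, s in st.items()}
        if not any(open_map.values()):
            continue
        f = _open_subtree_distance(tree, open_map)
        candidates = _x_loss_candidates(tree, f)
        cats = classify_tree(tree, params, statuses=st)
        loss_cells = set()
        for cid, is_open in open_map.items():
            if not is_open:
                continue
            # earliest qualifying ancestor-or-self on this open cell's path
            path = []
            cur: Optional[int] = cid
            while cur is not None:
                path.append(cur)
                cur = tree.cells[cur].parent
            for anc in reversed(path):  # root first
                if anc in candidates:
                    loss_cells.add(anc)
                    break
        for cid in sorted(loss_cells):
            cat = cats[cid]
            rows.append({
                "colony": k,
                "cell": cid,
                "generation": tree.cells[cid].generation,
                "delay": int(f[cid]),
                "lca_order": cat.order if cat.kind == KIND_LCA else np.nan,
            })
    return pd.DataFrame(rows, columns=["colony", "cell", "generation",
                                       "delay", "lca_order"])


def preparatory_switch_generation(tree: LineageTree, leaf_id: int) -> Optional[int]:
    """Generation at which the Tcf7/PU.1 switch is thrown along one lineage.

    Descriptive heuristic only: the first generation on the root-to-leaf
    path whose end-of-life Tcf7 exceeds PU.1 and stays above it for the rest
    of the lineage; None if the lineage never switches.
    """
    path = []
    cur: Optional[int] = leaf_id
    while cur is not None:
        path.append(tree.cells[cur])
        cur = tree.cells[cur].parent
    path.reverse()
    switched_from = None
    for cell in path:
        if cell.final_state.T > cell.final_state.P:
            if switched_from is None:
                switched_from = cell.generation
        else:
            switched_from = None
    return switched_from
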