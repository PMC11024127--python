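"""Hand-built annotated lineage trees and a brute-force LCA oracle.

The fixture trees are synthetic: their end-of-life gene counts and site
counts are representative values chosen so that each node carries the
intended status (open / closed with X / closed without X), not output of a
simulation.  They cover the documented corner cases of the category system:
an all-closed colony, an all-open colony, an order-1 LCA, the order-5 vs
order-6 asymmetric LCA, and a lineage that runs LCA -> closed post-LCA ->
LCA again.

``brute_force_lca_categories`` classifies by exhaustively enumerating every
cell's descendants (per daughter branch) and ancestors; it shares no code
with the production classifier and serves as its independent oracle.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .colony import Cell, LineageTree
from .epigenetics import RegulatoryRegion
from .grn import GeneState
from .lca import (KIND_LCA, KIND_OPEN, KIND_POST, KIND_PRE, LCACategory,
                  STATUS_OPEN, tree_statuses)

__all__ = [
    "SYNTHETIC_STATES",
    "build_status_tree",
    "fixture_trees",
    "random_status_tree",
    "brute_force_lca_categories",
]

#: synthetic end-of-life values realising each status letter:
#: "o" open region, "b" closed with X > 0 (black), "r" closed with X = 0 (red)
SYNTHETIC_STATES = {
    "o": (GeneState(R=2, T=110, G=4, P=0, X=0, N=7),
          RegulatoryRegion(C=10, I=90, O=400)),
    "b": (GeneState(R=1, T=3, G=1, P=5, X=6, N=7),
          RegulatoryRegion(C=420, I=60, O=20)),
    "r": (GeneState(R=1, T=90, G=3, P=0, X=0, N=7),
          RegulatoryRegion(C=150, I=250, O=100)),
}

TreeSpec = Union[str, Tuple[str, "TreeSpec", "TreeSpec"]]

_LIFETIME = 10.0  # hours per fixture cell; only ratios matter for the LCA logic


def build_status_tree(spec: TreeSpec) -> LineageTree:
    """Build an annotated LineageTree from a nested status spec.

    ``spec`` is a status letter for a leaf or a tuple
    ``(letter, left_spec, right_spec)`` for an internal cell.
    """
    cells: Dict[int, Cell] = {}
    max_end = 0.0

    def build(node: TreeSpec, cid: int, parent: Optional[int],
              generation: int, birth: float) -> None:
        nonlocal max_end
        letter = node if isinstance(node, str) else node[0]
        if letter not in SYNTHETIC_STATES:
            raise ValueError(f"unknown status letter {letter!r}")
        state, region = SYNTHETIC_STATES[letter]
        end = birth + _LIFETIME
        max_end = max(max_end, end)
        is_leaf = isinstance(node, str)
        cell = Cell(id=cid, parent=parent, generation=generation, birth=birth,
                    end=end, end_cause="censored" if is_leaf else "divided",
                    final_state=state, final_region=region)
        cells[cid] = cell
        if not is_leaf:
            _, left, right = node
            cell.children = (2 * cid + 1, 2 * cid + 2)
            build(left, 2 * cid + 1, cid, generation + 1, end)
            build(right, 2 * cid + 2, cid, generation + 1, end)

    build(spec, 0, None, 0, 0.0)
    tree = LineageTree(cells=cells, root_id=0, horizon=max_end)
    tree.validate()
    return tree


def _closed_chain(depth: int, tip: TreeSpec) -> TreeSpec:
    """A closed lineage of the given depth ending in ``tip``, with a closed
    leaf hanging off at every level."""
    node = tip
    for _ in range(depth):
        node = ("b", node, "b")
    return node


def fixture_trees() -> Dict[str, LineageTree]:
    """Deterministic small trees covering the category-system corner cases."""
    return {
        # no open cell anywhere: every cell is closed pre-LCA
        "all_closed": build_status_tree(
            ("b", ("b", "b", "r"), ("r", "b", "b"))),
        # every cell open
        "all_open": build_status_tree(
            ("o", ("o", "o", "o"), ("o", "o", "o"))),
        # both daughters open: the root is an order-1 LCA
        "order1": build_status_tree(("b", "o", "o")),
        # open at depth 5 in one branch, depth 6 in the other: LCA 5
        "order5_vs_6": build_status_tree(
            ("b", _closed_chain(4, "o"), _closed_chain(5, "o"))),
        # root LCA -> closed post-LCA child -> LCA grandchild (and open again)
        "post_lca_return": build_status_tree(
            ("b", "o", ("b", ("b", "o", "o"), "b"))),
    }


def random_status_tree(rng: np.random.Generator, max_depth: int = 5,
                       p_divide: float = 0.5, p_open: float = 0.25
                       ) -> LineageTree:
    """A random small annotated tree for classifier/oracle comparisons."""

    def grow(depth: int) -> TreeSpec:
        letter = ("o" if rng.random() < p_open
                  else ("b" if rng.random() < 0.5 else "r"))
        if depth < max_depth and rng.random() < p_divide:
            return (letter, grow(depth + 1), grow(depth + 1))
        return letter

    spec = grow(0)
    if isinstance(spec, str):  # ensure at least one division
        spec = (spec, grow(1), grow(1))
    return build_status_tree(spec)


def brute_force_lca_categories(tree: LineageTree,
                               statuses: Optional[Dict[int, str]] = None
                               ) -> Dict[int, LCACategory]:
    """Classify every cell by direct enumeration (oracle implementation).

    For each cell, all descendants of each daughter branch are enumerated
    with their generation distances, and all ancestors are walked explicitly;
    no results are shared between cells.
    """
    st = tree_statuses(tree, statuses=statuses)
    is_open = {cid: s == STATUS_OPEN for cid, s in st.items()}

    def branch_open_distances(child_id: int):
        """Distances (from the parent) of all open cells in this branch."""
        out = []
        frontier = [(child_id, 1)]
        while frontier:
            cid, d = frontier.pop()
            if is_open[cid]:
                out.append(d)
            for k in tree.children(cid):
                frontier.append((k, d + 1))
        return out

    lca_orders: Dict[int, int] = {}
    for cid in tree.cells:
        if is_open[cid]:
            continue
        kids = tree.children(cid)
        if len(kids) != 2:
            continue
        d_left = branch_open_distances(kids[0])
        d_right = branch_open_distances(kids[1])
        if d_left and d_right:
            lca_orders[cid] = min(min(d_left), min(d_right))

    cats: Dict[int, LCACategory] = {}
    for cid in tree.cells:
        if is_open[cid]:
            cats[cid] = LCACategory(KIND_OPEN)
        elif cid in lca_orders:
            cats[cid] = LCACategory(KIND_LCA, lca_orders[cid])
        else:
            # walk ancestors for the most recent LCA
            m = 0
            cur = tree.cells[cid].parent
            found = None
            while cur is not None:
                m += 1
                if cur in lca_orders:
                    found = m
                    break
                cur = tree.cells[cur].parent
            cats[cid] = (LCACategory(KIND_POST, found) if found is not None
                         else LCACategory(KIND_PRE))
    return cats
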