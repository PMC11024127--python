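"""Last-common-ancestor (LCA) classification of lineage trees.

Cells are compared through their relation to Bcl11b-open (committed) cells
rather than through absolute time or generation number, which vary widely
between colonies.  Every cell receives exactly one label, evaluated on its
end-of-life state:

* ``open`` — the regulatory region is open at the end of life.
* ``LCA n`` — a closed cell with at least one open descendant in *each* of
  its two daughter branches; the order n is the generation distance to the
  nearest open descendant (a daughter that is itself open is at distance 1).
* ``closed post-LCA m`` — a closed non-LCA cell with an LCA ancestor, m
  generations below its most recent LCA ancestor.
* ``closed pre-LCA`` — a closed cell with no LCA ancestor.

An open ancestor is never an LCA (LCAs are closed by definition), and a
closed cell whose open descendants all sit in one branch is never an LCA;
it falls to post- or pre-LCA by ancestry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .colony import Cell, LineageTree
from .epigenetics import EpigeneticParameters, is_region_open
from .grn import SPECIES_SHORT

__all__ = [
    "STATUS_OPEN",
    "STATUS_CLOSED_X_POSITIVE",
    "STATUS_CLOSED_X_ZERO",
    "LCACategory",
    "cell_status",
    "tree_statuses",
    "nearest_open_distance",
    "classify_tree",
    "category_statistics",
    "pooled_cell_table",
]

STATUS_OPEN = "open"
STATUS_CLOSED_X_POSITIVE = "closed_x_positive"
STATUS_CLOSED_X_ZERO = "closed_x_zero"

KIND_OPEN = "open"
KIND_LCA = "lca"
KIND_PRE = "closed_pre_lca"
KIND_POST = "closed_post_lca"


@dataclass(frozen=True)
class LCACategory:
    """One of: open, LCA n, closed pre-LCA, closed post-LCA m."""

    kind: str
    order: Optional[int] = None

    def __post_init__(self):
        if self.kind in (KIND_LCA, KIND_POST):
            if self.order is None or self.order < 1:
                raise ValueError(f"{self.kind} requires an order >= 1")
        elif self.order is not None:
            raise ValueError(f"{self.kind} does not carry an order")

    @property
    def label(self) -> str:
        if self.kind == KIND_OPEN:
            return "open"
        if self.kind == KIND_LCA:
            return f"LCA {self.order}"
        if self.kind == KIND_PRE:
            return "closed pre-LCA"
        return f"closed post-LCA {self.order}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "LCACategory":
        label = label.strip()
        if label == "open":
            return cls(KIND_OPEN)
        if label == "closed pre-LCA":
            return cls(KIND_PRE)
        if label.startswith("LCA "):
            return cls(KIND_LCA, int(label[4:]))
        if label.startswith("closed post-LCA "):
            return cls(KIND_POST, int(label[16:]))
        raise ValueError(f"unrecognised LCA category label {label!r}")


def cell_status(cell: Cell,
                params: Optional[EpigeneticParameters] = None) -> str:
    """End-of-life status: open region, or closed with / without X."""
    if cell.final_region is None or cell.final_state is None:
        raise ValueError(f"cell {cell.id} lacks end-of-life state; "
                         "cannot determine status")
    if is_region_open(cell.final_region, params):
        return STATUS_OPEN
    return (STATUS_CLOSED_X_POSITIVE if cell.final_state.X > 0
            else STATUS_CLOSED_X_ZERO)


def tree_statuses(tree: LineageTree,
                  params: Optional[EpigeneticParameters] = None,
                  statuses: Optional[Dict[int, str]] = None) -> Dict[int, str]:
    if statuses is not None:
        missing = set(tree.cells) - set(statuses)
        if missing:
            raise ValueError(f"missing statuses for cells {sorted(missing)[:5]}")
        return statuses
    return {cid: cell_status(c, params) for cid, c in tree.cells.items()}


def _ids_by_depth(tree: LineageTree) -> List[int]:
    """Cell ids ordered root-first (parents before children)."""
    order = []
    stack = [tree.root_id]
    while stack:
        cid = stack.pop()
        order.append(cid)
        stack.extend(tree.children(cid))
    return order


def _open_subtree_distance(tree: LineageTree,
                           open_map: Dict[int, bool]) -> Dict[int, float]:
    """f(cell) = generations from the cell to the nearest open node in its
    subtree, counting the cell itself as distance 0; inf if none."""
    order = _ids_by_depth(tree)
    f: Dict[int, float] = {}
    for cid in reversed(order):
        if open_map[cid]:
            f[cid] = 0.0
        else:
            kids = tree.children(cid)
            f[cid] = 1.0 + min((f[k] for k in kids), default=math.inf)
    return f


def nearest_open_distance(tree: LineageTree, cell_id: int,
                          params: Optional[EpigeneticParameters] = None,
                          statuses: Optional[Dict[int, str]] = None
                          ) -> Tuple[float, float]:
    """Per-daughter-branch minimal generation distance to an open descendant.

    A daughter that is itself open is at distance 1; a branch without any
    open cell yields inf.  Leaves return (inf, inf).
    """
    st = tree_statuses(tree, params, statuses)
    open_map = {cid: s == STATUS_OPEN for cid, s in st.items()}
    f = _open_subtree_distance(tree, open_map)
    kids = tree.children(cell_id)
    if not kids:
        return (math.inf, math.inf)
    return (1.0 + f[kids[0]], 1.0 + f[kids[1]])


def classify_tree(tree: LineageTree,
                  params: Optional[EpigeneticParameters] = None,
                  statuses: Optional[Dict[int, str]] = None
                  ) -> Dict[int, LCACategory]:
    """Assign every cell its LCA category (a partition of the tree)."""
    st = tree_statuses(tree, params, statuses)
    open_map = {cid: s == STATUS_OPEN for cid, s in st.items()}
    f = _open_subtree_distance(tree, open_map)

    order = _ids_by_depth(tree)
    is_lca: Dict[int, bool] = {}
    lca_order: Dict[int, int] = {}
    for cid in order:
        kids = tree.children(cid)
        if (not open_map[cid]) and len(kids) == 2 \
                and math.isfinite(f[kids[0]]) and math.isfinite(f[kids[1]]):
            is_lca[cid] = True
            lca_order[cid] = int(1 + min(f[kids[0]], f[kids[1]]))
        else:
            is_lca[cid] = False

    # distance (generations) up to the most recent LCA ancestor, if any
    up: Dict[int, Optional[int]] = {}
    for cid in order:
        parent = tree.cells[cid].parent
        if parent is None:
            up[cid] = None
        elif is_lca[parent]:
            up[cid] = 1
        elif up[parent] is not None:
            up[cid] = up[parent] + 1
        else:
            up[cid] = None

    cats: Dict[int, LCACategory] = {}
    for cid in order:
        if open_map[cid]:
            cats[cid] = LCACategory(KIND_OPEN)
        elif is_lca[cid]:
            cats[cid] = LCACategory(KIND_LCA, lca_order[cid])
        elif up[cid] is not None:
            cats[cid] = LCACategory(KIND_POST, up[cid])
        else:
            cats[cid] = LCACategory(KIND_PRE)
    return cats


def pooled_cell_table(trees: Sequence[LineageTree],
                      classifications: Optional[Sequence[Dict[int, LCACategory]]] = None,
                      params: Optional[EpigeneticParameters] = None
                      ) -> pd.DataFrame:
    """One row per cell over all trees: final counts, open fraction, category."""
    if classifications is None:
        classifications = [classify_tree(t, params) for t in trees]
    rows = []
    for k, (tree, cats) in enumerate(zip(trees, classifications)):
        for cid, cell in tree.cells.items():
            cat = cats[cid]
            row = {"colony": k, "cell": cid, "generation": cell.generation,
                   "category": cat.label, "kind": cat.kind, "order": cat.order}
            for name in SPECIES_SHORT:
                row[name] = getattr(cell.final_state, name)
            row["open_site_fraction"] = cell.final_region.open_fraction
            rows.append(row)
    return pd.DataFrame(rows)


def _category_sort_key(label: str) -> Tuple[int, int]:
    """Developmental order: pre-LCA, LCA 9..1, open; post-LCA 1..m after."""
    cat = LCACategory.from_label(label)
    if cat.kind == KIND_PRE:
        return (0, 0)
    if cat.kind == KIND_LCA:
        return (1, -cat.order)
    if cat.kind == KIND_OPEN:
        return (2, 0)
    return (3, cat.order)


def category_statistics(trees: Sequence[LineageTree],
                        classifications: Optional[Sequence[Dict[int, LCACategory]]] = None,
                        params: Optional[EpigeneticParameters] = None
                        ) -> pd.DataFrame:
    """Per-category counts plus mean and SD of the end-of-life values.

    Pools the cells of all trees; the SD uses ddof=1 and is NaN for
    single-cell categories (undefined, flagged rather than an error).
    Categories are reported in approximate developmental order.
    """
    table = pooled_cell_table(trees, classifications, params)
    value_cols = list(SPECIES_SHORT) + ["open_site_fraction"]
    out_rows = []
    for label, group in table.groupby("category"):
        row = {"category": label, "count": len(group)}
        for col in value_cols:
            row[f"mean_{col}"] = float(group[col].mean())
            row[f"sd_{col}"] = float(group[col].std(ddof=1))
        out_rows.append(row)
    df = pd.DataFrame(out_rows)
    if len(df):
        df = df.sort_values("category", key=lambda s: s.map(_category_sort_key),
                            ignore_index=True)
    total = sum(len(t) for t in trees)
    if len(df) and int(df["count"].sum()) != total:
        raise AssertionError("category counts do not partition the cells")
    return df
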