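"""Newick/NHX serialization of lineage trees.

Trees are written as standard Newick with the cell id as node label and the
cell lifetime (hours) as branch length, plus an NHX comment block per node
carrying the per-cell annotations: generation, birth/end times, end cause,
final gene counts, site counts, the status colour (white = open region,
black = closed with X > 0, red = closed with X = 0) and, optionally, the
LCA category.  Floats are written with ``repr`` so a round trip is
bit-identical.  Parsing uses dendropy for the Newick grammar and interprets
the NHX payload in-package; non-binary topologies are rejected and nodes
without annotations load with status "unknown" (classification then refuses
to run).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import dendropy

from .colony import Cell, LineageTree
from .epigenetics import EpigeneticParameters, RegulatoryRegion
from .grn import GeneState
from .lca import (LCACategory, STATUS_CLOSED_X_POSITIVE, STATUS_CLOSED_X_ZERO,
                  STATUS_OPEN, cell_status)

__all__ = ["export_tree", "parse_tree", "tree_to_newick", "status_colour"]

_COLOURS = {STATUS_OPEN: "white", STATUS_CLOSED_X_POSITIVE: "black",
            STATUS_CLOSED_X_ZERO: "red"}


def status_colour(cell: Cell,
                  params: Optional[EpigeneticParameters] = None) -> str:
    """Node colour: white = open, black = closed & X>0, red = closed & X=0."""
    return _COLOURS[cell_status(cell, params)]


def _fmt(x: float) -> str:
    return repr(float(x))


def _nhx_block(cell: Cell, params: Optional[EpigeneticParameters],
               category: Optional[LCACategory]) -> str:
    s = cell.final_state
    r = cell.final_region
    if s is None or r is None:
        raise ValueError(f"cell {cell.id} lacks end-of-life state")
    fields = [
        ("gen", str(cell.generation)),
        ("birth", _fmt(cell.birth)),
        ("end", _fmt(cell.end)),
        ("cause", cell.end_cause),
        ("R", str(s.R)), ("T", str(s.T)), ("G", str(s.G)),
        ("P", str(s.P)), ("X", str(s.X)), ("N", str(s.N)),
        ("C", str(r.C)), ("I", str(r.I)), ("O", str(r.O)), ("S", str(r.S)),
        ("color", status_colour(cell, params)),
    ]
    if category is not None:
        fields.append(("cat", category.label.replace(" ", "_")))
    return "[&&NHX:" + ":".join(f"{k}={v}" for k, v in fields) + "]"


def tree_to_newick(tree: LineageTree,
                   categories: Optional[Dict[int, LCACategory]] = None,
                   params: Optional[EpigeneticParameters] = None) -> str:
    """Serialize a lineage tree to a single-line Newick/NHX string."""

    def render(cid: int) -> str:
        cell = tree.cells[cid]
        kids = cell.children
        prefix = ""
        if kids:
            prefix = "(" + ",".join(render(k) for k in kids) + ")"
        cat = categories.get(cid) if categories else None
        return (f"{prefix}{cid}:{_fmt(cell.lifetime)}"
                f"{_nhx_block(cell, params, cat)}")

    return render(tree.root_id) + ";"


def export_tree(tree: LineageTree, path,
                categories: Optional[Dict[int, LCACategory]] = None,
                params: Optional[EpigeneticParameters] = None) -> None:
    """Write the tree to ``path`` as Newick/NHX (see module docstring)."""
    text = tree_to_newick(tree, categories, params)
    with open(path, "w") as fh:
        fh.write(text + "\n")


def _cell_from_node(node, cid: int, parent: Optional[int]) -> Tuple[Cell, Optional[str]]:
    ann: Dict[str, str] = {a.name: str(a.value) for a in node.annotations}
    length = node.edge.length
    if ann:
        state = GeneState(R=int(ann["R"]), T=int(ann["T"]), G=int(ann["G"]),
                          P=int(ann["P"]), X=int(ann["X"]), N=int(ann["N"]),
                          t=float(ann["end"]))
        region = RegulatoryRegion(C=int(ann["C"]), I=int(ann["I"]),
                                  O=int(ann["O"]), S=int(ann["S"]))
        cell = Cell(id=cid, parent=parent, generation=int(ann["gen"]),
                    birth=float(ann["birth"]), end=float(ann["end"]),
                    end_cause=ann["cause"], final_state=state,
                    final_region=region)
        cat = ann.get("cat")
        return cell, (cat.replace("_", " ") if cat else None)
    # bare Newick: reconstruct times from branch lengths, status unknown
    if length is None:
        raise ValueError(f"node {cid}: no NHX annotations and no branch length")
    cell = Cell(id=cid, parent=parent, generation=0, birth=0.0, end=None,
                end_cause=None, final_state=None, final_region=None)
    return cell, None


def parse_tree(path) -> Tuple[LineageTree, Dict[int, Optional[LCACategory]]]:
    """Parse a Newick/NHX file back into a LineageTree.

    Returns (tree, categories); ``categories`` maps a cell id to its stored
    LCA category or None.  Tree invariants are enforced on load and
    non-binary nodes are rejected.  Cells without annotations are loaded
    with unknown status (``final_state`` is None).
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              suppress_internal_node_taxa=True,
                              extract_comment_metadata=True)
    cells: Dict[int, Cell] = {}
    categories: Dict[int, Optional[LCACategory]] = {}

    def walk(node, parent: Optional[int]):
        label = node.label if node.label is not None else getattr(
            node.taxon, "label", None)
        if label is None:
            raise ValueError("node without a cell-id label")
        cid = int(label)
        n_children = len(node.child_nodes())
        if n_children not in (0, 2):
            raise ValueError(
                f"node {cid}: {n_children} children; lineage trees are "
                "strictly binary")
        cell, cat_label = _cell_from_node(node, cid, parent)
        if cell.end is None and node.edge.length is not None:
            # bare topology: synthesize times from branch lengths
            birth = cells[parent].end if parent is not None else 0.0
            gen = cells[parent].generation + 1 if parent is not None else 0
            cell.birth = birth
            cell.end = birth + float(node.edge.length)
            cell.generation = gen
            cell.end_cause = "divided" if n_children else "censored"
        if n_children:
            cell.end_cause = cell.end_cause or "divided"
        cells[cid] = cell
        categories[cid] = (LCACategory.from_label(cat_label)
                           if cat_label else None)
        kids = []
        for child in node.child_nodes():
            kids.append(walk(child, cid))
        cell.children = tuple(kids)
        return cid

    root_id = walk(dtree.seed_node, None)
    horizon = max(c.end for c in cells.values())
    tree = LineageTree(cells=cells, root_id=root_id, horizon=horizon)
    tree.validate()
    return tree, categories
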