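"""Readers and writers for graphs, forests, histories and run results.

Graphs travel as two-column tab-separated edge lists (``#`` comments
allowed; a ``# nodes:`` header preserves isolated nodes, which the
growth model can produce when a duplicate loses every copied edge).
Forests travel as Newick, one rooted tree per line, with integer leaf
labels; branch lengths and internal labels are ignored on read and
omitted on write.  Histories and run metadata travel as JSON.  All
writes are atomic: content goes to a temporary file in the target
directory which is then renamed into place.
"""

from __future__ import annotations

import io as _io
import json
import os
import tempfile
from pathlib import Path

import dendropy

from .types import DuplicationForest, GrowthHistory, PPIGraph

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_forest",
    "write_forest",
    "read_history",
    "write_history",
    "write_json",
    "atomic_write_text",
]


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename in the same directory."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".",
                               prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> PPIGraph:
    """Read an undirected simple graph from a two-column TSV edge list.

    Lines starting with ``#`` are comments, except a ``# nodes:``
    header which enumerates the full node set (needed to round-trip
    isolated nodes).  Duplicate rows collapse; self-loops are rejected
    (the model generates simple graphs without self-loops).
    """
    edges = set()
    nodes: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("nodes:"):
                    try:
                        nodes.update(int(tok)
                                     for tok in body[len("nodes:"):].split())
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: malformed nodes header") from None
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two integer "
                                 f"columns, got {line!r}")
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer node id "
                                 f"in {line!r}") from None
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop ({a}, {b}); "
                                 "the graph must be simple, without multiple "
                                 "edges and self-loops")
            edges.add((min(a, b), max(a, b)))
    return PPIGraph(edges=edges, nodes=nodes)


def write_edge_list(graph: PPIGraph, path) -> None:
    """Write a graph as a sorted, canonical two-column TSV edge list."""
    buf = _io.StringIO()
    buf.write("# nodes: " + " ".join(map(str, sorted(graph.nodes))) + "\n")
    for a, b in sorted(graph.edges):
        buf.write(f"{a}\t{b}\n")
    atomic_write_text(path, buf.getvalue())


# ---------------------------------------------------------------------------
# Newick forests
# ---------------------------------------------------------------------------

def _dendropy_node_to_tuple(node, path, lineno):
    children = node.child_nodes()
    if not children:
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label is not None:
            label = node.label
        try:
            leaf = int(label)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{lineno}: leaf label {label!r} is not "
                             "an integer node id") from None
        return leaf
    if len(children) != 2:
        raise ValueError(f"{path}:{lineno}: forest must be binary "
                         f"(found a node with {len(children)} children)")
    return tuple(_dendropy_node_to_tuple(c, path, lineno) for c in children)


def read_forest(path, require_two_trees: bool = True) -> DuplicationForest:
    """Read a duplication forest: one Newick tree per line.

    Leaf labels must be distinct integers; every internal node must
    have exactly two children.  Branch lengths are tolerated and
    discarded.  By default exactly two trees are required, because a
    history rooted at the two-node seed graph always yields two trees;
    pass ``require_two_trees=False`` for forests over general seeds.
    """
    trees = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                tree = dendropy.Tree.get(data=line, schema="newick",
                                         suppress_internal_node_taxa=True)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: Newick parse error: "
                                 f"{exc}") from None
            trees.append(_dendropy_node_to_tuple(tree.seed_node, path, lineno))
    if not trees:
        raise ValueError(f"{path}: no trees found")
    if require_two_trees and len(trees) != 2:
        raise ValueError(
            f"{path}: forest must contain exactly 2 trees when paired with "
            f"a seed-rooted history, found {len(trees)}")
    return DuplicationForest(trees)  # distinct-leaf check happens here


def _tuple_to_newick(tree) -> str:
    if not isinstance(tree, tuple):
        return str(tree)
    left, right = tree
    return f"({_tuple_to_newick(left)},{_tuple_to_newick(right)})"


def write_forest(forest: DuplicationForest, path) -> None:
    """Write a forest as Newick, one semicolon-terminated tree per line."""
    text = "".join(_tuple_to_newick(t) + ";\n" for t in forest.trees)
    atomic_write_text(path, text)


# ---------------------------------------------------------------------------
# Histories and generic JSON
# ---------------------------------------------------------------------------

def write_history(history: GrowthHistory, path) -> None:
    """Serialize a growth history (all intermediate states) to JSON."""
    payload = {
        "n_steps": history.n_steps,
        "anchors": list(map(int, history.anchors)),
        "duplicates": list(map(int, history.duplicates)),
        "graphs": [
            {"nodes": sorted(map(int, g.nodes)),
             "edges": [list(e) for e in sorted(g.edges)]}
            for g in history.graphs
        ],
        "forests": [
            [_tuple_to_newick(t) + ";" for t in f.trees]
            for f in history.forests
        ],
    }
    atomic_write_text(path, json.dumps(payload, indent=1) + "\n")


def _newick_string_to_tuple(text: str):
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)
    return _dendropy_node_to_tuple(tree.seed_node, "<history>", 0)


def read_history(path) -> GrowthHistory:
    with open(path) as fh:
        payload = json.load(fh)
    graphs = [PPIGraph(edges=[tuple(e) for e in g["edges"]],
                       nodes=g["nodes"]) for g in payload["graphs"]]
    forests = [DuplicationForest([_newick_string_to_tuple(t) for t in f])
               for f in payload["forests"]]
    return GrowthHistory(graphs=graphs, forests=forests,
                         anchors=payload["anchors"],
                         duplicates=payload["duplicates"])


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=1, default=_json_default)
                      + "\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
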