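"""Weighted directed graph view of the overlap matrix.

Each bin-group is a node; each strictly positive off-diagonal overlap score
becomes a directed weighted edge. No self-edges exist. Asymmetry of the two
directions of a pair is preserved verbatim — it carries information about
which group infiltrates which — so no symmetrisation is offered.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .overlap import OverlapMatrix

__all__ = ["to_graph", "write_graph", "read_graphml"]


def to_graph(m: OverlapMatrix, weight_threshold: float = 0.0) -> nx.DiGraph:
    """Overlap matrix as a :class:`networkx.DiGraph`.

    Nodes carry ``label`` (bin range or category) and ``size`` (point
    count); edges carry ``weight``. Edges with weight <= ``weight_threshold``
    are omitted (default keeps every positive edge); isolated nodes are
    kept, so the node set is always complete.
    """
    if not 0 <= weight_threshold < 1:
        raise ValueError("weight_threshold must lie in [0, 1)")
    g = nx.DiGraph()
    n = m.n_groups
    for i in range(n):
        g.add_node(i, label=m.node_labels[i], size=int(m.node_sizes[i]))
    src, dst = np.nonzero(m.m > weight_threshold)
    for i, j in zip(src.tolist(), dst.tolist()):
        g.add_edge(i, j, weight=float(m.m[i, j]))
    return g


def write_graph(g: nx.DiGraph, path, fmt: str = "graphml") -> None:
    """Serialise the overlap graph as GraphML or a 3-column TSV edge list."""
    path = Path(path)
    try:
        if fmt == "graphml":
            nx.write_graphml(g, path)
        elif fmt == "edgelist":
            with open(path, "w") as fh:
                fh.write("# source\ttarget\tweight\n")
                for u, v, w in g.edges.data("weight"):
                    fh.write(f"{u}\t{v}\t{w:.12g}\n")
        else:
            raise ValueError(f"unknown graph format {fmt!r}; use graphml or edgelist")
    except OSError as exc:
        raise OSError(f"could not write graph to {path}: {exc}") from exc


def read_graphml(path) -> nx.DiGraph:
    """Read back a GraphML overlap graph with integer node ids."""
    g = nx.read_graphml(path)
    return nx.relabel_nodes(nx.DiGraph(g), {n: int(n) for n in g.nodes})
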