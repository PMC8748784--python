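"""Exhaustive enumeration of unrooted binary tree topologies.

Used to validate the Robinson-Foulds implementation against brute force:
the (2n-5)!! distinct unrooted binary topologies on n labeled leaves are
generated by inserting one leaf at a time into every edge of every
smaller topology (3 x 5 x 7 = 105 trees for n = 6).
"""

from __future__ import annotations

import itertools

import networkx as nx


def all_unrooted_topologies(labels: list[str]) -> list[nx.Graph]:
    """All unrooted binary topologies with the given leaf labels.

    Leaves are the label strings; internal nodes are integers.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    counter = itertools.count()
    base = nx.Graph()
    center = next(counter)
    for leaf in labels[:3]:
        base.add_edge(center, leaf)
    trees = [base]
    for leaf in labels[3:]:
        grown = []
        for tree in trees:
            for u, v in list(tree.edges):
                t = tree.copy()
                t.remove_edge(u, v)
                w = next(counter)
                t.add_edge(u, w)
                t.add_edge(w, v)
                t.add_edge(w, leaf)
                grown.append(t)
        trees = grown
    return trees


def graph_to_nested(tree: nx.Graph, labels: list[str]):
    """Nested-tuple form rooted at the internal neighbor of the first
    leaf (multifurcating root; bipartition-equivalent to the unrooted
    topology)."""
    root = next(iter(tree.neighbors(labels[0])))

    def walk(node, parent):
        if isinstance(node, str):
            return node
        children = [n for n in tree.neighbors(node) if n != parent]
        return tuple(walk(c, node) for c in children)

    return walk(root, None)
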