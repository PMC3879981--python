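"""Shared test utilities: random tree generation and independent oracles.

The oracles here deliberately take different computational routes from the
library (edge-removal over a networkx graph instead of postorder leaf-set
accumulation, explicit set logic instead of rank bookkeeping) so that
agreement is informative.
"""

from __future__ import annotations

import math

import dendropy
import networkx as nx
import numpy as np

from clanprof.treeops import as_unrooted


def random_tree(labels, rng, with_lengths=True, support_rng=None):
    """Random topology over ``labels`` by random sequential joining."""
    parts = [f"{l}:{rng.uniform(0.05, 1.0):.4f}" if with_lengths else l for l in labels]
    rng.shuffle(parts)
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        support = "" if support_rng is None else str(int(support_rng.integers(0, 101)))
        length = f":{rng.uniform(0.05, 1.0):.4f}" if with_lengths else ""
        parts.append(f"({a},{b}){support}{length}")
    newick = "(" + ",".join(parts) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return as_unrooted(tree)


def tree_graph(tree):
    """networkx graph over the tree's nodes; leaves annotated with labels."""
    g = nx.Graph()
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            g.add_edge(nd, child)
    return g


def all_splits_by_edge_removal(tree):
    """Oracle split enumeration: remove each edge, take component leaf sets."""
    g = tree_graph(tree)
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        h = g.copy()
        h.remove_edge(nd.parent_node, nd)
        comp = nx.node_connected_component(h, nd)
        side = frozenset(n.taxon.label for n in comp if n.is_leaf())
        out.append((nd.edge, side))
    return out


def oracle_find_clan(tree, group):
    """Edge-removal clan oracle: the leaf set of the group, if it is one side
    of some split."""
    group = frozenset(group)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for edge, side in all_splits_by_edge_removal(tree):
        if side == group or leaves - side == group:
            return edge
    return None


def oracle_clan_distance(tree, defining_edge, clan_leaves, targets):
    """Breadth-first path-count oracle for internal edges between the clan's
    edge and the nearest target leaf."""
    g = tree_graph(tree)
    u, v = defining_edge.tail_node, defining_edge.head_node
    h = g.copy()
    h.remove_edge(u, v)
    head_comp = nx.node_connected_component(h, v)
    head_leaves = frozenset(n.taxon.label for n in head_comp if n.is_leaf())
    start = u if head_leaves == frozenset(clan_leaves) else v
    best = math.inf
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in targets:
            continue
        path = nx.shortest_path(h, start, leaf)
        best = min(best, len(path) - 2)  # drop the pendant edge
    return best


def oracle_partition(named_pattern, has_other):
    order = "RET"
    if named_pattern:
        return "".join(c for c in order if c in named_pattern)
    return "Other" if has_other else "FocalOnly"


def oracle_match(named_pattern, has_other, codes, exclusive):
    if exclusive:
        return set(named_pattern) == set(codes) and not has_other
    return set(codes) <= set(named_pattern)


def oracle_classify(members, query, focal_set, key):
    """Clean/dirty oracle: dirty iff some non-focal subject sorts before some
    focal subject; degenerate iff no non-focal subject exists."""
    subjects = [p for p in members if p != query]
    focal = [p for p in subjects if p in focal_set]
    foreign = [p for p in subjects if p not in focal_set]
    if not foreign:
        return "degenerate"
    for nf in foreign:
        for f in focal:
            if key(nf) < key(f):
                return "dirty"
    return "clean"


def oracle_vpi(categories, group):
    num = sum(1 for c in categories if group in c and c != "RET")
    den = sum(1 for c in categories if c != "FocalOnly")
    return num, den, (num / den if den else math.nan)
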