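"""Unrooted-tree computations on gene trees.

Everything here works on splits (bipartitions) of unrooted trees: detection of
a homogeneous clan for a named group of genomes, clan-to-group distances in
internal edges, the signed bootstrap balance-of-support between two candidate
partner groups, supported pairing calls, genus (congener) reduction on a guide
tree, in-paralog reduction, pruning, and supermatrix assembly.

A *clan* is the set of leaves on one side of an edge — the unrooted analogue
of a clade. A clan is *homogeneous* for a group when its leaf set is exactly
the group's leaves in that tree.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy


# ---------------------------------------------------------------------------
# basic tree plumbing
# ---------------------------------------------------------------------------

def as_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Treat ``tree`` as unrooted, collapsing a basal bifurcation in place.

    Newick files written by rooted-tree software carry a degree-2 root; that
    node would otherwise inflate internal-edge counts by one.
    """
    tree.is_rooted = False
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    return tree


def normalize_supports(tree: dendropy.Tree) -> None:
    """Attach ``node.support`` in [0, 100] from internal-node labels.

    Accepts integer labels 0–100 and reals in [0, 1] (scaled ×100 when they
    carry a decimal point). Non-numeric or absent labels yield ``None``.
    """
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        label = nd.label
        support = None
        if label is not None:
            try:
                value = float(label)
            except ValueError:
                value = None
            if value is not None:
                if "." in str(label) and 0.0 <= value <= 1.0:
                    value *= 100.0
                if 0.0 <= value <= 100.0:
                    support = value
        nd.support = support


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def child_side_leafsets(tree: dendropy.Tree):
    """Yield ``(edge, frozenset_of_child_side_leaf_labels)`` for every edge."""
    cache: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            cache[nd] = frozenset([nd.taxon.label])
        else:
            cache[nd] = frozenset().union(*(cache[c] for c in nd.child_nodes()))
        if nd.parent_node is not None:
            yield nd.edge, cache[nd]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Clan:
    """One side of a split of an unrooted tree."""

    leaf_set: frozenset
    defining_edge: dendropy.Edge
    support: float | None = None


@dataclass
class BalanceScore:
    group_x: str
    group_y: str
    score: int
    n_replicates: int
    strong: bool = False

    def __post_init__(self) -> None:
        if abs(self.score) > self.n_replicates:
            raise ValueError("balance score outside ±n_replicates")


@dataclass
class GeneTreeSet:
    """An ML tree with supports plus bootstrap replicates on the same leaves."""

    ml_tree: dendropy.Tree
    replicates: list
    n_replicates: int
    leaf_to_genome: Mapping[str, str]

    def group_leaves(self, group, tree=None) -> frozenset:
        """Leaf labels of ``tree`` (default: ML tree) whose genome is in ``group``."""
        members = group.members if hasattr(group, "members") else frozenset(group)
        tree = tree if tree is not None else self.ml_tree
        return frozenset(
            l.taxon.label
            for l in tree.leaf_node_iter()
            if self.leaf_to_genome[l.taxon.label] in members
        )


# ---------------------------------------------------------------------------
# clan detection and distances
# ---------------------------------------------------------------------------

def _as_leafset(tree, group) -> frozenset:
    if hasattr(group, "members"):
        raise TypeError(
            "pass explicit leaf labels; resolve GroupDef via GeneTreeSet.group_leaves"
        )
    return frozenset(group)


def find_homogeneous_clan(tree: dendropy.Tree, group_leaves: Iterable[str]):
    """Return the clan whose leaf set is exactly ``group_leaves``, or ``None``.

    ``group_leaves`` are leaf labels; labels absent from the tree raise a
    ValueError (the group must be represented).
    """
    want = _as_leafset(tree, group_leaves)
    present = leaf_labels(tree)
    eff = want & present
    if not eff:
        raise ValueError(f"group absent from tree: {sorted(want)}")
    for edge, side in child_side_leafsets(tree):
        if side == eff or (present - side) == eff:
            return Clan(
                leaf_set=eff,
                defining_edge=edge,
                support=getattr(edge.head_node, "support", None),
            )
    return None


def is_cohesive(tree: dendropy.Tree, group_leaves: Iterable[str]) -> bool:
    """True iff the group forms a homogeneous clan.

    Single-leaf groups are cohesive by convention, as are groups covering the
    whole tree (no outside leaf to disrupt them).
    """
    want = frozenset(group_leaves) & leaf_labels(tree)
    if not want:
        raise ValueError("group absent from tree")
    if len(want) == 1 or want == leaf_labels(tree):
        return True
    return find_homogeneous_clan(tree, want) is not None


def clan_distance(tree: dendropy.Tree, focal_clan: Clan, group_leaves: Iterable[str]):
    """Internal edges strictly between the clan's edge and the nearest group leaf.

    The count excludes both the clan's defining edge and the leaf's pendant
    edge; a group with no leaves in the tree is infinitely distant.
    """
    present = leaf_labels(tree)
    targets = frozenset(group_leaves) & present
    if not targets:
        return math.inf
    edge = focal_clan.defining_edge
    head, tail = edge.head_node, edge.tail_node
    if head is None or tail is None:
        raise ValueError("invalid clan: defining edge lacks two endpoints")
    head_side = frozenset(l.taxon.label for l in head.leaf_iter())
    if head_side == focal_clan.leaf_set:
        start = tail
    elif (present - head_side) == focal_clan.leaf_set:
        start = head
    else:
        raise ValueError("invalid clan: defining edge does not split off its leaf set")
    # BFS away from the clan, counting edges traversed
    dist = {start: 0}
    queue = deque([start])
    blocked = {head, tail}
    best = math.inf
    while queue:
        node = queue.popleft()
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            if nb in dist:
                continue
            if {node, nb} == blocked:
                continue  # never cross the defining edge
            dist[nb] = dist[node] + 1
            if nb.is_leaf():
                if nb.taxon.label in targets:
                    best = min(best, dist[nb] - 1)  # exclude the pendant edge
            else:
                queue.append(nb)
    return best


# ---------------------------------------------------------------------------
# balance of support and pairing
# ---------------------------------------------------------------------------

def balance_of_support(tree_set: GeneTreeSet, focal, x, y) -> BalanceScore:
    """Signed bootstrap count: replicates placing X nearer the focal clan
    than Y, minus the reverse.

    Per replicate: +1 if d(focal, X) < d(focal, Y), −1 if the reverse, 0 on
    ties; replicates lacking X or Y, or without a homogeneous focal clan,
    contribute 0. ``strong`` flags |score| > 0.70·n_replicates.
    """
    if tree_set.n_replicates < 1:
        raise ValueError("at least one bootstrap replicate required")
    score = 0
    focal_seen = False
    for rep in tree_set.replicates:
        focal_leaves = tree_set.group_leaves(focal, rep)
        if not focal_leaves:
            continue
        focal_seen = True
        x_leaves = tree_set.group_leaves(x, rep)
        y_leaves = tree_set.group_leaves(y, rep)
        if not x_leaves or not y_leaves:
            continue
        clan = find_homogeneous_clan(rep, focal_leaves)
        if clan is None:
            continue
        dx = clan_distance(rep, clan, x_leaves)
        dy = clan_distance(rep, clan, y_leaves)
        if dx < dy:
            score += 1
        elif dy < dx:
            score -= 1
    if not focal_seen:
        raise ValueError("focal group absent from all replicates")
    n = tree_set.n_replicates
    return BalanceScore(
        group_x=getattr(x, "code", "X"),
        group_y=getattr(y, "code", "Y"),
        score=score,
        n_replicates=n,
        strong=abs(score) > 0.70 * n,
    )


def pairing_support(
    tree_set: GeneTreeSet,
    focal,
    lineage_map: Mapping[str, str],
    min_support: float = 70.0,
):
    """Lineages strongly paired with the focal clan in the ML tree.

    Finds the minimal clan strictly containing the homogeneous focal clan
    whose defining-edge support is at least ``min_support`` and returns the
    lineages of its non-focal leaves; empty when the focal group is
    noncohesive or no such clan exists. Invariant to re-rooting (split-based).
    """
    tree = tree_set.ml_tree
    focal_leaves = tree_set.group_leaves(focal)
    if not focal_leaves:
        return set()
    present = leaf_labels(tree)
    if focal_leaves == present:
        return set()
    clan = find_homogeneous_clan(tree, focal_leaves)
    if clan is None:
        return set()
    candidates = []
    for edge, side in child_side_leafsets(tree):
        support = getattr(edge.head_node, "support", None)
        if support is None or support < min_support:
            continue
        for clan_side in (side, present - side):
            if focal_leaves < clan_side and clan_side != present:
                candidates.append(clan_side)
    if not candidates:
        return set()
    chosen = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
    return {
        lineage_map[tree_set.leaf_to_genome[leaf]]
        for leaf in chosen - focal_leaves
    }


# ---------------------------------------------------------------------------
# taxon reduction and pruning
# ---------------------------------------------------------------------------

def genus_reduce(guide_tree: dendropy.Tree, genus_map: Mapping[str, str]) -> frozenset:
    """Congener reduction: genera with >2 leaves forming a homogeneous clan in
    the guide tree are cut to two representatives, one per descendant of the
    clan's earliest split (lexicographically smallest leaf id in each).

    Genera with ≤2 leaves, and noncohesive genera, are untouched. Returns the
    retained leaf-label set.
    """
    labels = leaf_labels(guide_tree)
    by_genus: dict = {}
    for label in labels:
        by_genus.setdefault(genus_map[label], set()).add(label)
    retained = set(labels)
    for genus, members in sorted(by_genus.items()):
        if len(members) <= 2:
            continue
        clan = find_homogeneous_clan(guide_tree, members)
        if clan is None:
            continue
        work = guide_tree.clone(depth=1)
        outgroup = min(leaf_labels(work) - frozenset(members))
        og_node = next(
            l for l in work.leaf_node_iter() if l.taxon.label == outgroup
        )
        work.reroot_at_edge(og_node.edge, update_bipartitions=False)
        root_node = None
        for edge, side in child_side_leafsets(work):
            if side == frozenset(members):
                root_node = edge.head_node
                break
        if root_node is None:  # pragma: no cover - guarded by clan check
            continue
        subtrees = sorted(
            (sorted(l.taxon.label for l in child.leaf_iter()) for child in root_node.child_nodes()),
            key=lambda leaves: leaves[0],
        )
        keep = {leaves[0] for leaves in subtrees[:2]}
        retained -= members - keep
    return frozenset(retained)


def reduce_inparalogs(tree: dendropy.Tree, genome_of) -> frozenset:
    """Keep, per genome, the leaf with the shortest terminal branch.

    Ties break lexicographically on the leaf label. ``genome_of`` maps a leaf
    label to its genome. Returns the retained leaf-label set.
    """
    fn = genome_of if callable(genome_of) else (lambda l: genome_of[l])
    by_genome: dict = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        length = leaf.edge.length if leaf.edge.length is not None else 0.0
        by_genome.setdefault(fn(label), []).append((length, label))
    retained = set()
    for _, leaves in by_genome.items():
        retained.add(min(leaves)[1])
    return frozenset(retained)


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``; degree-2 nodes are suppressed with branch
    lengths summed. The input tree is untouched."""
    keep = set(taxa) & leaf_labels(tree)
    if not keep:
        raise ValueError("no requested taxa present in tree")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    return as_unrooted(pruned)


# ---------------------------------------------------------------------------
# supermatrix assembly
# ---------------------------------------------------------------------------

def build_supermatrix(alignments: Sequence, taxon_of):
    """Concatenate per-gene alignments into a genome-level supermatrix.

    Each alignment must have at most one sequence per genome (apply
    ``reduce_inparalogs`` first); genomes missing from a gene are padded with
    gaps. Returns ``(ConfAlignment, partitions)`` where partitions is a list
    of ``(gene_name, start, end)`` with 1-based inclusive column ranges.
    """
    from .io_formats import ConfAlignment  # local import, avoids a cycle

    fn = taxon_of if callable(taxon_of) else (lambda p: taxon_of[p])
    per_gene = []
    genomes: set = set()
    for idx, aln in enumerate(alignments):
        rows: dict = {}
        for sid, seq in aln.sequences:
            genome = fn(sid)
            if genome in rows:
                raise ValueError(
                    f"genome {genome!r} has multiple sequences in gene "
                    f"{aln.name or idx}; reduce in-paralogs first"
                )
            rows[genome] = seq
        per_gene.append((aln.name or f"gene{idx + 1}", rows, aln))
        genomes |= rows.keys()
    order = sorted(genomes)
    parts, pieces, confs = [], {g: [] for g in order}, []
    cursor = 1
    for name, rows, aln in per_gene:
        length = aln.n_columns
        for g in order:
            pieces[g].append(rows.get(g, "-" * length))
        parts.append((name, cursor, cursor + length - 1))
        confs.extend(aln.column_confidence)
        cursor += length
    supermatrix = ConfAlignment(
        sequences=[(g, "".join(pieces[g])) for g in order],
        column_confidence=confs,
        name="supermatrix",
    )
    return supermatrix, parts
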