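"""Homologous cluster construction seeded on focal-genome proteins.

The procedure is two-threshold: a graph is built over focal proteins with an
edge wherever a pair has *bidirectional* hits at a strict e-value cutoff
(default 1e-10); each connected component is then expanded into a cluster by
recruiting every subject hit by any component protein at a looser cutoff
(default 1e-5), deduplicated within the cluster. Copy number is classified
from the per-focal-genome member counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx


@dataclass
class FocalGraph:
    nodes: frozenset
    edges: frozenset  # frozensets of two protein ids

    def __post_init__(self) -> None:
        for e in self.edges:
            if not e <= self.nodes:
                raise ValueError(f"edge endpoint outside node set: {sorted(e)}")


@dataclass
class HomologCluster:
    cluster_id: str
    seed_protein: str
    members: frozenset
    focal_copy_counts: dict
    copy_class: str  # "single" | "multi"

    def __post_init__(self) -> None:
        if self.seed_protein not in self.members:
            raise ValueError("seed protein not a member of its own cluster")


def _genome_fn(protein_to_genome) -> Callable[[str], str]:
    return protein_to_genome if callable(protein_to_genome) else (
        lambda p: protein_to_genome[p]
    )


def build_focal_graph(hits, focal, protein_to_genome, e_bidir: float = 1e-10) -> FocalGraph:
    """Graph over focal proteins; edge (p, q) iff both directed hits exist at
    e-value ≤ ``e_bidir``. Self-hits are ignored."""
    if not focal.members:
        raise ValueError("focal group is empty")
    genome_of = _genome_fn(protein_to_genome)

    def is_focal(p: str) -> bool:
        return genome_of(p) in focal.members

    nodes: set = set()
    directed: set = set()
    for h in hits:
        q_focal, s_focal = is_focal(h.query_id), is_focal(h.subject_id)
        if q_focal:
            nodes.add(h.query_id)
        if s_focal:
            nodes.add(h.subject_id)
        if (
            q_focal
            and s_focal
            and h.query_id != h.subject_id
            and h.evalue <= e_bidir
        ):
            directed.add((h.query_id, h.subject_id))
    edges = frozenset(
        frozenset((p, q)) for p, q in directed if (q, p) in directed
    )
    return FocalGraph(nodes=frozenset(nodes), edges=edges)


def extract_clusters(
    graph: FocalGraph,
    hits,
    protein_to_genome,
    seed_priority: Sequence[str],
    e_member: float = 1e-5,
):
    """One cluster per connected component (isolated focal proteins included).

    Members are the component's focal proteins plus every subject hit by any
    of them at e-value ≤ ``e_member``. The seed is the component protein from
    the highest-priority genome present (``seed_priority`` is an ordered list
    of genome ids), ties broken lexicographically. Clusters are returned
    sorted by seed protein id.
    """
    genome_of = _genome_fn(protein_to_genome)
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(tuple(sorted(e)) for e in graph.edges)

    recruits: dict = {}
    for h in hits:
        if h.query_id in graph.nodes and h.evalue <= e_member:
            recruits.setdefault(h.query_id, set()).add(h.subject_id)

    priority = {gid: i for i, gid in enumerate(seed_priority)}
    clusters = []
    for component in nx.connected_components(g):
        focal_proteins = set(component)
        members = set(focal_proteins)
        for p in focal_proteins:
            # focal proteins of other components stay with their own cluster,
            # so clusters partition the focal proteins
            members |= {
                s
                for s in recruits.get(p, set())
                if s not in graph.nodes or s in focal_proteins
            }
        seed = min(
            focal_proteins,
            key=lambda p: (priority.get(genome_of(p), len(priority)), p),
        )
        counts: dict = {}
        for p in focal_proteins:
            counts[genome_of(p)] = counts.get(genome_of(p), 0) + 1
        clusters.append(
            HomologCluster(
                cluster_id="",
                seed_protein=seed,
                members=frozenset(members),
                focal_copy_counts=counts,
                copy_class=_copy_class(counts),
            )
        )
    clusters.sort(key=lambda c: c.seed_protein)
    for i, c in enumerate(clusters):
        c.cluster_id = f"C{i + 1:05d}"
    return clusters


def _copy_class(counts: Mapping[str, int]) -> str:
    return "single" if all(v == 1 for v in counts.values()) else "multi"


def classify_copy_number(cluster: HomologCluster) -> str:
    """``single`` iff every represented focal genome holds exactly one copy."""
    if not cluster.focal_copy_counts:
        raise ValueError(
            f"cluster {cluster.cluster_id} has no focal member; "
            "clusters are focal-seeded by construction"
        )
    return _copy_class(cluster.focal_copy_counts)
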