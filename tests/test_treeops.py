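import math

import dendropy
import numpy as np
import pytest

from clanprof.io_formats import ConfAlignment, GroupDef
from clanprof.treeops import (
    GeneTreeSet,
    as_unrooted,
    balance_of_support,
    build_supermatrix,
    child_side_leafsets,
    clan_distance,
    find_homogeneous_clan,
    genus_reduce,
    is_cohesive,
    leaf_labels,
    normalize_supports,
    pairing_support,
    prune_to_taxa,
    reduce_inparalogs,
)

from helpers import (
    all_splits_by_edge_removal,
    oracle_clan_distance,
    oracle_find_clan,
    random_tree,
)


def tree_of(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    as_unrooted(t)
    normalize_supports(t)
    return t


def tree_set(ml, replicates, genome_of=lambda l: l[0]):
    ml_tree = tree_of(ml)
    reps = [tree_of(r) for r in replicates]
    mapping = {l: genome_of(l) for l in leaf_labels(ml_tree)}
    for rep in reps:
        mapping.update({l: genome_of(l) for l in leaf_labels(rep)})
    return GeneTreeSet(ml_tree, reps, len(reps), mapping)


class TestHomogeneousClan:
    def test_cohesive_pair_found(self):
        t = tree_of("((a1,a2),(x,y));")
        clan = find_homogeneous_clan(t, {"a1", "a2"})
        assert clan is not None and clan.leaf_set == {"a1", "a2"}

    def test_disrupted_group_has_no_clan(self):
        t = tree_of("((a1,x),(a2,y));")
        assert find_homogeneous_clan(t, {"a1", "a2"}) is None

    def test_group_absent_rejected(self):
        t = tree_of("((a1,a2),(x,y));")
        with pytest.raises(ValueError, match="absent"):
            find_homogeneous_clan(t, {"z1", "z2"})

    def test_agrees_with_edge_removal_oracle(self, rng):
        labels = [f"{c}{i}" for c in "ab" for i in range(6)]
        for _ in range(120):
            t = random_tree(list(labels), rng)
            group = {l for l in labels if l.startswith("a")}
            got = find_homogeneous_clan(t, group)
            expect = oracle_find_clan(t, group)
            assert (got is None) == (expect is None)

    def test_cohesion_calls(self):
        assert is_cohesive(tree_of("((a1,a2),(x,y));"), {"a1", "a2"})
        assert not is_cohesive(tree_of("((a1,x),(a2,y));"), {"a1", "a2"})
        assert is_cohesive(tree_of("((a1,x),(z,y));"), {"a1"})  # single leaf

    def test_no_lgt_families_are_fully_cohesive(self, vertical_dataset):
        focal = vertical_dataset.focal_group()
        for fam in vertical_dataset.families:
            ts = fam.tree_set()
            leaves = ts.group_leaves(focal)
            assert is_cohesive(ts.ml_tree, leaves)


class TestClanDistance:
    def test_adjacent_leaf_distance_zero(self):
        t = tree_of("(((a1,a2),x),(y,z));")
        clan = find_homogeneous_clan(t, {"a1", "a2"})
        assert clan_distance(t, clan, {"x"}) == 0

    def test_two_internal_edges(self):
        # caterpillar: each successive group is one internal edge further out
        t = tree_of("((((a1,a2),(b1,b2)),(c1,c2)),((x1,x2),(y1,y2)));")
        clan = find_homogeneous_clan(t, {"a1", "a2"})
        assert clan_distance(t, clan, {"b1", "b2"}) == 1
        assert clan_distance(t, clan, {"c1"}) == 2
        assert clan_distance(t, clan, {"x1", "x2"}) == 3

    def test_absent_group_is_infinitely_far(self):
        t = tree_of("((a1,a2),(x,y));")
        clan = find_homogeneous_clan(t, {"a1", "a2"})
        assert clan_distance(t, clan, {"zzz"}) == math.inf

    def test_agrees_with_bfs_oracle(self, rng):
        # every edge defines a clan, so each random tree yields many cases
        from clanprof.treeops import Clan

        labels = [f"{c}{i}" for c in "abc" for i in range(4)]
        checked = 0
        for _ in range(60):
            t = random_tree(list(labels), rng)
            for edge, side in list(child_side_leafsets(t)):
                complement = set(labels) - side
                if not complement:
                    continue
                targets = {l for l in complement if l.startswith("b")}
                if not targets:
                    continue
                clan = Clan(leaf_set=frozenset(side), defining_edge=edge)
                got = clan_distance(t, clan, targets)
                expect = oracle_clan_distance(t, edge, side, targets)
                assert got == expect
                checked += 1
        assert checked > 200


class TestBalanceOfSupport:
    FOCAL = GroupDef("FOCAL", {"a"})
    X = GroupDef("X", {"x"})
    Y = GroupDef("Y", {"y"})

    def test_unanimous_support_is_plus_n(self):
        ts = tree_set(
            "(((a1,a2),(x1,x2)),(y1,y2),(z1,z2));",
            ["(((a1,a2),(x1,x2)),(y1,y2),(z1,z2));"] * 5,
        )
        b = balance_of_support(ts, self.FOCAL, self.X, self.Y)
        assert b.score == 5 and b.strong

    def test_equidistant_groups_score_zero(self):
        ts = tree_set(
            "((a1,a2),(x1,x2),(y1,y2));",
            ["((a1,a2),(x1,x2),(y1,y2));"] * 4,
        )
        b = balance_of_support(ts, self.FOCAL, self.X, self.Y)
        assert b.score == 0 and not b.strong

    def test_noncohesive_replicates_contribute_zero(self):
        ts = tree_set(
            "(((a1,x1),(a2,x2)),(y1,y2));",
            ["(((a1,x1),(a2,x2)),(y1,y2));"] * 3,
        )
        assert balance_of_support(ts, self.FOCAL, self.X, self.Y).score == 0

    def test_antisymmetry_and_bound_on_random_tree_sets(self, rng):
        labels = [f"{c}{i}" for c in "axy" for i in range(3)] + ["z0", "z1"]
        for _ in range(60):
            reps = [random_tree(list(labels), rng) for _ in range(6)]
            ml = random_tree(list(labels), rng)
            mapping = {l: l[0] for l in labels}
            ts = GeneTreeSet(ml, reps, len(reps), mapping)
            bxy = balance_of_support(ts, self.FOCAL, self.X, self.Y)
            byx = balance_of_support(ts, self.FOCAL, self.Y, self.X)
            assert bxy.score == -byx.score
            assert abs(bxy.score) <= ts.n_replicates

    def test_focal_absent_everywhere_rejected(self):
        ts = tree_set("((x1,x2),(y1,y2));", ["((x1,x2),(y1,y2));"])
        with pytest.raises(ValueError, match="focal"):
            balance_of_support(ts, self.FOCAL, self.X, self.Y)


class TestPairingSupport:
    LINEAGES = {"a": "FOCAL", "e": "E", "t": "T", "z": "OTHER"}

    def lineage_map(self):
        return dict(self.LINEAGES)

    def test_supported_sister_pairing(self):
        ts = tree_set(
            "(((a1,a2)90,(e1,e2)50)95,(t1,t2),(z1,z2));",
            ["((a1,a2),(e1,e2),((t1,t2),(z1,z2)));"],
        )
        got = pairing_support(ts, GroupDef("FOCAL", {"a"}), self.lineage_map(), 70)
        assert got == {"E"}

    def test_threshold_blocks_weak_pairing(self):
        ts = tree_set(
            "(((a1,a2)90,(e1,e2)50)60,(t1,t2),(z1,z2));",
            ["((a1,a2),(e1,e2),((t1,t2),(z1,z2)));"],
        )
        got = pairing_support(ts, GroupDef("FOCAL", {"a"}), self.lineage_map(), 70)
        assert got == set()

    def test_noncohesive_focal_pairs_nothing(self):
        ts = tree_set(
            "(((a1,e1)99,(a2,e2)99)99,(t1,t2),(z1,z2));",
            ["((a1,e1),(a2,e2),((t1,t2),(z1,z2)));"],
        )
        assert pairing_support(
            ts, GroupDef("FOCAL", {"a"}), self.lineage_map(), 70
        ) == set()

    @staticmethod
    def _cohesive_random_tree(rng, support_rng):
        """Random supported tree in which the focal pair is always a cherry."""
        labels = ["afocal"] + [f"{c}{i}" for c in "etz" for i in range(3)]
        t = random_tree(labels, rng, support_rng=support_rng)
        newick = t.as_string(schema="newick", suppress_rooting=True)
        newick = newick.replace("afocal", "(a0:0.1,a1:0.1)99")
        t2 = dendropy.Tree.get(data=newick, schema="newick")
        as_unrooted(t2)
        normalize_supports(t2)
        return t2

    def test_invariant_to_rerooting(self, rng):
        labels = ["a0", "a1"] + [f"{c}{i}" for c in "etz" for i in range(3)]
        support_rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            t = self._cohesive_random_tree(rng, support_rng)
            mapping = {l: l[0] for l in labels}
            ts = GeneTreeSet(t, [t], 1, mapping)
            base = pairing_support(ts, GroupDef("FOCAL", {"a"}), self.lineage_map(), 50)
            # reroot at an arbitrary leaf edge; supports stay attached to
            # their splits (node labels would otherwise migrate across the
            # old root path, a Newick representation artefact)
            full = leaf_labels(t)
            by_split = {}
            for edge, side in child_side_leafsets(t):
                key = min(side, full - side, key=sorted)
                by_split[key] = getattr(edge.head_node, "support", None)
            t2 = dendropy.Tree.get(
                data=t.as_string(schema="newick"), schema="newick"
            )
            leaf = next(l for l in t2.leaf_node_iter() if l.taxon.label == "z0")
            t2.reroot_at_edge(leaf.edge)
            for edge, side in child_side_leafsets(t2):
                key = min(side, full - side, key=sorted)
                edge.head_node.support = by_split.get(key)
            ts2 = GeneTreeSet(t2, [t2], 1, mapping)
            rerooted = pairing_support(
                ts2, GroupDef("FOCAL", {"a"}), self.lineage_map(), 50
            )
            assert rerooted == base
            hits += bool(base)
        assert hits > 0  # the check exercised non-empty pairings

    def test_agrees_with_clan_enumeration_oracle(self, rng):
        labels = ["a0", "a1"] + [f"{c}{i}" for c in "etz" for i in range(3)]
        support_rng = np.random.default_rng(17)
        nonempty = 0
        for _ in range(60):
            t = self._cohesive_random_tree(rng, support_rng)
            mapping = {l: l[0] for l in labels}
            ts = GeneTreeSet(t, [t], 1, mapping)
            focal_leaves = frozenset(l for l in labels if l.startswith("a"))
            got = pairing_support(ts, GroupDef("FOCAL", {"a"}), self.lineage_map(), 60)
            # oracle: enumerate all clans via edge removal
            all_leaves = leaf_labels(t)
            focal_clan = oracle_find_clan(t, focal_leaves)
            expect = set()
            if focal_clan is not None:
                candidates = []
                for edge, side in all_splits_by_edge_removal(t):
                    support = getattr(edge.head_node, "support", None)
                    if support is None or support < 60:
                        continue
                    for clan_side in (side, all_leaves - side):
                        if focal_leaves < clan_side and clan_side != all_leaves:
                            candidates.append(frozenset(clan_side))
                if candidates:
                    chosen = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
                    expect = {self.LINEAGES[l[0]] for l in chosen - focal_leaves}
            assert got == expect
            nonempty += bool(expect)
        assert nonempty > 0


class TestGenusReduce:
    def test_four_leaf_genus_clan_cut_to_two(self):
        t = tree_of("((((g1,g2),(g3,g4)),x),(y,z));")
        genus = {l: ("G" if l.startswith("g") else l) for l in leaf_labels(t)}
        retained = genus_reduce(t, genus)
        assert retained == {"g1", "g3", "x", "y", "z"}

    def test_two_genome_genus_untouched(self):
        t = tree_of("(((g1,g2),x),(y,z));")
        genus = {l: ("G" if l.startswith("g") else l) for l in leaf_labels(t)}
        assert genus_reduce(t, genus) == leaf_labels(t)

    def test_noncohesive_genus_untouched(self):
        t = tree_of("(((g1,x),(g2,y)),(g3,z));")
        genus = {l: ("G" if l.startswith("g") else l) for l in leaf_labels(t)}
        assert genus_reduce(t, genus) == leaf_labels(t)

    def test_matches_subtree_walk_oracle(self, rng):
        labels = [f"g{i}" for i in range(5)] + ["x0", "x1", "x2"]
        for _ in range(80):
            t = random_tree(list(labels), rng)
            genus = {l: ("G" if l.startswith("g") else l) for l in labels}
            retained = genus_reduce(t, genus)
            members = {l for l in labels if l.startswith("g")}
            edge = oracle_find_clan(t, members)
            if edge is None:
                assert retained == set(labels)
            else:
                assert len(retained & members) == 2
                assert retained - members == {"x0", "x1", "x2"}
                # the two representatives come from different sides of the
                # genus root: they cannot form a cherry inside another rep set
                kept = sorted(retained & members)
                assert kept[0] != kept[1]


class TestInParalogReduction:
    def test_keeps_shortest_terminal_branch(self):
        t = tree_of("((p1:0.3,p2:0.1):0.2,(q1:0.5,r1:0.4):0.1);")
        genome = {"p1": "P", "p2": "P", "q1": "Q", "r1": "R"}
        assert reduce_inparalogs(t, genome) == {"p2", "q1", "r1"}

    def test_identity_when_all_single_copy(self):
        t = tree_of("((p1:0.3,q1:0.1):0.2,(r1:0.5,s1:0.4):0.1);")
        genome = {l: l.upper() for l in leaf_labels(t)}
        assert reduce_inparalogs(t, genome) == leaf_labels(t)

    def test_matches_min_branch_oracle(self, rng):
        labels = [f"p{i}" for i in range(6)] + [f"q{i}" for i in range(3)]
        for _ in range(50):
            t = random_tree(list(labels), rng)
            genome = {l: l[0] for l in labels}
            retained = reduce_inparalogs(t, genome)
            lengths = {
                l.taxon.label: l.edge.length for l in t.leaf_node_iter()
            }
            for g in "pq":
                candidates = [(lengths[l], l) for l in labels if l[0] == g]
                assert min(candidates)[1] in retained
            assert len(retained) == 2


class TestPruneAndSupermatrix:
    def test_prune_to_three_leaves(self):
        t = tree_of("((a:1,b:1):1,(c:1,d:1):1);")
        pruned = prune_to_taxa(t, {"a", "b", "c"})
        assert leaf_labels(pruned) == {"a", "b", "c"}

    def test_prune_to_full_set_is_identity_on_splits(self, rng):
        labels = [f"t{i}" for i in range(8)]
        t = random_tree(list(labels), rng)
        pruned = prune_to_taxa(t, set(labels))
        want = {s for _, s in child_side_leafsets(t) if 1 < len(s) < 7}
        got = {s for _, s in child_side_leafsets(pruned) if 1 < len(s) < 7}

        def canon(splits):
            full = frozenset(labels)
            return {min(s, full - s, key=sorted) for s in splits}

        assert canon(got) == canon(want)

    def test_induced_splits_match_oracle(self, rng):
        labels = [f"t{i}" for i in range(10)]
        keep = set(labels[:6])
        for _ in range(40):
            t = random_tree(list(labels), rng)
            pruned = prune_to_taxa(t, keep)
            full_keep = frozenset(keep)

            def canon(splits):
                out = set()
                for s in splits:
                    if 1 < len(s) < len(full_keep) - 1:
                        out.add(min(s, full_keep - s, key=sorted))
                return out

            got = canon(s for _, s in child_side_leafsets(pruned))
            induced = canon(
                frozenset(s & keep) for _, s in child_side_leafsets(t)
            )
            assert got <= induced

    def test_supermatrix_concatenation_and_padding(self):
        g1 = ConfAlignment(
            sequences=[("p1", "AAAAA"), ("p2", "CCCCC")],
            column_confidence=[1.0] * 5,
            name="g1",
        )
        g2 = ConfAlignment(
            sequences=[("p1", "GGGGGGG")],
            column_confidence=[0.9] * 7,
            name="g2",
        )
        sm, parts = build_supermatrix([g1, g2], {"p1": "X", "p2": "Y"})
        assert sm.n_columns == 12
        assert parts == [("g1", 1, 5), ("g2", 6, 12)]
        rows = dict(sm.sequences)
        assert rows["X"] == "AAAAAGGGGGGG"
        assert rows["Y"] == "CCCCC" + "-" * 7

    def test_duplicate_genome_in_gene_rejected(self):
        g = ConfAlignment(
            sequences=[("p1", "AA"), ("p2", "CC")],
            column_confidence=[1.0, 1.0],
            name="g",
        )
        with pytest.raises(ValueError, match="in-paralog"):
            build_supermatrix([g], {"p1": "X", "p2": "X"})

    def test_column_bookkeeping_matches_index_oracle(self, rng):
        genes = []
        for i in range(5):
            n = int(rng.integers(2, 9))
            genomes = [f"G{j}" for j in range(4) if rng.random() < 0.7] or ["G0"]
            genes.append(
                ConfAlignment(
                    sequences=[(f"{g}.p{i}", "A" * n) for g in genomes],
                    column_confidence=[1.0] * n,
                    name=f"gene{i}",
                )
            )
        sm, parts = build_supermatrix(genes, lambda p: p.split(".")[0])
        assert parts[0][1] == 1
        for (_, s1, e1), (_, s2, _) in zip(parts, parts[1:]):
            assert s2 == e1 + 1
        assert parts[-1][2] == sm.n_columns == sum(g.n_columns for g in genes)
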