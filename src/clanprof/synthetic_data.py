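"""Ground-truth synthetic datasets for the pipeline.

The generator emulates the statistical structure the analysis assumes: a
three-genome focal clade with fixed internal topology ((A′,H′),S′) sitting in
a vertical reference phylogeny next to partner lineages R′ (archaeal
analogue), E′ (epsilonproteobacterial analogue), T′ (Thermotogae analogue)
and a heterogeneous "other" pool. Per gene family it samples a phyletic
pattern, prunes the reference tree to the present genomes, optionally plants
one lateral transfer by regrafting a focal leaf inside a donor lineage,
derives BLAST-like e-values from patristic distances through a log-linear
model, and emits NNI-perturbed bootstrap replicate topologies.

No residues are simulated — the pipeline consumes only similarity tables,
trees and annotation tables, and those are what the generator writes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GroupDef, SimilarityHit, write_similarity_table, write_taxonomy
from .profiles import GroupScheme
from .treeops import GeneTreeSet, as_unrooted, child_side_leafsets, prune_to_taxa

PATTERN_CATEGORIES = ("RET", "RE", "RT", "ET", "R", "E", "T", "Other", "FocalOnly")

#: illustrative defaults approximating the RET-heavy core-set proportions
DEFAULT_PATTERN_FREQS = {
    "RET": 0.43,
    "ET": 0.23,
    "RE": 0.06,
    "RT": 0.04,
    "R": 0.05,
    "E": 0.07,
    "T": 0.03,
    "Other": 0.07,
    "FocalOnly": 0.02,
}

FOCAL_GENOMES = ("Aqx", "Hyb", "Sul")  # A′, H′, S′
FOCAL_CODES = {"Aqx": "A", "Hyb": "H", "Sul": "S"}

COG_LETTERS = "JKLMNOCEGHIPQTUV"


def protein_genome(protein_id: str) -> str:
    """Genome id encoded in a synthetic protein id (``<genome>.<family>``)."""
    return protein_id.split(".", 1)[0]


@dataclass(frozen=True)
class EvalueModel:
    """log10 e = intercept − slope·d + noise_sd·ε, clipped to [1e-180, 10].

    With the default slope −14 the e-value grows with patristic distance d;
    the intercept −45 places within-focal pairs far below the 1e-10 graph
    threshold and the farthest within-family pair below the 1e-5 recruitment
    threshold under the reference branch lengths.
    """

    slope: float = -14.0
    intercept: float = -45.0
    noise_sd: float = 0.0

    def log10_evalue(self, distance: float, eps: float = 0.0) -> float:
        v = self.intercept - self.slope * distance + self.noise_sd * eps
        return min(max(v, -180.0), 1.0)


@dataclass
class SimConfig:
    seed: int = 0
    group_sizes: dict = field(
        default_factory=lambda: {"FOCAL": 3, "R": 8, "E": 6, "T": 4, "OTHER": 10}
    )
    n_families: int = 200
    pattern_freqs: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_FREQS))
    p_lgt: float = 0.1
    lgt_donor_weights: dict = field(
        default_factory=lambda: {"R": 1.0, "E": 1.0, "T": 1.0, "OTHER": 1.0}
    )
    evalue_model: EvalueModel = field(default_factory=EvalueModel)
    n_bootstrap: int = 100
    bootstrap_perturb: float = 0.1
    sister: str = "E"  # true sister lineage of the focal clade
    p_direct_map: float = 0.7
    p_unknown_function: float = 0.15

    def __post_init__(self) -> None:
        if self.group_sizes.get("FOCAL") != 3:
            raise ValueError("the focal clade has exactly three genomes")
        total = sum(self.pattern_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_freqs sum to {total}, expected 1")
        unknown = set(self.pattern_freqs) - set(PATTERN_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown pattern categories: {sorted(unknown)}")
        for p in (self.p_lgt, self.bootstrap_perturb):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sister not in ("R", "E", "T", "OTHER"):
            raise ValueError(f"unknown sister lineage {self.sister!r}")


@dataclass
class SimFamily:
    family_id: str
    true_pattern: str
    lgt_event: tuple | None  # (donor_lineage, recipient_protein_id)
    ml_tree: dendropy.Tree
    replicates: list
    hit_rows: list
    members: list
    true_cog: str

    def tree_set(self) -> GeneTreeSet:
        mapping = {
            l.taxon.label: protein_genome(l.taxon.label)
            for l in self.ml_tree.leaf_node_iter()
        }
        return GeneTreeSet(
            ml_tree=self.ml_tree,
            replicates=self.replicates,
            n_replicates=len(self.replicates),
            leaf_to_genome=mapping,
        )


@dataclass
class SimDataset:
    config: SimConfig
    taxonomy: pd.DataFrame
    families: list
    hits: list
    direct_map: pd.DataFrame
    hit_annotations: pd.DataFrame
    go_annotations: pd.DataFrame
    truth: pd.DataFrame
    genomes_by_lineage: dict

    def group_scheme(self) -> GroupScheme:
        return GroupScheme(
            focal_codes=dict(FOCAL_CODES),
            named={
                code: GroupDef(code, frozenset(self.genomes_by_lineage[code]))
                for code in ("R", "E", "T")
            },
        )

    def lineage_map(self) -> dict:
        out = {}
        for lineage, genomes in self.genomes_by_lineage.items():
            for g in genomes:
                out[g] = lineage
        return out

    def focal_group(self) -> GroupDef:
        return GroupDef("FOCAL", frozenset(FOCAL_GENOMES))

    def write(self, outdir) -> None:
        """Write the dataset in the exact formats the readers consume."""
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "trees"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "annotations"), exist_ok=True)
        write_taxonomy(self.taxonomy, os.path.join(outdir, "taxonomy.tsv"))
        write_similarity_table(self.hits, os.path.join(outdir, "hits.tsv"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        for name, df in (
            ("direct_map", self.direct_map),
            ("hit_annotations", self.hit_annotations),
            ("go_annotations", self.go_annotations),
        ):
            df.to_csv(
                os.path.join(outdir, "annotations", f"{name}.tsv"),
                sep="\t",
                index=False,
            )
        for fam in self.families:
            prefix = os.path.join(outdir, "trees", fam.family_id)
            kwargs = dict(
                schema="newick", suppress_rooting=True, suppress_annotations=True
            )
            with open(prefix + ".ml.nwk", "w") as fh:
                fh.write(fam.ml_tree.as_string(**kwargs))
            if fam.replicates:
                with open(prefix + ".boot.nwk", "w") as fh:
                    for rep in fam.replicates:
                        fh.write(rep.as_string(**kwargs))


# ---------------------------------------------------------------------------
# reference phylogeny
# ---------------------------------------------------------------------------

def _ladder(labels: Sequence[str], bl: float) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:{bl}"
    inner = _ladder(labels[:-1], bl)
    return f"({inner},{labels[-1]}:{bl}):{bl}"


def make_genomes(group_sizes: Mapping[str, int]) -> dict:
    prefixes = {"R": "R", "E": "E", "T": "T", "OTHER": "O"}
    out = {"FOCAL": list(FOCAL_GENOMES)}
    for lineage, prefix in prefixes.items():
        out[lineage] = [
            f"{prefix}{i + 1:02d}" for i in range(group_sizes[lineage])
        ]
    return out


def species_tree_newick(genomes_by_lineage: Mapping[str, Sequence[str]], sister: str) -> str:
    """Vertical reference phylogeny with ((A′,H′),S′) and ``sister`` adjacent.

    Partner-lineage clades are ladders with 0.05 branches so the clade root
    always touches a leaf; backbone stems are 0.3. Within-focal patristic
    distances (≤0.4) are therefore strictly below any focal-to-partner
    distance (≥0.85), which is what makes vertical families rank clean.
    """
    a, h, s = FOCAL_GENOMES
    focal = f"(({a}:0.1,{h}:0.1):0.1,{s}:0.2)"
    clades = {
        lin: f"({_ladder(genomes_by_lineage[lin], 0.05)})"
        if len(genomes_by_lineage[lin]) > 1
        else f"{genomes_by_lineage[lin][0]}"
        for lin in ("R", "E", "T", "OTHER")
    }
    core = f"({focal}:0.3,{clades[sister]}:0.3)"
    rest = [lin for lin in ("E", "T", "R") if lin != sister] + (
        ["OTHER"] if sister != "OTHER" else []
    )
    for lin in rest:
        core = f"({core}:0.3,{clades[lin]}:0.3)"
    return core + ";"


def make_taxonomy(genomes_by_lineage: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    rows = []
    genera = {"Aqx": "AquifexLike", "Hyb": "HydrogenobaculumLike", "Sul": "SulfurihydrogenibiumLike"}
    for g in genomes_by_lineage["FOCAL"]:
        rows.append((g, "Bacteria", "AquificaeLike", "AquificaeLike", genera[g], "hyperthermophile"))
    for i, g in enumerate(genomes_by_lineage["R"]):
        genus = "ArchGenA" if i < 3 else f"ArchGen{i}"
        rows.append((g, "Archaea", "EuryarchaeotaLike", "ArchClass", genus, "hyperthermophile"))
    for i, g in enumerate(genomes_by_lineage["E"]):
        rows.append((g, "Bacteria", "ProteobacteriaLike", "EpsilonLike", f"EpsGen{i}", "mesophile"))
    for i, g in enumerate(genomes_by_lineage["T"]):
        rows.append((g, "Bacteria", "ThermotogaeLike", "ThermotogaeLike", f"TogaGen{i}", "thermophile"))
    for i, g in enumerate(genomes_by_lineage["OTHER"]):
        rows.append((g, "Bacteria", f"OtherPhylum{i % 4}", f"OtherClass{i % 4}", f"OtherGen{i}", "mesophile"))
    return pd.DataFrame(
        rows,
        columns=["genome_id", "domain", "phylum", "class_name", "genus", "temp_class"],
    )


# ---------------------------------------------------------------------------
# per-family machinery
# ---------------------------------------------------------------------------

def _present_lineages(pattern: str) -> list:
    if pattern == "FocalOnly":
        return []
    if pattern == "Other":
        return ["OTHER"]
    return [c for c in "RET" if c in pattern]


def _relabelled_family_tree(species_tree, present, family_id):
    pruned = prune_to_taxa(species_tree, present)
    tree = dendropy.Tree.get(
        data=pruned.as_string(schema="newick"), schema="newick"
    )
    as_unrooted(tree)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = f"{leaf.taxon.label}.{family_id}"
    return tree


def _regraft(tree, recipient_label, donor_label, attach_length=0.02):
    """Detach the recipient leaf and reattach it on the midpoint of the donor
    leaf's pendant edge (single-gene transfer)."""
    by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    recipient = by_label[recipient_label]
    donor = by_label[donor_label]
    parent = recipient.parent_node
    parent.remove_child(recipient)
    tree.suppress_unifurcations()
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    half = (donor.edge.length or 0.05) / 2.0
    donor_parent = donor.parent_node
    donor_parent.remove_child(donor)
    mid = donor_parent.new_child(edge_length=half)
    donor.edge.length = half
    mid.add_child(donor)
    recipient.edge.length = attach_length
    mid.add_child(recipient)
    return tree


def _internal_edges(tree):
    return [
        nd.edge
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]


def _nni_perturb(tree, rng, prob):
    """Apply a random NNI at each internal edge with probability ``prob``."""
    for edge in _internal_edges(tree):
        if prob <= 0.0 or rng.random() >= prob:
            continue
        v, u = edge.head_node, edge.tail_node
        siblings = [c for c in u.child_nodes() if c is not v]
        children = v.child_nodes()
        if not siblings or not children:
            continue
        s = siblings[rng.integers(len(siblings))]
        c = children[rng.integers(len(children))]
        u.remove_child(s)
        v.remove_child(c)
        u.add_child(c)
        v.add_child(s)
    return tree


def _split_key(side: frozenset, all_leaves: frozenset, ref: str) -> frozenset:
    return frozenset(all_leaves - side) if ref in side else side


def _attach_supports_from_replicates(ml_tree, replicates) -> None:
    """Edge supports on the ML tree = split frequencies among the replicates,
    in percent."""
    all_leaves = frozenset(l.taxon.label for l in ml_tree.leaf_node_iter())
    if len(all_leaves) < 4 or not replicates:
        return
    ref = min(all_leaves)
    counts: dict = {}
    for rep in replicates:
        for _, side in child_side_leafsets(rep):
            if 1 < len(side) < len(all_leaves) - 1:
                key = _split_key(side, all_leaves, ref)
                counts[key] = counts.get(key, 0) + 1
    # deduplicate per-replicate double counting (a split seen from both sides)
    for edge, side in child_side_leafsets(ml_tree):
        nd = edge.head_node
        if nd.is_leaf():
            continue
        if 1 < len(side) < len(all_leaves) - 1:
            freq = counts.get(_split_key(side, all_leaves, ref), 0)
            support = 100.0 * min(freq, len(replicates)) / len(replicates)
            nd.support = support
            nd.label = f"{support:g}"


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    genomes = make_genomes(config.group_sizes)
    taxonomy = make_taxonomy(genomes)
    species = dendropy.Tree.get(
        data=species_tree_newick(genomes, config.sister), schema="newick"
    )
    as_unrooted(species)

    categories = list(PATTERN_CATEGORIES)
    freqs = np.array([config.pattern_freqs.get(c, 0.0) for c in categories])
    ss = np.random.SeedSequence(config.seed)
    family_seeds = ss.spawn(config.n_families)

    families, all_hits = [], []
    truth_rows = []
    direct_rows, hitann_rows, go_rows = [], [], []
    model = config.evalue_model
    donor_lineages = sorted(config.lgt_donor_weights)

    for idx in range(config.n_families):
        rng = np.random.default_rng(family_seeds[idx])
        family_id = f"fam{idx:04d}"
        pattern = categories[rng.choice(len(categories), p=freqs)]
        lineages = _present_lineages(pattern)
        present = list(genomes["FOCAL"])
        for lin in lineages:
            present.extend(genomes[lin])
        tree = _relabelled_family_tree(species, present, family_id)
        proteins = {g: f"{g}.{family_id}" for g in present}

        lgt_event = None
        if lineages and rng.random() < config.p_lgt:
            weights = np.array(
                [
                    config.lgt_donor_weights.get(lin, 0.0) if lin in lineages else 0.0
                    for lin in donor_lineages
                ]
            )
            if weights.sum() > 0:
                weights = weights / weights.sum()
                donor_lin = donor_lineages[rng.choice(len(donor_lineages), p=weights)]
                recipient_g = genomes["FOCAL"][rng.integers(3)]
                donor_g = genomes[donor_lin][rng.integers(len(genomes[donor_lin]))]
                _regraft(tree, proteins[recipient_g], proteins[donor_g])
                lgt_event = (donor_lin, proteins[recipient_g])

        # similarity hits: every focal protein queried against every member
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace if t.label in
                {l.taxon.label for l in tree.leaf_node_iter()}}
        hit_rows = []
        for fg in genomes["FOCAL"]:
            q = proteins[fg]
            for g in present:
                if g == fg:
                    continue
                s_id = proteins[g]
                d = pdm.patristic_distance(taxa[q], taxa[s_id])
                eps = rng.standard_normal() if model.noise_sd > 0 else 0.0
                v = model.log10_evalue(d, eps)
                hit_rows.append(
                    SimilarityHit(q, s_id, 10.0 ** v, max(0.0, round(10 - 2 * v, 1)))
                )
        all_hits.extend(hit_rows)

        # bootstrap replicates: NNI-perturbed copies of the (post-LGT) tree
        replicates = []
        for _ in range(config.n_bootstrap):
            rep = tree.clone(depth=1)
            _nni_perturb(rep, rng, config.bootstrap_perturb)
            replicates.append(rep)
        _attach_supports_from_replicates(tree, replicates)

        # functional annotation
        if rng.random() < config.p_unknown_function:
            cog = "unknown"
        else:
            cog = COG_LETTERS[rng.integers(len(COG_LETTERS))]
        if cog != "unknown":
            if rng.random() < config.p_direct_map:
                direct_rows.append((proteins["Aqx"], cog))
            for h in hit_rows:
                if h.query_id == proteins["Aqx"] and protein_genome(
                    h.subject_id
                ) not in FOCAL_CODES:
                    if rng.random() < 0.9:
                        hitann_rows.append((h.subject_id, cog, h.evalue))
            evidence = "IDA" if rng.random() < 0.8 else "IEA"
            go_rows.append((proteins["Sul"], cog, evidence))

        fam = SimFamily(
            family_id=family_id,
            true_pattern=pattern,
            lgt_event=lgt_event,
            ml_tree=tree,
            replicates=replicates,
            hit_rows=hit_rows,
            members=[proteins[g] for g in present],
            true_cog=cog,
        )
        families.append(fam)
        truth_rows.append(
            {
                "family_id": family_id,
                "pattern": pattern,
                "n_genomes": len(present),
                "lgt_donor": lgt_event[0] if lgt_event else "",
                "lgt_recipient": lgt_event[1] if lgt_event else "",
                "expect_clean": "" if pattern == "FocalOnly" else str(lgt_event is None),
                "expect_cohesive": str(lgt_event is None),
                "true_cog": cog,
            }
        )

    return SimDataset(
        config=config,
        taxonomy=taxonomy,
        families=families,
        hits=all_hits,
        direct_map=pd.DataFrame(direct_rows, columns=["protein_id", "cog_category"]),
        hit_annotations=pd.DataFrame(
            hitann_rows, columns=["protein_id", "cog_category", "evalue"]
        ),
        go_annotations=pd.DataFrame(
            go_rows, columns=["protein_id", "cog_category", "evidence_code"]
        ),
        truth=pd.DataFrame(truth_rows),
        genomes_by_lineage=genomes,
    )
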