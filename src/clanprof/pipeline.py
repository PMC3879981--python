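"""End-to-end orchestration: simulate → cluster → profile → classify →
treestats → vpi → heatmap, with a manifest recording inputs and thresholds.

The pipeline operates on a dataset directory in the layout the synthetic
generator writes (taxonomy.tsv, hits.tsv, trees/, annotations/) and drops its
stage outputs plus ``manifest.json`` and ``report.json`` into an output
directory. Every threshold of the analysis is a named, defaulted
configuration key.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .clustering import build_focal_graph, extract_clusters
from .funcstats import affinity_matrix, assign_function, plot_affinity_heatmap, vpi_table
from .io_formats import GroupDef, read_similarity_table, read_taxonomy, read_tree_set
from .profiles import (
    GroupScheme,
    build_profile,
    partition_pattern,
    profile_summary,
    rank_and_classify,
)
from .synthetic_data import (
    FOCAL_CODES,
    SimConfig,
    protein_genome,
    simulate_dataset,
)
from .treeops import balance_of_support, is_cohesive, pairing_support

STAGES = ("simulate", "cluster", "profile", "classify", "treestats", "vpi", "heatmap")

DEFAULT_THRESHOLDS = {
    "e_bidir": 1e-10,
    "e_member": 1e-5,
    "e_func": 1e-15,
    "trim": 0.80,
    "min_support": 70.0,
    "balance_strong": 0.70,
}


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    seed: int = 0
    simulate: dict | None = None  # SimConfig keyword overrides, or None to reuse
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    focal_priority: list = field(default_factory=lambda: ["Aqx", "Hyb", "Sul"])
    balance_pairs: list = field(default_factory=lambda: [["E", "T"], ["E", "R"], ["T", "R"]])

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key in ("e_bidir", "e_member", "e_func"):
            if not self.thresholds[key] > 0:
                raise ValueError(f"{key} must be positive")
        if not 0 <= self.thresholds["trim"] <= 1:
            raise ValueError("trim threshold must lie in [0, 1]")
        if not 0 <= self.thresholds["min_support"] <= 100:
            raise ValueError("min_support must lie in [0, 100]")


def scheme_from_taxonomy(taxonomy: pd.DataFrame) -> GroupScheme:
    """Derive the focal/R/E/T group scheme from a taxonomy table.

    Focal = the Aquificae-like phylum; R = domain Archaea; E = the
    epsilon-like class; T = the Thermotogae-like phylum, mirroring the
    original grouping semantics.
    """
    focal = sorted(
        taxonomy.loc[taxonomy["phylum"].str.contains("Aquificae"), "genome_id"]
    )
    if not focal:
        raise ValueError("taxonomy contains no Aquificae-like focal phylum")
    if set(focal) == set(FOCAL_CODES):
        codes = dict(FOCAL_CODES)
    else:
        codes = {g: chr(ord("A") + i) for i, g in enumerate(focal)}
    named = {
        "R": frozenset(taxonomy.loc[taxonomy["domain"] == "Archaea", "genome_id"]),
        "E": frozenset(
            taxonomy.loc[taxonomy["class_name"].str.contains("Epsilon"), "genome_id"]
        ),
        "T": frozenset(
            taxonomy.loc[taxonomy["phylum"].str.contains("Thermotogae"), "genome_id"]
        ),
    }
    return GroupScheme(
        focal_codes=codes,
        named={c: GroupDef(c, m) for c, m in named.items()},
    )


def lineage_map_from_taxonomy(taxonomy: pd.DataFrame, scheme: GroupScheme) -> dict:
    out = {}
    for g in taxonomy["genome_id"]:
        if g in scheme.focal_codes:
            out[g] = "FOCAL"
        else:
            out[g] = scheme.named_of(g) or "OTHER"
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "stages": [],
    }
    report: dict = {}

    def stage_done(name, **info):
        manifest["stages"].append({"name": name, "status": "complete", **info})

    # -- simulate -----------------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        dataset = simulate_dataset(SimConfig(**sim_kwargs))
        dataset.write(config.data_dir)
        stage_done("simulate", n_families=len(dataset.families))
    else:
        stage_done("simulate", skipped="existing dataset reused")

    tax_path = os.path.join(config.data_dir, "taxonomy.tsv")
    hits_path = os.path.join(config.data_dir, "hits.tsv")
    for path in (tax_path, hits_path):
        if not os.path.exists(path):
            raise FileNotFoundError(f"pipeline stage 'cluster': missing input {path}")
    manifest["inputs"] = {
        os.path.basename(p): _sha256(p) for p in (tax_path, hits_path)
    }

    taxonomy = read_taxonomy(tax_path)
    scheme = scheme_from_taxonomy(taxonomy)
    lineages = lineage_map_from_taxonomy(taxonomy, scheme)
    hits = read_similarity_table(hits_path, max_evalue=10.0)
    focal = scheme.focal_group()
    thr = config.thresholds

    # -- cluster ------------------------------------------------------------
    graph = build_focal_graph(hits, focal, protein_genome, e_bidir=thr["e_bidir"])
    clusters = extract_clusters(
        graph, hits, protein_genome, config.focal_priority, e_member=thr["e_member"]
    )
    pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "seed_protein": [c.seed_protein for c in clusters],
            "copy_class": [c.copy_class for c in clusters],
            "members": [",".join(sorted(c.members)) for c in clusters],
        }
    ).to_csv(os.path.join(config.out_dir, "clusters.tsv"), sep="\t", index=False)
    stage_done("cluster", n_clusters=len(clusters))
    report["n_clusters"] = len(clusters)

    # -- profile ------------------------------------------------------------
    profiles = [build_profile(c, protein_genome, scheme) for c in clusters]
    pd.DataFrame(
        {
            "cluster_id": [p.cluster_id for p in profiles],
            "focal_subset": ["".join(sorted(p.focal_subset)) for p in profiles],
            "category": [partition_pattern(p) for p in profiles],
            "has_other": [p.has_other for p in profiles],
        }
    ).to_csv(os.path.join(config.out_dir, "profiles.tsv"), sep="\t", index=False)
    stage_done("profile", n_profiles=len(profiles))

    # -- classify -----------------------------------------------------------
    ranked = [
        rank_and_classify(c, hits, protein_genome, scheme, config.focal_priority)
        for c in clusters
    ]
    summary = profile_summary(profiles, ranked)
    summary.to_csv(os.path.join(config.out_dir, "classification_summary.tsv"),
                   sep="\t", index=False)
    pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in ranked],
            "query": [r.query_protein for r in ranked],
            "classification": [r.classification for r in ranked],
        }
    ).to_csv(os.path.join(config.out_dir, "ranked.tsv"), sep="\t", index=False)
    n_clean = sum(r.classification == "clean" for r in ranked)
    n_dirty = sum(r.classification == "dirty" for r in ranked)
    stage_done("classify", n_clean=n_clean, n_dirty=n_dirty)
    report["n_clean"] = n_clean
    report["n_dirty"] = n_dirty

    # -- treestats ----------------------------------------------------------
    tree_rows = []
    tree_sets = {}
    for ml_path in sorted(glob.glob(os.path.join(config.data_dir, "trees", "*.ml.nwk"))):
        fam = os.path.basename(ml_path)[: -len(".ml.nwk")]
        boot_path = ml_path[: -len(".ml.nwk")] + ".boot.nwk"
        if not os.path.exists(boot_path):
            continue
        ts = read_tree_set(ml_path, boot_path, protein_genome)
        tree_sets[fam] = ts
        focal_leaves = ts.group_leaves(focal)
        cohesive = is_cohesive(ts.ml_tree, focal_leaves) if focal_leaves else False
        row = {"family_id": fam, "cohesive": cohesive}
        for x_code, y_code in config.balance_pairs:
            x, y = scheme.named[x_code], scheme.named[y_code]
            try:
                b = balance_of_support(ts, focal, x, y)
                row[f"balance_{x_code}{y_code}"] = b.score
            except ValueError:
                row[f"balance_{x_code}{y_code}"] = None
        row["pairing"] = ",".join(
            sorted(pairing_support(ts, focal, lineages, thr["min_support"]))
        )
        tree_rows.append(row)
    pd.DataFrame(tree_rows).to_csv(
        os.path.join(config.out_dir, "treestats.tsv"), sep="\t", index=False
    )
    stage_done("treestats", n_trees=len(tree_rows))
    report["n_trees"] = len(tree_rows)
    report["n_cohesive"] = sum(1 for r in tree_rows if r["cohesive"])

    # -- vpi ----------------------------------------------------------------
    ann_dir = os.path.join(config.data_dir, "annotations")
    direct = pd.read_csv(os.path.join(ann_dir, "direct_map.tsv"), sep="\t", dtype=str)
    hit_ann = pd.read_csv(os.path.join(ann_dir, "hit_annotations.tsv"), sep="\t")
    go_ann = pd.read_csv(os.path.join(ann_dir, "go_annotations.tsv"), sep="\t", dtype=str)
    direct_map = dict(zip(direct["protein_id"], direct["cog_category"]))
    assignments = {
        c.cluster_id: assign_function(c, direct_map, hit_ann, go_ann, thr["e_func"])
        for c in clusters
    }
    by_category: dict = {}
    for p in profiles:
        cat = assignments[p.cluster_id].cog_category
        by_category.setdefault(cat, []).append(p)
    vpi = vpi_table(by_category)
    vpi.to_csv(os.path.join(config.out_dir, "vpi.tsv"), sep="\t", index=False)
    stage_done("vpi", n_categories=len(vpi))

    # -- heatmap ------------------------------------------------------------
    trees_by_category: dict = {}
    for c in clusters:
        fam = c.seed_protein.split(".", 1)[1]
        if fam in tree_sets:
            cat = assignments[c.cluster_id].cog_category
            trees_by_category.setdefault(cat, []).append(tree_sets[fam])
    matrix = affinity_matrix(trees_by_category, focal, lineages, thr["min_support"])
    matrix.to_csv(os.path.join(config.out_dir, "affinity.tsv"), sep="\t")
    if matrix.size:
        plot_affinity_heatmap(matrix, os.path.join(config.out_dir, "heatmap.png"))
    stage_done("heatmap", n_categories=len(matrix))

    report["summary_table"] = summary.to_dict(orient="records")
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
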