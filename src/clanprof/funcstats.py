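"""Functional-category assignment, the Variable Preference Index, and the
category × lineage affinity matrix.

COG assignment follows a four-step priority: (1) a direct locus→COG map for
clusters containing a protein of the primary focal genome, (2) majority vote
over annotated BLAST matches at a strict e-value cutoff (default 1e-15),
(3) GO-derived COG labels restricted to experimentally or computationally
verified evidence codes, (4) "unknown"/poorly characterized. Voting ties fall
through to the next step so the assignment is deterministic.

The VPI for a partner group G, within one functional category, is the number
of non-ubiquitous profiles containing G (every partition category with G
except the ubiquitous one naming all partners) over the number of profiles
that have any partner at all (everything except focal-only profiles).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import HomologCluster
from .profiles import NAMED_ORDER, PhyleticProfile, partition_pattern
from .treeops import pairing_support

#: the 25 single-letter COG functional categories and their parent category
COG_PARENTS = {
    **{c: "information storage and processing" for c in "JAKLB"},
    **{c: "cellular processes and signaling" for c in "DYVTMNZWUO"},
    **{c: "metabolism" for c in "CGEFHIPQ"},
    **{c: "poorly characterized" for c in "RS"},
}

#: GO evidence codes accepted for step 3 of the assignment
ALLOWED_GO_EVIDENCE = frozenset(
    {"IMP", "IGI", "IPI", "IDA", "IEP", "ISS", "IGC", "ICA"}
)


@dataclass(frozen=True)
class FunctionAssignment:
    cluster_id: str
    cog_category: str  # single letter or "unknown"
    source: str  # direct_map | majority_vote | go_map | unassigned

    def __post_init__(self) -> None:
        if (self.source == "unassigned") != (self.cog_category == "unknown"):
            raise ValueError("source=unassigned iff cog_category='unknown'")


@dataclass
class VPIResult:
    group: str
    numerator: int
    denominator: int
    value: float  # NaN when undefined (denominator 0)

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def _unique_majority(votes: Iterable[str]):
    """Most frequent label, or ``None`` on an empty vote or a tie for first."""
    counts = Counter(votes)
    if not counts:
        return None
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def assign_function(
    cluster: HomologCluster,
    direct_map: Mapping[str, str],
    hit_annotations: pd.DataFrame,
    go_annotations: pd.DataFrame,
    e_max: float = 1e-15,
) -> FunctionAssignment:
    """Four-step priority COG assignment for one cluster.

    ``direct_map`` maps protein ids of the primary focal genome to COG
    letters. ``hit_annotations`` has columns (protein_id, cog_category,
    evalue): the COG of an annotated BLAST match and the e-value linking it
    to the cluster. ``go_annotations`` has columns (protein_id, cog_category,
    evidence_code): GO-derived COG labels. A tie at any voting step falls
    through to the next.
    """
    # step 1: direct map
    direct_votes = [
        direct_map[p] for p in sorted(cluster.members) if p in direct_map
    ]
    label = _unique_majority(direct_votes)
    if label is not None:
        return FunctionAssignment(cluster.cluster_id, label, "direct_map")
    # step 2: majority vote over annotated hits at e-value <= e_max
    if len(hit_annotations):
        sub = hit_annotations[
            hit_annotations["protein_id"].isin(cluster.members)
            & (hit_annotations["evalue"].astype(float) <= e_max)
        ]
        label = _unique_majority(sub["cog_category"])
        if label is not None:
            return FunctionAssignment(cluster.cluster_id, label, "majority_vote")
    # step 3: GO-derived labels with verified evidence
    if len(go_annotations):
        sub = go_annotations[
            go_annotations["protein_id"].isin(cluster.members)
            & go_annotations["evidence_code"].isin(ALLOWED_GO_EVIDENCE)
        ]
        label = _unique_majority(sub["cog_category"])
        if label is not None:
            return FunctionAssignment(cluster.cluster_id, label, "go_map")
    # step 4: unknown
    return FunctionAssignment(cluster.cluster_id, "unknown", "unassigned")


def parent_category(cog_letter: str) -> str:
    return COG_PARENTS.get(cog_letter, "poorly characterized")


def compute_vpi(category_profiles: Sequence, group: str) -> VPIResult:
    """VPI for one partner group over one functional category's profiles.

    ``category_profiles`` may hold PhyleticProfile objects or partition
    category strings. Numerator: profiles whose category contains ``group``,
    excluding the ubiquitous category naming every partner lineage.
    Denominator: all profiles except focal-only ones.
    """
    if group not in NAMED_ORDER:
        raise ValueError(f"invalid group code {group!r}; expected one of {NAMED_ORDER}")
    ubiquitous = NAMED_ORDER  # e.g. "RET"
    categories = [
        c if isinstance(c, str) else partition_pattern(c) for c in category_profiles
    ]
    numerator = sum(
        1 for c in categories if group in c and c != ubiquitous
    )
    denominator = sum(1 for c in categories if c != "FocalOnly")
    value = numerator / denominator if denominator else math.nan
    return VPIResult(
        group=group, numerator=numerator, denominator=denominator, value=value
    )


def vpi_table(profiles_by_category: Mapping[str, Sequence]) -> pd.DataFrame:
    """VPI for every named partner group across functional categories."""
    rows = []
    for category in sorted(profiles_by_category):
        profiles = profiles_by_category[category]
        row = {"category": category, "n_profiles": len(profiles)}
        for g in NAMED_ORDER:
            res = compute_vpi(profiles, g)
            row[f"vpi_{g}"] = res.value
        rows.append(row)
    return pd.DataFrame(rows)


def affinity_matrix(
    trees_by_category: Mapping[str, Sequence],
    focal,
    lineage_map: Mapping[str, str],
    min_support: float = 70.0,
) -> pd.DataFrame:
    """Fraction of each category's trees that strongly pair the focal clan
    with each lineage (rows: categories with ≥1 tree; columns: lineages)."""
    lineages = sorted(set(lineage_map.values()))
    rows: dict = {}
    for category in sorted(trees_by_category):
        tree_sets = trees_by_category[category]
        if not tree_sets:
            continue
        counts = Counter()
        for ts in tree_sets:
            for lin in pairing_support(ts, focal, lineage_map, min_support):
                counts[lin] += 1
        rows[category] = {
            lin: counts.get(lin, 0) / len(tree_sets) for lin in lineages
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=lineages).rename_axis(
        "category"
    )


def plot_affinity_heatmap(matrix: pd.DataFrame, out_path) -> None:
    """Render the affinity matrix as a blue-to-red heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.4 * matrix.shape[0])
    )
    im = ax.imshow(matrix.values, cmap="coolwarm", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=90)
    ax.set_yticks(range(matrix.shape[0]), labels=list(matrix.index))
    fig.colorbar(im, ax=ax, label="fraction of trees")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
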