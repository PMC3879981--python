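"""Phyletic profiles and the ranked-similarity clean/dirty classifier.

A phyletic profile records, per homolog cluster, which genomes are present,
which focal genomes (single-letter codes, e.g. A/H/S) are covered, which of
the named partner lineages (R = Archaea, E = Epsilonproteobacteria,
T = Thermotogae in the original setting) appear, and whether any genome
outside those groups appears. Profiles support the ø/* predicate notation:
``"ET-ø"`` means the named groups and no others accompany the focal lineage,
``"ET-*"`` means they are present and anything else may be too.

The ranked classifier orders a cluster's members by e-value against a focal
query protein; a cluster is *clean* when the other focal proteins occupy
exactly the top consecutive ranks 2…k+1, *dirty* when a foreign protein
interleaves, and *degenerate* when there is no non-focal member at all.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .clustering import HomologCluster
from .io_formats import GroupDef

#: canonical ordering of named partner-lineage codes in pattern strings
NAMED_ORDER = "RET"

_PATTERN_RE = re.compile(r"^([A-Z]+)-([*øo0])$")


@dataclass(frozen=True)
class GroupScheme:
    """How genomes map onto focal codes and named partner lineages.

    ``focal_codes`` maps each focal genome id to its single-letter code;
    ``named`` maps a lineage code (subset of ``NAMED_ORDER``) to its GroupDef.
    Genomes in neither are "other".
    """

    focal_codes: Mapping[str, str]
    named: Mapping[str, GroupDef]

    @property
    def focal_genomes(self) -> frozenset:
        return frozenset(self.focal_codes)

    def focal_group(self) -> GroupDef:
        return GroupDef("FOCAL", frozenset(self.focal_codes))

    def named_of(self, genome: str):
        for code, group in self.named.items():
            if genome in group.members:
                return code
        return None


@dataclass(frozen=True)
class PhyleticProfile:
    cluster_id: str
    present_genomes: frozenset
    focal_subset: frozenset  # focal codes, non-empty
    named_pattern: frozenset  # subset of the named lineage codes
    has_other: bool

    def __post_init__(self) -> None:
        if not self.focal_subset:
            raise ValueError("focal_subset must be non-empty")


@dataclass
class RankedProfile:
    cluster_id: str
    query_protein: str
    ranked_subjects: list  # (protein_id, evalue) ascending, ranks 2..n+1
    focal_ranks: list
    k: int
    classification: str  # "clean" | "dirty" | "degenerate"


def build_profile(
    cluster: HomologCluster, protein_to_genome, scheme: GroupScheme
) -> PhyleticProfile:
    """Genome-level presence profile of a cluster with pattern labels."""
    genome_of = protein_to_genome if callable(protein_to_genome) else (
        lambda p: protein_to_genome[p]
    )
    present = set()
    for p in cluster.members:
        try:
            present.add(genome_of(p))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"member protein {p!r} maps to no genome") from exc
    focal_subset = frozenset(
        scheme.focal_codes[g] for g in present if g in scheme.focal_codes
    )
    named_pattern = frozenset(
        code for code in scheme.named if present & scheme.named[code].members
    )
    named_members = frozenset().union(
        *(g.members for g in scheme.named.values())
    ) if scheme.named else frozenset()
    has_other = bool(present - scheme.focal_genomes - named_members)
    return PhyleticProfile(
        cluster_id=cluster.cluster_id,
        present_genomes=frozenset(present),
        focal_subset=focal_subset,
        named_pattern=named_pattern,
        has_other=has_other,
    )


def partition_pattern(profile: PhyleticProfile) -> str:
    """Mutually exclusive profile category: the named pattern when non-empty,
    else ``"Other"`` or ``"FocalOnly"``."""
    if profile.named_pattern:
        return "".join(c for c in NAMED_ORDER if c in profile.named_pattern) + "".join(
            sorted(profile.named_pattern - set(NAMED_ORDER))
        )
    return "Other" if profile.has_other else "FocalOnly"


def parse_pattern_query(query: str):
    """Parse a pattern predicate such as ``"ET-*"`` or ``"E-ø"``.

    Returns ``(frozenset_of_codes, exclusive)``. The ASCII aliases ``o`` and
    ``0`` are accepted for ``ø``.
    """
    m = _PATTERN_RE.match(query)
    if not m:
        raise ValueError(f"malformed pattern query: {query!r}")
    letters, marker = m.groups()
    codes = frozenset(letters)
    if len(codes) != len(letters):
        raise ValueError(f"repeated lineage code in pattern query: {query!r}")
    if not codes <= set(NAMED_ORDER):
        raise ValueError(
            f"pattern query {query!r} names codes outside {NAMED_ORDER!r}"
        )
    return codes, marker != "*"


def match_pattern(profile: PhyleticProfile, query: str) -> bool:
    """ø/* predicate on a profile.

    ``X-*`` (inclusive): all named groups of X present, others unconstrained.
    ``X-ø`` (exclusive): all of X present and no genome outside the focal
    lineage and X — other named lineages and "other" genomes both absent.
    """
    codes, exclusive = parse_pattern_query(query)
    if exclusive:
        return profile.named_pattern == codes and not profile.has_other
    return codes <= profile.named_pattern


def rank_and_classify(
    cluster: HomologCluster,
    hits,
    protein_to_genome,
    scheme: GroupScheme,
    query_priority: Sequence[str],
) -> RankedProfile:
    """Rank a cluster's members by e-value against the focal query protein.

    The query comes from the highest-priority focal genome represented in the
    cluster (lexicographically smallest protein if several copies). Subjects
    sort by ascending e-value, ties by descending bit score then protein id;
    a missing query→subject hit ranks last (e-value +inf). ``clean`` iff the
    other focal proteins occupy exactly ranks 2…k+1; ``degenerate`` when the
    cluster has no non-focal member.
    """
    genome_of = protein_to_genome if callable(protein_to_genome) else (
        lambda p: protein_to_genome[p]
    )
    query = None
    for gid in query_priority:
        candidates = sorted(p for p in cluster.members if genome_of(p) == gid)
        if candidates:
            query = candidates[0]
            break
    if query is None:
        raise ValueError(
            f"no protein from priority genomes {list(query_priority)} in "
            f"cluster {cluster.cluster_id}"
        )
    lookup: dict = {}
    for h in hits:
        if h.query_id != query:
            continue
        key = h.subject_id
        cur = lookup.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur[0], -cur[1]):
            lookup[key] = (h.evalue, h.bitscore)
    subjects = sorted(
        (p for p in cluster.members if p != query),
        key=lambda p: (
            lookup.get(p, (math.inf, 0.0))[0],
            -lookup.get(p, (math.inf, 0.0))[1],
            p,
        ),
    )
    focal_set = {
        p for p in cluster.members if genome_of(p) in scheme.focal_genomes
    } - {query}
    k = len(focal_set)
    focal_ranks = sorted(
        rank for rank, p in enumerate(subjects, start=2) if p in focal_set
    )
    if len(subjects) == len(focal_set):
        classification = "degenerate"
    elif focal_ranks == list(range(2, k + 2)):
        classification = "clean"
    else:
        classification = "dirty"
    return RankedProfile(
        cluster_id=cluster.cluster_id,
        query_protein=query,
        ranked_subjects=[
            (p, lookup.get(p, (math.inf, 0.0))[0]) for p in subjects
        ],
        focal_ranks=focal_ranks,
        k=k,
        classification=classification,
    )


def percent(numerator: int, denominator: int):
    """Whole-number percentage, round-half-up (``None`` on a 0 denominator)."""
    if denominator == 0:
        return None
    return int(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def profile_summary(
    profiles: Sequence[PhyleticProfile], ranked: Sequence[RankedProfile]
) -> pd.DataFrame:
    """Counts and whole-number percentages per focal-subset × pattern category.

    ``profiles`` and ``ranked`` must be aligned by cluster_id. Degenerate
    (focal-only) clusters are excluded from the clean/dirty denominators.
    """
    if [p.cluster_id for p in profiles] != [r.cluster_id for r in ranked]:
        raise ValueError("profiles and classifications not aligned by cluster_id")
    rows: dict = {}
    for p, r in zip(profiles, ranked):
        subset = "".join(sorted(p.focal_subset))
        key = (subset, partition_pattern(p))
        entry = rows.setdefault(
            key, {"n": 0, "clean": 0, "dirty": 0, "degenerate": 0}
        )
        entry["n"] += 1
        entry[r.classification] += 1
    out = []
    for (subset, category), entry in sorted(rows.items()):
        denom = entry["clean"] + entry["dirty"]
        out.append(
            {
                "focal_subset": subset,
                "category": category,
                "n": entry["n"],
                "n_clean": entry["clean"],
                "n_dirty": entry["dirty"],
                "n_degenerate": entry["degenerate"],
                "pct_clean": percent(entry["clean"], denom),
                "pct_dirty": percent(entry["dirty"], denom),
            }
        )
    df = pd.DataFrame(
        out,
        columns=[
            "focal_subset",
            "category",
            "n",
            "n_clean",
            "n_dirty",
            "n_degenerate",
            "pct_clean",
            "pct_dirty",
        ],
    )
    # nullable ints keep whole-number percentages printable next to NAs
    df["pct_clean"] = df["pct_clean"].astype("Int64")
    df["pct_dirty"] = df["pct_dirty"].astype("Int64")
    return df
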