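"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* similarity hits — BLAST tabular (``-outfmt 6``) TSV; only columns 1, 2, 11
  and 12 (query, subject, e-value, bit score) are interpreted, a bare 4-column
  dialect is also accepted;
* taxonomy and annotation tables — header-bearing TSV, via pandas;
* gene trees — Newick (maximum-likelihood tree plus bootstrap replicates),
  via dendropy, with edge supports normalised to the 0–100 scale;
* confidence-annotated alignments — FASTA plus a one-line sidecar file of
  comma-separated per-column posterior probabilities in [0, 1].

Alignment-column trimming at a consensus-confidence threshold also lives here
because it is a pure transformation of the on-disk alignment representation.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .treeops import GeneTreeSet, normalize_supports, as_unrooted

GAP_CHARS = frozenset({"-", "."})

TEMP_CLASSES = frozenset(
    {"mesophile", "thermophile", "hyperthermophile", "psychrophile", "unknown"}
)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity record (a BLASTP-style hit)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for ({self.query_id},{self.subject_id})")


@dataclass(frozen=True)
class TaxonRecord:
    genome_id: str
    domain: str
    phylum: str
    class_name: str
    genus: str
    temp_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.temp_class not in TEMP_CLASSES:
            raise ValueError(
                f"temp_class {self.temp_class!r} not in {sorted(TEMP_CLASSES)}"
            )


@dataclass(frozen=True)
class GroupDef:
    """A named group of genomes (e.g. the focal lineage, or partner lineage R)."""

    code: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class ConfAlignment:
    """A multiple alignment with one confidence value per column.

    ``sequences`` is an ordered list of ``(id, residues)`` pairs; all rows have
    equal length, matching ``len(column_confidence)``.
    """

    sequences: list
    column_confidence: list
    name: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ncol = lengths.pop() if lengths else 0
        if len(self.column_confidence) != ncol:
            raise ValueError(
                f"confidence track length {len(self.column_confidence)} != "
                f"alignment length {ncol}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.column_confidence)


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# similarity tables
# ---------------------------------------------------------------------------

def parse_similarity_rows(lines: Iterable[str], max_evalue: float):
    """Parse outfmt-6-like rows, filter by ``max_evalue`` and deduplicate.

    Duplicate ordered (query, subject) pairs are collapsed keeping the
    smallest e-value; e-value ties keep the larger bit score, then the first
    occurrence. Output order is order of first occurrence.
    """
    best: dict = {}
    order: list = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 12:
            q, s, ev, bs = parts[0], parts[1], parts[10], parts[11]
        elif len(parts) >= 4:
            q, s, ev, bs = parts[0], parts[1], parts[2], parts[3]
        else:
            raise ValueError(f"malformed similarity row at line {lineno}: {line!r}")
        try:
            evalue = float(ev)
            bitscore = float(bs)
        except ValueError as exc:
            raise ValueError(
                f"malformed similarity row at line {lineno}: {line!r}"
            ) from exc
        if evalue < 0:
            raise ValueError(f"negative e-value at line {lineno}: {evalue}")
        if evalue > max_evalue:
            continue
        hit = SimilarityHit(q, s, evalue, bitscore)
        key = (q, s)
        if key not in best:
            best[key] = hit
            order.append(key)
        else:
            cur = best[key]
            if (hit.evalue, -hit.bitscore) < (cur.evalue, -cur.bitscore):
                best[key] = hit
    return [best[k] for k in order]


def read_similarity_table(path, max_evalue: float = 10.0):
    """Read a BLAST tabular file, keeping hits with e-value ≤ ``max_evalue``."""
    with _open_text(path) as fh:
        return parse_similarity_rows(fh, max_evalue)


def write_similarity_table(hits: Sequence[SimilarityHit], path) -> None:
    """Write hits as 12-column outfmt-6 rows (unused columns zero-filled)."""
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# taxonomy and annotation tables
# ---------------------------------------------------------------------------

TAXONOMY_COLUMNS = ["genome_id", "domain", "phylum", "class_name", "genus", "temp_class"]


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    if df["genome_id"].duplicated().any():
        dups = sorted(df.loc[df["genome_id"].duplicated(), "genome_id"])
        raise ValueError(f"duplicate genome_id in taxonomy table: {dups}")
    bad = set(df["temp_class"]) - TEMP_CLASSES
    if bad:
        raise ValueError(f"unknown temp_class values: {sorted(bad)}")
    return df[TAXONOMY_COLUMNS].copy()


def write_taxonomy(df: pd.DataFrame, path) -> None:
    df[TAXONOMY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# tree sets
# ---------------------------------------------------------------------------

def _resolve_leaves(tree: dendropy.Tree, leaf_to_genome) -> dict:
    """Map every leaf label of ``tree`` through ``leaf_to_genome``.

    ``leaf_to_genome`` may be a mapping or a callable; unresolvable labels
    raise a ValueError listing all offenders.
    """
    if callable(leaf_to_genome):
        fn = leaf_to_genome
    else:
        fn = lambda l: leaf_to_genome[l]  # noqa: E731
    mapping, bad = {}, []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        try:
            mapping[label] = fn(label)
        except (KeyError, ValueError):
            bad.append(label)
    if bad:
        raise ValueError(f"unresolvable leaf labels: {sorted(bad)}")
    return mapping


def read_tree_set(ml_path, bootstrap_path, leaf_to_genome) -> GeneTreeSet:
    """Read an ML Newick tree plus its bootstrap replicates.

    All trees are treated as unrooted. Edge supports on the ML tree are read
    from internal-node labels and normalised to [0, 100] (a real in [0, 1]
    with a decimal point is scaled ×100). Every replicate must carry exactly
    the ML tree's leaf set.
    """
    tns = dendropy.TaxonNamespace()
    ml = dendropy.Tree.get(path=str(ml_path), schema="newick", taxon_namespace=tns)
    as_unrooted(ml)
    normalize_supports(ml)
    if os.path.getsize(bootstrap_path) == 0:
        raise ValueError(f"empty bootstrap replicate file: {bootstrap_path}")
    replicates = dendropy.TreeList.get(
        path=str(bootstrap_path), schema="newick", taxon_namespace=tns
    )
    if len(replicates) == 0:
        raise ValueError(f"empty bootstrap replicate file: {bootstrap_path}")
    ml_leaves = {l.taxon.label for l in ml.leaf_node_iter()}
    for i, rep in enumerate(replicates):
        as_unrooted(rep)
        rep_leaves = {l.taxon.label for l in rep.leaf_node_iter()}
        if rep_leaves != ml_leaves:
            extra = sorted(rep_leaves - ml_leaves)
            lost = sorted(ml_leaves - rep_leaves)
            raise ValueError(
                f"replicate {i} leaf set differs from ML tree "
                f"(extra={extra}, missing={lost})"
            )
    genome_of = _resolve_leaves(ml, leaf_to_genome)
    return GeneTreeSet(
        ml_tree=ml,
        replicates=list(replicates),
        n_replicates=len(replicates),
        leaf_to_genome=genome_of,
    )


def write_tree_set(tree_set: GeneTreeSet, ml_path, bootstrap_path) -> None:
    tree_set.ml_tree.write(
        path=str(ml_path),
        schema="newick",
        suppress_rooting=True,
        suppress_annotations=True,
    )
    with open(bootstrap_path, "w") as fh:
        for rep in tree_set.replicates:
            fh.write(
                rep.as_string(
                    schema="newick", suppress_rooting=True, suppress_annotations=True
                )
            )


# ---------------------------------------------------------------------------
# confidence-annotated alignments
# ---------------------------------------------------------------------------

def read_conf_alignment(fasta_path, conf_path=None, name=None) -> ConfAlignment:
    """Read FASTA plus the parallel one-line confidence sidecar.

    The sidecar defaults to ``<fasta_path>.conf`` and holds comma-separated
    reals in [0, 1], one per alignment column.
    """
    from Bio import SeqIO

    if conf_path is None:
        conf_path = str(fasta_path) + ".conf"
    sequences = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    with _open_text(conf_path) as fh:
        text = fh.read().strip()
    confidences = [float(x) for x in text.split(",")] if text else []
    for c in confidences:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"column confidence {c} outside [0, 1]")
    if name is None:
        name = os.path.splitext(os.path.basename(str(fasta_path)))[0]
    return ConfAlignment(sequences=sequences, column_confidence=confidences, name=name)


def write_conf_alignment(aln: ConfAlignment, fasta_path, conf_path=None) -> None:
    if conf_path is None:
        conf_path = str(fasta_path) + ".conf"
    with _open_text(fasta_path, "wt") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")
    with _open_text(conf_path, "wt") as fh:
        fh.write(",".join(f"{c:g}" for c in aln.column_confidence) + "\n")


def trim_alignment(aln: ConfAlignment, threshold: float):
    """Delete every column whose confidence is below ``threshold``.

    Returns ``(trimmed, removed_residue_count, removed_fraction)`` where the
    fraction is over non-gap residues of the input. Idempotent at a fixed
    threshold; row order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = [j for j, c in enumerate(aln.column_confidence) if c >= threshold]
    drop = [j for j, c in enumerate(aln.column_confidence) if c < threshold]
    removed = sum(
        1 for _, seq in aln.sequences for j in drop if seq[j] not in GAP_CHARS
    )
    total = sum(
        1 for _, seq in aln.sequences for ch in seq if ch not in GAP_CHARS
    )
    trimmed = ConfAlignment(
        sequences=[(sid, "".join(seq[j] for j in keep)) for sid, seq in aln.sequences],
        column_confidence=[aln.column_confidence[j] for j in keep],
        name=aln.name,
    )
    fraction = removed / total if total else 0.0
    return trimmed, removed, fraction


# ---------------------------------------------------------------------------
# supermatrix output
# ---------------------------------------------------------------------------

def write_supermatrix(aln: ConfAlignment, partitions, out_prefix) -> None:
    """Write a supermatrix as relaxed PHYLIP + FASTA + RAxML-style partitions.

    ``partitions`` is a list of ``(name, start, end)`` with 1-based inclusive
    column ranges.
    """
    nseq = len(aln.sequences)
    ncol = aln.n_columns
    with open(f"{out_prefix}.phy", "w") as fh:
        fh.write(f"{nseq} {ncol}\n")
        for sid, seq in aln.sequences:
            fh.write(f"{sid}  {seq}\n")
    with open(f"{out_prefix}.fasta", "w") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")
    with open(f"{out_prefix}.partitions", "w") as fh:
        for name, start, end in partitions:
            fh.write(f"WAG, {name} = {start}-{end}\n")
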