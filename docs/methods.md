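# Methods

`clanprof` implements a phylogenomic-affinity analysis for a small focal
clade of prokaryotic genomes — the motivating case is a three-genome
hyperthermophile lineage (an *Aquifex*-like, a *Hydrogenobaculum*-like and a
*Sulfurihydrogenibium*-like genome, coded A/H/S) whose gene families show
conflicting affinities to an archaeal group (R), an epsilonproteobacterial
group (E), a Thermotogae-like group (T) and everything else ("other"). The
package takes BLAST-style all-vs-all similarity tables, a taxonomy table and
per-family gene trees, and asks two complementary questions: *which partner
lineages co-occur with the focal clade* (phyletic profiles) and *which
partner lineages sit next to it in gene trees* (clan analysis).

## Homolog clustering

Clusters are seeded on focal proteins with a two-threshold rule. A graph is
built whose nodes are focal proteins and whose edges connect pairs with
**bidirectional** hits at e ≤ `e_bidir` (default 1e-10). Each connected
component becomes one cluster; every subject hit by a component protein at
e ≤ `e_member` (default 1e-5) is recruited as a member. Copy number is
`single` iff every represented focal genome contributes exactly one protein.

Two boundary rules are worth stating. Non-focal subjects may legitimately be
recruited into several clusters (the merging rule deduplicates only within a
cluster). Focal proteins, however, always stay with their own component —
recruiting them elsewhere would break the guarantee that clusters partition
the focal proteome, which downstream profile counts rely on.

## Phyletic profiles, ø/* predicates, clean/dirty ranking

A profile records genome-level presence, the focal subset (e.g. AHS), the
named-partner pattern (a subset of {R, E, T}) and whether any genome outside
those groups is present. Patterns support two predicates: `X-*` (inclusive:
all groups of X present, others unconstrained) and `X-ø` (exclusive: all of
X and nothing beyond the focal clade and X). Partition categories
(RET, RE, RT, ET, R, E, T, Other, FocalOnly) are mutually exclusive and
exhaustive.

The ranked classifier sorts a cluster's members by e-value against a query
protein drawn from the highest-priority focal genome present (priority
A > H > S; the smallest protein id on a copy tie). With k other focal
proteins in the cluster, the family is **clean** when they occupy exactly
ranks 2…k+1, **dirty** when any foreign protein interleaves, and
**degenerate** when there is no foreign member at all (degenerate families
are excluded from clean/dirty denominators). Missing query→subject records
rank last rather than erroring, since truncated BLAST output is routine.
E-value ties break by descending bit score, then protein id — so a focal and
a foreign protein with identical scores resolve deterministically; this is a
tie-break convention, not a biological claim.

Printed percentages are whole numbers computed with round-half-up, matching
the convention of the summary tables this analysis style produces.

## Clan statistics on unrooted trees

All tree work is split-based and root-agnostic; trees read as rooted are
collapsed to their unrooted form first. A *clan* is one side of an edge. The
focal group is *cohesive* in a tree when some edge has exactly the focal
leaves on one side (single-leaf groups, and trees with no outside leaf, are
cohesive by convention).

**Clan distance.** The distance from the focal clan to a group is the number
of internal edges strictly between the clan's defining edge and the pendant
edge of the group's nearest leaf. Nearest-leaf is the weakest reading of
"separated by fewer internal edges"; distances to a group's nearest clan or
to all members would also be consistent with the bounded score below, but
require stronger assumptions.

**Balance of support.** For groups X and Y over n bootstrap replicates, each
replicate contributes +1 if X is closer to the homogeneous focal clan, −1 if
Y is, and 0 on ties, when either group is absent, or when the replicate has
no homogeneous focal clan. The score is antisymmetric in (X, Y) and bounded
by ±n; |score| > 0.70·n is flagged "strong".

**Pairing support.** In the supported ML tree, the minimal clan strictly
containing the homogeneous focal clan whose defining edge has support ≥ 70
defines the pairing; the lineages of its non-focal leaves are credited. Ties
in clan size break on the sorted leaf tuple. Note that on an unrooted tree
whose pruned form is a trifurcation of the focal clade and exactly two
partner clades, sisterhood is undefined and the minimal-clan rule credits
the smaller clade — a property of unrooted topology, not an artefact.

**Reductions.** Genera with more than two genomes forming a homogeneous clan
in a guide tree are cut to two representatives, one from each descendant of
the clan's earliest split (lexicographically smallest leaf in each; on a
polytomy at the attachment node the two subtrees with smallest leaf ids are
used). In-paralogs reduce to the leaf with the shortest terminal branch,
ties lexicographic. Supermatrices concatenate per-gene alignments with gap
padding for missing genomes and a 1-based inclusive partition table.

## Functional statistics

COG assignment is a four-step priority: direct locus→COG map for clusters
containing the primary focal genome; majority vote over annotated matches at
e ≤ 1e-15; GO-derived labels restricted to experimental/computational
evidence codes (IMP, IGI, IPI, IDA, IEP, ISS, IGC, ICA); else "unknown".
Ties at any vote fall through to the next step so the result is independent
of row order. The 25 single-letter categories roll up into the four parent
categories for reporting.

The Variable Preference Index for group G within one functional category is

    VPI_G = (# non-ubiquitous profiles containing G) /
            (# profiles with at least one partner)

i.e. numerator over partition categories containing G except the ubiquitous
RET category; denominator over everything except FocalOnly. VPI lies in
[0, 1]; adding FocalOnly profiles leaves it unchanged, adding RET profiles
can only lower it, and VPI_R + VPI_E + VPI_T ≤ 2. A zero denominator is
flagged undefined (NaN) rather than zero. The affinity matrix reports, per
functional category, the fraction of trees whose pairing includes each
lineage; one tree may credit several lineages, so rows need not sum to 1.

## Synthetic data generator

The generator defines the conditions the tests and acceptance metrics are
run under. Its reference phylogeny is fixed: the focal clade ((A′,H′),S′)
with branch lengths 0.1/0.1/0.2 (crown depths ≤ 0.4), partner-lineage clades
as ladders with 0.05 branches (so each clade root touches a leaf and
nearest-leaf distances are deterministic), and 0.3 backbone stems. The true
sister of the focal clade is E′ by default, with T′, R′ and the "other" pool
successively further out. Default group sizes are 3/8/6/4/10 for
FOCAL/R′/E′/T′/other.

Per family the generator samples a partition category (defaults are
RET-heavy, illustrative of a conserved core set: RET 0.43, ET 0.23, E 0.07,
RE 0.06, R 0.05, RT 0.04, T 0.03, Other 0.07, FocalOnly 0.02), prunes the
reference tree to the present genomes, and — with probability `p_lgt` — 
regrafts one focal leaf onto the midpoint of a random donor-lineage leaf's
pendant edge (single-gene transfer; the recipient then sits inside the donor
clade, so the family is expected noncohesive and, in almost all placements,
dirty). A present lineage contributes **all** of its genomes: subsampling
within lineages would randomise nearest-leaf clan distances and make exact
balance-of-support expectations impossible to state.

E-values derive from patristic distances d through log10 e = −45 + 14·d
(plus optional Gaussian noise on the log scale), clipped to [1e-180, 10].
The slope and intercept follow from the tree geometry: within-focal pairs
(d ≤ 0.4) fall below the 1e-10 graph threshold, and the farthest
within-family pair (d ≈ 2.2) stays below the 1e-5 recruitment threshold, so
noise-free vertical families reconstruct exactly. Bit scores are a fixed
monotone transform of log10 e. Hits are emitted for focal queries only —
the pipeline never consults foreign-query rows.

Bootstrap replicates are NNI perturbations of the true topology (each
internal edge rearranged with probability `bootstrap_perturb`), not
alignment resampling — the pipeline consumes only topologies. ML-tree edge
supports are the split frequencies among the replicates, in percent.

What the generator does **not** emulate: residue-level evolution, realistic
BLAST score statistics, rate variation across lineages, partial genome
presence within a lineage, multi-copy families, or transfers of whole
subtrees. Passing tests therefore demonstrate correctness of the analysis
logic under the stated model, not robustness to every pathology of real
genome data.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use 500-family datasets (no
bootstrap replicates) for recovery metrics, 10 families × 100 replicates for
balance-of-support, and ≥1,000 random instances per operation for oracle
equivalence; the whole suite runs in well under a minute. All randomness
flows from a single seed through `numpy.random.SeedSequence`, and a fixed
seed reproduces byte-identical generator output and pipeline reports.

## Known limitations

* The clan-distance definition (nearest leaf, internal edges only) is one of
  several defensible readings; scores are comparable within this package but
  not necessarily against implementations using nearest-clan distances.
* Pairing calls on two-partner trifurcations favour the smaller lineage (see
  above); interpret per-pattern pairings accordingly.
* The alignment-confidence sidecar format carries one consensus posterior
  per column; how upstream aligners combine per-residue confidences into
  that consensus is outside the package's scope.
* No correction for unequal taxon sampling across partner lineages is
  applied; the VPI inherits that sensitivity.
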