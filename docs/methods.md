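# Methods

## Why lineage-tailored completeness

Single-copy-gene (SCG) completeness estimation assumes the marker set is
present exactly once in every genome of the clade under study. For reduced,
often host-dependent lineages (the DPANN archaea being the motivating case)
that assumption fails for many universal markers, deflating completeness and
making quality thresholds (e.g. the ≥ 50% reporting bar) reject genuinely
good bins. The curation procedure here rebuilds the marker set from the data:

- **Tier filtering.** Reference genomes are filtered on an *external* prior
  completeness estimate (e.g. from a general-purpose estimator run with an
  archaeal marker set) at 50% and 75% cutoffs, both inclusive. The tiers
  trade sample size against trust in marker absence; the package computes
  collections on any tier and reports both, with the 75% tier the default
  choice for a final collection and the 50% tier a consistency check, since
  there is no principled way to combine them into one set.
- **Prevalence rules.** A marker survives when its prevalence (fraction of
  genomes with ≥ 1 copy) is ≥ 0.75 over the whole tier **and** > 0.50 within
  *each* "classic" lineage separately. The per-lineage test is enforced per
  lineage rather than pooled: pooling would let one well-sampled lineage mask
  total absence in another, which is exactly the failure mode a tailored
  collection must avoid. Boundary semantics are ≥ for the overall rule and
  strict > for the per-lineage rule.
- **Cross-collection comparison.** When several source collections model the
  same gene with different HMM profiles, `compare_collections` groups
  equivalent markers (transitive closure over user-supplied pairs) and keeps
  the variant with the highest prevalence, on the theory that a weaker
  profile under-detects; ties resolve by a caller-given collection priority.

## Completeness and redundancy

Both are presence fractions over the curated collection: completeness counts
markers at ≥ 1 copy, redundancy markers at ≥ 2 copies. Redundancy is
count-based, not excess-copy-weighted — a marker at 5 copies contributes the
same as one at 2 — matching the convention in which reported values are
k/collection-size fractions (so 1/93 → 1.1% at one decimal). Serialized
reports round to one decimal; in-memory values stay full precision.
Redundancy can never exceed completeness, and markers outside the collection
never influence either.

Two gates consume the estimates. The reporting gate (C ≥ 50%, R ≤ 10%,
both inclusive) decides whether a MAG is worth reporting at all. The
candidate-species gate (C ≥ 90%, R < 10% strict, ≥ 18 tRNAs, 16S ≥ 1000 bp)
qualifies a MAG as type material for naming a species. The asymmetry at
R = 10% (reporting passes, species fails) is deliberate and preserved.

## Phylogenomic selection and supermatrices

A marker qualifies for concatenated phylogenomics when present in ≥ 80% of
the reference genomes and nearly single-copy: the standard deviation of its
copy number, computed *only over genomes that carry it*, must be < 1.25. The
SD convention is configurable — sample (n−1, default) or population (n) —
because the copies vector [1,1,1,1,4] gives 1.342 (reject) versus 1.200
(select): near the cutoff the convention is the decision. A marker carried by
a single genome has SD 0 by definition.

For an existing per-marker alignment set, markers present in < 50% of the
genome set are eliminated before concatenation (at exactly 50% they are
kept). Concatenation is deterministic: markers in lexicographic order,
missing genome × marker blocks gap-filled with `-`, and a contiguous 1-based
inclusive partition table written as `PROT, marker = start-end`. A genome
with multiple sequences for one marker is, by default, gap-filled for that
marker (the most conservative resolution); `longest` (most non-gap residues,
first-seen tie-break) and `error` policies are available. Alignment and
trimming are upstream concerns; the concatenator consumes pre-aligned,
pre-trimmed FASTA.

## Relative evolutionary divergence

RED linearly interpolates each internal node between its parent's value and
the leaves: `RED(n) = P + (a/(a+b))·(1−P)` with a the branch to the parent
and b the arithmetic mean of path lengths from n to *all* its descendant
leaves (not to its children — the all-leaves average is the published
definition of the statistic). Root is 0, every leaf 1; when a + b = 0 the
node inherits P. With strictly positive branch lengths RED strictly
increases root-to-leaf, which the suite checks on simulated trees. Trees with
a basal multifurcation and no explicit rooted flag are rejected with an
instruction to root first.

Rank medians are computed over the RED values of labelled taxa (GTDB-style
`c__/o__/f__/g__` internal labels, or caller-supplied leaf sets resolved to
their MRCA). Circumscription assigns the rank with the nearest median and
flags whether the value falls within ±0.05 of it; exact ties (to machine
precision, 1e-12) resolve toward the more inclusive rank and are reported
rather than silently dropped. The RED-scaled tree writer replaces each branch
with the RED increment so root-to-node depth equals RED; recomputing RED on
the written tree reproduces the table to < 1e-9, which is also a regression
test.

Species delimitation is single-linkage clustering on a pairwise identity
matrix: genomes with identity ≥ 95% (ANI default) join one cluster, and
conspecificity propagates through chains. Matrices must be symmetric within a
tolerance (0.1 points by default; minor asymmetry is averaged) with values in
[0, 100]. AAI-based genus/family grouping is the same operation with a
caller-set threshold.

## Heme-binding motifs

Candidates are intervals C-X(s)-C-H with spacer s ∈ [1, 4]; spacer residues
are unrestricted (C, H and the ambiguity letter X allowed), but the literal
C/H positions must be real C and H — X never matches them, so unknown
residues cannot create motifs. The default count is the maximum number of
pairwise-disjoint candidates, computed by earliest-end greedy selection
(optimal for interval scheduling; verified exhaustively against a brute-force
maximum-disjoint-subset search over all 3^10 strings on {A,C,H}). The
rationale is chemical: one heme binds one C-Xn-C-H unit, so overlapping
candidates sharing residues cannot all be occupied. An `all_anchors` mode
counts anchor cysteines instead, for sensitivity comparisons. A protein with
≥ 10 sites is classified a high-heme cytochrome; any display capping of
counts is a plotting concern and never applied to stored values.

## Synthetic data: what it emulates and what it does not

- **Marker matrices**: per-genome Bernoulli presence at a set completeness
  fraction, with present markers duplicated to exactly 2 copies at a set
  duplication rate. Defaults (93 markers, 200 genomes, completeness 0.75,
  duplication 0.05) mirror a realistic tailored-collection study size. The
  model is i.i.d. across markers: it does not emulate phylogenetically
  correlated absence, contig-linked marker loss, or shared contamination —
  so parameter-recovery tests validate the estimator's arithmetic, not its
  robustness to structured missingness in real bins.
- **Heme proteomes**: planted motifs (random spacer lengths) separated by
  background drawn from the 18 amino acids excluding C and H, making
  planted-count recovery exact by construction. Real proteomes have C and H
  in background, where overlap resolution matters — that regime is covered by
  the exhaustive oracle test instead.
- **Trees**: coalescent-style random joins with i.i.d. exponential branch
  lengths (strictly positive by rejection), internal nodes labelled with the
  rank whose target depth fraction is nearest. This supports RED property
  tests; it is not a model of sequence evolution or of real taxonomic depth
  distributions.

All generators are deterministic given their seed, byte-for-byte.

## Numerical and design choices

- Copy counts from HMMER hits count *distinct query proteins* per profile
  (full-sequence e-value, ≤ 1e-20 default), so multi-domain proteins count
  once; per-profile thresholds can override the global cutoff.
- Genomes listed but absent from a hits file become zero rows: absence is
  signal for completeness estimation, not missing data.
- Empty marker subsets, empty genome subsets, missing priors, duplicate
  ids, negative branch lengths, and non-amino-acid characters all raise
  validation errors naming the offending item; unreachable tier cutoffs
  return an empty set with a warning rather than an error.
- Problem sizes in the test and acceptance runs (200-genome matrices,
  1000-protein proteomes, 8-40-leaf trees, exhaustive enumerations at ≤ 4×4
  matrices and length-10 strings) were chosen as the smallest sizes at which
  the statistical checks are stable.

## Known limitations

- The curated collection is flat: no lineage-specific collocated marker sets
  or strain-heterogeneity corrections.
- Reproducing a published collection's exact membership requires the original
  genome set and HMM profiles; the package reproduces the *procedure* and its
  boundary behaviour, not externally derived marker lists.
- ANI/AAI are consumed precomputed; computing them from sequences is out of
  scope, as are alignment, trimming and tree inference.
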