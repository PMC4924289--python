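# Methods

## The problem and the model

Presence/absence surveys of a reference gene set across many species
conflate two very different kinds of "absence": true gene loss, and
failure of a draft genome's annotation or assembly to expose the gene.
`orthofuzz` treats homologue detection as an evidence-reconciliation
problem with three independent streams per (gene, species) cell —
protein-vs-protein reciprocal search, genome-level gene-model
refinement, and read-depth support — and only then interprets the
resulting profile phylogenetically.

### Fuzzy reciprocal best hits

For seed gene *g* and species proteome *P*, let bit(g→s) be the bitscore
of the best local alignment of *g* against *s*. With fuzz factor
*f* ∈ (0, 1]:

* forward set: F(g) = { s : bit(g→s) ≥ f · maxₜ bit(g→t) }
* membership: s is a homologue of *g* iff s ∈ F(g) and g ∈ F′(s), where
  F′ is the same construction on the reverse search of *s* against the
  seed proteome.

With *f* = 1 and unique maxima this is exactly classical RBH; lowering
*f* only ever adds members (member sets are nested in *f*), which is
what makes the criterion robust to near-tied recent duplicates:
|members| ≥ 2 is reported as a co-orthologous pair. Fuzziness operates
on bitscores rather than E-values because bitscores are length-stable
and comparable across databases of different size.

Hits are admitted to the test only if E ≤ 1e−5 and the alignment covers
≥ 30 % of the query. These pre-filters are deliberately permissive: no
single alignment-score threshold separates true from false homologues
across two dozen genomes, so borderline judgement is deferred to the
downstream evidence tiers. The fuzz factor defaults to 0.9 and is
logged on every run; it is an explicit configuration field, not a
hidden constant.

### Internal alignment

The built-in aligner is an exact Smith–Waterman with affine gaps
(Gotoh recurrences), BLOSUM62, gap open −11 and extend −1 (a gap of
length *k* scores −11 − *k*), and gapped Karlin–Altschul constants
λ = 0.267, K = 0.041 for bitscore/E-value conversion — the standard
protein-search parameterisation, so internal bitscores are commensurate
with external tabular hits, which can be substituted at any stage.
Traceback tie-breaking is fixed (diagonal, then up, then left; gap runs
close as early as possible) and the best cell is the first in row-major
order, making alignments bit-reproducible. Only the single best local
alignment per pair is reported; multi-HSP logic is left to external
search tools. The dynamic-programming kernel is JIT-compiled with
numba; the first call in a session pays a few seconds of compilation.

### Refinement tiers

When an external protein-to-genome prediction overlaps published
models (same contig and strand, ≥ 30 shared exonic bases — about ten
codons, a conservative floor against assembly noise), both model
proteins are aligned to the seed and compared by the fraction of the
seed they cover. Coverage deltas are absolute percentage points with
inclusive thresholds: Δ ≥ 0.15 → major refinement, 0.05 ≤ Δ < 0.15 →
minor, Δ < 0.05 → the published model stands. A small epsilon (1e−9)
keeps the inclusive boundaries stable under float arithmetic. A
prediction overlapping ≥ 2 published models is a major refinement of
class `split`; one overlapping none is `novel` when no published model
matched the seed at all. The converse pathology — one published model
covering ≥ 2 predicted loci — is reported as class `merged`.
Antisense overlap is treated as distinct loci.

### Read-depth rescue

Read-vs-protein alignments (12-column tabular, protein-space
coordinates; translation and frame are the upstream aligner's job) are
piled into per-residue depth vectors. A candidate gene is *supported*
when breadth of coverage ≥ `min_coverage` (default 0.8) and
|median depth − median(reference medians)| ≤ `depth_k` (default 3) ×
MAD of the reference medians, where the reference set is the confirmed
homologues of the same species and the MAD is floored at 1 so perfectly
uniform references do not degenerate. The qualitative judgement
"depth and coverage consistent with confirmed homologues" has no single
established quantification; this rule is an explicit, configurable
formalisation of it. With no confirmed reference the code refuses to
guess and falls back (explicitly) to the coverage-only rule.

### Evidence matrix and Dollo parsimony

Per cell the best case across streams is kept, under
`published_ok > minor > major > read_only > absent`; a positive FRB
call contributes `published_ok`, refinement tiers their own level
(`novel` maps into the major band), a supported read verdict
`read_only`. Note the consequence: a homologue whose published model is
mildly truncated but still FRB-detectable shows as `published_ok` in
the matrix; the refinement report, not the matrix, carries the tier
detail, and recovery scoring of planted corruption reads the
reconciliation assignments for exactly this reason.

Gain/loss histories use Dollo parsimony — a single gain, any number of
losses — rather than free Fitch parsimony: multi-domain protein
families essentially never re-evolve, and Dollo is deterministic. The
gain sits at the MRCA of the carrier species; the loss set is the set
of maximal all-absent subtrees below it, which is provably the
minimum-loss single-gain explanation. Edges are identified by the leaf
set below them, which is stable across serialisation. Support-annotated
trees can be post-processed by collapsing internal edges with support
below a threshold (default 50) into polytomies; supports given as
fractions ≤ 1 are auto-rescaled to the 0–100 scale with a warning.

## The synthetic generator

`synthetic_data.simulate` draws, deterministically from one seed: a
random rooted binary species tree (default 12 target species); one
ancestral protein per gene (default 40 genes, lengths 120–300 aa);
presence evolved from a root origin with Bernoulli per-branch loss
(default 0.05); per-branch uniform substitution at rate 0.02 per
residue (≈ 80–90 % pairwise identity between seed and targets — well
inside FRB's comfort zone, isolating pipeline logic from alignment
sensitivity); recent duplications at rate 0.05 (near-identical copies,
0.01 divergence); decoy genes (0.25 per seed gene) as negative
controls; and per present cell one corruption mode (defaults: 0.5
intact, 0.15 minor truncation, 0.15 major truncation, 0.1 split, 0.05
merged, 0.05 model absent). Truncations are drawn inside (5 %, 15 %)
and (15 %, 40 %) with a small guard band so alignment end-trimming
cannot push a draw across a tier boundary. Reads are uniform
protein-space intervals of 33 residues at Poisson-matched counts giving
mean depth 20. The reference species is an out-of-tree seed source (one
mutation step off the root), so seeds always exist even under extreme
loss settings.

Loci are single-exon with a fixed 3:1 nucleotide:protein code and
random intergenic spacers. Merged corruption fuses the gene with a
freshly planted decoy neighbour into one published model; candidate
("predicted") models are emitted for every true locus, emulating the
pooled output of several protein-to-genome search strategies.

**Identifiability of planted losses.** Loss draws are conditioned on
being Dollo-canonical: configurations whose event set differs from the
maximal-absent-subtree representation of the leaf pattern they generate
(independent losses of two sibling clades, loss of an entire root
child, a gene lost from every target) are indistinguishable from the
canonical history given *any* presence data, so they are resampled, and
an all-absent gene records the empty history. Recovery scoring against
planted events is therefore well-posed.

**What passing means — and does not.** The generator has no indels, no
splice structure, no sequencing error, no compositional bias, and
divergence low enough that local alignment is never the limiting
factor. Recovery scores near 1.0 therefore certify the *logic* of the
pipeline (reciprocity, tiering, overlap pathology detection, rescue,
Dollo placement), not its sensitivity on deeply diverged or
structurally messy real genomes, where alignment quality and manual
inspection dominate.

## Numerical and design choices

* Internal genomic coordinates are 0-based half-open; GFF3 and tabular
  interfaces convert at the boundary. Exons are stored on forward-strand
  coordinates with strand as a flag, so interval arithmetic is
  strand-agnostic.
* Readers reject malformed records rather than repairing them; hit
  tables beyond 12 columns are accepted with a warning (widest tool
  compatibility), fewer than 12 are an error naming the line.
* All per-query hit lists are sorted by descending bitscore then subject
  id; candidate-model ties break on model id. Together with the fixed
  alignment traceback this makes every stage deterministic, and reruns
  byte-identical.
* Degenerate inputs have defined behaviour: empty proteome → all calls
  negative; no presence leaf → empty Dollo history; empty read set →
  zero profile; empty reference set → explicit coverage-only fallback.

## Problem sizes used in validation

The test suite checks the alignment kernel against exhaustive
enumeration over monotone matchings (500 random pairs, length ≤ 8,
4-letter alphabet), FRB against its literal membership definition
(1,000 random tables up to 6×6, four fuzz levels, with nesting), tier
boundaries over the full delta grid, Dollo against exhaustive
single-gain/any-loss minimisation on every rooted binary shape with
≤ 8 leaves and every multifurcating shape with ≤ 6 (all 2ⁿ patterns
each), support collapse against a bipartition-set oracle on 200 random
trees, and the end-to-end experiment at 12 species × 40 genes. These
sizes keep the whole suite within a few minutes on one CPU while
covering each search space exhaustively where enumeration is feasible.

## Known limitations

* FRB operates on whole-protein bitscores; domain shuffling or partial
  homology can produce asymmetric calls the method does not model.
* The merged/split detectors reason over exonic overlap only; they do
  not attempt to re-annotate the locus.
* The read-evidence module consumes protein-space alignments; it cannot
  distinguish a missing locus from an unassembled one (that
  interpretation needs genomic context).
* Dollo parsimony by construction forbids regain; horizontally
  transferred or convergently re-acquired genes will be forced into a
  single-origin history.
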