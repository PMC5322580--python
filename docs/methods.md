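# Methods

## Problem setting

A de novo transcriptome assembly of a non-model organism (the motivating
system is a halophilic green microalga) is annotated by BLASTX against a
large protein database. The raw contig set is redundant: several contigs
hit the same protein because of assembly fragments, chimeras and
isoforms. The package reduces this set to one representative transcript
per protein and per KEGG Orthology (KO) group, quantifies assembly
quality, scores term enrichment in condition gene sets, and explains the
redundancy it removed.

## The reduction chain

**Top hit.** Per query contig only the best alignment is kept: minimal
E-value, ties broken by maximal bitscore, then maximal aligned length,
then lexicographically smallest subject accession. Multiple HSPs per
query–subject pair are resolved here as well (best single HSP); HSP
chaining is not attempted — no chaining procedure is defined for this
pipeline, and a single dominant HSP is the common case for transcript
queries.

**Three-step criterion.** A top hit is retained iff

1. E-value ≤ 1e−10, and
2. subject coverage = aligned length (aa) / subject protein length (aa)
   ≥ 0.80,

both thresholds inclusive. The coverage ratio is taken against the full
subject protein length: of the readings the phrase "length percentage of
the query sequence ≥ 80% of the subject protein sequence alignment"
admits, this is the only one that rejects fragment hits, which is the
filter's evident purpose. Among survivors sharing a protein accession
exactly one is kept — minimal E-value, ties by longer query contig, then
lexicographic query id (the tie-break mirrors the KO-collapse rule
below). Because the coverage rule needs the subject length on every row,
the canonical BLAST tabular dialect is the 12 standard columns plus
`slen` as a 13th ("std12+slen"); plain 12-column input is accepted when
a protein-length table is supplied separately.

**KO collapse.** Transcripts whose protein maps to a KO are grouped by
KO; each group keeps the record with ascending E-value rank 1, ties by
descending contig length, then lexicographic contig id. Records without
a KO stay in the non-redundant set but are absent from the KO-unique
set. The filter chain is idempotent, output protein ids and KOs are
unique by construction, and the sizes shrink monotonically
(|KO-unique| ≤ |non-redundant| ≤ |top hits| ≤ |hits|).

## Assembly metrics

N50 is the length at which the descending cumulative contig length
first reaches half the total; the comparison is `2·cum ≥ total` in
integer arithmetic so odd totals have no floating-point ambiguity. GC is
pooled (total G+C over total unambiguous bases, N excluded from the
denominator), the genome-level convention used for cross-species
comparison — not a mean of per-contig fractions. Completeness is
|annotated ∩ core| / |core| against a supplied core-gene id list; the
operation is catalogue-agnostic (CEGMA/BUSCO-style catalogues are
consumed, never recomputed).

## Differential expression and enrichment

Quantification and posterior inference happen upstream (e.g. RSEM +
EBSeq); the package consumes a per-contig table of signed posterior fold
change and PPEE (posterior probability of equal expression). The signed
convention reports a ratio r ≥ 1 as +r and r < 1 as −1/r, so a value of
−3.1 means 3.1-fold down. Calls use |FC| ≥ 2 and PPEE ≤ 0.05, inclusive;
PPEE is treated as FDR-like and not corrected further.

Enrichment of term b in gene set K(a) uses the hypergeometric upper
tail p = Σ_{k=m}^{min(n,M)} C(M,k)C(N−M,n−k)/C(N,n) and score
−log₁₀ p. The summation index runs from the observed overlap m to
min(n, M) — the only truncation that yields a probability. N counts only
background genes bearing ≥ 1 term of the tested ontology, and n is the
condition-set intersection with that annotated background, so the
count invariants (m ≤ min(M,n), M ≤ N, n ≤ N) always hold; unannotated
genes carry no evidence for or against any term. The tail is evaluated
with scipy's hypergeometric survival function (log-gamma based; checked
in the tests against exact rational arithmetic at ≤ 1e−10 relative
error over the full N ≤ 60 domain). Scores are comparable only within
one background. Raw scores are the primary output; a Benjamini–Hochberg
FDR column is appended as a clearly-labelled extra.

## Redundancy-event classification

Contigs sharing a best-hit protein are aligned pairwise with a global
affine-gap Needleman–Wunsch/Gotoh DP written in-house: integer scores
(match +2, mismatch −3, gap open −5, gap extend −2; a length-L gap costs
open + L·extend), fully deterministic traceback (ties prefer diagonal,
then up, then left), identity computed over matched columns only,
terminal gaps reported as overhangs and internal gap runs as blocks.
A hand-rolled DP is used because the classification depends on exact,
reproducible gap bookkeeping that off-the-shelf aligners do not expose;
the implementation is verified against an exhaustive recursion on short
strings.

The decision cascade per pair, with defaults I_min = 0.90,
G_min = 30 nt, T_end = 15 nt, O_min = 10 aa:

1. subject-interval overlap < O_min → gene breakage;
2. identity < I_min → false assembly;
3. an internal gap block ≥ G_min → alternative splicing
   (exon-skipping-like if the block sits in the shorter sequence,
   intron-retention-like in the longer, unresolved otherwise);
4. max terminal overhang > T_end → alternative start/end isoform;
5. otherwise → start/end isoform, flagged near-identical.

Gap runs closer than T_end to an alignment end are treated as terminal
variation in steps 3–4: when the bases at a sequence end coincidentally
match the bases across the junction, an end gap can slide inward at
equal score, and the diagonal-preferring traceback then reports it one
or a few columns inside the alignment. Counting such runs as splicing
would mislabel clean terminal extensions. The defaults are set so a
codon-scale indel is not called splicing but an exon-scale one is; all
four thresholds are configurable. Alternative 5′/3′ splice sites and
mutually exclusive exons are not distinguishable from a pairwise
nucleotide alignment alone and collapse into the two subtypes —
resolving them needs genome or long-read evidence, which is out of
scope. A group's label is its most severe pair under
false assembly > alternative splicing > gene breakage > isoform.

## Synthetic fixtures

The generator emulates the study inputs as pure functions of
(parameters, seed): a proteome of 150–400-residue proteins (uniform),
one synthetic gene per protein (3 nt/residue, i.i.d. bases at GC 0.54 —
the pooled GC reported for the motivating transcriptome), contigs cut
from the genes by event-specific surgery, BLAST rows whose E-values
decrease monotonically with aligned length × identity (a plausibility
heuristic — only ordering and the 1e−10 threshold matter downstream),
an annotation map with partial KO coverage and shared KOs, and a DE
table with a planted up-regulated set at posterior fold change ≥ 4 and
background |FC| < 2. Junk contigs and decoy hits are built to fail
exactly one filter rule each, and decoys always rank below the true hit
so planted truth is preserved through top-hit selection.

What the fixtures do **not** model: real BLAST score statistics,
coverage-dependent assembly errors, expression-count noise
(negative-binomial or otherwise), paralogy, and genuine splice-site
structure. Passing tests therefore demonstrate that the algorithms
implement their definitions and recover planted structure — not that
the thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances:
50–120 proteins per fixture, 50 planted groups per event type per noise
level (two seeds × 25), 1,000-row hit tables for the filter-chain
comparison, and exhaustive kernel validation over all (N, M, n, m) with
N ≤ 60. These sizes give exact, auditable oracles (integer arithmetic,
brute-force references) while exercising every code path.

Determinism throughout: writers sort records by primary id and emit
byte-stable output; the pipeline report digests every output file with
SHA-256; every random choice flows from a single integer seed through
`numpy.random.default_rng`. Degenerate inputs fail loudly — empty
contig sets, all-ambiguous sequences, empty backgrounds and singleton
redundancy groups raise errors rather than returning conventions.

## Known limitations

* The coverage formula (subject-based) is a design choice; a
  query-based reading would retain long contigs with short aligned
  cores that this implementation rejects.
* Enrichment p-values are raw upper tails; the BH column is a
  convenience, not part of the score definition.
* Event classification is pairwise and nucleotide-level; it cannot
  separate all four splicing subcategories and does not verify splice
  sites against a genome.
* The merge step namespaces colliding ids but performs no sequence-level
  deduplication across sources.
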