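# Methods

This note documents the models, algorithms, numerical choices and
limitations behind plastcomp, in the order the pipeline runs them.

## Coordinates and gene models

GenBank flat files use 1-based inclusive coordinates; everything inside the
package is 0-based half-open, converted only at the I/O boundary, which
eliminates off-by-one drift between modules. A feature's location parts are
kept in transcript (5′→3′) order; all derived sequences are returned in
transcript orientation, so no downstream module ever sees strand. An
origin-spanning exon is stored unwrapped (its end may exceed the genome
length) and re-split only when serialized.

Introns are defined structurally: the genomic gaps between consecutive
exons of a cis-spliced transcript. A junction is classified trans-spliced —
no genomic intron exists — when its flanking exons lie on different strands
or the gap is negative or implausibly large (> 20 kb). This reproduces the
rps12 situation (5′ exon in the LSC, exons II–III in the IR) without
special-casing the gene name. IR-duplicated genes are kept as separate
copies with `copy_index` 1/2 assigned by genomic position; reports use the
lower-coordinate copy and attach a warning if the copies disagree
structurally, rather than silently merging them.

Pseudogenes are taken from the annotation (a `/pseudo` qualifier or a
pseudogene marker in the name); the package does not adjudicate whether a
region someone annotated as a gene is "really" functional.

## Inverted-repeat detection

Seeds are exact 25-mers shared between the doubled circular sequence and
its reverse complement. Seed pairs (i, j) belonging to one
reverse-complementary match lie on a common anti-diagonal (i + j constant),
so merging consecutive seeds per anti-diagonal yields all *maximal* exact
reverse-complementary segment pairs in roughly linear time; k = 25 makes
chance seeds negligible at plastome scale (~10⁻⁵ expected per genome).
Among disjoint pairs at least `min_len` long, the detector takes the
longest (ties: smallest start) — exact-first, because plastid IRs are
near-identical. With `max_mismatch` > 0 the best exact pair is extended
outward greedily, each flank independently, never ending on a mismatch
(trailing mismatches are trimmed and refunded). The default `min_len` is
10 kb in library calls (real plastome IRs are ≥ 20 kb), 1 kb in the
pipeline config so that reduced synthetic genomes work unchanged.

The greedy mismatch extension can overshoot a planted boundary by a base or
two when a chance match follows a budgeted mismatch; exact mode (the
default) recovers planted coordinates exactly, which is what the tests
assert.

Failure to find any qualifying pair returns a "no-IR" result (None), not an
exception: plastomes genuinely lacking the IR exist.

## Composition conventions

AT% = 100·(A+T)/(A+C+G+T); N is excluded from the denominator. "Coding" is
the merged union of exon intervals over all non-pseudogene features — CDS,
tRNA, rRNA, ncRNA alike, with both IR copies counted — introns are intron
bases not already inside some exon union, and intergenic is the remainder,
so the three fractions close to 100% identically (the tests allow ±0.02 for
reporting-time rounding). AT of "the IR" is computed on one copy. Reports
round half-up to two decimals; internal values are full precision. A
`cds_only` switch restricts coding to protein-coding exons for sensitivity
analyses, since conventions differ between published tables.

## Pairwise alignment

Global alignment is Gotoh's three-state affine dynamic programme; a gap of
length n costs `gap_open + (n−1)·gap_extend`. Rows are computed with numpy:
the match and vertical-gap states depend only on the previous row, and the
horizontal-gap state within a row is resolved by a running prefix maximum
(Y[j] = ext·j + max_k (src[k] + open − ext·(k+1))), so each row is O(m)
vector work. Traceback pointers are packed two bits per state into one
uint8 matrix; ties break diagonal > up > left, making alignments
deterministic. The implementation is validated against Biopython's
`PairwiseAligner` and, in the acceptance tests, against an independent
memoized recursion over all alignments.

Nucleotide scoring defaults to match +1, mismatch −2, gap open −10, gap
extend −0.5. The mismatch/extension ratio matters: with a mild mismatch
penalty and expensive extension, the optimal alignment of a long *random*
insertion smears it into chance-match chunks separated by short gaps,
destroying the one-event-one-gap correspondence that InDel cataloguing
depends on. With mismatch −2 a chance column costs −1.25 on average while a
gap column costs −0.5, so a contiguous gap dominates any smearing; opening
a second gap must buy ≥ 20 points of chance matches, which essentially
never happens. Protein alignments use BLOSUM62 with −11/−1. Scoring is
configurable; percent identity uses all alignment columns (gap columns
included) by default, with an ungapped-columns mode available, because
published identity values differ in this convention.

Local alignment (Smith–Waterman) reports hits best-first, skipping hits
that overlap an already accepted hit on the subject. Score thresholds for
homology mining should be calibrated on shuffled queries (the tests
demonstrate the procedure).

## Identity matrix and divergence classes

Genes are paired across species by annotation name, case-insensitively;
tRNA anticodon suffixes are significant (trnP-UGG ≠ trnP-GGG). The default
comparison unit is the full annotated gene span (exons + introns), which is
what makes intron-rich genes classify as divergent; a switch compares
spliced sequences instead. A gene missing from more than `max_missing`
species is dropped with a warning. Identity 100 in a pair ⇒ conserved for
that pair; minimum identity < 95 anywhere ⇒ highly divergent; bins at 5%
steps from 80 follow the usual summary convention.

## Progressive multiple alignment

Guide order comes from UPGMA (scipy average linkage) on 8-mer Jaccard
distances — for the ≥ 95%-identical sequences this pipeline aligns, merge
order is insensitive to the distance flavour, and the k-mer distance avoids
O(n²) full alignments; a switch recovers DP-identity guide distances.
Profiles are merged with the same affine DP on expected column scores
F_A·S·F_Bᵀ (residue frequency vectors; gaps carry no mass). Fixed scoring
and deterministic tie-breaks make the output bit-reproducible for a given
input. Externally computed alignments can be supplied anywhere an `Msa` is
accepted.

## InDel events

An event is a maximal run of alignment columns in which at least one row is
gapped. Staggered or nested gaps inside one run form a single event whose
`min_len` is the smallest per-row gap length and `max_len` the column span,
which is how published event tables print ranges like "12–39". Polarity is
relative to the majority state (majority residues ⇒ deletion in the gapped
minority; majority gaps ⇒ insertion in the residue minority). Location
(exon / intron / boundary) maps the event's column span through the
ungapped reference row onto the reference species' gene model; a zero-width
span (insertion relative to the reference) is located by its insertion
point, junction points giving "boundary". Specificity: the minority side of
the gap/residue pattern (ties count the gapped side) is species-specific if
a single species, genus-specific if exactly one genus's full membership,
else shared. Translation uses the plastid/bacterial genetic code (NCBI
table 11) via Biopython; the terminal stop is dropped and an internal stop
truncates with a warning rather than failing, since real annotations
contain recent frameshifts.

## Supermatrix phylogeny

Distance + neighbor joining deliberately stands in for full maximum
likelihood: the claims built on the tree (deep-clade monophyly at high
support) are robust to that substitution, and an ML engine is out of scope.
Jukes–Cantor distances (p ≥ 3/4 ⇒ saturated, infinite) exclude gap/N sites
pairwise; Kimura 2-parameter is available. NJ picks the first minimal
Q-matrix pair in index order (determinism) and clamps negative branch
lengths to zero. Bootstrap replicates resample supermatrix columns with
replacement using one seeded generator; replicates with non-finite
distances are skipped and counted; supports are percentages of successful
replicates carrying each internal bipartition of the point tree.
Bipartitions are canonicalized as the side excluding the lexicographically
smallest taxon, making comparisons rooting-invariant. On additive distance
matrices NJ provably recovers the generating topology; the tests verify
this exhaustively against path-length oracles up to n = 8.

## The synthetic cohort (what it does and does not emulate)

`make_ancestor` builds a ~23 kb circular genome — LSC 12 kb, IR 4 kb × 2,
SSC 3.2 kb, roughly 10× smaller than a real plastome so the full pipeline
runs in seconds — with AT-rich sequence (62%, the plastome regime) and a
15-gene roster covering every structural case the pipeline handles:
intronless CDSs, one- and two-intron genes, intron-bearing tRNAs, an rRNA,
minus-strand genes, IR-duplicated genes and a trans-spliced rps12 with its
5′ exon in the LSC. CDSs are stop-free with proper start/stop codons. The
four bases flanking the IR are pinned so the planted repeat is *maximal*
(otherwise a chance flank match extends it by a base).

`evolve_cohort` evolves 12 species (four "Nicotiana", three "Solanum",
one each "Capsicum"/"Atropa"/"Datura", two distant outgroups) along a fixed
genus-structured tree whose ingroup depths put worst pairwise divergences
near 2% — the regime in which whole-gene identities sit in the high 90s and
only large planted indels push a gene below the 95% divergence threshold.
Nineteen planted events define the study conditions, mirroring the sizes
and sharing patterns such studies report: among them a 141 bp in-frame
species-specific insertion in accD (47 aa), 24 bp shared across one genus
plus one outside species, a 9 bp genus-specific insertion, and a 102 bp
genus-specific deletion in a tRNA intron. Background substitutions and
indels (Poisson per branch, indel:substitution ratio 0.04, lengths ≤ 12)
are added on every branch.

Design constraints that make the truth log exactly recoverable:

- all events live in ancestor coordinates inside globally disjoint windows
  kept ≥ 30 bp apart, and ≥ 18 bp from every exon/intron/intergenic
  boundary, so alignment gap placement is unambiguous and location labels
  cannot be shifted across a junction;
- indels for all branches are placed before any substitution, and
  substitutions avoid the indel windows (a substitution flanking a gap
  makes gap placement ambiguous);
- coding indels are in-frame, placed at codon boundaries on plus-strand
  genes only (orientation-specific payloads for minus-strand genes are not
  worth the complexity), with stop-free inserted codons;
- at most one substitution per codon cohort-wide, never in a stop codon and
  never creating one — two individually-silent hits in one codon can
  combine into a stop on a shared path, and losing the terminal stop
  silently lengthens a protein;
- the IR is held fixed: real IRs evolve concertedly and their genes are
  observed to be exceptionally conserved, and freezing them keeps each
  species' quadripartite structure exactly detectable. The genus-level
  intron deletion is therefore planted in an LSC tRNA intron rather than
  the IR-resident tRNA where a real cohort showed it.

Randomness is one integer seed fanned out into independent streams keyed by
role ("ancestor", one per tree branch, "planted"), so adding a species
never perturbs the events of unrelated branches. Replaying the event log
over the ancestor reproduces each species' sequence bit-exactly
(`SyntheticTruth.replay`), and annotations are lifted over the per-species
indels so every emitted record carries valid gene models.

What passing on this cohort does **not** show about real data: the
generator has no rate heterogeneity, no selection, no IR boundary shifts or
rearrangements, no annotation errors, and its events are deliberately
well-separated — real alignments contain overlapping and repeat-mediated
indels whose counts are aligner-dependent. The pipeline's behaviour on
those is exercised only qualitatively (events concentrate where planted;
catalogues of messy genes may legitimately differ between aligners).

## Pipeline and reproducibility

The pipeline isolates per-file parse failures (reported in the manifest,
run continues), records a config hash, seed, input SHA-256s, per-stage
timings and warnings, and is byte-deterministic for a fixed seed and config
(the manifest's wall-clock timings excepted). Stage reports mirror the
tables such comparative studies publish: a region table, a composition
table, the split-gene length table, the identity matrix with divergence
calls, nucleotide and protein InDel catalogues, and a newick tree with
bootstrap supports.

`scripts/acceptance.py` re-runs the standard synthetic study from a seed
and reports only quantities measured at run time. Problem sizes there — a
23 kb genome, 12 taxa, 16 genes, 1000 oracle alignment pairs, 500 bootstrap
replicates, 25 additive-recovery trials — were chosen so the whole script
completes in a few minutes on one CPU while still exercising every stage at
meaningful scale.

## Known limitations

- The aligner keeps full traceback matrices; pairs much beyond ~10 kb per
  sequence get memory-hungry. Gene-scale inputs (the intended use) are far
  below that.
- Identity of the full 116-gene × 45-pair matrix on real plastomes is
  minutes, not seconds; the per-gene DP is exact, not banded.
- The IR detector returns one repeat pair; repeat families beyond the
  single large IR, and IR expansion/contraction analyses, are out of scope.
- NJ + JC is not ML; branch lengths are not interpretable as substitution
  rates under a rich model, and only topology + support claims should be
  read off the tree.
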