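# Methods

## Scope and data model

The package analyses translated spidroin (spider fibroin) genes: proteins
with conserved ~100-residue N- and C-terminal domains (NTD/CTD) flanking a
repetitive core. All coordinates are 0-based half-open internally and on
disk; 1-based closed coordinates appear only in human-readable output
(`sequence_io.to_one_based_closed`). FASTA headers contribute their first
whitespace-delimited token as the gene identifier; species tags are always
caller-supplied rather than inferred from headers, because joint
two-species analyses need explicit provenance.

## Candidate screening

Terminal-domain homology uses in-package Smith–Waterman local alignment
(Bio.Align.PairwiseAligner) with BLOSUM62 and affine gaps costing
11 + (k−1) for a gap of length k. Significance is a Karlin–Altschul-style
expectation E = K·m·n·e^(−λS) with the standard gapped BLOSUM62
parameters λ = 0.267, K = 0.041, where m is the query length and n the
summed library length; hits are retained at E ≤ 1e-6. When a query
exceeds 300 residues, NTD hits are sought only in the first 150 residues
and CTD hits in the last 150 — terminal domains are ~100 aa, and the
windows keep glycine-rich repetitive cores from producing spurious
terminal calls. Per query at most one best NTD and one best CTD hit are
reported (highest score, then lowest E, then lexicographic reference id).

Fragment categorisation is a total function onto five categories: both
termini without gap evidence → `complete`; both termini with gap evidence
→ `internal_gap`; NTD only → `five_prime_end`; CTD only →
`three_prime_end`; neither terminus → `repetitive`. Gap evidence is an
explicit input (a run of ≥ 10 `X` residues strictly inside the sequence,
`has_internal_gap`), since assembly-gap evidence originates upstream of
this package. Repetitive-core evidence (≥ 3 GPGQQ repeats, a poly-A run
≥ 6, or ≥ 30% catalog-motif coverage) is computed and exposed, but a
candidate with no terminal hit is categorised `repetitive` regardless:
candidates reach this stage only through homology or signature screening,
so the no-terminal, no-signature cell of the decision table is not
reachable in practice and collapsing it keeps the function total.

Class assignment uses precedence: concordant NTD/CTD homology, then
internal-motif class votes, then expression (top silk gland mapped
through MA→MaSp, MI→MiSp, FL→FLAG, AG→AgSp, tubuliform→TuSp).
Conflicting terminal labels fall through to the weaker evidence as a
tiebreaker and otherwise yield `unclassified` with the evidence recorded.

## Motif discovery, painting, grouping

Cores are the residues left after masking a hard 100-residue window at
each terminus; sequences shorter than two windows have empty cores.
Discovery enumerates repeated substrings of the cores level-wise (a
repeated (L+1)-mer must extend a repeated L-mer), keeps lengths 4–41
whose leftmost-greedy non-overlapping occurrence total across all cores
is ≥ 3 (`min_total_occurrences`, exposed), and prunes any candidate
contained in a longer candidate with the identical all-match occurrence
set. This deterministic enumeration replaces probabilistic motif seeding
plus manual curation; it finds every exactly-repeated pattern, at the
price of also reporting composite periodic variants (e.g. doubled tandem
units), which downstream grouping and collapse absorb.

Painting locates each catalog variant in each core with leftmost-greedy
non-overlapping matching per variant — tandem copies are never
double-counted at shifted offsets — while overlaps between *different*
variants are allowed. Wildcards: lowercase `x` matches any residue; `z`
is the same wildcard, used only to mark independent positions within one
description (`DTxSYzTGEY` style).

Grouping is a reproducible surrogate for what is usually manual curation:
variants first bucket into fixed residue-composition classes (poly-A
≥ 80% alanine; GA-dinucleotide-like, only G and A; glycine-rich ≥ 1/3 G;
Ser/Thr/Val-rich ≥ 60% S+T+V), then single-linkage clustering at
normalised edit distance ≤ 0.25 (edlib Levenshtein / longer length)
yields subgroups. Variants fitting no composition class cluster by edit
distance alone; multi-member clusters become their own groups and
singletons are `unassigned`. Description collapse merges equal-length
variants of a subgroup differing at one position into a wildcard
description, repeated to fixpoint; the merge respects the ≤ 50% wildcard
density bound and is idempotent.

## Cassette detection

Painted occurrences of each gene are sorted by (start, longer-first) and
chained: an occurrence overlapping the chain tail is skipped (cassette
occurrences may not share motif occurrences), a gap ≤ 20 residues
extends the chain, a larger gap closes it. Chains are segmented
left-to-right into windows of at most 6 components; windows of ≥ 2
components are candidate cassette occurrences, and a component tuple
becomes a cassette type when it recurs ≥ 2 times dataset-wide
(`min_type_support`, the operationalisation of "enriched", exposed as a
knob). Curation removes occurrences leaving the core or violating the
gap bound and re-applies the support threshold so no type dangles.
Cassette groups collect types whose components map to the same ordered
tuple of motif groups; group descriptions join collapsed component
descriptions with `_` at junctions where any member occurrence shows a
positive gap (`xGG_GGx`).

## Sharing statistics

A type is shared when it has at least one occurrence in each species;
type identity across species is pattern equality after wildcard collapse
(collapse first, then compare). All percentages are re-derived from raw
counts and rounded half-up to one decimal (`decimal.Decimal`), matching
the usual presentation of such tables. Origin breakdowns split a
species' private types into single-gene, within-class and across-class;
the three always sum to the private total. Top-k rankings order by total
occurrence count with lexicographic tie-break, and shared entries whose
class sets are disjoint between species carry a cross-class flag.

## 2^−ΔΔCt expression

Replicate Cts aggregate per (sample, tissue, target); "Undetermined"
wells are treated as censored at the instrument limit of 40 cycles and
excluded from means — a fully censored group stays censored and any
quantity depending on it is flagged not-quantifiable rather than imputed,
because imputing would fabricate expression. ΔCt subtracts the reference
gene (default `RPL13a`), ΔΔCt subtracts the calibrator tissue (default
`legs`), RQ = 2^−ΔΔCt; the calibrator's RQ is exactly 1 by construction.
Replicate scatter is reported as the ΔΔCt standard deviation propagated
in quadrature over the four mean Cts; no significance testing and no
amplification-efficiency (Pfaffl-style) correction is applied. Any
replicate count is accepted.

## Synthetic data: what it emulates and what it does not

A `SpidroinGrammar` builds genes as NTD + cassette instances + CTD:
motifs from a pool (lengths 4–41), cassette templates of 2–6 pool
indices, within-cassette spacers of 2–12 residues (≤ 20, so planted
cassettes are detectable) and inter-cassette spacers of 25–40 residues
(> 20, so planted cassettes are separable). The default pool carries
field-typical motifs (GPGPQGPS, GPGQQ, poly-A, GYGGQ, GGSGGGL, [GGP]₃,
an S/T/V-rich spacer motif, GGAGQGGY) with 6–12 cassette instances per
gene. Four alphabets — NTD body (ILVM), CTD body (HNC), spacers (DEKR),
motifs (GPASQYT) — are chosen to be mutually low-scoring under BLOSUM62
and mutually disjoint where it matters, so that (i) a motif can match
neither inside spacers nor across junctions, making planted occurrences
exactly the paintable occurrences, and (ii) a terminal-domain reference
cannot hit the core or the opposite terminus by chance at E ≤ 1e-6.
Class-specific terminal templates differ by a 20-residue diagnostic
block, letting homology tell the seven classes apart.

The two-species generator draws a universe of random motif types (none a
substring of another), marks each shared with probability
`shared_fraction` (Bernoulli per type) and alternates the rest between
species; per-species cassette templates pair up the pool and the
per-gene repeats cycle through them, so every pooled type is realised
and planted presence equals pool membership. The truncation harness
produces the five fragment categories with cut points ≥ 10 residues away
from the terminal windows. The Ct generator plants
Ct = base − log2(fold) + N(0, sd) per replicate with a flat reference
gene and unit calibrator fold.

All generators derive independent component streams from one master
seed (numpy SeedSequence.spawn) and are byte-reproducible. What the
generator does *not* emulate: substitution/indel divergence within motif
families (planted motifs are exact copies, so discovery recall here does
not measure robustness to mutated repeats), nucleotide-level artefacts
(codon structure, assembly error), realistic spidroin length
distributions (generated genes are hundreds, not thousands, of residues),
or biological correlations between motif content and expression. Passing
tests therefore demonstrate algorithmic correctness against the stated
definitions, not field performance on diverged real repertoires.

## Numerical and design choices

* Alignment engine in-package rather than an external search tool keeps
  the repository self-contained; the E ≤ 1e-6 threshold, 100-residue
  terminal cutoff, 4–41 motif lengths, 2–6 cassette components and
  20-residue gap bound are the field-standard values this pipeline
  targets.
* Discovery's `min_total_occurrences = 3` and cassette
  `min_type_support = 2` are the package's own defaults where no
  published threshold exists; both are exposed.
* Percentages round half-up to one decimal; interval arithmetic is
  0-based half-open everywhere; ties in rankings break lexicographically;
  variant/cassette identifiers sort by (length descending, pattern), so
  every output is deterministic given inputs.
* Degenerate inputs: empty FASTA → empty list; empty catalog → no
  occurrences; repetition-free cores → empty catalog; empty occurrence
  tables → zero-count reports; an all-censored Ct group never yields a
  numeric RQ.
* Gene exclusion lists (e.g. a gene omitted from motif analysis) are
  honoured via the `exclude` key of the CLI YAML config.

## Problem sizes used in validation

The bundled validation and the acceptance script run at desk scale:
12-gene single-species datasets (~250-residue cores) for discovery/
painting/cassette recovery, 2 × 20 genes over 200 motif types for
sharing recovery, a 200-case truncation suite (50 genes × 4 modes), and
100–500 seeded Ct tables for the expression checks. These sizes give
binomial error bars comfortably inside the asserted tolerances while the
whole suite runs in seconds.

## Known limitations

* Discovery is exact-match: motif variants differing by substitutions
  are separate variants until grouping/collapse merges their
  descriptions; heavily diverged repeats in real spidroins may fragment
  into many variants.
* The Karlin–Altschul parameters are the standard gapped BLOSUM62
  constants, not re-estimated per scoring system; E-values are therefore
  calibrated approximately, which is adequate at the 1e-6 threshold but
  not for fine significance ranking.
* Whether the same variant may overlap itself is resolved as
  non-overlapping (greedy); cassette chains may not share motif
  occurrences. Both are package conventions where the field has no
  stated rule.
* No nucleotide-level handling, no probabilistic motif models, no
  phylogenetic interpretation, no enrichment null model for cassettes.
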