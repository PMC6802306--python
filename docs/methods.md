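# Methods

This note documents the models, parameter choices, and numerical
conventions behind `fusionbench`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Fusion construction

A fusion design joins the spliced prefix of a *donor* gene (through the 3'
end of a chosen exon, in transcription sense) to the spliced suffix of an
*acceptor* gene (from the 5' start of a chosen exon). Constraints:

- both partners are protein-coding (GTF `gene_biotype`/`gene_type`
  attribute; the key list is configurable because GTF dialects differ);
- each partner contributes ≥ 100 transcribed bases;
- the junction falls at consensus splice sites, read strand-aware on the
  genome: GT immediately 3' of the donor exon and AG immediately 5' of the
  acceptor exon in transcription sense (so `AC`/`CT` on the genomic plus
  strand for minus-strand genes);
- a gene participates in at most one fusion per sample.

One transcript per gene is chosen uniformly at random; admissible
donor/acceptor exons are drawn at random from the candidates. Internal
coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on load.

## Expression and read model

Fusion expression is drawn uniformly on log₂(TPM) ∈ [1, 15]. Background
(reference-transcript) expression draws log₂(TPM) from a normal with mean 2
and SD 2 — a configurable log-normal stand-in for an empirical expression
profile estimated from real data. The joint profile is renormalized to sum
to 10⁶ TPM.

Reads follow a deliberately simple paired-end model rather than an external
read simulator: fragment length ~ Normal(mean 300, SD 50 by default;
configurable), truncated to [read length, transcript length]; fragment start
uniform; expected fragments per transcript ∝ TPM × effective length
(length − mean fragment length + 1, floored at 1); FR mate orientation with
the originating strand chosen by fair coin; uniform per-base substitution
errors (drawn from a separate seeded stream so placements are invariant to
the error settings); constant base quality. Transcripts shorter than the
read length are excluded with a warning. Read lengths 50 and 101 are the
conventional paired-end settings exercised by the tests; any length is
accepted.

The simulator records every fragment placement (source, start, length,
orientation flip). This record is the ground truth for evidence counts: the
"perfect caller" in `pipeline.py` converts each fusion-crossing fragment
into an idealized split or spanning event with exact anchors, and an
independent bookkeeper recomputes, by direct arithmetic on the same record,
which designs the filter cascade must recover (after collapsing duplicate
placements exactly as alignment-level deduplication would). Pipeline output
is tested for *set equality* against that prediction — a stronger check than
a recall bound alone, since a design with ≥ 2 crossing fragments can still
legitimately fail the support rules (e.g. two spanning fragments with no
split read, or split-only support with short anchors).

When mapping perfect-caller intervals to the genome, transcript offsets near
the breakpoint are projected linearly, ignoring intron structure; this is
adequate for the similarity-region and aggregation logic the events feed
and is not a general liftover.

## Filter cascade conventions

- **Duplicate key**: (kind, gene pair, both intervals, both breakpoints);
  read names are ignored — identical placements are PCR/optical duplicates.
- **Spanning attachment**: a spanning fragment supports breakpoints
  consistent with its mate intervals in transcript sense; it is counted
  once, toward the breakpoint with most split support (ties → 5'-most).
  Spanning-only gene pairs form a nominal candidate so later stages see
  every pair (the basic filter then removes them for lack of a split read).
- **Paralog dominance** requires strictly greater evidence; ties keep both
  candidates. Evidence is junction + spanning fragments (configurable).
- **Promiscuity**: a candidate is dropped when some partner's best candidate
  has ≥ 20× its evidence; afterwards any gene with ≥ 10 remaining partners
  loses all its candidates.
- **Expression floor**: 0.1 FFPM, boundary inclusive (the rule discards
  candidates with *less* support). FFPM is computed as
  `fragments × 10⁶ / total fragments`, multiplying first so the defining
  case (1 fragment per 10 M) is exact in floating point.
- Stage order: similarity exclusion → dedup → sense-sense aggregation →
  basic → paralog → promiscuity → red herring → expression. The three
  annotation-based advanced filters commute on tables where their grounds
  are independent; order can matter when one filter's removals change
  another's dominance inputs, which is why the order is fixed and logged.

## Contig validation conventions

- Overhang splitting uses 25-base overhangs truncated at contig ends
  (degenerate short contigs must not crash).
- External spliced realignment is replaced by ungapped exact-match extension
  of the native alignment into the overhang against the provided genome at
  the stated locus; a precomputed-extension input mode is also accepted.
  This preserves the 12-base decision rule ("beyond 12" eliminates, so 12
  exactly passes — the strict reading; the threshold is configurable) while
  remaining fixture-controllable.
- Breakpoint complexity is mononucleotide Shannon entropy, base 2, over
  12-base windows on each side (alphabet/order are not standardized in the
  field; this is the simplest choice and is configurable). Values lie in
  [0, 2] and are reverse-complement invariant.
- Read support from a read-to-contig alignment table: a junction fragment
  has a read covering the breakpoint with ≥ 1 base on each side
  (configurable anchor); a spanning fragment has mates entirely on opposite
  sides. Validated contigs then pass through the same advanced filters as
  read-mapping candidates.

## Scoring conventions

- Strict matching is order-sensitive (reverse order is a lenient
  allowance). Lenient matching accepts reverse order and, on either side, a
  genomically overlapping gene or a likely paralog (paralog proxying can be
  toggled off).
- Each truth positive is credited at most once; exact matches claim truth
  entries before proxy matches, and surplus proxy matches of an
  already-claimed positive are ignored (neither TP nor FP). Predictions
  matching uncertain entries are ignored by default, or scored FP under the
  "penalize uncertain" alternative. FN never counts uncertain entries.
- The threshold sweep visits every integer from the minimum to the maximum
  observed evidence (junction + spanning; methods reporting a single count
  supply it as junction reads). F1 is 0 when precision + recall is 0.
- PR-AUC is a trapezoid over the (recall, precision) points sorted by
  recall, prefixed by an anchor at (0, precision of the highest-threshold
  point), with no extrapolation past the maximum achieved recall. This makes
  the two-point example ((0.5, 1.0), (1.0, 0.5) → 0.875) exactly
  integrable and never rewards unreached recall.
- Crowd truth: votes are counted per lenient equivalence class, computed
  once over the union of calls by union-find (without an annotation bundle,
  only reverse-order merging applies). A class is positive with ≥ n counted
  votes, a false positive with ≤ 1, and uncertain in between; excluded
  methods are still scored but cast no votes. Classes are represented by
  their lexicographically smallest member pair. Positives nest as n grows.
- Leaderboards rank methods per truth set by descending AUC with tied ranks
  averaged, then order methods by median rank.

## Problem sizes used by the test suite

The bundled checks run on synthetic fixtures sized for a desk machine:
genomes of 2 chromosomes × 100–450 kb, 16–44 genes of 3–6 exons, 8–20
fusions per sample, and 20k–200k read pairs; the advanced-filter
equivalence checks use 1,000 random 12-candidate tables. These sizes are a
deliberate choice: every property asserted (construction constraints,
count expectations, filter-rule equivalence, end-to-end recall) is scale
free, so larger runs exercise the same code paths without changing the
assertions.

## What the synthetic data does not show

The generator emulates coverage proportional to expression, split/spanning
evidence across breakpoints, and expression-dependent detectability. It
does not model reverse-transcription template switching, intron retention,
intergenic transcription, indels or quality-dependent errors, multimapping
ambiguity, or real paralog structure — so passing tests demonstrate the
correctness of the filtering and scoring logic, not caller accuracy on real
tumors. The wisdom-of-crowds machinery accepts real multi-method prediction
tables in the shared TSV format for that purpose; the real-data acceptance
check documents the expected figures and activates when those external
tables are placed under `data/`.

## Known limitations

- The similarity filter trusts the supplied aligned-region table; it does
  not compute alignments.
- STAR junction parsing assigns segments to genes by maximal exon overlap
  and drops records not assignable to two distinct genes; overlapping-gene
  loci can therefore be attributed to the dominant gene.
- The contig validator's extension measure is ungapped and cannot model
  spliced extensions across introns.
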