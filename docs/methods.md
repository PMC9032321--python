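# Methods

## Pipeline model

The package implements a three-stage analysis of insect-specific RNA
viruses in metatranscriptomes, plus the synthetic-data machinery that
makes every stage testable offline.

### Contig triage

A contig enters the candidate set when it has at least one
viral-reference alignment with E-value ≤ `evalue_max` and its length is
≥ `min_contig_length`. Both thresholds are inclusive; the length
threshold is stated as "at least" in common practice, while the E-value
boundary is ambiguous in most write-ups — we chose inclusive on both
sides for symmetry. Defaults are `evalue_max = 1e-20` and
`min_contig_length = 3000` nt, the standard operating point for
RNA-virus discovery in insect transcriptomes.

Candidates are then relabelled from a comprehensive search in which each
hit carries a subject category (`viral`, `cellular`, `unknown`). The
best hit is ranked by bitscore, with ties broken by smaller E-value and
then lexicographic subject id — bitscore is the standard ranking and the
remaining tie-breaks make the verdict deterministic. A best hit of
category `unknown` yields `unresolved`, never `viral`: the entire
purpose of the second pass is removing false positives, so uncertainty
must not promote a contig. Because a contig can score well against both
viral and insect proteins, each verdict also carries a *margin* column
(best viral bitscore minus best cellular bitscore) so borderline calls
are visible rather than silently decided.

### Genome annotation

An ORF is an ATG-initiated, stop-terminated maximal span in a fixed
frame and strand; nested ATGs sharing a stop are suppressed
(longest-per-stop), ORFs running off the sequence end are not reported.
Defaults — `min_protein_len = 100` aa, plus strand only — suit
positive-sense RNA virus genomes, and all four criteria are exposed.
Translation uses the standard genetic code; codons containing N
translate to `X` (ambiguous assembly positions are tolerated) while an
internal stop is an error naming the codon index, since a claimed CDS
with an internal stop indicates an upstream bug rather than data noise.

UTR segmentation is plus-strand-relative: the 5′ UTR is everything
upstream of the first plus-strand ORF, the 3′ UTR everything downstream
of the last, so for a single-ORF genome
`utr5 + orf + utr3 = genome_length` exactly. Overlap detection is purely
interval-based on half-open coordinates (touching ORFs do not overlap);
whether an overlap arises from a frameshift element is out of scope.
Internally all coordinates are 0-based half-open; report files emit
1-based inclusive coordinates in a GFF3-like layout.

### Zero-mismatch sRNA mapping

Reads are size-selected to 18–30 nt (inclusive), reads containing N are
dropped (exact matching with N is undefined) with a logged tally, and
identical sequences are collapsed to (sequence, count) pairs. Mapping
reports *every* exact occurrence of a read on either strand — no
mismatch tolerance, no gaps, no best-site selection. All-sites reporting
is the conservative superset: downstream counting weights each site by
the read's collapse count, and either multi-map convention (once per
read, once per site) can be derived from it; the `map` command reports
both side by side.

The index hashes fixed-length seeds (the minimum read length) to genome
positions and verifies each candidate against the full query, so a
lookup costs O(query length) per occurrence independent of genome size.
Genome positions containing N never match (N seeds are not indexed, and
verification is literal string equality against N-free queries).

Antisense coordinate convention: `five_prime_pos` is the genome offset
of the read's 5′ nucleotide — the leftmost offset of the matched span
for sense placements and the rightmost for antisense. All positional
statistics are 5′-start profiles; mirrored-axis plotting conventions are
applied only in the report writer (antisense counts negated).

### vsiRNA signature statistics

Every tally runs in two weightings: *unique* (each collapsed read once
per site) and *total* (weighted by collapse count); unique never exceeds
total elementwise. The 5′-terminal composition is computed at a single
analysis length, default 21 nt — the Dicer product length at which the
bias is biologically expected — and reported in the RNA alphabet (U for
T) to match the field's plotting convention; DNA letters are used
everywhere else. The A/U bias is `f(A) + f(U)` with 0.5 as the unbiased
baseline. Empty strata (no reads at the analysis length) report NaN
rather than 0 so that absence of data is distinguishable from absence of
bias.

Hotspot calling has no community-standard definition, so this package's
definition is deliberately simple and fully config-exposed: smooth the
per-offset 5′-start counts with a centered moving sum of width `window`
(default 21 nt, one product length), call offsets whose smoothed value
*strictly* exceeds the `quantile` quantile (default 0.99) of all
smoothed values and is positive, and merge calls separated by ≤
`merge_gap` (default 10 nt) into intervals, each reporting its raw peak
count. Strict exceedance makes a flat profile call nothing. One
well-posedness caveat follows directly from the quantile semantics: the
detector separates signal from background only when true hotspots
occupy at least `1 − quantile` of genome positions (after smoothing
spread); below that occupancy the threshold sits at background level and
~1% of background offsets are called by construction. The hotspot
simulations therefore plant hotspots wide enough (50 nt on a 6-kb
genome) to be in the well-posed regime.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; all are bit-reproducible given (spec, seed) via a single
`numpy` Generator per call.

**Genomes** are i.i.d. base sequences at a chosen GC content with ORFs
planted at exact coordinates. Start (ATG) and stop codons are anchored;
ORF bodies are cleared of in-frame stops; an in-frame stop is placed
immediately upstream of each planted ATG when those positions are free
(preventing upstream start extension under the longest-per-stop rule);
and a bounded repair loop removes any residual spurious ORF at or above
the shortest planted protein length, using point mutations checked to
leave every planted frame stop-free and every anchor intact. The result:
ORF prediction at `min_protein_len` = shortest planted protein recovers
the planted layout *exactly*, which the tests exploit as ground truth.
Same-frame overlapping ORFs are rejected as infeasible (their codons
contradict). Two presets encode the architectures the pipeline targets:
a 9716-nt single-ORF genome (181 / 9297 / 238 nt segmentation) and a
20,193-nt four-ORF genome (76-nt 5′ UTR, 1046-nt 3′ UTR, one 22-nt
overlap between the last two ORFs in different frames). The four
internal ORF boundaries of the nido-like preset are this package's
choice, constrained to reproduce the architecture's published segment
lengths; the overlap size is a free choice. GC defaults (0.40 / 0.45)
reflect the AT-rich composition typical of insect RNA viruses.

**Libraries** draw read lengths from a size distribution (default: 0.60
at 21 nt, the remaining mass spread over 18–30 nt with a shoulder at
20/22 nt), strands by a Bernoulli draw (default 0.5 sense), and 5′-start
positions uniformly over N-free windows, scaled by hotspot rate
multipliers. The 5′-terminal bias (default U 0.40 / A 0.35 / C 0.15 /
G 0.10) is imposed only at the analysis length, by sampling the target
5′ base first and then the start position conditionally among positions
carrying that base — exact conditional sampling rather than
accept/reject, so the bias holds in expectation whenever each base has
at least one eligible start; if a base has none, generation fails with
advice to use a longer genome. Other lengths inherit genome composition.
Host background reads are i.i.d. sequences re-drawn until they match
neither genome strand, removing all dependence on a real host genome.
The generator does **not** model sequencing error, quality-score
structure, adapter contamination, or the transcript-abundance coverage
bias of real libraries — so passing tests demonstrate statistical
correctness of the estimators on clean exact-match data, not robustness
to platform artifacts (which the zero-mismatch design sidesteps by
construction).

**Triage fixtures** give every candidate a screen-passing
viral-reference hit (length ≥ 3000 nt, E-value ≤ 1e-20) and plant the
comprehensive-search outcome: the chosen viral contigs get a viral best
hit; the rest get a cellular hit that outscores their incidental viral
hit by at least 100 bits, so planted labels and triage verdicts coincide
exactly.

## Problem sizes and numerical choices

Simulation-based tests use 50,000-read libraries for point-estimate
recovery (binomial standard errors ≈ 0.002, comfortably inside the
±0.01 assertions), 100 × 10,000 reads for the A/U-bias sign check,
100 × 20,000 reads for hotspot recovery, and 200 instances of
(5-kb genome × 1000 reads) for mapper-vs-oracle equivalence — sizes at
which the checked properties are stable across seeds while the whole
suite stays fast. Percentages are rounded to one decimal in reports;
TSV numbers are rendered at six significant digits; base-fraction sums
are asserted to 1e-9. Verdict and mapping outputs are deterministically
ordered (documented sort keys) so reruns are byte-identical.

## Known limitations

- Homology search, assembly, and phylogenetics are consumed or out of
  scope, never executed: the tabular alignment input must be produced
  (and its 13th category column assigned) by the caller or the fixture
  generator.
- The exact-match mapper is not a general aligner: one sequencing error
  makes a read invisible, which is the intended semantics for vsiRNA
  counting but undercounts on noisy libraries.
- UTR segmentation assumes plus-strand coding (positive-sense viruses);
  genomes with only minus-strand ORFs get zero-length UTRs in the
  generator's ground truth and are rejected by `segment_genome`.
- Hotspot calls depend on the three exposed knobs; intervals are not
  significance-tested, and the quantile threshold is only meaningful in
  the occupancy regime described above.
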