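# Methods

This note documents the models, conventions, and numerical choices behind
genoscene, and what the synthetic fixtures do and do not demonstrate.

## Coordinate model

All internal coordinates are 0-based, half-open. 1-based inclusive
coordinates appear in exactly three places: locstring parsing, VCF I/O
(via pysam), and table/export display columns. This keeps ±1 drift confined
to well-marked boundaries.

A view's horizontal axis is a `DisplayedRegions` stack: an ordered list of
regions, possibly from different chromosomes, possibly listing the same
interval twice (permitted, logged), each optionally reversed. The transform

    px(x) = (Σ_{j<i} len_j + w_i(x)) / bpPerPx + i · interRegionPadding

places base `x` of region `i`, with `w_i(x) = x − start_i` forward and
`end_i − 1 − x` reversed. `px_to_bp` inverts it by scanning the stack and
flooring `(px − base) · bpPerPx` with a +1e-6 absolute guard against
float round-off from the division/multiplication pair; offsets inside
padding return a distinct gap marker rather than a coordinate.
`interRegionPadding` defaults to 2 px and region boundaries render as
vertical separators. Reversal flips drawing direction only; stored
coordinates stay on the forward strand.

Reference-name equivalence (e.g. `1` vs `chr1`) is alias-table driven and
case-sensitive — no heuristic `chr` stripping. An alias file supplies one
line per sequence: canonical name, then tab-separated aliases.

## Feature and signal readers

GFF3/GTF/BED parse into one nested `Feature` tree; `Parent=` (GFF3) and
`gene_id`/`transcript_id` (GTF, limited to gene/transcript/exon/CDS — what a
feature track draws) drive assembly. Multi-parent GFF3 features are
duplicated under each parent and logged; children escaping their parent's
span are logged, not fatal. Region queries use tabix when the file is
bgzip-compressed and indexed, else scan-and-filter; both paths apply the
same overlap predicate (`start < regionEnd and end > regionStart`).

VCF goes through pysam: all samples and genotypes are retained, END
semantics for symbolic alleles come from pysam's record `stop`, and breakend
ALT strings are preserved verbatim for the SV toolkit. BigWig bins report
the mean of covered bases only; a bin with no covered base is missing
(`None`), not zero. GC content excludes non-ACGT bases from the denominator.
Three-frame translation covers the three frames of the given strand
(biopython's standard table; ambiguity codes that don't resolve become X;
the trailing partial codon is dropped).

## Alignments

`assign_rows` is greedy first-fit over intervals sorted by start (ties:
longer first, then id). Left-endpoint greedy coloring is optimal on interval
graphs, so `rowCount` equals the maximum overlap depth of the padded
intervals; the tests check this against a brute-force sweep. Pileup
intervals include soft-clip extents so clipped reads do not visually collide.

Coverage adds depth for M/=/X only — deletions and introns (D/N) consume
reference without depth — and conserves mass: Σ(bin mean × bin width)
equals the per-base aligned overlap.

MM/ML decoding walks the delta-encoded skip counts over occurrences of the
canonical base along the *original* read: for reverse-strand alignments the
stored SEQ is the reverse complement, so occurrences are counted from the
stored 3′ end on the complemented base. Reported positions are stored-SEQ
indices (what a renderer needs). ML maps byte `v` to likelihood
`(v + 0.5)/256`. `encode_modifications` is the exact inverse and is used to
round-trip fixture reads; only `+`-strand MM groups are supported, and each
group's `.`/`?` mode flag is carried through.

Read policies: filters (flag masks, min MAPQ, tag equality), stable sorts
(start; observed base at a position in the order A, C, G, T, deletion,
other; tag value), and color classes (strand, MAPQ bands at 30/60,
insert-size bands, tag value, modification presence). Insert-size bands
default to median ± 3 robust SDs estimated from the loaded reads, and are
configurable — the rule itself is a package choice. Reads without SEQ are
laid out but excluded from base-sort and modification policies.

## Structural variants

The four VCF 4.2 breakend forms map to join orientations as follows
(joinSide = the side of POS retained at the junction):

| ALT form | joinSide      | mateJoinSide  |
|----------|---------------|---------------|
| `t[p[`   | left_of_pos   | right_of_pos  |
| `t]p]`   | left_of_pos   | left_of_pos   |
| `]p]t`   | right_of_pos  | left_of_pos   |
| `[p[t`   | right_of_pos  | right_of_pos  |

The anchor base is the `t` character adjacent to the local break; the rest
of `t` is novel inserted sequence. `format_breakend ∘ parse_breakend_alt`
is the identity on all four forms. Mate pairing prefers MATEID and falls
back to reciprocal coordinate matching; unpaired records become single-ended
events with a warning. Symbolic `<DEL>/<DUP>/<INV>/<TRA>` records become
two-ended events from POS and INFO END (CHR2 when present), matching
Sniffles-style output.

The table filter grammar (the package's own, versioned with the config
format): whitespace-joined clauses are ANDed; a clause is `column=value`
(exact), `column~value` (substring), `column<n`/`>`/`<=`/`>=` (numeric), or
a bare token matched as substring against any text column. Column names come
from the canonical table header (`id, refName, start, end, mateRef, matePos,
type, info.*`). Filtering is associative: filtering by `e1 + " " + e2`
equals filtering by `e1` then `e2`.

Breakpoint panels are windows of `windowBp` centered on each event end,
clamped to sequence bounds. Split evidence groups alignments by read name,
orders segments by their clip-derived span on the original read, and emits
one connector per adjacent pair, anchored at the reference coordinate of
each segment's clip boundary (alignment end for forward segments, start for
reverse, and vice versa for the following segment).

## Synteny

All query coordinates are stored forward-strand regardless of source
convention: chain minus-strand coordinates are converted with
`(qSize − qEnd, qSize − qStart)`; delta `qs > qe` flips into the strand
flag. CIGAR convention: M advances both axes, I the query only, D/N the
target only; every parsed block satisfies the consumption invariant
(target consumption = tEnd − tStart, query = qEnd − qStart).

Delta distances: a value `d` means |d| − 1 matched positions then one gap —
in the query for positive `d` (a target-only base, D) and in the target for
negative `d` (I); the remainder after the last distance is matches, and a
missing 0 terminator is an error. Chain triplets `size dt dq` become
M/D/I runs and the header spans are validated against their sums; a CIGAR
ending in a gap is written as a final triplet plus a zero-size terminator,
since the standard bare final size cannot express it. MCScan anchors yield
one block per gene pair (strand = agreement of the two BED strands) plus
one merged block per `###` group, strand by majority vote with ties `+`;
`mashmap.out`-style rows are accepted by the PAF parser in permissive mode.

Dotplot paths walk the CIGAR stepwise ((tStart, qStart) → (tEnd, qEnd) for
`+`; the query coordinate steps downward from qEnd for `−`); endpoints are
exactly the block corners and the target coordinate never decreases.

## Rendering

SVG output is deterministic by construction: ordered groups, sequential
ids, attributes serialized in sorted order, floats formatted to three
decimals with trailing zeros stripped, and no timestamps. Geometry tests
parse the SVG back and compare coordinates against the module-level
transforms.

Conventions and defaults (all configurable where it matters):

- Tick policy: major ticks at the largest power of ten ≤ viewWidthBp/5;
  labels are 1-based with thin-space thousands grouping.
- y grows downward (SVG native); the dotplot query axis is inverted at
  render time so the origin reads bottom-left.
- Pileup rows are 8 px tall with 1 px padding.
- Circle layout: angular spans proportional to region lengths, clockwise
  from the rotation offset, with one gap angle per boundary; the spans sum
  to 2π − n·gap (tested to 1e-9). Chord endpoints sit exactly on the layout
  radius; the quadratic control point is the endpoint midpoint pulled toward
  the center by a factor of 0.2 (an aesthetic choice).
- Breakpoint connectors are cubic curves whose control points sit halfway
  into the inter-panel gap; the variant line is green with 6 px
  perpendicular feet pointing toward the retained side (left for
  `left_of_pos`). Soft clips render blue, insertions purple, connectors
  black — the field's usual color words, exposed in one palette table.
- Linear synteny ribbons join (tStart, tEnd) on the top edge to
  (qStart, qEnd) on the bottom edge, crossed for `−` blocks; `cigar-level`
  detail draws one polygon per match run.

## Text index

The trix-style dialect is self-defined and versioned (`# genoscene-trix 1`
header in the `.ixx`): `.ix` holds `term docId,wordPos ...` lines, terms
lowercased, strictly sorted, unique, hits sorted by docId; `.ixx` stores the
first 5 characters of every 64th term (right-padded) plus the 10-digit
lowercase-hex byte offset of that line. Byte compatibility with other trix
writers is not asserted — an explicit, testable spec was preferred over
silent incompatibility. Search lowercases the prefix, seeks via the last
`.ixx` entry strictly before the prefix key (a same-prefix stride entry may
already lie past the needle), and ranks exact-term hits before proper-prefix
hits, each group sorted by docId. Track indexing encodes
`refName:start-end|trackId|displayName` (1-based display coordinates) as the
docId so a hit decodes directly to a location; indexed fields default to
Name/ID/description-like attributes and features lacking them are skipped.

## Config, sessions, CLI

The JSON config dialect is minimal and versioned (`formatVersion: 1`):
assemblies (FASTA + optional alias/cytoband files) and tracks (unique
trackId; type ∈ feature, quantitative, alignments, variant, synteny,
reference; synteny tracks name exactly two assemblies, all others one).
Schema errors carry JSON-pointer locations. Sessions are ordered view lists
and round-trip through export/import. Locstrings accept `-` and `..` range
separators, thousands commas, bare refNames (whole sequence), aliases, and a
`[rev]` suffix for reversed display. The CLI is a thin shell — every
behavior is reachable through library calls alone — and logs
`LEVEL component message` lines to stderr.

## Synthetic fixtures: what they emulate and what they don't

`make_genome` draws uniform A/C/G/T per chromosome from one seeded
generator; every generator in the module is deterministic per seed, and the
bundled `sv-demo` preset (2 × 100 kb, a reciprocal translocation —
two junction events — plus a 10 kb inversion and a 500 bp deletion, 2 kb
reads at 10× coverage, 20% of unsplit reads carrying MM/ML tags) is the
package's standing desk-scale test condition.

Reads are error-free by default, and their alignments are obtained by
lifting each read's derived-genome interval through the SV map rather than
by running an aligner. This is deliberate: every clip boundary lands
*exactly* on an engineered breakpoint, so evidence-geometry assertions can
be exact. A real aligner would add mismatches, ambiguous clip placement at
microhomology, MAPQ variation, and chimeric artifacts; passing tests
therefore demonstrate the correctness of the geometry, bookkeeping, and
rendering pipeline, not robustness to noisy alignment. Likewise uniform
base composition means no repeats, so multi-mapping never occurs. Deletions
shorter than a read appear as D operations within one alignment (as an
aligner would produce for small deletions); translocation and inversion
junctions split reads into primary + supplementary records with mutual SA
tags.

A reciprocal translocation's two junctions share breakpoint coordinates, so
a breakpoint view centered on either junction collects the split reads of
both — the fixture truth accounts for this when counting expected
connectors.

## Numerical choices

- `px_to_bp` floors with +1e-6; region-boundary comparisons use 1e-9.
- Circle-layout conservation is asserted to 1e-9; chord endpoint radius to
  0.5 px (serialization rounds coordinates to three decimals).
- Sorting everywhere is stable; missing values sort last in tables
  regardless of direction; layout ties break longer-interval-first, then id.
- Seeds: every stochastic fixture takes an explicit seed; the acceptance
  script derives sub-seeds below 2³¹ from its single `--seed`.

## Known limitations

- GTF assembly covers gene/transcript/exon/CDS only; BigBed and Hi-C inputs
  are out of scope, as are REST feature adapters.
- CRAM requires an explicit reference FASTA (no reference-registry lookup;
  the tool stays offline).
- Three-frame translation covers the forward strand only (six-frame display
  is a caller-side composition).
- Paired-end insert evidence in the breakpoint view is limited to split
  reads' SA-derived segments; mate-pair-only connectors are not emitted.
- The config importer does not attempt fidelity to any external browser's
  config schema; it is a converter target, not a drop-in.
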