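# genoscene

A headless genome-browser engine: the computational core of a modern
multi-view genome browser as a Python library plus a small CLI, with no GUI.
It parses standard genomics formats, computes track layouts and
structural-variant/synteny geometry, and emits **deterministic,
publication-quality SVG** for six view types:

- **linear genome view** — ruler, reference sequence/GC, gene features,
  quantitative signal, multi-sample variants, and read pileups with soft-clip
  and insertion markup;
- **dotplot** and **linear synteny** views of pairwise whole-genome
  alignments (PAF, MUMmer `.delta`, UCSC `.chain`, MCScan `.anchors`);
- **circular (Circos-style)** overview with chords for long-range
  rearrangements;
- **breakpoint split view** — two stacked panels showing the split-read
  evidence for one structural variant, connectors between supplementary
  alignments, and the variant call with join-orientation "feet";
- **SV inspector** — a filterable event table combined with the circular
  overview.

It is intended for people who need reproducible static figures and
scriptable genome-browser computations: pipeline authors rendering QC
panels, method developers who need pileup/synteny geometry as data, and
anyone validating SV calls from breakend (BND) VCFs.

## The computations at the core

- **Discontiguous coordinate transform.** A view shows an ordered stack of
  regions (possibly from different chromosomes, possibly reversed). For a
  base `x` in region `i`, `px(x) = (Σ_{j<i} len_j + offset_i(x)) / bpPerPx +
  i · padding`, where `offset_i` mirrors within reversed regions;
  `px_to_bp` is its exact inverse on region interiors. Every renderer is
  built on this one transform.
- **Pileup layout.** Reads sorted by start take the lowest row whose last
  occupied end plus padding does not overlap. Left-endpoint greedy coloring
  is optimal on interval graphs, so the row count equals the maximum
  coverage depth — checked against a brute-force sweep in the tests.
- **Breakend grammar.** The four VCF bracket forms `t[p[`, `t]p]`, `]p]t`,
  `[p[t` map to (joinSide, mateJoinSide) orientations; parsing and
  formatting are exact inverses, and mates are paired via MATEID or
  reciprocal coordinates.
- **Base modifications.** MM tags are decoded by walking the delta-encoded
  skip counts over the canonical base along the *original* read (from the
  stored sequence's 3′ end on the complement for reverse-strand
  alignments); ML bytes map to likelihood `(v + 0.5)/256`.
- **trix text index.** A two-file prefix index (`.ix` sorted term lines,
  `.ixx` sparse 5-char/hex-offset table) gives seek-based name search for
  the location box.

## Worked example

Everything below runs offline: the `fixtures` command generates a 2 × 100 kb
genome carrying a reciprocal translocation (chr1:30,000 / chr2:40,000, i.e.
two junction events), a 10 kb inversion, and a 500 bp deletion, then
simulates error-free long reads whose split alignments land exactly on the
engineered breakpoints.

```bash
genoscene fixtures make --preset sv-demo --seed 1 --out demo
genoscene sv-inspect --vcf demo/truth.vcf --filter "type=BND" \
    --out-table demo/events.tsv --out-circular demo/overview.svg
cat demo/events.tsv
```

```
2 events
id        refName  start  end    mateRef  matePos  type  info.MATEID  info.SVTYPE
tra1_j1a  chr1     30000  30000  chr2     40001    BND   tra1_j1b     BND
tra1_j2b  chr1     30001  30001  chr2     40000    BND   tra1_j2a     BND
```

The filter kept exactly the two translocation junctions (coordinates are
1-based in tables; the deletion and inversion rows were filtered out).
`demo/overview.svg` shows both junctions as chords between the chr1 and
chr2 arcs.

```bash
genoscene render breakpoint --config demo/config.json --vcf demo/truth.vcf \
    --alignments reads --window 4000 --out demo/breakpoint.svg
# INFO genoscene.cli wrote demo/breakpoint.svg with 20 connectors
```

The two panels are centered on the junction ends. The 20 black curves are
the 20 simulated reads that straddle a junction within the windows (the two
reciprocal junctions share breakpoint coordinates, so the panels legitimately
collect the evidence for both); the green variant line's feet point toward
the retained side of each breakend. Rendering the same command twice
produces byte-identical SVG.

Other views, same config:

```bash
genoscene render linear   --config demo/config.json --loc "chr1:29,000-31,000" \
    --tracks genes,reads,svs --out demo/linear.svg
genoscene render dotplot  --config demo/config.json --track synteny --out demo/dot.svg
genoscene render synteny  --config demo/config.json --track synteny --out demo/syn.svg
genoscene text-index --track genes=demo/genes.gff3 --out demo/names
genoscene search --index demo/names --query gene0002
# chr1:5303-6202|genes|GENE0002
```

## Layout

```
src/genoscene/
  genome.py      assemblies, aliases, cytobands, regions, bp<->px transform
  features.py    GFF3/GTF/BED/VCF/BigWig readers, GC content, translation
  alignments.py  pileup layout, coverage, CIGAR math, MM/ML, read policies
  sv.py          breakend grammar, mate pairing, BEDPE/fusion, filtering,
                 breakpoint evidence
  synteny.py     PAF/delta/chain/anchors parsers, dotplot paths
  svg.py         deterministic scene construction for all views
  textindex.py   trix-style .ix/.ixx build and prefix search
  table.py       sortable/filterable feature tables, tsv/csv export
  config.py      JSON config/session model, locstrings
  cli.py         the `genoscene` command
  fixtures.py    synthetic genomes, SVs, reads, synteny with exact truth
```

See `docs/methods.md` for the model, conventions, and design decisions.
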