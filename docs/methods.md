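# Methods

## Scope and model

`landingpad` treats neutral-site discovery as interval algebra on a
gene-level annotation plus a stranded per-base count signal. The model
deliberately uses the **gene span** (the GFF3 `gene` feature) rather
than exon unions or transcript models: the filter's question is whether
an intergenic gap is free of transcription, and in a compact genome the
gene span is the natural unit for both the "flanking genes transcribed"
test and the gap boundaries. Transcript-aware refinement would only
move gap edges inward and is out of scope.

Coordinates are 0-based half-open everywhere inside the package; the
GFF3 reader/writer and the GenBank writer are the only places ±1
arithmetic occurs. Readers reject out-of-bounds or malformed records
rather than repairing them.

Coverage is consumed, never produced: the package reads per-strand
bedGraph or fixed-step wiggle tracks of raw counts and densifies them to
one integer per base. Whether those counts came from unique or
multi-mapped reads is upstream policy.

## The stepwise filter and its parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_neutral_len` | 11 | bp | strict "> 10 bp" read-free run |
| `min_gene_mean_coverage` | 0 | reads/bp | transcription threshold, strict `mean > t` |
| `centromere_halfwidth` | 50 000 | bp | masked zone each side of a centromere |
| `zero_threshold` | 0 | reads | per-base count treated as "no reads" |
| `combine_strands` | true | — | zero runs use plus+minus counts |

Decisions worth recording:

- **"> 10 bp" is read literally** as length ≥ 11. With deep data
  (~100 reads per transcribed base) a single read-free base is already
  informative, but the stricter bound is the stated criterion.
- **Transcription evidence** defaults to "any mapped read on the gene's
  own strand" (`mean > 0`). At realistic depth any genuinely expressed
  gene passes; the threshold is exposed because shallow libraries need a
  higher bar.
- **Zero runs pool both strands** by default: a gap is only neutral if
  neither gene's 3′UTR reads into it on either strand. Per-strand mode
  exists for diagnostic use.
- **One locus per gap**: when a gap holds several qualifying runs the
  longest is kept, ties broken by midpoint closest to the gap midpoint,
  then leftmost. A single representative matches the one-construct-
  per-site design downstream.
- **Centromere mask half-width** has no published value; 50 kb is a
  deliberately conservative default on a genome whose chromosomes are
  hundreds of kb, and it is a first-class parameter.
- Benchmark loci that fail the criteria can be injected after the
  filter via an allowlist; they are flagged `non_neutral=True` and share
  the NL numbering in coordinate order.
- `require_convergent` / `require_transcription` toggles exist so the
  decoy-specificity of the fixture can be audited filter by filter; the
  defaults reproduce the full criterion set.

NL identifiers are assigned after all filtering, in (chromosome order,
neutral-region start) order, so the naming is stable under any
permutation of the input annotation.

## Construct design

**Domestication.** Sites of the configured enzymes (BbsI `GAAGAC`, also
searched as `GTCTTC`; ZraI `GACGTC`, palindromic) are removed by exactly
one substitution per occurrence. The substitution is chosen
deterministically — positions scanned left to right within the site,
bases in order A<C<G<T — and accepted only if it destroys the target
site, creates no new site of any configured enzyme on either strand,
and does not revert an earlier edit. The sequence is rescanned after
each edit, so overlapping and nested occurrences converge; a site with
no admissible fix raises an error naming it. Any admissible single-base
edit satisfies the biological intent; determinism is what makes arms
reproducible across runs.

**Arms.** The two 550 bp arms are cut from the 1100 bp centered on the
neutral region's midpoint (floored for even lengths) and domesticated
**jointly** as one 1100-mer, so a site straddling the arm junction is
also caught. The midpoint, not the gap edges, centers the arms: the
insertion point then sits maximally far from both flanking 3′ ends.

**Linearization.** The left arm's outermost 12 bp are searched for a
suffix of `GACGTC` (length ≥ 3, mirrored as a prefix at the right arm's
downstream end). A partial at offset `off` with length `k` is completed
by trimming the `off` boundary bases and adding the missing `6−k` bases
outside the arm; after the blunt `GAC│GTC` cut the integrated homology
region is shorter by `off + k − 3 ≤ 3` bp (recorded per end as
`arm_delta`). Without a usable partial, a full site is placed outside
the arm — homology region unchanged, three non-genomic bases retained on
the fragment (`extra_bp`). This is why homology regions "vary by a few
nucleotides" between constructs. Both thresholds (minimum partial
length 3, maximum boundary trim 3, search window 12) are arguments.

**Assembly.** The construct is left arm + ordered payload parts + right
arm (+ linearization half-sites when planned). Parts still carrying
recognition sites are domesticated at assembly time: CDS parts by
synonymous codon swaps only (replacement codons tried in descending
usage frequency; translation preserved by construction), all other
parts by the single-base rule. The final sequence is verified site-free
on both strands except the two planned terminal ZraI sites; violation is
an error, not a warning.

**Back-translation** encodes each residue with its most frequent codon,
ties broken alphabetically — deliberately not a codon optimizer; it is
the reproducible baseline the codon-usage table defines.

**Genotyping anchors.** The outer anchors are the 25 bp of genome ending
100 bp outside each arm; the inner anchors are the cassette's first and
last 25 bp; all are oriented 5′→3′ toward their junction. The reported
junction span is measured from the outer anchor's junction-proximal edge
to the inner anchor's far edge: `offset + arm_len + anchor_len` = 675 bp
at defaults. (The full physical amplicon adds the outer anchor's own
25 bp.) Anchor extraction is coordinate bookkeeping only; melting
temperature and dimer checks are out of scope.

## The synthetic fixture

The generator emulates the *inputs* of the scan, not sequencing reads.
Each chromosome (default 2 × 150 kb) is a row of two-gene units:
planted neutral units (convergent, both genes covered at Poisson mean
100 reads/bp on their own strand, 8–25 bp of readthrough into the gap
from each side, a forced all-zero neutral region of 15–60 bp) and one
decoy per class, each violating exactly one criterion. Gene lengths are
uniform in [300, 2000] bp; intra-unit gaps are ≥ 30 bp; spacers between
units are completely covered by a constant background track so no
accidental intergenic gap can qualify — this is also what makes the
decoy-specificity audits exact. One BbsI/ZraI motif is written into
each planted arm window so domestication is exercised on every designed
construct. The centromere (1 kb, near the chromosome end) gets a
centromere-adjacent decoy placed just inside the 50 kb mask zone.

What the fixture does **not** emulate: mapping artifacts, multimapper
inflation, repeat regions, coverage batch effects, fractional/normalized
tracks, overlapping or nested genes, and annotation errors. Passing the
recovery tests therefore shows the filter logic and bookkeeping are
exact under clean counts — not that real libraries are free of those
complications; on real data the transcription threshold and mask width
are the knobs that absorb them.

Validity envelope for exact recovery (asserted in tests): intergenic
gaps ≥ 30 bp, planted neutral length ≥ `min_neutral_len`, depth ≥ 5
reads/bp. All randomness flows from one `numpy` PCG64 generator, so a
seed fixes every output byte.

The codon-usage table used in tests and examples
(`synthetic_codon_table`) is synthetic: standard genetic code with
seeded pseudo-frequencies. Real analyses should pass an organism table
as TSV (codon, residue, frequency).

## Numerical and degenerate-input choices

- Zero-run detection is a vectorized boundary scan; it agrees with a
  per-base brute-force oracle on randomized arrays (tested), including
  empty intervals and all-zero intervals clipped at interval edges.
- Overlapping genes produce no intergenic region; genes with strand `.`
  are dropped at parse time with a warning and never pair their
  neighbours across the gap they occupied.
- Design windows clipped at a chromosome end are flagged `truncated`;
  arm cutting refuses a window that cannot supply the full 1100 bp.
- `z = height + 1 mm` keeps the tip clearance explicit and separate from
  the mass-derived height; plate area and gel density have no shipped
  defaults because they are apparatus properties, so the `zoffset`
  command requires them.
- Dilution planning rejects non-geometric factor chains: a serial
  transfer with fixed per-step ratio cannot realize them.

## Problem sizes

Tests and the acceptance script run on the 2 × 150 kb two-chromosome
fixture (34 genes, 5 planted loci, 12 decoys), 500 randomized coverage
arrays for the zero-run oracle, 300–1000 randomized 1100 bp windows for
the domestication suite, and 20 fixture seeds for the monotonicity
audit. These sizes were chosen so the full pipeline exercises every
branch while a complete run stays in the tens of seconds; the scan
itself is linear in genome length and runs unchanged on full genomes —
point `landingpad scan` at a real FASTA/GFF3/bedGraph set (e.g. a
reference genome with deep stranded RNA-seq mapped by any splice-aware
aligner) to reproduce a genome-wide locus catalogue.

## Known limitations

- Gene-span transcription testing can miss a gene whose annotation is
  wrong at the 3′ end; the neutral-region zero-run is the backstop.
- Single-base domestication does not respect reading frames in arms
  (arms are non-coding by construction of the filter, but an arm
  overlapping a mis-annotated CDS would be edited bluntly).
- The linearization planner models ZraI only; other blunt cutters would
  need their own half-site geometry.
- BigWig input is not implemented; convert to bedGraph text first.
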