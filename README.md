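# landingpad

Neutral-site ("landing pad") discovery and integration-construct design
for compact, gene-dense eukaryotic genomes.

## The problem

Targeted transgene integration needs genomic loci where an insertion
neither disrupts native genes nor lands inside transcribed sequence. In a
compact genome with short intergenic spaces, the safest candidates are
the gaps between **convergent (3′–3′) gene pairs**: both flanking genes
point their 3′ ends at the gap, so the only transcription that can cross
it is 3′UTR readthrough — and that is directly measurable with stranded
RNA-seq. `landingpad` implements the resulting stepwise filter and
everything needed to turn each surviving locus into a transformable
homologous-recombination construct.

A candidate intergenic gap is kept when:

1. its flanking gene pair is convergent (`+` then `−`),
2. both flanking genes show RNA-seq evidence of transcription
   (mean own-strand per-base count > *t*, default *t* = 0),
3. the gap contains a **neutral region**: a maximal run of > 10 bp with
   zero mapped reads on both strands combined (no overlapping 3′UTRs),
4. the neutral region lies outside a masked zone of ± *w* bp around each
   centromere (default *w* = 50 kb).

Survivors are named `NL001, NL002, …` in (chromosome, coordinate) order.
For each locus the designer exports a 3 kb window around the neutral
region's midpoint, cuts the central 1100 bp into two 550 bp homology
arms, **domesticates** them against BbsI (`GAAGAC`) and ZraI (`GACGTC`)
with deterministic single-base edits, plans blunt-end ZraI linearization
from partial sites already present at the arm boundaries (so integrated
homology regions may vary in length by a few nucleotides), assembles the
payload cassette, and extracts four genotyping anchors ~100 bp outside
the arms and just inside the cassette. Protein payloads are
back-translated with the most frequent codon per residue from a supplied
codon-usage table; sites inside a CDS are removed by synonymous codon
swaps only. The package also carries the robotic-plating geometry used
to plate transformants on gellan-gum plates,

    gel_height_mm = weight_g / (area_mm² × density_g_per_mm³),
    z = gel_height + 1 mm,

and a serial-dilution planner for geometric chains (neat, 1:3, 1:9,
1:27).

A seeded synthetic-fixture generator (`landingpad.synth_fixtures`)
produces a multi-chromosome genome, gene-only GFF3, stranded bedGraph
coverage with 3′UTR readthrough, and a centromere BED, with planted
neutral loci and six classes of labelled decoys — each violating exactly
one filter criterion — so the whole pipeline is testable end to end
without any external data.

## Worked example

```bash
landingpad simulate --seed 1 --outdir fixture
# wrote fixture to fixture: 34 genes, 5 recoverable planted loci, 12 decoys

landingpad scan --fasta fixture/genome.fa --gff3 fixture/genes.gff3 \
    --cov-plus fixture/coverage_plus.bedgraph \
    --cov-minus fixture/coverage_minus.bedgraph \
    --centromeres fixture/centromeres.bed --out-bed loci.bed
# 5 candidate loci -> loci.bed
```

`loci.bed` now holds the five neutral regions, e.g.
`chr1  5447  5485  NL001  0  .` — a 38 bp read-free interval between a
convergent transcribed gene pair. The same from Python, continuing into
construct design:

```python
import landingpad as lp
from landingpad.synth_fixtures import example_cassette, synthetic_codon_table

fx = lp.generate_fixture(lp.FixtureParams(seed=1))
loci = lp.scan_neutral_loci(fx.genome, fx.genes, fx.coverage, fx.centromeres)
locus = loci[0]

table = synthetic_codon_table(1)
parts = example_cassette(table, 1)
window = lp.design_window(fx.genome, locus.chrom, locus.center)
arms = lp.cut_arms(window, locus.center)
lin = lp.plan_linearization(arms)
construct = lp.assemble_construct(arms, parts, lin, codon_table=table,
                                  name=locus.nl_id)
anchors = lp.genotyping_anchors(fx.genome, locus.chrom, locus.center,
                                construct.cassette_sequence)
```

which prints (via the fields shown):

```
NL001: chr1:5447-5485 (38 bp read-free) between g1_003(+) and g1_004(-)
arms: 2 x 550 bp, 3 domestication edit(s)
linearization: left=fallback, right=fallback
construct: 2935 bp, cassette 1823 bp
junction amplicon span: 675 bp
```

The three edits are the single-base substitutions that removed the
BbsI/ZraI occurrences inside the 1100 bp arm region (one of them seeded
by the fixture); the construct carries exactly two terminal ZraI sites
for blunt linearization and none internally; and 675 bp = 100 (offset) +
550 (arm) + 25 (anchor) is the predicted junction-amplicon span used for
integration genotyping. `landingpad design` writes the same constructs
as annotated GenBank plus an edit log; `landingpad zoffset` and
`landingpad dilute` expose the plating math.

To scan real data instead of a fixture, pass a genome FASTA, a GFF3 with
`gene` features, per-strand bedGraph (or fixed-step wiggle) tracks of raw
per-base read counts, and optionally a centromere BED and an allowlist
BED of benchmark loci to carry through flagged as non-neutral.

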