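"""Seeded synthetic genomes with planted neutral loci and labelled decoys.

The generator emulates the inputs of a neutral-site scan on a compact,
gene-dense genome: a multi-chromosome FASTA, a gene-only GFF3, stranded
per-base coverage tracks with 3'UTR readthrough into intergenic gaps, and
a centromere BED. Each chromosome is laid out as a row of two-gene units.
Planted units are convergent, transcribed pairs whose gap contains an
exactly known read-free neutral region; decoy units each violate exactly
one scan criterion:

``divergent_pair``      genes face 5'-5' (orientation filter)
``tandem_pair``         genes on the same strand (orientation filter)
``silent_flank``        one flanking gene without reads (transcription)
``short_run``           read-free run of <= 10 bp (neutral-region length)
``readthrough_filled``  3' readthrough covers the whole gap (no run)
``centromere_adjacent`` valid site inside the masked centromere zone

Spacers between units are fully covered with a constant background track
so that only the constructed gaps can ever qualify. Everything is drawn
from one seeded generator, so identical parameters give byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from landingpad.arm_design import BBSI, ZRAI
from landingpad.genome_io import (
    CentromereMap,
    GeneFeature,
    GenomeSequence,
    StrandedCoverage,
    write_bedgraph,
    write_fasta,
    write_gff3,
)

DECOY_CLASSES = (
    "divergent_pair",
    "tandem_pair",
    "silent_flank",
    "short_run",
    "readthrough_filled",
    "centromere_adjacent",
)


class FixtureError(ValueError):
    """Raised when the requested fixture cannot be packed."""


@dataclass(frozen=True)
class FixtureParams:
    """Study conditions for the synthetic genome.

    Defaults emulate a deep stranded RNA-seq experiment on a compact
    genome: ~100 reads per transcribed base, gene lengths of 0.3-2 kb,
    intergenic gaps of at least 30 bp with short 3'UTR readthrough on
    each side, and planted neutral regions comfortably above the >10 bp
    acceptance length.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_len: int = 150_000
    planted_per_chrom: tuple[int, ...] = (3, 2)
    decoys_per_chrom: tuple[str, ...] = DECOY_CLASSES
    gene_len_range: tuple[int, int] = (300, 2000)
    readthrough_range: tuple[int, int] = (8, 25)
    planted_neutral_len_range: tuple[int, int] = (15, 60)
    coverage_depth: float = 100.0
    spacer_range: tuple[int, int] = (40, 120)
    spacer_fill: int = 3
    margin: int = 1600
    centromere: bool = True
    centromere_width: int = 1000
    centromere_halfwidth: int = 50_000
    seeded_sites_per_window: int = 1

    def __post_init__(self) -> None:
        if len(self.planted_per_chrom) != self.n_chroms:
            raise ValueError("planted_per_chrom must have n_chroms entries")
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be > 0")
        if self.planted_neutral_len_range[0] < 11:
            raise ValueError("planted neutral regions must be > 10 bp to be "
                             "recoverable")


@dataclass(frozen=True)
class PlantedLocus:
    chrom: str
    gap_start: int
    gap_end: int
    neutral_start: int
    neutral_end: int
    left_gene: str
    right_gene: str
    recoverable: bool = True
    reason: str = ""


@dataclass(frozen=True)
class Decoy:
    chrom: str
    gap_start: int
    gap_end: int
    decoy_class: str
    left_gene: str
    right_gene: str


@dataclass
class SyntheticTruthSet:
    """Ground truth emitted alongside the fixture files."""

    planted: list[PlantedLocus] = field(default_factory=list)
    decoys: list[Decoy] = field(default_factory=list)
    seeded_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def recoverable(self) -> list[PlantedLocus]:
        return [p for p in self.planted if p.recoverable]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tchrom\tgap_start\tgap_end\tneutral_start\t"
                     "neutral_end\tclass\tleft_gene\tright_gene\t"
                     "recoverable\treason\n")
            for p in self.planted:
                fh.write(
                    f"planted\t{p.chrom}\t{p.gap_start}\t{p.gap_end}\t"
                    f"{p.neutral_start}\t{p.neutral_end}\t.\t{p.left_gene}\t"
                    f"{p.right_gene}\t{int(p.recoverable)}\t{p.reason or '.'}\n"
                )
            for d in self.decoys:
                fh.write(
                    f"decoy\t{d.chrom}\t{d.gap_start}\t{d.gap_end}\t.\t.\t"
                    f"{d.decoy_class}\t{d.left_gene}\t{d.right_gene}\t0\t.\n"
                )
            for chrom, pos, enzyme in self.seeded_sites:
                fh.write(f"seeded_site\t{chrom}\t{pos}\t.\t.\t.\t{enzyme}"
                         f"\t.\t.\t.\t.\n")


@dataclass
class Fixture:
    """In-memory fixture plus a writer for the on-disk dialects."""

    params: FixtureParams
    genome: GenomeSequence
    genes: list[GeneFeature]
    coverage: dict[str, StrandedCoverage]
    centromeres: CentromereMap
    truth: SyntheticTruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "cov_plus": outdir / "coverage_plus.bedgraph",
            "cov_minus": outdir / "coverage_minus.bedgraph",
            "centromeres": outdir / "centromeres.bed",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        for i, chrom in enumerate(self.genome.chrom_names):
            cov = self.coverage[chrom]
            write_bedgraph(cov.plus, chrom, paths["cov_plus"], append=i > 0)
            write_bedgraph(cov.minus, chrom, paths["cov_minus"], append=i > 0)
        with open(paths["centromeres"], "w") as fh:
            for chrom, s, e in self.centromeres.entries:
                fh.write(f"{chrom}\t{s}\t{e}\tcentromere\t0\t.\n")
        self.truth.to_tsv(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    kind: str                     # "planted" or a decoy class
    left_strand: str
    right_strand: str


def _unit_spec(kind: str, alt: bool) -> _Unit:
    if kind in ("planted", "silent_flank", "short_run", "readthrough_filled",
                "centromere_adjacent"):
        return _Unit(kind, "+", "-")
    if kind == "divergent_pair":
        return _Unit(kind, "-", "+")
    if kind == "tandem_pair":
        return _Unit(kind, "+", "+") if not alt else _Unit(kind, "-", "-")
    raise ValueError(f"unknown unit kind {kind}")


def generate_fixture(params: FixtureParams | None = None,
                     outdir: str | Path | None = None) -> Fixture:
    """Generate the synthetic genome, annotation, coverage and truth set.

    Deterministic for a fixed seed. Genes never overlap; every intergenic
    gap inside a unit is >= 30 bp; spacers between units are fully
    covered by a constant background track so no unintended neutral
    region can arise. Raises :class:`FixtureError` when the requested
    units do not fit on the chromosome.
    """
    params = params or FixtureParams()
    rng = np.random.default_rng(params.seed)
    sequences: dict[str, str] = {}
    genes: list[GeneFeature] = []
    coverage: dict[str, StrandedCoverage] = {}
    cen_entries: list[tuple[str, int, int]] = []
    truth = SyntheticTruthSet()

    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=params.chrom_len)
        plus = np.zeros(params.chrom_len, dtype=np.int64)
        minus = np.zeros(params.chrom_len, dtype=np.int64)

        if params.centromere:
            cen_end = params.chrom_len - 200
            cen_start = cen_end - params.centromere_width
            cen_entries.append((chrom, cen_start, cen_end))
            mask_start = cen_start - params.centromere_halfwidth
        else:
            cen_start = mask_start = params.chrom_len

        kinds = ["planted"] * params.planted_per_chrom[ci] + [
            k for k in params.decoys_per_chrom if k != "centromere_adjacent"
        ]
        order = rng.permutation(len(kinds))
        kinds = [kinds[i] for i in order]

        cursor = params.margin
        gene_no = 0
        prev_right: GeneFeature | None = None

        def _next_gene_id() -> str:
            nonlocal gene_no
            gene_no += 1
            return f"g{ci + 1:d}_{gene_no:03d}"

        def _place_unit(kind: str, at: int) -> int:
            """Lay one two-gene unit starting at ``at``; returns its end."""
            nonlocal prev_right
            unit = _unit_spec(kind, alt=bool(rng.integers(0, 2)))
            L1, L2 = rng.integers(*params.gene_len_range, size=2)
            rt_l, rt_r = rng.integers(*params.readthrough_range, size=2)
            if kind in ("planted", "centromere_adjacent"):
                nlen = int(rng.integers(*params.planted_neutral_len_range))
                gap = int(rt_l + nlen + rt_r)
            elif kind == "short_run":
                rt_l = rt_r = int(rng.integers(12, 21))
                nlen = int(rng.integers(5, 11))
                gap = int(rt_l + nlen + rt_r)
            elif kind == "readthrough_filled":
                gap = int(rng.integers(30, 61))
            elif kind in ("tandem_pair", "silent_flank"):
                # one-sided readthrough plus a guaranteed >10 bp zero run,
                # so the unit violates only its own criterion
                gap = int(rt_l + rng.integers(20, 61))
                rt_r = rt_l
            else:  # divergent_pair: both 3' ends face away, gap uncovered
                gap = int(rng.integers(30, 81))

            lg_start, lg_end = at, at + int(L1)
            gap_start, gap_end = lg_end, lg_end + gap
            rg_start, rg_end = gap_end, gap_end + int(L2)
            if rg_end > params.chrom_len:
                raise FixtureError(
                    f"{chrom}: unit {kind} does not fit (needs up to "
                    f"{rg_end}, chromosome is {params.chrom_len} bp)"
                )

            left = GeneFeature(_next_gene_id(), chrom, lg_start, lg_end,
                               unit.left_strand)
            right = GeneFeature(_next_gene_id(), chrom, rg_start, rg_end,
                                unit.right_strand)

            silent_right = kind == "silent_flank"
            for gene, silent in ((left, False), (right, silent_right)):
                if silent:
                    continue
                track = plus if gene.strand == "+" else minus
                track[gene.start:gene.end] = rng.poisson(
                    params.coverage_depth, gene.length
                )

            def _fill(track, s, e):
                track[s:e] = np.maximum(
                    rng.poisson(params.coverage_depth, e - s), 1
                )

            if kind in ("planted", "centromere_adjacent", "short_run"):
                _fill(plus, gap_start, gap_start + rt_l)
                _fill(minus, gap_end - rt_r, gap_end)
                neutral = (gap_start + int(rt_l), gap_end - int(rt_r))
            elif kind == "readthrough_filled":
                _fill(plus, gap_start, gap_end)
                _fill(minus, gap_start, gap_end)
                neutral = None
            elif kind == "silent_flank":
                _fill(plus, gap_start, gap_start + rt_l)
                neutral = None
            elif kind == "tandem_pair":
                if unit.left_strand == "+":
                    _fill(plus, gap_start, gap_start + rt_l)
                else:
                    _fill(minus, gap_end - rt_r, gap_end)
                neutral = None
            else:  # divergent_pair: both 3' ends face away from the gap
                neutral = None

            if kind == "planted":
                truth.planted.append(PlantedLocus(
                    chrom, gap_start, gap_end, neutral[0], neutral[1],
                    left.gene_id, right.gene_id,
                ))
            else:
                truth.decoys.append(Decoy(chrom, gap_start, gap_end, kind,
                                          left.gene_id, right.gene_id))

            genes.extend([left, right])
            prev_right = right
            return rg_end

        for kind in kinds:
            if prev_right is not None:
                spacer = int(rng.integers(*params.spacer_range))
                start = prev_right.end + spacer
            else:
                start = cursor
            cursor = _place_unit(kind, start)

        # fill every inter-unit spacer completely with background signal
        # (done after placement so gene coordinates are known)
        chrom_genes = [g for g in genes if g.chrom == chrom]

        if params.centromere and "centromere_adjacent" in params.decoys_per_chrom:
            if cursor > mask_start - 5000:
                raise FixtureError(
                    f"{chrom}: units spill into the centromere mask zone — "
                    "shorten the unit list or enlarge the chromosome"
                )
            decoy_at = mask_start + 1000
            end = _place_unit("centromere_adjacent", decoy_at)
            if end > cen_start - 50:
                raise FixtureError(f"{chrom}: centromere decoy overlaps the "
                                   "centromere")
            chrom_genes = [g for g in genes if g.chrom == chrom]
        elif cursor > params.chrom_len:
            raise FixtureError(f"{chrom}: units do not fit")

        chrom_genes.sort(key=lambda g: g.start)
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            in_unit_gap = any(
                (a.gene_id, b.gene_id) == (p.left_gene, p.right_gene)
                for p in truth.planted
            ) or any(
                (a.gene_id, b.gene_id) == (d.left_gene, d.right_gene)
                for d in truth.decoys
            )
            if not in_unit_gap and b.start > a.end:
                plus[a.end:b.start] = params.spacer_fill

        # seed restriction-site motifs inside planted arm windows
        for p in truth.planted:
            if p.chrom != chrom:
                continue
            center = (p.neutral_start + p.neutral_end) // 2
            for si in range(params.seeded_sites_per_window):
                enz = BBSI if (si + len(truth.seeded_sites)) % 2 == 0 else ZRAI
                lo, hi = center - 500, center + 500 - len(enz.recognition)
                pos = int(rng.integers(lo, hi))
                seq[pos:pos + len(enz.recognition)] = _encode(enz.recognition)
                truth.seeded_sites.append((chrom, pos, enz.name))

        sequences[chrom] = _decode(seq)
        coverage[chrom] = StrandedCoverage(chrom=chrom, plus=plus, minus=minus)

    genome = GenomeSequence(sequences)
    fixture = Fixture(
        params=params, genome=genome,
        genes=sorted(genes, key=lambda g: (g.chrom, g.start)),
        coverage=coverage,
        centromeres=CentromereMap(cen_entries),
        truth=truth,
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture


_B2I = {b: i for i, b in enumerate("ACGT")}


def _encode(s: str) -> np.ndarray:
    return np.array([_B2I[c] for c in s], dtype=np.int64)


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Synthetic payload material (codon table, cassette parts)
# ---------------------------------------------------------------------------

def synthetic_codon_table(seed: int = 1):
    """A synthetic codon-usage table: standard genetic code with seeded
    pseudo-frequencies (per-thousand scale). Stands in for an organism
    table in tests and examples; the real pipeline reads one from TSV.
    """
    from landingpad.arm_design import _CODON_TO_AA, CodonUsageTable

    rng = np.random.default_rng(seed)
    freqs = {
        codon: (aa, float(np.round(rng.uniform(0.5, 40.0), 2)))
        for codon, aa in sorted(_CODON_TO_AA.items())
    }
    return CodonUsageTable(freqs)


def example_cassette(codon_table=None, seed: int = 1, cds_residues: int = 240):
    """A synthetic reporter cassette: promoter, back-translated CDS,
    terminator and a selection-marker block, as CassettePart objects.
    """
    from landingpad.arm_design import CassettePart, back_translate

    codon_table = codon_table or synthetic_codon_table(seed)
    rng = np.random.default_rng(seed + 7)
    aa_letters = "ACDEFGHIKLMNPQRSTVWY"
    protein = "M" + "".join(
        aa_letters[i] for i in rng.integers(0, len(aa_letters),
                                            size=cds_residues - 1)
    )
    cds = back_translate(protein, codon_table, include_stop=True)

    def _rand_dna(n: int) -> str:
        return _decode(rng.integers(0, 4, size=n))

    return [
        CassettePart("promoter_constitutive", "promoter", _rand_dna(220)),
        CassettePart("reporter_cds", "cds", cds),
        CassettePart("terminator", "terminator", _rand_dna(180)),
        CassettePart("selection_marker", "marker", _rand_dna(700)),
    ]


# ---------------------------------------------------------------------------
# In-silico integration
# ---------------------------------------------------------------------------

def splice_integration(genome: GenomeSequence, construct) -> GenomeSequence:
    """Splice a designed construct into the genome at its locus.

    The (possibly edited) homology arms replace their genomic footprint
    and the cassette is inserted between them, so the output length is
    the input length plus the cassette length. Arms that differ from the
    genome at positions other than their recorded edits are rejected.
    """
    arms = construct.arms
    chrom = arms.chrom
    seq = genome[chrom]
    left_ref = seq[arms.left_start:arms.center]
    right_ref = seq[arms.center:arms.right_end]
    edit_offsets = {e.window_offset for e in arms.edits}
    for label, arm, ref, base in (
        ("left", arms.left_arm, left_ref, 0),
        ("right", arms.right_arm, right_ref, arms.arm_len),
    ):
        mismatches = {
            base + i for i, (a, r) in enumerate(zip(arm, ref)) if a != r
        }
        if not mismatches <= edit_offsets:
            raise ValueError(
                f"{label} arm differs from the genome beyond its recorded "
                f"edits at offsets {sorted(mismatches - edit_offsets)[:5]}"
            )
    cassette = construct.cassette_sequence
    new_seq = (seq[:arms.left_start] + arms.left_arm + cassette +
               arms.right_arm + seq[arms.right_end:])
    sequences = dict(genome.sequences)
    sequences[chrom] = new_seq
    return GenomeSequence(sequences)
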