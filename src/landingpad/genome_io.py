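"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. GFF3 and GenBank are the
only places 1-based inclusive arithmetic happens, on the way in and out.
Readers reject malformed or out-of-bounds records instead of repairing
them silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes other than N
_AMBIGUITY = set("RYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """An ordered collection of chromosome sequences (upper-case ACGTN)."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: half-open interval on a stranded chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """Position of the 3' end (the last transcribed base boundary)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class StrandedCoverage:
    """Per-base raw read counts for the + and - strands of one chromosome."""

    chrom: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        if len(self.plus) != len(self.minus):
            raise ValueError(f"{self.chrom}: strand arrays differ in length")

    def combined(self) -> np.ndarray:
        return self.plus + self.minus


@dataclass
class CentromereMap:
    """At most one centromere interval (0-based half-open) per chromosome."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, start, end in self.entries:
            if chrom in seen:
                raise ValueError(f"multiple centromere entries for {chrom}")
            if not (0 <= start < end):
                raise ValueError(f"bad centromere interval on {chrom}")
            seen.add(chrom)

    def for_chrom(self, chrom: str) -> tuple[int, int] | None:
        for c, s, e in self.entries:
            if c == chrom:
                return (s, e)
        return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, ambiguous_to_n: bool = False) -> GenomeSequence:
    """Read a genome FASTA into upper-case ACGTN sequences.

    Lower-case is upper-cased and RNA U becomes T. IUPAC ambiguity codes
    other than N are rejected unless ``ambiguous_to_n`` maps them to N.
    Duplicate headers and empty records are format errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: empty FASTA header")
        if name in sequences:
            raise FormatError(f"{path}: duplicate header {name!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty record {name!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            if ambiguous_to_n and bad <= _AMBIGUITY:
                table = str.maketrans({c: "N" for c in bad})
                seq = seq.translate(table)
            else:
                raise FormatError(
                    f"{path}: record {name!r} contains non-ACGTN characters "
                    f"{sorted(bad)}"
                )
        sequences[name] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence | dict[str, str], path: str | Path,
                width: int = 70) -> None:
    seqs = genome.sequences if isinstance(genome, GenomeSequence) else genome
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneFeature]:
    """Read gene-level features from GFF3 into 0-based half-open coordinates.

    Only ``feature_type`` rows are kept; transcript/exon children are
    ignored (the gene span stands in for the transcript model). Records
    with strand '.' or '?' are dropped with a warning since orientation
    logic cannot classify them. Output is sorted by (chrom, start).
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: dropping feature with strand %r", path, lineno, strand
                )
                continue
            gene_id = _gff3_attr(attrs, "ID") or f"{feature_type}_{lineno}"
            genes.append(
                GeneFeature(gene_id=gene_id, chrom=chrom,
                            start=start1 - 1, end=end1, strand=strand)
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def write_gff3(genes: Iterable[GeneFeature], path: str | Path,
               source: str = "landingpad") -> None:
    """Emit gene features back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Coverage (bedGraph / fixed-step wiggle)
# ---------------------------------------------------------------------------

def read_coverage(path_plus: str | Path, path_minus: str | Path,
                  genome: GenomeSequence) -> dict[str, StrandedCoverage]:
    """Read one coverage track per strand into dense per-base arrays.

    Accepts bedGraph (0-based half-open) or fixed-step wiggle (1-based)
    in either file; bases absent from the file have count 0. Intervals
    beyond a chromosome end are format errors.
    """
    plus = _read_track(path_plus, genome)
    minus = _read_track(path_minus, genome)
    return {
        chrom: StrandedCoverage(chrom=chrom, plus=plus[chrom], minus=minus[chrom])
        for chrom in genome.chrom_names
    }


def _read_track(path: str | Path, genome: GenomeSequence) -> dict[str, np.ndarray]:
    arrays = {
        chrom: np.zeros(genome.length(chrom), dtype=np.int64)
        for chrom in genome.chrom_names
    }
    fixed_chrom: str | None = None
    fixed_pos = 0
    fixed_step = 1
    fixed_span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                fixed_chrom = kv["chrom"]
                fixed_pos = int(kv["start"]) - 1  # wiggle is 1-based
                fixed_step = int(kv.get("step", 1))
                fixed_span = int(kv.get("span", 1))
                if fixed_chrom not in arrays:
                    raise FormatError(f"{path}:{lineno}: unknown chrom {fixed_chrom}")
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep wiggle unsupported")
            fields = line.split()
            if fixed_chrom is not None and len(fields) == 1:
                value = float(fields[0])
                end = fixed_pos + fixed_span
                if end > len(arrays[fixed_chrom]):
                    raise FormatError(
                        f"{path}:{lineno}: position {end} beyond end of {fixed_chrom}"
                    )
                arrays[fixed_chrom][fixed_pos:end] += int(round(value))
                fixed_pos += fixed_step
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected bedGraph 4 columns")
            chrom, start_s, end_s, value_s = fields
            if chrom not in arrays:
                raise FormatError(f"{path}:{lineno}: unknown chrom {chrom}")
            start, end = int(start_s), int(end_s)
            if end > len(arrays[chrom]) or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) beyond end of "
                    f"{chrom} (length {len(arrays[chrom])})"
                )
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            arrays[chrom][start:end] += int(round(float(value_s)))
    for arr in arrays.values():
        if (arr < 0).any():
            raise FormatError(f"{path}: negative coverage counts")
    return arrays


def write_bedgraph(array: np.ndarray, chrom: str, path: str | Path,
                   append: bool = False) -> None:
    """Write a dense per-base array as run-length-compressed bedGraph.

    Zero runs are omitted (absent bases read back as 0).
    """
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if len(array) == 0:
            return
        boundaries = np.flatnonzero(np.diff(array)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(array)]))
        for s, e in zip(starts, ends):
            v = int(array[s])
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(loci: Sequence, path: str | Path) -> None:
    """Write candidate loci as BED6 (name = NL id, score 0, strand '.')."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.neutral.start}\t{locus.neutral.end}\t"
                f"{locus.nl_id}\t0\t.\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3+ intervals as (chrom, start, end, name)."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            out.append((fields[0], start, end, name))
    return out


def read_centromeres(path: str | Path, genome: GenomeSequence | None = None
                     ) -> CentromereMap:
    entries = []
    for chrom, start, end, _name in read_bed(path):
        if genome is not None:
            if chrom not in genome:
                raise FormatError(f"{path}: unknown chrom {chrom}")
            if end > genome.length(chrom):
                raise FormatError(f"{path}: centromere beyond end of {chrom}")
        entries.append((chrom, start, end))
    return CentromereMap(entries)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def write_genbank(construct, path: str | Path) -> None:
    """Write a construct as an annotated GenBank record.

    Feature locations follow the GenBank convention internally handled by
    Biopython (FeatureLocation is 0-based half-open in memory, serialized
    1-based inclusive on disk).
    """
    record = SeqRecord(
        Seq(construct.full_sequence),
        id=construct.name[:16] or "construct",
        name=construct.name[:16] or "construct",
        description=construct.description,
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for label, start, end, kind in construct.feature_table():
        record.features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=1),
                type=kind,
                qualifiers={"label": [label]},
            )
        )
    SeqIO.write(record, str(path), "genbank")


def read_genbank(path: str | Path) -> SeqRecord:
    return SeqIO.read(str(path), "genbank")
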