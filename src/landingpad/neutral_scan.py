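"""Stepwise neutral-locus filter.

The scan walks every intergenic gap of an annotated genome and keeps only
those flanked by a convergent (3'-3') gene pair in which both genes show
RNA-seq evidence of transcription and the gap contains a 'neutral region':
a maximal run longer than 10 bp with no mapped reads on either strand,
taken as evidence that neither gene's 3'UTR reads through the gap.
Candidates falling inside a masked zone around a centromere are removed.
Survivors receive NL identifiers in (chromosome, start) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from landingpad.genome_io import (
    CentromereMap,
    GeneFeature,
    GenomeSequence,
    StrandedCoverage,
)

CONVERGENT = "convergent"
DIVERGENT = "divergent"
TANDEM_PLUS = "tandem_plus"
TANDEM_MINUS = "tandem_minus"

_ORIENTATION = {
    ("+", "-"): CONVERGENT,
    ("-", "+"): DIVERGENT,
    ("+", "+"): TANDEM_PLUS,
    ("-", "-"): TANDEM_MINUS,
}


@dataclass(frozen=True)
class ScanParams:
    """Thresholds of the stepwise filter.

    min_neutral_len
        Minimum length (bp) of a zero-coverage run; the default 11
        encodes the strict '>10 bp' criterion.
    min_gene_mean_coverage
        A flanking gene counts as transcribed when its mean own-strand
        per-base count exceeds this (strict inequality); 0 means 'any
        mapped read'.
    centromere_halfwidth
        Mask half-width (bp) added on both sides of each centromere.
    zero_threshold
        Per-base combined count at or below which a base counts as
        read-free (0 = literally no mapped reads).
    combine_strands
        Zero runs use plus+minus coverage by default; False restricts
        the run test to each strand independently (a base is read-free
        only if both strands are).
    require_convergent / require_transcription
        Individual filter toggles, mainly for specificity audits.
    """

    min_neutral_len: int = 11
    min_gene_mean_coverage: float = 0.0
    centromere_halfwidth: int = 50_000
    zero_threshold: int = 0
    combine_strands: bool = True
    require_convergent: bool = True
    require_transcription: bool = True

    def __post_init__(self) -> None:
        if self.min_neutral_len < 1:
            raise ValueError("min_neutral_len must be >= 1")
        if self.centromere_halfwidth < 0:
            raise ValueError("centromere_halfwidth must be >= 0")
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be >= 0")


@dataclass(frozen=True)
class IntergenicRegion:
    """Gap between two adjacent non-overlapping genes on one chromosome."""

    chrom: str
    start: int
    end: int
    left_gene: GeneFeature
    right_gene: GeneFeature
    orientation: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NeutralRegion:
    """Maximal read-free run inside an intergenic gap."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateLocus:
    """A validated neutral site, named NL### in coordinate order."""

    nl_id: str
    intergenic: IntergenicRegion
    neutral: NeutralRegion
    non_neutral: bool = False

    @property
    def chrom(self) -> str:
        return self.neutral.chrom

    @property
    def center(self) -> int:
        """Midpoint of the neutral region (floored for even lengths)."""
        return (self.neutral.start + self.neutral.end) // 2


@dataclass(frozen=True)
class Rejection:
    """Audit record: why an intergenic region fell out of the pipeline."""

    chrom: str
    start: int
    end: int
    stage: str
    reason: str


def find_intergenic_regions(genes: Sequence[GeneFeature]) -> list[IntergenicRegion]:
    """Enumerate gaps between adjacent genes, classified by strand pair.

    Genes are grouped per chromosome and sorted by start; each adjacent
    pair with a positive gap yields one region. Pairs of overlapping or
    abutting genes yield none.
    """
    regions: list[IntergenicRegion] = []
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        for left, right in zip(ordered, ordered[1:]):
            if right.start <= left.end:
                continue  # overlap or no gap
            regions.append(
                IntergenicRegion(
                    chrom=chrom,
                    start=left.end,
                    end=right.start,
                    left_gene=left,
                    right_gene=right,
                    orientation=_ORIENTATION[(left.strand, right.strand)],
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def gene_is_transcribed(gene: GeneFeature, coverage: StrandedCoverage,
                        params: ScanParams | None = None) -> tuple[bool, float]:
    """Mean own-strand coverage over the gene span, tested against threshold."""
    params = params or ScanParams()
    if gene.end > len(coverage.plus):
        raise ValueError(
            f"gene {gene.gene_id} extends beyond coverage of {coverage.chrom}"
        )
    track = coverage.plus if gene.strand == "+" else coverage.minus
    mean = float(track[gene.start:gene.end].mean())
    return mean > params.min_gene_mean_coverage, mean


def find_zero_runs(coverage: StrandedCoverage, interval: tuple[int, int],
                   params: ScanParams | None = None) -> list[NeutralRegion]:
    """Maximal read-free runs within ``interval``, length-filtered.

    A base is read-free when its combined (or per-strand, see
    ``ScanParams.combine_strands``) count is <= ``zero_threshold``.
    Runs shorter than ``min_neutral_len`` are dropped; runs are returned
    left to right.
    """
    params = params or ScanParams()
    start, end = interval
    if start < 0 or end > len(coverage.plus):
        raise ValueError(f"interval [{start},{end}) outside coverage bounds")
    if end <= start:
        return []
    if params.combine_strands:
        free = (coverage.plus[start:end] + coverage.minus[start:end]) \
            <= params.zero_threshold
    else:
        free = (coverage.plus[start:end] <= params.zero_threshold) \
            & (coverage.minus[start:end] <= params.zero_threshold)
    runs: list[NeutralRegion] = []
    padded = np.concatenate(([False], free, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= params.min_neutral_len:
            runs.append(NeutralRegion(chrom=coverage.chrom,
                                      start=start + int(s), end=start + int(e)))
    return runs


def apply_centromere_mask(regions: Sequence[NeutralRegion],
                          centromeres: CentromereMap,
                          params: ScanParams | None = None,
                          rejections: list[Rejection] | None = None,
                          ) -> list[NeutralRegion]:
    """Drop neutral regions intersecting a centromere +/- halfwidth zone."""
    params = params or ScanParams()
    kept: list[NeutralRegion] = []
    for region in regions:
        cen = centromeres.for_chrom(region.chrom)
        if cen is not None:
            lo = cen[0] - params.centromere_halfwidth
            hi = cen[1] + params.centromere_halfwidth
            if region.start < hi and region.end > lo:
                if rejections is not None:
                    rejections.append(Rejection(
                        region.chrom, region.start, region.end,
                        "centromere_mask",
                        f"intersects masked zone [{lo},{hi})",
                    ))
                continue
        kept.append(region)
    return kept


def _pick_run(runs: list[NeutralRegion], region: IntergenicRegion
              ) -> NeutralRegion:
    """Single representative run: longest; tie -> midpoint closest to the
    intergenic midpoint; still tied -> leftmost."""
    mid = (region.start + region.end) / 2

    def key(r: NeutralRegion) -> tuple:
        return (-r.length, abs((r.start + r.end) / 2 - mid), r.start)

    return min(runs, key=key)


def scan_neutral_loci(
    genome: GenomeSequence,
    genes: Sequence[GeneFeature],
    coverage: dict[str, StrandedCoverage],
    centromeres: CentromereMap | None = None,
    params: ScanParams | None = None,
    allowlist: Sequence[tuple[str, int, int]] | None = None,
    rejections: list[Rejection] | None = None,
) -> list[CandidateLocus]:
    """Run the full stepwise filter and assign NL identifiers.

    Pipeline order: intergenic gaps -> convergent orientation -> both
    flanking genes transcribed -> longest qualifying zero run per gap ->
    centromere mask -> NL ids in (chromosome order, start) order.

    ``allowlist`` intervals (chrom, start, end) are injected after the
    filter as extra loci flagged ``non_neutral=True`` — the mechanism for
    carrying a benchmark site that fails the criteria. ``rejections``
    collects one audit record per filtered-out gap.
    """
    params = params or ScanParams()
    centromeres = centromeres or CentromereMap([])
    for chrom in {g.chrom for g in genes}:
        if chrom not in coverage:
            raise ValueError(f"no coverage for annotated chromosome {chrom}")

    chrom_rank = {c: i for i, c in enumerate(genome.chrom_names)}
    survivors: list[tuple[IntergenicRegion, NeutralRegion]] = []
    for region in find_intergenic_regions(genes):
        cov = coverage[region.chrom]
        if params.require_convergent and region.orientation != CONVERGENT:
            _log(rejections, region, "orientation",
                 f"gene pair is {region.orientation}, not convergent")
            continue
        if params.require_transcription:
            silent = [
                g.gene_id for g in (region.left_gene, region.right_gene)
                if not gene_is_transcribed(g, cov, params)[0]
            ]
            if silent:
                _log(rejections, region, "transcription",
                     f"no RNA-seq evidence for {','.join(silent)}")
                continue
        runs = find_zero_runs(cov, (region.start, region.end), params)
        if not runs:
            _log(rejections, region, "neutral_region",
                 f"no read-free run of >= {params.min_neutral_len} bp")
            continue
        best = _pick_run(runs, region)
        masked = apply_centromere_mask([best], centromeres, params)
        if not masked:
            _log(rejections, region, "centromere_mask",
                 "neutral region inside masked centromere zone")
            continue
        survivors.append((region, best))

    survivors.sort(key=lambda pair: (chrom_rank.get(pair[1].chrom, len(chrom_rank)),
                                     pair[1].start))

    extra: list[tuple[IntergenicRegion, NeutralRegion]] = []
    if allowlist:
        for chrom, start, end in allowlist:
            neutral = NeutralRegion(chrom=chrom, start=start, end=end)
            dummy_gene_l = GeneFeature("allowlist_left", chrom,
                                       max(0, start - 1), max(1, start), "+")
            dummy_gene_r = GeneFeature("allowlist_right", chrom, end, end + 1, "-")
            region = IntergenicRegion(chrom, start, end, dummy_gene_l,
                                      dummy_gene_r, CONVERGENT)
            extra.append((region, neutral))
        extra.sort(key=lambda pair: (chrom_rank.get(pair[1].chrom, len(chrom_rank)),
                                     pair[1].start))

    loci: list[CandidateLocus] = []
    merged = [(r, n, False) for r, n in survivors] + \
             [(r, n, True) for r, n in extra]
    merged.sort(key=lambda t: (chrom_rank.get(t[1].chrom, len(chrom_rank)),
                               t[1].start))
    for i, (region, neutral, is_allow) in enumerate(merged, 1):
        loci.append(CandidateLocus(
            nl_id=f"NL{i:03d}", intergenic=region, neutral=neutral,
            non_neutral=is_allow,
        ))
    return loci


def _log(rejections: list[Rejection] | None, region: IntergenicRegion,
         stage: str, reason: str) -> None:
    if rejections is not None:
        rejections.append(
            Rejection(region.chrom, region.start, region.end, stage, reason)
        )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def locus_report(loci: Sequence[CandidateLocus],
                 genes: Sequence[GeneFeature],
                 genome: GenomeSequence,
                 bin_width: int = 10_000,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate loci and per-chromosome gene density.

    Returns ``(locus_table, density_table)``. The locus table has one row
    per candidate with its intervals, flanking gene ids/strands and the
    distance from the neutral region to each flanking gene's 3' end. The
    density table counts annotated gene bp per fixed-width bin on every
    chromosome (including those without loci), for plotting.
    """
    rows = []
    for locus in loci:
        ig = locus.intergenic
        rows.append({
            "nl_id": locus.nl_id,
            "chrom": locus.chrom,
            "intergenic_start": ig.start,
            "intergenic_end": ig.end,
            "neutral_start": locus.neutral.start,
            "neutral_end": locus.neutral.end,
            "neutral_len": locus.neutral.length,
            "left_gene": ig.left_gene.gene_id,
            "left_strand": ig.left_gene.strand,
            "right_gene": ig.right_gene.gene_id,
            "right_strand": ig.right_gene.strand,
            "dist_left_3prime": locus.neutral.start - ig.left_gene.three_prime,
            "dist_right_3prime": ig.right_gene.three_prime - locus.neutral.end,
            "non_neutral": locus.non_neutral,
        })
    locus_table = pd.DataFrame(
        rows, columns=[
            "nl_id", "chrom", "intergenic_start", "intergenic_end",
            "neutral_start", "neutral_end", "neutral_len",
            "left_gene", "left_strand", "right_gene", "right_strand",
            "dist_left_3prime", "dist_right_3prime", "non_neutral",
        ]
    )

    density_rows = []
    for chrom in genome.chrom_names:
        clen = genome.length(chrom)
        nbins = max(1, -(-clen // bin_width))
        bins = np.zeros(nbins, dtype=np.int64)
        for g in genes:
            if g.chrom != chrom:
                continue
            start, end = g.start, min(g.end, clen)
            b0, b1 = start // bin_width, (end - 1) // bin_width
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_width)
                hi = min(end, (b + 1) * bin_width)
                bins[b] += hi - lo
        for b, bp in enumerate(bins):
            density_rows.append({
                "chrom": chrom,
                "bin_start": b * bin_width,
                "bin_end": min((b + 1) * bin_width, clen),
                "gene_bp": int(bp),
            })
    density_table = pd.DataFrame(
        density_rows, columns=["chrom", "bin_start", "bin_end", "gene_bp"]
    )
    return locus_table, density_table
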