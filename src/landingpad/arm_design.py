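"""Homology-arm and construct design for a candidate neutral locus.

From a validated locus the designer exports a 3000 bp window, cuts the
central 1100 bp into two 550 bp homology arms, domesticates them against
BbsI (GAAGAC) and ZraI (GACGTC) with deterministic single-base edits,
plans blunt-end ZraI linearization using partial sites already present at
the arm boundaries, assembles the payload cassette between the arms, and
extracts genotyping anchor sequences around the integration junctions.
Protein payloads are back-translated with the most frequent codon per
residue from a supplied codon-usage table; restriction sites inside a CDS
are removed by synonymous codon swaps only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


class DesignError(ValueError):
    """Raised when a design step cannot satisfy its contract."""


# ---------------------------------------------------------------------------
# Enzymes and site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme recognition motif."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        if set(self.recognition) - set(_BASES):
            raise ValueError(f"{self.name}: motif must be over ACGT")

    @property
    def palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


BBSI = EnzymeSpec("BbsI", "GAAGAC")
ZRAI = EnzymeSpec("ZraI", "GACGTC")
DEFAULT_ENZYMES: tuple[EnzymeSpec, ...] = (BBSI, ZRAI)


@dataclass(frozen=True)
class SiteHit:
    enzyme: str
    strand: str
    start: int
    end: int


def _find_all(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def find_sites(sequence: str, enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES
               ) -> list[SiteHit]:
    """All recognition-site occurrences on either strand, left to right.

    Palindromic motifs are reported once per position on strand '+';
    non-palindromic motifs are additionally searched as their reverse
    complement (reported on strand '-'). N never matches.
    """
    hits: list[SiteHit] = []
    for enz in enzymes:
        L = len(enz.recognition)
        for pos in _find_all(sequence, enz.recognition):
            hits.append(SiteHit(enz.name, "+", pos, pos + L))
        if not enz.palindromic:
            for pos in _find_all(sequence, revcomp(enz.recognition)):
                hits.append(SiteHit(enz.name, "-", pos, pos + L))
    hits.sort(key=lambda h: (h.start, h.enzyme, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Domestication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteEdit:
    """One single-base substitution that destroyed a recognition site."""

    window_offset: int
    original_base: str
    new_base: str
    enzyme: str
    site_span: tuple[int, int]


def _hit_key(h: SiteHit) -> tuple[str, str, int]:
    return (h.enzyme, h.strand, h.start)


def domesticate(sequence: str,
                enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES,
                ) -> tuple[str, list[SiteEdit]]:
    """Remove every recognition site with deterministic single-base edits.

    Sites are processed left to right and rescanned after each edit. For
    each site the candidate positions are scanned left to right within
    the site span and candidate bases in the order A<C<G<T; the first
    substitution that (a) destroys the site, (b) creates no new site of
    any configured enzyme on either strand, and (c) does not revert a
    previous edit, is applied. Output length equals input length.
    """
    if set(sequence) - set(_BASES):
        raise DesignError("domestication requires unambiguous ACGT sequence")
    seq = sequence
    edits: list[SiteEdit] = []
    edited_positions: set[int] = set()
    guard = 0
    while True:
        hits = find_sites(seq, enzymes)
        if not hits:
            break
        guard += 1
        if guard > len(sequence) + 10:
            raise DesignError("domestication failed to converge")
        target = hits[0]
        before = {_hit_key(h) for h in hits}
        fixed = False
        for pos in range(target.start, target.end):
            if pos in edited_positions:
                continue
            for base in _BASES:
                if base == seq[pos]:
                    continue
                candidate = seq[:pos] + base + seq[pos + 1:]
                after = {_hit_key(h) for h in find_sites(candidate, enzymes)}
                if _hit_key(target) in after:
                    continue  # site survives
                if not after <= before:
                    continue  # created a new site somewhere
                edits.append(SiteEdit(
                    window_offset=pos,
                    original_base=seq[pos],
                    new_base=base,
                    enzyme=target.enzyme,
                    site_span=(target.start, target.end),
                ))
                edited_positions.add(pos)
                seq = candidate
                fixed = True
                break
            if fixed:
                break
        if not fixed:
            raise DesignError(
                f"no admissible single-base fix for {target.enzyme} site at "
                f"{target.start} (strand {target.strand})"
            )
    return seq, edits


# ---------------------------------------------------------------------------
# Design window and homology arms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignWindow:
    """Genomic window (default 3000 bp) centered on a locus."""

    chrom: str
    start: int
    end: int
    center: int
    sequence: str
    truncated: bool = False


def design_window(genome, chrom: str, center: int,
                  window_len: int = 3000) -> DesignWindow:
    """Export the design window around a locus center, clipping at
    chromosome ends (flagged ``truncated``)."""
    clen = genome.length(chrom)
    start = center - window_len // 2
    end = start + window_len
    truncated = start < 0 or end > clen
    start_c, end_c = max(0, start), min(clen, end)
    return DesignWindow(
        chrom=chrom, start=start_c, end=end_c, center=center,
        sequence=genome[chrom][start_c:end_c], truncated=truncated,
    )


@dataclass(frozen=True)
class HomologyArmPair:
    """Two domesticated homology arms flanking the integration point."""

    chrom: str
    center: int
    arm_len: int
    left_arm: str
    right_arm: str
    edits: tuple[SiteEdit, ...]

    @property
    def left_start(self) -> int:
        return self.center - self.arm_len

    @property
    def right_end(self) -> int:
        return self.center + self.arm_len

    def edits_in_left(self) -> list[SiteEdit]:
        return [e for e in self.edits if e.window_offset < self.arm_len]

    def edits_in_right(self) -> list[SiteEdit]:
        return [e for e in self.edits if e.window_offset >= self.arm_len]


def cut_arms(window: DesignWindow, center: int | None = None,
             arm_len: int = 550,
             enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES,
             ) -> HomologyArmPair:
    """Cut the 2 x ``arm_len`` bp around the locus center into arms and
    domesticate them jointly (so the arm junction context is also clean).
    """
    center = window.center if center is None else center
    if window.start > center - arm_len or window.end < center + arm_len:
        raise DesignError(
            f"window [{window.start},{window.end}) does not cover "
            f"[{center - arm_len},{center + arm_len}) — locus unusable at "
            f"arm length {arm_len}"
        )
    lo = center - arm_len - window.start
    source = window.sequence[lo:lo + 2 * arm_len]
    domesticated, edits = domesticate(source, enzymes)
    return HomologyArmPair(
        chrom=window.chrom, center=center, arm_len=arm_len,
        left_arm=domesticated[:arm_len], right_arm=domesticated[arm_len:],
        edits=tuple(edits),
    )


# ---------------------------------------------------------------------------
# Linearization (partial ZraI completion)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearizationEnd:
    """Plan for one outer arm boundary.

    ``added`` bases complete (or, in fallback mode, constitute) the ZraI
    site outside the arm; ``trim`` bases are removed from the arm's outer
    end so the partial site sits flush at the boundary. After blunt
    digestion the integrated homology region differs from the genomic arm
    by ``arm_delta`` bp (<= 0; bases consumed by the upstream half-site)
    and carries ``extra_bp`` non-genomic bases (3 in fallback mode).
    """

    side: str                # "left" | "right"
    mode: str                # "completion" | "fallback"
    enzyme: str
    added: str
    trim: int
    arm_delta: int
    extra_bp: int


@dataclass(frozen=True)
class LinearizationPlan:
    left: LinearizationEnd
    right: LinearizationEnd
    enzyme: EnzymeSpec = ZRAI


def _plan_end(arm: str, side: str, enzyme: EnzymeSpec,
              partial_site_min: int, search_window: int,
              boundary_delta_max: int) -> LinearizationEnd:
    motif = enzyme.recognition
    L = len(motif)
    best: tuple[int, int, int] | None = None  # (delta, off, k)
    for off in range(0, search_window):
        for k in range(L - 1, partial_site_min - 1, -1):
            if off + k > search_window:
                continue
            delta = off + k - (L // 2)
            if delta > boundary_delta_max or delta < 0:
                continue
            if side == "left":
                match = arm[off:off + k] == motif[L - k:]
            else:
                n = len(arm)
                match = arm[n - off - k:n - off] == motif[:k]
            if match:
                cand = (delta, off, k)
                if best is None or cand < best:
                    best = cand
    if best is not None:
        delta, off, k = best
        added = motif[:L - k] if side == "left" else motif[k:]
        return LinearizationEnd(side=side, mode="completion", enzyme=enzyme.name,
                                added=added, trim=off, arm_delta=-delta,
                                extra_bp=0)
    return LinearizationEnd(side=side, mode="fallback", enzyme=enzyme.name,
                            added=motif, trim=0, arm_delta=0, extra_bp=L // 2)


def plan_linearization(arms: HomologyArmPair,
                       enzyme: EnzymeSpec = ZRAI,
                       partial_site_min: int = 3,
                       search_window: int = 12,
                       boundary_delta_max: int = 3) -> LinearizationPlan:
    """Plan blunt-end linearization flush with the arm boundaries.

    Each outer arm end is searched (outermost ``search_window`` bp) for a
    partial ZraI site — a motif suffix at the left arm's upstream end or
    prefix at the right arm's downstream end, length >= ``partial_site_min``.
    The partial is completed into a full site by adding the missing bases
    outside the arm, trimming at most ``boundary_delta_max`` boundary
    bases; the homology region then shortens by up to that much after
    digestion (recorded per end). Without a usable partial, a full site
    is placed just outside the arm (homology region unchanged, three
    non-genomic bases retained on the fragment). The fallback always
    succeeds, so every construct can be linearized.
    """
    return LinearizationPlan(
        left=_plan_end(arms.left_arm, "left", enzyme, partial_site_min,
                       search_window, boundary_delta_max),
        right=_plan_end(arms.right_arm, "right", enzyme, partial_site_min,
                        search_window, boundary_delta_max),
        enzyme=enzyme,
    )


# ---------------------------------------------------------------------------
# Codon usage and back-translation
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Codon -> (amino acid, usage frequency) for one organism.

    All 64 codons of the standard nuclear code must be present, with the
    amino-acid column agreeing with the standard genetic code. Stops are
    recorded under '*'.
    """

    frequencies: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        if set(self.frequencies) != _ALL_CODONS:
            missing = _ALL_CODONS - set(self.frequencies)
            extra = set(self.frequencies) - _ALL_CODONS
            raise ValueError(
                f"codon table must list all 64 codons "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for codon, (aa, freq) in self.frequencies.items():
            expected = _CODON_TO_AA[codon]
            if aa != expected:
                raise ValueError(
                    f"{codon} assigned to {aa}, standard code says {expected}"
                )
            if freq < 0:
                raise ValueError(f"{codon}: negative frequency")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        """Read a 3-column TSV: codon, amino acid (1-letter, '*' = stop),
        frequency (per-thousand or fraction — only relative order matters).
        """
        freqs: dict[str, tuple[str, float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, aa, freq = line.split("\t")
                codon = codon.upper().replace("U", "T")
                if codon in freqs:
                    raise ValueError(f"duplicate codon {codon}")
                freqs[codon] = (aa, float(freq))
        return cls(freqs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# codon\tamino_acid\tfrequency\n")
            for codon in sorted(self.frequencies):
                aa, freq = self.frequencies[codon]
                fh.write(f"{codon}\t{aa}\t{freq:g}\n")

    def codons_for(self, aa: str) -> list[str]:
        """Codons for one residue, ordered by descending frequency then
        alphabetically (the deterministic preference order)."""
        cands = [c for c, (a, _) in self.frequencies.items() if a == aa]
        if not cands:
            raise KeyError(f"no codons for residue {aa!r}")
        return sorted(cands, key=lambda c: (-self.frequencies[c][1], c))

    def best_codon(self, aa: str) -> str:
        return self.codons_for(aa)[0]


_CODON_TO_AA: dict[str, str] = {}
for _c1 in _BASES:
    for _c2 in _BASES:
        for _c3 in _BASES:
            _codon = _c1 + _c2 + _c3
            _CODON_TO_AA[_codon] = (
                "*" if _codon in _STANDARD.stop_codons
                else _STANDARD.forward_table[_codon]
            )
_ALL_CODONS = set(_CODON_TO_AA)


def back_translate(protein: str, codon_table: CodonUsageTable,
                   include_stop: bool = False) -> str:
    """Encode each residue with its most frequent codon (tie ->
    alphabetically first). A single trailing '*' is honoured; other
    unknown residues are errors. Translating the output reproduces the
    input protein.
    """
    protein = protein.strip()
    residues = list(protein)
    if residues and residues[-1] == "*":
        residues.pop()
        include_stop = True
    cds = []
    for i, aa in enumerate(residues):
        if aa == "*" or aa not in _AA_LETTERS:
            raise DesignError(f"unknown residue {aa!r} at position {i}")
        cds.append(codon_table.best_codon(aa))
    if include_stop:
        cds.append(codon_table.best_codon("*"))
    return "".join(cds)


_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def synonymous_domesticate(cds: str, codon_table: CodonUsageTable,
                           enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES,
                           ) -> tuple[str, list[SiteEdit]]:
    """Remove recognition sites from a CDS by synonymous codon swaps only.

    For each site (left to right, rescanned after each fix) the codons
    overlapping the site are tried left to right; replacement codons for
    the same residue are tried in descending usage frequency. The first
    swap that destroys the site without creating a new one is applied.
    Translation is preserved by construction.
    """
    if len(cds) % 3 != 0:
        raise DesignError("CDS length must be a multiple of 3")
    seq = cds
    edits: list[SiteEdit] = []
    guard = 0
    while True:
        hits = find_sites(seq, enzymes)
        if not hits:
            break
        guard += 1
        if guard > len(cds):
            raise DesignError("CDS domestication failed to converge")
        target = hits[0]
        before = {_hit_key(h) for h in hits}
        first_codon = target.start // 3
        last_codon = (target.end - 1) // 3
        fixed = False
        for ci in range(first_codon, last_codon + 1):
            current = seq[ci * 3:ci * 3 + 3]
            aa = _CODON_TO_AA[current]
            for alt in codon_table.codons_for(aa):
                if alt == current:
                    continue
                candidate = seq[:ci * 3] + alt + seq[ci * 3 + 3:]
                after = {_hit_key(h) for h in find_sites(candidate, enzymes)}
                if _hit_key(target) in after or not after <= before:
                    continue
                for off in range(3):
                    if current[off] != alt[off]:
                        edits.append(SiteEdit(
                            window_offset=ci * 3 + off,
                            original_base=current[off],
                            new_base=alt[off],
                            enzyme=target.enzyme,
                            site_span=(target.start, target.end),
                        ))
                seq = candidate
                fixed = True
                break
            if fixed:
                break
        if not fixed:
            raise DesignError(
                f"{target.enzyme} site at {target.start} cannot be removed "
                "synonymously"
            )
    return seq, edits


# ---------------------------------------------------------------------------
# Construct assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassettePart:
    """One payload part: promoter, CDS, terminator, marker, ..."""

    name: str
    role: str       # "promoter" | "cds" | "terminator" | "marker" | "misc"
    sequence: str


_ROLE_TO_GB = {
    "promoter": "promoter",
    "cds": "CDS",
    "terminator": "terminator",
    "marker": "misc_feature",
}


@dataclass
class ConstructDesign:
    """A fully assembled integration construct."""

    name: str
    description: str
    arms: HomologyArmPair
    parts: list[CassettePart]
    linearization: LinearizationPlan | None
    cassette_edits: list[SiteEdit] = field(default_factory=list)

    @property
    def cassette_sequence(self) -> str:
        return "".join(p.sequence for p in self.parts)

    def _layout(self) -> list[tuple[str, str, str]]:
        """(label, sequence, genbank feature kind) tiles, in order."""
        tiles: list[tuple[str, str, str]] = []
        left, right = self.arms.left_arm, self.arms.right_arm
        if self.linearization is not None:
            lin = self.linearization
            left = left[lin.left.trim:]
            right = right[:len(right) - lin.right.trim]
            if lin.left.added:
                tiles.append((f"{lin.left.enzyme}_half_site", lin.left.added,
                              "misc_feature"))
        tiles.append(("left_homology_arm", left, "misc_feature"))
        for p in self.parts:
            tiles.append((p.name, p.sequence, _ROLE_TO_GB.get(p.role,
                                                              "misc_feature")))
        tiles.append(("right_homology_arm", right, "misc_feature"))
        if self.linearization is not None and self.linearization.right.added:
            lin = self.linearization
            tiles.append((f"{lin.right.enzyme}_half_site", lin.right.added,
                          "misc_feature"))
        return tiles

    @property
    def full_sequence(self) -> str:
        return "".join(seq for _, seq, _ in self._layout())

    def feature_table(self) -> list[tuple[str, int, int, str]]:
        out, pos = [], 0
        for label, seq, kind in self._layout():
            out.append((label, pos, pos + len(seq), kind))
            pos += len(seq)
        return out


def assemble_construct(arms: HomologyArmPair,
                       cassettes: Sequence[CassettePart],
                       linearization: LinearizationPlan | None = None,
                       codon_table: CodonUsageTable | None = None,
                       enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES,
                       name: str = "construct",
                       description: str = "") -> ConstructDesign:
    """Concatenate left arm, payload parts and right arm into a construct.

    Parts still carrying recognition sites are domesticated first: CDS
    parts synonymously (a codon table is then required), all other parts
    with the single-base rule. The final full sequence contains no
    configured site on either strand outside the planned linearization
    half-sites.
    """
    clean_parts: list[CassettePart] = []
    cassette_edits: list[SiteEdit] = []
    for part in cassettes:
        if find_sites(part.sequence, enzymes):
            if part.role == "cds":
                if codon_table is None:
                    raise DesignError(
                        f"part {part.name}: CDS carries a recognition site "
                        "but no codon table was supplied"
                    )
                fixed, edits = synonymous_domesticate(part.sequence,
                                                      codon_table, enzymes)
            else:
                fixed, edits = domesticate(part.sequence, enzymes)
            clean_parts.append(CassettePart(part.name, part.role, fixed))
            cassette_edits.extend(edits)
        else:
            clean_parts.append(part)
    construct = ConstructDesign(
        name=name, description=description, arms=arms,
        parts=clean_parts, linearization=linearization,
        cassette_edits=cassette_edits,
    )
    _check_site_free(construct, enzymes)
    return construct


def _check_site_free(construct: ConstructDesign,
                     enzymes: Sequence[EnzymeSpec]) -> None:
    full = construct.full_sequence
    allowed: set[tuple[str, int]] = set()
    if construct.linearization is not None:
        lin_enz = construct.linearization.enzyme
        L = len(lin_enz.recognition)
        allowed = {(lin_enz.name, 0), (lin_enz.name, len(full) - L)}
    for hit in find_sites(full, enzymes):
        if (hit.enzyme, hit.start) not in allowed:
            raise DesignError(
                f"assembled construct retains a {hit.enzyme} site at "
                f"{hit.start} (strand {hit.strand})"
            )


def digest_linearized(construct: ConstructDesign) -> str:
    """In-silico blunt ZraI digestion of the assembled construct.

    Cuts at the center of each terminal site planned by the
    linearization and returns the central fragment.
    """
    if construct.linearization is None:
        raise DesignError("construct has no linearization plan")
    enzyme = construct.linearization.enzyme
    full = construct.full_sequence
    L = len(enzyme.recognition)
    cuts = [h.start + L // 2 for h in find_sites(full, (enzyme,))]
    if len(cuts) != 2:
        raise DesignError(
            f"expected exactly 2 {enzyme.name} sites in the construct, "
            f"found {len(cuts)}"
        )
    return full[cuts[0]:cuts[1]]


# ---------------------------------------------------------------------------
# Genotyping anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypingAnchors:
    """Four anchor sequences around the two integration junctions.

    All anchors read 5'->3' toward the junction they flank. Outer anchors
    are genomic, ending ``offset`` bp outside the corresponding arm;
    inner anchors are the first/last ``anchor_len`` bp of the cassette.
    ``junction_span`` is the predicted genotyping amplicon span measured
    from the outer anchor's junction-proximal end to the inner anchor's
    far edge: offset + arm_len + anchor_len.
    """

    outer_left: str
    inner_left: str
    inner_right: str
    outer_right: str
    offset: int
    anchor_len: int
    arm_len: int

    @property
    def junction_span(self) -> int:
        return self.offset + self.arm_len + self.anchor_len


def genotyping_anchors(genome, chrom: str, center: int, cassette: str,
                       arm_len: int = 550, offset: int = 100,
                       anchor_len: int = 25) -> GenotypingAnchors:
    """Extract the four genotyping anchors for a locus and cassette.

    The outer-left anchor occupies genome[arm_start - offset - anchor_len,
    arm_start - offset) on the plus strand; the outer-right anchor is the
    mirror interval beyond the right arm, reverse-complemented. Inner
    anchors come from the cassette's first and last ``anchor_len`` bp,
    oriented toward the nearest junction.
    """
    seq = genome[chrom]
    arm_start = center - arm_len
    arm_end = center + arm_len
    ol_start = arm_start - offset - anchor_len
    or_end = arm_end + offset + anchor_len
    if ol_start < 0 or or_end > len(seq):
        raise DesignError(
            f"anchor would run off chromosome {chrom} "
            f"([{ol_start},{or_end}) vs length {len(seq)})"
        )
    if len(cassette) < anchor_len:
        raise DesignError("cassette shorter than anchor length")
    return GenotypingAnchors(
        outer_left=seq[ol_start:ol_start + anchor_len],
        inner_left=revcomp(cassette[:anchor_len]),
        inner_right=cassette[-anchor_len:],
        outer_right=revcomp(seq[or_end - anchor_len:or_end]),
        offset=offset, anchor_len=anchor_len, arm_len=arm_len,
    )
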