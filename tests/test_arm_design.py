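"""Construct design: site scanning, domestication, arms, linearization,
assembly, genotyping anchors and back-translation."""

import numpy as np
import pytest

from landingpad.arm_design import (
    BBSI,
    DEFAULT_ENZYMES,
    ZRAI,
    CassettePart,
    DesignError,
    assemble_construct,
    back_translate,
    cut_arms,
    design_window,
    digest_linearized,
    domesticate,
    find_sites,
    genotyping_anchors,
    plan_linearization,
    revcomp,
    synonymous_domesticate,
    translate,
)
from landingpad.genome_io import GenomeSequence
from landingpad.synth_fixtures import synthetic_codon_table

MOTIFS = ("GAAGAC", "GTCTTC", "GACGTC")


def naive_site_scan(seq):
    """Sliding-window oracle for recognition-site occurrences."""
    hits = []
    for i in range(len(seq)):
        if seq[i:i + 6] == "GAAGAC":
            hits.append(("BbsI", "+", i))
        if seq[i:i + 6] == "GTCTTC":
            hits.append(("BbsI", "-", i))
        if seq[i:i + 6] == "GACGTC":
            hits.append(("ZraI", "+", i))
    return sorted(hits)


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _seed_sites(rng, seq, k):
    """Overwrite k random non-overlapping-ish positions with motifs."""
    seq = list(seq)
    for _ in range(k):
        motif = MOTIFS[int(rng.integers(0, 3))]
        pos = int(rng.integers(0, len(seq) - 6))
        seq[pos:pos + 6] = motif
    return "".join(seq)


class TestFindSites:
    def test_palindrome_reported_once(self):
        assert [(h.enzyme, h.strand, h.start)
                for h in find_sites("AAGACGTCAA")] == [("ZraI", "+", 2)]

    def test_both_strands_for_nonpalindromic(self):
        seq = "GAAGAC" + "AAAT" + "GTCTTC"
        hits = [(h.enzyme, h.strand, h.start) for h in find_sites(seq)]
        assert hits == [("BbsI", "+", 0), ("BbsI", "-", 10)]

    def test_n_never_matches(self):
        assert find_sites("GAAGNCGACGTNGTCTTN") == []

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            seq = _seed_sites(rng, _rand_dna(rng, 200),
                              int(rng.integers(0, 4)))
            got = sorted((h.enzyme, h.strand, h.start)
                         for h in find_sites(seq))
            assert got == naive_site_scan(seq)


class TestDomesticate:
    def test_single_site_single_edit(self):
        seq = "TTGAAGACTT"
        out, edits = domesticate(seq)
        assert len(out) == len(seq)
        assert len(edits) == 1
        diff = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert diff == [edits[0].window_offset]
        assert 2 <= diff[0] < 8
        assert find_sites(out) == []
        # the deterministic pick must be admissible among all 18
        # single-base substitutions of the site
        admissible = []
        for pos in range(2, 8):
            for base in "ACGT":
                if base == seq[pos]:
                    continue
                cand = seq[:pos] + base + seq[pos + 1:]
                if not find_sites(cand):
                    admissible.append((pos, base))
        assert (edits[0].window_offset, edits[0].new_base) in admissible

    def test_site_free_sequence_is_fixed_point(self):
        seq = "ACGTACGTACGT"
        out, edits = domesticate(seq)
        assert out == seq and edits == []

    def test_property_suite_on_seeded_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n_sites = int(rng.integers(0, 6))
            seq = _seed_sites(rng, _rand_dna(rng, 1100), n_sites)
            initial = len(find_sites(seq))
            out, edits = domesticate(seq)
            assert find_sites(out) == []
            assert len(out) == len(seq)
            assert len(edits) <= initial
            hamming = sum(a != b for a, b in zip(seq, out))
            assert hamming == len(edits)

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            seq = _seed_sites(rng, _rand_dna(rng, 400),
                              int(rng.integers(1, 4)))
            once, _ = domesticate(seq)
            twice, edits = domesticate(once)
            assert twice == once and edits == []

    def test_ambiguous_sequence_rejected(self):
        with pytest.raises(DesignError):
            domesticate("ACGTN")

    def test_domestication_postconditions_hypothesis(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        dna = st.text(alphabet="ACGT", min_size=0, max_size=80)

        @settings(max_examples=300, derandomize=True, deadline=None)
        @given(dna, dna, st.sampled_from(MOTIFS))
        def check(prefix, suffix, motif):
            seq = prefix + motif + suffix
            out, edits = domesticate(seq)
            assert find_sites(out) == []
            assert len(out) == len(seq)
            assert sum(a != b for a, b in zip(seq, out)) == len(edits)

        check()


class TestWindowAndArms:
    def test_window_slices_genome(self, fixture):
        chrom = fixture.genome.chrom_names[0]
        w = design_window(fixture.genome, chrom, 5000)
        assert (w.start, w.end) == (3500, 6500)
        assert w.sequence == fixture.genome[chrom][3500:6500]
        assert not w.truncated

    def test_window_truncated_at_chromosome_end(self, fixture):
        chrom = fixture.genome.chrom_names[0]
        w = design_window(fixture.genome, chrom, 1000)
        assert w.truncated and w.start == 0

    def test_arm_index_arithmetic(self, fixture):
        chrom = fixture.genome.chrom_names[0]
        w = design_window(fixture.genome, chrom, 5000)
        arms = cut_arms(w, 5000)
        source = fixture.genome[chrom][4450:5550]
        if not arms.edits:
            assert arms.left_arm == source[:550]
            assert arms.right_arm == source[550:]
        # arm fidelity: Hamming distance equals edits per arm
        left_src, right_src = source[:550], source[550:]
        assert sum(a != b for a, b in zip(arms.left_arm, left_src)) == \
            len(arms.edits_in_left())
        assert sum(a != b for a, b in zip(arms.right_arm, right_src)) == \
            len(arms.edits_in_right())

    def test_arms_over_seeded_site_are_domesticated(self, fixture):
        """Fixture planting writes BbsI/ZraI motifs inside arm windows; the
        cut arms must carry edits exactly there and end up site-free."""
        planted = fixture.truth.planted[0]
        center = (planted.neutral_start + planted.neutral_end) // 2
        seeded = [s for s in fixture.truth.seeded_sites
                  if s[0] == planted.chrom
                  and center - 550 <= s[1] < center + 550]
        assert seeded, "fixture must seed a site in the first arm window"
        w = design_window(fixture.genome, planted.chrom, center)
        arms = cut_arms(w, center)
        assert find_sites(arms.left_arm + arms.right_arm) == []
        assert len(arms.edits) >= len(seeded)

    def test_truncated_window_is_unusable(self, fixture):
        chrom = fixture.genome.chrom_names[0]
        w = design_window(fixture.genome, chrom, 300)
        with pytest.raises(DesignError, match="unusable|cover"):
            cut_arms(w, 300)


class TestLinearization:
    def _arms(self, left, right):
        from landingpad.arm_design import HomologyArmPair

        return HomologyArmPair(chrom="c1", center=1000,
                               arm_len=len(left), left_arm=left,
                               right_arm=right, edits=())

    def test_completion_of_partial_suffix(self):
        arms = self._arms("GTC" + "A" * 547, "T" * 550)
        plan = plan_linearization(arms)
        assert plan.left.mode == "completion"
        assert plan.left.added == "GAC"
        assert plan.left.trim == 0 and plan.left.arm_delta == 0

    def test_fallback_prepends_full_site(self):
        arms = self._arms("TTTT" + "A" * 546, "T" * 550)
        plan = plan_linearization(arms)
        assert plan.left.mode == "fallback"
        assert plan.left.added == "GACGTC"
        assert plan.left.arm_delta == 0 and plan.left.extra_bp == 3

    def test_offset_partial_trims_boundary(self):
        # arm starts AA+GTC...: trim the 2 boundary bases, complete with GAC
        arms = self._arms("AAGTC" + "T" * 545, "T" * 550)
        plan = plan_linearization(arms)
        assert plan.left.mode == "completion"
        assert plan.left.trim == 2
        assert plan.left.arm_delta == -2

    def test_digestion_yields_blunt_fragment_at_arm_termini(
            self, fixture, cassette_parts, codon_table):
        from landingpad import scan_neutral_loci

        loci = scan_neutral_loci(fixture.genome, fixture.genes,
                                 fixture.coverage, fixture.centromeres)
        for locus in loci:
            w = design_window(fixture.genome, locus.chrom, locus.center)
            arms = cut_arms(w, locus.center)
            plan = plan_linearization(arms)
            construct = assemble_construct(arms, cassette_parts, plan,
                                           codon_table=codon_table)
            frag = digest_linearized(construct)
            # the fragment is the arm termini shifted by the recorded
            # per-end deltas, plus extra non-genomic half-site bases in
            # fallback mode, around the cassette
            if plan.left.mode == "completion":
                left_part = arms.left_arm[-plan.left.arm_delta:]
            else:
                left_part = "GTC" + arms.left_arm
            if plan.right.mode == "completion":
                n = len(arms.right_arm)
                right_part = arms.right_arm[:n + plan.right.arm_delta]
            else:
                right_part = arms.right_arm + "GAC"
            assert frag == left_part + construct.cassette_sequence + right_part


class TestAssembly:
    def test_length_conservation_and_features(self, fixture, codon_table):
        from landingpad import scan_neutral_loci

        locus = scan_neutral_loci(fixture.genome, fixture.genes,
                                  fixture.coverage, fixture.centromeres)[0]
        w = design_window(fixture.genome, locus.chrom, locus.center)
        arms = cut_arms(w, locus.center)
        parts = [CassettePart("cassette", "misc", "ATAT" * 500)]
        construct = assemble_construct(arms, parts, linearization=None,
                                       codon_table=codon_table)
        assert len(construct.full_sequence) == 550 + 2000 + 550
        assert construct.full_sequence == \
            arms.left_arm + parts[0].sequence + arms.right_arm
        # feature table tiles the sequence
        feats = construct.feature_table()
        assert feats[0][1] == 0 and feats[-1][2] == 3100

    def test_empty_cassette_is_arms_only(self, fixture, codon_table):
        from landingpad import scan_neutral_loci

        locus = scan_neutral_loci(fixture.genome, fixture.genes,
                                  fixture.coverage, fixture.centromeres)[0]
        w = design_window(fixture.genome, locus.chrom, locus.center)
        arms = cut_arms(w, locus.center)
        construct = assemble_construct(arms, [], None)
        assert construct.full_sequence == arms.left_arm + arms.right_arm

    def test_cds_site_removed_synonymously(self, codon_table, fixture):
        from landingpad import scan_neutral_loci

        locus = scan_neutral_loci(fixture.genome, fixture.genes,
                                  fixture.coverage, fixture.centromeres)[0]
        w = design_window(fixture.genome, locus.chrom, locus.center)
        arms = cut_arms(w, locus.center)
        # build a CDS that contains a BbsI site in frame
        cds = back_translate("MGKTEV" * 20, codon_table, include_stop=True)
        assert len(cds) % 3 == 0
        poisoned = cds[:30] + "GAAGAC" + cds[36:]
        construct = assemble_construct(
            arms, [CassettePart("cds", "cds", poisoned)], None,
            codon_table=codon_table)
        fixed = construct.parts[0].sequence
        assert find_sites(fixed) == []
        assert translate(fixed) == translate(poisoned)

    def test_final_sequence_site_free_on_both_strands(
            self, fixture, cassette_parts, codon_table):
        from landingpad import scan_neutral_loci

        locus = scan_neutral_loci(fixture.genome, fixture.genes,
                                  fixture.coverage, fixture.centromeres)[0]
        w = design_window(fixture.genome, locus.chrom, locus.center)
        arms = cut_arms(w, locus.center)
        plan = plan_linearization(arms)
        construct = assemble_construct(arms, cassette_parts, plan,
                                       codon_table=codon_table)
        hits = find_sites(construct.full_sequence)
        assert all(h.enzyme == "ZraI" for h in hits)
        assert len(hits) == 2  # only the two planned terminal sites


class TestGenotypingAnchors:
    def test_outer_left_coordinates(self):
        seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(12000))
        genome = GenomeSequence({"c1": seq})
        anchors = genotyping_anchors(genome, "c1", 10550, "A" * 2000,
                                     arm_len=550, offset=100, anchor_len=25)
        assert anchors.outer_left == seq[9875:9900]
        assert anchors.outer_right == revcomp(seq[11200:11225])
        assert anchors.junction_span == 675

    def test_anchor_off_chromosome_is_error(self, fixture):
        with pytest.raises(DesignError):
            genotyping_anchors(fixture.genome,
                               fixture.genome.chrom_names[0], 600,
                               "A" * 100)

    def test_anchors_unique_in_spliced_genome(self, fixture, cassette_parts,
                                              codon_table):
        from landingpad import scan_neutral_loci, splice_integration

        locus = scan_neutral_loci(fixture.genome, fixture.genes,
                                  fixture.coverage, fixture.centromeres)[0]
        w = design_window(fixture.genome, locus.chrom, locus.center)
        arms = cut_arms(w, locus.center)
        construct = assemble_construct(arms, cassette_parts, None,
                                       codon_table=codon_table)
        spliced = splice_integration(fixture.genome, construct)
        anchors = genotyping_anchors(fixture.genome, locus.chrom,
                                     locus.center,
                                     construct.cassette_sequence)
        hay = spliced[locus.chrom]
        for a in (anchors.outer_left, anchors.inner_left,
                  anchors.inner_right, anchors.outer_right):
            assert hay.count(a) + hay.count(revcomp(a)) == 1


class TestBackTranslate:
    def test_met_is_atg(self, codon_table):
        assert back_translate("M", codon_table) == "ATG"

    def test_round_trip_random_proteins(self, codon_table):
        rng = np.random.default_rng(3)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            protein = "".join(letters[i] for i in
                              rng.integers(0, 20, size=rng.integers(1, 80)))
            cds = back_translate(protein, codon_table)
            assert translate(cds) == protein

    def test_frequency_tie_breaks_alphabetically(self):
        from landingpad.arm_design import _CODON_TO_AA, CodonUsageTable

        freqs = {c: (aa, 1.0) for c, aa in _CODON_TO_AA.items()}
        freqs["CTG"] = ("L", 40.0)
        freqs["TTA"] = ("L", 40.0)
        table = CodonUsageTable(freqs)
        assert table.best_codon("L") == "CTG"

    def test_unknown_residue_rejected(self, codon_table):
        with pytest.raises(DesignError):
            back_translate("MXQ", codon_table)

    def test_codon_table_tsv_round_trip(self, codon_table, tmp_path):
        from landingpad.arm_design import CodonUsageTable

        p = tmp_path / "codons.tsv"
        codon_table.to_tsv(p)
        again = CodonUsageTable.from_tsv(p)
        assert again.frequencies == codon_table.frequencies


class TestSynonymousDomestication:
    def test_translation_preserved_and_sites_removed(self, codon_table):
        rng = np.random.default_rng(9)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        done = 0
        for _ in range(200):
            protein = "M" + "".join(
                letters[i] for i in rng.integers(0, 20, size=60))
            cds = back_translate(protein, codon_table)
            pos = 3 * int(rng.integers(2, 18))
            poisoned = cds[:pos] + "GAAGACGTC" + cds[pos + 9:]
            if not find_sites(poisoned):
                continue
            fixed, edits = synonymous_domesticate(poisoned, codon_table)
            assert find_sites(fixed) == []
            assert translate(fixed) == translate(poisoned)
            assert edits
            done += 1
        assert done > 50
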