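"""Feature detectors: recoding signals, UTR motifs, coverage, stitching."""

import re

import numpy as np
import pytest

from mycovir.core_seq import NucSeq, find_orfs, normalize_sequence
from mycovir.errors import (
    IllegalPatternCharacter,
    LengthMismatch,
    NoForwardOrf,
    OrfOrderViolation,
    WindowOutOfBounds,
)
from mycovir.genome_features import (
    conserved_utr_motif,
    coverage_from_sam,
    coverage_track,
    extend_and_stitch,
    extract_utrs,
    find_junction,
    find_readthrough,
    find_slippery_sites,
    read_coverage_tsv,
    search_degenerate_motif,
)
from mycovir.synthetic import make_reads, make_virus


def _rand_seq(rng, n):
    return NucSeq("r", "".join(rng.choice(list("ACGT"), n)))


class TestSlipperySites:
    def test_canonical_heptamer(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(list("ACGT"), 200))
        seq = NucSeq("s", body[:50] + "GGGTTTT" + body[50:])
        sites = find_slippery_sites(seq, (40, 70))
        match = [s for s in sites if s.position == 50]
        assert match and match[0].x == "G" and match[0].y == "T"
        assert not match[0].low_complexity

    def test_homopolymer_flagged_not_dropped(self):
        (site,) = find_slippery_sites(NucSeq("s", "AAAAAAC"))
        assert (site.x, site.y, site.z) == ("A", "A", "C")
        assert site.low_complexity

    def test_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(7)
        seq = _rand_seq(rng, 2000)
        got = [s.position for s in find_slippery_sites(seq)]
        oracle = [m.start() for m in
                  re.finditer(r"(?=(.)\1\1(.)\2\2.)", seq.residues)]
        assert got == oracle

    def test_window_bounds_checked(self):
        with pytest.raises(WindowOutOfBounds):
            find_slippery_sites(NucSeq("s", "ACGTACG"), (0, 99))


class TestJunction:
    @pytest.mark.parametrize(
        "kind,shift",
        [("tetramer_AUGA", -1), ("pentamer_overlap", -1), ("spaced", +1)],
    )
    def test_generator_junctions_classified(self, kind, shift):
        segs, truth = make_virus("victorivirus", seed=3,
                                 overrides={"junction_kind": kind})
        orfs = {(o.start, o.end): o
                for o in find_orfs(segs[0], min_len_aa=100)}
        t_cp, t_rdrp = truth.orfs
        j = find_junction(orfs[(t_cp["start"], t_cp["end"])],
                          orfs[(t_rdrp["start"], t_rdrp["end"])], segs[0])
        assert j is not None
        assert j.kind == kind
        assert j.frame_shift == shift
        assert j.orf2_start_pos == truth.junction_orf2_start

    def test_distant_orfs_are_independent(self):
        segs, truth = make_virus("fusarivirus", seed=1)
        orfs = {(o.start, o.end): o
                for o in find_orfs(segs[0], min_len_aa=100)}
        o1 = orfs[(truth.orfs[0]["start"], truth.orfs[0]["end"])]
        o2 = orfs[(truth.orfs[1]["start"], truth.orfs[1]["end"])]
        assert find_junction(o1, o2, segs[0]) is None

    def test_order_violation(self):
        segs, truth = make_virus("victorivirus", seed=4)
        orfs = {(o.start, o.end): o
                for o in find_orfs(segs[0], min_len_aa=100)}
        t_cp, t_rdrp = truth.orfs
        with pytest.raises(OrfOrderViolation):
            find_junction(orfs[(t_rdrp["start"], t_rdrp["end"])],
                          orfs[(t_cp["start"], t_cp["end"])], segs[0])


class TestReadthrough:
    def test_generator_archetype_recovered(self):
        segs, truth = make_virus("ambiguivirus", seed=5)
        rt = find_readthrough(find_orfs(segs[0], min_len_aa=100), segs[0])
        assert rt is not None
        assert rt.stop_codon == "TAG"
        assert rt.orf2_in_same_frame
        assert rt.fused_length_aa == truth.readthrough_fused_aa

    def test_ochre_stop_is_not_readthrough(self):
        # ORF ends TAA; in-frame continuation exists but the stop is wrong
        seq = normalize_sequence(
            "ATG" + "AAA" * 60 + "TAA" + "GGA" * 80 + "TAA")
        assert find_readthrough(find_orfs(seq, min_len_aa=10), seq) is None

    def test_frameshifted_second_orf_is_not_readthrough(self):
        # amber stop, but the downstream frame hits an immediate stop
        seq = normalize_sequence(
            "ATG" + "AAA" * 60 + "TAG" + "TGA" + "G" + "ATG" + "GGA" * 80
            + "TAA")
        assert find_readthrough(find_orfs(seq, min_len_aa=10), seq) is None


class TestUtrs:
    def test_flanks(self):
        seq = _rand_seq(np.random.default_rng(0), 120)
        orfs = find_orfs(seq, min_len_aa=1)
        fake = [o for o in orfs if o.strand == "+"]
        if not fake:
            pytest.skip("no forward ORF in random draw")
        utr5, utr3 = extract_utrs(seq, fake)
        first = min(o.start for o in fake)
        last = max(o.end for o in fake)
        assert utr5.residues == seq.residues[:first]
        assert utr3.residues == seq.residues[last:]

    def test_orf_at_origin_gives_empty_utr5(self):
        seq = normalize_sequence("ATGAAATAA" + "C" * 20)
        utr5, utr3 = extract_utrs(seq, find_orfs(seq, min_len_aa=1))
        assert len(utr5) == 0 and utr3.residues == "C" * 20

    def test_requires_forward_orf(self):
        seq = normalize_sequence("ACGTACGTACGT")
        with pytest.raises(NoForwardOrf):
            extract_utrs(seq, [])

    def test_random_placements_match_slicing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = _rand_seq(rng, 200)
            orfs = [o for o in find_orfs(seq, min_len_aa=2)
                    if o.strand == "+"]
            if not orfs:
                continue
            utr5, utr3 = extract_utrs(seq, orfs)
            assert len(utr5) + len(utr3) <= len(seq)
            assert seq.residues.startswith(utr5.residues)
            assert seq.residues.endswith(utr3.residues)


class TestConservedUtrMotif:
    def test_planted_degenerate_motif(self):
        # the two variants differ at three positions (-> Y codes); flanks
        # mismatch everywhere so extension stops at the motif edges
        u1 = NucSeq("a", "A" * 30 + "TCACAATATCACA" + "G" * 30)
        u2 = NucSeq("b", "C" * 30 + "TCACAACATTATA" + "T" * 30)
        block = conserved_utr_motif([u1, u2], min_len=13,
                                    min_conservation=0.8)
        assert block is not None
        assert block.consensus == "TCACAAYATYAYA"
        assert len(block.consensus) == 13

    def test_identical_utrs_return_whole_utr(self):
        u = NucSeq("a", "ACGTTGCAGGTACCATGA")
        block = conserved_utr_motif([u, NucSeq("b", u.residues)], min_len=8)
        assert block.consensus == u.residues
        assert all(c == 1.0 for c in block.conservation)

    def test_unrelated_utrs_rarely_yield_a_block(self):
        # with only two sequences, near-identical 13-mers between long
        # random UTRs arise by chance; the property is evaluated at the
        # short 5'UTR lengths typical of segmented mycovirus genomes
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(100):
            u1 = _rand_seq(rng, 60)
            u2 = _rand_seq(rng, 60)
            if conserved_utr_motif([u1, u2], min_len=13,
                                   min_conservation=0.9) is not None:
                hits += 1
        assert hits <= 5  # null in >= 95% of trials

    def test_generator_shared_motif_recovered(self):
        segs, truth = make_virus("partitivirus", seed=9)
        utrs = []
        for seg in segs:
            orfs = [o for o in find_orfs(seg, min_len_aa=100)
                    if o.strand == "+"]
            utrs.append(extract_utrs(seg, orfs)[0])
        block = conserved_utr_motif(utrs, min_len=10)
        assert block is not None and truth.utr5_motif in block.consensus


class TestDegenerateMotif:
    def test_paper_style_patterns(self):
        seq = NucSeq("s", "GGTTTCATTAGAGG")
        assert search_degenerate_motif(seq, "TYTCATTARR") == [2]
        utr = NucSeq("u", "CCC" + "AGGGTTCC" + "AAA")
        assert search_degenerate_motif(utr, "AGGGUUCC") == [3]

    def test_n_matches_everywhere(self):
        assert search_degenerate_motif(NucSeq("s", "ACGTN"), "N") == \
            [0, 1, 2, 3, 4]

    def test_matches_brute_force_oracle(self):
        from mycovir.core_seq import IUPAC_SETS

        rng = np.random.default_rng(5)
        seq = _rand_seq(rng, 500)
        pattern = "TRYCANNW"
        got = search_degenerate_motif(seq, pattern)
        want = [
            p for p in range(len(seq) - len(pattern) + 1)
            if all(seq.residues[p + j] in IUPAC_SETS[c]
                   for j, c in enumerate(pattern))
        ]
        assert got == want

    def test_illegal_pattern(self):
        with pytest.raises(IllegalPatternCharacter):
            search_degenerate_motif(NucSeq("s", "ACGT"), "AXQ")


class TestCoverage:
    def test_normalization(self):
        track = coverage_track([2, 4, 4, 2])
        assert list(track.normalized) == [0.5, 1.0, 1.0, 0.5]
        assert track.mean_coverage == 3.0

    def test_all_zero(self):
        track = coverage_track([0, 0, 0])
        assert list(track.normalized) == [0, 0, 0]
        assert track.total_reads == 0

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            coverage_track([1, 2], genome_length=5)

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("1\t3\n2\t5\n4\t1\n")
        track = read_coverage_tsv(p, genome_length=4)
        assert list(track.counts) == [3, 5, 0, 1]

    def test_sam_route_counts_aligned_bases(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:ref\tLN:12\n"
            "r1\t0\tref\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
            "r2\t0\tref\t3\t60\t2M2D2M\t*\t0\t0\tGTAC\tIIII\n"
            "r3\t256\tref\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"  # secondary
        )
        track = coverage_from_sam(sam)
        # r1 covers 0-3; r2 covers 2-3, skips 4-5 (deletion), covers 6-7
        assert list(track.counts) == [1, 1, 2, 2, 0, 0, 1, 1, 0, 0, 0, 0]
        assert track.total_reads == 2

    def test_simulated_depth_is_close_to_nominal(self):
        segs, _ = make_virus("partitivirus", seed=2)
        _, cov = make_reads(segs, depth=50, read_len=100, seed=4)
        for counts in cov.values():
            track = coverage_track(counts)
            assert abs(track.mean_coverage - 50) / 50 < 0.2


@pytest.fixture(scope="module")
def genome_and_reads():
    rng = np.random.default_rng(31)
    genome = _rand_seq(rng, 1000)
    reads, _ = make_reads([genome], depth=30, read_len=100, seed=6)
    return genome, [NucSeq(r[0], r[1]) for r in reads]


class TestExtendAndStitch:
    def test_split_genome_reassembled(self, genome_and_reads):
        genome, reads = genome_and_reads
        c1 = NucSeq("c1", genome.residues[:420])
        c2 = NucSeq("c2", genome.residues[570:])
        merged = extend_and_stitch([c1, c2], reads)
        assert merged is not None
        assert merged.residues == genome.residues

    def test_no_bridging_reads_gives_none(self, genome_and_reads):
        genome, reads = genome_and_reads
        c1 = NucSeq("c1", genome.residues[:420])
        c2 = NucSeq("c2", genome.residues[570:])
        inside = [r for r in reads
                  if r.residues in genome.residues[:400]
                  or r.residues in genome.residues[600:]]
        assert extend_and_stitch([c1, c2], inside) is None

    def test_reverse_complement_reads_equivalent(self, genome_and_reads):
        genome, reads = genome_and_reads
        c1 = NucSeq("c1", genome.residues[:420])
        c2 = NucSeq("c2", genome.residues[570:])
        flipped = [r.reverse_complement() for r in reads]
        merged = extend_and_stitch([c1, c2], flipped)
        assert merged is not None and merged.residues == genome.residues

    def test_extension_supported_by_reads_only(self, genome_and_reads):
        genome, reads = genome_and_reads
        c1 = NucSeq("c1", genome.residues[200:500])
        grown = extend_and_stitch([c1], reads)
        assert grown is not None
        assert grown.residues in genome.residues
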