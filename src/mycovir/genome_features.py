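"""Family-diagnostic genome feature detectors.

Mycovirus families leave characteristic signatures in their genomes beyond
the RdRP itself: totiviruses express an ORF1-ORF2 fusion through a -1
ribosomal frameshift at a slippery heptamer (X XXY YYZ); victoriviruses
re-initiate translation at a start codon overlapping or closely trailing
the upstream stop (AUGA tetramer, UGAUG/UAAUG pentamers, or a short
spacer); ambiguiviruses continue through an amber (UAG) stop in-frame to
fuse ORF1 with the RdRP; multi-segment families (partiti-, chryso-,
alternaviruses) share conserved 5'UTR motifs across segments. This module
detects each signature, plus per-base read-coverage tracks and greedy
read-based contig extension/stitching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_seq import IUPAC_SETS, NucSeq, OrfCall
from .errors import (
    AmbiguousExtension,
    IllegalPatternCharacter,
    LengthMismatch,
    NoForwardOrf,
    OrfOrderViolation,
    WindowOutOfBounds,
)


@dataclass(frozen=True)
class SlipperySite:
    """An X XXY YYZ heptamer enabling -1 ribosomal frameshifting."""

    position: int
    heptamer: str
    x: str
    y: str
    z: str
    low_complexity: bool = False  # x == y: homopolymer-like heptamer
    evidence: str = ""  # free text, e.g. external pseudoknot support


@dataclass(frozen=True)
class JunctionMotif:
    kind: str  # tetramer_AUGA | pentamer_overlap | spaced
    orf1_stop_pos: int
    orf2_start_pos: int
    frame_shift: int
    junction_string: str


@dataclass(frozen=True)
class ReadthroughCall:
    stop_codon: str
    orf1_end: int
    orf2_in_same_frame: bool
    fused_length_aa: int


@dataclass
class UtrConsensus:
    aligned_block: list  # per-position {base: count}
    consensus: str
    conservation: list
    offsets: list  # block start in each input UTR

    @property
    def length(self) -> int:
        return len(self.consensus)

    def render(self, min_conservation: float = 0.8) -> str:
        """Consensus with weakly conserved positions in lowercase."""
        return "".join(
            c.lower() if f < min_conservation else c
            for c, f in zip(self.consensus, self.conservation)
        )


@dataclass
class CoverageTrack:
    counts: np.ndarray
    normalized: np.ndarray
    total_reads: int
    mean_coverage: float


def find_slippery_sites(
    seq: NucSeq, search_window: tuple[int, int] | None = None
) -> list[SlipperySite]:
    """Report every X XXY YYZ heptamer in the window, ascending position.

    The pattern admits x == y (homopolymer-like heptamers); such calls carry
    a low-complexity flag rather than being dropped.
    """
    lo, hi = search_window if search_window is not None else (0, len(seq))
    if lo < 0 or hi > len(seq) or lo > hi:
        raise WindowOutOfBounds(f"window [{lo}, {hi}) outside sequence")
    r = seq.residues
    sites = []
    for p in range(lo, min(hi, len(r)) - 6):
        h = r[p : p + 7]
        if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            sites.append(
                SlipperySite(p, h, h[0], h[3], h[6],
                             low_complexity=h[0] == h[3])
            )
    return sites


#: how far (nt) ORF2's start may sit from ORF1's stop to count as a junction
JUNCTION_WINDOW = 10


def find_junction(
    orf1: OrfCall, orf2: OrfCall, seq: NucSeq
) -> JunctionMotif | None:
    """Classify the victorivirus-style stop/start junction between two ORFs.

    ``tetramer_AUGA``: ORF2's AUG overlaps ORF1's stop so the four
    nucleotides read AUGA (-1 frame). ``pentamer_overlap``: the stop's last
    nucleotide is the start's first (UGAUG or UAAUG; -1 frame). ``spaced``:
    ORF2's start lies a few nucleotides upstream of ORF1's stop in the +1
    frame (termination-reinitiation with a short spacer). Anything farther
    than ``JUNCTION_WINDOW`` nt is treated as independent ORFs (None).
    """
    if orf1.strand != orf2.strand:
        raise OrfOrderViolation("junction requires ORFs on the same strand")
    if orf1.start >= orf2.start:
        raise OrfOrderViolation("orf1 must precede orf2")
    stop_start = orf1.end - 3
    s2 = orf2.start
    rel_frame = (s2 - orf1.start) % 3
    r = seq.residues
    if s2 == orf1.end - 4 and r[s2 : s2 + 4] == "ATGA":
        return JunctionMotif("tetramer_AUGA", stop_start, s2, -1,
                             r[s2 : s2 + 4])
    if s2 == orf1.end - 1 and r[s2 : s2 + 3] == "ATG":
        return JunctionMotif("pentamer_overlap", stop_start, s2, -1,
                             r[stop_start : stop_start + 5])
    if stop_start - JUNCTION_WINDOW <= s2 <= stop_start + JUNCTION_WINDOW \
            and rel_frame == 1:
        return JunctionMotif("spaced", stop_start, s2, +1,
                             r[min(s2, stop_start) : orf1.end])
    return None


def find_readthrough(
    orfs: Sequence[OrfCall],
    seq: NucSeq,
    min_extension_aa: int = 50,
) -> ReadthroughCall | None:
    """Detect ambiguivirus-style amber (UAG) stop-codon readthrough.

    Looks for a forward-strand ORF terminating in TAG whose reading frame
    continues past the stop to a second in-frame stop at least
    ``min_extension_aa`` codons downstream; reports the fused ORF1-RdRP
    protein length. ORFs ending in UAA/UGA, or putative second ORFs in a
    shifted frame, never qualify.
    """
    if not orfs:
        return None
    r = seq.residues
    for orf in sorted(orfs, key=lambda o: o.start):
        if orf.strand != "+" or not orf.has_stop:
            continue
        if r[orf.end - 3 : orf.end] != "TAG":
            continue
        pos = orf.end
        n_codons = 0
        while pos + 3 <= len(r):
            codon = r[pos : pos + 3]
            if codon in ("TAA", "TAG", "TGA"):
                if n_codons >= min_extension_aa:
                    fused = (pos - orf.start) // 3 - 1  # minus readthrough stop
                    return ReadthroughCall("TAG", orf.end, True, fused)
                break
            n_codons += 1
            pos += 3
        else:
            if n_codons >= min_extension_aa:
                fused = (pos - orf.start) // 3 - 1
                return ReadthroughCall("TAG", orf.end, True, fused)
    return None


def extract_utrs(
    segment: NucSeq, orfs: Sequence[OrfCall]
) -> tuple[NucSeq, NucSeq]:
    """5'/3' untranslated regions flanking the forward-strand ORFs."""
    fwd = [o for o in orfs if o.strand == "+"]
    if not fwd:
        raise NoForwardOrf(f"no forward-strand ORF on {segment.id}")
    first = min(o.start for o in fwd)
    last = max(o.end for o in fwd)
    return (
        segment.slice(0, first, id_suffix="|5utr"),
        segment.slice(last, len(segment), id_suffix="|3utr"),
    )


# ---------------------------------------------------------------------------
# conserved UTR motif discovery

_IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC_SETS.items()}

#: columns at least this conserved are "strong"; two adjacent weak columns
#: terminate block extension
_STRONG = 0.75


def _column(utrs: Sequence[str], offsets: Sequence[int], j: int):
    bases = [u[o + j] for u, o in zip(utrs, offsets)]
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    top = max(counts.values())
    return counts, top / len(bases)


def conserved_utr_motif(
    utrs: Sequence[NucSeq],
    min_len: int = 8,
    min_conservation: float = 0.8,
    anchor_k: int = 6,
) -> UtrConsensus | None:
    """Highest-scoring gapless block shared by all UTRs, or None.

    Seeded k-mer anchoring: every ``anchor_k``-mer present in all UTRs
    (first occurrence each) fixes a gapless alignment diagonal, which is
    extended outward column by column until two consecutive weak columns
    (conservation < 0.75) or a sequence edge; terminal weak columns are
    trimmed. Blocks shorter than ``min_len`` or with mean per-position
    conservation below ``min_conservation`` are discarded; the survivor
    with the greatest summed conservation wins. The consensus collapses
    each column's observed bases to the minimal covering IUPAC code.
    """
    if len(utrs) < 2:
        raise ValueError("need at least two UTRs")
    strings = [u.residues for u in utrs]
    if any(len(s) < min_len for s in strings):
        return None
    # k-mer -> occurrence offsets per UTR (capped; a motif k-mer can also
    # occur elsewhere by chance, so every placement combination is tried)
    occ: list[dict[str, list[int]]] = []
    max_occ = 4
    for s in strings:
        d: dict[str, list[int]] = {}
        for i in range(len(s) - anchor_k + 1):
            hits = d.setdefault(s[i : i + anchor_k], [])
            if len(hits) < max_occ:
                hits.append(i)
        occ.append(d)
    shared = set(occ[0])
    for d in occ[1:]:
        shared &= set(d)

    from itertools import product

    best: UtrConsensus | None = None
    best_score = -1.0
    candidates = []
    for kmer in sorted(shared):
        candidates.extend(product(*(d[kmer] for d in occ)))
    for offsets in candidates:
        left_room = min(offsets)
        right_room = min(len(s) - o for s, o in zip(strings, offsets))
        # extend right from the anchor
        hi = anchor_k
        weak_run = 0
        while hi < right_room:
            _, cons = _column(strings, offsets, hi)
            weak_run = weak_run + 1 if cons < _STRONG else 0
            if weak_run >= 2:
                hi -= 1  # drop the first of the two weak columns
                break
            hi += 1
        # extend left
        lo = 0
        weak_run = 0
        while lo > -left_room:
            _, cons = _column(strings, offsets, lo - 1)
            weak_run = weak_run + 1 if cons < _STRONG else 0
            if weak_run >= 2:
                lo += 1
                break
            lo -= 1
        # trim terminal weak columns
        while hi > lo and _column(strings, offsets, hi - 1)[1] < _STRONG:
            hi -= 1
        while lo < hi and _column(strings, offsets, lo)[1] < _STRONG:
            lo += 1
        length = hi - lo
        if length < min_len:
            continue
        cols, conss = [], []
        for j in range(lo, hi):
            counts, cons = _column(strings, offsets, j)
            cols.append(counts)
            conss.append(cons)
        mean_cons = sum(conss) / length
        if mean_cons < min_conservation:
            continue
        # score above the ~0.5 background so a short perfect block beats a
        # long mediocre one
        score = sum(c - 0.5 for c in conss)
        if score > best_score:
            consensus = "".join(
                _IUPAC_FROM_SET.get(frozenset(c), "N") for c in cols
            )
            best = UtrConsensus(cols, consensus, conss,
                                [o + lo for o in offsets])
            best_score = score
    return best


def search_degenerate_motif(seq: NucSeq, pattern: str) -> list[int]:
    """All 0-based offsets where the IUPAC pattern matches the sequence.

    A pattern position matches when its base set contains the sequence
    base (sequence degeneracy codes are matched literally against the
    pattern sets, i.e. an N in the target only matches a pattern N).
    """
    if not pattern:
        raise IllegalPatternCharacter("empty pattern")
    pat = pattern.upper().replace("U", "T")
    for ch in pat:
        if ch not in IUPAC_SETS:
            raise IllegalPatternCharacter(f"illegal IUPAC code {ch!r}")
    sets = [IUPAC_SETS[ch] for ch in pat]
    r = seq.residues
    hits = []
    for p in range(len(r) - len(pat) + 1):
        if all(r[p + j] in s or r[p + j] == pat[j]
               for j, s in enumerate(sets)):
            hits.append(p)
    return hits


# ---------------------------------------------------------------------------
# coverage

def coverage_track(counts: Sequence[int] | np.ndarray,
                   genome_length: int | None = None) -> CoverageTrack:
    """Per-base coverage with the 0-1 normalization used in density plots.

    The maximum-covered position normalizes to 1; an all-zero track stays
    all zero. ``total_reads`` is not recoverable from counts alone and is
    reported as the rounded count-sum divided by nothing — callers with
    read-level data should prefer :func:`coverage_from_sam`.
    """
    arr = np.asarray(counts, dtype=np.int64)
    if genome_length is not None and len(arr) != genome_length:
        raise LengthMismatch(
            f"{len(arr)} counts for genome of {genome_length} nt"
        )
    if (arr < 0).any():
        raise ValueError("negative coverage count")
    peak = arr.max() if len(arr) else 0
    normalized = arr / peak if peak > 0 else np.zeros_like(arr, dtype=float)
    return CoverageTrack(arr, normalized, int(arr.sum()),
                         float(arr.mean()) if len(arr) else 0.0)


def read_coverage_tsv(path: str | Path, genome_length: int | None = None
                      ) -> CoverageTrack:
    """Two-column (1-based position, count) TSV to a coverage track."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            pos, cnt = line.split()[:2]
            pairs.append((int(pos), int(cnt)))
    n = genome_length if genome_length is not None else max(p for p, _ in pairs)
    counts = np.zeros(n, dtype=np.int64)
    for pos, cnt in pairs:
        if not 1 <= pos <= n:
            raise LengthMismatch(f"position {pos} outside genome of {n} nt")
        counts[pos - 1] = cnt
    return coverage_track(counts, genome_length)


def coverage_from_sam(path: str | Path, reference: str | None = None
                      ) -> CoverageTrack:
    """Coverage from a SAM file via pysam.

    Counts each reference base covered by an aligned read base (CIGAR
    M/=/X); deletions advance the reference without contributing coverage;
    secondary and supplementary alignments are excluded.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r") as sam:
        if reference is None:
            reference = sam.references[0]
        n = sam.get_reference_length(reference)
        counts = np.zeros(n, dtype=np.int64)
        total = 0
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != reference:
                continue
            total += 1
            pos = aln.reference_start
            for op, length in aln.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X cover the reference
                    counts[pos : pos + length] += 1
                    pos += length
                elif op == 2:  # D advances without coverage
                    pos += length
                # I/S/H consume the read only
    track = coverage_track(counts)
    track.total_reads = total
    return track


# ---------------------------------------------------------------------------
# read-based contig extension and stitching

_SEED_LEN = 15


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _overlapping_reads(contig: str, reads: list[str],
                       seed_index: dict[str, list[tuple[int, int]]],
                       min_overlap: int, max_mismatch: int):
    """(read_idx, offset) pairs where the read aligns past the contig's 3' end."""
    out = []
    n = len(contig)
    seen = set()
    # seed with the contig's terminal 15-mers
    for s in range(max(0, n - min_overlap), n - _SEED_LEN + 1):
        kmer = contig[s : s + _SEED_LEN]
        for ridx, rpos in seed_index.get(kmer, ()):  # read[rpos:] matches here
            offset = s - rpos  # read start relative to contig
            if (ridx, offset) in seen:
                continue
            seen.add(ridx)
            seen.add((ridx, offset))
            read = reads[ridx]
            ov_start = max(0, offset)
            ov_len = min(n, offset + len(read)) - ov_start
            if ov_len < min_overlap or offset + len(read) <= n:
                continue
            if _mismatches(contig[ov_start : ov_start + ov_len],
                           read[ov_start - offset : ov_start - offset + ov_len],
                           max_mismatch) > max_mismatch:
                continue
            out.append((ridx, offset))
    return out


def _extend_right(contig: str, reads: list[str], seed_index,
                  min_overlap: int, max_mismatch: int) -> str:
    while True:
        support = _overlapping_reads(contig, reads, seed_index,
                                     min_overlap, max_mismatch)
        if not support:
            return contig
        n = len(contig)
        # consensus one column at a time over all supporting reads
        extension = []
        col = n
        while True:
            votes: dict[str, int] = {}
            for ridx, offset in support:
                read = reads[ridx]
                j = col - offset
                if 0 <= j < len(read):
                    votes[read[j]] = votes.get(read[j], 0) + 1
            if not votes:
                break
            ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                raise AmbiguousExtension(
                    f"tie {ranked[0][0]}/{ranked[1][0]} at extension column {col}"
                )
            extension.append(ranked[0][0])
            col += 1
        if not extension:
            return contig
        contig = contig + "".join(extension)


def _revcomp(s: str) -> str:
    return NucSeq("x", s).reverse_complement().residues


def extend_and_stitch(
    contigs: Sequence[NucSeq],
    reads: Sequence[NucSeq],
    min_overlap: int = 30,
    max_mismatch: int = 1,
) -> NucSeq | None:
    """Extend contig ends with overlapping reads; bridge two contigs.

    Reads (either orientation) seeding an exact 15-mer against a contig end
    and verifying a >= ``min_overlap`` overlap with <= ``max_mismatch``
    mismatches vote, column by column, on the extension consensus; an
    unresolvable tie raises :class:`AmbiguousExtension`. With two contigs
    the first is extended until its 3' end overlaps the second (same
    overlap/mismatch rule), and the merged sequence is returned; None when
    no read chain bridges the gap. Deterministic given inputs.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    if not 1 <= len(contigs) <= 2:
        raise ValueError("extend_and_stitch takes one or two contigs")
    pool: list[str] = []
    for r in reads:
        pool.append(r.residues)
        pool.append(_revcomp(r.residues))
    seed_index: dict[str, list[tuple[int, int]]] = {}
    for ridx, read in enumerate(pool):
        for rpos in range(len(read) - _SEED_LEN + 1):
            seed_index.setdefault(read[rpos : rpos + _SEED_LEN], []).append(
                (ridx, rpos)
            )

    left = contigs[0].residues
    if len(contigs) == 1:
        grown = _extend_right(left, pool, seed_index, min_overlap, max_mismatch)
        grown = _revcomp(
            _extend_right(_revcomp(grown), pool, seed_index,
                          min_overlap, max_mismatch)
        )
        if grown == left:
            return None
        return NucSeq(contigs[0].id + "|extended", grown)

    right = contigs[1].residues

    def try_merge(a: str, b: str) -> str | None:
        max_ov = min(len(a), len(b))
        for ov in range(max_ov, min_overlap - 1, -1):
            if _mismatches(a[-ov:], b[:ov], max_mismatch) <= max_mismatch:
                return a + b[ov:]
        return None

    for _ in range(2000):  # growth is monotone; bound is defensive
        merged = try_merge(left, right)
        if merged is not None:
            return NucSeq(f"{contigs[0].id}+{contigs[1].id}", merged)
        grown = _extend_right(left, pool, seed_index, min_overlap, max_mismatch)
        if grown == left:
            return None
        left = grown
    return None
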