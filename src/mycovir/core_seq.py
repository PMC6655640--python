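"""Nucleotide and protein sequence primitives.

Everything downstream of contig ingest builds on this module: IUPAC-aware
sequence normalization, translation under the standard and mold-mitochondrial
codon tables (the latter reads TGA as tryptophan, which is what makes intact
mitovirus ORFs visible at all), six-frame ORF discovery, and the composition
statistics used to characterize coat proteins and mitovirus genomes.

Coordinates are 0-based half-open internally; report layers convert to
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    EmptySequence,
    IllegalCharacter,
    LengthNotMultipleOfThree,
    ProteinShorterThanBins,
)

#: IUPAC nucleotide one-letter codes (after U->T normalization).
IUPAC_NT = set("ACGTNRYSWKMBDHV")

#: Base sets for each IUPAC code, used by degenerate motif matching.
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

STANDARD = "standard"
MOLD_MITO = "mold_mito"


def _build_codon_maps() -> tuple[dict[str, str], dict[str, str]]:
    table1 = CodonTable.unambiguous_dna_by_id[1]
    standard = dict(table1.forward_table)
    for stop in table1.stop_codons:
        standard[stop] = "*"
    mito = dict(standard)
    mito["TGA"] = "W"  # the single difference that matters for mitoviruses
    return standard, mito


_STANDARD_MAP, _MOLD_MITO_MAP = _build_codon_maps()
_CODON_MAPS = {STANDARD: _STANDARD_MAP, MOLD_MITO: _MOLD_MITO_MAP}


@dataclass(frozen=True)
class NucSeq:
    """A normalized nucleotide sequence (DNA alphabet, uppercase)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(self.id, self.residues.translate(_COMPLEMENT)[::-1])

    def slice(self, start: int, end: int, id_suffix: str = "") -> "NucSeq":
        return NucSeq(self.id + id_suffix, self.residues[start:end])


@dataclass(frozen=True)
class OrfCall:
    """A predicted open reading frame.

    ``start``/``end`` are 0-based half-open offsets on the forward strand of
    the source sequence; the stop codon, when present, is inside ``[start,
    end)`` but excluded from ``aa``. ``frame`` is the offset modulo 3 in the
    reading strand's own coordinates.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    codon_table: str
    aa: str
    has_start: bool
    has_stop: bool

    @property
    def aa_length(self) -> int:
        return len(self.aa)


@dataclass
class CompositionProfile:
    """Per-bin fraction of a residue set along a protein."""

    residues_of_interest: frozenset
    n_bins: int
    bin_fractions: list = field(default_factory=list)


def normalize_sequence(raw: str, seq_id: str = "seq") -> NucSeq:
    """Normalize raw input to an uppercase DNA-alphabet :class:`NucSeq`.

    Whitespace is stripped, lowercase raised, U re-written as T. Any
    character outside the IUPAC nucleotide alphabet raises
    :class:`IllegalCharacter` naming the offender and its offset (in the
    whitespace-stripped string).
    """
    if not raw or not raw.strip():
        raise EmptySequence("empty input sequence")
    cleaned = re.sub(r"\s+", "", raw).upper().replace("U", "T")
    for i, ch in enumerate(cleaned):
        if ch not in IUPAC_NT:
            raise IllegalCharacter(ch, i)
    return NucSeq(seq_id, cleaned)


def translate(seq: NucSeq | str, codon_table: str = STANDARD) -> str:
    """Translate a coding sequence; stops render as ``*``.

    Codons containing degenerate codes translate to ``X`` (and, in the ORF
    finder, terminate nothing). ``mold_mito`` differs from ``standard`` only
    at TGA, which encodes tryptophan.
    """
    residues = seq.residues if isinstance(seq, NucSeq) else seq
    if len(residues) % 3 != 0:
        raise LengthNotMultipleOfThree(
            f"length {len(residues)} not divisible by 3"
        )
    table = _CODON_MAPS[codon_table]
    out = []
    for i in range(0, len(residues), 3):
        out.append(table.get(residues[i : i + 3], "X"))
    return "".join(out)


def _orfs_one_strand(
    residues: str,
    seq_id: str,
    strand: str,
    seq_len: int,
    codon_table: str,
    min_len_aa: int,
    require_start: bool,
) -> list[OrfCall]:
    table = _CODON_MAPS[codon_table]
    orfs: list[OrfCall] = []
    n = len(residues)
    for frame in range(3):
        region_start = frame
        first_atg: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = residues[pos : pos + 3]
            aa = table.get(codon, "X")
            if first_atg is None and codon == "ATG":
                first_atg = pos
            if aa == "*":
                orfs.extend(
                    _emit(residues, seq_id, strand, seq_len, codon_table,
                          frame, region_start, pos + 3, first_atg, True,
                          min_len_aa, require_start)
                )
                region_start = pos + 3
                first_atg = None
            pos += 3
        # open-ended region running to the end of the frame
        if pos > region_start:
            orfs.extend(
                _emit(residues, seq_id, strand, seq_len, codon_table,
                      frame, region_start, pos, first_atg, False,
                      min_len_aa, require_start)
            )
    return orfs


def _emit(residues, seq_id, strand, seq_len, codon_table, frame,
          region_start, region_end, first_atg, has_stop,
          min_len_aa, require_start):
    if require_start:
        if first_atg is None:
            return []
        start = first_atg
        has_start = True
    else:
        start = region_start
        has_start = residues[start : start + 3] == "ATG"
    coding_end = region_end - 3 if has_stop else region_end
    if coding_end <= start:
        return []
    aa = translate(residues[start:coding_end], codon_table)
    if len(aa) < min_len_aa:
        return []
    if strand == "+":
        fwd_start, fwd_end = start, region_end
    else:
        fwd_start, fwd_end = seq_len - region_end, seq_len - start
    return [OrfCall(seq_id, fwd_start, fwd_end, strand, frame,
                    codon_table, aa, has_start, has_stop)]


def find_orfs(
    seq: NucSeq,
    codon_table: str = STANDARD,
    min_len_aa: int = 100,
    require_start: bool = True,
) -> list[OrfCall]:
    """Six-frame ORF discovery.

    Within each reading frame the sequence is partitioned at stop codons;
    each stop-bounded region yields at most one call, running from its first
    ATG (or the region start when ``require_start`` is false) to the stop
    (included in the coordinates, excluded from the translation) or to the
    end of the frame. Output is sorted by descending protein length, ties
    broken by ascending start then strand (+ before -).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    fwd = _orfs_one_strand(seq.residues, seq.id, "+", len(seq),
                           codon_table, min_len_aa, require_start)
    rc = seq.reverse_complement()
    rev = _orfs_one_strand(rc.residues, seq.id, "-", len(seq),
                           codon_table, min_len_aa, require_start)
    orfs = fwd + rev
    orfs.sort(key=lambda o: (-o.aa_length, o.start, 0 if o.strand == "+" else 1))
    return orfs


def at_content(seq: NucSeq) -> float:
    """Percent A+T on the given strand; N counts in the denominator only."""
    if len(seq) == 0:
        raise EmptySequence("cannot compute A+T content of empty sequence")
    r = seq.residues
    return 100.0 * (r.count("A") + r.count("T")) / len(r)


def gc_content(seq: NucSeq) -> float:
    if len(seq) == 0:
        raise EmptySequence("cannot compute G+C content of empty sequence")
    r = seq.residues
    return 100.0 * (r.count("G") + r.count("C")) / len(r)


def binned_composition(
    aa: str, residues: Iterable[str], n_bins: int
) -> CompositionProfile:
    """Fraction of ``residues`` in each of ``n_bins`` contiguous protein bins.

    Used to quantify the A/G/P enrichment toward the C terminus of
    victorivirus coat proteins: the protein is cut into equal bins (the
    remainder goes to the final bin) and each bin reports the fraction of
    its residues that belong to the set.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(aa) < n_bins:
        raise ProteinShorterThanBins(
            f"protein of {len(aa)} aa cannot fill {n_bins} bins"
        )
    wanted = frozenset(residues)
    size = len(aa) // n_bins
    fractions = []
    for b in range(n_bins):
        lo = b * size
        hi = (b + 1) * size if b < n_bins - 1 else len(aa)
        chunk = aa[lo:hi]
        fractions.append(sum(1 for c in chunk if c in wanted) / len(chunk))
    return CompositionProfile(wanted, n_bins, fractions)


# ---------------------------------------------------------------------------
# FASTA io (Biopython-backed, 60-column wrap)

def read_fasta(path: str | Path) -> list[NucSeq]:
    return [
        normalize_sequence(str(rec.seq), seq_id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Sequence[NucSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_protein_fasta(
    proteins: Sequence[tuple[str, str]], path: str | Path
) -> None:
    records = [SeqRecord(Seq(aa), id=pid, description="") for pid, aa in proteins]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
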