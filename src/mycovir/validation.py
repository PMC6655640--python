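"""Validation checks against user-supplied reference genome files.

These helpers re-run the feature detectors on real deposited genome
records (GenBank flat files or FASTA the user has downloaded themselves;
nothing here touches the network). They exist to spot-check the detectors
against published genomes — e.g. the slippery heptamer of a totivirus
record, or the coding-strand A+U content of deposited mitovirus genomes.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .core_seq import NucSeq, at_content, normalize_sequence
from .genome_features import SlipperySite, find_slippery_sites


def load_record(path: str | Path) -> NucSeq:
    """Read the first record of a GenBank or FASTA file."""
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} \
        else "fasta"
    rec = next(SeqIO.parse(str(path), fmt))
    return normalize_sequence(str(rec.seq), seq_id=rec.id)


def slippery_site_positions_1based(
    path: str | Path,
    heptamer: str | None = "GGGTTTT",
    window: tuple[int, int] | None = None,
) -> list[int]:
    """1-based start positions of slippery heptamers in a genome record.

    With ``heptamer`` set, only sites whose sequence matches it are
    reported (e.g. the canonical G GGU UUU).
    """
    seq = load_record(path)
    sites: list[SlipperySite] = find_slippery_sites(seq, window)
    return [s.position + 1 for s in sites
            if heptamer is None or s.heptamer == heptamer]


def max_at_content(paths: list[str | Path]) -> float:
    """Largest coding-strand A+U percentage across genome records."""
    return max(at_content(load_record(p)) for p in paths)
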