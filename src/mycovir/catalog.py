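"""The mycovirus catalog: 59 genomes from 44 fungal hosts.

A machine-readable transcription of the survey's genome catalog ships with
the package (``data/survey_catalog.tsv``): one row per (segment, protein),
grouped here into one entry per virus. ``summarize`` reproduces the
catalog-level statistics — virus and host counts, genome-class tallies and
percentages, and per-virus combined genome lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import InvalidClass, MissingColumn
from .taxonomy import _host_key

VALID_CLASSES = {"dsRNA", "(+)ssRNA", "ssRNA"}

_REQUIRED = ["host", "virus_family", "virus_name", "abbrev", "virus_class",
             "bioproject_sra", "segment_number", "length_nt", "accession",
             "protein_id", "length_aa"]


@dataclass
class SegmentRecord:
    number: int
    length_nt: int
    accession: str
    proteins: list = field(default_factory=list)  # (protein_id, length_aa)


@dataclass
class CatalogEntry:
    host: str
    virus_family: str
    virus_name: str
    abbrev: str
    virus_class: str
    bioproject_sra: str
    segments: list = field(default_factory=list)

    @property
    def combined_length_nt(self) -> int:
        return sum(s.length_nt for s in self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def protein_lengths(self) -> dict:
        out = {}
        for seg in self.segments:
            for pid, aa in seg.proteins:
                out.setdefault(pid, aa)
        return out


@dataclass
class SummaryStats:
    n_viruses: int
    n_hosts: int
    class_counts: dict
    family_counts: dict
    class_percent: dict
    strand_split_percent: dict  # dsRNA vs single-stranded (both ss classes)
    combined_length_nt: dict  # abbrev -> nt


def packaged_catalog_path() -> Path:
    return Path(resources.files("mycovir") / "data" / "survey_catalog.tsv")


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load and validate the catalog TSV into one entry per virus."""
    path = Path(path) if path is not None else packaged_catalog_path()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise MissingColumn("catalog file is empty") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise MissingColumn(f"catalog missing column(s) {missing!r}")
    entries: dict[str, CatalogEntry] = {}
    for _, row in df.iterrows():
        cls = row["virus_class"].strip()
        if cls not in VALID_CLASSES:
            raise InvalidClass(f"{row['abbrev']}: {cls!r}")
        entry = entries.get(row["abbrev"])
        if entry is None:
            entry = CatalogEntry(
                host=row["host"].strip(),
                virus_family=row["virus_family"].strip(),
                virus_name=row["virus_name"].strip(),
                abbrev=row["abbrev"].strip(),
                virus_class=cls,
                bioproject_sra=row["bioproject_sra"].strip(),
            )
            entries[row["abbrev"]] = entry
        number = int(row["segment_number"])
        seg = next((s for s in entry.segments if s.number == number), None)
        if seg is None:
            seg = SegmentRecord(number, int(row["length_nt"]),
                                row["accession"].strip())
            entry.segments.append(seg)
        seg.proteins.append((row["protein_id"].strip(),
                             int(row["length_aa"])))
    out = list(entries.values())
    for e in out:
        if not e.segments or any(s.length_nt <= 0 for s in e.segments):
            raise InvalidClass(f"{e.abbrev}: bad segment lengths")
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize(entries: list[CatalogEntry]) -> SummaryStats:
    """Catalog-level tallies; order of entries does not matter.

    Host uniqueness counts distinct (species, strain) pairs, so two strains
    of the same fungal species are two hosts. Percentages round to the
    nearest integer, half away from zero. The strand split lumps the two
    single-stranded classes together, mirroring how the survey reports the
    dsRNA share against "the remaining" positive/single-strand genomes.
    """
    if not entries:
        raise ValueError("no catalog entries")
    n = len(entries)
    hosts = {_host_key(e.host) for e in entries}
    class_counts: dict[str, int] = {}
    family_counts: dict[str, int] = {}
    for e in entries:
        class_counts[e.virus_class] = class_counts.get(e.virus_class, 0) + 1
        family_counts[e.virus_family] = family_counts.get(e.virus_family, 0) + 1
    class_percent = {
        c: _round_half_away(100 * k / n) for c, k in class_counts.items()
    }
    ds = class_counts.get("dsRNA", 0)
    ss = n - ds
    strand_split = {
        "dsRNA": _round_half_away(100 * ds / n),
        "ssRNA": _round_half_away(100 * ss / n),
    }
    combined = {e.abbrev: e.combined_length_nt for e in entries}
    return SummaryStats(n, len(hosts), class_counts, family_counts,
                        class_percent, strand_split, combined)


def max_protein_length(entries: list[CatalogEntry], family: str,
                       protein_id: str = "RdRP") -> int:
    """Largest protein of the given id among entries of one family."""
    best = 0
    for e in entries:
        if e.virus_family != family:
            continue
        for seg in e.segments:
            for pid, aa in seg.proteins:
                if pid == protein_id:
                    best = max(best, aa)
    return best
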