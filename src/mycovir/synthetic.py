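"""Ground-truthed synthetic mycovirus genomes, transcriptomes and reads.

Every pipeline stage is testable without downloads: each family archetype
emits a genome (or segment set) carrying the family's diagnostic features
— a planted RdRP motif-block chain so the profile screen fires, and the
recoding signals, UTR motifs, composition biases and codon-table quirks
the feature detectors look for — together with a ground-truth record that
the corresponding detector contract can verify. Decoy host transcripts
are ORF-bearing but RdRP-free. Segment lengths are drawn inside the
ranges observed for each family in the survey catalog this package
models.

All generation is deterministic given (archetype, seed, overrides).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_seq import MOLD_MITO, STANDARD, NucSeq, find_orfs, at_content
from .errors import OverrideOutOfRange, ReadLongerThanSegment
from .rdrp_screen import _DEFAULT_BLOCKS

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# synonymous codon sets under the standard table
_CODONS_FOR: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            from .core_seq import _STANDARD_MAP  # noqa: E402

            _aa = _STANDARD_MAP[_codon]
            if _aa != "*":
                _CODONS_FOR.setdefault(_aa, []).append(_codon)

_TRIAD_RE = __import__("re").compile(r"[GSA]DD|GDN")


@dataclass
class Archetype:
    name: str
    family: str
    genome_class: str
    model_name: str
    segment_length_ranges: list
    codon_table: str = STANDARD
    feature_plan: tuple = ()


ARCHETYPES: dict[str, Archetype] = {
    a.name: a
    for a in [
        Archetype("totivirus", "Totiviridae", "dsRNA", "RdRP_4",
                  [(4580, 5364)], feature_plan=("slippery_site",)),
        Archetype("victorivirus", "Totiviridae", "dsRNA", "RdRP_4",
                  [(4580, 5364)],
                  feature_plan=("junction", "agp_coat", "utr5_octamer")),
        Archetype("unirnavirus", "Unclassified dsRNA", "dsRNA", "RdRP_5",
                  [(2900, 3400)], feature_plan=("plus_one_orf2",)),
        Archetype("partitivirus", "Partitiviridae", "dsRNA", "RdRP_5",
                  [(1700, 2300), (1500, 2300)],
                  feature_plan=("shared_utr5_motif",)),
        Archetype("chrysovirus", "Chrysoviridae", "dsRNA", "RdRP_4",
                  [(3400, 3600), (3000, 3200), (2900, 3100), (2700, 3000)],
                  feature_plan=("shared_utr5_motif", "caa_repeats")),
        Archetype("alternavirus", "Alternaviridae", "dsRNA", "RdRP_4",
                  [(3400, 3600), (2700, 2800), (2400, 2500)],
                  feature_plan=("shared_utr5_motif", "add_triad")),
        Archetype("mitovirus", "Mitovirus", "(+)ssRNA", "Mitovir_RNA_pol",
                  [(2283, 2595)], codon_table=MOLD_MITO,
                  feature_plan=("mito_code", "high_at")),
        Archetype("ambiguivirus", "Ambiguiviridae", "ssRNA", "RdRP_3",
                  [(2798, 3911)],
                  feature_plan=("amber_readthrough", "gdn_triad")),
        Archetype("hypovirus", "Hypoviridae", "(+)ssRNA", "RdRP_1",
                  [(9069, 11000)], feature_plan=("utr5_15mer",)),
        Archetype("endornavirus", "Endornaviridae", "dsRNA", "RdRP_2",
                  [(14296, 16495)], feature_plan=("polyprotein",)),
        Archetype("fusarivirus", "Fusariviridae", "(+)ssRNA", "RdRP_1",
                  [(5969, 7835)], feature_plan=("orf2",)),
        Archetype("yadokarivirus", "Yadokariviridae", "(+)ssRNA", "RdRP_1",
                  [(3507, 3621)], feature_plan=()),
        Archetype("ourmia_like", "Ourmia-like virus", "(+)ssRNA", "RdRP_2",
                  [(2600, 2800)], feature_plan=()),
    ]
}

#: conserved 5'UTR 15-mer shared by betahypoviruses
HYPOVIRUS_UTR5_15MER = "CTGGTTTATACTCTG"
#: victorivirus 5'UTR octamer
VICTORIVIRUS_OCTAMER = "AGGGTTCC"


@dataclass
class GroundTruth:
    archetype: str
    family: str
    genome_class: str
    codon_table: str
    model_name: str
    segment_lengths: list = field(default_factory=list)
    orfs: list = field(default_factory=list)  # dicts: segment/start/end/strand/role
    triad: tuple | None = None  # (label, aa offset within RdRP protein)
    slippery_position: int | None = None  # segment 0 offset
    junction_kind: str | None = None
    junction_orf2_start: int | None = None
    readthrough_fused_aa: int | None = None
    utr5_motif: str | None = None
    utr5_motif_positions: list | None = None
    at_percent: list = field(default_factory=list)
    rdrp_aa: str = ""
    cp_aa: str | None = None

    def rdrp_orf(self) -> dict:
        return next(o for o in self.orfs if o["role"] == "rdrp")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


# ---------------------------------------------------------------------------
# low-level emitters

def _random_nt(rng, n: int, at: float = 0.5) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(_NT, size=n, p=p))


def _scrub_triads(aa: str, rng) -> str:
    """Replace accidental catalytic-triad patterns in random protein."""
    chars = list(aa)
    while True:
        m = _TRIAD_RE.search("".join(chars))
        if not m:
            return "".join(chars)
        chars[m.start() + 1] = "L"  # break the xDx core


def _random_aa(rng, n: int, scrub_triads: bool = False) -> str:
    aa = "".join(rng.choice(list(_AA20), size=n))
    return _scrub_triads(aa, rng) if scrub_triads else aa


def _codons(rng, aa: str, at_weight: float = 0.0, mito_w: bool = False) -> str:
    """Reverse-translate; optionally bias synonymous choice toward A/T-rich
    codons and encode tryptophan as TGA (mold-mitochondrial reading)."""
    out = []
    for c in aa:
        if mito_w and c == "W":
            out.append("TGA")
            continue
        options = _CODONS_FOR[c]
        if at_weight > 0:
            w = np.array(
                [(1 + s.count("A") + s.count("T")) ** at_weight for s in options]
            )
            out.append(options[rng.choice(len(options), p=w / w.sum())])
        else:
            out.append(options[rng.integers(len(options))])
    return "".join(out)


def _rdrp_protein(rng, model_name: str, n_aa: int,
                  triad_override: str | None = None) -> tuple[str, int]:
    """A protein of ``n_aa`` residues carrying the model's motif blocks in
    order with random linkers; returns (protein, triad offset)."""
    blocks = list(_DEFAULT_BLOCKS[model_name])
    if triad_override:
        m = _TRIAD_RE.search(blocks[-1])
        blocks[-1] = (blocks[-1][: m.start()] + triad_override
                      + blocks[-1][m.end():])
    total_blocks = sum(len(b) for b in blocks)
    spare = n_aa - total_blocks
    if spare < 4 * (len(blocks) + 1):
        raise ValueError(f"RdRP protein of {n_aa} aa too short for blocks")
    cuts = np.sort(rng.integers(2, spare - 2, size=len(blocks)))
    linkers = []
    prev = 0
    for c in list(cuts) + [spare]:
        linkers.append(_random_aa(rng, int(c - prev), scrub_triads=True))
        prev = c
    parts = [linkers[0]]
    for b, l in zip(blocks, linkers[1:]):
        parts.append(b)
        parts.append(l)
    aa = "".join(parts)
    triad_m = _TRIAD_RE.search(blocks[-1])
    block3_start = len(aa) - len(linkers[-1]) - len(blocks[-1])
    triad_pos = block3_start + triad_m.start()
    # boundaries between linkers and blocks can recreate triad patterns;
    # break every match except the planted one
    chars = list(aa)
    while True:
        spurious = [m for m in _TRIAD_RE.finditer("".join(chars))
                    if m.start() != triad_pos]
        if not spurious:
            break
        chars[spurious[0].start() + 1] = "L"
    return "".join(chars), triad_pos


def _with_frame_stop(utr: str) -> str:
    """End a UTR with an in-frame stop so the next ORF's stop-bounded
    region begins exactly at the UTR/ORF boundary."""
    return utr[:-3] + "TAA" if len(utr) >= 3 else "TAA"


def _orf_cds(rng, aa: str, stop: str = "TAA", at_weight: float = 0.0,
             mito_w: bool = False) -> str:
    return "ATG" + _codons(rng, aa, at_weight, mito_w) + stop


def _verify_orfs(segment: NucSeq, truth_orfs, codon_table: str,
                 min_len_aa: int = 100) -> bool:
    found = {(o.start, o.end, o.strand)
             for o in find_orfs(segment, codon_table, min_len_aa=min_len_aa)}
    return all((o["start"], o["end"], o["strand"]) in found
               for o in truth_orfs)


# ---------------------------------------------------------------------------
# family builders (each returns segments + a partially filled truth)

def _simple_genome(rng, truth, length, model_name, utr5_extra="",
                   orf2_aa: int = 0, triad_override=None):
    """Mono-segment genome: 5'UTR | RdRP ORF | [ORF2] | 3'UTR."""
    utr5_len = max(60, int(rng.integers(60, 140)))
    orf2_budget = (orf2_aa + 2) * 3 + 6 if orf2_aa else 0
    utr3_min = 50
    rdrp_aa_len = (length - utr5_len - orf2_budget - utr3_min - 6) // 3
    aa, triad_pos = _rdrp_protein(rng, model_name, rdrp_aa_len, triad_override)
    utr5 = _with_frame_stop(utr5_extra + _random_nt(rng, utr5_len - len(utr5_extra)))
    cds = _orf_cds(rng, aa)
    parts = [utr5, cds]
    pos = len(utr5)
    orfs = [{"segment": 0, "start": pos, "end": pos + len(cds),
             "strand": "+", "role": "rdrp"}]
    pos += len(cds)
    if orf2_aa:
        gap = _with_frame_stop(_random_nt(rng, 24))
        aa2 = _random_aa(rng, orf2_aa)
        cds2 = _orf_cds(rng, aa2)
        parts.append(gap)
        pos += len(gap)
        orfs.append({"segment": 0, "start": pos, "end": pos + len(cds2),
                     "strand": "+", "role": "orf2"})
        parts.append(cds2)
        pos += len(cds2)
    tail = length - pos
    parts.append(_random_nt(rng, max(tail, 30)))
    seg = "".join(parts)
    truth.orfs = orfs
    truth.triad = (triad_override or _TRIAD_RE.search(
        _DEFAULT_BLOCKS[model_name][-1]).group(0), triad_pos + 1)
    truth.rdrp_aa = "M" + aa
    return [seg]


def _build_victorivirus(rng, truth, length, junction_kind):
    cp_len = int(rng.integers(650, 800))
    # A/G/P-enriched tail: last two of ten bins
    bin_size = cp_len // 10
    head = cp_len - 2 * bin_size
    agp = list("AGP")
    other = [c for c in _AA20 if c not in agp]

    def draw(n, p_agp):
        out = []
        for _ in range(n):
            if rng.random() < p_agp:
                out.append(agp[rng.integers(3)])
            else:
                out.append(other[rng.integers(len(other))])
        return "".join(out)

    cp_aa = draw(head, 0.15) + draw(2 * bin_size, 0.50)
    utr5_len = int(rng.integers(120, 200))
    oct_pos = int(rng.integers(10, utr5_len - 20))
    utr5 = _with_frame_stop(
        _random_nt(rng, oct_pos) + VICTORIVIRUS_OCTAMER
        + _random_nt(rng, utr5_len - oct_pos - 8)
    )
    cp_start = len(utr5)

    rdrp_len = int(rng.integers(420, 560))
    rdrp_aa, triad_pos = _rdrp_protein(rng, "RdRP_4", rdrp_len)

    if junction_kind == "tetramer_AUGA":
        cp_cds = "ATG" + _codons(rng, cp_aa[:-1]) + "GCA"  # final Ala ends in A
        cp_block = cp_cds + "TGA"
        j = cp_start + len(cp_block)  # end of ORF1
        rdrp_start = j - 4
        # protein = M K <rdrp_aa>; 'AA' completes the forced AAA lysine codon
        downstream = "AA" + _codons(rng, rdrp_aa) + "TAA"
        rdrp_aa_full = "MK" + rdrp_aa
        triad_full = triad_pos + 2
    elif junction_kind == "pentamer_overlap":
        cp_cds = "ATG" + _codons(rng, cp_aa)
        cp_block = cp_cds + "TAA"
        j = cp_start + len(cp_block)
        rdrp_start = j - 1
        downstream = "TG" + _codons(rng, rdrp_aa) + "TAA"
        rdrp_aa_full = "M" + rdrp_aa
        triad_full = triad_pos + 1
    else:  # spaced, +1 frame: ...CAT GCA TGA with AUG spanning the codons
        cp_cds = "ATG" + _codons(rng, cp_aa[:-2]) + "CAT" + "GCA"
        cp_block = cp_cds + "TGA"
        j = cp_start + len(cp_block)
        rdrp_start = j - 8
        downstream = "T" + _codons(rng, rdrp_aa) + "TAA"  # completes GAT (Asp)
        rdrp_aa_full = "MHD" + rdrp_aa
        triad_full = triad_pos + 3
    rdrp_end = cp_start + len(cp_block) + len(downstream)
    utr3 = _random_nt(rng, max(50, length - rdrp_end))
    seg = utr5 + cp_block + downstream + utr3
    truth.orfs = [
        {"segment": 0, "start": cp_start, "end": j, "strand": "+",
         "role": "cp"},
        {"segment": 0, "start": rdrp_start, "end": rdrp_end, "strand": "+",
         "role": "rdrp"},
    ]
    truth.junction_kind = junction_kind
    truth.junction_orf2_start = rdrp_start
    truth.triad = ("GDD", triad_full)
    truth.utr5_motif = VICTORIVIRUS_OCTAMER
    truth.utr5_motif_positions = [[oct_pos]]
    truth.cp_aa = cp_aa
    truth.rdrp_aa = rdrp_aa_full
    return [seg]


def _build_totivirus(rng, truth, length):
    utr5_len = int(rng.integers(80, 160))
    utr5 = _with_frame_stop(_random_nt(rng, utr5_len))
    cp_start = len(utr5)
    cp_len = int(rng.integers(640, 760))
    slip_codon = int(cp_len - rng.integers(30, 50))
    # G GGU UUU planted as Gly-Phe codons GGG TTT followed by a T-led codon
    cp_aa = (_random_aa(rng, slip_codon) + "GFF"
             + _random_aa(rng, cp_len - slip_codon - 3))
    cp_cds = []
    for k, c in enumerate(cp_aa):
        if k == slip_codon:
            cp_cds.append("GGG")
        elif k in (slip_codon + 1, slip_codon + 2):
            cp_cds.append("TTT")
        else:
            cp_cds.append(_codons(rng, c))
    cp_block = "ATG" + "".join(cp_cds) + "TGA"
    slip_pos = cp_start + 3 + 3 * slip_codon
    cp_end = cp_start + len(cp_block)

    # RdRP ORF two nt downstream of the CP stop: the -1 frame relative to CP
    rdrp_len = int(rng.integers(420, 540))
    rdrp_aa, triad_pos = _rdrp_protein(rng, "RdRP_4", rdrp_len)
    downstream = _codons(rng, rdrp_aa) + "TAA"
    spacer = _random_nt(rng, 2)
    rdrp_start = cp_end + 2
    rdrp_end = rdrp_start + 3 + len(downstream)
    utr3 = _random_nt(rng, max(50, length - rdrp_end))
    seg = utr5 + cp_block + spacer + "ATG" + downstream + utr3
    truth.orfs = [
        {"segment": 0, "start": cp_start, "end": cp_end, "strand": "+",
         "role": "cp"},
        {"segment": 0, "start": rdrp_start, "end": rdrp_end, "strand": "+",
         "role": "rdrp"},
    ]
    truth.slippery_position = slip_pos
    truth.triad = ("GDD", triad_pos + 1)
    truth.cp_aa = cp_aa
    truth.rdrp_aa = "M" + rdrp_aa
    return [seg]


def _build_multiseg(rng, truth, arche, lengths):
    """Partiti-/chryso-/alternavirus: RdRP on segment 1, shared 5'UTR motif."""
    motif = "".join(rng.choice(_NT, size=13))
    if "caa_repeats" in arche.feature_plan:
        motif = motif + "CAACAACAA"
    triad_override = "ADD" if "add_triad" in arche.feature_plan else None
    segs, positions = [], []
    for si, seg_len in enumerate(lengths):
        utr5_len = int(rng.integers(60, 110))
        mpos = int(rng.integers(5, utr5_len - len(motif) - 5))
        utr5 = (_random_nt(rng, mpos) + motif
                + _random_nt(rng, utr5_len - mpos - len(motif)))
        utr5 = _with_frame_stop(utr5)
        positions.append([mpos])
        utr3_min = 40
        aa_len = (seg_len - len(utr5) - utr3_min - 6) // 3
        if si == 0:
            aa, triad_pos = _rdrp_protein(rng, arche.model_name, aa_len,
                                          triad_override)
            truth.triad = (triad_override or "GDD", triad_pos + 1)
            truth.rdrp_aa = "M" + aa
            role = "rdrp"
        else:
            aa = _random_aa(rng, aa_len)
            role = "cp" if si == 1 else "hp"
            if si == 1:
                truth.cp_aa = aa
        cds = _orf_cds(rng, aa)
        start = len(utr5)
        truth.orfs.append({"segment": si, "start": start,
                           "end": start + len(cds), "strand": "+",
                           "role": role})
        seg = utr5 + cds + _random_nt(rng, max(seg_len - start - len(cds),
                                               utr3_min))
        segs.append(seg)
    truth.utr5_motif = motif
    truth.utr5_motif_positions = positions
    return segs


def _build_mitovirus(rng, truth, length):
    for _ in range(40):  # draw until A+U lands in the mitovirus range
        utr5_len = int(rng.integers(60, 120))
        utr3_min = 50
        aa_len = (length - utr5_len - utr3_min - 6) // 3
        aa, triad_pos = _rdrp_protein(rng, "Mitovir_RNA_pol", aa_len)
        # guarantee internal UGA-tryptophans (the mitochondrial signature)
        aa_l = list(aa)
        for k in range(20, len(aa_l) - 20, len(aa_l) // 4):
            aa_l[k] = "W"
        aa = _scrub_triads("".join(aa_l), rng)
        utr5 = _with_frame_stop(_random_nt(rng, utr5_len, at=0.68))
        cds = "ATG" + _codons(rng, aa, at_weight=3.0, mito_w=True) + "TAA"
        seg = utr5 + cds + _random_nt(rng, max(length - utr5_len - len(cds),
                                               utr3_min), at=0.68)
        at = at_content(NucSeq("m", seg))
        if 62.0 <= at <= 73.0 and "TGA" in cds[3:-3]:
            start = len(utr5)
            truth.orfs = [{"segment": 0, "start": start,
                           "end": start + len(cds), "strand": "+",
                           "role": "rdrp"}]
            m = _TRIAD_RE.search(aa)
            truth.triad = ("GDD", m.start() + 1 if m else None)
            truth.rdrp_aa = "M" + aa
            return [seg]
    raise RuntimeError("mitovirus A+U target not reached")


def _build_ambiguivirus(rng, truth, length):
    utr5_len = int(rng.integers(80, 200))
    utr5 = _with_frame_stop(_random_nt(rng, utr5_len))
    orf1_aa = _random_aa(rng, int(rng.integers(150, 260)), scrub_triads=True)
    orf1_cds = _orf_cds(rng, orf1_aa, stop="TAG")
    orf1_start = len(utr5)
    orf1_end = orf1_start + len(orf1_cds)
    rdrp_len = int(rng.integers(300, 420))
    rdrp_aa, triad_pos = _rdrp_protein(rng, "RdRP_3", rdrp_len)
    # ORF2 begins immediately after the amber stop, in the same frame
    orf2_cds = _orf_cds(rng, rdrp_aa, stop="TAA")
    orf2_start = orf1_end
    orf2_end = orf2_start + len(orf2_cds)
    utr3 = _random_nt(rng, max(40, length - orf2_end))
    seg = utr5 + orf1_cds + orf2_cds + utr3
    truth.orfs = [
        {"segment": 0, "start": orf1_start, "end": orf1_end, "strand": "+",
         "role": "orf1"},
        {"segment": 0, "start": orf2_start, "end": orf2_end, "strand": "+",
         "role": "rdrp"},
    ]
    truth.readthrough_fused_aa = (orf2_end - 3 - orf1_start) // 3 - 1
    truth.triad = ("GDN", triad_pos + 1)  # +1 for the ORF2 Met
    truth.rdrp_aa = "M" + rdrp_aa
    return [seg]


def make_virus(
    archetype: str,
    seed: int,
    overrides: dict | None = None,
) -> tuple[list[NucSeq], GroundTruth]:
    """Deterministically build one synthetic virus of the given family.

    ``overrides`` may set ``segment_lengths`` (inside the archetype ranges)
    and, for the victorivirus archetype, ``junction_kind``.
    """
    arche = ARCHETYPES[archetype]
    overrides = dict(overrides or {})
    rng = np.random.default_rng(seed)
    lengths = overrides.pop("segment_lengths", None)
    if lengths is None:
        lengths = [int(rng.integers(lo, hi + 1))
                   for lo, hi in arche.segment_length_ranges]
    else:
        for L, (lo, hi) in zip(lengths, arche.segment_length_ranges):
            if not lo <= L <= hi:
                raise OverrideOutOfRange(
                    f"segment length {L} outside [{lo}, {hi}]"
                )
    junction_kind = overrides.pop("junction_kind", None)
    if overrides:
        raise OverrideOutOfRange(f"unknown overrides {sorted(overrides)!r}")

    for attempt in range(40):
        truth = GroundTruth(archetype, arche.family, arche.genome_class,
                            arche.codon_table, arche.model_name)
        if archetype == "victorivirus":
            kind = junction_kind or ["tetramer_AUGA", "pentamer_overlap",
                                     "spaced"][int(rng.integers(3))]
            segs = _build_victorivirus(rng, truth, lengths[0], kind)
        elif archetype == "totivirus":
            segs = _build_totivirus(rng, truth, lengths[0])
        elif archetype in ("partitivirus", "chrysovirus", "alternavirus"):
            segs = _build_multiseg(rng, truth, arche, lengths)
        elif archetype == "mitovirus":
            segs = _build_mitovirus(rng, truth, lengths[0])
        elif archetype == "ambiguivirus":
            segs = _build_ambiguivirus(rng, truth, lengths[0])
        elif archetype == "hypovirus":
            segs = _simple_genome(
                rng, truth, lengths[0], arche.model_name,
                utr5_extra=_random_nt(rng, 12) + HYPOVIRUS_UTR5_15MER)
            truth.utr5_motif = HYPOVIRUS_UTR5_15MER
        elif archetype == "fusarivirus":
            segs = _simple_genome(rng, truth, lengths[0], arche.model_name,
                                  orf2_aa=int(rng.integers(380, 600)))
        elif archetype == "unirnavirus":
            segs = _simple_genome(rng, truth, lengths[0], arche.model_name,
                                  orf2_aa=int(rng.integers(150, 260)))
        else:  # endornavirus, yadokarivirus, ourmia_like
            segs = _simple_genome(rng, truth, lengths[0], arche.model_name)

        records = [
            NucSeq(f"{archetype}_s{seed}_seg{i + 1}", s)
            for i, s in enumerate(segs)
        ]
        truth.segment_lengths = [len(r) for r in records]
        truth.at_percent = [at_content(r) for r in records]
        ok = True
        for si, rec in enumerate(records):
            seg_orfs = [o for o in truth.orfs if o["segment"] == si]
            if not _verify_orfs(rec, seg_orfs, arche.codon_table):
                ok = False
                break
        if ok:
            return records, truth
    raise RuntimeError(f"could not realize archetype {archetype!r}")


# ---------------------------------------------------------------------------
# transcriptome and reads

def make_decoy(rng, decoy_id: str) -> NucSeq:
    """ORF-bearing host-like transcript without RdRP motif blocks."""
    utr5 = _with_frame_stop(_random_nt(rng, int(rng.integers(40, 200))))
    aa = _random_aa(rng, int(rng.integers(150, 400)))
    cds = _orf_cds(rng, aa)
    utr3 = _random_nt(rng, int(rng.integers(40, 300)))
    return NucSeq(decoy_id, utr5 + cds + utr3)


def make_transcriptome(
    n_decoys: int,
    viruses: Sequence[tuple[list[NucSeq], GroundTruth]],
    seed: int,
) -> tuple[list[NucSeq], dict]:
    """Mix virus segments among decoy transcripts, deterministically shuffled.

    Returns the contig list (renamed ``contig_NNNN``) and a truth map from
    contig id to either ``{"kind": "decoy"}`` or the source virus/segment.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    entries = []
    for vi, (segments, truth) in enumerate(viruses):
        for si, seg in enumerate(segments):
            entries.append((seg, {"kind": "virus", "virus_index": vi,
                                  "archetype": truth.archetype,
                                  "family": truth.family,
                                  "segment": si,
                                  "has_rdrp": si == truth.rdrp_orf()["segment"]}))
    for d in range(n_decoys):
        entries.append((make_decoy(rng, f"decoy{d}"), {"kind": "decoy"}))
    order = rng.permutation(len(entries))
    contigs, truth_map = [], {}
    for new_idx, old_idx in enumerate(order):
        seq, info = entries[int(old_idx)]
        cid = f"contig_{new_idx + 1:04d}"
        contigs.append(NucSeq(cid, seq.residues))
        truth_map[cid] = info
    return contigs, truth_map


def make_reads(
    segments: Sequence[NucSeq],
    depth: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Uniform shotgun reads over each segment, both strands.

    Returns ``(reads, truth_coverage)`` where reads are (id, sequence,
    quality) triples with constant quality, and truth coverage maps segment
    id to the exact per-base count array implied by the sampled positions
    (error-independent, aligner-independent).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    rng = np.random.default_rng(seed)
    reads = []
    coverage = {}
    for seg in segments:
        L = len(seg)
        if read_len > L:
            raise ReadLongerThanSegment(
                f"read length {read_len} exceeds segment {seg.id} ({L} nt)"
            )
        n_reads = int(round(depth * L / read_len))
        counts = np.zeros(L, dtype=np.int64)
        for k in range(n_reads):
            start = int(rng.integers(0, L - read_len + 1))
            counts[start : start + read_len] += 1
            sub = seg.residues[start : start + read_len]
            if error_rate > 0:
                mask = rng.random(read_len) < error_rate
                if mask.any():
                    chars = np.array(list(sub))
                    for pos in np.nonzero(mask)[0]:
                        choices = [b for b in "ACGT" if b != chars[pos]]
                        chars[pos] = choices[int(rng.integers(3))]
                    sub = "".join(chars)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                sub = NucSeq("r", sub).reverse_complement().residues
            # origin is encoded in the id, wgsim-style: seg|index|1-based pos|strand
            reads.append((f"{seg.id}|{k}|{start + 1}|{strand}", sub,
                          "I" * read_len))
        coverage[seg.id] = counts
    return reads, coverage


def recover_features(
    segments: Sequence[NucSeq],
    truth: GroundTruth,
    models: dict | None = None,
) -> dict[str, bool]:
    """Re-detect every planted feature with the detectors at their defaults.

    Returns a map from feature name to recovery success; this is the
    contract check behind the end-to-end synthetic validation: a generated
    genome is only as good as its ability to be rediscovered.
    """
    from .genome_features import (
        conserved_utr_motif,
        extract_utrs,
        find_junction,
        find_readthrough,
        find_slippery_sites,
        search_degenerate_motif,
    )
    from .rdrp_screen import classify_triad, default_models, scan_orf
    from .taxonomy import assign_genome_class

    if models is None:
        models = default_models()
    out: dict[str, bool] = {}
    orf_calls: dict[tuple, object] = {}
    ok_orfs = True
    for si, seg in enumerate(segments):
        found = {(o.start, o.end, o.strand): o
                 for o in find_orfs(seg, truth.codon_table, min_len_aa=100)}
        for o in truth.orfs:
            if o["segment"] != si:
                continue
            key = (o["start"], o["end"], o["strand"])
            if key in found:
                orf_calls[(si, o["role"])] = found[key]
            else:
                ok_orfs = False
    out["orfs"] = ok_orfs

    rdrp_t = truth.rdrp_orf()
    rdrp = orf_calls.get((rdrp_t["segment"], "rdrp"))
    hit = None
    if rdrp is not None:
        hit = scan_orf(rdrp, models[truth.model_name])
    out["rdrp_scan"] = hit is not None and hit.evalue <= 1e-3

    if truth.triad and truth.triad[1] is not None and rdrp is not None:
        call = classify_triad(rdrp.aa)
        out["triad"] = (call.label, call.position) == truth.triad

    if truth.slippery_position is not None:
        cp = orf_calls.get((0, "cp"))
        if cp is None:
            out["slippery_site"] = False
        else:
            sites = find_slippery_sites(
                segments[0], (max(0, cp.end - 180), cp.end))
            out["slippery_site"] = any(
                s.position == truth.slippery_position for s in sites)

    if truth.junction_kind is not None:
        cp = orf_calls.get((0, "cp"))
        rd = orf_calls.get((0, "rdrp"))
        j = find_junction(cp, rd, segments[0]) if cp and rd else None
        out["junction"] = j is not None and j.kind == truth.junction_kind

    if truth.readthrough_fused_aa is not None:
        rt = find_readthrough(
            list(find_orfs(segments[0], truth.codon_table, min_len_aa=100)),
            segments[0])
        out["readthrough"] = (rt is not None
                              and rt.fused_length_aa ==
                              truth.readthrough_fused_aa)

    if truth.utr5_motif is not None:
        utr5s = []
        for si, seg in enumerate(segments):
            fwd = [o for o in find_orfs(seg, truth.codon_table,
                                        min_len_aa=100) if o.strand == "+"]
            utr5s.append(extract_utrs(seg, fwd)[0])
        if len(utr5s) >= 2:
            block = conserved_utr_motif(utr5s, min_len=10)
            out["utr_motif"] = (block is not None
                                and truth.utr5_motif in block.consensus)
        else:
            out["utr_motif"] = bool(
                search_degenerate_motif(utr5s[0], truth.utr5_motif))

    if "high_at" in ARCHETYPES[truth.archetype].feature_plan:
        out["at_range"] = all(62.0 <= a <= 73.0 for a in truth.at_percent)
    if "mito_code" in ARCHETYPES[truth.archetype].feature_plan:
        std_found = {(o.start, o.end)
                     for o in find_orfs(segments[0], STANDARD,
                                        min_len_aa=100)}
        out["mito_code_required"] = (
            (rdrp_t["start"], rdrp_t["end"]) not in std_found)

    out["genome_class"] = (assign_genome_class(truth.family)
                           == truth.genome_class)
    return out


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_coverage(coverage: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg_id, counts in coverage.items():
            for pos, c in enumerate(counts, start=1):
                fh.write(f"{seg_id}\t{pos}\t{c}\n")
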