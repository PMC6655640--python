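"""Post-assembly discovery pipeline: triage, characterize, demarcate.

Mirrors the post-assembly half of an RdRP-based virus discovery workflow:
contigs are screened for RdRP-like proteins, flagged candidates are
characterized (ORF layout, UTRs, recoding signals, catalytic triad,
composition, genome class when the family is known), and — when identity
values against nearest known relatives are supplied — run through the
species-demarcation rules. The report is plain JSON-able data with a
single top-level seed; coordinates in the report are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .core_seq import NucSeq, at_content, read_fasta
from .genome_features import (
    extract_utrs,
    find_junction,
    find_readthrough,
    find_slippery_sites,
)
from .rdrp_screen import (
    DEFAULT_EVALUE_MAX,
    ProfileHit,
    classify_triad,
    default_models,
    parse_domtblout,
    predict_orfs_both_tables,
    triage_contigs,
)
from .taxonomy import (
    SpeciesCandidate,
    assign_genome_class,
    default_rules,
    demarcate,
)
from .errors import NoForwardOrf, UnknownFamily


def _report_coords(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open to 1-based inclusive."""
    return start0 + 1, end0


def characterize_candidate(
    contig: NucSeq,
    family: str | None = None,
    min_len_aa: int = 100,
) -> dict:
    """Feature workup of a single candidate contig."""
    orfs = predict_orfs_both_tables(contig, min_len_aa=min_len_aa)
    fwd = sorted([o for o in orfs if o.strand == "+"], key=lambda o: o.start)
    out: dict = {
        "seq_id": contig.id,
        "length_nt": len(contig),
        "at_percent": round(at_content(contig), 2),
        "orfs": [
            {
                "start": _report_coords(o.start, o.end)[0],
                "end": _report_coords(o.start, o.end)[1],
                "strand": o.strand,
                "codon_table": o.codon_table,
                "aa_length": o.aa_length,
            }
            for o in orfs
        ],
    }
    try:
        utr5, utr3 = extract_utrs(contig, orfs)
        out["utr5_length"] = len(utr5)
        out["utr3_length"] = len(utr3)
    except NoForwardOrf:
        pass
    if fwd:
        first = fwd[0]
        lo = max(0, first.end - 180)
        sites = find_slippery_sites(contig, (lo, min(first.end, len(contig))))
        out["slippery_sites"] = [
            {"position": s.position + 1, "heptamer": s.heptamer,
             "low_complexity": s.low_complexity}
            for s in sites
        ]
        triad = classify_triad(fwd[-1].aa)
        out["triad"] = {"label": triad.label,
                        "position": None if triad.position is None
                        else triad.position + 1}
    if len(fwd) >= 2:
        junction = None
        for o1 in fwd:
            for o2 in fwd:
                if o2.start <= o1.start or junction is not None:
                    continue
                junction = find_junction(o1, o2, contig)
        if junction is not None:
            out["junction"] = {
                "kind": junction.kind,
                "orf1_stop": junction.orf1_stop_pos + 1,
                "orf2_start": junction.orf2_start_pos + 1,
                "frame_shift": junction.frame_shift,
            }
        rt = find_readthrough(fwd, contig)
        if rt is not None:
            out["readthrough"] = {
                "stop_codon": rt.stop_codon,
                "fused_length_aa": rt.fused_length_aa,
            }
    if family:
        try:
            out["family"] = family
            out["genome_class"] = assign_genome_class(family)
        except UnknownFamily:
            out["genome_class"] = "unknown"
    return out


def run_pipeline(config: Mapping) -> dict:
    """Run triage -> characterization -> optional demarcation.

    Config keys: ``contigs`` (FASTA path or NucSeq list), optional
    ``domtblout`` (external hits path), ``evalue_max``, ``min_len_aa``,
    ``families`` ({seq_id: family}), ``identities``
    ({seq_id: {taxon, identities, host, known_hosts}}), ``seed``.
    """
    contigs = config["contigs"]
    if isinstance(contigs, (str, Path)):
        contigs = read_fasta(contigs)
    evalue_max = float(config.get("evalue_max", DEFAULT_EVALUE_MAX))
    min_len_aa = int(config.get("min_len_aa", 100))
    seed = int(config.get("seed", 0))
    families = config.get("families", {}) or {}
    external: list[ProfileHit] | None = None
    models = None
    if config.get("domtblout"):
        with open(config["domtblout"]) as fh:
            external = parse_domtblout(fh)
    else:
        models = config.get("models") or default_models()
    table = triage_contigs(contigs, models=models, evalue_max=evalue_max,
                           external_hits=external, min_len_aa=min_len_aa)
    by_id = {c.id: c for c in contigs}
    candidates = []
    rules = config.get("rules") or default_rules()
    identities = config.get("identities", {}) or {}
    for _, row in table.iterrows():
        contig = by_id[row["seq_id"]]
        cand = characterize_candidate(contig, families.get(contig.id),
                                      min_len_aa=min_len_aa)
        cand["best_hit"] = {
            "model": row["model_name"],
            "bit_score": float(row["bit_score"]),
            "evalue": float(row["evalue"]),
        }
        dem = identities.get(contig.id)
        if dem:
            call = demarcate(
                SpeciesCandidate(dem["taxon"], dem["identities"],
                                 dem.get("host", ""),
                                 dem.get("known_hosts", [])),
                rules,
            )
            cand["species_call"] = {
                "status": call.status,
                "taxon": call.taxon,
                "rationale": call.rationale,
            }
        candidates.append(cand)
    return {
        "schema_version": 1,
        "tool_version": __version__,
        "seed": seed,
        "parameters": {"evalue_max": evalue_max, "min_len_aa": min_len_aa,
                       "external_hits": external is not None},
        "n_contigs": len(contigs),
        "n_candidates": len(candidates),
        "candidates": candidates,
    }


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
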