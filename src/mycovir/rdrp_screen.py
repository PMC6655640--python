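"""Viral RdRP triage of assembled contigs.

The discovery marker for RNA viruses in transcriptome assemblies is the
RNA-dependent RNA polymerase: eukaryotic hosts do not encode one, so any
contig whose predicted protein resembles an RdRP profile is a virus
candidate. Two routes feed the screen:

* an internal motif-profile scanner: each profile is an ordered set of
  ungapped position-specific score matrices (one per conserved RdRP motif
  block); an ORF's score is the best in-order, non-overlapping placement of
  all blocks. Significance is a decoy-calibrated exceedance estimate — the
  expected count of equal-or-better scores among shuffled/random decoys,
  scaled to the search size — and is explicitly *not* an HMMER e-value;
* ingestion of HMMER3 ``--domtblout`` tables produced externally, the
  bit-exact route when real profile HMMs are available.

The six bundled profiles are toy models built from short consensus blocks
of the conserved RdRP motifs (A/B/C-style, including the catalytic triad);
they are sufficient to recover planted RdRPs in synthetic data and to
exercise the pipeline, and are replaceable by user-supplied models.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .core_seq import MOLD_MITO, STANDARD, NucSeq, OrfCall, find_orfs
from .errors import MalformedRow, UncalibratedModel

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: uniform background; the toy profiles make no composition claim
BACKGROUND = np.full(20, 0.05)

#: survival-probability floor below which a chain is reported at all;
#: corresponds to roughly one spurious hit per 10^4 decoy scans
REPORTING_SF = 1e-4

#: consensus probability used when expanding a consensus block to a PSSM
CONSENSUS_P = 0.6


def _consensus_pssm(consensus: str) -> np.ndarray:
    """Log-odds PSSM (bits) from a consensus string; extra column scores X."""
    L = len(consensus)
    pssm = np.empty((L, 21))
    off = math.log2(((1.0 - CONSENSUS_P) / 19.0) / 0.05)
    for k, aa in enumerate(consensus):
        pssm[k, :20] = off
        pssm[k, _AA_INDEX[aa]] = math.log2(CONSENSUS_P / 0.05)
        pssm[k, 20] = -1.0  # unknown residue
    return pssm


@dataclass(frozen=True)
class Calibration:
    """Gumbel parameters of the null chain-score distribution."""

    location: float
    scale: float
    n_decoys: int
    decoy_len: int
    seed: int

    def sf(self, score: float) -> float:
        z = (score - self.location) / self.scale
        # Gumbel survival, numerically safe far in the right tail
        if z > 40:
            return math.exp(-z)
        return -math.expm1(-math.exp(-z))


@dataclass
class ProfileModel:
    """An ordered-block motif profile for one RdRP family."""

    name: str
    block_consensus: tuple[str, ...]
    provenance: str = "bundled-toy"
    calibration: Calibration | None = None
    _pssms: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self._pssms:
            self._pssms = [_consensus_pssm(c) for c in self.block_consensus]

    @property
    def total_block_len(self) -> int:
        return sum(len(c) for c in self.block_consensus)

    @property
    def consensus_protein(self) -> str:
        return "".join(self.block_consensus)


@dataclass(frozen=True)
class ProfileHit:
    seq_id: str
    orf_index: int
    model_name: str
    bit_score: float
    evalue: float
    ali_start: int
    ali_end: int


@dataclass(frozen=True)
class TriadCall:
    """Catalytic triad of the RdRP palm (motif C / domain VI)."""

    label: str  # GDD, SDD, GDN, ADD or none
    position: int | None


def _encode(aa: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in aa.upper()], dtype=np.intp)


def _block_position_scores(idx: np.ndarray, pssm: np.ndarray) -> np.ndarray:
    """Score of placing the block at every start offset of the protein."""
    L = len(pssm)
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for k in range(L):
        scores += pssm[k, idx[k : k + n]]
    return scores


def chain_score(aa: str, model: ProfileModel) -> tuple[float, int, int] | None:
    """Best in-order, non-overlapping placement of all blocks.

    Returns (score, start of first block, end of last block) or None when
    the protein is too short to host the chain.
    """
    idx = _encode(aa)
    if len(idx) < model.total_block_len:
        return None
    pssms = model._pssms
    lens = [len(p) for p in pssms]
    scores0 = _block_position_scores(idx, pssms[0])
    best = scores0
    # DP over blocks: prefix[p] = best chain ending with current block at p
    starts = [np.arange(len(scores0))]
    choice: list[np.ndarray] = []
    for b in range(1, len(pssms)):
        sb = _block_position_scores(idx, pssms[b])
        # previous block must end at or before this block's start
        shift = lens[b - 1]
        prev = np.full(len(sb), -np.inf)
        argprev = np.full(len(sb), -1, dtype=np.intp)
        run = -np.inf
        argrun = -1
        for p in range(len(sb)):
            q = p - shift
            if 0 <= q < len(best) and best[q] > run:
                run = best[q]
                argrun = q
            prev[p] = run
            argprev[p] = argrun
        best = sb + prev
        choice.append(argprev)
        starts.append(np.arange(len(sb)))
    p_last = int(np.argmax(best))
    total = float(best[p_last])
    if not np.isfinite(total):
        return None
    # backtrack to the first block's placement
    p = p_last
    for b in range(len(pssms) - 1, 0, -1):
        p = int(choice[b - 1][p])
    return total, p, p_last + lens[-1]


def calibrate(
    model: ProfileModel,
    seed: int,
    n_decoys: int = 200,
    decoy_len: int = 300,
) -> ProfileModel:
    """Fit the null chain-score distribution on random decoy proteins.

    Decoys are drawn from the background residue frequencies at a fixed
    length; the empirical scores are summarized by Gumbel location/scale via
    the method of moments. The seed is stored so reports can cite it.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ORDER))
    scores = []
    for _ in range(n_decoys):
        decoy = "".join(rng.choice(letters, size=decoy_len, p=BACKGROUND))
        res = chain_score(decoy, model)
        if res is not None:
            scores.append(res[0])
    arr = np.asarray(scores)
    scale = float(arr.std(ddof=1) * math.sqrt(6) / math.pi)
    location = float(arr.mean() - 0.5772156649 * scale)
    cal = Calibration(location, scale, n_decoys, decoy_len, seed)
    return replace(model, calibration=cal, _pssms=model._pssms)


def scan_orf(
    orf: OrfCall | str,
    model: ProfileModel,
    seq_id: str = "",
    orf_index: int = 0,
    search_scale: float = 1.0,
) -> ProfileHit | None:
    """Scan one predicted protein against one calibrated profile.

    Returns the best chain placement as a hit, or None when the chain score
    does not clear the reporting floor (the null survival probability
    ``REPORTING_SF``). The e-value-like statistic is the expected count of
    equal-or-better scores among the calibration decoys, corrected for the
    length of the query relative to the decoys and for ``search_scale``
    (the number of comparable scans in the enclosing search).
    """
    if model.calibration is None:
        raise UncalibratedModel(f"model {model.name} has no calibration")
    if isinstance(orf, OrfCall):
        aa = orf.aa
        seq_id = seq_id or orf.seq_id
    else:
        aa = orf
    res = chain_score(aa, model)
    if res is None:
        return None
    score, start, end = res
    cal = model.calibration
    sf = cal.sf(score)
    if sf > REPORTING_SF:
        return None
    length_scale = max(1.0, len(aa) / cal.decoy_len)
    evalue = cal.n_decoys * sf * length_scale * search_scale
    return ProfileHit(seq_id, orf_index, model.name, round(score, 2),
                      float(evalue), start, end)


def classify_triad(aa: str, window: tuple[int, int] | None = None) -> TriadCall:
    """Locate the motif-C catalytic triad in a polymerase protein.

    Recognizes the canonical GDD, the SDD variant, the alternavirus ADD and
    the ambiguivirus GDN. When ``window`` (0-based half-open, e.g. a profile
    hit's alignment span) is given the search is restricted to it. The first
    match in sequence order wins.
    """
    hay = aa.upper()
    lo, hi = (0, len(hay)) if window is None else window
    m = re.search(r"[GSA]DD|GDN", hay[lo:hi])
    if not m:
        return TriadCall("none", None)
    return TriadCall(m.group(0), lo + m.start())


# ---------------------------------------------------------------------------
# bundled toy profiles

_DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    # motif A / motif B / motif C-style blocks; the third block carries the
    # catalytic triad. Toys, not Pfam: provenance is a model field.
    "RdRP_1": ("DYSKFDQSQS", "GMPSGSPITS", "SLYGDDLIVS"),
    "RdRP_2": ("DASDFDKSQH", "GVPSGMMITS", "AQMSGDDSLL"),
    "RdRP_3": ("DWSRFDATVS", "ELMGSWLTTL", "YVLGDNQIIS"),
    "RdRP_4": ("DFSNFDQSQH", "GIASGSMNTS", "LLMGDDVIMS"),
    "RdRP_5": ("DYDKFDSTVT", "RWLGSTINSV", "IATGDDVLIS"),
    "Mitovir_RNA_pol": ("DLSKWDWSVQ", "RYCGLMNSLL", "NRGDDVLISL"),
}

DEFAULT_CALIBRATION_SEED = 20190724


def default_models(
    seed: int = DEFAULT_CALIBRATION_SEED, calibrated: bool = True
) -> dict[str, ProfileModel]:
    """The six bundled RdRP family profiles, calibrated unless asked not to."""
    models = {}
    for i, (name, blocks) in enumerate(sorted(_DEFAULT_BLOCKS.items())):
        model = ProfileModel(name, blocks)
        if calibrated:
            model = calibrate(model, seed=seed + i)
        models[name] = model
    return models


# ---------------------------------------------------------------------------
# HMMER3 domtblout ingestion (the bit-exact external route)

_N_DOMTBL_FIELDS = 23  # fixed columns before free-text description


def parse_domtblout(stream: TextIO | Iterable[str]) -> list[ProfileHit]:
    """Parse HMMER3 per-domain table rows into :class:`ProfileHit` records.

    Expects the hmmscan orientation: target = profile model, query = the
    translated ORF. Query names of the form ``<seq_id>|orf<k>`` carry the
    ORF index; otherwise the index is 0. Alignment coordinates convert from
    1-based inclusive to 0-based half-open.
    """
    hits = []
    for i, line in enumerate(stream):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _N_DOMTBL_FIELDS:
            raise MalformedRow(i, len(fields))
        model_name = fields[0]
        query = fields[3]
        if "|orf" in query:
            seq_id, _, tail = query.rpartition("|orf")
            orf_index = int(tail)
        else:
            seq_id, orf_index = query, 0
        hits.append(
            ProfileHit(
                seq_id=seq_id,
                orf_index=orf_index,
                model_name=model_name,
                bit_score=float(fields[13]),
                evalue=float(fields[12]),
                ali_start=int(fields[17]) - 1,
                ali_end=int(fields[18]),
            )
        )
    return hits


def write_domtblout(hits: Sequence[ProfileHit], stream: TextIO) -> None:
    """Emit hits in the domtblout column layout (fixture writer)."""
    stream.write("#" + " " * 30 + "--- full sequence --- "
                 "-------------- this domain --------------\n")
    stream.write("# target name        accession   tlen query name"
                 "           accession   qlen   E-value  score  bias"
                 "   #  of  c-Evalue  i-Evalue  score  bias  from"
                 "    to  from    to  from    to  acc description\n")
    for h in hits:
        query = f"{h.seq_id}|orf{h.orf_index}"
        row = (
            f"{h.model_name:<20} - {h.ali_end - h.ali_start:>6} "
            f"{query:<20} - {h.ali_end:>6} "
            f"{h.evalue:>9.2g} {h.bit_score:>6.1f} 0.0 "
            f"1 1 {h.evalue:>9.2g} {h.evalue:>9.2g} {h.bit_score:>6.1f} 0.0 "
            f"1 {h.ali_end - h.ali_start:>5} "
            f"{h.ali_start + 1:>5} {h.ali_end:>5} "
            f"{h.ali_start + 1:>5} {h.ali_end:>5} 0.99 -\n"
        )
        stream.write(row)


# ---------------------------------------------------------------------------
# contig triage

DEFAULT_EVALUE_MAX = 10.0


def predict_orfs_both_tables(
    contig: NucSeq, min_len_aa: int = 100
) -> list[OrfCall]:
    """ORFs under both codon tables, deduplicated on identical translations."""
    orfs = find_orfs(contig, STANDARD, min_len_aa=min_len_aa)
    seen = {(o.start, o.end, o.strand, o.aa) for o in orfs}
    for o in find_orfs(contig, MOLD_MITO, min_len_aa=min_len_aa):
        key = (o.start, o.end, o.strand, o.aa)
        if key not in seen:
            seen.add(key)
            orfs.append(o)
    orfs.sort(key=lambda o: (-o.aa_length, o.start, 0 if o.strand == "+" else 1))
    return orfs


def _better(a: ProfileHit, b: ProfileHit | None) -> bool:
    if b is None:
        return True
    if a.evalue != b.evalue:
        return a.evalue < b.evalue
    if a.bit_score != b.bit_score:
        return a.bit_score > b.bit_score
    return a.model_name < b.model_name


def triage_contigs(
    contigs: Sequence[NucSeq],
    models: dict[str, ProfileModel] | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    external_hits: Sequence[ProfileHit] | None = None,
    min_len_aa: int = 100,
) -> pd.DataFrame:
    """Flag contigs whose predicted proteins resemble viral RdRPs.

    Each contig's ORFs (both codon tables) are scanned against every model —
    or joined against externally computed hits — and the contig's best hit
    with e-value <= ``evalue_max`` is kept. One row per flagged contig,
    ordered by ascending e-value then sequence id.
    """
    if not contigs:
        raise ValueError("triage requires at least one contig")
    rows = []
    for contig in contigs:
        orfs = predict_orfs_both_tables(contig, min_len_aa=min_len_aa)
        best: ProfileHit | None = None
        best_orf: OrfCall | None = None
        if external_hits is not None:
            for h in external_hits:
                if h.seq_id != contig.id or h.evalue > evalue_max:
                    continue
                if _better(h, best):
                    best = h
                    best_orf = orfs[h.orf_index] if h.orf_index < len(orfs) else None
        else:
            if models is None:
                models = default_models()
            for k, orf in enumerate(orfs):
                for model in models.values():
                    h = scan_orf(orf, model, orf_index=k)
                    if h is None or h.evalue > evalue_max:
                        continue
                    if _better(h, best):
                        best = h
                        best_orf = orf
        if best is not None:
            rows.append(
                {
                    "seq_id": contig.id,
                    "orf_index": best.orf_index,
                    "orf_start": best_orf.start if best_orf else pd.NA,
                    "orf_end": best_orf.end if best_orf else pd.NA,
                    "strand": best_orf.strand if best_orf else pd.NA,
                    "codon_table": best_orf.codon_table if best_orf else pd.NA,
                    "model_name": best.model_name,
                    "bit_score": best.bit_score,
                    "evalue": best.evalue,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["seq_id", "orf_index", "orf_start", "orf_end", "strand",
                 "codon_table", "model_name", "bit_score", "evalue"],
    )
    if len(df):
        df = df.sort_values(["evalue", "seq_id"], kind="stable").reset_index(drop=True)
    return df
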