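# Methods

This note documents the models and procedures behind `mycovir`, the
assumptions they make, the parameters that matter, and the limits of what
the synthetic validation can show.

## ORF prediction under two genetic codes

ORFs are called in all six frames. Within a frame the sequence is
partitioned at stop codons; each stop-bounded region contributes at most
one call, from its first ATG (or from the region start when
`require_start=False`) through the stop. This "longest ORF per region"
convention matches the behavior of common ORF callers and makes output
deterministic; nested shorter ORFs starting at internal ATGs are not
reported. Codons containing degenerate bases translate to `X` and never
terminate an ORF.

Two codon tables are supported: the standard code and the
mold-mitochondrial variant, identical except that TGA encodes tryptophan.
The distinction is biologically load-bearing: mitoviruses replicate in
mitochondria and use TGA-tryptophan freely, so their single RdRP ORF
appears hopelessly fragmented under the standard code. Triage therefore
predicts ORFs under both tables and deduplicates identical calls.

The triage default `min_len_aa = 100` is an ecosystem convention (the
common default of transcriptome ORF callers), not a biological constant;
it is configurable down to 1. Coordinates are 0-based half-open
internally; report and CLI output convert to 1-based inclusive.

## The RdRP profile screen

The screen's premise is that a viral RdRP is a strong sequence signature
absent from host genomes. Each bundled profile is an ordered set of three
ungapped position-specific score matrices — consensus blocks standing in
for the conserved polymerase motifs (A/B/C-style, the third carrying the
catalytic triad) — expanded to log-odds with consensus probability 0.6
against a uniform background. An ORF's score is the best-scoring in-order,
non-overlapping placement of all blocks (dynamic programming over block
order and position; verified against exhaustive placement enumeration in
the tests).

This scanner is deliberately **not** a profile-HMM implementation.
Significance is a decoy-calibrated exceedance estimate: each model's null
chain-score distribution is fit (Gumbel, method of moments) on 200 random
proteins of 300 aa drawn from the background, with the calibration seed
stored on the model. The reported statistic is the expected count of
equal-or-better scores among those decoys, scaled by query length and
search size; hits are only emitted at all when the null survival
probability is below 1e-4 (about one spurious hit per 10^4 decoy scans —
measured specificity on ORF-bearing decoy transcripts is higher). Users
with real profile HMMs run `hmmscan` themselves and feed the
`--domtblout` table to `parse_domtblout`, the bit-exact route; the
screening threshold there follows the over-inclusive e-value cut-off of
10.0, with downstream characterization doing the confirmation work.

The six bundled blocks are toys sufficient for synthetic-data recovery,
not Pfam models; model provenance is a field on `ProfileModel`, not a
constant.

## Feature detectors

* **Slippery sites** (`X XXY YYZ`): every matching heptamer in the window
  is reported; the pattern admits x = y, and such homopolymer-like calls
  carry a `low_complexity` flag rather than being suppressed. Pseudoknot
  confirmation is out of scope; the record has a free-text evidence field
  for external structure results.
* **Termination–reinitiation junctions**: classified from the geometry of
  ORF1's stop and ORF2's start — ATGA tetramer (−1 frame), one-base
  stop/start overlap (TGATG/TAATG pentamers, −1), or a start a few bases
  upstream of the stop in the +1 frame. ORF2 starts farther than 10 nt
  from the stop are treated as independent ORFs.
* **Amber readthrough**: an ORF ending in TAG whose frame continues to a
  second stop at least `min_extension_aa = 50` codons downstream is
  reported with the fused protein length. UAA/UGA stops and shifted-frame
  continuations never qualify.
* **Degenerate motif search**: IUPAC-code window matching, equal to the
  brute-force scan by construction and by test.
* **Conserved UTR blocks**: gapless blocks shared by all input UTRs are
  found by exact k-mer anchoring (k = 6, all occurrence combinations up
  to 4 per UTR) and column-wise extension; extension stops at two
  consecutive weak columns (conservation < 0.75), terminal weak columns
  are trimmed, and blocks must reach `min_len` with mean conservation ≥
  `min_conservation` (default 0.8). The consensus collapses each column
  to the minimal covering IUPAC code; text rendering lowercases weak
  positions. Blocks are ranked by conservation summed above a 0.5
  background, so a short perfect block outranks a long mediocre one.

  A statistical caveat: with only two UTRs the chance floor is
  substantial. Measured on random sequence pairs, 13-nt blocks at ≥ 90%
  mean conservation arise in roughly a fifth of 150-nt UTR pairs, falling
  to a few percent at the 50–80 nt UTR lengths typical of segmented
  mycovirus genomes. Significance judgments should therefore weigh UTR
  length and segment count; the false-positive property in the test suite
  is evaluated at 60-nt UTRs for this reason.
* **Coverage**: per-base counts normalized so the maximum position equals
  1 (all-zero tracks stay zero). Input routes: truth counts from the
  simulator, a two-column TSV, or SAM via pysam (M/=/X cover the
  reference, D advances it, secondary/supplementary alignments excluded).
* **Extension/stitching**: greedy and deterministic. Reads (either
  orientation) anchor to a contig end by exact 15-mer seed, verify an
  overlap of ≥ `min_overlap` (default 30) with ≤ `max_mismatch` (default
  1) mismatches, and vote column-by-column on the extension consensus;
  an unresolved tie raises `AmbiguousExtension` rather than guessing. The
  defaults are conventions — published manual read-based extensions do
  not state tolerances.

## Percent identity and demarcation

Pairwise identity comes from a global affine-gap alignment (Gotoh) with
fixed scoring — BLOSUM62, gap open 10, extend 0.5 for proteins; match
2 / mismatch −3, open 5, extend 2 for nucleotide — and a deterministic
traceback preference (substitution, then gap, in a fixed order). Identity
is 100 × identical columns / columns ungapped in both sequences. This is
a documented approximation of the Clustal Omega percent-identity matrix,
whose exact denominator convention differs; values reproduced against
published matrices should be compared with about a one-point tolerance.
Arguments are canonically ordered before alignment so the function is
exactly symmetric. Alignment trimming retains columns whose non-gap
fraction meets the gap threshold (default 0.9, i.e. a gap in up to 10% of
rows is tolerated).

The demarcation engine stores one rule per taxon: identity thresholds on
whichever metrics that taxon uses (RdRP, CP, nucleotide, ORF1), a
comparator (strict `<` except where the source criteria are stated as
`≤` — Alphapartitivirus and Fusarivirus), and a host requirement (always
on). A candidate is a `new_species` when every set threshold passes and
its host is new; `known_species` when at least one identity exceeds its
threshold and the host is the same species (strains of one species count
as one host) or a congeneric one, which additionally raises a
related-genus advisory; anything else, including taxa with no agreed
criteria (Alternavirus), is `indeterminate`. The engine is monotone:
lowering identities can never turn a new-species call into a known one.

## The synthetic-data generator

Each family archetype deterministically emits segments inside the length
ranges observed for that family in the survey catalog, with the family's
diagnostic features planted and recorded as ground truth: RdRP ORFs carry
the profile's consensus blocks with random linkers (so screen sensitivity
tests are about the scanner, not biology), with the catalytic triad
substituted per family (ADD for alternaviruses, GDN for ambiguiviruses);
victoriviruses get an A/G/P-enriched coat-protein tail and one of the
three junction geometries; totiviruses a G GGU UUU heptamer upstream of
the ORF1 stop; multi-segment families a shared 5′UTR motif (chrysoviruses
additionally CAA repeats); hypoviruses the conserved 15-mer in the 5′UTR;
mitoviruses are drawn until coding-strand A+U lands in the 62–73% range
and carry internal TGA-tryptophans so only the mitochondrial code yields
an intact ORF. Accidental triad patterns and misplaced ATGs are scrubbed
or rejected-and-resampled so that every planted feature is recoverable by
its detector at defaults — a property checked exhaustively
(`recover_features`) in the tests and the acceptance script.

Decoy transcripts are ORF-bearing, GC-balanced random sequences without
RdRP blocks; no attempt is made to mimic real host codon usage,
repetitive elements, or assembly artifacts. Reads have uniform start
positions, both strands, substitution errors only, and constant quality.
Consequently, passing tests demonstrate the internal consistency of
detector contracts and the pipeline's discrimination between planted
signal and featureless background — not performance on real
transcriptomes, where chimeric contigs, host genes with weak profile
similarity, and uneven coverage all occur.

## Problem sizes and numerical choices

The validation study uses 50 decoys plus 3 planted mono-segment viruses
for end-to-end triage, 13 archetypes × 8 seeds (~490 feature checks) for
recovery, 100 decoy transcripts for specificity, and 200 shuffles per
calibration; these sizes give stable statistics in seconds on one core.
Ties are broken deterministically throughout (ORF ordering by length then
position then strand; model ties by bit score then name; alignment
traceback by fixed state preference). Degenerate inputs are defined
explicitly: empty UTRs are legal, all-zero coverage normalizes to zero,
and proteins shorter than a model's combined block length scan to null.

## Known limitations

* The internal scanner's statistic is calibrated on composition-neutral
  decoys; strongly biased real proteins (e.g. collagen-like repeats) may
  need user-supplied HMMs via the domtblout route.
* Identity values are alignment-dependent near co-optimal alignments;
  the fixed tie-break makes them reproducible, not canonical.
* The generator does not simulate assembly; contigs are exact genome
  segments.
* No RNA secondary-structure prediction, no phylogenetics, no frameshift
  efficiency modeling; clade placement and pseudoknot confirmation are
  the user's concern.
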