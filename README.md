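# mycovir

Most fungal virus (mycovirus) infections are cryptic: no symptoms, no
particles isolated, nothing but viral RNA hiding inside ordinary RNA-seq
samples. Because nearly all known mycoviruses have dsRNA or (+)ssRNA
genomes, the one reliable discovery marker is the viral RNA-dependent RNA
polymerase (RdRP) — an enzyme no eukaryotic host genome encodes. `mycovir`
implements the post-assembly half of that discovery workflow as a tested,
reusable Python library:

* **Triage** — predict ORFs in assembled contigs under both the standard
  and mold-mitochondrial codon tables (mitoviruses encode tryptophan as
  UGA, so their single ORF is invisible under the standard code) and flag
  contigs whose proteins match viral RdRP motif profiles. Two routes:
  an internal ordered-motif-block scanner with decoy-calibrated e-value-like
  statistics, or ingestion of HMMER3 `--domtblout` tables for bit-exact
  parity with external `hmmscan` runs (profile families RdRP_1–RdRP_5 and
  Mitovir_RNA_pol; screening cut-off 10.0 to stay over-inclusive).
* **Characterization** — family-diagnostic genome features: the
  X XXY YYZ slippery heptamer of totivirus −1 ribosomal frameshifting;
  victorivirus termination–reinitiation junctions (AUGA tetramer,
  UGAUG/UAAUG pentamer overlaps, short +1-frame spacers); ambiguivirus
  amber (UAG) readthrough fusing ORF1 to the RdRP; catalytic-triad calls
  (GDD / SDD / ADD / GDN); conserved 5′UTR motifs shared across the
  segments of partiti-, chryso- and alternaviruses; degenerate (IUPAC)
  motif search; per-base coverage tracks normalized to a 0–1 scale; and
  greedy read-based contig extension/stitching.
* **Species demarcation** — global-alignment percent identity
  (identical columns / columns ungapped in both), identity matrices,
  alignment trimming by column gap fraction, and an ICTV-style rules
  engine: per-taxon thresholds (e.g. Totivirus RdRP < 50%,
  Victorivirus RdRP < 90% and CP < 80%, Chrysovirus 70%/53%,
  Alphapartitivirus ≤ 90%/≤ 80%, Mitovirus RdRP < 90%) combined with a
  fungal-host criterion to call `new_species` / `known_species` /
  `indeterminate`.
* **Synthetic data** — deterministic per-family genome archetypes with
  ground truth (planted RdRP blocks, recoding signals, UTR motifs, A+U
  targets), decoy host transcripts, and shotgun reads, so the whole
  pipeline is testable without downloads.
* **Catalog** — a machine-readable transcription of a 59-genome mycovirus
  survey catalog (44 fungal hosts) with summary statistics.

## Worked example

```python
from mycovir import (make_virus, make_transcriptome, triage_contigs,
                     default_models, run_pipeline)

# three planted viruses hidden among 50 host-like decoy transcripts
viruses = [make_virus(a, seed=101 + i)
           for i, a in enumerate(["victorivirus", "mitovirus",
                                  "ambiguivirus"])]
contigs, truth = make_transcriptome(50, viruses, seed=77)

table = triage_contigs(contigs, default_models())
print(table[["seq_id", "model_name", "evalue"]])
```

prints the three planted contigs and nothing else:

```
        seq_id       model_name        evalue
0  contig_0041           RdRP_3  1.774202e-11
1  contig_0032           RdRP_4  1.456922e-10
2  contig_0053  Mitovir_RNA_pol  3.643389e-10
```

— `contig_0032` is the victorivirus (totivirus-family profile RdRP_4),
`contig_0053` the mitovirus (flagged only because ORFs are also predicted
under the mold-mitochondrial code), and `contig_0041` the ambiguivirus
(tombus-like profile RdRP_3, whose RdRP carries the unusual GDN triad);
the e-values are decoy-calibrated exceedance estimates, far below the
screening cut-off of 10. Passing the same contigs to
`run_pipeline({"contigs": contigs, ...})` adds the per-candidate feature
workup (junction kind, triad, A+U content, genome class).

Catalog summary from the command line:

```sh
$ mycovir summarize
{
 "class_counts": {
  "(+)ssRNA": 20,
  "dsRNA": 34,
  "ssRNA": 5
 },
 ...
 "n_hosts": 44,
 "n_viruses": 59,
 "strand_split_percent": {
  "dsRNA": 58,
  "ssRNA": 42
 }
}
```

i.e. 59 viral genomes from 44 distinct fungal host strains, 34 of them
dsRNA (58%), with the single-stranded classes making up the remaining 42%.

Other subcommands: `mycovir simulate`, `triage`, `characterize`,
`classify`, `run` (see `mycovir --help`).

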