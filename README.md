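# metamethyl

Toolkit for **metaepigenomics**: recovering the DNA methylation systems of
uncultured prokaryotes from single-molecule sequencing kinetics of
metagenome-assembled genomes (MAGs).

Most of what is known about prokaryotic DNA methylation — N6-methyladenine
(m6A), N4-methylcytosine (m4C), 5-methylcytosine (m5C) laid down by
methyltransferases (MTases), often as part of restriction-modification (RM)
systems — comes from culturable strains, which are a thin slice of microbial
diversity. Single-molecule sequencing reads methylation directly from
kinetic signals, so a metagenome sequenced this way yields both draft
genomes and their methylomes. `metamethyl` implements the downstream
inference chain for that setting:

1. **Modification calling** — per-site, per-strand one-sided t test on mean
   log2 interpulse-duration (IPD) ratios, Phred-scaled as
   QV = −10·log10 p, with a 25×-per-strand coverage floor;
2. **Motif discovery** — greedy extraction of degenerate IUPAC motifs
   (e.g. `GANTC`, `GAANNNNTTC`) from methylated-site contexts, with the
   standard exclusion rule (<50 occurrences or <1% methylated);
3. **Motif algebra** — strand-specific occurrence counting, reverse-
   complement pairing of double-strand methylation, merging of
   near-duplicate motifs, and novelty assessment against known recognition
   sequences;
4. **Methylation profiles** — per-contig methylated fractions over the
   motif panel and a silhouette-style congruence score that quantifies how
   well methylation patterns support the genome binning;
5. **MTase–motif congruence** — matching annotated MTase genes to detected
   motifs, flagging RM systems from gene neighbourhoods, and proposing
   specificities for orphan MTase/motif pairs.

Since raw kinetic data at metagenome scale is not desk-reproducible, the
package ships (a) a seeded synthetic community generator (genomes with
distinct composition signatures, planted methylation systems at partial
fractions, abundance-scaled per-site kinetics) so the whole chain is
testable against ground truth, and (b) packaged survey tables from a
freshwater-lake metaepigenomic study (29 detected motifs across 10 draft
genomes; 28 MTase/REase/specificity genes) for the paper-facing analyses.

## Worked example

Reproduce the survey tallies from the packaged tables:

```bash
$ metamethyl fixtures
{
  "n_motif_rows": 29,
  "n_genomes": 10,
  "n_distinct_motifs": 22,
  "n_novel_groups": 9,
  "n_groups_total": 15,
  "congruence_tally": {
    "congruent": 7,
    "incongruent": 7,
    "proposed": 6,
    "unresolved": 0
  },
  "n_m_records": 20,
  "n_rm_systems": 9,
  "n_ratio_rows_consistent": 29
}
```

Reading: the 29 motif rows across 10 genomes collapse to 22 distinct
patterns; after pairing reverse-complement partners (double-strand
methylation) and merging near-duplicate detections among the motifs absent
from the reference, 9 novel motif groups remain. Of the 20 MTase genes, 7
carry a closest-match recognition motif congruent with a motif detected in
their own genome, 9 sit in candidate RM systems, and 6 orphan MTases are
paired with leftover motifs of matching modification type (for example the
m4C MTase whose closest homolog recognises ACGGC is assigned the detected
m4C motif GCWGC).

Run the full synthetic pipeline end to end:

```bash
$ metamethyl all --seed 7 --out-dir runs/demo
{
  "config_hash": "437a0b7d84558f6c",
  "seed": 7,
  "n_contigs": 39,
  "n_genomes": 4,
  "n_called_sites": 11671,
  "n_motifs": 4,
  "n_distinct_motifs": 4,
  "n_novel_groups": 0,
  "recovery": {
    "n_planted": 6,
    "n_recovered_exact": 4,
    "n_spurious": 0
  },
  "bin_congruence": 0.9822905313650787,
  "congruence_tally": {
    "congruent": 4,
    "incongruent": 2,
    "proposed": 0,
    "unresolved": 0
  }
}
```

The default community has four 200 kb genomes at abundances 8:4:2:1 around
a mean of 30 subreads per strand. The four systems of the two well-covered
genomes are recovered exactly with no spurious motifs; the two systems of
the rare genomes (16× and 8×) fall below the 25×-per-strand detection floor
— the expected dropout for rare community members. Per-contig methylation
profiles separate the recovered bins almost perfectly (congruence 0.98).
The run directory contains the contig FASTA, kinetics and called-site TSVs,
the motif table, the per-contig profile matrix, the congruence report and a
`summary.json`; re-running with the same seed reproduces every file
byte-for-byte.

The same stages are available individually (`metamethyl simulate`, `call`,
`discover`) and as library functions (`metamethyl.call_sites`,
`discover_genome_motifs`, `dedupe_and_group`, `bin_congruence`,
`genome_congruence`, ...).

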