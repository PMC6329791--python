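# Methods

`metamethyl` reimplements the analysis chain of a metaepigenomic survey:
from per-site single-molecule kinetic summaries to called DNA modifications,
degenerate methylated motifs, per-contig methylation profiles, and
methyltransferase (MTase) assignments. Because raw single-molecule
sequencing data is not desk-reproducible, the package pairs the analysis
chain with a seeded synthetic community generator so that every stage can be
tested against known ground truth.

## Modification calling

Single-molecule sequencing slows at modified template bases; the signal at a
site is the ratio of observed to expected interpulse duration (IPD) across
the subreads covering it. We summarise each (contig, position, strand) by
the subread count n, and the sample mean and sd of the per-subread log2 IPD
ratios, and test one-sidedly for a positive location:

    t = mean * sqrt(n) / max(sd, sd_floor),   p = P(T_{n-1} >= t),
    QV = -10 log10 p   (capped at qv_cap)

Defaults: `sd_floor = 0.1` (guards against degenerate sample sds),
`qv_cap = 1000`, `qv_min = 20` (p <= 0.01), `min_cov_per_strand = 25`
following the standard recommendation of >25 subreads per strand for
reliable detection. Vendor modification QVs come from a proprietary kinetic
model and are not numerically comparable; published QV columns are therefore
not reproduction targets here, while site/occurrence counts and ratios are.

At QV 20 roughly 1% of unmodified strand-positions pass by construction.
This matters downstream: on a 200 kb genome those ~4000 borderline false
calls outnumber the contexts of a typical motif. Motif discovery therefore
reads its contexts at a stricter `qv_context_min = 30` while site-level
outputs keep the standard cutoff.

## Motif discovery

Each called site contributes a ±10 bp context centred on the methylated
base (minus-strand contexts reverse-complemented). Candidates are extracted
greedily:

1. **Seed**: the (offset, base) column with the highest frequency among
   remaining contexts; the search stops when no column exceeds the
   background 0.25 by `enrich_min = 0.15`.
2. **Refine**: within the seeded subset, offsets with information content
   `2 - H >= ic_min = 0.5` bits are kept; each kept offset gets the minimal
   IUPAC code covering at least 70% of the subset, the pattern is re-matched
   against all contexts and the loop repeats to a fixed point. The coarse
   70% coverage during refinement sheds contexts of co-occurring motifs
   caught in the seed; the converged subset then receives the final minimal
   codes at coverage `1 - eps` with `eps = 0.05`.
3. **Accept**: the pattern (interior offsets failing `ic_min` stay N, so
   bipartite spacer motifs arise naturally), its matched contexts are
   removed, and the search iterates up to `max_motifs = 20`.

The centre base is forced to the subset majority of A or C; the motif's
modification type follows from it (A → m6A, C → m4C by default, since
kinetics-only type classification is out of scope). Candidates are
summarised per genome and filtered by the standard exclusion rule: fewer
than 50 occurrences or a methylation fraction below 1% (boundary values
retained).

Two methylation ratios are reported. `ratio_pct` divides called sites by
**all** occurrences — the convention of published motif tables, which
underestimates true methylation wherever coverage limits detection (with
Poisson(30) coverage and a 25x floor, ~16% of occurrences are never
assessable). `frac_est` divides by occurrences whose methylated position
passes the coverage floor and is the quantity compared against planted
fractions in tests; it still carries the (small) miss rate of the t test at
the planted effect size.

## Motif algebra, reduction and novelty

Motifs are IUPAC strings with one methylated offset. Occurrence counting is
strand-specific (palindromes count once per strand per duplex site), which
is the only convention consistent with published occurrence magnitudes.
Cross-genome deduplication is by exact pattern string. Novelty against a
reference of known recognition sequences is exact pattern equality up to
reverse complement — degenerate subsumption does not confer known status.

Non-reference motifs are merged by single-linkage over two relations:

- **rc-compatible** (double-strand methylation pairs): the reverse
  complement of one pattern, slid over the other with full containment,
  intersects non-emptily at every overlapping position; footprint lengths
  may differ by at most 1, and both motifs must carry the same modification
  class (adenine vs cytosine).
- **similarity-mergeable** (incomplete detections of one motif): same
  modification type and, aligned at the methylated bases, at most one
  conflicting position and at most one unpaired end position.

The two caps are the package's own calibration of an informally described
procedure: without them, short patterns slide compatibly into any longer
motif's N spacer and the reduction collapses. With them, the packaged
29-row survey table reduces to 22 distinct motifs and its 16 non-reference
patterns to 9 novel groups (five complementary pairs, one near-duplicate
trio, three singletons), matching the survey's own reduction. Ties in
grouping are resolved by lexicographic pattern order for determinism.

`reverse_complement` maps a motif to the opposite strand's description of
the same site: the methylated offset maps to `len-1-offset`, where the
pattern holds the complementary base. The motif validity rule accepts the
complement (T for m6A, G for m4C/m5C) at the methylated position for this
reason.

## Methylation profiles and binning congruence

Contigs of one organism share a methylation pattern, so per-contig
methylated fractions over the detected motif panel can corroborate a
genome binning. Entries are undefined when a contig has fewer than
`min_occ = 10` assessable occurrences of a motif (when kinetics are
supplied, occurrences below the coverage floor do not count — a thinly
covered contig is unknown, not unmethylated). The congruence score is the
mean silhouette over contigs under L1 distance restricted to pairwise
defined entries (pairs sharing fewer than 3 defined entries are excluded).
The score is diagnostic only; no re-binning is attempted.

## MTase-motif congruence

An M-role gene is *congruent* when its closest database match's recognition
motif equals a motif detected in the same genome (up to reverse complement)
with exactly agreeing modification type. M genes with a
restriction-endonuclease (R) gene within `window = 5` gene indices on the
same contig are flagged as candidate restriction-modification systems;
Type I MTases accept a specificity-subunit (S) gene as evidence instead
(their REase subunits often evade annotation), and fused
restriction-methylation proteins are systems by themselves. Orphan pairing:
each detected-but-unexplained motif is assigned the unique incongruent
MTase of compatible modification type ("nonspecific" closest matches are
compatible with anything during proposal, with nothing during congruence);
multi-way ties are broken by a neighbouring REase whose cleavage target
equals the motif, else left unresolved.

## Synthetic community generator

The generator emulates the study conditions at desk scale:

- **Genomes**: Markov-chain sequences (order 0-3, default 1) with
  per-genome GC content and a seeded context jitter giving each genome a
  distinct oligonucleotide signature; fragmented into log-normal contigs
  (median ~20 kb, minimum 5 kb) so profile tests see several contigs per
  genome.
- **Methylation**: each strand-specific occurrence of a planted motif is
  methylated independently with the system's fraction.
- **Kinetics**: coverage ~ Poisson with abundance-scaled genome means;
  per-subread log2 IPD ratios ~ Normal(delta, sigma) at methylated and
  Normal(0, sigma) at unmethylated sites, emitted as per-site (n, mean, sd)
  sufficient statistics. Defaults sigma = 1.0 and delta 1.3 / 0.8 / 0.25
  for m6A / m4C / m5C: no kinetic effect sizes are published for the survey
  instrument, so the deltas are free parameters chosen once to reproduce
  the qualitative detectability ordering m6A > m4C > m5C (at 30x, per-site
  power ~1.0 / ~0.97 / ~0.14 at QV 20).
- **Default community**: 4 genomes x 200 kb, abundances 8:4:2:1, community
  coverage mean 30 per strand (so genome coverages 64/32/16/8x): the two
  abundant genomes exceed the 25x guidance while the rare two drop below
  it, making rare-genome dropout observable. Each genome carries 1-2
  common prokaryotic systems (GANTC, GCWGC, GATC, TTAA, GAANNNNTTC, AGCT)
  at fractions 0.80-0.98.

All outputs are pure functions of the spec and seed (numpy `SeedSequence`
spawning per stage); identical re-runs are byte-identical.

What the generator does **not** emulate: sequence context effects on IPD
(real kinetic signal varies with the surrounding bases and the vendor model
corrects for it), read-level errors, assembly artefacts, strain
heterogeneity within a bin, and inter-site correlation of coverage.
Passing tests therefore demonstrate the statistical machinery and its
calibration on idealised kinetics, not performance on real instrument data.

## Test problem sizes

The seeded power study uses 20 communities of 4 x 200 kb genomes at a flat
30x per strand, planting the survey's 4-5 bp and bipartite 10 bp motifs at
fractions 0.80-0.99 (the survey's 8 bp motifs occur ~12 times in 200 kb and
would be excluded by the <50 occurrence rule, so they are not plantable at
this scale). Expected behaviour, verified in `tests/test_acceptance.py`:
exact m6A recovery >= 90%, m4C >= 70%, m5C strictly lower; detection-
adjusted fraction estimates within 5 points of planted (plus binomial
tolerance); binning congruence > 0.5 on the default community and <= 0
under permuted labels.
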