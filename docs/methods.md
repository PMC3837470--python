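# Methods

## Biological model

A-to-I RNA editing is the deamination of adenosine (A) to inosine (I) by
ADAR enzymes, which act only on double-stranded RNA. Inosine base-pairs
like guanosine (G), so both reverse transcription and sequencing report
edited positions as G. An edited site therefore surfaces as an A→G
mismatch between a gene's genomic sequence and its transcript evidence
(ESTs or cDNA reads): genomically A→G on plus-strand genes and T→C on
minus-strand genes.

Three biological regularities drive the filter cascade:

1. **Clustering.** ADAR binds a duplex and edits promiscuously, producing
   bunches of nearby edited adenosines. Isolated A→G mismatches are far
   more likely to be sequencing error or polymorphism than editing.
2. **Double-strandedness.** Editing requires a duplex substrate, most
   often formed by a nearby inverted repeat (in primates, typically a pair
   of oppositely oriented Alu elements). A genuine site should have a
   reverse-complement partner arm within hairpin-forming range.
3. **Not a DNA polymorphism.** An A/G SNP produces the same genome-vs-
   transcript signature; catalogued SNP positions are excluded.

## Pipeline

**Step 1 — mismatch extraction.** Each gene (stored in genomic plus-strand
orientation, with its transcribed strand recorded) is locally aligned
against every transcript sequence with an affine-gap Smith–Waterman kernel
(match +1, mismatch −2, gap open −5, gap extend −2; a gap of length L costs
5 + 2(L−1); N is a wildcard scoring 0 and never counts as a match).
Transcripts are unoriented, so both orientations are tried and the better
kept. Alignments shorter than 50 aligned columns or below 90% identity are
discarded as spurious — the literature the workflow derives from gives no
thresholds for this gate, so these are explicit, configurable defaults.
Columns where the gene reads A and the transcript G (transcribed frame)
become candidate sites; candidates at the same genomic position merge
across transcripts, and the Number of Aligned ESTs (NAE) counts all
supporting transcripts.

**Step 2 — clustering filter.** Within one gene-transcript alignment, a
candidate survives iff it belongs to a maximal run of ≥ 4 A-G mismatch
columns in which every column between consecutive run members is an exact
match — no gaps and no other mismatch types. All members of a qualifying
run are retained, and no maximum spacing is imposed beyond the
no-gap/no-other-mismatch rule. Clusters are evaluated per alignment; a
merged site survives if it is clustered in at least one supporting
alignment.

**Step 3 — repeat classification.** Sites are labeled T0 (inside an Alu
annotation), T1 (inside any other repeat), or T2 (unique sequence), with
the covering repeat attached for reporting. The repeat input is BED6+3
(name, class, family); an annotation counts as Alu when its family is
"Alu" or its name starts with "Alu", case-insensitively.

**Step 4 — double-strand (inverted repeat) search.** A probe is built as
the reverse complement of the region centered on the site: for T0 sites
the full Alu interval, otherwise 251 nt including the mismatch (125 nt of
flank each side). The probe is locally aligned against a window of at most
4001 nt centered on the site. The site is annotated double-stranded when
the alignment covers at least 85% of the probe length — ⌈0.85 × 251⌉ = 214
aligned nucleotides for the default probe — at ≥ 85% identity over the
aligned columns (identity is computed over aligned columns, the natural
reading where the source rule is ambiguous). Near gene boundaries the
probe is truncated with the mismatch kept inside, and the 85% length rule
scales to the truncated length. A trivial self-hit — an alignment whose
footprint covers more than half of the probe's own source interval, which
happens when the source arm is a reverse-complement palindrome — is
rejected by masking the source interval with N and re-searching: the
partner must be a distinct arm.

**Step 5 — SNP exclusion.** Sites at catalogued SNP positions are removed
and logged.

**Step 6 — read support and significance.** Steps 2–5 are mandatory
filters; Step 6 only annotates. Short reads are placed ungapped at every
locus with ≤ 2 mismatches, both orientations, all placements reported
(bowtie `-a -v 2` semantics). The pileup column over each site is tallied
in the transcribed frame (reverse placements contribute complemented
bases; minus-strand genes are complemented once more). Only A and G reads
enter the statistics — a column is not discarded for containing other
bases, which would throw away nearly every real column with one sequencing
error; the non-A/G reads are ignored. A site with fewer than 5 A/G reads
is annotated *unknown* (a stricter ≥ 5 G-reads rule is available as a
config switch).

Expected A/G frequencies are calibrated empirically: at every known
editing site with ≥ 5 A/G reads, the column frequencies fA = A/(A+G) and
fG = G/(A+G) are computed and averaged, unweighted, across sites. For each
testable candidate the observed counts are compared against the expected
frequencies scaled to the observed A/G depth and rounded half-up — giving
a valid integer 2×2 table [[obs_A, obs_G], [exp_A, exp_G]] — with a
two-sided Fisher exact test (minimum-likelihood two-sided rule, as in
scipy). P-values are adjusted jointly across testable sites by
Benjamini–Hochberg, and adjusted p ≤ α (default 0.01) is flagged
"significant" purely as a labeled threshold: the p-value measures
consistency of the observed column with the calibrated expectation, and no
directional interpretation is imposed.

Sites are reported with chromosome, 1-based position, strand, region
class, NAE and its color bin (yellow 1–5, orange 6–10, red 11–19, fuxia
≥ 20 — the legend bins overlap at 20 and fuxia takes precedence), a
known-site flag, p-value and adjusted p-value ("NA" when unknown), in TXT,
XML and BED dialects.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cluster_min_run` | 4 | minimum A-G mismatches per qualifying cluster |
| `probe_len` | 251 nt | probe length outside Alu regions (site included) |
| `window_len` | 4001 nt | search window centered on the site |
| `min_len_frac` | 0.85 | minimum aligned fraction of the probe |
| `min_identity` | 0.85 | minimum identity of the probe alignment |
| `est_min_aligned_length` | 50 | gene-vs-EST gate (aligned columns) |
| `est_min_identity` | 0.90 | gene-vs-EST gate (identity) |
| `min_reads` | 5 | minimum A/G reads for testing and calibration |
| `alpha` | 0.01 | FDR threshold for the "significant" label |
| match/mismatch/gap | +1/−2/−5,−2 | Smith–Waterman scores |

All are configuration keys; none is hard-coded.

## Synthetic data

`inosite.synthetic` generates complete, seeded study conditions entirely
in memory (optionally written as FASTA/BED files): random uniform-ACGT
genes carrying planted edit clusters (members forced to the reference
adenosine base, 60 nt apart so a 50-nt read spans at most one member and a
fully edited read still passes the ≤ 2-mismatch rule), a planted
reverse-complement partner arm ~200 nt downstream of each cluster's probe
region, three dedicated covering ESTs per cluster of which a fraction
(default 0.6) carry G at all members, unedited background ESTs, uniform-
start error-free reads edited per-site with the same fraction, and
isolated known sites used only for calibration. Every scenario also
plants negative controls: one cluster of size 3, one cluster of size 4
without a partner arm, and (by default 2) cluster members catalogued as
SNPs. The default condition is 2 genes × 5000 nt (one per strand), 2
qualifying clusters, read depth 20× at 50 nt — sized so a full end-to-end
run finishes in tens of seconds on one core.

What the generator does **not** emulate: sequencing errors and quality
strings, indels, transcript splicing, non-uniform coverage, repeat-derived
multi-mapping ambiguity beyond the planted inverted repeats, and realistic
Alu sequence content (repeat classification consults annotations only, so
planted repeats are labeled intervals over random sequence). Passing the
recovery tests therefore demonstrates the correctness of the filter logic
under the stated geometry, not performance on real genome-scale data.

One measurable artifact of the planted geometry: reads drawn from the
partner arm also place (reverse-orientation, zero mismatches) onto the
source arm, contributing unedited A bases to the site column and diluting
the observed G fraction by roughly half relative to the calibration sites,
which have no partner arm. Candidate p-values in the default scenario are
correspondingly small. This is faithful to how an aligner reporting all
valid placements would behave over a perfect inverted repeat.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only in reports.
- The Smith–Waterman kernel is exact dynamic programming (no seeding
  heuristics); it is verified in the suite against an independent
  full-DP Gotoh oracle, as are read placement (exhaustive scan), the
  clustering rule (window enumeration), the Fisher p-value
  (hypergeometric enumeration, exhaustive to depth 30) and BH (literal
  step-up).
- Where several co-optimal local alignments exist, the reported one is the
  aligner's first traceback; scores are invariant under ties, per-column
  statistics (identity) may differ between co-optima.
- Expected-count rounding is half-up (`floor(x + 0.5)`), so the expected
  row always sums to the observed A/G depth.
- Degenerate inputs: empty EST lists, empty SNP/known sets and missing
  reads degrade gracefully (empty results or unknown significance);
  calibration with zero qualifying columns is an error when called
  directly and a warning (all-unknown significance) inside the pipeline.
- Gene-model (BED12) isoform annotation is not implemented; per-site
  reports carry sequence-level fields only.

## Known limitations

- Exact DP alignment is desk-scale: suitable for gene-sized inputs, not
  genome-wide screens.
- The double-strand test is purely alignment-based; no thermodynamic RNA
  secondary-structure prediction is attempted, and C-to-U or other editing
  types are out of scope.
- Calibration pools all known sites; there is no per-tissue
  stratification, and the test has low power at the minimum depth of 5.
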