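# inosite

Detection of candidate A-to-I RNA editing sites in genomic sequences from
genome-vs-transcript mismatches.

A-to-I editing deaminates adenosine to inosine in double-stranded RNA;
inosine is read as guanosine downstream, so edited positions appear as A→G
mismatches between a gene's genomic sequence and its transcript evidence
(ESTs/cDNA). `inosite` is a library and command-line tool for researchers
who want to screen gene regions for such candidates: it extracts A-G
mismatch columns from gene-vs-EST local alignments and passes them through
the classical filter cascade

1. **clustering** — keep only mismatches in runs of ≥ 4 A-G columns with
   nothing but exact matches in between (ADAR edits in bunches; isolated
   mismatches are noise),
2. **repeat classification** — T0 (Alu), T1 (other repeat), T2 (unique),
3. **double-strand test** — a reverse-complement probe centered on the
   site (251 nt, or the full Alu) must re-align within a 4001-nt window at
   ≥ 85% of its length (⌈0.85·251⌉ = 214 nt) and ≥ 85% identity,
4. **SNP exclusion** — positions catalogued as SNPs are removed,

then annotates survivors with short-read support (ungapped placement,
all loci, ≤ 2 mismatches — bowtie `-a -v 2` semantics). For each site with
≥ 5 A/G reads it tests the observed A/G pileup counts (o_A, o_G) against
expected counts (e_A, e_G) obtained by scaling empirically calibrated
frequencies — the average of f_A = A/(A+G), f_G = G/(A+G) over covered
known editing sites — to the same depth, with a two-sided Fisher exact
test on [[o_A, o_G], [e_A, e_G]], followed by Benjamini–Hochberg FDR
adjustment (α = 0.01). Sites without sufficient coverage are annotated
*unknown* rather than dropped. Reports (TXT/XML/BED) carry chromosome,
1-based position, strand, region class, the Number of Aligned ESTs (NAE)
with its color bin, known-site flag, and the raw and adjusted p-values.

A fully seeded synthetic-scenario generator (`inosite.synthetic`, also the
`simulate` subcommand) builds complete input sets — genes with planted
edit clusters inside planted inverted repeats, edited ESTs and reads, SNP
decoys, calibration sites — so the entire pipeline is testable without any
downloads.

## Worked example

```bash
inosite simulate --seed 7 -o demo     # synthetic inputs + demo/config.ini
inosite run -c demo/config.ini
```

prints

```
10 candidate sites written to demo/out
  1_mismatch_extraction: 19 in, 19 out, 0 discarded
  2_clustering: 19 in, 16 out, 3 discarded
  3_region_classification: 16 in, 16 out, 0 discarded
  4_dsrna: 16 in, 12 out, 4 discarded
  5_snp_exclusion: 12 in, 10 out, 2 discarded
  6_read_support: 10 in, 10 out, 0 discarded
```

Nineteen distinct A-G mismatch positions come out of the gene-vs-EST
alignments. The clustering filter drops the 3 members of the planted
too-small cluster, the double-strand filter drops the 4-site cluster
planted without an inverted-repeat partner, and the SNP filter removes the
2 planted SNP decoys, leaving exactly the 10 planted qualifying sites.
The report begins:

```
chrom	position	strand	gene_id	region_class	nae	color	known	pvalue	adjusted_pvalue
chr1	231	+	gene0	T0	2	yellow	no	0.000413299	0.00137766
chr1	291	+	gene0	T0	2	yellow	no	0.00422776	0.00704627
```

Each row is one candidate: here a site at chr1:231 inside an Alu
annotation (T0), supported by 2 ESTs (NAE 2, yellow bin), not a known
site, with its Fisher p-value and BH-adjusted p-value from the read
pileup. Library users get the same results as
`inosite.run_pipeline(PipelineConfig(...))`, which returns the site list,
per-step accounting and report paths.

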