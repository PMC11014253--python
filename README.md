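# epibis

Simultaneous genetic and epigenetic inference from bisulfite- and
enzymatic-conversion sequencing (WGBS, EM-seq, NOMe-seq), in pure
scientific Python: a conversion-aware read aligner over dual 3-base
FM-indexes, a joint SNP + methylation pileup caller, conversion QC, the
read-level run-length-encoded **epiBED** format, and a fully
truth-tracked read simulator that exercises the whole stack.

## Who this is for

Converted sequencing turns every unmethylated cytosine into a genetic
difference (C→T on the top strand, G→A on the bottom), which breaks
ordinary aligners and variant callers. `epibis` is for anyone who wants
to extract *both* signals — methylation levels and SNPs — from the same
reads, down to single-molecule phased epi-haplotypes, and for method
developers who need a compact, fully-instrumented desk-scale
implementation of the whole pipeline with exact truth tables.

## The core ideas

**Alignment.** The reference is held as a 2-bit packed 4-base genome
plus two FM-indexes over in-silico converted copies of the forward +
reverse strand concatenation: the *C-less* index (C→T) and the *G-less*
index (G→A); the two indexed texts are exact reverse complements of one
another. Reads are converted the same way, seeded by maximal exact
matches in the matching index, filtered for compatibility with the
original 4-base genome, chained, and extended against the original bases
with an **asymmetric substitution matrix**: a read T may align to a
reference C (and read A to reference G, on the opposite strand)
penalty-free, but never the reverse:

    s(ref, read) = +a   if ref == read, or (C→T | G→A) on the strand's
                        conversion sense
                   -b   otherwise          (affine gaps: -(q + k*e))

Equally optimal placements are reported with MAPQ 0; otherwise
MAPQ = round(60·(best − second)/best).

**Calling.** Pileup base support uses a six-letter alphabet
{A,C,G,T,R,Y}: Y replaces a T seen on a C→T-converted read (could be C
or T), R an A on a G→A-converted read. Four conservative rules reduce
the ambiguous mass onto {A,C,G,T} using opposite-strand or unconverted
evidence, and a Bayesian model over the 10 diploid genotypes
(parameters: sequencing error *e*, contamination *c*, polymorphism rate
θ) yields the genotype and its quality GQ. Methylation is the beta value
β = M/(M+U) per cytosine on its informative strand; NOMe-seq assays
split sites into HCG (endogenous methylation), GCH (accessibility), GCG
(excluded) and CCG (kept, flagged).

**epiBED.** One BED row per molecule carries run-length-encoded
methylation and variant states (`2x1M3x` decodes to `xxMxxx`),
mate-overlap aware so nothing is counted twice, and convertible to a
read × CpG matrix for allele-specific methylation (Fisher exact).

## Worked example

```
epibis simulate --out sim --genome-length 20000 --depth 30 --seed 11
epibis index sim.fa idx
epibis align idx sim_R1.fastq sim_R2.fastq -o aln.sam --mark-dup
epibis pileup aln.sam idx -o pileup.vcf
epibis vcf2bed pileup.vcf -t cg  -o cpg.bed
epibis vcf2bed pileup.vcf -t snp -o snp.bed
epibis qc aln.sam idx --prefix qc
```

The run prints, step by step:

```
[epibis] INFO simulated 3000 pairs -> sim_R[12].fastq
[epibis] INFO indexed 1 contigs (20000 bp) -> idx
[epibis] INFO aligned 6000/6000 reads -> aln.sam
[epibis] INFO wrote 19993 sites -> pileup.vcf
[epibis] INFO 1763 rows (cg channel)
[epibis] INFO 21 rows (snp channel)
```

`snp.bed` holds the recovered genotypes (position, ref, alt, GT, GQ):

```
chr1  1551  1552  G  T  1/1  47
chr1  2592  2593  A  G  1/1  69
chr1  3250  3251  A  T  0/1  99
```

and `qc.qc.txt` the conversion diagnostics — CpG retention ≈ 0.72
(methylation plus conversion failure) against a CpA/CpC/CpT background
of ≈ 0.021, matching the simulated 98% conversion rate:

```
total_reads:6000
mapped_reads:6000
optimally_mapped_reads:6000
retention_CpG:0.716451
retention_CpA:0.020821
retention_CpC:0.020255
retention_CpT:0.021347
background_nonconversion:0.02089
cpa_methylation_flag:0
```

The simulator writes truth tables (`sim.truth_snps.tsv`,
`sim.truth_meth.tsv`, `sim.truth_reads.tsv`) so every number above can
be checked against the planted ground truth.

## Layout

| module | contents |
|---|---|
| `epibis.reference` | packed genome, C-less/G-less FM-indexes, persistence |
| `epibis.align` | seeding, chaining, asymmetric extension DP, MAPQ, pairing, duplicates, SAM |
| `epibis.calling` | pileup, six-letter support, genotyping, methylation, VCF/BED, SNP filter |
| `epibis.epibed` | RLE encode/decode, mate merge, matrix export, ASM test |
| `epibis.qc` | retention by context, M-bias, background conversion, read filtering |
| `epibis.bisim` | diploid genome / methylation / read simulator with truth tables |
| `epibis.cli` | `epibis index / align / pileup / vcf2bed / filter-snps / epibed / asm / qc / simulate` |

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
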