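# Methods

This note documents the models, conventions and deliberate design
choices behind `epibis`, in the spirit of a methods supplement: what is
computed, under which assumptions, and what the bundled simulations do
and do not demonstrate.

## Reference representation and indexing

The 4-base genome is stored 2-bit packed with a separate N mask;
unpacking is exact, including N positions. Two FM-indexes are built,
each over the concatenation of the forward and reverse strands of the
genome: the C-less index applies C→T to both strands, the G-less index
G→A. After conversion the two indexed texts are exact reverse
complements of one another, so running plain backward search on both
indexes is equivalent in result set to a bidirectional search on one
index; we chose the two-index realization for its simplicity. Each
strand of the concatenation is terminated by its own sentinel, ordered
before all bases. N bases and contig junctions are represented in the
indexed text by a separator symbol that can never match a query, so
seeds cannot cross an N run or a contig boundary; the packed 4-base
reference retains N.

The suffix array is built by prefix doubling (O(n log² n), vectorized),
appropriate at the desk scales this package targets; construction is
pluggable. Suffix-array samples are kept at text positions divisible by
the sampling step (default 4) and occurrence counts are checkpointed
every 64 BWT symbols; both are configurable and provably do not affect
any query result, only the time/memory trade-off (this invariance is
tested for steps {1, 4, 32}).

## Strand chemistry and search copies

Four bisulfite strand identities exist: the original top and bottom
strands (OT, OB) and their PCR complements (CTOT, CTOB). What matters
downstream is the *reference-space conversion sense*: OT and CTOT
alignments show C→T against the top-strand reference, OB and CTOB show
G→A. The C→T copy of a read finds OT as forward hits and OB as
reverse-strand hits of the C-less index; the G→A copy finds CTOB
(forward) and CTOT (reverse) in the G-less index. Directional libraries
constrain mate 1 to the C→T copy and mate 2 to the G→A copy;
non-directional mode searches both copies for every read. After
alignment the conversion sense is reassessed from the observed
ref-C/read-T vs ref-G/read-A counts; ties (including zero evidence)
keep the seeding tag and set an ambiguity flag.

## Seeding, chaining, extension

Seeds are maximal exact matches (default minimum 19 bp) between a
converted read copy and the matching index, found by greedy
right-to-left backward search: each match is extended as far left as
possible and the search restarts immediately left of the failing
position. This finds the full seed set for reads with isolated
mismatches; it is not a complete SMEM enumeration in highly repetitive
contexts, a deliberate simplification at desk scale.

Located seeds are filtered for compatibility with the original 4-base
genome *before* chaining: every position must be an exact match or a
strand-consistent conversion (ref C/read T for OT/CTOT; ref G/read A
for OB/CTOB). A seed violating this at isolated positions (e.g. a
sequencing error that happens to agree with the converted genome but
not the original) is split into its compatible runs rather than
discarded, which preserves sensitivity to reads carrying such errors.
Compatible seeds are chained by genomic proximity (same contig, strand
and conversion tag; reference gap ≤ 100 bp; diagonal drift ≤ band
width), and a chain scores the read coverage of its seeds after overlap
trimming. Up to `max_top_chains` chains (default 50) are extended, and
at most `max_total_chains` (default 200) are examined.

Extension runs against the original 4-base bases with the asymmetric
substitution matrix (match +1, mismatch −4, conversion-consistent pairs
+1, anything involving N scores 0; gap of length k costs 6 + k).
A gap-free placement on the chain diagonal is accepted when every
position is compatible — its score then provably equals the DP optimum —
otherwise a banded affine-gap local DP (Gotoh) is run on a window
around the projected placement. The DP vectorizes each row with a
prefix-max identity for the horizontal gap state that is equivalent to
the standard Gotoh recurrence (every gap chain originates at a non-gap
cell); equality with an independent exhaustive implementation is
asserted over hundreds of randomized windows with planted indels.
Unextended read ends become soft clips. NM excludes
conversion-consistent differences (they are not genetic distance); a
separate tag (`ZC`) carries the conversion count.

MAPQ is 0 whenever two or more placements share the best score — the
one hard behavioural constraint — and otherwise
round(60·(best − second)/best), clamped to [0, 60], with second = 0 for
a unique hit. The gap-ratio formula is this package's declared
convention: monotone in the score gap and deterministic.

Paired-end alignment scores mate combinations with a proper-pair bonus
when the pair is FR-oriented, on one contig, conversion-consistent
(OT+CTOT or OB+CTOB) and within mean ± 4 SD of the insert model.
Pairing is never forced: mates without a consistent combination are
reported at their own best placements with the proper-pair flag unset,
which is what tolerates chimeric inserts from pre-amplification
protocols.

Duplicate marking uses only coordinates — contig, unclipped 5′ position
of each mate, orientation and bisulfite tag — never base content, so
differing conversion (methylation) patterns cannot split a duplicate
group; the highest total base-quality record per signature survives.

## Joint calling

Pileup excludes unmapped, secondary, duplicate, MAPQ < 40 records and
bases under Q20 (all configurable). Overlapping mates contribute one
observation per position: agreement keeps the better quality, a base
disagreement is adjudicated by base quality and dropped on a tie. The
epiBED mate merge applies the same rule (any in-overlap disagreement is
conflict-filtered to F), which makes matrix column sums equal pileup
betas exactly when base qualities are flat; with heterogeneous
qualities the pileup may keep a higher-quality base where the merge
filters, a documented, deliberate divergence.

Six-letter support maps T-on-C→T-strand observations to Y and
A-on-G→A-strand observations to R; the four reduction rules (stated in
the module docstring, R handled mirror-wise) move that ambiguous mass
onto {A,C,G,T} only when opposite-strand or unconverted evidence — or
the reference base — justifies it. "Unambiguous evidence" means at
least one reduced-alphabet read (threshold configurable). Reduction is
conservative by construction: C/T heterozygotes are genotyped from the
unambiguous strand only, so their recall at fixed depth is at most that
of, say, A/T sites — an asymmetry inherent to the chemistry.

The genotype model treats each reduced count as independent
observations with per-read likelihood
P(b | g=a₁/a₂) = (1−c)·½[P(b|a₁)+P(b|a₂)] + c·P(b|ref), where
P(b|a) = 1−e if b=a else e/3. Priors over the 10 diploid states:
hom-ref 1 − 3θ/2, each ref/alt het θ, each hom-alt θ/2, each alt/alt
het θ² (normalized). GQ = −10·log₁₀(1 − max posterior), capped at 99.
The mixture likelihood and the θ-based priors are declared conventions
of this package (defaults e = 0.01, c = 0, θ = 10⁻³).

Methylation: a reference C is informed only by C→T-class reads
(retained C / converted T), a reference G only by G→A-class reads.
WGBS contexts are CpG, CpA, CpC, CpT from the adjacent base on the
informative strand. NOMe-seq: GCH sites feed the accessibility channel,
HCG the methylation channel, GCG is excluded as ambiguous, and CCG is
retained but flagged so users can filter the small off-target
methyltransferase effect post hoc. CpG dyads may be destranded
(`destrand_cpg`), the conventional reporting unit, summing the two
strands' counts.

The two-tier variant filter drops GQ ≤ 5, hom-ref and (optionally)
non-canonical-contig records, then keeps records outside the exclusion
intervals that either intersect a common-SNP interval with MAF ≥ 0.05
and have GQ ≥ 15, or otherwise have GQ ≥ 60.

## Conversion QC

Retention is classified per informative-strand cytosine observation
into CpG/CpA/CpC/CpT with per-read-position arrays (M-bias) split by
mate. The background non-conversion rate is the pooled CpC+CpT
retention; the CpA-methylation flag fires when the 99% Clopper–Pearson
lower bound of CpA retention exceeds the 99% upper bound of the pooled
background, so with no CpA methylation the flag fires with probability
on the order of 10⁻⁴ per dataset while a true CpA level of 0.05 at
10× on a 10 kb genome separates the intervals essentially always.
The failed-conversion read filter removes reads showing ≥ 3 CpH
cytosines with > 2 retained (both thresholds configurable; declared
conventions, as is the CI-separation rule).

## The simulator and what passing tests show

`bisim` emulates: an i.i.d. random genome at a set GC fraction (default
0.42); SNPs planted at rate 10⁻³, heterozygous with probability 0.5,
assigned to one of two haplotypes; per-cytosine methylation betas drawn
from Beta(mk, (1−m)k) with context means (CpG 0.7, CpH 0 by default)
and concentration k = 0.2 — strongly bimodal, as real methylomes are —
with the two cytosines of a CpG dyad sharing one beta (CpG methylation
is strand-symmetric in vivo); per-molecule Bernoulli methylation
states; conversion of unmethylated cytosines at rate 0.98 on the
molecule's strand; i.i.d. sequencing error 10⁻³; paired 100 bp reads at
30× with a Normal(300, 30) insert; directional or non-directional
strand assignment; optional chimeric mate-2 and exact-copy duplicate
injection. One RNG stream keyed by the mandatory seed makes output
byte-reproducible. Quality strings are constant Q37.

Not emulated: indels (the extension DP is instead verified directly
against an exhaustive oracle), PCR/optical duplicate families beyond
exact copies, quality-dependent or context-dependent error profiles,
M-bias artifacts, CNVs, and methylation on SNP-created cytosines
(simulated unmethylated). Consequently the end-to-end recovery results
(≥ 99% placement, CpG beta MAE ≤ 0.05 at destranded depth ≥ 10, hom-alt
SNP recall/precision ≥ 0.95 after the two-tier filter) demonstrate
internal correctness of the pipeline under idealized error models, not
performance on real libraries with adapter contamination, biased
conversion or repetitive genomes.

Problem sizes used by the shipped checks were chosen for a desk-scale
package: the headline simulation is 100 kb at 30× (15,000 pairs), the
FM-index cross-validation uses 20 genomes up to 10 kb with 1000
patterns each, the DP oracle 500 windows up to 80 bp, and the QC flag
calibration 100 + 100 seeded 10 kb runs at 10×.

## Numerical and tie-breaking conventions

Internal coordinates are 0-based; SAM is 1-based and BED half-open at
serialization only. Candidate ordering is everywhere
(score desc, contig index asc, position asc, bisulfite tag lexical),
making all outputs deterministic without any RNG in the aligner.
Genotype posteriors are computed in log space and renormalized;
posterior sums are asserted to 10⁻⁹. Zero-depth columns yield missing
genotypes; beta values are undefined (and withheld) below the depth
threshold. Degenerate beta means (0 or 1) bypass the Beta sampler and
are exact.

## Known limitations

* The suffix-array builder and occurrence table are dense; genome-scale
  (GB) indexing would need compressed structures out of scope here.
* Chimeric mates are reported as two independent alignments; no
  split/supplementary (SA-tag) records are emitted.
* Somatic (tumor/normal) genotyping, indel calling and CNV estimation
  are out of scope; the VCF FILTER column is reserved.
* The epiBED insertion side-field is an in-memory attribute, not part
  of the serialized dialect (version 1.0).
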