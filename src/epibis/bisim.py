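"""Synthetic bisulfite-sequencing data with full truth tables.

The simulator emulates a diploid genome with planted SNPs, per-cytosine
methylation levels drawn per dinucleotide context, strand-specific
bisulfite conversion of unmethylated cytosines, sequencing error, and
paired-end reads with a configurable insert-size model.  Directional
libraries emit OT/OB molecules (mate 1 from the converted strand, mate 2
its PCR complement); non-directional mode makes all four strand tags
equally likely by swapping the mates at random.  An optional chimera rate
replaces mate 2 with a read from an unrelated locus, and a duplicate rate
re-emits exact copies for duplicate-marking tests.

All randomness comes from one ``numpy.random.default_rng`` stream keyed by
``rng_seed``; identical configurations are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    Reference, PackedReference, encode_bases, decode_bases, revcomp,
    REF_A, REF_C, REF_G, REF_T,
)
from .align import OT, OB, CTOT, CTOB, AlignmentResult, Read

_BASES = "ACGT"
CONTEXTS = ("CpG", "CpA", "CpC", "CpT")


@dataclass
class SimConfig:
    genome_length: int = 100_000
    contig_count: int = 1
    gc_fraction: float = 0.42
    snp_rate: float = 1e-3
    het_fraction: float = 0.5
    meth_cpg: float = 0.7
    meth_cpa: float = 0.0
    meth_cpc: float = 0.0
    meth_cpt: float = 0.0
    meth_gpc: float | None = None   # NOMe accessibility channel, optional
    beta_concentration: float = 0.2
    conversion_rate: float = 0.98
    sequencing_error_rate: float = 0.001
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 30.0
    mode: str = "directional"
    chimera_rate: float = 0.0
    dup_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "snp_rate", "het_fraction", "meth_cpg",
                     "meth_cpa", "meth_cpc", "meth_cpt", "conversion_rate",
                     "sequencing_error_rate", "chimera_rate", "dup_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")

    def context_mean(self, context: str) -> float:
        return {"CpG": self.meth_cpg, "CpA": self.meth_cpa,
                "CpC": self.meth_cpc, "CpT": self.meth_cpt}[context]


@dataclass
class TruthTables:
    snps: pd.DataFrame        # contig,pos0,ref,alt,genotype
    cytosines: pd.DataFrame   # contig,pos0,strand,context,beta
    reads: pd.DataFrame       # name,mate,contig,pos0,strand,bs_strand,chimeric,duplicate_of


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random genome + planted SNP truth.  Returns (Reference, snp table)."""
    rng = rng or np.random.default_rng(config.rng_seed)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = config.genome_length // config.contig_count
    contigs = []
    snp_rows = []
    for ci in range(config.contig_count):
        n = per if ci < config.contig_count - 1 else config.genome_length - per * (config.contig_count - 1)
        codes = rng.choice(4, size=n, p=p).astype(np.uint8)
        name = f"chr{ci + 1}"
        contigs.append((name, decode_bases(codes)))
        is_snp = rng.random(n) < config.snp_rate
        for pos in np.flatnonzero(is_snp):
            ref_b = _BASES[codes[pos]]
            alt_b = _BASES[(codes[pos] + rng.integers(1, 4)) % 4]
            het = rng.random() < config.het_fraction
            snp_rows.append((name, int(pos), ref_b, alt_b, "het" if het else "hom"))
    snps = pd.DataFrame(snp_rows, columns=["contig", "pos0", "ref", "alt", "genotype"])
    return Reference(tuple(contigs)), snps


def _haplotypes(ref: Reference, snps: pd.DataFrame, rng: np.random.Generator):
    """Two haplotype code arrays per contig (het alt assigned to one of them)."""
    haps = {}
    for name, seq in ref.contigs:
        codes = encode_bases(seq)
        h0, h1 = codes.copy(), codes.copy()
        for row in snps[snps.contig == name].itertuples():
            alt = encode_bases(row.alt)[0]
            if row.genotype == "hom":
                h0[row.pos0] = alt
                h1[row.pos0] = alt
            else:
                (h0 if rng.random() < 0.5 else h1)[row.pos0] = alt
        haps[name] = (h0, h1)
    return haps


def assign_methylation(config: SimConfig, ref: Reference,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cytosine (both strands) true beta drawn Beta(mean*k, (1-mean)*k).

    Context is assessed on the reference strand carrying the cytosine:
    a '+' row is a reference C classified by the next base, a '-' row is a
    reference G classified by the complemented previous base.  Degenerate
    means (0 or 1) yield exact betas.

    CpG methylation is strand-symmetric, as in real methylomes: the two
    cytosines of a CpG dyad (top C at p, bottom C at p+1) share a single
    beta draw.  The default concentration (0.2) makes CpG betas strongly
    bimodal, again matching real methylomes.  CpH draws are independent.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    k = config.beta_concentration
    rows = []
    dyad_beta: dict[tuple[str, int], float] = {}
    for name, seq in ref.contigs:
        codes = encode_bases(seq)
        n = len(codes)
        nxt = np.append(codes[1:], REF_A)
        prv = np.append(REF_A, codes[:-1])
        for strand in "+-":
            if strand == "+":
                positions = np.flatnonzero(codes == REF_C)
                partner = nxt[positions]
                ctx = np.select(
                    [partner == REF_G, partner == REF_A, partner == REF_C],
                    ["CpG", "CpA", "CpC"], default="CpT")
            else:
                positions = np.flatnonzero(codes == REF_G)
                partner = prv[positions]
                ctx = np.select(
                    [partner == REF_C, partner == REF_T, partner == REF_G],
                    ["CpG", "CpA", "CpC"], default="CpT")
            for pos, c in zip(positions, ctx):
                pos = int(pos)
                mean = config.context_mean(c)
                dyad = None
                if c == "CpG":
                    # top C at p and bottom C at p+1 form one dyad
                    dyad = (name, pos) if strand == "+" else (name, pos - 1)
                if dyad is not None and dyad in dyad_beta:
                    beta = dyad_beta[dyad]
                elif mean <= 0.0:
                    beta = 0.0
                elif mean >= 1.0:
                    beta = 1.0
                else:
                    beta = float(rng.beta(mean * k, (1 - mean) * k))
                if dyad is not None:
                    dyad_beta[dyad] = beta
                rows.append((name, pos, strand, c, beta))
    df = pd.DataFrame(rows, columns=["contig", "pos0", "strand", "context", "beta"])
    return df.sort_values(["contig", "pos0", "strand"]).reset_index(drop=True)


def _convert_molecule(top_codes: np.ndarray, start: int, beta_plus: dict,
                      beta_minus: dict, bs: str, conversion_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Bisulfite-convert one molecule; returns the strand sequence 5'->3'."""
    if bs == OT:
        strand_seq = top_codes.copy()
        c_idx = np.flatnonzero(strand_seq == REF_C)
        betas = np.array([beta_plus.get(start + int(i), 0.0) for i in c_idx])
    else:  # OB: bottom strand
        strand_seq = encode_bases(revcomp(decode_bases(top_codes)))
        c_idx = np.flatnonzero(strand_seq == REF_C)
        top_pos = start + len(top_codes) - 1 - c_idx
        betas = np.array([beta_minus.get(int(p), 0.0) for p in top_pos])
    if len(c_idx):
        methylated = rng.random(len(c_idx)) < betas
        converted = ~methylated & (rng.random(len(c_idx)) < conversion_rate)
        strand_seq[c_idx[converted]] = REF_T
    return strand_seq


def _apply_error(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    err = rng.random(len(codes)) < rate
    if err.any():
        codes = codes.copy()
        codes[err] = (codes[err] + rng.integers(1, 4, int(err.sum()))) % 4
    return codes


def simulate_reads(config: SimConfig, ref: Reference, meth: pd.DataFrame,
                   snps: pd.DataFrame, rng: np.random.Generator | None = None):
    """Paired-end FASTQ records + per-read truth.

    Returns (r1_records, r2_records, reads_truth) where each record is a
    (name, sequence, quality) tuple.  Pair count is
    round(genome_length * depth / (2 * read_length)).
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    haps = _haplotypes(ref, snps, rng)
    beta_plus: dict[str, dict[int, float]] = {}
    beta_minus: dict[str, dict[int, float]] = {}
    for row in meth.itertuples():
        d = beta_plus if row.strand == "+" else beta_minus
        d.setdefault(row.contig, {})[row.pos0] = row.beta
    names = [n for n, _ in ref.contigs]
    lengths = np.array([len(s) for _, s in ref.contigs], dtype=float)
    contig_p = lengths / lengths.sum()
    rl = config.read_length
    n_pairs = int(round(config.genome_length * config.depth / (2 * rl)))
    qual = "F" * rl  # Phred 37

    r1_out, r2_out, truth = [], [], []

    def draw_fragment():
        ci = int(rng.choice(len(names), p=contig_p))
        name = names[ci]
        L = int(lengths[ci])
        frag = int(np.clip(round(rng.normal(config.insert_mean, config.insert_sd)), rl, L))
        start = int(rng.integers(0, L - frag + 1))
        hap = haps[name][int(rng.integers(0, 2))]
        bs = OT if rng.random() < 0.5 else OB
        top = hap[start: start + frag]
        strand_seq = _convert_molecule(top, start, beta_plus.get(name, {}),
                                       beta_minus.get(name, {}), bs,
                                       config.conversion_rate, rng)
        return name, start, frag, bs, strand_seq

    for i in range(n_pairs):
        name, start, frag, bs, strand_seq = draw_fragment()
        m1 = strand_seq[:rl]
        m2 = encode_bases(revcomp(decode_bases(strand_seq[-rl:])))
        if bs == OT:
            t1 = (name, start, "+", OT)
            t2 = (name, start + frag - rl, "-", CTOT)
        else:
            t1 = (name, start + frag - rl, "-", OB)
            t2 = (name, start, "+", CTOB)
        chimeric = False
        if config.chimera_rate and rng.random() < config.chimera_rate:
            cname, cstart, cfrag, cbs, cseq = draw_fragment()
            m2 = encode_bases(revcomp(decode_bases(cseq[-rl:])))
            t2 = ((cname, cstart + cfrag - rl, "-", CTOT) if cbs == OT
                  else (cname, cstart, "+", CTOB))
            chimeric = True
        if config.mode == "non_directional" and rng.random() < 0.5:
            m1, m2 = m2, m1
            t1, t2 = t2, t1
        m1 = _apply_error(m1, config.sequencing_error_rate, rng)
        m2 = _apply_error(m2, config.sequencing_error_rate, rng)
        rname = f"sim{i}"
        r1_out.append((rname, decode_bases(m1), qual))
        r2_out.append((rname, decode_bases(m2), qual))
        truth.append((rname, 1, *t1, chimeric, ""))
        truth.append((rname, 2, *t2, chimeric, ""))
        if config.dup_rate and rng.random() < config.dup_rate:
            dname = f"sim{i}d"
            r1_out.append((dname, decode_bases(m1), qual))
            r2_out.append((dname, decode_bases(m2), qual))
            truth.append((dname, 1, *t1, chimeric, rname))
            truth.append((dname, 2, *t2, chimeric, rname))

    reads = pd.DataFrame(truth, columns=["name", "mate", "contig", "pos0",
                                         "strand", "bs_strand", "chimeric",
                                         "duplicate_of"])
    return r1_out, r2_out, reads


def simulate(config: SimConfig):
    """Full simulation: genome, methylation truth, reads.

    Returns (Reference, TruthTables, r1_records, r2_records).  Draws are
    made from a single stream in this documented order: genome+SNPs,
    methylation betas, haplotype assignment, then reads.
    """
    rng = np.random.default_rng(config.rng_seed)
    ref, snps = simulate_genome(config, rng)
    meth = assign_methylation(config, ref, rng)
    r1, r2, reads = simulate_reads(config, ref, meth, snps, rng)
    return ref, TruthTables(snps, meth, reads), r1, r2


def write_fastq(records, path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header[1:].split()[0], seq, qual))
    return out


def truth_alignments(config: SimConfig):
    """Reads placed at their true positions as AlignmentResult records.

    Bypasses the aligner: used to exercise pileup/QC/epiBED on inputs whose
    placements are exact by construction.  Mate records carry proper-pair
    flags and full-length match CIGARs (the simulator plants no indels).
    """
    ref, truth, r1, r2 = simulate(config)
    packed = PackedReference.from_reference(ref)
    rl = config.read_length
    by_key = {(row.name, row.mate): row for row in truth.reads.itertuples()}
    out = []
    for mate, records in ((1, r1), (2, r2)):
        for name, seq, qual in records:
            row = by_key[(name, mate)]
            if row.strand == "-":
                seq = revcomp(seq)
            flag = 1 | 2 | (64 if mate == 1 else 128)
            if row.strand == "-":
                flag |= 16
            else:
                flag |= 32
            other = by_key[(name, 3 - mate)]
            aln = AlignmentResult(
                read_name=name, contig=row.contig, pos0=int(row.pos0),
                cigar=f"{rl}M", genome_strand=row.strand, bs_strand=row.bs_strand,
                score=rl, suboptimal_score=0, n_equal_best=1, mapq=60,
                nm=0, conversions=0, sequence=seq,
                qualities=np.full(rl, 37, dtype=np.int16), mate=mate, flag=flag,
                mate_contig=other.contig, mate_pos0=int(other.pos0),
            )
            out.append(aln)
    out.sort(key=lambda a: (a.contig, a.pos0))
    return packed, truth, out
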