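"""Joint SNP + methylation pileup calling with VCF/BED emission.

Calling from converted reads is ambiguous: a read T on the C->T-converted
strand may be a genetic T or a converted (unmethylated) C, and a read A on
the G->A strand may be an A or a converted G.  The pileup therefore counts
base support over a six-letter alphabet {A,C,G,T,R,Y}: Y replaces a T seen
on an OT/CTOT read, R replaces an A seen on an OB/CTOB read.  Four
conservative rules then redistribute the ambiguous Y (mirror-wise R) mass
onto the four-letter alphabet:

1. unambiguous evidence for exactly one of {C,T}: Y is added to that base;
2. unambiguous evidence for both: Y is ignored;
3. no unambiguous evidence and the reference is not C/T: Y is ignored;
4. no unambiguous evidence and the reference is C or T: Y is added to the
   reference allele.

Genotypes come from a Bayesian model over the 10 diploid states with a
per-observation mixture likelihood parameterized by the sequencing error
rate e, the contamination rate c and the polymorphism rate theta.

Methylation is extracted per cytosine on its informative strand only
(OT-class reads inform reference C positions, OB-class reads inform
reference G positions) with the beta value M/(M+U).  NOMe-seq assays split
cytosines into HCG (endogenous methylation), GCH (accessibility), GCG
(ambiguous, excluded) and CCG (retained but flagged for post-hoc
filtering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Iterator

import numpy as np

from .reference import PackedReference, REF_A, REF_C, REF_G, REF_T, REF_N, encode_bases
from .align import AlignmentResult, parse_cigar, converts_c_to_t, ZS_TO_TAG

SIX_LETTERS = ("A", "C", "G", "T", "R", "Y")
FOUR_LETTERS = ("A", "C", "G", "T")
GENOTYPES = tuple("".join(g) for g in combinations_with_replacement("ACGT", 2))

WGBS_CONTEXTS = ("CpG", "CpA", "CpC", "CpT")


@dataclass
class PileupParams:
    min_mapq: int = 40
    min_baseq: int = 20
    min_depth: int = 1


@dataclass
class Observation:
    base: str
    baseq: int
    bs_strand: str
    mate: int
    read_name: str


@dataclass
class PileupColumn:
    contig: str
    pos0: int
    ref_base: str
    observations: list[Observation]

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class AlleleSupport:
    counts: dict[str, float] = field(default_factory=lambda: {b: 0.0 for b in SIX_LETTERS})

    def total(self) -> float:
        return sum(self.counts.values())


@dataclass
class GenotypeParams:
    error_rate: float = 0.01
    contamination: float = 0.0
    theta: float = 1e-3

    def __post_init__(self):
        for v in (self.error_rate, self.contamination, self.theta):
            if not (0.0 <= v < 1.0):
                raise ValueError("rates must be in [0, 1)")


@dataclass
class GenotypeCall:
    genotype: str | None       # e.g. "AG"; None = missing
    gq: int
    log_likelihoods: dict[str, float]
    posteriors: dict[str, float]
    depth: int

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype is None or len(set(self.genotype)) == 1 and self.genotype[0] == self._ref

    _ref: str = "N"


@dataclass
class CytosineCall:
    contig: str
    pos0: int
    strand: str
    context: str          # CpG/CpA/CpC/CpT or HCG/GCH
    retained: int
    converted: int
    flags: tuple[str, ...] = ()

    @property
    def depth(self) -> int:
        return self.retained + self.converted

    @property
    def beta(self) -> float | None:
        d = self.depth
        return self.retained / d if d else None


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def _iter_aligned_columns(pos0: int, cigar: str) -> Iterator[tuple[int, int]]:
    """Yield (ref_pos0, read_index) over M ops of an alignment record."""
    i = 0
    j = pos0
    for length, op in parse_cigar(cigar):
        if op == "M":
            for k in range(length):
                yield j + k, i + k
            i += length
            j += length
        elif op in ("I", "S"):
            i += length
        elif op == "D":
            j += length


def _record_fields(rec):
    """Uniform access for AlignmentResult and pysam.AlignedSegment."""
    if isinstance(rec, AlignmentResult):
        quals = rec.qualities
        return (rec.contig, rec.pos0, rec.cigar, rec.sequence,
                quals, rec.bs_strand, rec.mapq, rec.flag, rec.read_name,
                rec.mate or 0)
    # pysam record
    if rec.is_unmapped:
        return (None,) * 10
    tag = ZS_TO_TAG.get(rec.get_tag("ZS") if rec.has_tag("ZS") else "++", "OT")
    mate = 1 if rec.is_read1 else (2 if rec.is_read2 else 0)
    return (rec.reference_name, rec.reference_start, rec.cigarstring,
            rec.query_sequence, np.asarray(rec.query_qualities),
            tag, rec.mapping_quality, rec.flag, rec.query_name, mate)


def pileup(records: Iterable, packed: PackedReference,
           params: PileupParams | None = None) -> Iterator[PileupColumn]:
    """Pileup columns over all covered positions, sorted by coordinate.

    Excludes unmapped, duplicate-flagged, MAPQ < min_mapq records and
    bases below min_baseq; overlapping mates of a pair contribute at most
    one observation per position (higher base quality wins).
    """
    params = params or PileupParams()
    by_contig: dict[str, dict[int, dict]] = {}
    for rec in records:
        contig, pos0, cigar, seq, quals, bs, mapq, flag, name, mate = _record_fields(rec)
        if contig is None or flag & (4 | 256 | 1024 | 2048):
            continue
        if mapq < params.min_mapq:
            continue
        cols = by_contig.setdefault(contig, {})
        for rpos, qidx in _iter_aligned_columns(pos0, cigar):
            q = int(quals[qidx])
            if q < params.min_baseq:
                continue
            obs = Observation(seq[qidx], q, bs, mate, name)
            slot = cols.setdefault(rpos, {})
            if name in slot:
                prev = slot[name]
                # mate overlap: agreement keeps the better quality; a base
                # disagreement is adjudicated by quality, or dropped on a
                # tie (no way to tell which mate erred)
                if prev is None:
                    continue
                if obs.base == prev.base:
                    if obs.baseq > prev.baseq:
                        slot[name] = obs
                elif obs.baseq > prev.baseq:
                    slot[name] = obs
                elif obs.baseq == prev.baseq:
                    slot[name] = None
            else:
                slot[name] = obs
    for contig in sorted(by_contig):
        ref_codes = packed.codes(contig)
        for pos0 in sorted(by_contig[contig]):
            obs = [o for o in by_contig[contig][pos0].values() if o is not None]
            if not obs:
                continue
            ref_base = "ACGTN"[ref_codes[pos0]]
            yield PileupColumn(contig, pos0, ref_base, obs)


# ---------------------------------------------------------------------------
# six-letter support and reduction
# ---------------------------------------------------------------------------

def sixletter_base(base: str, bs_strand: str) -> str:
    """Map one observation to the six-letter support alphabet."""
    if converts_c_to_t(bs_strand) and base == "T":
        return "Y"
    if not converts_c_to_t(bs_strand) and base == "A":
        return "R"
    return base


def sixletter_support(column: PileupColumn) -> AlleleSupport:
    sup = AlleleSupport()
    for o in column.observations:
        b = sixletter_base(o.base, o.bs_strand)
        if b in sup.counts:
            sup.counts[b] += 1
    return sup


def reduce_support(support: AlleleSupport, ref_base: str) -> dict[str, float]:
    """Apply the four Y-redistribution rules (and their R mirror)."""
    out = {b: support.counts.get(b, 0.0) for b in FOUR_LETTERS}

    def redistribute(amb: str, pair: tuple[str, str]):
        mass = support.counts.get(amb, 0.0)
        if mass <= 0:
            return
        a, b = pair
        has_a, has_b = out[a] > 0, out[b] > 0
        if has_a != has_b:                      # rule 1
            out[a if has_a else b] += mass
        elif has_a and has_b:                   # rule 2
            pass
        elif ref_base in pair:                  # rule 4
            out[ref_base] += mass
        # rule 3: ignored

    redistribute("Y", ("C", "T"))
    redistribute("R", ("A", "G"))
    return out


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def _genotype_priors(ref_base: str, theta: float) -> dict[str, float]:
    """Declared prior convention: hom-ref 1-3theta/2, ref het theta,
    hom-alt theta/2, non-ref het theta^2; normalized."""
    pri = {}
    for g in GENOTYPES:
        a, b = g
        n_ref = (a == ref_base) + (b == ref_base)
        if n_ref == 2:
            pri[g] = 1 - 1.5 * theta
        elif n_ref == 1:
            pri[g] = theta
        elif a == b:
            pri[g] = theta / 2
        else:
            pri[g] = theta * theta
    z = sum(pri.values())
    return {g: p / z for g, p in pri.items()}


def genotype(reduced: dict[str, float], ref_base: str,
             params: GenotypeParams | None = None) -> GenotypeCall:
    """Posterior over the 10 diploid genotypes from reduced base counts.

    Per-observation likelihood of base b under genotype g = a1/a2:
    (1-c) * mean_i P(b | a_i) + c * P(b | ref) with P(b | a) = 1-e for
    b == a and e/3 otherwise.  GQ = -10 log10(1 - max posterior), capped
    at 99.
    """
    params = params or GenotypeParams()
    depth = int(round(sum(reduced.values())))
    if depth == 0 or ref_base not in FOUR_LETTERS:
        return GenotypeCall(None, 0, {}, {}, 0)
    e, c = params.error_rate, params.contamination

    def p_base(b: str, a: str) -> float:
        return 1 - e if b == a else e / 3

    logl = {}
    for g in GENOTYPES:
        a1, a2 = g
        ll = 0.0
        for b, cnt in reduced.items():
            if cnt <= 0:
                continue
            p = (1 - c) * 0.5 * (p_base(b, a1) + p_base(b, a2)) + c * p_base(b, ref_base)
            ll += cnt * math.log(max(p, 1e-300))
        logl[g] = ll
    priors = _genotype_priors(ref_base, params.theta)
    logpost = {g: logl[g] + math.log(priors[g]) for g in GENOTYPES}
    mx = max(logpost.values())
    weights = {g: math.exp(v - mx) for g, v in logpost.items()}
    z = sum(weights.values())
    post = {g: w / z for g, w in weights.items()}
    best = max(GENOTYPES, key=lambda g: (post[g], g))
    err = 1 - post[best]
    gq = 99 if err < 1e-10 else min(99, int(round(-10 * math.log10(max(err, 1e-300)))))
    call = GenotypeCall(best, max(gq, 0), logl, post, depth)
    call._ref = ref_base
    return call


# ---------------------------------------------------------------------------
# methylation / accessibility extraction
# ---------------------------------------------------------------------------

def _context_wgbs(ref_codes: np.ndarray, pos0: int, strand: str) -> str | None:
    n = len(ref_codes)
    if strand == "+":
        nxt = ref_codes[pos0 + 1] if pos0 + 1 < n else REF_N
        return {REF_G: "CpG", REF_A: "CpA", REF_C: "CpC", REF_T: "CpT"}.get(int(nxt))
    prv = ref_codes[pos0 - 1] if pos0 > 0 else REF_N
    # bottom-strand dinucleotide: complement of the previous top base
    return {REF_C: "CpG", REF_T: "CpA", REF_G: "CpC", REF_A: "CpT"}.get(int(prv))


def _context_nome(ref_codes: np.ndarray, pos0: int, strand: str):
    """(context, flags) for NOMe; context None when excluded/uninformative."""
    n = len(ref_codes)
    if strand == "+":
        before = int(ref_codes[pos0 - 1]) if pos0 > 0 else REF_N
        after = int(ref_codes[pos0 + 1]) if pos0 + 1 < n else REF_N
        g_before, g_after = before == REF_G, after == REF_G
        c_before = before == REF_C
    else:
        # bottom strand: 5' neighbour is the next top base complemented
        before = int(ref_codes[pos0 + 1]) if pos0 + 1 < n else REF_N
        after = int(ref_codes[pos0 - 1]) if pos0 > 0 else REF_N
        g_before, g_after = before == REF_C, after == REF_C
        c_before = before == REF_G
    if g_before and g_after:
        return None, ()          # GCG: ambiguous, excluded
    if g_before:
        return "GCH", ()         # accessibility channel
    if g_after:
        flags = ("CCG",) if c_before else ()
        return "HCG", flags      # methylation channel (CCG retained, flagged)
    return None, ()


def call_methylation(column: PileupColumn, packed: PackedReference,
                     assay: str = "WGBS", min_depth: int = 1) -> CytosineCall | None:
    """Cytosine methylation call from one pileup column, or None.

    Only strand-informative observations count: OT-class reads at reference
    C (retained C / converted T), OB-class reads at reference G (retained
    G / converted A).
    """
    ref_codes = packed.codes(column.contig)
    ref = int(ref_codes[column.pos0])
    if ref == REF_C:
        strand, retained_base, converted_base, want_ct = "+", "C", "T", True
    elif ref == REF_G:
        strand, retained_base, converted_base, want_ct = "-", "G", "A", False
    else:
        return None
    if assay.upper() == "NOME":
        context, flags = _context_nome(ref_codes, column.pos0, strand)
        if context is None:
            return None
    else:
        context = _context_wgbs(ref_codes, column.pos0, strand)
        flags = ()
        if context is None:
            return None
    retained = converted = 0
    for o in column.observations:
        if converts_c_to_t(o.bs_strand) != want_ct:
            continue
        if o.base == retained_base:
            retained += 1
        elif o.base == converted_base:
            converted += 1
    if retained + converted < min_depth:
        return None
    return CytosineCall(column.contig, column.pos0, strand, context,
                        retained, converted, flags)


def destrand_cpg(calls: Iterable[CytosineCall]) -> list[CytosineCall]:
    """Merge the two strands of each CpG dyad into one record.

    CpG methylation is palindromic, so the top-strand C at p and the
    bottom-strand C at p+1 measure the same dyad; merged records carry the
    top-strand coordinate, summed counts and strand '.'.  Non-CpG calls
    pass through unchanged.
    """
    merged: dict[tuple[str, int], CytosineCall] = {}
    out: list[CytosineCall] = []
    for c in calls:
        if c.context != "CpG":
            out.append(c)
            continue
        key = (c.contig, c.pos0 if c.strand == "+" else c.pos0 - 1)
        prev = merged.get(key)
        if prev is None:
            merged[key] = CytosineCall(c.contig, key[1], ".", "CpG",
                                       c.retained, c.converted, c.flags)
        else:
            merged[key] = CytosineCall(prev.contig, prev.pos0, ".", "CpG",
                                       prev.retained + c.retained,
                                       prev.converted + c.converted, prev.flags)
    out.extend(merged.values())
    out.sort(key=lambda c: (c.contig, c.pos0))
    return out


# ---------------------------------------------------------------------------
# VCF / BED emission
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=epibis
##INFO=<ID=CX,Number=1,Type=String,Description="Cytosine context">
##INFO=<ID=N5,Number=0,Type=Flag,Description="NOMe CCG context flag">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth after filters">
##FORMAT=<ID=SP,Number=1,Type=String,Description="Six-letter allele support A,C,G,T,R,Y">
##FORMAT=<ID=CV,Number=1,Type=Integer,Description="Converted cytosine count">
##FORMAT=<ID=RT,Number=1,Type=Integer,Description="Retained cytosine count">
"""


def _genotype_string(call: GenotypeCall, ref_base: str, alts: list[str]) -> str:
    if call.genotype is None:
        return "./."
    alleles = [ref_base] + alts
    idx = {a: i for i, a in enumerate(alleles)}
    return "/".join(str(idx[a]) for a in sorted(call.genotype))


@dataclass
class SiteRecord:
    contig: str
    pos0: int
    ref_base: str
    genotype_call: GenotypeCall | None
    support: AlleleSupport | None
    cytosine: CytosineCall | None


def call_sites(records, packed: PackedReference,
               pileup_params: PileupParams | None = None,
               genotype_params: GenotypeParams | None = None,
               assay: str = "WGBS") -> list[SiteRecord]:
    """Full joint caller: pileup -> support -> genotype + methylation."""
    out = []
    for col in pileup(records, packed, pileup_params):
        sup = sixletter_support(col)
        red = reduce_support(sup, col.ref_base)
        gcall = genotype(red, col.ref_base, genotype_params)
        meth = call_methylation(col, packed, assay)
        out.append(SiteRecord(col.contig, col.pos0, col.ref_base, gcall, sup, meth))
    return out


def write_vcf(sites: list[SiteRecord], packed: PackedReference, path,
              sample: str = "sample", emit_all: bool = False) -> None:
    """VCF 4.2 with genotype + cytosine records.

    By default emits sites that are non-hom-ref calls or cytosine context
    sites; ``emit_all`` writes every covered site.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for n, l in zip(packed.names, packed.lengths):
            fh.write(f"##contig=<ID={n},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for s in sites:
            g = s.genotype_call
            alts = []
            if g and g.genotype:
                alts = sorted(set(g.genotype) - {s.ref_base})
            is_variant = bool(alts)
            if not (is_variant or s.cytosine or emit_all):
                continue
            info = []
            if s.cytosine:
                info.append(f"CX={s.cytosine.context}")
                if "CCG" in s.cytosine.flags:
                    info.append("N5")
            fmt = ["GT", "GQ", "DP", "SP"]
            sup = ",".join(f"{b}{int(s.support.counts[b])}" for b in SIX_LETTERS) if s.support else "."
            vals = [
                _genotype_string(g, s.ref_base, alts) if g else "./.",
                str(g.gq if g and g.genotype else 0),
                str(g.depth if g else 0),
                sup,
            ]
            if s.cytosine:
                fmt += ["RT", "CV"]
                vals += [str(s.cytosine.retained), str(s.cytosine.converted)]
            fh.write("\t".join([
                s.contig, str(s.pos0 + 1), ".", s.ref_base,
                ",".join(alts) if alts else ".", ".", ".",
                ";".join(info) if info else ".",
                ":".join(fmt), ":".join(vals),
            ]) + "\n")


def vcf2bed(vcf_path, channel: str, min_depth: int = 1) -> list[tuple]:
    """Extract a BED channel from a pileup VCF.

    Channels: ``cg``/``ch`` (WGBS methylation by context), ``hcg``/``gch``
    (NOMe), emitting (chrom, start0, end, beta, depth); ``snp`` emitting
    (chrom, start0, end, ref, alt, GT, GQ) for non-hom-ref calls.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            sm = rec.samples[0]
            if channel == "snp":
                if not rec.alts:
                    continue
                gt = sm.get("GT")
                if gt is None or all(a in (0, None) for a in gt):
                    continue
                depth = sm.get("DP") or 0
                if depth < min_depth:
                    continue
                gt_str = "/".join(str(a) for a in gt)
                out.append((rec.chrom, rec.pos - 1, rec.pos, rec.ref,
                            ",".join(rec.alts), gt_str, sm.get("GQ")))
            else:
                cx = rec.info.get("CX")
                if cx is None:
                    continue
                wanted = {
                    "cg": {"CpG"}, "ch": {"CpA", "CpC", "CpT"},
                    "hcg": {"HCG"}, "gch": {"GCH"},
                }[channel]
                if cx not in wanted:
                    continue
                rt, cv = sm.get("RT"), sm.get("CV")
                if rt is None or cv is None:
                    continue
                depth = rt + cv
                if depth < min_depth or depth == 0:
                    continue
                out.append((rec.chrom, rec.pos - 1, rec.pos,
                            round(rt / depth, 6), depth))
    return out


def write_bed(rows: list[tuple], path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# dbSNP-prior variant filter
# ---------------------------------------------------------------------------

def read_bed_intervals(path):
    """BED -> {contig: IntervalTree}; fourth column (if any) kept as data."""
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            data = parts[3] if len(parts) > 3 else None
            trees.setdefault(chrom, IntervalTree()).addi(start, end, data)
    return trees


def filter_variants(vcf_path, out_path, common_snp_trees=None,
                    exclusion_trees=None, gq_common: int = 15,
                    gq_other: int = 60, maf_floor: float = 0.05,
                    gq_hard_floor: int = 5,
                    canonical_contigs: set[str] | None = None) -> int:
    """Two-tier genotype-quality filter with a common-SNP prior.

    Drops GQ <= hard floor, hom-ref and non-canonical-contig records, then
    keeps records outside the exclusion intervals that either intersect a
    common SNP (MAF >= maf_floor, from the BED name column when present)
    with GQ >= gq_common, or otherwise have GQ >= gq_other.  Returns the
    number of records written.
    """
    import pysam

    common_snp_trees = common_snp_trees or {}
    exclusion_trees = exclusion_trees or {}
    kept = 0
    with pysam.VariantFile(str(vcf_path)) as vcf, open(out_path, "w") as out:
        out.write(str(vcf.header))
        for rec in vcf:
            if not rec.alts:
                continue
            sm = rec.samples[0]
            gt = sm.get("GT")
            if gt is None or all(a in (0, None) for a in gt):
                continue
            gq = sm.get("GQ") or 0
            if gq <= gq_hard_floor:
                continue
            if canonical_contigs is not None and rec.chrom not in canonical_contigs:
                continue
            pos0 = rec.pos - 1
            excl = exclusion_trees.get(rec.chrom)
            if excl is not None and excl.overlaps(pos0, pos0 + 1):
                continue
            common = common_snp_trees.get(rec.chrom)
            in_common = False
            if common is not None:
                for iv in common.overlap(pos0, pos0 + 1):
                    maf = float(iv.data) if iv.data not in (None, "") else 1.0
                    if maf >= maf_floor:
                        in_common = True
                        break
            if (in_common and gq >= gq_common) or gq >= gq_other:
                out.write(str(rec))
                kept += 1
    return kept
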