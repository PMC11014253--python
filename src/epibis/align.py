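"""Seed-and-extend alignment of converted reads with asymmetric scoring.

The pipeline per read: in-silico convert (C->T and/or G->A copies), find
maximal exact matches of each copy in the matching 3-base FM-index, filter
the located seeds for compatibility with the 4-base genome, chain colinear
seeds, and extend the best chains against the original (4-base) reference
with a substitution matrix that allows conversion asymmetry: a read T may
align to a reference C (on the top conversion strand) and a read A to a
reference G (bottom strand) penalty free, but never the reverse.

Strand bookkeeping.  Four bisulfite strand identities exist: OT and OB
(the original top/bottom strands) and their PCR complements CTOT/CTOB.
What downstream code needs is the *reference-space* conversion sense of an
alignment: OT and CTOT alignments show C->T against the top-strand
reference, OB and CTOB show G->A.  The C->T read copy finds OT (forward
hits in the C-less index) and OB (reverse hits); the G->A copy finds CTOB
(forward hits in the G-less index) and CTOT (reverse).  In a directional
library mate 1 is searched with the C->T copy only and mate 2 with the
G->A copy; non-directional mode searches both copies for every mate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .reference import (
    REF_A, REF_C, REF_G, REF_T, REF_N,
    C_LESS, G_LESS, ConvertedIndex, GenomeIndex, PackedReference,
    encode_bases, decode_bases, revcomp_codes, _FM_FROM_REF,
)

# bisulfite strand tags and their SAM ZS values
OT, OB, CTOT, CTOB = "OT", "OB", "CTOT", "CTOB"
AMBIGUOUS = "AMBIGUOUS"
ZS_VALUE = {OT: "++", CTOT: "+-", OB: "-+", CTOB: "--"}
ZS_TO_TAG = {v: k for k, v in ZS_VALUE.items()}

CT_CLASS = frozenset({OT, CTOT})  # reference-space C->T conversions
GA_CLASS = frozenset({OB, CTOB})  # reference-space G->A conversions


def converts_c_to_t(bs_strand: str) -> bool:
    """True when the alignment's reference-space conversion sense is C->T."""
    return bs_strand in CT_CLASS


@dataclass(frozen=True)
class Read:
    name: str
    sequence: str
    qualities: np.ndarray  # Phred scores, same length
    mate: int | None = None  # 1, 2 or None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("|sequence| must equal |qualities|")
        if len(self.sequence) < 1:
            raise ValueError("read length must be >= 1")

    @classmethod
    def from_strings(cls, name: str, sequence: str, quality_string: str | None = None,
                     mate: int | None = None) -> "Read":
        if quality_string is None:
            quals = np.full(len(sequence), 37, dtype=np.int16)
        else:
            quals = np.frombuffer(quality_string.encode(), dtype=np.uint8).astype(np.int16) - 33
        return cls(name, sequence.upper(), quals, mate)


@dataclass
class ScoringParams:
    """Alignment knobs (BWA-MEM-style defaults, all configurable)."""

    match_score: int = 1
    mismatch_penalty: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    band_width: int = 100
    min_seed_len: int = 19
    max_top_chains: int = 50
    max_total_chains: int = 200
    max_xa_hits: int = 5
    max_chain_gap: int = 100
    max_seed_hits: int = 64
    proper_pair_bonus: int = 10

    def __post_init__(self):
        if self.mismatch_penalty < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("penalties must be >= 0")
        if self.min_seed_len < 10:
            raise ValueError("min_seed_len must be >= 10")


@dataclass(frozen=True)
class Seed:
    read_offset: int        # offset in the read as sequenced
    length: int
    contig: str
    ref_position0: int      # leftmost genome coordinate of the match
    genome_strand: str      # '+' or '-'
    bs_strand: str          # OT / OB / CTOT / CTOB

    def aligned_offset(self, read_len: int) -> int:
        """Offset of the seed within the reference-oriented read."""
        if self.genome_strand == "+":
            return self.read_offset
        return read_len - (self.read_offset + self.length)

    @property
    def diagonal(self) -> int:
        return self.ref_position0  # adjusted by caller with aligned offset


@dataclass
class SeedChain:
    seeds: list[Seed]
    contig: str
    genome_strand: str
    bs_strand: str
    score: int = 0


@dataclass
class AlignmentResult:
    read_name: str
    contig: str | None
    pos0: int               # 0-based leftmost; SAM pos1 at serialization
    cigar: str
    genome_strand: str
    bs_strand: str
    score: int
    suboptimal_score: int
    n_equal_best: int
    mapq: int
    nm: int                 # edit distance excluding allowed conversions
    conversions: int        # count of conversion-consistent differences
    sequence: str = ""      # reference-oriented sequence
    qualities: np.ndarray | None = None
    mate: int | None = None
    flag: int = 0
    alternates: list = field(default_factory=list)  # (contig, strand, pos0, cigar, nm)
    n_alternates: int = 0
    strand_ambiguous: bool = False
    mate_contig: str | None = None
    mate_pos0: int = -1
    tlen: int = 0
    is_duplicate: bool = False

    @property
    def mapped(self) -> bool:
        return self.contig is not None

    @property
    def pos1(self) -> int:
        return self.pos0 + 1

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    def reference_span(self) -> int:
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MD")


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


# ---------------------------------------------------------------------------
# read conversion and seeding
# ---------------------------------------------------------------------------

def convert_read(read: Read, mode: str = "directional") -> list[tuple[str, str, str]]:
    """Return the in-silico converted search copies of a read.

    Each item is (converted_sequence, copy_kind, index_kind) where copy_kind
    is "CT" (all C->T, searched in the C-less index) or "GA" (all G->A,
    searched in the G-less index).  Directional libraries constrain mate 1
    (and single-end reads) to the CT copy and mate 2 to the GA copy;
    non-directional mode searches both copies for every mate.
    """
    ct = (read.sequence.replace("C", "T"), "CT", C_LESS)
    ga = (read.sequence.replace("G", "A"), "GA", G_LESS)
    if mode == "non_directional":
        return [ct, ga]
    if read.mate == 2:
        return [ga]
    return [ct]


_COPY_TAGS = {("CT", "+"): OT, ("CT", "-"): OB, ("GA", "+"): CTOB, ("GA", "-"): CTOT}


def generate_seeds(read: Read, indexes: GenomeIndex, params: ScoringParams,
                   mode: str = "directional") -> list[Seed]:
    """Maximal exact matches (>= min_seed_len) of the converted read copies.

    Greedy right-to-left: backward-search extends each match as far left as
    possible, then restarts immediately left of the failing position.
    """
    seeds: list[Seed] = []
    n = len(read.sequence)
    if n < params.min_seed_len:
        return seeds
    for conv_seq, copy_kind, index_kind in convert_read(read, mode):
        index = indexes.by_kind(index_kind)
        codes = _encode_lenient(conv_seq)
        e = n
        while e >= params.min_seed_len:
            lower, upper = 0, index.n
            i = e
            while i > 0:
                sym = codes[i - 1]
                if sym < 0:  # N: never matches
                    break
                nlo, nhi = index.step(int(sym), lower, upper)
                if nlo >= nhi:
                    break
                lower, upper, i = nlo, nhi, i - 1
            length = e - i
            if length >= params.min_seed_len:
                from .reference import SAInterval
                hits, _trunc = index.locate(SAInterval(lower, lower + (upper - lower), length),
                                            max_hits=params.max_seed_hits)
                for contig, pos0, strand in hits:
                    seeds.append(Seed(
                        read_offset=i, length=length, contig=contig,
                        ref_position0=pos0, genome_strand=strand,
                        bs_strand=_COPY_TAGS[(copy_kind, strand)],
                    ))
            e = i - 1 if i < e else e - 1
    return seeds


def _encode_lenient(seq: str) -> np.ndarray:
    """Sequence -> FM codes with N (or anything non-ACGT) as -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int16)
    for base, code in zip(b"ACGT", (2, 3, 4, 5)):  # FM codes
        out[arr == base] = code
    return out


# ---------------------------------------------------------------------------
# asymmetric scoring and the 4-base compatibility filter
# ---------------------------------------------------------------------------

def _allowed_pair_mask(ref_codes: np.ndarray, read_codes: np.ndarray,
                       bs_strand: str) -> np.ndarray:
    """Boolean mask of positions that are match / allowed conversion / N."""
    eq = ref_codes == read_codes
    if converts_c_to_t(bs_strand):
        conv = (ref_codes == REF_C) & (read_codes == REF_T)
    else:
        conv = (ref_codes == REF_G) & (read_codes == REF_A)
    any_n = (ref_codes == REF_N) | (read_codes == REF_N)
    return eq | conv | any_n


def asymmetric_score(ref_base: str, read_base: str, bs_strand: str,
                     params: ScoringParams) -> int:
    """Score of a single aligned base pair under conversion asymmetry."""
    r, q = encode_bases(ref_base)[0], encode_bases(read_base)[0]
    if r == REF_N or q == REF_N:
        return 0
    if r == q:
        return params.match_score
    if converts_c_to_t(bs_strand) and r == REF_C and q == REF_T:
        return params.match_score
    if not converts_c_to_t(bs_strand) and r == REF_G and q == REF_A:
        return params.match_score
    return -params.mismatch_penalty


def substitution_matrix(bs_strand: str, params: ScoringParams) -> np.ndarray:
    """5x5 matrix indexed [ref_code, read_code] implementing the asymmetry."""
    m = np.full((5, 5), -params.mismatch_penalty, dtype=np.int32)
    for b in range(4):
        m[b, b] = params.match_score
    if converts_c_to_t(bs_strand):
        m[REF_C, REF_T] = params.match_score
    else:
        m[REF_G, REF_A] = params.match_score
    m[REF_N, :] = 0
    m[:, REF_N] = 0
    return m


def split_incompatible_seed(seed: Seed, packed: PackedReference, read: Read,
                            min_len: int) -> list[Seed]:
    """Split a located 3-base seed at 4-base-incompatible positions.

    A sequencing error can agree with the converted genome yet violate the
    conversion asymmetry against the original bases (e.g. a read C over a
    reference T on the OT strand).  Such positions break the seed; the
    compatible runs of length >= min_len survive as independent seeds.
    """
    ref = packed.codes(seed.contig)[seed.ref_position0: seed.ref_position0 + seed.length]
    read_codes = encode_bases(read.sequence)
    if seed.genome_strand == "-":
        read_codes = revcomp_codes(read_codes)
    n = len(read.sequence)
    a = seed.aligned_offset(n)
    sub = read_codes[a: a + seed.length]
    if len(ref) != seed.length or len(sub) != seed.length:
        return []
    mask = _allowed_pair_mask(ref, sub, seed.bs_strand)
    if mask.all():
        return [seed]
    out = []
    run_start = None
    for k in range(seed.length + 1):
        good = k < seed.length and mask[k]
        if good and run_start is None:
            run_start = k
        elif not good and run_start is not None:
            run_len = k - run_start
            if run_len >= min_len:
                if seed.genome_strand == "+":
                    roff = seed.read_offset + run_start
                else:
                    # aligned offset a+run_start maps back to read coords
                    roff = n - (a + run_start + run_len)
                out.append(Seed(
                    read_offset=roff, length=run_len, contig=seed.contig,
                    ref_position0=seed.ref_position0 + run_start,
                    genome_strand=seed.genome_strand, bs_strand=seed.bs_strand,
                ))
            run_start = None
    return out


def check_four_base_compatibility(seed: Seed, packed: PackedReference,
                                  read: Read) -> bool:
    """Accept a located seed only if the original (4-base) bases obey the
    conversion asymmetry of the seed's bisulfite strand over its whole span."""
    ref = packed.codes(seed.contig)[seed.ref_position0: seed.ref_position0 + seed.length]
    read_codes = encode_bases(read.sequence)
    if seed.genome_strand == "-":
        read_codes = revcomp_codes(read_codes)
    a = seed.aligned_offset(len(read.sequence))
    sub = read_codes[a: a + seed.length]
    if len(ref) != seed.length or len(sub) != seed.length:
        return False
    return bool(_allowed_pair_mask(ref, sub, seed.bs_strand).all())


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_seeds(seeds: Sequence[Seed], params: ScoringParams,
                read_len: int) -> list[SeedChain]:
    """Merge colinear seeds (same contig/strand/bs tag, bounded reference gap
    and diagonal drift) into chains scored by trimmed read coverage."""
    keyed = sorted(
        seeds,
        key=lambda s: (s.bs_strand, s.contig, s.genome_strand,
                       s.ref_position0 - s.aligned_offset(read_len), s.ref_position0),
    )
    chains: list[SeedChain] = []
    open_chain: SeedChain | None = None
    for s in keyed:
        diag = s.ref_position0 - s.aligned_offset(read_len)
        if open_chain is not None:
            last = open_chain.seeds[-1]
            ldiag = last.ref_position0 - last.aligned_offset(read_len)
            same_group = (
                last.bs_strand == s.bs_strand
                and last.contig == s.contig
                and last.genome_strand == s.genome_strand
                and abs(diag - ldiag) <= params.band_width
                and s.ref_position0 >= last.ref_position0
                and s.ref_position0 - (last.ref_position0 + last.length) <= params.max_chain_gap
                and s.aligned_offset(read_len) + s.length
                    > last.aligned_offset(read_len)  # colinear in the read
            )
            if same_group:
                open_chain.seeds.append(s)
                continue
            chains.append(open_chain)
        open_chain = SeedChain([s], s.contig, s.genome_strand, s.bs_strand)
    if open_chain is not None:
        chains.append(open_chain)

    for ch in chains:
        covered = 0
        last_end = -1
        for s in sorted(ch.seeds, key=lambda s: s.aligned_offset(read_len)):
            a0 = s.aligned_offset(read_len)
            a1 = a0 + s.length
            covered += max(0, a1 - max(a0, last_end))
            last_end = max(last_end, a1)
        ch.score = covered
    chains.sort(key=lambda c: (-c.score, c.contig,
                               c.seeds[0].ref_position0, c.bs_strand))
    return chains


# ---------------------------------------------------------------------------
# extension: gap-free fast path + banded affine-gap DP
# ---------------------------------------------------------------------------

NEG = -(10 ** 9)


def local_affine_align(read_codes: np.ndarray, ref_codes: np.ndarray,
                       sub: np.ndarray, gap_open: int, gap_extend: int,
                       band_width: int | None = None):
    """Local (Smith–Waterman) alignment with affine gaps (Gotoh).

    A gap of length k costs gap_open + k*gap_extend.  Rows are vectorized
    with numpy; the horizontal gap state uses the prefix-max identity
    E[i][j] = max_{k<j}( max(M,F,0)[i][k] + k*ge ) - go - j*ge, which is
    equivalent to the standard Gotoh recurrence because every gap chain
    originates at a non-gap cell.

    Returns (score, cigar_ops, read_start, read_end, ref_start, ref_end)
    with half-open read/ref coordinates of the aligned core; cigar_ops is a
    list of (length, op) over M/I/D (no clips).  Score 0 means no positive
    alignment.
    """
    n, m = len(read_codes), len(ref_codes)
    go, ge = gap_open, gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    Em = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Fm = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    jidx = np.arange(m + 1, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        subrow = sub[ref_codes, read_codes[i - 1]]  # length m
        M = np.empty(m + 1, dtype=np.int32)
        M[0] = NEG
        M[1:] = H[i - 1, :m] + subrow
        F = np.maximum(H[i - 1] - go - ge, Fm[i - 1] - ge)
        G = np.maximum(np.maximum(M, F), 0)
        A = G + jidx * ge
        P = np.maximum.accumulate(A)
        E = np.full(m + 1, NEG, dtype=np.int64)
        E[1:] = P[:-1] - go - jidx[1:] * ge
        Hrow = np.maximum(G, E).astype(np.int32)
        H[i] = Hrow
        Em[i] = E
        Fm[i] = F
        rb = int(Hrow.max())
        if rb > best:
            best = rb
            bi = i
            bj = int(np.argmax(Hrow))
    if best <= 0:
        return 0, [], 0, 0, 0, 0

    # traceback (any co-optimal path)
    ops: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[ref_codes[j - 1], read_codes[i - 1]]:
                ops.append("M")
                i, j = i - 1, j - 1
            elif H[i, j] == Em[i, j]:
                state = "E"
            elif H[i, j] == Fm[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":  # gap in read (consumes reference) -> D
            ops.append("D")
            if j > 1 and Em[i, j] == Em[i, j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F: gap in reference (consumes read) -> I
            ops.append("I")
            if i > 1 and Fm[i, j] == Fm[i - 1, j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    ops.reverse()
    read_end, ref_end = bi, bj
    read_start = read_end - sum(1 for o in ops if o in "MI")
    ref_start = ref_end - sum(1 for o in ops if o in "MD")
    cigar_ops: list[tuple[int, str]] = []
    for o in ops:
        if cigar_ops and cigar_ops[-1][1] == o:
            cigar_ops[-1] = (cigar_ops[-1][0] + 1, o)
        else:
            cigar_ops.append((1, o))
    return int(best), cigar_ops, read_start, read_end, ref_start, ref_end


def _path_stats(read_codes, ref_codes, cigar_ops, read_start, ref_start, bs_strand):
    """NM (conversion-aware) and conversion count along an alignment path."""
    nm = conv = 0
    i, j = read_start, ref_start
    ct = converts_c_to_t(bs_strand)
    for length, op in cigar_ops:
        if op == "M":
            r = ref_codes[j: j + length]
            q = read_codes[i: i + length]
            is_conv = ((r == REF_C) & (q == REF_T)) if ct else ((r == REF_G) & (q == REF_A))
            any_n = (r == REF_N) | (q == REF_N)
            mism = (r != q) & ~is_conv & ~any_n
            nm += int(mism.sum())
            conv += int(is_conv.sum())
            i += length
            j += length
        elif op == "I":
            nm += length
            i += length
        elif op == "D":
            nm += length
            j += length
    return nm, conv


def extend_alignment(chain: SeedChain, packed: PackedReference, read: Read,
                     params: ScoringParams) -> AlignmentResult | None:
    """Extend a seed chain against the 4-base reference.

    Attempts a gap-free placement on the chain's diagonal first; if any
    disallowed substitution remains, falls back to banded affine-gap DP on
    a reference window around the projected placement.  The returned score
    is the local-DP optimum for that window.
    """
    n = len(read.sequence)
    read_codes = encode_bases(read.sequence)
    quals = read.qualities
    if chain.genome_strand == "-":
        read_codes = revcomp_codes(read_codes)
        quals = quals[::-1]
    ref_all = packed.codes(chain.contig)
    first = chain.seeds[0]
    diag = first.ref_position0 - first.aligned_offset(n)

    sub = substitution_matrix(chain.bs_strand, params)

    # gap-free fast path at the seed diagonal
    if 0 <= diag and diag + n <= len(ref_all):
        window = ref_all[diag: diag + n]
        if _allowed_pair_mask(window, read_codes, chain.bs_strand).all():
            contrib = sub[window, read_codes]
            score = int(contrib.sum())
            nm, conv = _path_stats(read_codes, window, [(n, "M")], 0, 0, chain.bs_strand)
            return AlignmentResult(
                read_name=read.name, contig=chain.contig, pos0=diag,
                cigar=f"{n}M", genome_strand=chain.genome_strand,
                bs_strand=chain.bs_strand, score=score, suboptimal_score=0,
                n_equal_best=1, mapq=0, nm=nm, conversions=conv,
                sequence=decode_bases(read_codes), qualities=quals, mate=read.mate,
            )

    pad = min(params.band_width, 3 * params.gap_extend + params.gap_open + 10)
    wstart = max(0, diag - pad)
    wend = min(len(ref_all), diag + n + pad)
    if wend <= wstart:
        return None
    window = ref_all[wstart:wend]
    score, ops, rs, re_, fs, fe = local_affine_align(
        read_codes, window, sub, params.gap_open, params.gap_extend,
        band_width=params.band_width)
    if score <= 0 or not ops:
        return None
    nm, conv = _path_stats(read_codes, window, ops, rs, fs, chain.bs_strand)
    cigar_parts = []
    if rs > 0:
        cigar_parts.append((rs, "S"))
    cigar_parts.extend(ops)
    if re_ < n:
        cigar_parts.append((n - re_, "S"))
    cigar = "".join(f"{l}{o}" for l, o in cigar_parts)
    return AlignmentResult(
        read_name=read.name, contig=chain.contig, pos0=wstart + fs,
        cigar=cigar, genome_strand=chain.genome_strand,
        bs_strand=chain.bs_strand, score=score, suboptimal_score=0,
        n_equal_best=1, mapq=0, nm=nm, conversions=conv,
        sequence=decode_bases(read_codes), qualities=quals, mate=read.mate,
    )


# ---------------------------------------------------------------------------
# MAPQ, strand reassessment, the full per-read pipeline
# ---------------------------------------------------------------------------

def compute_mapq(best_score: int, suboptimal: int, n_equal_best: int) -> int:
    """0 on ties; otherwise round(60 * (best - second) / best), clamped.

    The tie->0 rule is the one hard constraint; the gap-ratio formula is a
    declared convention of this implementation (monotone in the score gap,
    60 for a unique hit with no competitor).
    """
    if n_equal_best > 1:
        return 0
    if best_score <= 0:
        return 0
    mapq = round(60 * (best_score - max(suboptimal, 0)) / best_score)
    return max(0, min(60, mapq))


def reassess_conversion_strand(aln: AlignmentResult, packed: PackedReference):
    """Count reference C/read-T vs G/read-A evidence inside the alignment and
    return (tag, ambiguous).  Ties (including 0-0) keep the seeding tag and
    flag ambiguity; a contradicting majority flips the conversion class while
    preserving the genome strand."""
    ref = packed.codes(aln.contig)
    read_codes = encode_bases(aln.sequence)
    i = j = 0
    ct = ga = 0
    j = aln.pos0
    for length, op in parse_cigar(aln.cigar):
        if op == "M":
            r = ref[j: j + length]
            q = read_codes[i: i + length]
            ct += int(((r == REF_C) & (q == REF_T)).sum())
            ga += int(((r == REF_G) & (q == REF_A)).sum())
            i += length
            j += length
        elif op in "IS":
            i += length
        elif op == "D":
            j += length
    if ct == ga:
        return aln.bs_strand, True
    want_ct = ct > ga
    if want_ct == converts_c_to_t(aln.bs_strand):
        return aln.bs_strand, False
    if want_ct:
        return (OT if aln.genome_strand == "+" else CTOT), False
    return (CTOB if aln.genome_strand == "+" else OB), False


def _unmapped(read: Read) -> AlignmentResult:
    return AlignmentResult(
        read_name=read.name, contig=None, pos0=-1, cigar="*",
        genome_strand="+", bs_strand=OT, score=0, suboptimal_score=0,
        n_equal_best=0, mapq=0, nm=0, conversions=0,
        sequence=read.sequence, qualities=read.qualities, mate=read.mate, flag=4,
    )


def align_candidates(read: Read, indexes: GenomeIndex, params: ScoringParams,
                     mode: str = "directional") -> list[AlignmentResult]:
    """All extended candidate placements of a read, best first."""
    packed = indexes.packed
    raw_seeds = generate_seeds(read, indexes, params, mode)
    if not raw_seeds:
        return []
    # 4-base compatibility filter before chaining: incompatible positions
    # split a seed into its compatible runs
    seeds: list[Seed] = []
    for s in raw_seeds:
        seeds.extend(split_incompatible_seed(s, packed, read, params.min_seed_len))
    if not seeds:
        return []
    chains = chain_seeds(seeds, params, len(read.sequence))
    results: dict[tuple, AlignmentResult] = {}
    visited = extended = 0
    for chain in chains:
        visited += 1
        if visited > params.max_total_chains:
            break
        if extended >= params.max_top_chains:
            break
        extended += 1
        aln = extend_alignment(chain, packed, read, params)
        if aln is None:
            continue
        key = (aln.contig, aln.genome_strand, aln.pos0, aln.bs_strand)
        prev = results.get(key)
        if prev is None or aln.score > prev.score:
            results[key] = aln
    order = {name: i for i, name in enumerate(packed.names)}
    out = sorted(results.values(),
                 key=lambda a: (-a.score, order[a.contig], a.pos0, a.bs_strand))
    return out


def finalize_primary(read: Read, candidates: list[AlignmentResult],
                     params: ScoringParams, packed: PackedReference) -> AlignmentResult:
    """Pick the primary alignment, assign MAPQ/XA/XB, reassess the strand."""
    if not candidates:
        return _unmapped(read)
    best = candidates[0]
    n_equal = sum(1 for c in candidates if c.score == best.score)
    subopt = candidates[1].score if len(candidates) > 1 else 0
    best.n_equal_best = n_equal
    best.suboptimal_score = subopt
    best.mapq = compute_mapq(best.score, subopt, n_equal)
    tag, ambiguous = reassess_conversion_strand(best, packed)
    best.bs_strand = tag
    best.strand_ambiguous = ambiguous
    alternates = candidates[1:]
    best.n_alternates = len(alternates)
    if 0 < len(alternates) <= params.max_xa_hits:
        best.alternates = [(a.contig, a.genome_strand, a.pos0, a.cigar, a.nm)
                           for a in alternates]
    if best.genome_strand == "-":
        best.flag |= 16
    return best


def align_read(read: Read, indexes: GenomeIndex, params: ScoringParams | None = None,
               mode: str = "directional") -> AlignmentResult:
    params = params or ScoringParams()
    cands = align_candidates(read, indexes, params, mode)
    return finalize_primary(read, cands, params, indexes.packed)


# ---------------------------------------------------------------------------
# paired-end alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertModel:
    mean: float = 300.0
    sd: float = 30.0
    n_sigma: float = 4.0


def _pair_compatible(a1: AlignmentResult, a2: AlignmentResult,
                     model: InsertModel) -> bool:
    if not (a1.mapped and a2.mapped) or a1.contig != a2.contig:
        return False
    if a1.genome_strand == a2.genome_strand:
        return False
    if converts_c_to_t(a1.bs_strand) != converts_c_to_t(a2.bs_strand):
        return False
    left, right = (a1, a2) if a1.pos0 <= a2.pos0 else (a2, a1)
    if left.genome_strand != "+":
        return False  # FR orientation only
    tlen = right.pos0 + right.reference_span() - left.pos0
    return abs(tlen - model.mean) <= model.n_sigma * model.sd


def align_pair(read1: Read, read2: Read, indexes: GenomeIndex,
               params: ScoringParams | None = None, mode: str = "directional",
               insert_model: InsertModel | None = None
               ) -> tuple[AlignmentResult, AlignmentResult]:
    """Align a mate pair; prefer consistent pairs, never force pairing.

    Each mate is seeded and extended independently, candidate pairs get a
    proper-pair bonus when orientation/insert fit the insert model, and
    mates with no consistent pairing are reported from their own best
    placements with the proper-pair flag unset (chimera-tolerant).
    """
    params = params or ScoringParams()
    model = insert_model or InsertModel()
    read1 = replace(read1, mate=1) if read1.mate != 1 else read1
    read2 = replace(read2, mate=2) if read2.mate != 2 else read2
    c1 = align_candidates(read1, indexes, params, mode)
    c2 = align_candidates(read2, indexes, params, mode)

    best_pair = None
    best_pair_score = NEG
    for a1 in c1[:20]:
        for a2 in c2[:20]:
            s = a1.score + a2.score
            if _pair_compatible(a1, a2, model):
                s += params.proper_pair_bonus
                if s > best_pair_score:
                    best_pair_score = s
                    best_pair = (a1, a2, True)
    proper = False
    if best_pair is not None and best_pair[2]:
        a1, a2, proper = best_pair
        # re-rank each mate's list so the paired placement is primary
        c1 = [a1] + [c for c in c1 if c is not a1]
        c2 = [a2] + [c for c in c2 if c is not a2]
    p1 = finalize_primary(read1, c1, params, indexes.packed)
    p2 = finalize_primary(read2, c2, params, indexes.packed)
    for p, other, flag_self in ((p1, p2, 64), (p2, p1, 128)):
        p.flag |= 1 | flag_self
        if not p.mapped:
            p.flag |= 4
        if not other.mapped:
            p.flag |= 8
        elif other.genome_strand == "-":
            p.flag |= 32
        if other.mapped:
            p.mate_contig = other.contig
            p.mate_pos0 = other.pos0
    if proper and p1.mapped and p2.mapped:
        p1.flag |= 2
        p2.flag |= 2
        left, right = (p1, p2) if p1.pos0 <= p2.pos0 else (p2, p1)
        tlen = right.pos0 + right.reference_span() - left.pos0
        left.tlen, right.tlen = tlen, -tlen
    return p1, p2


# ---------------------------------------------------------------------------
# duplicate marking
# ---------------------------------------------------------------------------

def _unclipped_five_prime(aln: AlignmentResult) -> int:
    ops = parse_cigar(aln.cigar)
    lead = ops[0][0] if ops and ops[0][1] == "S" else 0
    trail = ops[-1][0] if ops and ops[-1][1] == "S" else 0
    if aln.genome_strand == "+":
        return aln.pos0 - lead
    return aln.pos0 + aln.reference_span() + trail - 1


def mark_duplicates(records: list[AlignmentResult]) -> list[AlignmentResult]:
    """Flag duplicates by coordinate signature, conversion-aware by design.

    Signature: contig, unclipped 5' position of each mate, orientation and
    bisulfite strand tag — never base content, so differing conversion
    (methylation) patterns cannot split a duplicate group.  The highest
    total-base-quality record (pair) survives per signature.
    """
    by_name: dict[str, list[AlignmentResult]] = {}
    for r in records:
        by_name.setdefault(r.read_name, []).append(r)
    groups: dict[tuple, list[tuple[float, list[AlignmentResult]]]] = {}
    for name, recs in by_name.items():
        mapped = [r for r in recs if r.mapped]
        if not mapped:
            continue
        parts = []
        for r in sorted(mapped, key=lambda r: (r.mate or 0)):
            parts.append((r.contig, _unclipped_five_prime(r), r.genome_strand, r.bs_strand))
        sig = tuple(sorted(parts))
        quality = sum(float(np.sum(r.qualities)) for r in mapped if r.qualities is not None)
        groups.setdefault(sig, []).append((quality, recs))
    for sig, members in groups.items():
        if len(members) < 2:
            continue
        members.sort(key=lambda t: -t[0])
        for _, recs in members[1:]:
            for r in recs:
                r.is_duplicate = True
                r.flag |= 1024
    return records


# ---------------------------------------------------------------------------
# SAM emission
# ---------------------------------------------------------------------------

def sam_header(packed: PackedReference) -> "pysam.AlignmentHeader":
    import pysam

    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in zip(packed.names, packed.lengths)],
        "PG": [{"ID": "epibis", "PN": "epibis"}],
    })


def to_aligned_segment(aln: AlignmentResult, header) -> "pysam.AlignedSegment":
    import pysam

    seg = pysam.AlignedSegment(header)
    seg.query_name = aln.read_name
    seg.flag = aln.flag
    if aln.mapped:
        seg.reference_id = header.get_tid(aln.contig)
        seg.reference_start = aln.pos0
        seg.mapping_quality = aln.mapq
        seg.cigarstring = aln.cigar
    else:
        seg.reference_id = -1
        seg.reference_start = -1
        seg.mapping_quality = 0
    seg.query_sequence = aln.sequence
    if aln.qualities is not None:
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(int(q) + 33) for q in aln.qualities))
    if aln.mate_contig is not None:
        seg.next_reference_id = header.get_tid(aln.mate_contig)
        seg.next_reference_start = aln.mate_pos0
        seg.template_length = aln.tlen
    else:
        seg.next_reference_id = -1
        seg.next_reference_start = -1
    if aln.mapped:
        tags = [("NM", aln.nm), ("AS", aln.score), ("XS", aln.suboptimal_score),
                ("ZS", ZS_VALUE[aln.bs_strand]), ("ZC", aln.conversions)]
        if aln.alternates:
            xa = "".join(
                f"{c},{'+' if st == '+' else '-'}{p + 1},{cg},{nm};"
                for c, st, p, cg, nm in aln.alternates)
            tags.append(("XA", xa))
        tags.append(("XB", aln.n_alternates))
        seg.set_tags(tags)
    return seg


def write_sam(path, packed: PackedReference, alignments: Iterable[AlignmentResult],
              sort: bool = True) -> None:
    import pysam

    header = sam_header(packed)
    segs = [to_aligned_segment(a, header) for a in alignments]
    if sort:
        segs.sort(key=lambda s: (s.reference_id if s.reference_id >= 0 else 1 << 30,
                                 s.reference_start))
        hd = header.to_dict()
        hd["HD"]["SO"] = "coordinate"
        header = pysam.AlignmentHeader.from_dict(hd)
        segs = [pysam.AlignedSegment.fromstring(s.to_string(), header) for s in segs]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for s in segs:
            out.write(s)
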