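"""epiBED: read-level run-length-encoded methylation + variant records.

One BED-compliant row per read (or merged mate pair) captures, per
reference position, both the epigenetic state and the genetic state of a
single molecule, enabling phased epi-haplotype and allele-specific
methylation analysis.

Dialect (version 1.0) — columns, tab separated::

    chrom  start0  end  read_name  mate  bs_strand  rle_meth  rle_var [rle_acc]

``mate`` is 1, 2 or 0 for a merged pair; ``bs_strand`` is the four-state
bisulfite tag.  Both RLE strings decode to exactly end - start0 symbols,
always written as count+symbol pairs (e.g. "2x1M3x").

Methylation alphabet: M retained cytosine, U converted cytosine,
F filtered (low base quality or mate conflict), D deletion, x irrelevant.
Variant alphabet: A/C/G/T observed base at a supplied variant site, with
R when a G->A conversion makes the base ambiguous (an A seen on an
OB/CTOB read) and Y for the C->T mirror; F/D/x as above.  Insertions do
not consume reference positions and are recorded in a side field
(``insertions`` attribute; serialized as a comment-safe suffix is *not*
part of the dialect).  A NOMe run adds a third RLE column holding the
accessibility (GCH) channel with the same alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import EPIBED_DIALECT_VERSION
from .reference import PackedReference, REF_C, REF_G, encode_bases
from .align import AlignmentResult, parse_cigar, converts_c_to_t
from .calling import _context_wgbs, _context_nome, sixletter_base

MATE_MERGED = 0


@dataclass
class EpiBedRecord:
    chrom: str
    start0: int
    end: int
    read_name: str
    mate: int                 # 1, 2 or 0 (merged)
    bs_strand: str
    rle_meth: str
    rle_var: str
    rle_acc: str | None = None
    insertions: tuple[tuple[int, str], ...] = ()  # (ref_pos0, inserted seq)

    def __post_init__(self):
        for rle in (self.rle_meth, self.rle_var, self.rle_acc):
            if rle is not None and rle_length(rle) != self.end - self.start0:
                raise ValueError("RLE length must equal end - start0")

    @property
    def span(self) -> int:
        return self.end - self.start0


_RLE_RE = re.compile(r"(\d+)(.)")


def rle_encode(literal: str) -> str:
    if not literal:
        return ""
    out = []
    prev, count = literal[0], 1
    for ch in literal[1:]:
        if ch == prev:
            count += 1
        else:
            out.append(f"{count}{prev}")
            prev, count = ch, 1
    out.append(f"{count}{prev}")
    return "".join(out)


def rle_decode(rle: str) -> str:
    return "".join(int(n) * ch for n, ch in _RLE_RE.findall(rle))


def rle_length(rle: str) -> int:
    return sum(int(n) for n, _ in _RLE_RE.findall(rle))


def decode(record: EpiBedRecord) -> str:
    """Per-position methylation state string (exact inverse of the RLE)."""
    s = rle_decode(record.rle_meth)
    if len(s) != record.span:
        raise ValueError("decoded length mismatch")
    return s


def decode_var(record: EpiBedRecord) -> str:
    s = rle_decode(record.rle_var)
    if len(s) != record.span:
        raise ValueError("decoded length mismatch")
    return s


def encode_read(aln: AlignmentResult, packed: PackedReference,
                variant_sites: dict[tuple[str, int], object] | None = None,
                min_baseq: int = 20, assay: str = "WGBS") -> EpiBedRecord | None:
    """Walk one alignment and emit its epiBED record.

    Per reference position: M/U for retained/converted cytosines of the
    methylation channel (informative strand only), F for bases below
    min_baseq, the observed base letter at supplied variant sites (R/Y when
    the conversion strand makes it ambiguous), D under deletions and x
    elsewhere.  NOMe assays route GCH states to a third accessibility
    channel and exclude GCG cytosines.
    """
    if not aln.mapped:
        return None
    variant_sites = variant_sites or {}
    ref_codes = packed.codes(aln.contig)
    read = aln.sequence
    quals = aln.qualities
    nome = assay.upper() == "NOME"
    meth, var, acc = [], [], []
    insertions = []
    i, j = 0, aln.pos0
    ct = converts_c_to_t(aln.bs_strand)

    def classify(rpos: int, qidx: int):
        m = v = a = "x"
        base = read[qidx]
        q = int(quals[qidx]) if quals is not None else 60
        low = q < min_baseq
        ref = int(ref_codes[rpos])
        informative = (ref == REF_C and ct) or (ref == REF_G and not ct)
        if informative:
            if nome:
                context, _flags = _context_nome(ref_codes, rpos, "+" if ct else "-")
            else:
                context = _context_wgbs(ref_codes, rpos, "+" if ct else "-")
            channel = None
            if context is not None:
                channel = "acc" if (nome and context == "GCH") else "meth"
            if channel is not None:
                if low:
                    state = "F"
                elif ct:
                    state = "M" if base == "C" else ("U" if base == "T" else "x")
                else:
                    state = "M" if base == "G" else ("U" if base == "A" else "x")
                if channel == "meth":
                    m = state
                else:
                    a = state
        if (aln.contig, rpos) in variant_sites:
            v = "F" if low else sixletter_base(base, aln.bs_strand)
        return m, v, a

    for length, op in parse_cigar(aln.cigar):
        if op == "M":
            for k in range(length):
                m, v, a = classify(j + k, i + k)
                meth.append(m)
                var.append(v)
                acc.append(a)
            i += length
            j += length
        elif op == "S":
            i += length
        elif op == "I":
            insertions.append((j, read[i: i + length]))
            i += length
        elif op == "D":
            meth.extend("D" * length)
            var.extend("D" * length)
            acc.extend("D" * length)
            j += length
    end = j
    return EpiBedRecord(
        chrom=aln.contig, start0=aln.pos0, end=end, read_name=aln.read_name,
        mate=aln.mate or 0, bs_strand=aln.bs_strand,
        rle_meth=rle_encode("".join(meth)), rle_var=rle_encode("".join(var)),
        rle_acc=rle_encode("".join(acc)) if nome else None,
        insertions=tuple(insertions),
    )


def merge_mates(r1: EpiBedRecord, r2: EpiBedRecord) -> EpiBedRecord:
    """Overlap-aware merge of a mate pair into one phased molecule record.

    Where both mates cover a position, agreeing states are kept once (no
    double counting) and any disagreement — including an informative state
    against an uninformative one — becomes F (conflict-filtered), matching
    the pileup's tie-drop rule for overlapping mates.  The gap between
    disjoint mates is filled with x.  Commutative in its arguments.
    """
    if (r1.chrom, r1.read_name) != (r2.chrom, r2.read_name):
        raise ValueError("can only merge mates of the same pair on one contig")
    start = min(r1.start0, r2.start0)
    end = max(r1.end, r2.end)
    n = end - start
    ov_lo = max(r1.start0, r2.start0) - start
    ov_hi = min(r1.end, r2.end) - start

    def overlay(get):
        out = ["x"] * n
        for r in (r1, r2):
            s = get(r)
            for k, ch in enumerate(s):
                idx = r.start0 - start + k
                if not (ov_lo <= idx < ov_hi):
                    out[idx] = ch
        if ov_lo < ov_hi:
            s1 = get(r1)
            s2 = get(r2)
            for idx in range(ov_lo, ov_hi):
                a = s1[idx + start - r1.start0]
                b = s2[idx + start - r2.start0]
                out[idx] = a if a == b else "F"
        return "".join(out)

    acc = None
    if r1.rle_acc is not None and r2.rle_acc is not None:
        acc = rle_encode(overlay(lambda r: rle_decode(r.rle_acc)))
    return EpiBedRecord(
        chrom=r1.chrom, start0=start, end=end, read_name=r1.read_name,
        mate=MATE_MERGED, bs_strand=r1.bs_strand,
        rle_meth=rle_encode(overlay(decode)),
        rle_var=rle_encode(overlay(decode_var)),
        rle_acc=acc,
        insertions=tuple(sorted(set(r1.insertions) | set(r2.insertions))),
    )


def merge_pairs(records: Iterable[EpiBedRecord]) -> list[EpiBedRecord]:
    """Merge mate pairs sharing a read name; singletons pass through."""
    by_name: dict[str, list[EpiBedRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.read_name not in by_name:
            order.append(r.read_name)
        by_name.setdefault(r.read_name, []).append(r)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 2 and group[0].chrom == group[1].chrom:
            out.append(merge_mates(group[0], group[1]))
        else:
            out.extend(group)
    return out


def to_matrix(records: Iterable[EpiBedRecord], packed: PackedReference,
              contig: str, start0: int, end: int,
              include_snps: Sequence[int] = (),
              require_complete: bool = False) -> pd.DataFrame:
    """Read-by-CpG state matrix for a region (+ optional SNP columns).

    Rows are molecules (merged pairs occupy one row), columns the
    top-strand coordinates of CpG dyads in [start0, end) plus any
    requested SNP positions (labelled "snp:<pos>").  Cells hold M/U/F (or
    the observed base letter for SNP columns); missing coverage is NaN.
    ``require_complete`` keeps only rows covering every column.  Rows are
    sorted by mean methylation (most methylated first).
    """
    ref = packed.codes(contig)
    cpg_cols = [p for p in range(start0, min(end, len(ref) - 1))
                if ref[p] == REF_C and ref[p + 1] == REF_G]
    snp_cols = [f"snp:{p}" for p in include_snps]
    rows = {}
    for r in records:
        if r.chrom != contig or r.end <= start0 or r.start0 >= end:
            continue
        meth = decode(r)
        var = decode_var(r)
        row = {}
        for p in cpg_cols:
            # a CpG dyad is informed at p (top C) or p+1 (bottom C)
            state = None
            for q in (p, p + 1):
                if r.start0 <= q < r.end:
                    ch = meth[q - r.start0]
                    if ch in "MUF":
                        state = ch
                        break
            if state is not None:
                row[p] = state
        for p in include_snps:
            if r.start0 <= p < r.end:
                ch = var[p - r.start0]
                if ch != "x":
                    row[f"snp:{p}"] = ch
        if row:
            rows[r.read_name] = row
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[*cpg_cols, *snp_cols])
    if require_complete and len(df):
        df = df.dropna()
    if len(df):
        meth_part = df[cpg_cols].apply(
            lambda col: col.map({"M": 1.0, "U": 0.0}), axis=0)
        df = df.loc[meth_part.mean(axis=1).sort_values(ascending=False).index]
    return df


@dataclass
class AsmResult:
    cpg_pos0: int
    allele_a: str
    allele_b: str
    beta_a: float | None
    beta_b: float | None
    p_value: float | None
    tested: bool
    n_a: int = 0
    n_b: int = 0


def asm_test(matrix: pd.DataFrame, snp_column: str,
             min_reads_per_allele: int = 3) -> list[AsmResult]:
    """Allele-specific methylation: per-CpG Fisher exact test.

    For each CpG column, reads are split by their base at ``snp_column``
    (the two most frequent alleles) and the 2x2 allele-by-M/U table is
    tested two-sided (hypergeometric).  Alleles with fewer than
    min_reads_per_allele informative reads are reported untested.  No
    multiple-testing correction is applied; callers may BH-adjust the
    returned p-values.
    """
    from scipy.stats import fisher_exact

    out = []
    alleles = matrix[snp_column].dropna()
    counts = alleles.value_counts()
    if len(counts) < 2:
        top = counts.index[0] if len(counts) else "N"
        return [AsmResult(int(c), top, "N", None, None, None, False)
                for c in matrix.columns if not str(c).startswith("snp:")]
    a, b = counts.index[:2]
    for col in matrix.columns:
        if str(col).startswith("snp:"):
            continue
        sub = matrix[[col, snp_column]].dropna()
        sub = sub[sub[col].isin(["M", "U"])]
        am = ((sub[snp_column] == a) & (sub[col] == "M")).sum()
        au = ((sub[snp_column] == a) & (sub[col] == "U")).sum()
        bm = ((sub[snp_column] == b) & (sub[col] == "M")).sum()
        bu = ((sub[snp_column] == b) & (sub[col] == "U")).sum()
        na, nb = am + au, bm + bu
        beta_a = am / na if na else None
        beta_b = bm / nb if nb else None
        if na < min_reads_per_allele or nb < min_reads_per_allele:
            out.append(AsmResult(int(col), a, b, beta_a, beta_b, None, False,
                                 int(na), int(nb)))
            continue
        _, p = fisher_exact([[am, au], [bm, bu]], alternative="two-sided")
        out.append(AsmResult(int(col), a, b, beta_a, beta_b, float(p), True,
                             int(na), int(nb)))
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_epibed(records: Iterable[EpiBedRecord], path) -> None:
    """Coordinate-sorted, tab-separated, gzip-compatible emission."""
    import gzip

    recs = sorted(records, key=lambda r: (r.chrom, r.start0, r.end, r.read_name))
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(f"#epibed dialect={EPIBED_DIALECT_VERSION}\n")
        for r in recs:
            cols = [r.chrom, str(r.start0), str(r.end), r.read_name,
                    str(r.mate), r.bs_strand, r.rle_meth, r.rle_var]
            if r.rle_acc is not None:
                cols.append(r.rle_acc)
            fh.write("\t".join(cols) + "\n")


def read_epibed(path) -> list[EpiBedRecord]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"malformed epiBED row: {line!r}")
            rec = EpiBedRecord(
                chrom=parts[0], start0=int(parts[1]), end=int(parts[2]),
                read_name=parts[3], mate=int(parts[4]), bs_strand=parts[5],
                rle_meth=parts[6], rle_var=parts[7],
                rle_acc=parts[8] if len(parts) > 8 else None,
            )
            out.append(rec)
    return out
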