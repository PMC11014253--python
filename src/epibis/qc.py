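"""Conversion and bias diagnostics for converted sequencing experiments.

Cytosine retention outside CpG context diagnoses conversion chemistry:
with complete conversion and no CpH methylation, every CpA/CpC/CpT
cytosine should read as T (A on the bottom strand).  Splitting CpH into
CpA, CpC and CpT separates genuine non-CpG methylation — which in real
tissues concentrates at CpA — from conversion failure, which hits all
three contexts equally.  The pooled CpC+CpT retention therefore estimates
the background non-conversion rate, and CpA retention in excess of it
flags genuine CpA methylation.  Per-read-position retention arrays
(M-bias) expose end-repair and adaptase artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.stats import beta as beta_dist

from .reference import PackedReference, REF_C, REF_G, REF_T, REF_A, encode_bases
from .align import AlignmentResult, parse_cigar, converts_c_to_t

CONTEXTS = ("CpG", "CpA", "CpC", "CpT")


@dataclass
class RetentionProfile:
    """Retained/total cytosine observations split by dinucleotide context,
    plus per-read-position arrays for mates 1 and 2 (M-bias)."""

    retained: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    total: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    # position arrays keyed (context, mate) -> [retained_by_pos, total_by_pos]
    by_position: dict[tuple, list] = field(default_factory=dict)
    max_read_length: int = 0

    def retention(self, context: str) -> float | None:
        t = self.total[context]
        return self.retained[context] / t if t else None

    def add(self, context: str, mate: int, read_pos: int, retained: bool):
        self.retained[context] += int(retained)
        self.total[context] += 1
        key = (context, mate)
        arrs = self.by_position.get(key)
        if arrs is None:
            arrs = [np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)]
            self.by_position[key] = arrs
        if read_pos >= len(arrs[0]):
            grow = read_pos + 1 - len(arrs[0])
            arrs[0] = np.append(arrs[0], np.zeros(grow, dtype=np.int64))
            arrs[1] = np.append(arrs[1], np.zeros(grow, dtype=np.int64))
        arrs[0][read_pos] += int(retained)
        arrs[1][read_pos] += 1
        self.max_read_length = max(self.max_read_length, read_pos + 1)

    def add_bulk(self, context: str, mate: int, read_pos: np.ndarray,
                 retained: np.ndarray):
        """Vectorized accumulation for one read's observations."""
        if len(read_pos) == 0:
            return
        self.retained[context] += int(retained.sum())
        self.total[context] += len(read_pos)
        key = (context, mate)
        arrs = self.by_position.get(key)
        top = int(read_pos.max()) + 1
        if arrs is None:
            arrs = [np.zeros(top, dtype=np.int64), np.zeros(top, dtype=np.int64)]
            self.by_position[key] = arrs
        elif top > len(arrs[0]):
            grow = top - len(arrs[0])
            arrs[0] = np.append(arrs[0], np.zeros(grow, dtype=np.int64))
            arrs[1] = np.append(arrs[1], np.zeros(grow, dtype=np.int64))
        np.add.at(arrs[0], read_pos, retained.astype(np.int64))
        np.add.at(arrs[1], read_pos, 1)
        self.max_read_length = max(self.max_read_length, top)


_CTX_PLUS = {REF_G: "CpG", REF_A: "CpA", REF_C: "CpC", REF_T: "CpT"}
_CTX_MINUS = {REF_C: "CpG", REF_T: "CpA", REF_G: "CpC", REF_A: "CpT"}


def _observations(rec: AlignmentResult, packed: PackedReference,
                  min_baseq: int = 0):
    """(contexts, read_positions, retained_mask, cph_mask) for one record.

    Only informative-strand cytosine observations that read as retained or
    converted count; other bases (errors, SNPs) are excluded.  Read
    positions are in original sequencing orientation (M-bias convention).
    """
    ref = packed.codes(rec.contig)
    n = len(rec.sequence)
    read_codes = encode_bases(rec.sequence)
    ct = converts_c_to_t(rec.bs_strand)
    # build ref/read index arrays over M ops
    rpos_parts, qpos_parts = [], []
    i, j = 0, rec.pos0
    for length, op in parse_cigar(rec.cigar):
        if op == "M":
            rpos_parts.append(np.arange(j, j + length))
            qpos_parts.append(np.arange(i, i + length))
            i += length
            j += length
        elif op in ("I", "S"):
            i += length
        elif op == "D":
            j += length
    if not rpos_parts:
        return [], None, None, None
    rpos = np.concatenate(rpos_parts)
    qpos = np.concatenate(qpos_parts)
    refb = ref[rpos]
    readb = read_codes[qpos]
    if ct:
        informative = refb == REF_C
        retained_b, converted_b = REF_C, REF_T
        partner = np.where(rpos + 1 < len(ref), ref[np.minimum(rpos + 1, len(ref) - 1)], 255)
        ctx_map = _CTX_PLUS
    else:
        informative = refb == REF_G
        retained_b, converted_b = REF_G, REF_A
        partner = np.where(rpos - 1 >= 0, ref[np.maximum(rpos - 1, 0)], 255)
        ctx_map = _CTX_MINUS
    informative &= (readb == retained_b) | (readb == converted_b)
    if rec.qualities is not None and min_baseq > 0:
        quals = np.asarray(rec.qualities)
        informative &= quals[qpos] >= min_baseq
    idx = np.flatnonzero(informative)
    if len(idx) == 0:
        return [], None, None, None
    retained = readb[idx] == retained_b
    # read position in sequencing orientation
    q = qpos[idx]
    if rec.genome_strand == "-":
        q = n - 1 - q
    contexts = np.array([ctx_map.get(int(p), "") for p in partner[idx]])
    return contexts, q, retained, None


def retention_by_context(records: Iterable[AlignmentResult],
                         packed: PackedReference,
                         min_baseq: int = 0) -> RetentionProfile:
    """Classify every informative cytosine observation by context and
    retained/converted status, indexed by read position for M-bias."""
    profile = RetentionProfile()
    for rec in records:
        if not rec.mapped or rec.flag & (4 | 256 | 1024 | 2048):
            continue
        contexts, q, retained, _ = _observations(rec, packed, min_baseq)
        if len(contexts) == 0:
            continue
        mate = rec.mate or 1
        for ctx in CONTEXTS:
            sel = contexts == ctx
            if sel.any():
                profile.add_bulk(ctx, mate, q[sel], retained[sel])
    return profile


@dataclass
class BackgroundEstimate:
    rate: float | None            # pooled CpC+CpT retention
    ci_low: float | None
    ci_high: float | None
    cpa_retention: float | None
    cpa_flag: bool                # evidence of genuine CpA methylation
    n_background: int = 0
    n_cpa: int = 0


def _clopper_pearson(k: int, n: int, alpha: float = 0.01):
    if n == 0:
        return None, None
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def infer_conversion_background(profile: RetentionProfile,
                                alpha: float = 0.01) -> BackgroundEstimate:
    """Background non-conversion from pooled CpC+CpT retention.

    The CpA-methylation flag fires when the Clopper-Pearson lower bound of
    CpA retention clears the upper bound of the pooled background — i.e.
    when the two binomial CIs separate, so chance alone fires at roughly
    alpha^2 / 4.
    """
    k_bg = profile.retained["CpC"] + profile.retained["CpT"]
    n_bg = profile.total["CpC"] + profile.total["CpT"]
    k_a, n_a = profile.retained["CpA"], profile.total["CpA"]
    if n_bg == 0:
        return BackgroundEstimate(None, None, None,
                                  k_a / n_a if n_a else None, False, 0, n_a)
    rate = k_bg / n_bg
    lo, hi = _clopper_pearson(k_bg, n_bg, alpha)
    cpa = k_a / n_a if n_a else None
    flag = False
    if n_a:
        a_lo, _a_hi = _clopper_pearson(k_a, n_a, alpha)
        flag = a_lo is not None and a_lo > hi
    return BackgroundEstimate(rate, lo, hi, cpa, flag, n_bg, n_a)


def filter_failed_conversion_reads(records: Iterable[AlignmentResult],
                                   packed: PackedReference,
                                   max_cph_retained: int = 2,
                                   min_cph_seen: int = 3):
    """Split records into (kept, removed) by per-read CpH retention.

    A read showing at least ``min_cph_seen`` CpH cytosines of which more
    than ``max_cph_retained`` are retained is deemed a conversion failure.
    Reads with too few CpH observations are always kept.
    """
    kept, removed = [], []
    for rec in records:
        if not rec.mapped:
            kept.append(rec)
            continue
        contexts, q, retained, _ = _observations(rec, packed)
        if len(contexts) == 0:
            kept.append(rec)
            continue
        cph = contexts != "CpG"
        seen = int(cph.sum())
        ret = int((retained & cph).sum())
        if seen >= min_cph_seen and ret > max_cph_retained:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


@dataclass
class QCReport:
    total_reads: int
    mapped_reads: int
    optimally_mapped_reads: int   # primary with MAPQ >= 40
    duplicate_reads: int
    profile: RetentionProfile
    background: BackgroundEstimate
    failed_conversion_reads: int


def qc_report(records: list[AlignmentResult], packed: PackedReference,
              min_optimal_mapq: int = 40,
              max_cph_retained: int = 2, min_cph_seen: int = 3) -> QCReport:
    total = len(records)
    mapped = sum(1 for r in records if r.mapped and not r.flag & (256 | 2048))
    optimal = sum(1 for r in records
                  if r.mapped and not r.flag & (256 | 2048) and r.mapq >= min_optimal_mapq)
    dups = sum(1 for r in records if r.flag & 1024)
    usable = [r for r in records if r.mapped and not r.flag & (256 | 1024 | 2048)]
    profile = retention_by_context(usable, packed)
    background = infer_conversion_background(profile)
    _, removed = filter_failed_conversion_reads(usable, packed,
                                                max_cph_retained, min_cph_seen)
    return QCReport(total, mapped, optimal, dups, profile, background,
                    len(removed))


def write_qc_report(report: QCReport, prefix) -> None:
    """Flat key:value metrics file + M-bias TSV (MultiQC-ingestable text)."""
    prefix = str(prefix)
    with open(prefix + ".qc.txt", "w") as fh:
        fh.write(f"total_reads:{report.total_reads}\n")
        fh.write(f"mapped_reads:{report.mapped_reads}\n")
        fh.write(f"optimally_mapped_reads:{report.optimally_mapped_reads}\n")
        fh.write(f"duplicate_reads:{report.duplicate_reads}\n")
        fh.write(f"failed_conversion_reads:{report.failed_conversion_reads}\n")
        for ctx in CONTEXTS:
            r = report.profile.retention(ctx)
            fh.write(f"retention_{ctx}:{'' if r is None else round(r, 6)}\n")
        bg = report.background
        fh.write(f"background_nonconversion:{'' if bg.rate is None else round(bg.rate, 6)}\n")
        if bg.ci_low is not None:
            fh.write(f"background_ci:{round(bg.ci_low, 6)},{round(bg.ci_high, 6)}\n")
        fh.write(f"cpa_methylation_flag:{int(bg.cpa_flag)}\n")
    with open(prefix + ".mbias.tsv", "w") as fh:
        fh.write("context\tmate\tposition\tretained\ttotal\n")
        for (ctx, mate), (ret, tot) in sorted(report.profile.by_position.items()):
            for pos in range(len(tot)):
                fh.write(f"{ctx}\t{mate}\t{pos}\t{ret[pos]}\t{tot[pos]}\n")
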