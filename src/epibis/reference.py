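"""Packed 4-base reference and the two 3-base FM-indexes used for seeding.

A conversion-aware aligner cannot search reads against the plain genome:
after bisulfite (or enzymatic) treatment an unmethylated C reads as T, so
exact seeding is done against *converted* copies of the genome instead.
Two indexes are built, each over the concatenation of the forward and the
reverse strand of the genome:

* the **C-less** index converts every C to T,
* the **G-less** index converts every G to A.

The two indexed texts are exact reverse complements of one another (apply
A<->T, C<->G after conversion), which is what lets a plain backward search
on each index together emulate a bidirectional search.  The 4-base genome
is kept alongside as a 2-bit packed array (with an N mask) for the
compatibility filter and for seed extension, which always score against
the original bases.

Coordinates are 0-based internally; conversion to SAM (1-based) happens
only at serialization.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

INDEX_FORMAT_VERSION = "1"

# 4-base reference code space (used by the aligner and DP).
REF_A, REF_C, REF_G, REF_T, REF_N = 0, 1, 2, 3, 4
_REF_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGTN", (REF_A, REF_C, REF_G, REF_T, REF_N)):
    _REF_CODE[_b] = _c
_REF_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)
REF_COMPLEMENT = np.array([REF_T, REF_G, REF_C, REF_A, REF_N], dtype=np.uint8)

# FM-index code space.  Sentinels sort before all bases; SEP is used for N
# and for contig boundaries and never occurs in a query pattern, so exact
# matches can cross neither an N nor a contig junction.
FM_SENT_FWD, FM_SENT_REV, FM_A, FM_C, FM_G, FM_T, FM_SEP = 0, 1, 2, 3, 4, 5, 6
FM_NSYMBOLS = 7
_FM_FROM_REF = np.array([FM_A, FM_C, FM_G, FM_T, FM_SEP], dtype=np.uint8)
_FM_COMPLEMENT = np.zeros(FM_NSYMBOLS, dtype=np.uint8)
_FM_COMPLEMENT[[FM_A, FM_C, FM_G, FM_T, FM_SEP]] = [FM_T, FM_G, FM_C, FM_A, FM_SEP]
_FM_CHAR = {FM_SENT_FWD: "$", FM_SENT_REV: "#", FM_A: "A", FM_C: "C",
            FM_G: "G", FM_T: "T", FM_SEP: "N"}

C_LESS = "C_LESS"
G_LESS = "G_LESS"


class ReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class Reference:
    """Ordered collection of named contigs over {A,C,G,T,N} (uppercase)."""

    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.contigs:
            raise ReferenceError("reference must contain at least one contig")
        seen = set()
        for name, seq in self.contigs:
            if not name:
                raise ReferenceError("contig names must be nonempty")
            if name in seen:
                raise ReferenceError(f"duplicate contig name {name!r}")
            seen.add(name)
            if not seq:
                raise ReferenceError(f"contig {name!r} is empty")
            bad = _first_bad_base(seq)
            if bad is not None:
                raise ReferenceError(
                    f"contig {name!r}: non-ACGTN character {seq[bad]!r} at position {bad}"
                )

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        from Bio import SeqIO

        path = str(path)
        if path.endswith(".gz"):
            import gzip

            with gzip.open(path, "rt") as fh:
                recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
        else:
            recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
        return cls(tuple(recs))

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def __getitem__(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)


def _first_bad_base(seq: str) -> int | None:
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = _REF_CODE[arr] < 0
    if bad.any():
        return int(np.argmax(bad))
    return None


def encode_bases(seq: str) -> np.ndarray:
    """ACGTN string -> reference codes (uint8)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _REF_CODE[arr]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ReferenceError(f"non-ACGTN character {seq[pos]!r} at position {pos}")
    return codes.astype(np.uint8)


def decode_bases(codes: np.ndarray) -> str:
    return _REF_BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return REF_COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode_bases(revcomp_codes(encode_bases(seq)))


class PackedReference:
    """2-bit packed genome with an N mask; round-trips the input exactly.

    Bases are stored 4-per-byte; N positions keep a placeholder base and are
    restored through the mask on unpacking.  ``codes`` decodes (and caches)
    a whole contig as uint8 reference codes for fast slicing during
    alignment.
    """

    def __init__(self, names, lengths, packed, n_masks):
        self.names = list(names)
        self.lengths = list(lengths)
        self._packed = list(packed)
        self._n_masks = list(n_masks)
        self._cache: dict[int, np.ndarray] = {}
        self._index = {n: i for i, n in enumerate(self.names)}
        # cumulative 0-based offsets of each contig in the concatenated genome
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)]).astype(np.int64)

    @classmethod
    def from_reference(cls, ref: Reference) -> "PackedReference":
        names, lengths, packed, masks = [], [], [], []
        for name, seq in ref.contigs:
            codes = encode_bases(seq)
            n_mask = codes == REF_N
            two_bit = np.where(n_mask, 0, codes).astype(np.uint8)
            pk = np.zeros((len(codes) + 3) // 4, dtype=np.uint8)
            for shift in range(4):
                part = two_bit[shift::4]
                pk[: len(part)] |= part << (2 * shift)
            names.append(name)
            lengths.append(len(seq))
            packed.append(pk)
            masks.append(np.packbits(n_mask))
        return cls(names, lengths, packed, masks)

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def contig_index(self, name: str) -> int:
        return self._index[name]

    def codes(self, contig: str | int) -> np.ndarray:
        i = contig if isinstance(contig, int) else self._index[contig]
        cached = self._cache.get(i)
        if cached is None:
            n = self.lengths[i]
            pk = self._packed[i]
            out = np.empty(len(pk) * 4, dtype=np.uint8)
            for shift in range(4):
                out[shift::4] = (pk >> (2 * shift)) & 3
            out = out[:n]
            mask = np.unpackbits(self._n_masks[i])[:n].astype(bool)
            out[mask] = REF_N
            self._cache[i] = out
            cached = out
        return cached

    def fetch(self, contig: str | int, start: int = 0, end: int | None = None) -> str:
        codes = self.codes(contig)
        return decode_bases(codes[start:end])

    def base(self, contig: str | int, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)

    def to_reference(self) -> Reference:
        return Reference(tuple((n, self.fetch(n)) for n in self.names))


@dataclass(frozen=True)
class SAInterval:
    """Half-open interval of suffix-array rows plus matched pattern length."""

    lower: int
    upper: int
    matched: int = 0

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")

    @property
    def size(self) -> int:
        return self.upper - self.lower

    @property
    def empty(self) -> bool:
        return self.upper <= self.lower


def _build_suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers) on an int array."""
    n = len(text)
    rank = np.asarray(text, dtype=np.int64)
    idx = np.arange(n)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.zeros(n, dtype=np.int64)
        ahead = idx + k
        valid = ahead < n
        key2[valid] = rank[ahead[valid]] + 1
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        new_rank = np.empty(n, dtype=np.int64)
        boundary = np.empty(n, dtype=np.int64)
        boundary[0] = 0
        boundary[1:] = (np.diff(r1) != 0) | (np.diff(r2) != 0)
        new_rank[sa] = np.cumsum(boundary)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa.astype(np.int64)
        k *= 2


class ConvertedIndex:
    """FM-index over one in-silico converted forward+reverse genome text.

    Layout of the indexed text (sentinels ordered before all bases)::

        conv(contig1) SEP conv(contig2) ... $  conv(revcomp(genome)) ... #

    ``sa_spacing`` samples the suffix array at text positions divisible by
    the spacing; ``occ_spacing`` checkpoints the occurrence table.  Neither
    changes any query result, only the speed/memory trade-off.
    """

    def __init__(self, kind: str, text: np.ndarray, names, lengths,
                 sa_spacing: int = 4, occ_spacing: int = 64,
                 _precomputed: dict | None = None):
        if kind not in (C_LESS, G_LESS):
            raise ValueError(f"unknown conversion kind {kind!r}")
        self.kind = kind
        self.text = text
        self.names = list(names)
        self.lengths = list(lengths)
        self.sa_spacing = int(sa_spacing)
        self.occ_spacing = int(occ_spacing)
        # layout: contigs joined by single SEP
        starts = []
        off = 0
        for ln in self.lengths:
            starts.append(off)
            off += ln + 1
        self.layout_starts = np.asarray(starts, dtype=np.int64)
        self.layout_length = off - 1  # length of the forward region
        self.n = len(text)

        if _precomputed is not None:
            self.sa_sampled = _precomputed["sa_sampled"]
            self.bwt = _precomputed["bwt"]
            self.counts = _precomputed["counts"]
            self.checkpoints = _precomputed["checkpoints"]
        else:
            sa = _build_suffix_array(text)
            self.bwt = text[(sa - 1) % self.n]
            sampled = np.full(self.n, -1, dtype=np.int64)
            mask = (sa % self.sa_spacing) == 0
            sampled[mask] = sa[mask]
            self.sa_sampled = sampled
            self.counts = self._cumulative_counts(text)
            self.checkpoints = self._build_checkpoints(self.bwt, self.occ_spacing)

    # -- construction ------------------------------------------------------
    @classmethod
    def build(cls, ref: Reference | PackedReference, kind: str,
              sa_spacing: int = 4, occ_spacing: int = 64) -> "ConvertedIndex":
        packed = ref if isinstance(ref, PackedReference) else PackedReference.from_reference(ref)
        pieces = [_FM_FROM_REF[packed.codes(n)] for n in packed.names]
        fwd = pieces[0]
        for p in pieces[1:]:
            fwd = np.concatenate([fwd, [FM_SEP], p])
        rev = _FM_COMPLEMENT[fwd][::-1]
        fwd = cls._convert(fwd, kind)
        rev = cls._convert(rev, kind)
        text = np.concatenate(
            [fwd, [FM_SENT_FWD], rev, [FM_SENT_REV]]
        ).astype(np.uint8)
        return cls(kind, text, packed.names, packed.lengths,
                   sa_spacing=sa_spacing, occ_spacing=occ_spacing)

    @staticmethod
    def _convert(codes: np.ndarray, kind: str) -> np.ndarray:
        out = codes.copy()
        if kind == C_LESS:
            out[out == FM_C] = FM_T
        else:
            out[out == FM_G] = FM_A
        return out

    @staticmethod
    def _cumulative_counts(text: np.ndarray) -> np.ndarray:
        hist = np.bincount(text, minlength=FM_NSYMBOLS)
        return np.concatenate([[0], np.cumsum(hist)])[:FM_NSYMBOLS].astype(np.int64)

    @staticmethod
    def _build_checkpoints(bwt: np.ndarray, spacing: int) -> np.ndarray:
        n = len(bwt)
        ncp = n // spacing + 1
        cp = np.zeros((FM_NSYMBOLS, ncp), dtype=np.int64)
        onehot = np.zeros((FM_NSYMBOLS, n), dtype=np.int64)
        onehot[bwt, np.arange(n)] = 1
        csum = np.cumsum(onehot, axis=1)
        for q in range(1, ncp):
            cp[:, q] = csum[:, q * spacing - 1]
        return cp

    # -- core queries ------------------------------------------------------
    def occ(self, symbol: int, i: int) -> int:
        """Occurrences of symbol in bwt[:i]."""
        q, r = divmod(i, self.occ_spacing)
        cnt = int(self.checkpoints[symbol, q])
        if r:
            base = q * self.occ_spacing
            cnt += int(np.count_nonzero(self.bwt[base : base + r] == symbol))
        return cnt

    def step(self, symbol: int, lower: int, upper: int) -> tuple[int, int]:
        c0 = int(self.counts[symbol])
        return c0 + self.occ(symbol, lower), c0 + self.occ(symbol, upper)

    def lf(self, row: int) -> int:
        sym = int(self.bwt[row])
        return int(self.counts[sym]) + self.occ(sym, row)

    def encode_pattern(self, pattern: str) -> np.ndarray | None:
        """Pattern string -> FM codes; None if it contains a symbol that can
        never match (N, or an excluded letter is handled naturally by an
        empty interval)."""
        try:
            codes = encode_bases(pattern)
        except ReferenceError:
            return None
        if (codes == REF_N).any():
            return None
        return _FM_FROM_REF[codes]

    def backward_search(self, pattern: str | np.ndarray) -> SAInterval:
        if isinstance(pattern, str):
            codes = self.encode_pattern(pattern)
            if codes is None:
                return SAInterval(0, 0, 0)
        else:
            codes = pattern
        if len(codes) > self.n:
            return SAInterval(0, 0, 0)
        lower, upper = 0, self.n
        matched = 0
        for sym in codes[::-1]:
            lower, upper = self.step(int(sym), lower, upper)
            if lower >= upper:
                return SAInterval(lower, lower, matched)
            matched += 1
        return SAInterval(lower, upper, matched)

    def suffix_position(self, row: int) -> int:
        """Text offset of the suffix at a suffix-array row (LF walking)."""
        steps = 0
        while self.sa_sampled[row] < 0:
            row = self.lf(row)
            steps += 1
        return int((self.sa_sampled[row] + steps) % self.n)

    def resolve(self, text_offset: int, length: int):
        """Map a match at a text offset to (contig, pos0, strand) or None.

        ``pos0`` is the leftmost genome coordinate covered by the match.
        Matches touching a sentinel/separator are unmappable (cannot occur
        for patterns over {A,C,G,T}).
        """
        L = self.layout_length
        if text_offset + length <= L:
            p0 = text_offset
        elif text_offset > L:  # reverse-strand region
            r = text_offset - (L + 1)
            p0 = L - r - length
            if p0 < 0:
                return None
        else:
            return None
        i = int(bisect_right(self.layout_starts, p0) - 1)
        start = int(self.layout_starts[i])
        pos = p0 - start
        if pos + length > self.lengths[i]:
            return None  # spans a contig separator
        strand = "+" if text_offset + length <= L else "-"
        return self.names[i], int(pos), strand

    def locate(self, interval: SAInterval, max_hits: int = 64):
        """Genomic coordinates for every row of an interval.

        Returns ``(hits, truncated)`` where hits is a list of
        (contig, pos0, strand) and truncated flags that the interval held
        more than max_hits rows.
        """
        hits = []
        truncated = interval.size > max_hits
        for row in range(interval.lower, min(interval.upper, interval.lower + max_hits)):
            off = self.suffix_position(row)
            res = self.resolve(off, interval.matched)
            if res is not None:
                hits.append(res)
        return hits, truncated

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": INDEX_FORMAT_VERSION,
            "kind": self.kind,
            "sa_spacing": self.sa_spacing,
            "occ_spacing": self.occ_spacing,
            "names": self.names,
            "lengths": self.lengths,
        }
        (d / "meta.json").write_text(json.dumps(meta))
        np.savez(d / "arrays.npz", text=self.text, bwt=self.bwt,
                 sa_sampled=self.sa_sampled, counts=self.counts,
                 checkpoints=self.checkpoints)

    @classmethod
    def load(cls, directory) -> "ConvertedIndex":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        if meta["format_version"] != INDEX_FORMAT_VERSION:
            raise ValueError("unsupported index format version")
        arrays = np.load(d / "arrays.npz")
        pre = {k: arrays[k] for k in ("sa_sampled", "bwt", "counts", "checkpoints")}
        return cls(meta["kind"], arrays["text"], meta["names"], meta["lengths"],
                   sa_spacing=meta["sa_spacing"], occ_spacing=meta["occ_spacing"],
                   _precomputed=pre)

    def indexed_text(self, include_sentinels: bool = True) -> str:
        s = "".join(_FM_CHAR[int(c)] for c in self.text)
        return s if include_sentinels else s.replace("$", "").replace("#", "")


class GenomeIndex:
    """Bundle of packed reference + C-less + G-less indexes (one directory)."""

    def __init__(self, packed: PackedReference, c_less: ConvertedIndex,
                 g_less: ConvertedIndex):
        self.packed = packed
        self.c_less = c_less
        self.g_less = g_less

    @classmethod
    def build(cls, ref: Reference, sa_spacing: int = 4, occ_spacing: int = 64) -> "GenomeIndex":
        packed = PackedReference.from_reference(ref)
        return cls(
            packed,
            ConvertedIndex.build(packed, C_LESS, sa_spacing, occ_spacing),
            ConvertedIndex.build(packed, G_LESS, sa_spacing, occ_spacing),
        )

    def by_kind(self, kind: str) -> ConvertedIndex:
        return self.c_less if kind == C_LESS else self.g_less

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.packed.to_reference().to_fasta(d / "reference.fa")
        self.c_less.save(d / "c_less")
        self.g_less.save(d / "g_less")
        (d / "version.json").write_text(
            json.dumps({"format_version": INDEX_FORMAT_VERSION})
        )

    @classmethod
    def load(cls, directory) -> "GenomeIndex":
        d = Path(directory)
        if not (d / "version.json").exists():
            raise FileNotFoundError(f"{d} is not an index directory")
        ref = Reference.from_fasta(d / "reference.fa")
        return cls(
            PackedReference.from_reference(ref),
            ConvertedIndex.load(d / "c_less"),
            ConvertedIndex.load(d / "g_less"),
        )


def build_packed_reference(ref: Reference) -> PackedReference:
    return PackedReference.from_reference(ref)


def build_converted_index(ref: Reference, kind: str, **kw) -> ConvertedIndex:
    return ConvertedIndex.build(ref, kind, **kw)
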