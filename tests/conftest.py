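"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (string scans, triple-loop DP) and
never share code with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from epibis.reference import Reference, GenomeIndex, PackedReference


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def naive_occurrences(text: str, pattern: str) -> list[int]:
    """All start offsets of pattern in text by straight scanning."""
    out = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def oracle_local_affine(read: str, ref: str, sub_score, gap_open: int,
                        gap_extend: int) -> int:
    """Plain triple-matrix Gotoh local alignment, loops only.

    ``sub_score(ref_base, read_base)`` returns the substitution score.
    A gap of length k costs gap_open + k*gap_extend.
    """
    n, m = len(read), len(ref)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub_score(ref[j - 1], read[i - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_genotype_posteriors(counts: dict[str, float], ref: str,
                               e: float, c: float, theta: float) -> dict[str, float]:
    """Direct summation over all 10 diploid genotypes (independent of the
    implementation's log-space arithmetic)."""
    from itertools import combinations_with_replacement

    def pb(b, a):
        return 1 - e if b == a else e / 3

    genos = ["".join(g) for g in combinations_with_replacement("ACGT", 2)]
    pri = {}
    for g in genos:
        nref = g.count(ref)
        if nref == 2:
            pri[g] = 1 - 1.5 * theta
        elif nref == 1:
            pri[g] = theta
        elif g[0] == g[1]:
            pri[g] = theta / 2
        else:
            pri[g] = theta * theta
    z = sum(pri.values())
    post = {}
    for g in genos:
        lik = 1.0
        for b, cnt in counts.items():
            p = (1 - c) * 0.5 * (pb(b, g[0]) + pb(b, g[1])) + c * pb(b, ref)
            lik *= p ** cnt
        post[g] = lik * pri[g] / z
    total = sum(post.values())
    return {g: v / total for g, v in post.items()}


@pytest.fixture(scope="session")
def small_genome() -> str:
    return random_genome(np.random.default_rng(101), 2000, gc=0.45)


@pytest.fixture(scope="session")
def small_index(small_genome) -> GenomeIndex:
    return GenomeIndex.build(Reference((("chr1", small_genome),)))


@pytest.fixture(scope="session")
def two_contig_index() -> GenomeIndex:
    rng = np.random.default_rng(103)
    ref = Reference((
        ("chrA", random_genome(rng, 800)),
        ("chrB", random_genome(rng, 600)),
    ))
    return GenomeIndex.build(ref)
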