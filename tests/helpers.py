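"""Shared constructors and independent brute-force oracles for the tests.

The oracles here deliberately avoid the code paths they check: Jaccard via
per-base sets, confirmation via all-pairs distance arithmetic, Fisher tails
via exact integer enumeration of the hypergeometric support.
"""

from __future__ import annotations

import math
from fractions import Fraction

from chromlink.io_formats import Contact, GenomicInterval, Peak


def iv(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


_COUNTER = [0]


def peak(chrom, start, end, lnc="L1", mark="H3K27ac", sign="+", pid=None):
    if pid is None:
        _COUNTER[0] += 1
        pid = f"p{_COUNTER[0]}"
    return Peak(iv(chrom, start, end), mark, sign, pid, lnc)


def contact(chrom, start, end, lnc="L1", exp="exp1"):
    return Contact(iv(chrom, start, end), lnc, exp)


def jaccard_by_bases(a: GenomicInterval, b: GenomicInterval) -> float:
    """Per-base set computation; only sensible for short intervals."""
    if a.chrom != b.chrom:
        return 0.0
    sa = set(range(a.start, a.end))
    sb = set(range(b.start, b.end))
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def confirmed_by_all_pairs(peaks, contacts, w: int) -> list[bool]:
    """O(n*m) confirmation verdicts by direct extended-overlap arithmetic."""
    out = []
    for p in peaks:
        ok = False
        for c in contacts:
            if c.lncrna_id != p.lncrna_id or c.interval.chrom != p.interval.chrom:
                continue
            if (c.interval.start - w < p.interval.end
                    and c.interval.end + w > p.interval.start):
                ok = True
                break
        out.append(ok)
    return out


def exact_fisher_tails(a: int, b: int, c: int, d: int) -> tuple[Fraction, Fraction]:
    """(right, left) tail probabilities by enumeration of the support.

    Margins (a+b, c+d, a+c) fixed; exact rational arithmetic.
    """
    r1, r2, K = a + b, c + d, a + c
    N = r1 + r2
    denom = math.comb(N, K)
    lo, hi = max(0, K - r2), min(K, r1)
    right = sum(math.comb(r1, k) * math.comb(r2, K - k) for k in range(a, hi + 1))
    left = sum(math.comb(r1, k) * math.comb(r2, K - k) for k in range(lo, a + 1))
    return Fraction(right, denom), Fraction(left, denom)
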