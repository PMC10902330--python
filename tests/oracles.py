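"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the cosinor oracle
is a shrinking brute-force grid search over (mesor, a, b); the motif
oracle enumerates every concrete expansion of an IUPAC string and counts
substring occurrences; the Fisher and hypergeometric oracles enumerate
tables with ``math.comb``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def grid_search_cosinor(y, t, period, n_iter=40, n_pts=13):
    """Brute-force least squares for y = m + a cos(wt) + b sin(wt).

    Shrinking 3-D grid search; returns (mesor, amplitude_peak_to_trough,
    phase in [0, 2pi), rss).
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    w = 2 * np.pi / period
    cos_t, sin_t = np.cos(w * t), np.sin(w * t)
    span = max(y.max() - y.min(), 1.0)
    centers = np.array([y.mean(), 0.0, 0.0])
    half = np.array([span, span, span])
    for _ in range(n_iter):
        axes = [np.linspace(c - h, c + h, n_pts) for c, h in zip(centers, half)]
        M, A, B = np.meshgrid(*axes, indexing="ij")
        pred = (
            M[..., None]
            + A[..., None] * cos_t[None, None, None, :]
            + B[..., None] * sin_t[None, None, None, :]
        )
        rss = ((pred - y) ** 2).sum(axis=-1)
        idx = np.unravel_index(np.argmin(rss), rss.shape)
        centers = np.array([axes[k][idx[k]] for k in range(3)])
        half = half * (2.0 / (n_pts - 1)) * 1.5
    m, a, b = centers
    amp = 2.0 * math.hypot(a, b)
    phase = math.atan2(b, a) % (2 * np.pi) if amp > 1e-9 else 0.0
    resid = y - (m + a * cos_t + b * sin_t)
    return m, amp, phase, float(resid @ resid)


def expand_iupac(motif: str) -> list[str]:
    return ["".join(p) for p in itertools.product(*(IUPAC[c] for c in motif.upper()))]


def _count_overlapping(seq: str, word: str) -> int:
    count, i = 0, seq.find(word)
    while i != -1:
        count += 1
        i = seq.find(word, i + 1)
    return count


def regex_expansion_count(seq: str, motif: str, both_strands: bool = True) -> int:
    """Total overlapping matches by exhaustive expansion of the IUPAC string."""
    total = sum(_count_overlapping(seq, w) for w in expand_iupac(motif))
    if both_strands:
        rc = motif.upper().translate(str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))[::-1]
        total += sum(_count_overlapping(seq, w) for w in expand_iupac(rc))
    return total


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Probability-mass criterion; tables whose probability ties the observed
    one (within 1e-7 relative) are included.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    denom = math.comb(n, c1)

    def pmf(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), by enumeration."""
    denom = math.comb(M, n)
    return sum(
        math.comb(K, x) * math.comb(M - K, n - x) / denom
        for x in range(k, min(K, n) + 1)
    )


def holm_by_hand(p_values):
    """Step-down Holm: sort, multiply by m-i, enforce monotone, cap at 1."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj
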