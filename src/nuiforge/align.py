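"""Global pairwise alignment (Gotoh affine-gap DP, numpy-vectorized rows).

Scoring follows the pairwise comparison scheme used for cluster identity:
match +1, mismatch -4, any comparison involving N scores ``n_score`` (0),
gap opening -4, gap extension 0 by default.  Case is ignored.

The vectorized inner recurrence for the "gap in a" state assumes
``gap_open <= gap_extend`` (true for every sensible scheme here); this is
asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NINF = -1.0e30
_EPS = 1e-6

# guard margin kept on each side when stripping shared prefix/suffix so the
# DP can re-optimize around the boundary
_STRIP_MARGIN = 8
_STRIP_MIN_LEN = 512


@dataclass
class PairwiseScheme:
    """Scoring constants for pairwise identity alignment."""

    match: float = 1.0
    mismatch: float = -4.0
    n_score: float = 0.0
    gap_open: float = -4.0
    gap_extend: float = 0.0


@dataclass
class Alignment:
    score: float
    aligned_a: str
    aligned_b: str

    def matched_columns(self) -> int:
        """Columns where both rows carry the same determined base."""
        n = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x != "-" and y != "-":
                ux, uy = x.upper(), y.upper()
                if ux == uy and ux != "N":
                    n += 1
        return n


def _pair_score(a: str, b: str, scheme: PairwiseScheme) -> float:
    """Score of a gapless column-by-column alignment of equal-length strings."""
    s = 0.0
    for x, y in zip(a, b):
        ux, uy = x.upper(), y.upper()
        if ux == "N" or uy == "N":
            s += scheme.n_score
        elif ux == uy:
            s += scheme.match
        else:
            s += scheme.mismatch
    return s


def _gotoh(a: str, b: str, scheme: PairwiseScheme) -> Alignment:
    op, ex = scheme.gap_open, scheme.gap_extend
    assert op <= ex, "vectorized recurrence requires gap_open <= gap_extend"
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return Alignment(0.0, "", "")
    if n == 0:
        return Alignment(op + ex * (m - 1), "-" * m, b)
    if m == 0:
        return Alignment(op + ex * (n - 1), a, "-" * n)
    if (n + 1) * (m + 1) > 300_000_000:
        raise ValueError(f"alignment problem too large: {n} x {m}")

    ua = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    ub = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    b_is_n = ub == ord("N")

    M = np.full((n + 1, m + 1), NINF, dtype=np.float64)
    Ix = np.full((n + 1, m + 1), NINF, dtype=np.float64)
    Iy = np.full((n + 1, m + 1), NINF, dtype=np.float64)
    M[0, 0] = 0.0
    if n >= 1:
        Ix[1:, 0] = op + ex * np.arange(n, dtype=np.float64)
    if m >= 1:
        Iy[0, 1:] = op + ex * np.arange(m, dtype=np.float64)

    js = np.arange(1, m + 1, dtype=np.float64)
    h_prev = np.maximum(np.maximum(M[0], Ix[0]), Iy[0])
    for i in range(1, n + 1):
        ai = ua[i - 1]
        if ai == ord("N"):
            sub = np.full(m, scheme.n_score)
        else:
            sub = np.where(
                b_is_n,
                scheme.n_score,
                np.where(ub == ai, scheme.match, scheme.mismatch),
            )
        M[i, 1:] = h_prev[:-1] + sub
        Ix[i, :] = np.maximum(h_prev + op, Ix[i - 1, :] + ex)
        Ix[i, 0] = op + ex * (i - 1)
        G = np.maximum(M[i, :], Ix[i, :])
        T = G - ex * np.arange(m + 1, dtype=np.float64)
        runmax = np.maximum.accumulate(T)
        Iy[i, 1:] = op + ex * (js - 1.0) + runmax[:-1]
        Iy[i, 0] = NINF
        h_prev = np.maximum(np.maximum(M[i], Ix[i]), Iy[i])

    def pick(i: int, j: int) -> int:  # 0 = M, 1 = Ix, 2 = Iy
        vals = (M[i, j], Ix[i, j], Iy[i, j])
        return int(np.argmax(vals))

    score = max(M[n, m], Ix[n, m], Iy[n, m])
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = pick(n, m)
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i > 0 or j > 0:
                state = pick(i, j)
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            stay = i > 1 and Ix[i, j] <= Ix[i - 1, j] + ex + _EPS and Ix[
                i, j
            ] >= Ix[i - 1, j] + ex - _EPS
            i -= 1
            state = 1 if stay and Ix[i, j] > NINF / 2 else pick(i, j)
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            stay = j > 1 and Iy[i, j] <= Iy[i, j - 1] + ex + _EPS and Iy[
                i, j
            ] >= Iy[i, j - 1] + ex - _EPS
            j -= 1
            state = 2 if stay and Iy[i, j] > NINF / 2 else pick(i, j)
    return Alignment(float(score), "".join(reversed(out_a)), "".join(reversed(out_b)))


def global_align(a: str, b: str, scheme: PairwiseScheme | None = None) -> Alignment:
    """Optimal global alignment of two sequences under the pairwise scheme."""
    scheme = scheme or PairwiseScheme()
    if a.upper() == b.upper():
        return Alignment(_pair_score(a, b, scheme), a, b)
    # long, highly similar sequences: strip shared ends, align the middle
    if min(len(a), len(b)) > _STRIP_MIN_LEN:
        ua, ub = a.upper(), b.upper()
        p = 0
        limit = min(len(a), len(b))
        while p < limit and ua[p] == ub[p]:
            p += 1
        s = 0
        while s < limit - p and ua[len(a) - 1 - s] == ub[len(b) - 1 - s]:
            s += 1
        p = max(0, p - _STRIP_MARGIN)
        s = max(0, s - _STRIP_MARGIN)
        if p + s > _STRIP_MARGIN:
            mid = _gotoh(a[p : len(a) - s], b[p : len(b) - s], scheme)
            pre_score = _pair_score(a[:p], b[:p], scheme)
            suf_score = (
                _pair_score(a[len(a) - s :], b[len(b) - s :], scheme) if s else 0.0
            )
            return Alignment(
                pre_score + mid.score + suf_score,
                a[:p] + mid.aligned_a + (a[len(a) - s :] if s else ""),
                b[:p] + mid.aligned_b + (b[len(b) - s :] if s else ""),
            )
    return _gotoh(a, b, scheme)
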