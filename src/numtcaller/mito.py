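"""Helpers for circular mitochondrial coordinates and sequence matching.

The human mitochondrial genome is circular (16,569 bp in rCRS coordinates),
and Numt source fragments may span the replication origin, so every interval
on the mitochondrial contig is treated modulo its length.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def circular_length(start: int, end: int, mito_length: int) -> int:
    """Length of the circular interval [start, end).

    ``end <= start`` denotes an origin-wrapping fragment; ``end == start``
    is ambiguous and rejected, while ``end == mito_length`` with ``start == 0``
    is the full circle.
    """
    if start == end:
        raise ValueError("zero-length mitochondrial fragment")
    if end > start:
        return end - start
    return mito_length - start + end


def circular_slice(seq: str, start: int, end: int) -> str:
    """Extract the circular interval [start, end) from ``seq``."""
    n = len(seq)
    length = circular_length(start, end, n)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: (start + length) - n]


def circular_interval_from_points(points, mito_length: int):
    """Smallest circular interval [start, end) covering all points.

    Computed as the complement of the largest gap between consecutive points
    on the circle, which stays correct for fragments wrapping the origin.
    Returns None for empty input.
    """
    pts = sorted({int(p) % mito_length for p in points})
    if not pts:
        return None
    if len(pts) == 1:
        return (pts[0], (pts[0] + 1) % mito_length)
    gaps = []
    for i in range(len(pts)):
        nxt = pts[(i + 1) % len(pts)]
        gap = (nxt - pts[i]) % mito_length
        gaps.append((gap, i))
    gap, i = max(gaps)
    start = pts[(i + 1) % len(pts)]
    end = (pts[i] + 1) % mito_length
    return (start, end)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


class CircularMatcher:
    """Ungapped scanner of query tails against a circular sequence.

    The target is doubled so alignments crossing the origin are found by a
    plain linear scan; both strands are searched.
    """

    def __init__(self, mito_seq: str):
        self.length = len(mito_seq)
        self.seq = mito_seq.upper()
        self._fwd = _encode(self.seq + self.seq)

    def best_match(self, query: str):
        """Return (identity, offset, strand) of the best ungapped placement.

        ``offset`` is the 0-based start on the forward circle; strand is
        '+'/'-'. Queries longer than the circle are truncated to one turn.
        """
        q = query.upper()
        if len(q) > self.length:
            q = q[: self.length]
        best = (-1.0, 0, "+")
        for strand, qs in (("+", q), ("-", revcomp(q))):
            arr = _encode(qs)
            windows = np.lib.stride_tricks.sliding_window_view(
                self._fwd[: self.length + len(arr) - 1], len(arr)
            )
            scores = (windows == arr).mean(axis=1)
            i = int(np.argmax(scores))
            ident = float(scores[i])
            if ident > best[0]:
                best = (ident, i % self.length, strand)
        return best

    def matches(self, query: str, min_identity: float = 0.9) -> bool:
        return self.best_match(query)[0] >= min_identity
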