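"""Haar-Walsh wavelet packet transform on dyadic signals.

The wavelet packet transform (WPT) recursively splits *every* branch of the
filter cascade, not just the low-pass one, so a signal of length ``2**M``
yields ``M`` coefficient rows of length ``2**M`` each.  Row ``j`` is organised
as ``2**j`` frequency blocks of ``2**(M-j)`` translations; the basis vector
behind coefficient ``(j, b, t)`` is a Walsh (+/-1 step) function living on the
dyadic interval of ``2**j`` samples starting at ``t * 2**j``.

With the Haar filters in the orthonormal convention,

    low  = (x[2t] + x[2t+1]) / sqrt(2)
    high = (x[2t] - x[2t+1]) / sqrt(2)

every row is an orthonormal change of basis, so energy is conserved at each
depth (Parseval) and each row inverts exactly.  Frequency blocks are kept in
natural (filter-cascade) order: the low-pass child of block ``b`` is ``2b``
and the high-pass child is ``2b + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class CoefficientIndex:
    """Position of one coefficient: depth ``j``, frequency block ``b``,
    translation ``t``.  The flat index within row ``j`` is
    ``b * 2**(M - j) + t``."""

    depth: int
    block: int
    translation: int

    def flat(self, M: int) -> int:
        return self.block * (1 << (M - self.depth)) + self.translation


@dataclass
class WPTTable:
    """Full coefficient table of one signal.

    ``coeffs[j]`` is the length-``2**M`` row at depth ``j``; ``coeffs[0]`` is
    the input signal itself.  Rows 0..max_depth are populated.
    """

    M: int
    coeffs: list[np.ndarray]

    @property
    def max_depth(self) -> int:
        return len(self.coeffs) - 1

    def row(self, j: int) -> np.ndarray:
        return self.coeffs[j]

    def coefficient(self, idx: CoefficientIndex) -> float:
        return float(self.coeffs[idx.depth][idx.flat(self.M)])


def _check_dyadic(n: int) -> int:
    M = int(n).bit_length() - 1
    if n <= 0 or (1 << M) != n:
        raise ValueError(f"signal length {n} is not a power of two")
    return M


def haar_wpt_forward(values: np.ndarray, max_depth: int | None = None) -> WPTTable:
    """Full Haar wavelet packet analysis down to ``max_depth``.

    Each depth-``j`` row is split blockwise into pairwise sums and differences
    scaled by ``1/sqrt(2)``; children are stored contiguously (natural order).
    """
    x = np.asarray(values, dtype=float).ravel()
    M = _check_dyadic(x.size)
    if max_depth is None:
        max_depth = M
    if not 0 <= max_depth <= M:
        raise ValueError(f"max_depth {max_depth} outside 0..{M}")

    rows = [x.copy()]
    for j in range(max_depth):
        prev = rows[-1].reshape(1 << j, -1)          # blocks x block length
        pairs = prev.reshape(1 << j, -1, 2)
        low = (pairs[:, :, 0] + pairs[:, :, 1]) / _SQRT2
        high = (pairs[:, :, 0] - pairs[:, :, 1]) / _SQRT2
        nxt = np.stack([low, high], axis=1).reshape(-1)
        rows.append(nxt)
    return WPTTable(M=M, coeffs=rows)


def haar_wpt_inverse(table: WPTTable, depth: int) -> np.ndarray:
    """Reconstruct the original signal from row ``depth`` alone."""
    if not 0 <= depth <= table.max_depth:
        raise ValueError(f"row {depth} not populated (max {table.max_depth})")
    row = table.coeffs[depth].copy()
    for j in range(depth, 0, -1):
        cur = row.reshape(1 << (j - 1), 2, -1)       # parent blocks x (low, high)
        low, high = cur[:, 0, :], cur[:, 1, :]
        even = (low + high) / _SQRT2
        odd = (low - high) / _SQRT2
        row = np.stack([even, odd], axis=2).reshape(-1)
    return row


def support_interval(idx: CoefficientIndex, samples_per_bp: int = 32) -> tuple[float, float]:
    """Half-open bp interval covered by the basis vector of ``idx``.

    A depth-``j`` packet spans ``2**j`` samples, i.e. ``2**j / samples_per_bp``
    bp, and translation ``t`` places it at ``t`` support-lengths from origin.
    """
    length = (1 << idx.depth) / samples_per_bp
    return (idx.translation * length, (idx.translation + 1) * length)


def walsh_sign_pattern(depth: int, block: int) -> np.ndarray:
    """+/-1 sign pattern of the natural-order Walsh packet ``(depth, block)``.

    Built by the synthesis recursion: the low child repeats the parent
    pattern, the high child appends its negation.  Independent of the
    analysis cascade, so it serves as its oracle.
    """
    if not 0 <= block < (1 << depth):
        raise ValueError(f"block {block} outside 0..{(1 << depth) - 1}")
    s = np.ones(1)
    for shift in range(depth - 1, -1, -1):
        bit = (block >> shift) & 1
        s = np.concatenate([s, -s]) if bit else np.concatenate([s, s])
    return s


def walsh_packet_function(idx: CoefficientIndex, M: int) -> np.ndarray:
    """Explicit unit-norm basis vector of coefficient ``idx`` on ``2**M`` samples.

    Its inner product with any signal equals the corresponding forward-WPT
    coefficient.
    """
    n = 1 << M
    size = 1 << idx.depth
    t = idx.translation
    if not 0 <= t < (1 << (M - idx.depth)):
        raise ValueError(f"translation {t} out of range at depth {idx.depth}")
    v = np.zeros(n)
    v[t * size:(t + 1) * size] = walsh_sign_pattern(idx.depth, idx.block) / np.sqrt(size)
    return v
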