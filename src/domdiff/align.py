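"""Global pairwise alignment and percent identity.

A deterministic Needleman-Wunsch aligner with linear gap costs, used as the
in-repo stand-in for the percent-identity matrices that external tools
(CLUSTALW/MALIGN-style) would produce.  Determinism matters because
co-optimal alignments can carry different match counts; the traceback
therefore breaks ties with a fixed preference: diagonal (substitution),
then up (gap in the second sequence), then left (gap in the first).

Percent identity is gap-excluded: 100 x matches / number of alignment
columns where both sequences hold a residue.
"""

from __future__ import annotations

import numpy as np

from .model import GAP

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


def _score_matrix(a: str, b: str, match: float, mismatch: float,
                  gap: float) -> np.ndarray:
    """Fill the (len(a)+1, len(b)+1) DP score matrix.

    Rows are filled with a max-plus prefix scan: with linear gap costs the
    left-dependency max(H[i, k] + gap*(j-k)) reduces to a cumulative maximum,
    so each row is one vectorised pass.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)

    H = np.empty((n + 1, m + 1), dtype=float)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    offs = gap * np.arange(m + 1)  # cost of trailing gap run ending at column j
    for i in range(1, n + 1):
        # candidate without the left move: diagonal vs up
        cand = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap)
        scan = np.empty(m + 1)
        scan[0] = H[i, 0]
        scan[1:] = cand - offs[1:]
        np.maximum.accumulate(scan, out=scan)
        H[i, 1:] = scan[1:] + offs[1:]
    return H


def global_align(a: str, b: str, match: float = DEFAULT_MATCH,
                 mismatch: float = DEFAULT_MISMATCH,
                 gap: float = DEFAULT_GAP) -> tuple[float, str, str]:
    """Optimal global alignment of ``a`` and ``b``.

    Returns ``(score, aligned_a, aligned_b)``.  Among co-optimal alignments
    the one reached by the diagonal > up > left traceback preference is
    returned, so the result is a deterministic function of the inputs.
    """
    if not a or not b:
        raise ValueError("global alignment requires non-empty sequences")
    H = _score_matrix(a, b, match, mismatch, gap)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            ra.append(a[i - 1])
            rb.append(GAP)
            i -= 1
            continue
        ra.append(GAP)
        rb.append(b[j - 1])
        j -= 1
    return float(H[len(a), len(b)]), "".join(reversed(ra)), "".join(reversed(rb))


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Gap-excluded percent identity of an aligned pair of rows."""
    paired = 0
    matches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != GAP and y != GAP:
            paired += 1
            if x == y:
                matches += 1
    if paired == 0:
        return 0.0
    return 100.0 * matches / paired


def global_align_identity(a: str, b: str, match: float = DEFAULT_MATCH,
                          mismatch: float = DEFAULT_MISMATCH,
                          gap: float = DEFAULT_GAP) -> tuple[float, str, str]:
    """Percent identity under the optimal global alignment.

    Returns ``(identity, aligned_a, aligned_b)``.  Co-optimal alignments can
    differ in match count, and the traceback preference is not symmetric in
    its arguments, so the pair is aligned in canonical (sorted) order and the
    rows swapped back: identity(a, b) == identity(b, a) always holds.
    """
    if a <= b:
        _, ra, rb = global_align(a, b, match=match, mismatch=mismatch, gap=gap)
    else:
        _, rb, ra = global_align(b, a, match=match, mismatch=mismatch, gap=gap)
    return percent_identity(ra, rb), ra, rb
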