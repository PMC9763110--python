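"""Vectorised genomic-interval primitives.

All coordinates are 0-based half-open ``[start, end)``. Operations that act
"within a key" take an integer key array (e.g. an encoding of sample ×
chromosome × CNV type) and never mix intervals across keys. The trick used
throughout is to lift coordinates into a keyed space ``key * 2**40 + coord``
so that intervals belonging to different keys can never touch; 2**40 exceeds
any chromosome length and keys stay far below 2**23, so the composite fits an
int64 without overflow.
"""

from __future__ import annotations

import numpy as np

_SHIFT = np.int64(1) << np.int64(40)

__all__ = [
    "merge_keyed",
    "pair_overlaps",
    "intersect_keyed",
    "covered_length",
]


def _as_i64(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    return tuple(np.asarray(a, dtype=np.int64) for a in arrays)


def merge_keyed(
    keys: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of intervals within each key.

    Returns ``(keys, starts, ends)`` of the merged, disjoint intervals sorted
    by (key, start). Abutting intervals ([0,5) and [5,9)) are kept separate:
    only a strict basepair overlap merges, so segment counts stay faithful to
    the underlying coverage runs.
    """
    keys, starts, ends = _as_i64(keys, starts, ends)
    if keys.size == 0:
        return keys, starts, ends
    s = keys * _SHIFT + starts
    e = keys * _SHIFT + ends
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    cummax_e = np.maximum.accumulate(e)
    first = np.empty(s.size, dtype=bool)
    first[0] = True
    first[1:] = s[1:] >= cummax_e[:-1]
    idx = np.flatnonzero(first)
    out_s = s[idx]
    out_e = np.maximum.reduceat(e, idx)
    out_k = out_s >> np.int64(40)
    return out_k, out_s - out_k * _SHIFT, out_e - out_k * _SHIFT


def pair_overlaps(
    akeys: np.ndarray,
    astarts: np.ndarray,
    aends: np.ndarray,
    bkeys: np.ndarray,
    bstarts: np.ndarray,
    bends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices ``(ai, bi)`` of every pair with the same key and >=1 bp overlap.

    Neither side needs to be disjoint; ``b`` is swept in start order with a
    running maximum of ends, candidates are expanded and then filtered to
    exact overlap, so the result is correct for arbitrarily overlapping
    inputs.
    """
    akeys, astarts, aends, bkeys, bstarts, bends = _as_i64(
        akeys, astarts, aends, bkeys, bstarts, bends
    )
    if akeys.size == 0 or bkeys.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    a_s = akeys * _SHIFT + astarts
    a_e = akeys * _SHIFT + aends
    b_s = bkeys * _SHIFT + bstarts
    b_e = bkeys * _SHIFT + bends
    border = np.argsort(b_s, kind="stable")
    b_s, b_e = b_s[border], b_e[border]
    b_cummax = np.maximum.accumulate(b_e)
    lo = np.searchsorted(b_cummax, a_s, side="right")
    hi = np.searchsorted(b_s, a_e, side="left")
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    ai = np.repeat(np.arange(akeys.size, dtype=np.int64), counts)
    offsets = np.cumsum(counts) - counts
    bi = np.arange(total, dtype=np.int64) - np.repeat(offsets, counts) + np.repeat(lo, counts)
    keep = (a_e[ai] > b_s[bi]) & (a_s[ai] < b_e[bi])
    return ai[keep], border[bi[keep]]


def intersect_keyed(
    akeys: np.ndarray,
    astarts: np.ndarray,
    aends: np.ndarray,
    bkeys: np.ndarray,
    bstarts: np.ndarray,
    bends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Basepair intersection of two keyed interval sets (per key).

    Inputs are unioned first, so the output is the set of maximal runs
    covered by both sides, disjoint within each key and sorted.
    """
    ak, as_, ae = merge_keyed(akeys, astarts, aends)
    bk, bs, be = merge_keyed(bkeys, bstarts, bends)
    ai, bi = pair_overlaps(ak, as_, ae, bk, bs, be)
    out_k = ak[ai]
    out_s = np.maximum(as_[ai], bs[bi])
    out_e = np.minimum(ae[ai], be[bi])
    order = np.lexsort((out_s, out_k))
    return out_k[order], out_s[order], out_e[order]


def covered_length(
    qkeys: np.ndarray,
    qstarts: np.ndarray,
    qends: np.ndarray,
    tkeys: np.ndarray,
    tstarts: np.ndarray,
    tends: np.ndarray,
) -> np.ndarray:
    """Bases of each query interval covered by the union of a track.

    Returns an int64 array aligned with the queries. The track may contain
    overlapping intervals; it is unioned per key before clipping.
    """
    qkeys, qstarts, qends = _as_i64(qkeys, qstarts, qends)
    tk, ts, te = merge_keyed(tkeys, tstarts, tends)
    qi, ti = pair_overlaps(qkeys, qstarts, qends, tk, ts, te)
    out = np.zeros(qkeys.size, dtype=np.int64)
    if qi.size:
        clip = np.minimum(qends[qi], te[ti]) - np.maximum(qstarts[qi], ts[ti])
        np.add.at(out, qi, clip)
    return out
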