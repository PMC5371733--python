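"""Light-weight genomic interval arithmetic on (start, end) half-open pairs.

All coordinates are 0-based half-open. Interval *sets* are represented as
lists/arrays of (start, end) pairs grouped by chromosome (and strand where it
matters); the helpers below operate on one chromosome's worth of intervals at
a time or on ``{chrom: Nx2 array}`` dicts.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "merge",
    "total_length",
    "intersect_length",
    "jaccard",
    "overlaps_any",
]


def _as_array(ivals) -> np.ndarray:
    a = np.asarray(ivals, dtype=np.int64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("intervals must be an Nx2 array of (start, end)")
    if np.any(a[:, 0] >= a[:, 1]):
        raise ValueError("intervals must satisfy start < end")
    return a


def merge(ivals) -> np.ndarray:
    """Merge overlapping or bookended intervals into maximal disjoint runs."""
    a = _as_array(ivals)
    if len(a) == 0:
        return a
    a = a[np.argsort(a[:, 0], kind="stable")]
    out = [list(a[0])]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(ivals) -> int:
    m = merge(ivals)
    if len(m) == 0:
        return 0
    return int((m[:, 1] - m[:, 0]).sum())


def intersect_length(a, b) -> int:
    """Total nucleotides covered by both interval sets (one chromosome)."""
    ma, mb = merge(a), merge(b)
    i = j = 0
    tot = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i, 0], mb[j, 0])
        e = min(ma[i, 1], mb[j, 1])
        if s < e:
            tot += e - s
        if ma[i, 1] < mb[j, 1]:
            i += 1
        else:
            j += 1
    return int(tot)


def jaccard(a, b) -> float:
    """Nucleotide-level Jaccard index |a∩b| / |a∪b| of two interval sets.

    ``a`` and ``b`` may be Nx2 arrays (single chromosome) or dicts keyed by
    chromosome (or (chrom, strand)). Both-empty input returns 0 with a warning.
    """
    if isinstance(a, dict) or isinstance(b, dict):
        if not isinstance(a, dict) or not isinstance(b, dict):
            raise TypeError("jaccard: both arguments must be dicts or both arrays")
        keys = set(a) | set(b)
        inter = sum(
            intersect_length(a.get(k, []), b.get(k, [])) for k in keys
        )
        la = sum(total_length(a.get(k, [])) for k in keys)
        lb = sum(total_length(b.get(k, [])) for k in keys)
    else:
        inter = intersect_length(a, b)
        la, lb = total_length(a), total_length(b)
    union = la + lb - inter
    if union == 0:
        warnings.warn("jaccard of two empty interval sets; defined as 0")
        return 0.0
    return inter / union


def intersect(a, b) -> np.ndarray:
    """Intervals covered by both sets (one chromosome), as a merged Nx2 array."""
    ma, mb = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i, 0], mb[j, 0])
        e = min(ma[i, 1], mb[j, 1])
        if s < e:
            out.append((s, e))
        if ma[i, 1] < mb[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def overlaps_any(start: int, end: int, ivals) -> bool:
    """True iff [start, end) overlaps at least one interval in the set."""
    a = _as_array(ivals)
    if len(a) == 0 or start >= end:
        return False
    return bool(np.any((a[:, 0] < end) & (a[:, 1] > start)))
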