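"""Bit-level kernels for the greedy matrix-correction search.

Matrices are packed into a 64-bit integer (cell (r, c) -> bit r*8+c) and
the 24 parity/checksum constraints into mask arrays, so that evaluating a
candidate bit flip costs a handful of popcounts: linear (XOR-type) checks
are updated incrementally with a per-cell toggle mask, the two nonlinear
checksum bits are recomputed.  The best-first search runs under numba with
a manual binary heap keyed by (overall weight, depth, insertion order).
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_CELLS = 48

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return np.uint64((x * _H01) >> np.uint64(56))


@njit(cache=True)
def violated_mask(bits, cov_mask, storage, shift):
    """24-bit mask of constraints whose stored bit mismatches."""
    bits = np.uint64(bits)  # guard against boxed python ints at the boundary
    viol = np.uint64(0)
    for j in range(cov_mask.shape[0]):
        pop = _popcount(bits & cov_mask[j])
        expected = (pop >> np.uint64(shift[j])) & np.uint64(1)
        stored = (bits >> np.uint64(storage[j])) & np.uint64(1)
        if expected != stored:
            viol |= np.uint64(1) << np.uint64(j)
    return viol


@njit(cache=True)
def _child_violated(child, viol, c, cov_mask, storage, shift, toggle, nonlin):
    """Violation mask after flipping cell ``c``: XOR-type constraints toggle,
    the (few) nonlinear checksum bits covering ``c`` are recomputed."""
    child = np.uint64(child)
    v = np.uint64(viol) ^ toggle[c]
    nl = nonlin[c]
    for j in range(cov_mask.shape[0]):
        if (nl >> np.uint64(j)) & np.uint64(1):
            pop = _popcount(child & cov_mask[j])
            expected = (pop >> np.uint64(shift[j])) & np.uint64(1)
            stored = (child >> np.uint64(storage[j])) & np.uint64(1)
            bit = np.uint64(1) << np.uint64(j)
            if expected != stored:
                v |= bit
            else:
                v &= ~bit
    return v


@njit(cache=True)
def _weight(viol, cover_by_cell, ncov, parity_mask, n_parity):
    """Overall matrix weight: summed cell weights over matched parity bits.

    A covered cell's weight is its number of violated covering checks; a
    storage cell's weight counts covered cells implicated by more than one
    violated check (computed via the co-coverage identity).
    """
    viol = np.uint64(viol)  # guard against boxed python ints at the boundary
    matched = n_parity - np.int64(_popcount(viol & np.uint64(parity_mask)))
    if matched == 0:
        return np.inf
    eq4 = np.int64(0)
    eq5 = np.int64(0)
    for c in range(N_CELLS):
        cnt = np.int64(_popcount(viol & cover_by_cell[c]))
        eq4 += cnt
        if cnt > 1:
            eq5 += ncov[c]
    return (eq4 + eq5) / matched


@njit(cache=True, inline="always")
def _heap_less(w, d, s, i, j):
    if w[i] != w[j]:
        return w[i] < w[j]
    if d[i] != d[j]:
        return d[i] > d[j]  # deeper first: commit to a descent, queue backtracks
    return s[i] < s[j]


# open-addressing visited set: keys are 48-bit matrices, so the all-ones
# 64-bit word can serve as the empty slot sentinel
_EMPTY = np.uint64(0xFFFFFFFFFFFFFFFF)
_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True)
def _visited_add(table, mask, key):
    """Insert ``key`` if absent; returns True when it was already present."""
    h = np.int64((key * _HASH_MULT) >> np.uint64(40)) & mask
    while True:
        k = table[h]
        if k == key:
            return True
        if k == _EMPTY:
            table[h] = key
            return False
        h = (h + 1) & mask


@njit(cache=True)
def _visited_grow(table, mask):
    new = np.full((mask + 1) * 2, _EMPTY, dtype=np.uint64)
    new_mask = np.int64(new.shape[0] - 1)
    for i in range(table.shape[0]):
        k = table[i]
        if k != _EMPTY:
            _visited_add(new, new_mask, k)
    return new, new_mask


@njit(cache=True)
def _heap_push(w, d, s, v, size, wi, di, si, vi):
    i = size
    w[i], d[i], s[i], v[i] = wi, di, si, vi
    while i > 0:
        p = (i - 1) >> 1
        if _heap_less(w, d, s, i, p):
            w[i], w[p] = w[p], w[i]
            d[i], d[p] = d[p], d[i]
            s[i], s[p] = s[p], s[i]
            v[i], v[p] = v[p], v[i]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(w, d, s, v, size):
    last = size - 1
    w[0], w[last] = w[last], w[0]
    d[0], d[last] = d[last], d[0]
    s[0], s[last] = s[last], s[0]
    v[0], v[last] = v[last], v[0]
    i = 0
    while True:
        l, r = 2 * i + 1, 2 * i + 2
        best = i
        if l < last and _heap_less(w, d, s, l, best):
            best = l
        if r < last and _heap_less(w, d, s, r, best):
            best = r
        if best == i:
            break
        w[i], w[best] = w[best], w[i]
        d[i], d[best] = d[best], d[i]
        s[i], s[best] = s[best], s[i]
        v[i], v[best] = v[best], v[i]
        i = best
    return last


@njit(cache=True)
def search_correct(bits, cov_mask, storage, shift, impl_mask, toggle, nonlin,
                   cover_by_cell, ncov, parity_mask, n_parity, max_part,
                   max_flips, max_expansions):
    """Best-first search for the nearest consistent matrix within
    ``max_flips`` bit flips.

    Children are generated only for cells implicated by a currently
    violated constraint.  Nodes that provably cannot reach consistency in
    the remaining flips are pruned: one flip repairs at most ``max_part``
    violated constraints (the densest cell participation in the layout),
    so a node needs at least ``ceil(violations / max_part)`` further flips.
    Consistent matrices are recorded as they are discovered and the search
    continues (restricted to strictly closer candidates) until the
    expansion budget is spent, returning the consistent matrix reached
    with the fewest flips.

    Returns ``(ok, corrected_bits, expansions)``.
    """
    bits = np.uint64(bits)
    cap = 4096
    hw = np.empty(cap, dtype=np.float64)
    hd = np.empty(cap, dtype=np.int64)
    hs = np.empty(cap, dtype=np.int64)
    hv = np.empty(cap, dtype=np.uint64)
    size = 0
    seq = 0

    vtable = np.full(8192, _EMPTY, dtype=np.uint64)
    vmask = np.int64(vtable.shape[0] - 1)
    vcount = 1
    _visited_add(vtable, vmask, bits)

    root_viol = violated_mask(bits, cov_mask, storage, shift)
    if root_viol == np.uint64(0):
        return True, bits, 0
    w0 = _weight(root_viol, cover_by_cell, ncov, parity_mask, n_parity)
    size = _heap_push(hw, hd, hs, hv, size, w0, 0, seq, bits)
    seq += 1

    expansions = 0
    best_bits = np.uint64(0)
    best_depth = np.int64(max_flips + 1)
    while size > 0 and expansions < max_expansions:
        size = _heap_pop(hw, hd, hs, hv, size)
        cur = hv[size]
        depth = hd[size]
        expansions += 1
        viol = violated_mask(cur, cov_mask, storage, shift)
        if viol == np.uint64(0):
            if depth < best_depth:
                best_bits, best_depth = cur, depth
            if best_depth <= 1:
                break
            continue
        # deepest useful level: one less than the best solution found so far
        limit = max_flips if best_depth > max_flips else best_depth - 1
        if depth >= limit:
            continue
        nviol = np.int64(_popcount(viol))
        if depth + (nviol + max_part - 1) // max_part > limit:
            continue
        cand = np.uint64(0)
        for j in range(cov_mask.shape[0]):
            if (viol >> np.uint64(j)) & np.uint64(1):
                cand |= impl_mask[j]
        for c in range(N_CELLS):
            if not (cand >> np.uint64(c)) & np.uint64(1):
                continue
            child = cur ^ (np.uint64(1) << np.uint64(c))
            cviol = _child_violated(child, viol, c, cov_mask, storage, shift,
                                    toggle, nonlin)
            ncv = np.int64(_popcount(cviol))
            if depth + 1 + (ncv + max_part - 1) // max_part > limit:
                # provably hopeless from here; do not mark visited, a
                # shorter path to this state may still be viable
                continue
            if _visited_add(vtable, vmask, child):
                continue
            vcount += 1
            if 4 * vcount > 3 * (vmask + 1):
                vtable, vmask = _visited_grow(vtable, vmask)
            cw = _weight(cviol, cover_by_cell, ncov, parity_mask, n_parity)
            if size >= cap:
                hw2 = np.empty(cap * 2, dtype=np.float64)
                hd2 = np.empty(cap * 2, dtype=np.int64)
                hs2 = np.empty(cap * 2, dtype=np.int64)
                hv2 = np.empty(cap * 2, dtype=np.uint64)
                hw2[:cap] = hw
                hd2[:cap] = hd
                hs2[:cap] = hs
                hv2[:cap] = hv
                hw, hd, hs, hv = hw2, hd2, hs2, hv2
                cap *= 2
            size = _heap_push(hw, hd, hs, hv, size, cw, depth + 1, seq, child)
            seq += 1
    if best_depth <= max_flips:
        return True, best_bits, expansions
    return False, bits, expansions
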