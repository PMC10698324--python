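"""Numba kernel for exact mfe assignment over all 2^L HP sequences.

The energy of sequence s in structure c is minus the number of contacts of c
whose two residues are both H.  Writing the sequence code as low bits
(residues 0..lb-1) and high bits, the contact count splits into a low-only
table A[c, s_low], a high-only table B[c, s_high], and a cross term counted
with popcount masks rebuilt per (c, s_high).  The kernel streams over high
blocks so the per-block running max/argmax/tie arrays stay in cache.
"""
from __future__ import annotations

import numpy as np
from numba import njit


def split_tables(pair_i: np.ndarray, pair_j: np.ndarray, ptr: np.ndarray,
                 lb: int, n_high_bits: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-structure contact-count tables split at bit lb.

    Returns (A, B, cross_i, cross_j, cross_ptr): A[c, s_low] counts contacts with
    both residues below lb, B[c, s_high] those with both at or above lb, and the
    cross arrays list contacts straddling the split (low index, high index - lb).
    """
    n_struct = len(ptr) - 1
    nlow = 1 << lb
    low = np.arange(nlow, dtype=np.int64)
    A = np.zeros((n_struct, nlow), dtype=np.uint8)
    nhigh = 1 << n_high_bits
    high = np.arange(nhigh, dtype=np.int64)
    B = np.zeros((n_struct, nhigh), dtype=np.uint8)
    ci, cj = [], []
    cptr = [0]
    for c in range(n_struct):
        for t in range(ptr[c], ptr[c + 1]):
            i, j = int(pair_i[t]), int(pair_j[t])
            if j < lb:
                A[c] += ((low >> i) & (low >> j) & 1).astype(np.uint8)
            elif i >= lb:
                B[c] += ((high >> (i - lb)) & (high >> (j - lb)) & 1).astype(np.uint8)
            else:
                ci.append(i)
                cj.append(j - lb)
        cptr.append(len(ci))
    return (A, B, np.asarray(ci, dtype=np.int64), np.asarray(cj, dtype=np.int64),
            np.asarray(cptr, dtype=np.int64))


@njit(cache=True)
def _assign_kernel(A, B, cross_i, cross_j, cptr, n_high_bits):  # pragma: no cover
    n_struct, nlow = A.shape
    nhigh = 1 << n_high_bits
    pc = np.zeros(nlow, dtype=np.uint8)
    for s in range(1, nlow):
        pc[s] = pc[s >> 1] + (s & 1)
    out = np.empty(nlow * nhigh, dtype=np.int32)
    best = np.empty(nlow, dtype=np.int16)
    arg = np.empty(nlow, dtype=np.int32)
    tie = np.empty(nlow, dtype=np.uint8)
    for sh in range(nhigh):
        for sl in range(nlow):
            best[sl] = -1
            arg[sl] = -1
            tie[sl] = 0
        for c in range(n_struct):
            b = np.int16(B[c, sh])
            m1 = 0
            m2 = 0
            m3 = 0
            for t in range(cptr[c], cptr[c + 1]):
                if (sh >> cross_j[t]) & 1:
                    bit = 1 << cross_i[t]
                    if m1 & bit == 0:
                        m1 |= bit
                    elif m2 & bit == 0:
                        m2 |= bit
                    else:
                        m3 |= bit
            Ac = A[c]
            if m3 != 0:
                for sl in range(nlow):
                    e = np.int16(Ac[sl]) + b + pc[sl & m1] + pc[sl & m2] + pc[sl & m3]
                    if e > best[sl]:
                        best[sl] = e
                        arg[sl] = c
                        tie[sl] = 0
                    elif e == best[sl]:
                        tie[sl] = 1
            elif m2 != 0:
                for sl in range(nlow):
                    e = np.int16(Ac[sl]) + b + pc[sl & m1] + pc[sl & m2]
                    if e > best[sl]:
                        best[sl] = e
                        arg[sl] = c
                        tie[sl] = 0
                    elif e == best[sl]:
                        tie[sl] = 1
            elif m1 != 0:
                for sl in range(nlow):
                    e = np.int16(Ac[sl]) + b + pc[sl & m1]
                    if e > best[sl]:
                        best[sl] = e
                        arg[sl] = c
                        tie[sl] = 0
                    elif e == best[sl]:
                        tie[sl] = 1
            else:
                for sl in range(nlow):
                    e = np.int16(Ac[sl]) + b
                    if e > best[sl]:
                        best[sl] = e
                        arg[sl] = c
                        tie[sl] = 0
                    elif e == best[sl]:
                        tie[sl] = 1
        base = sh * nlow
        for sl in range(nlow):
            if tie[sl]:
                out[base + sl] = -1
            else:
                out[base + sl] = arg[sl]
    return out


def assign_all_sequences(catalogue, lb: int | None = None) -> np.ndarray:
    """Unique-mfe structure id (or -1 for degenerate) for every HP sequence code.

    Exact over all 2^L sequences; ties at the minimum energy yield -1 (UNFOLDED).
    """
    L = catalogue.L
    if lb is None:
        lb = min(13, L - 1)
    pair_i, pair_j, ptr = catalogue.contact_arrays()
    A, B, ci, cj, cptr = split_tables(pair_i, pair_j, ptr, lb, L - lb)
    return _assign_kernel(A, B, ci, cj, cptr, L - lb)
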