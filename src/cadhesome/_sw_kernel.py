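"""Numba-compiled Smith-Waterman scoring kernels (Gotoh affine gaps).

Score-only kernels used by :mod:`cadhesome.sequence_search`.  A gap of
length g costs open + g*extend, so the kernel's opening step subtracts
open+extend and each extension subtracts extend.  Scores are exact -- no
banding, no seeding heuristics.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_score(profile, subject, gap_open_first, gap_extend):
    """Optimal local alignment score.

    ``profile`` is the query score profile, shape (m, alphabet);
    ``subject`` an int32 encoded sequence; ``gap_open_first`` the cost of a
    gap's first residue (open + extend), ``gap_extend`` each further one.
    """
    m = profile.shape[0]
    n = subject.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    E = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(m):
        diag = 0
        F = 0
        row = profile[i]
        for j in range(1, n + 1):
            e = H[j] - gap_open_first
            if E[j] - gap_extend > e:
                e = E[j] - gap_extend
            E[j] = e
            f = H[j - 1] - gap_open_first
            if F - gap_extend > f:
                f = F - gap_extend
            F = f
            h = diag + row[subject[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_many(profile, db, offsets, gap_open_first, gap_extend, out):
    """Score one query profile against concatenated subjects.

    ``db`` holds all subject sequences back to back; subject k occupies
    ``db[offsets[k]:offsets[k+1]]``.  Results land in ``out``.
    """
    for k in range(offsets.shape[0] - 1):
        out[k] = sw_score(
            profile, db[offsets[k] : offsets[k + 1]], gap_open_first, gap_extend
        )
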