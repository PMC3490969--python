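"""Shared pairwise-comparison kernels.

All diversity/differentiation statistics reduce to two matrices over sequence
pairs: the count of differing sites and the count of comparable sites, under
pairwise deletion (a column is compared for a pair iff both rows carry an
unambiguous base there).
"""

from __future__ import annotations

import numpy as np


def diff_and_comparable(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair difference and comparable-site counts.

    Parameters
    ----------
    codes
        (n, L) int8 matrix; values >= 0 are bases, negatives are missing.

    Returns
    -------
    (ndiff, ncomp)
        Symmetric (n, n) int64 matrices with zero diagonals.
    """
    n = codes.shape[0]
    valid = codes >= 0
    ndiff = np.zeros((n, n), dtype=np.int64)
    ncomp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        ncomp_row = both.sum(axis=1)
        ndiff_row = (both & (codes[i] != codes[i + 1 :])).sum(axis=1)
        ncomp[i, i + 1 :] = ncomp_row
        ndiff[i, i + 1 :] = ndiff_row
    ndiff += ndiff.T
    ncomp += ncomp.T
    return ndiff, ncomp


def p_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Per-pair proportion of differing sites; NaN where no site is comparable."""
    ndiff, ncomp = diff_and_comparable(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ncomp > 0, ndiff / np.maximum(ncomp, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    return p
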