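"""Deterministic feature-ranking helpers.

Two conventions are used in the package:

* ``ordinal_rank`` — every feature gets a distinct rank 1..d; ties are broken
  toward the lower feature index.  Used wherever a total ordering is needed
  (top-k ablation, global rank aggregation).
* ``dense_rank`` — tied values share a rank and ranks step by one per distinct
  value.  Used for rank profiles where "all equal" should read as "all rank 1".
"""

from __future__ import annotations

import numpy as np


def ordinal_rank(importance: np.ndarray) -> np.ndarray:
    """Rank features per row: 1 = most important, ties -> lower index first.

    Parameters
    ----------
    importance : array of shape (n, d) or (d,)

    Returns
    -------
    integer array of the same shape with each row a permutation of 1..d.
    """
    imp = np.atleast_2d(np.asarray(importance, dtype=float))
    n, d = imp.shape
    # stable argsort on -imp keeps the lower index first among ties
    order = np.argsort(-imp, axis=1, kind="stable")
    ranks = np.empty((n, d), dtype=np.int64)
    np.put_along_axis(ranks, order, np.arange(1, d + 1)[None, :], axis=1)
    if np.ndim(importance) == 1:
        return ranks[0]
    return ranks


def dense_rank(importance: np.ndarray) -> np.ndarray:
    """Dense ranks per row: 1 = most important, equal values share a rank."""
    imp = np.atleast_2d(np.asarray(importance, dtype=float))
    n, d = imp.shape
    ranks = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        uniq = np.unique(-imp[i])  # ascending on negated = descending on value
        ranks[i] = np.searchsorted(uniq, -imp[i]) + 1
    if np.ndim(importance) == 1:
        return ranks[0]
    return ranks


def top_k_indices(importance: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most important entries of a 1-D vector (ties -> lower index)."""
    imp = np.asarray(importance, dtype=float)
    order = np.argsort(-imp, kind="stable")
    return order[:k]
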