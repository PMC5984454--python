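"""Rank-order global similarity.

Raw local distances are converted, per feature, to dense ranks over the
case-base (ties share a rank; the next distinct value takes the next
integer, so the maximal rank equals the number of distinct distance values
N').  The weighted global similarity of case i to the target is

    S_i = sum_f w_f * (N'_f - rank_f(i)) / (N'_f - 1)

which maps every feature's contribution onto [0, 1]: the nearest distinct
distance contributes 1, the farthest 0.  A feature with a single distinct
distance value (N'_f = 1) is uninformative and contributes the constant 1,
which preserves case ordering and keeps S's upper bound attainable.
Because only ranks enter, S is invariant under any strictly increasing
transform of a feature's distances.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .profiles import FEATURES


def rank_distances(d) -> tuple[np.ndarray, int]:
    """Dense ranks of a distance vector and the distinct-value count N'."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.shape[0] == 0:
        raise ValueError("distance vector must be one-dimensional and nonempty")
    ranks = rankdata(d, method="dense").astype(int)
    return ranks, int(ranks.max())


def global_similarity(rank_table: dict, weights: dict) -> np.ndarray:
    """Weighted rank-order similarity of every case to the target.

    Parameters
    ----------
    rank_table : dict
        ``feature -> (ranks, n_distinct)`` as produced by
        :func:`rank_distances` per feature.
    weights : dict
        ``feature -> weight``; must cover exactly the rank table's features.
    """
    if set(rank_table) != set(weights):
        raise KeyError(
            f"weight/feature mismatch: {sorted(rank_table)} vs {sorted(weights)}"
        )
    n_cases = None
    s = None
    for f, (ranks, n_distinct) in rank_table.items():
        ranks = np.asarray(ranks)
        if n_cases is None:
            n_cases = ranks.shape[0]
            s = np.zeros(n_cases)
        if n_distinct <= 1:
            term = np.ones(n_cases)
        else:
            term = (n_distinct - ranks) / (n_distinct - 1)
        s += weights[f] * term
    return s


def similarity_to(cases, target, weights, frechet_scale=None) -> np.ndarray:
    """Convenience: distances -> ranks -> similarity in one call."""
    from .distances import distance_table

    dt = distance_table(cases, target, frechet_scale=frechet_scale)
    rt = {f: rank_distances(dt[f]) for f in FEATURES}
    return global_similarity(rt, weights)
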