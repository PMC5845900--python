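"""Minimal-redundancy maximal-relevance (mRMR) feature ranking.

Features are discretized (quantile bins), and greedy forward selection ranks
them by either criterion:

    MID:  max_i [ I(x_i, h) - (1/|S|) sum_{j in S} I(x_i, x_j) ]
    MIQ:  max_i [ I(x_i, h) / ((1/|S|) sum_{j in S} I(x_i, x_j)) ]

where ``h`` is the binary target, ``S`` the already-selected set and ``I``
the plug-in mutual information (in nats) of the empirical joint distribution.
The first feature maximizes relevance alone, where the two criteria coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_CODE = -1
_EPS = 1e-12  # MIQ denominator guard for fully independent candidates


def discretize(column: np.ndarray, bins: int = 10) -> np.ndarray:
    """Quantile-bin a column into integer codes; missing gets its own code.

    Ties go to the lower bin (searchsorted on right-open quantile edges);
    columns that are already discrete (at most ``bins`` distinct values) pass
    through as dense integer codes. Missing values map to ``MISSING_CODE``.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    col = np.asarray(column, dtype=float)
    out = np.full(col.shape, MISSING_CODE, dtype=int)
    obs = ~np.isnan(col)
    vals = col[obs]
    if vals.size == 0:
        return out
    uniq = np.unique(vals)
    if uniq.size <= bins:
        out[obs] = np.searchsorted(uniq, vals)
        return out
    edges = np.quantile(vals, np.linspace(0, 1, bins + 1)[1:-1])
    out[obs] = np.searchsorted(edges, vals, side="left")
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two integer-coded vectors.

    Rows where either code is ``MISSING_CODE`` are dropped pairwise. The
    estimate is non-negative and symmetric by construction.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = (a != MISSING_CODE) & (b != MISSING_CODE)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 complete pairs")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))
    return max(mi, 0.0)


@dataclass
class MRMRState:
    """Bookkeeping of one greedy mRMR run (selected order, MI caches)."""

    selected: list = field(default_factory=list)
    relevance: dict = field(default_factory=dict)      # i -> I(x_i, h)
    redundancy: dict = field(default_factory=dict)     # (i, j) -> I(x_i, x_j)
    criterion: str = "MID"
    scores: list = field(default_factory=list)         # criterion value per step


def mrmr_rank(F, labels: np.ndarray, criterion: str = "MID", k: int = 80,
              bins: int = 10, return_state: bool = False):
    """Greedy mRMR ranking of the columns of a feature matrix.

    ``F`` may be a FeatureMatrix or a 2-D array. Exactly ``k`` column indices
    are returned in selection order; ties break toward the lower column
    index. ``criterion`` is ``"MID"`` (difference) or ``"MIQ"`` (quotient).
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be 'MID' or 'MIQ'")
    X = F.values if hasattr(F, "values") and not isinstance(F, np.ndarray) else F
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=int)
    n, p = X.shape
    if k > p:
        raise ValueError("k exceeds the number of columns")
    codes = np.stack([discretize(X[:, j], bins) for j in range(p)], axis=1)
    ycode = y.astype(int)
    state = MRMRState(criterion=criterion)
    rel = np.array([mutual_information(codes[:, j], ycode) for j in range(p)])
    state.relevance = {j: float(rel[j]) for j in range(p)}
    remaining = list(range(p))
    red_sum = np.zeros(p)
    while len(state.selected) < k:
        if not state.selected:
            crit = rel.copy()
        else:
            mean_red = red_sum / len(state.selected)
            if criterion == "MID":
                crit = rel - mean_red
            else:
                crit = rel / np.maximum(mean_red, _EPS)
        crit_rem = [(crit[j], j) for j in remaining]
        best = max(crit_rem, key=lambda t: (t[0], -t[1]))
        j_star = best[1]
        state.selected.append(j_star)
        state.scores.append(float(best[0]))
        remaining.remove(j_star)
        for j in remaining:
            mij = mutual_information(codes[:, j], codes[:, j_star])
            state.redundancy[(min(j, j_star), max(j, j_star))] = mij
            red_sum[j] += mij
    if return_state:
        return state.selected, state
    return state.selected


def ranking_report(F, labels, criterion: str = "MID", k: int = 80,
                   bins: int = 10) -> pd.DataFrame:
    """CSV-ready report: rank, column index, tag, relevance, redundancy, score."""
    sel, state = mrmr_rank(F, labels, criterion, k, bins, return_state=True)
    tags = F.tags if hasattr(F, "tags") else [{} for _ in sel]
    rows = []
    for rank, j in enumerate(sel):
        reds = [state.redundancy.get((min(j, s), max(j, s)))
                for s in sel[:rank]]
        rows.append(dict(rank=rank + 1, column=j, tag=str(tags[j]),
                         relevance=state.relevance[j],
                         mean_redundancy=float(np.mean(reds)) if reds else 0.0,
                         criterion_value=state.scores[rank]))
    return pd.DataFrame(rows)
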