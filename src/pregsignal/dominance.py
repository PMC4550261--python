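"""David's Scores and Normalized David's Scores from agonistic interactions.

Given a win matrix S with s_ij = interactions won by i over j, the dyadic
win proportion is P_ij = s_ij / (s_ij + s_ji).  The chance-corrected index
D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1) shrinks sparse dyads toward 0.5
and is the default; the plain-proportion variant is kept behind a switch.
DS_i = w_i + w2_i - l_i - l2_i with w, w2, l, l2 the (weighted) win/loss
sums, and NDS = (DS + N(N-1)/2) / N rescales to [0, N-1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def matrix_from_interactions(
    interactions: pd.DataFrame, ids: list[str] | None = None
) -> pd.DataFrame:
    """N x N win-count matrix (rows = winners) from an interaction list."""
    w = interactions["winner_id"].astype(str)
    l = interactions["loser_id"].astype(str)
    if ids is None:
        ids = sorted(set(w) | set(l))
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for a, b in zip(w, l):
        mat.loc[a, b] += 1
    return mat


def dyadic_indices(matrix: np.ndarray | pd.DataFrame, corrected: bool = True) -> np.ndarray:
    """Dyadic dominance indices D_ij; unobserved dyads get 0.5.

    ``corrected=True`` applies the chance correction
    D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1); ``False`` returns raw P_ij.
    """
    S = np.asarray(matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("win matrix must be square")
    if S.shape[0] < 2:
        raise ValueError("need at least two individuals")
    if (S < 0).any():
        raise ValueError("win counts must be non-negative")
    n = S + S.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n > 0, S / np.where(n > 0, n, 1), 0.5)
    D = P - (P - 0.5) / (n + 1.0) if corrected else P
    np.fill_diagonal(D, 0.0)
    return D


def davids_score(D: np.ndarray) -> np.ndarray:
    """DS = w + w2 - l - l2 from a dyadic index matrix (diagonal zero)."""
    w = D.sum(axis=1)
    l = D.sum(axis=0)
    w2 = D @ w
    l2 = D.T @ l
    return w + w2 - l - l2


def normalized_davids_score(ds: np.ndarray, n: int | None = None) -> np.ndarray:
    """NDS = (DS + N(N-1)/2) / N, in [0, N-1] with mean (N-1)/2."""
    ds = np.asarray(ds, dtype=float)
    n = n or ds.size
    return (ds + n * (n - 1) / 2.0) / n


def rank_individuals(
    matrix: pd.DataFrame, corrected: bool = True
) -> pd.DataFrame:
    """DS, NDS and deterministic ordinal ranks for every individual.

    Rank 1 is the highest NDS; ties are broken by total wins, then by id.
    """
    ids = list(matrix.index)
    D = dyadic_indices(matrix, corrected=corrected)
    ds = davids_score(D)
    nds = normalized_davids_score(ds, len(ids))
    wins = np.asarray(matrix, dtype=float).sum(axis=1)
    order = sorted(range(len(ids)), key=lambda i: (-nds[i], -wins[i], ids[i]))
    rank = np.empty(len(ids), dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    return pd.DataFrame(
        {"individual": ids, "DS": ds, "NDS": nds, "total_wins": wins.astype(int), "rank": rank}
    ).set_index("individual")


def rank_age_correlation(ranks: pd.DataFrame, roster: pd.DataFrame) -> float:
    """Pearson correlation between ordinal rank and age (collinearity check).

    With small samples rank and age are often perfectly confounded; values
    near +/-1 mean rank cannot enter a model alongside age.
    """
    merged = ranks.join(roster.set_index("female_id")["age"], how="inner")
    r = np.corrcoef(merged["rank"], merged["age"])[0, 1]
    return float(r)
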