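"""Similarity-percentage (SIMPER) decomposition of Bray-Curtis dissimilarity.

For every between-group pair of cells (j, k) the Bray-Curtis dissimilarity
splits exactly over species:

    delta_i(j, k) = |y_ij - y_ik| / sum_s (y_sj + y_sk)

A species' contribution is the mean of delta_i over all between-group
pairs, so contributions sum to the average between-group dissimilarity.
The ranked table is truncated at the first species reaching the cumulative
cutoff (default 90%), so cumulative totals slightly exceed the cutoff.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


class Simper(BaseEstimator):
    """Rank species (or guilds) by contribution to between-group dissimilarity.

    Parameters
    ----------
    cutoff : cumulative contribution fraction at which the ranked table is
        truncated (default 0.90).

    Attributes (after :meth:`fit`)
    ------------------------------
    table_ : truncated ranked table (contribution_pct, cumulative_pct and
        per-group mean abundances on the scale of the input matrix).
    contributions_ : untruncated per-species contributions (same columns).
    average_dissimilarity_ : overall mean between-group Bray-Curtis value.
    groups_ : the two group labels, in order of first appearance.
    """

    def __init__(self, cutoff: float = 0.90):
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, grouping):
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must lie in (0, 1]")
        g = pd.Series(np.asarray(grouping), index=X.index)
        levels = list(pd.unique(g))
        if len(levels) != 2:
            raise ValueError(f"SIMPER needs exactly two groups, got {levels}")
        Y1 = X.loc[g == levels[0]].to_numpy(dtype=float)
        Y2 = X.loc[g == levels[1]].to_numpy(dtype=float)
        if np.any(Y1 < 0) or np.any(Y2 < 0):
            raise ValueError("SIMPER requires nonnegative abundances")
        if Y1.shape[0] == 0 or Y2.shape[0] == 0:
            raise ValueError("both groups must contain at least one cell")

        diff = np.abs(Y1[:, None, :] - Y2[None, :, :])       # (n1, n2, S)
        den = Y1.sum(axis=1)[:, None] + Y2.sum(axis=1)[None, :]
        if np.any(den == 0):
            warnings.warn(
                "all-zero cell pairs contribute zero dissimilarity", stacklevel=2
            )
            den = np.where(den == 0, 1.0, den)
        delta = diff / den[:, :, None]
        contrib = delta.mean(axis=(0, 1))                    # per species
        avg_diss = float(contrib.sum())
        if avg_diss <= 0:
            raise ValueError(
                "all between-group dissimilarities are zero; contributions undefined"
            )

        pct = 100.0 * contrib / avg_diss
        full = pd.DataFrame(
            {
                "contribution": contrib,
                "contribution_pct": pct,
                f"mean_{levels[0]}": Y1.mean(axis=0),
                f"mean_{levels[1]}": Y2.mean(axis=0),
            },
            index=X.columns,
        )
        full = full.sort_values("contribution_pct", ascending=False, kind="stable")
        full["cumulative_pct"] = full["contribution_pct"].cumsum()
        # keep items until the cumulative percentage first reaches the cutoff
        reached = np.flatnonzero(full["cumulative_pct"].to_numpy() >= 100.0 * self.cutoff - 1e-9)
        last = reached[0] if reached.size else len(full) - 1
        self.table_ = full.iloc[: last + 1].copy()
        self.contributions_ = full
        self.average_dissimilarity_ = avg_diss
        self.groups_ = tuple(levels)
        return self


def simper(X: pd.DataFrame, grouping, cutoff: float = 0.90):
    """Functional wrapper: returns ``(table, average_dissimilarity)``."""
    est = Simper(cutoff=cutoff).fit(X, grouping)
    return est.table_, est.average_dissimilarity_
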