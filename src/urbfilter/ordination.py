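"""Principal coordinates analysis, centroid distances and vector overlays.

PCoA embeds a (semi-)metric distance matrix through the eigendecomposition
of its Gower-centered inner-product matrix.  Semi-metrics such as
Bray-Curtis can produce negative eigenvalues; these are reported but their
axes are never embedded, and the percentage explained is computed over the
positive eigenvalues only.  Group centroids live in the full principal
coordinate space, so centroid distances are computed directly from block
means of G (keeping negative-eigenvalue components with their sign) rather
than from a truncated embedding.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

from .distance import gower_center

_TOL = 1e-8


class PCoA(BaseEstimator):
    """Metric ordination of a distance matrix.

    Parameters
    ----------
    n_axes : number of coordinate axes requested (fewer are returned, with
        a warning, if the matrix has fewer positive eigenvalues).
    correction : ``None`` (default: negative eigenvalues reported, not
        embedded) or ``"lingoes"`` (adds the constant that makes all
        off-diagonal squared distances Euclidean).

    Attributes (after :meth:`fit`)
    ------------------------------
    coordinates_ : DataFrame (objects x axes), column-centered, axis k
        scaled by sqrt(eigenvalue k).
    eigenvalues_ : all eigenvalues, sorted descending (negatives included).
    pct_explained_ : % of the positive-eigenvalue total per returned axis.
    """

    def __init__(self, n_axes: int = 2, correction=None):
        self.n_axes = n_axes
        self.correction = correction

    def fit(self, D):
        if isinstance(D, DistanceMatrix):
            ids, Dv = list(D.ids), D.data
        else:
            Dv = np.asarray(D, dtype=float)
            ids = [str(i) for i in range(Dv.shape[0])]
        if self.correction == "lingoes":
            G0 = gower_center(Dv)
            lam_min = scipy.linalg.eigvalsh(G0)[0]
            if lam_min < -_TOL:
                d2 = Dv ** 2 - 2.0 * lam_min
                np.fill_diagonal(d2, 0.0)
                Dv = np.sqrt(d2)
        elif self.correction is not None:
            raise ValueError("correction must be None or 'lingoes'")
        G = gower_center(Dv)
        lam, vec = scipy.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        scale = max(abs(lam[0]), 1.0)
        pos = lam > _TOL * scale
        n_pos = int(pos.sum())
        k = min(self.n_axes, n_pos)
        if k < self.n_axes:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; returning {k} axes",
                stacklevel=2,
            )
        coords = vec[:, :k] * np.sqrt(lam[:k])
        self.coordinates_ = pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i + 1}" for i in range(k)]
        )
        self.eigenvalues_ = lam
        pos_total = lam[pos].sum()
        self.pct_explained_ = 100.0 * lam[:k] / pos_total if pos_total > 0 else np.zeros(k)
        self.n_negative_ = int((lam < -_TOL * scale).sum())
        return self

    def fit_transform(self, D) -> pd.DataFrame:
        return self.fit(D).coordinates_


def pcoa(D, n_axes: int = 2) -> PCoA:
    """Functional wrapper: returns the fitted :class:`PCoA` estimator."""
    return PCoA(n_axes=n_axes).fit(D)


def centroid_distances(D, grouping) -> DistanceMatrix:
    """Distances between group centroids in full principal-coordinate space.

    Squared centroid distances come from block averages of the
    Gower-centered matrix, ``d2(g, h) = C_gg + C_hh - 2 C_gh`` with
    ``C_gh`` the mean of the G block; negative-eigenvalue components enter
    with their sign, so a semi-metric can yield a (slightly) negative
    squared distance -- clamped to 0 with a warning.
    """
    if isinstance(D, DistanceMatrix):
        ids, Dv = list(D.ids), D.data
    else:
        Dv = np.asarray(D, dtype=float)
        ids = [str(i) for i in range(Dv.shape[0])]
    g = pd.Series(np.asarray(grouping), index=ids)
    groups = list(pd.unique(g))
    if any((g == grp).sum() < 1 for grp in groups):
        raise ValueError("every group needs at least one member")
    G = gower_center(Dv)
    masks = [np.asarray(g == grp) for grp in groups]
    C = np.array(
        [[G[np.ix_(mi, mj)].mean() for mj in masks] for mi in masks]
    )
    d2 = np.diag(C)[:, None] + np.diag(C)[None, :] - 2.0 * C
    if np.any(d2 < -_TOL):
        warnings.warn(
            "negative squared centroid distance clamped to 0 (semi-metric input)",
            stacklevel=2,
        )
    d2 = np.clip(d2, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    out = np.sqrt(d2)
    out = (out + out.T) / 2.0
    return DistanceMatrix(out, ids=[str(grp) for grp in groups])


def vector_fit(
    coordinates: pd.DataFrame,
    X: pd.DataFrame,
    threshold: float = 0.75,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate item abundances with ordination axes (vector overlay).

    Each item (species or guild column of ``X``, row-aligned with the
    ordination) gets a correlation coefficient per plotted axis and a
    ``shown`` flag that is True iff the maximum absolute correlation
    strictly exceeds ``threshold``.  Zero-variance items get missing
    correlations and are never shown.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    Xa = X.loc[coordinates.index]
    rows = []
    for item in Xa.columns:
        y = Xa[item].to_numpy(dtype=float)
        rec = {}
        if np.std(y) == 0:
            rec = {f"r_{ax}": np.nan for ax in coordinates.columns}
            rec["shown"] = False
        else:
            if method == "spearman":
                y = pd.Series(y).rank().to_numpy()
            for ax in coordinates.columns:
                a = coordinates[ax].to_numpy(dtype=float)
                if method == "spearman":
                    a = pd.Series(a).rank().to_numpy()
                if np.std(a) == 0:
                    rec[f"r_{ax}"] = np.nan
                else:
                    rec[f"r_{ax}"] = float(np.corrcoef(y, a)[0, 1])
            rs = [abs(v) for v in rec.values() if np.isfinite(v)]
            rec["shown"] = bool(rs and max(rs) > threshold)
        rows.append(rec)
    out = pd.DataFrame(rows, index=Xa.columns)
    out.index.name = "item_id"
    return out
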