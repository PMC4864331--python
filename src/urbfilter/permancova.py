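"""Distance-based permutational analysis of (co)variance (PERMANCOVA).

Partitions a Gower-centered dissimilarity matrix over a sequential (Type I)
model built from an optional continuous covariate, an optional random
factor, a fixed factor, and all their interactions, in the fixed order

    covariate, A, B, covariate x A, covariate x B, A x B, covariate x A x B

(A = random factor, B = fixed factor).  For each term the table reports the
rank (df), sum of squares, mean square, a pseudo-F against the term's
denominator mean square, a permutation p-value, a Monte-Carlo p-value when
too few distinguishable permutations exist, and a method-of-moments
component of variation expressed as a percentage.

Conventions (all overridable or echoed in the fitted ``scheme_``):

* Mixed-model denominators: the fixed factor is tested over its interaction
  with the random factor; every other term is tested over the residual.
* Terms tested over the residual use Freedman-Lane permutation of residuals
  under the reduced model (all preceding terms).
* The fixed factor tested over the interaction permutes intact habitat
  blocks within each level of the random factor -- the small number of
  distinguishable relabellings is what triggers the Monte-Carlo p-value.
* Monte-Carlo p-values draw the null pseudo-F from ratios of weighted
  chi-square sums whose weights are the eigenvalues of the denominator's
  projected G block.
* Variance components: (MS_term - MS_denominator) / c_term with the EMS
  multiplier c_term computed from the design; negative estimates are
  truncated at zero before normalising to 100%.

With a univariate response, Euclidean distances and a single fixed factor
the pseudo-F is exactly the classical one-way ANOVA F.
"""
from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

from .distance import gower_center

RESIDUAL = "Residual"
_EPS = 1e-12
_MANY = 10 ** 18  # stand-in count for astronomically many permutations


class DesignError(ValueError):
    """The model design is incomplete, confounded or otherwise singular."""


# ---------------------------------------------------------------------------
# design construction

def _onehot(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype("category")).to_numpy(dtype=float)


def _interact(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    n = M1.shape[0]
    return (M1[:, :, None] * M2[:, None, :]).reshape(n, -1)


def _term_blocks(meta, covariate, random_factor, fixed_factor):
    """Raw design block per term, in the canonical sequential order."""
    terms: list[tuple[str, np.ndarray]] = []
    c = A = B = None
    if covariate is not None:
        x = meta[covariate].to_numpy(dtype=float)
        c = (x - x.mean())[:, None]
        terms.append((covariate, c))
    if random_factor is not None:
        A = _onehot(meta[random_factor])
        if A.shape[1] < 2:
            raise DesignError(f"factor {random_factor!r} needs >= 2 levels")
        terms.append((random_factor, A))
    if fixed_factor is not None:
        B = _onehot(meta[fixed_factor])
        if B.shape[1] < 2:
            raise DesignError(f"factor {fixed_factor!r} needs >= 2 levels")
        terms.append((fixed_factor, B))
    if c is not None and A is not None:
        terms.append((f"{covariate} x {random_factor}", c * A))
    if c is not None and B is not None:
        terms.append((f"{covariate} x {fixed_factor}", c * B))
    if A is not None and B is not None:
        terms.append((f"{random_factor} x {fixed_factor}", _interact(A, B)))
    if c is not None and A is not None and B is not None:
        terms.append(
            (f"{covariate} x {random_factor} x {fixed_factor}", c * _interact(A, B))
        )
    if not terms:
        raise DesignError("the design has no terms")
    return terms


def _sequential_basis(terms, n):
    """Orthonormal basis increments per term (sequential / Type I spans)."""
    Q = np.ones((n, 1)) / math.sqrt(n)
    bases = []
    for name, X in terms:
        Xr = X - Q @ (Q.T @ X)
        Xr = Xr - Q @ (Q.T @ Xr)  # second pass for numerical safety
        q, r, _ = scipy.linalg.qr(Xr, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        top = d[0] if d.size else 0.0
        scale = max(np.linalg.norm(X), 1.0)
        if top <= 1e-8 * scale:
            raise DesignError(
                f"term '{name}' is entirely confounded with earlier terms"
            )
        rank = int(np.sum(d > 1e-8 * top))
        bases.append(q[:, :rank])
        Q = np.hstack([Q, q[:, :rank]])
    return bases, Q


def _block_slices(bases):
    slices, start = [], 0
    for q in bases:
        slices.append(slice(start, start + q.shape[1]))
        start += q.shape[1]
    return slices, start


def _cap_factorial(n: int) -> int:
    return math.factorial(n) if n <= 20 else _MANY


# ---------------------------------------------------------------------------
# estimator

class Permancova(BaseEstimator):
    """Sequential distance-based PERMANCOVA with a mixed two-factor design.

    Parameters
    ----------
    fixed_factor, random_factor, covariate : column names in the metadata
        frame; any subset may be ``None`` (at least one term is required).
    n_perms : permutations for the p_perm column (0 skips permutation).
    mc_threshold : a term whose number of distinguishable permutations is
        below this gets a Monte-Carlo p-value (p_MC).
    mc_draws : Monte-Carlo sample size for p_MC.
    denominator_map : optional dict term-name -> denominator term-name
        overriding the default mixed-model map.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : per-term table (df, SS, MS, pseudo_F, p_perm, p_MC,
        unique_perms, denominator, CV_pct) plus a Residual row.
    total_ss_ : trace of the Gower-centered matrix.
    scheme_ : dict echoing the permutation scheme and denominator map used.
    """

    def __init__(
        self,
        fixed_factor=None,
        random_factor=None,
        covariate=None,
        n_perms: int = 10000,
        mc_threshold: int = 1000,
        mc_draws: int = 10000,
        seed=None,
        denominator_map: dict | None = None,
    ):
        self.fixed_factor = fixed_factor
        self.random_factor = random_factor
        self.covariate = covariate
        self.n_perms = n_perms
        self.mc_threshold = mc_threshold
        self.mc_draws = mc_draws
        self.seed = seed
        self.denominator_map = denominator_map

    # -- fitting ------------------------------------------------------------

    def fit(self, D, metadata: pd.DataFrame):
        if isinstance(D, DistanceMatrix):
            ids, Dv = list(D.ids), D.data
        else:
            Dv = np.asarray(D, dtype=float)
            ids = list(metadata.index.astype(str))
        if not np.all(np.isfinite(Dv)):
            raise ValueError("distance matrix contains non-finite entries")
        meta = metadata.copy()
        meta.index = meta.index.astype(str)
        missing = [i for i in ids if i not in meta.index]
        if missing:
            raise DesignError(f"metadata missing for cells: {missing[:5]}")
        meta = meta.loc[ids]
        n = len(ids)

        G = gower_center(Dv)
        terms = _term_blocks(meta, self.covariate, self.random_factor, self.fixed_factor)
        names = [t[0] for t in terms]
        bases, _ = _sequential_basis(terms, n)
        slices, p_total = _block_slices(bases)
        dfs = np.array([q.shape[1] for q in bases])
        df_res = n - 1 - int(dfs.sum())
        if df_res <= 0:
            raise DesignError("the design is saturated: no residual df left")

        ss = np.array([float(np.sum(q * (G @ q))) for q in bases])
        total = float(np.trace(G))
        ss_res = total - float(ss.sum())
        ms = ss / dfs
        ms_res = ss_res / df_res

        dmap = self._denominators(names)
        ms_of = dict(zip(names, ms), **{RESIDUAL: ms_res})
        df_of = dict(zip(names, dfs), **{RESIDUAL: df_res})
        F = np.array([ms[i] / ms_of[dmap[name]] for i, name in enumerate(names)])

        rng_root = np.random.SeedSequence(self.seed)
        streams = [np.random.default_rng(s) for s in rng_root.spawn(len(names) + 1)]

        p_perm = np.full(len(names), np.nan)
        p_mc = np.full(len(names), np.nan)
        uniques = np.zeros(len(names), dtype=object)
        for i, name in enumerate(names):
            den = dmap[name]
            if den == RESIDUAL:
                distinguishable = _cap_factorial(n)
                if self.n_perms > 0:
                    p_perm[i], n_unique = self._freedman_lane(
                        G, bases, slices, i, dfs, df_res, F[i], streams[i]
                    )
                else:
                    n_unique = 0
            else:
                p_perm[i], n_unique, distinguishable = self._relabel_blocks(
                    G, meta, names, den, name, F[i]
                )
            uniques[i] = min(distinguishable, n_unique) if self.n_perms else distinguishable
            if distinguishable < self.mc_threshold:
                w, df_den = self._mc_weights(G, bases, slices, names, den, df_res)
                p_mc[i] = self._mc_pvalue(F[i], w, int(dfs[i]), df_den, streams[-1])

        cv = self._variance_components(terms, bases, names, ms, ms_res, dfs, dmap, ms_of)

        rows = []
        for i, name in enumerate(names):
            rows.append(
                {
                    "df": int(dfs[i]),
                    "SS": ss[i],
                    "MS": ms[i],
                    "pseudo_F": F[i],
                    "p_perm": p_perm[i],
                    "p_MC": p_mc[i],
                    "unique_perms": int(uniques[i]) if uniques[i] < _MANY else _MANY,
                    "denominator": dmap[name],
                    "CV_pct": cv[name],
                }
            )
        rows.append(
            {
                "df": df_res,
                "SS": ss_res,
                "MS": ms_res,
                "pseudo_F": np.nan,
                "p_perm": np.nan,
                "p_MC": np.nan,
                "unique_perms": 0,
                "denominator": "",
                "CV_pct": cv[RESIDUAL],
            }
        )
        self.results_ = pd.DataFrame(rows, index=names + [RESIDUAL])
        self.results_.index.name = "term"
        self.total_ss_ = total
        self.scheme_ = {
            "ss": "sequential (Type I), covariate first",
            "p_perm": (
                "Freedman-Lane permutation of residuals under the reduced model; "
                "fixed factor tested over the interaction permutes intact "
                "habitat blocks within random-factor levels"
            ),
            "p_MC": "ratio of chi-square sums weighted by denominator-block eigenvalues",
            "denominators": dmap,
        }
        return self

    # -- internals ----------------------------------------------------------

    def _denominators(self, names) -> dict:
        dmap = {name: RESIDUAL for name in names}
        if self.random_factor and self.fixed_factor:
            dmap[self.fixed_factor] = f"{self.random_factor} x {self.fixed_factor}"
        if self.denominator_map:
            unknown = set(self.denominator_map) - set(names)
            if unknown:
                raise DesignError(f"denominator_map names unknown terms: {sorted(unknown)}")
            dmap.update(self.denominator_map)
        for name, den in dmap.items():
            if den != RESIDUAL and den not in names:
                raise DesignError(f"denominator {den!r} of {name!r} is not a model term")
        return dmap

    def _freedman_lane(self, G, bases, slices, i, dfs, df_res, F_obs, rng):
        """Permutation p-value for term i tested over the residual."""
        n = G.shape[0]
        Z = np.hstack([np.ones((n, 1)) / math.sqrt(n)] + bases[:i])
        R = G - Z @ (Z.T @ G)
        R = R - (R @ Z) @ Z.T
        R = (R + R.T) / 2.0
        Qall = np.hstack(bases)
        starts = np.array([s.start for s in slices])
        tr_R = float(np.trace(R))
        df_i = int(dfs[i])

        count = 0
        f_values = []
        remaining = int(self.n_perms)
        batch = 256
        while remaining > 0:
            b = min(batch, remaining)
            remaining -= b
            idx = np.argsort(rng.random((b, n)), axis=1)
            Qp = Qall[idx]                      # (b, n, p)
            T = np.matmul(R, Qp)                # (b, n, p)
            diag = np.sum(Qp * T, axis=1)       # (b, p): diag of Qp' R Qp
            block = np.add.reduceat(diag, starts, axis=1)
            ss_i = block[:, i]
            ss_res = tr_R - block.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss_i / df_i) / (ss_res / df_res)
            f = np.where(ss_res > 0, f, np.inf)
            count += int(np.sum(f >= F_obs - _EPS))
            f_values.append(np.round(f, 9))
        n_unique = len(np.unique(np.concatenate(f_values))) if f_values else 0
        p = (count + 1) / (self.n_perms + 1)
        return p, n_unique

    def _relabel_blocks(self, G, meta, names, den_name, term_name, F_obs):
        """Permutation p-value for the fixed factor tested over A x B.

        Relabels the fixed-factor assignment of whole habitat blocks within
        each random-factor level; the number of distinguishable relabellings
        is the product of per-level factorials (tiny for a 2-level factor).
        """
        n = len(meta)
        A = meta[self.random_factor]
        Bcol = meta[self.fixed_factor]
        cities = list(pd.unique(A))
        per_city = []
        for city in cities:
            levels = list(pd.unique(Bcol[A == city]))
            per_city.append([dict(zip(levels, p)) for p in itertools.permutations(levels)])
        total = int(np.prod([len(x) for x in per_city]))
        combos = itertools.product(*per_city)
        if total > max(self.n_perms, 1):
            combos = itertools.islice(combos, max(self.n_perms, 1))
            total = max(self.n_perms, 1)

        f_values = []
        for combo in combos:
            newB = Bcol.copy()
            for city, mapping in zip(cities, combo):
                mask = (A == city).to_numpy()
                newB.iloc[mask] = Bcol.iloc[mask].map(mapping).to_numpy()
            meta2 = meta.copy()
            meta2[self.fixed_factor] = newB
            terms2 = _term_blocks(
                meta2, self.covariate, self.random_factor, self.fixed_factor
            )
            bases2, _ = _sequential_basis(terms2, n)
            names2 = [t[0] for t in terms2]
            ss2 = {
                nm: float(np.sum(q * (G @ q))) for nm, q in zip(names2, bases2)
            }
            df2 = {nm: q.shape[1] for nm, q in zip(names2, bases2)}
            f_values.append(
                (ss2[term_name] / df2[term_name]) / (ss2[den_name] / df2[den_name])
            )
        f_values = np.asarray(f_values)
        p = float(np.mean(f_values >= F_obs - _EPS))  # identity relabelling included
        n_unique = len(np.unique(np.round(f_values, 9)))
        return p, n_unique, total

    def _mc_weights(self, G, bases, slices, names, den_name, df_res):
        """Eigenvalue weights (per denominator df) of the denominator block."""
        if den_name == RESIDUAL:
            n = G.shape[0]
            Q = np.hstack([np.ones((n, 1)) / math.sqrt(n)] + list(bases))
            R = G - Q @ (Q.T @ G)
            R = R - (R @ Q) @ Q.T
            lam = scipy.linalg.eigvalsh((R + R.T) / 2.0)
            df_den = df_res
        else:
            q = bases[names.index(den_name)]
            lam = scipy.linalg.eigvalsh(q.T @ G @ q)
            df_den = q.shape[1]
        top = np.max(np.abs(lam)) if lam.size else 0.0
        lam = lam[np.abs(lam) > 1e-10 * max(top, 1.0)]
        if lam.size == 0:
            lam = np.array([max(top, _EPS)])
        return lam / df_den, df_den

    def _mc_pvalue(self, F_obs, w, df_num, df_den, rng):
        draws = int(self.mc_draws)
        count = 0
        remaining, batch = draws, 2000
        while remaining > 0:
            b = min(batch, remaining)
            remaining -= b
            num = (rng.chisquare(df_num, size=(b, len(w))) * w).sum(axis=1) / df_num
            den = (rng.chisquare(df_den, size=(b, len(w))) * w).sum(axis=1) / df_den
            with np.errstate(divide="ignore", invalid="ignore"):
                f = num / den
            f = np.where(den > 0, f, np.inf)
            count += int(np.sum(f >= F_obs - _EPS))
        return (count + 1) / (draws + 1)

    def _variance_components(self, terms, bases, names, ms, ms_res, dfs, dmap, ms_of):
        """Method-of-moments components of variation, as % of their sum."""
        comps = {}
        for i, (name, U) in enumerate(terms):
            q = bases[i]
            c = float(np.sum((U.T @ q) ** 2)) / dfs[i]
            v = (ms[i] - ms_of[dmap[name]]) / c if c > 0 else 0.0
            comps[name] = max(v, 0.0)
        comps[RESIDUAL] = ms_res
        tot = sum(comps.values())
        if tot <= 0:
            return {k: 0.0 for k in comps}
        return {k: 100.0 * v / tot for k, v in comps.items()}


def permancova(
    D,
    metadata: pd.DataFrame,
    fixed_factor=None,
    random_factor=None,
    covariate=None,
    n_perms: int = 10000,
    mc_threshold: int = 1000,
    seed=None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`Permancova`; returns the table."""
    est = Permancova(
        fixed_factor=fixed_factor,
        random_factor=random_factor,
        covariate=covariate,
        n_perms=n_perms,
        mc_threshold=mc_threshold,
        seed=seed,
        **kwargs,
    ).fit(D, metadata)
    return est.results_
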