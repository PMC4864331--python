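"""Resampling null model for random vs. nonrandom urban species absences.

For each city, the periurban community defines a species pool (per-species
relative abundances).  Random urban communities are simulated by drawing,
with replacement, the same number of individuals as the city's pooled urban
community from that pool (multinomial sampling).  A species absent from the
urban habitat is *chance-absent* if the mode of its simulated abundances is
zero -- i.e. its absence is compatible with random assembly -- and an
*urban avoider* otherwise.  City-level loss metrics compare the observed
fraction of periurban species missing from urban habitat with the fraction
expected under the null model, and report the "tolerance" richness left
after removing avoiders.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import substream
from .tables import validate_cells, validate_survey

FATE_PRESENT = "present"
FATE_CHANCE = "chance_absent"
FATE_AVOIDER = "avoider"


def build_pool(
    survey: pd.DataFrame,
    cells: pd.DataFrame,
    city,
    include_exotics: bool = True,
    traits: pd.DataFrame | None = None,
):
    """Species pool and urban community size for one city.

    The pool holds per-species periurban relative abundances over the
    species recorded anywhere in the city (urban or periurban); species
    absent from both habitats are excluded.  ``N`` is the total number of
    individuals in the city's urban cells.

    Returns ``(pool, urban_counts, N)`` with ``pool`` and ``urban_counts``
    aligned Series.
    """
    mask = cells["city"] == city
    if not mask.any():
        raise ValueError(f"unknown city {city!r}")
    sub = survey.loc[cells.index[mask]]
    hab = cells.loc[sub.index, "habitat"]
    urban = sub[hab == "urban"]
    peri = sub[hab == "periurban"]
    if urban.empty or peri.empty:
        raise ValueError(f"city {city!r} needs at least one urban and one periurban cell")

    urban_tot = urban.sum(axis=0)
    peri_tot = peri.sum(axis=0)
    recorded = (urban_tot + peri_tot) > 0
    if not include_exotics:
        if traits is None:
            raise ValueError("traits table required for include_exotics=False")
        recorded &= survey.columns.map(
            lambda s: traits.loc[s, "origin"] != "exotic" if s in traits.index else True
        ).to_numpy()
    urban_tot = urban_tot[recorded]
    peri_tot = peri_tot[recorded]
    peri_total = int(peri_tot.sum())
    if peri_total == 0:
        raise ValueError(f"city {city!r} has no periurban individuals")
    pool = peri_tot / peri_total
    N = int(urban_tot.sum())
    return pool, urban_tot, N


def simulate_random_communities(pool, N: int, n_sims: int, rng) -> np.ndarray:
    """Draw ``n_sims`` random communities of ``N`` individuals from ``pool``.

    Each row is one multinomial(N, pool) draw; row sums all equal N.
    """
    p = np.asarray(pool, dtype=float)
    if N < 1:
        raise ValueError("urban community size N must be >= 1")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("pool proportions must sum to 1")
    return rng.multinomial(N, p / p.sum(), size=int(n_sims))


def _column_mode(col: np.ndarray, tiebreak: str) -> int:
    counts = np.bincount(col)
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    return int(candidates[0] if tiebreak == "smallest" else candidates[-1])


def classify_fates(
    sim_matrix: np.ndarray,
    urban_counts,
    pool,
    mode_tiebreak: str = "smallest",
) -> pd.DataFrame:
    """Classify each species as present, chance-absent or avoider.

    The modal simulated abundance decides the fate of absentees: mode 0
    means the absence is expected under random assembly.  Ties in the mode
    are broken toward the smallest value by default, which is conservative
    (it favours chance-absent over avoider).
    """
    if mode_tiebreak not in ("smallest", "largest"):
        raise ValueError("mode_tiebreak must be 'smallest' or 'largest'")
    urban = np.asarray(urban_counts, dtype=int)
    modes = np.array(
        [_column_mode(sim_matrix[:, j], mode_tiebreak) for j in range(sim_matrix.shape[1])]
    )
    fate = np.where(
        urban > 0, FATE_PRESENT, np.where(modes == 0, FATE_CHANCE, FATE_AVOIDER)
    )
    index = urban_counts.index if hasattr(urban_counts, "index") else pd.RangeIndex(len(urban))
    out = pd.DataFrame(
        {
            "pool_proportion": np.asarray(pool, dtype=float),
            "urban_abundance": urban,
            "sim_mode": modes,
            "fate": fate,
        },
        index=index,
    )
    out.index.name = "species_id"
    return out


def loss_metrics(fates: pd.DataFrame, sim_matrix: np.ndarray) -> dict:
    """City-level loss summary from classified fates and the simulations.

    * observed loss: % of periurban species absent from the urban habitat;
    * random loss: % shortfall of mean simulated richness relative to
      periurban richness (loss attributable to random dispersal alone);
    * tolerance richness: total recorded species minus avoiders.
    """
    peri_present = fates["pool_proportion"] > 0
    S_peri = int(peri_present.sum())
    if S_peri == 0:
        raise ValueError("no periurban species: loss metrics undefined")
    absent = peri_present & (fates["urban_abundance"] == 0)
    sim_richness = (sim_matrix > 0).sum(axis=1)
    n_avoiders = int((fates["fate"] == FATE_AVOIDER).sum())
    S_total = len(fates)
    return {
        "S_periurban": S_peri,
        "S_urban_shared": int((peri_present & (fates["urban_abundance"] > 0)).sum()),
        "S_total": S_total,
        "observed_loss_pct": 100.0 * absent.sum() / S_peri,
        "random_loss_pct": 100.0 * (S_peri - sim_richness.mean()) / S_peri,
        "tolerance_richness": S_total - n_avoiders,
        "n_avoiders": n_avoiders,
        "n_chance_absent": int((fates["fate"] == FATE_CHANCE).sum()),
    }


class NullModel(BaseEstimator):
    """Classify urban absences per city and compute loss metrics.

    Parameters
    ----------
    n_sims : number of random communities per city (default 999).
    seed : master seed; each city gets an independent substream derived
        from it, so adding or dropping a city leaves the others unchanged.
    mode_tiebreak : "smallest" (conservative default) or "largest".
    include_exotics : whether exotic species enter the periurban pool;
        requires a traits table when False.

    Attributes (after :meth:`fit`)
    ------------------------------
    fates_ : per-species fate table with a ``city`` column.
    loss_ : per-city loss summary (one row per city).
    sims_ : dict city -> simulated community matrix (n_sims x species).
    """

    def __init__(
        self,
        n_sims: int = 999,
        seed=None,
        mode_tiebreak: str = "smallest",
        include_exotics: bool = True,
    ):
        self.n_sims = n_sims
        self.seed = seed
        self.mode_tiebreak = mode_tiebreak
        self.include_exotics = include_exotics

    def fit(self, survey: pd.DataFrame, cells: pd.DataFrame, traits: pd.DataFrame | None = None):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        survey = validate_survey(survey)
        cells = validate_cells(cells, survey)
        fates_frames, loss_rows, sims = [], [], {}
        for city in pd.unique(cells["city"]):
            rng = substream(self.seed, "nullmodel", city)
            pool, urban_tot, N = build_pool(
                survey, cells, city, self.include_exotics, traits
            )
            sim = simulate_random_communities(pool, N, self.n_sims, rng)
            fates = classify_fates(sim, urban_tot, pool, self.mode_tiebreak)
            fates.insert(0, "city", city)
            fates_frames.append(fates)
            loss_rows.append({"city": city, **loss_metrics(fates, sim)})
            sims[city] = sim
        self.fates_ = pd.concat(fates_frames)
        self.loss_ = pd.DataFrame(loss_rows).set_index("city")
        self.sims_ = sims
        return self


def run_null_model(survey, cells, traits=None, **params):
    """Functional wrapper: returns ``(loss_summary, species_fates)``."""
    model = NullModel(**params).fit(survey, cells, traits)
    return model.loss_, model.fates_
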