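"""Community-level transforms: fourth-root scaling, diversity, guild sums.

The fourth-root transform is the standard severe down-weighting of dominant
species used before Bray-Curtis community analyses.  Evenness defaults to
Pielou's J' = H'/ln(S) with natural logarithms ("log-evenness"); the index
choice is configurable because several log-based evenness measures exist,
and the one actually used is recorded in the result's ``attrs``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .tables import DIET_GUILDS, HABITAT_GUILDS, TableValidationError

EVENNESS_METHODS = ("pielou", "shannon")


def fourth_root(survey: pd.DataFrame) -> pd.DataFrame:
    """Replace every abundance y with y**(1/4).  Zeros are preserved."""
    vals = survey.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("fourth_root requires nonnegative abundances")
    return pd.DataFrame(vals ** 0.25, index=survey.index, columns=survey.columns)


def richness_evenness(survey: pd.DataFrame, method: str = "pielou") -> pd.DataFrame:
    """Per-cell species richness and evenness from raw counts.

    Richness counts species with a positive abundance.  Evenness is
    undefined (NaN) for cells with fewer than two species, because
    ln(S) = 0 degenerates; such cells are meant to be dropped from evenness
    analyses only.

    Parameters
    ----------
    survey : raw (untransformed) counts, cells x species.
    method : "pielou" for J' = H'/ln(S), or "shannon" for raw H' (nats).
    """
    if method not in EVENNESS_METHODS:
        raise ValueError(f"method must be one of {EVENNESS_METHODS}")
    counts = survey.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("richness_evenness requires nonnegative counts")
    richness = (counts > 0).sum(axis=1)
    even = np.full(len(survey), np.nan)
    for i, row in enumerate(counts):
        s = richness[i]
        if s <= 1:
            continue
        h = entropy(row[row > 0])  # Shannon H', natural log
        even[i] = h / np.log(s) if method == "pielou" else h
    out = pd.DataFrame(
        {"richness": richness.astype(int), "evenness": even}, index=survey.index
    )
    out.attrs["evenness_method"] = method
    return out


def aggregate_guilds(
    survey: pd.DataFrame, traits: pd.DataFrame, resource_group: str
) -> pd.DataFrame:
    """Sum species abundances into guilds of one resource group.

    ``resource_group`` is ``"diet"`` (7 canonical guilds) or ``"habitat"``
    (4 canonical guilds).  Output columns follow the canonical guild order,
    restricted to guilds with at least one member species; per-cell total
    abundance is conserved.  Species present in the survey but unmapped in
    ``traits`` raise an error naming them.
    """
    if resource_group == "diet":
        col, canonical = "diet_guild", DIET_GUILDS
    elif resource_group == "habitat":
        col, canonical = "habitat_guild", HABITAT_GUILDS
    else:
        raise ValueError("resource_group must be 'diet' or 'habitat'")
    unmapped = survey.columns.difference(traits.index)
    if len(unmapped):
        raise TableValidationError(
            f"species without a {col}: {list(map(str, unmapped))}"
        )
    membership = traits.loc[survey.columns, col]
    out = {}
    for guild in canonical:
        members = membership.index[membership == guild]
        if len(members):
            out[guild] = survey[members].sum(axis=1)
    return pd.DataFrame(out, index=survey.index)
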