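"""Survey, cell and trait tables: schemas, validation and delimited-text I/O.

The package operates on three aligned :class:`pandas.DataFrame` objects:

* ``survey`` -- cells x species abundance matrix of nonnegative integer
  point-count totals; index = cell_id, columns = species_id.
* ``cells``  -- per-cell metadata with columns ``city``,
  ``habitat`` (``urban`` / ``periurban``) and ``veg_cover`` (fraction of the
  grid cell covered by vegetation, in [0, 1]).
* ``traits`` -- per-species table with columns ``diet_guild``,
  ``habitat_guild`` and ``origin`` (``native`` / ``exotic``).  Diet and
  preferred-habitat guilds are two mutually exclusive resource groupings.

Files are UTF-8 CSV with a mandatory header row and the identifier in the
first column.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical diet guilds (7).
DIET_GUILDS = (
    "carnivore",
    "carrion",
    "frugivore",
    "granivore",
    "insectivore",
    "nectarivore",
    "omnivore",
)
#: Canonical preferred-habitat guilds (4).
HABITAT_GUILDS = ("forest", "open", "water_wetland", "generalist")
ORIGINS = ("native", "exotic")
HABITATS = ("urban", "periurban")

_CELL_COLUMNS = ("city", "habitat", "veg_cover")
_TRAIT_COLUMNS = ("diet_guild", "habitat_guild", "origin")


class SchemaError(ValueError):
    """A required column or header is missing from an input table."""


class TableValidationError(ValueError):
    """Table contents violate an invariant (negative counts, duplicates...)."""


def _canon(label) -> str:
    """Normalise a categorical label: case-insensitive, '/'->'_', ' '->'_'."""
    s = str(label).strip().lower()
    for ch in ("/", "-", " "):
        s = s.replace(ch, "_")
    return {"water_wetlands": "water_wetland", "wetland": "water_wetland"}.get(s, s)


def _check_unique(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()].unique()
    if len(dup):
        raise TableValidationError(f"duplicate {what}: {list(map(str, dup[:5]))}")


def validate_survey(survey: pd.DataFrame, integer: bool = True) -> pd.DataFrame:
    """Validate a cells x species abundance matrix.

    Entries must be nonnegative and (for raw counts) integer-valued; row and
    column labels must be unique.  Returns the validated frame with numeric
    dtype.
    """
    _check_unique(survey.index, "cell_id")
    _check_unique(pd.Index(survey.columns), "species_id")
    try:
        vals = survey.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TableValidationError(f"non-numeric abundance: {exc}") from None
    if not np.all(np.isfinite(vals)):
        raise TableValidationError("abundance matrix contains non-finite entries")
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise TableValidationError(
            f"negative abundance for cell {survey.index[i]!r}, "
            f"species {survey.columns[j]!r}"
        )
    if integer and not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise TableValidationError(
            f"non-integer abundance for cell {survey.index[i]!r}, "
            f"species {survey.columns[j]!r}"
        )
    out = survey.astype(int) if integer else survey.astype(float)
    return out


def validate_cells(cells: pd.DataFrame, survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate per-cell metadata and (optionally) its alignment to a survey."""
    missing = [c for c in _CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cells table is missing columns: {missing}")
    _check_unique(cells.index, "cell_id")
    out = cells.copy()
    out["habitat"] = out["habitat"].map(_canon)
    bad = sorted(set(out["habitat"]) - set(HABITATS))
    if bad:
        raise TableValidationError(f"unknown habitat labels: {bad}")
    veg = out["veg_cover"].to_numpy(dtype=float)
    if np.any(~np.isfinite(veg)) or np.any(veg < 0) or np.any(veg > 1):
        raise TableValidationError("veg_cover must lie in [0, 1]")
    if survey is not None:
        absent = survey.index.difference(out.index)
        if len(absent):
            raise TableValidationError(
                f"survey cells without metadata: {list(map(str, absent[:5]))}"
            )
        out = out.loc[survey.index]
    return out


def validate_traits(traits: pd.DataFrame, survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate the per-species guild table.

    Guild labels are matched case-insensitively against the canonical sets.
    Species present in ``survey`` but absent from ``traits`` are reported
    with a warning (they can still take part in taxonomic analyses, just not
    in guild aggregation).
    """
    missing = [c for c in _TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise SchemaError(f"traits table is missing columns: {missing}")
    _check_unique(traits.index, "species_id")
    out = traits.copy()
    for col, allowed in (
        ("diet_guild", DIET_GUILDS),
        ("habitat_guild", HABITAT_GUILDS),
        ("origin", ORIGINS),
    ):
        out[col] = out[col].map(_canon)
        bad = sorted(set(out[col]) - set(allowed))
        if bad:
            raise TableValidationError(f"unknown {col} labels: {bad}")
    if survey is not None:
        untraited = survey.columns.difference(out.index)
        if len(untraited):
            warnings.warn(
                "species without trait records: "
                f"{list(map(str, untraited))}",
                stacklevel=2,
            )
    return out


def read_survey(
    survey_path,
    cells_path=None,
    traits_path=None,
):
    """Read and validate the survey / cells / traits CSV triple.

    Returns ``(survey, cells, traits)``; ``cells`` and ``traits`` are
    ``None`` when the corresponding path is not given.  The cells table is
    reindexed to the survey's cell order.
    """
    survey = validate_survey(pd.read_csv(survey_path, index_col=0))
    cells = traits = None
    if cells_path is not None:
        cells = validate_cells(pd.read_csv(cells_path, index_col=0), survey)
    if traits_path is not None:
        traits = validate_traits(pd.read_csv(traits_path, index_col=0), survey)
    return survey, cells, traits


def write_tables(outdir, **frames) -> dict:
    """Write named DataFrames as ``<name>.csv`` under ``outdir``.

    Returns a mapping name -> written path.  Output is deterministic (no
    timestamps), so identical inputs yield byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in frames.items():
        if frame is None:
            continue
        path = outdir / f"{name}.csv"
        frame.to_csv(path)
        written[name] = path
    return written
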