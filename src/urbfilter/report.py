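"""End-to-end pipeline: simulate/load -> null model -> PERMANCOVA -> SIMPER -> PCoA.

``run_all`` executes every stage with seeds derived deterministically from
one master seed, writes tidy CSVs (plus an optional figure set) and a
manifest recording the configuration, its hash and every seed consumed.
Outputs carry no timestamps, so a given (config, seed) pair reproduces
byte-identical CSV files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import aggregate_guilds, fourth_root, richness_evenness
from .distance import bray_curtis, euclidean
from .nullmodel import NullModel
from .ordination import PCoA, centroid_distances, vector_fit
from .permancova import Permancova
from .simper import Simper
from .simulate import GeneratorConfig, generate_study
from .tables import read_survey, write_tables

#: The five community responses analysed by default.
RESPONSES = ("richness", "evenness", "community", "diet_guilds", "habitat_guilds")

_GUILD_RESPONSES = {"diet_guilds": "diet", "habitat_guilds": "habitat"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    generator: GeneratorConfig | None = None
    survey_path: str | None = None
    cells_path: str | None = None
    traits_path: str | None = None
    seed: int = 0
    n_sims: int = 999
    n_perms: int = 10000
    cutoff: float = 0.90
    vector_threshold: float = 0.75
    responses: tuple = RESPONSES
    evenness_method: str = "pielou"
    make_figures: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        d["responses"] = list(self.responses)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode("utf8")
        ).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) ^ zlib.crc32(stage.encode("utf8"))) & 0x7FFFFFFF


def _response_distance(response, survey, cells, traits, evenness_method):
    """Distance matrix + aligned metadata for one response variable."""
    meta = cells.copy()
    if response == "richness":
        div = richness_evenness(survey, evenness_method)
        return euclidean(div[["richness"]]), meta
    if response == "evenness":
        div = richness_evenness(survey, evenness_method)
        keep = div["evenness"].notna()
        return euclidean(div.loc[keep, ["evenness"]]), meta.loc[keep]
    if response == "community":
        return bray_curtis(fourth_root(survey)), meta
    if response in _GUILD_RESPONSES:
        if traits is None:
            raise PipelineError(
                f"response {response!r} needs a traits table (none configured)"
            )
        guilds = aggregate_guilds(survey, traits, _GUILD_RESPONSES[response])
        return bray_curtis(fourth_root(guilds)), meta
    raise PipelineError(f"unknown response {response!r}")


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage; returns the result frames and writes them under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    seeds_used: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- data ---------------------------------------------------------------
    def _data():
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=_stage_seed(config.seed, "simulate"))
            seeds_used["simulate"] = gen.seed
            survey, cells, traits, truth = generate_study(gen)
        else:
            if config.survey_path is None or config.cells_path is None:
                raise ValueError("either a generator config or survey/cells paths are required")
            survey, cells, traits = read_survey(
                config.survey_path, config.cells_path, config.traits_path
            )
            truth = None
        return survey, cells, traits, truth

    survey, cells, traits, truth = stage("data", _data)
    write_tables(outdir, survey=survey, cells=cells, traits=traits, ground_truth=truth)

    # -- null model ---------------------------------------------------------
    def _null():
        seeds_used["nullmodel"] = _stage_seed(config.seed, "nullmodel")
        nm = NullModel(n_sims=config.n_sims, seed=seeds_used["nullmodel"]).fit(
            survey, cells, traits
        )
        return nm

    nm = stage("nullmodel", _null)
    results["loss_summary"] = nm.loss_
    results["species_fates"] = nm.fates_
    write_tables(outdir, loss_summary=nm.loss_, species_fates=nm.fates_)

    # -- PERMANCOVA per response --------------------------------------------
    for response in config.responses:
        def _perm(response=response):
            D, meta = _response_distance(
                response, survey, cells, traits, config.evenness_method
            )
            seeds_used[f"permancova_{response}"] = _stage_seed(
                config.seed, f"permancova_{response}"
            )
            est = Permancova(
                fixed_factor="habitat",
                random_factor="city",
                covariate="veg_cover",
                n_perms=config.n_perms,
                seed=seeds_used[f"permancova_{response}"],
            ).fit(D, meta)
            return est.results_

        table = stage(f"permancova_{response}", _perm)
        results[f"permancova_{response}"] = table
        write_tables(outdir, **{f"permancova_{response}": table})

    # -- SIMPER -------------------------------------------------------------
    def _simper():
        out = {}
        transformed = fourth_root(survey)
        for city in pd.unique(cells["city"]):
            idx = cells.index[cells["city"] == city]
            est = Simper(cutoff=config.cutoff).fit(
                transformed.loc[idx], cells.loc[idx, "habitat"]
            )
            tab = est.table_.copy()
            tab.insert(0, "city", city)
            out[f"simper_species_{city}"] = tab
        if traits is not None:
            for level in ("diet", "habitat"):
                guilds = fourth_root(aggregate_guilds(survey, traits, level))
                est = Simper(cutoff=config.cutoff).fit(guilds, cells["habitat"])
                out[f"simper_{level}_guilds"] = est.table_
        return out

    simper_tables = stage("simper", _simper)
    results.update(simper_tables)
    write_tables(outdir, **simper_tables)

    # -- ordination ---------------------------------------------------------
    def _ordination():
        out = {}
        transformed = fourth_root(survey)
        group = cells["city"].astype(str) + ":" + cells["habitat"].astype(str)
        D = bray_curtis(transformed)
        Dc = centroid_distances(D, group)
        est = PCoA(n_axes=2).fit(Dc)
        coords = est.coordinates_
        means = transformed.groupby(group.to_numpy()).mean().loc[coords.index]
        overlay = vector_fit(coords, means, threshold=config.vector_threshold)
        out["pcoa_centroids"] = coords
        out["pcoa_vectors"] = overlay
        out["pcoa_eigenvalues"] = pd.DataFrame(
            {
                "eigenvalue": est.eigenvalues_,
                "pct_explained": [
                    est.pct_explained_[i] if i < len(est.pct_explained_) else float("nan")
                    for i in range(len(est.eigenvalues_))
                ],
            }
        )
        return out

    ord_tables = stage("ordination", _ordination)
    results.update(ord_tables)
    write_tables(outdir, **ord_tables)

    if config.make_figures:
        stage("figures", lambda: _figures(results, outdir))

    manifest = {
        "package": "urbfilter",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seeds_used": seeds_used,
        "evenness_method": config.evenness_method,
        "stages": sorted(results),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _figures(results, outdir) -> None:
    """Loss bar chart and centroid ordination plot (convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    loss = results["loss_summary"]
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(loss))
    width = 0.35
    ax.bar([i - width / 2 for i in x], loss["observed_loss_pct"], width, label="observed")
    ax.bar([i + width / 2 for i in x], loss["random_loss_pct"], width, label="random")
    ax.set_xticks(list(x))
    ax.set_xticklabels(loss.index)
    ax.set_ylabel("species loss (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "loss_summary.png", dpi=150)
    plt.close(fig)

    coords = results["pcoa_centroids"]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
    for label, row in coords.iterrows():
        ax.annotate(label, (row.iloc[0], row.iloc[1]), fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(outdir / "pcoa_centroids.png", dpi=150)
    plt.close(fig)
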