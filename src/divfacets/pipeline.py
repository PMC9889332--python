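"""End-to-end orchestration: one config reproduces the full analysis
(alpha, beta, gamma, contrasts, accumulation, complementarity) with
deterministic seeding and a run manifest."""

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import regional
from .alpha import alpha_table, assemblage_diversity
from .beta import beta_pairs_table
from .complementarity import cell_table, replace_cells
from .io import (
    DataError,
    read_community_csv,
    read_grid_csv,
    read_newick,
    read_trait_csv,
    read_trait_schema,
    validate_dataset,
)
from .traitspace import gower_distance, nmds_embed

log = logging.getLogger("divfacets")

__all__ = ["PipelineConfig", "run_pipeline", "homogenization_signature"]

# per-stage sub-seed offsets fanned out from the global seed, so adding a
# stage never perturbs earlier stages' randomness
_SEED_NMDS, _SEED_GAMMA, _SEED_ACCUM = 101, 211, 307

NATURAL_HABITATS = ("forest", "savannah")


@dataclass
class PipelineConfig:
    community: str
    traits: str
    traits_schema: str
    tree: str
    grid: str | None = None
    replacements: str | None = None  # YAML: cell_id -> [species, ...]
    out_dir: str = "divfacets_out"
    k: int = 3
    n_starts: int = 20
    max_iter: int = 300
    n_draws: int = 1000
    group_sizes: dict = field(default_factory=lambda: {"forest": 7, "savannah": 8})
    elevation_max: float | None = None
    facets: tuple = ("taxonomic", "functional", "phylogenetic")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "group_sizes" in raw:
            raw["group_sizes"] = dict(raw["group_sizes"])
        if "facets" in raw:
            raw["facets"] = tuple(raw["facets"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.12g")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write alpha/beta/gamma/contrasts/curve[/cells]
    CSVs plus a manifest.  Any stage failure aborts with the stage name and
    removes partial outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        cm = read_community_csv(cfg.community)
        kinds, units = read_trait_schema(cfg.traits_schema)
        tt = read_trait_csv(cfg.traits, kinds, units)
        phy = read_newick(cfg.tree)
        rep = validate_dataset(cm, tt, phy)
        for w in rep.warnings:
            log.warning(w)
        rep.raise_if_invalid()
        if cfg.elevation_max is not None:
            stage = "elevation_filter"
            n_before = cm.n_sites
            cm = regional.elevation_filter(cm, cfg.elevation_max)
            log.info("elevation filter kept %d of %d sites", cm.n_sites, n_before)

        stage = "traitspace"
        dm = gower_distance(tt)
        ts = nmds_embed(dm, k=cfg.k, n_starts=cfg.n_starts,
                        max_iter=cfg.max_iter, seed=cfg.seed + _SEED_NMDS)
        log.info("NMDS stress-1 = %.4f (k=%d)", ts.stress, ts.k)
        space = pd.DataFrame(ts.coords, index=ts.labels,
                             columns=[f"axis{i + 1}" for i in range(ts.k)])
        space.index.name = "species_id"
        outputs["space"] = out_dir / "space.csv"
        space.to_csv(outputs["space"])

        stage = "alpha"
        alpha = alpha_table(cm, ts, phy)
        outputs["alpha"] = out_dir / "alpha.csv"
        _write_csv(alpha, outputs["alpha"])

        stage = "beta"
        beta = pd.concat(
            [beta_pairs_table(cm, facet, ts=ts, phy=phy) for facet in cfg.facets],
            ignore_index=True)
        n_nan = int(beta["dissimilarity"].isna().sum())
        if n_nan:
            log.warning("%d undefined beta pair(s) reported as NaN", n_nan)
        outputs["beta"] = out_dir / "beta.csv"
        _write_csv(beta, outputs["beta"])

        stage = "gamma"
        gamma_rows = []
        for facet in cfg.facets:
            gs = regional.subsample_gamma(
                cm, ts, phy, cfg.group_sizes, facet, n_draws=cfg.n_draws,
                seed=cfg.seed + _SEED_GAMMA, habitat_class="natural")
            gamma_rows.append({"habitat_class": "natural", "facet": facet,
                               "draws": gs.draws, "median": gs.median,
                               "sd": gs.sd, "min": gs.min, "max": gs.max})
            farm_sites = cm.sites_by_habitat("farmland")
            rec = assemblage_diversity(cm, ts, phy, farm_sites, assemblage_id="farmland")
            value = {"taxonomic": float(rec.richness), "functional": rec.fric,
                     "phylogenetic": rec.pd}[facet]
            gamma_rows.append({"habitat_class": "farmland", "facet": facet,
                               "draws": 1, "median": value, "sd": 0.0,
                               "min": value, "max": value})
        gamma = pd.DataFrame(gamma_rows)
        outputs["gamma"] = out_dir / "gamma.csv"
        _write_csv(gamma, outputs["gamma"])

        stage = "contrasts"
        natural_sites = set(cm.sites_by_habitat(*NATURAL_HABITATS))
        contrast_rows = []
        for metric in ("richness", "fric", "pd"):
            nat = alpha.loc[alpha.site_id.isin(natural_sites), metric]
            farm = alpha.loc[~alpha.site_id.isin(natural_sites), metric]
            try:
                hc = regional.compare_groups(nat, farm, metric_name=f"alpha_{metric}",
                                             group_labels=("natural", "farmland"))
            except DataError as exc:
                log.warning("skipping alpha_%s contrast: %s", metric, exc)
                continue
            contrast_rows.append(hc)
        log.warning("beta t-tests treat non-independent pairwise values as "
                    "observations, as in the source design")
        for facet in cfg.facets:
            sub = beta[beta.facet == facet]
            nat = sub.loc[sub.habitat_class.isin(NATURAL_HABITATS), "dissimilarity"]
            farm = sub.loc[sub.habitat_class == "farmland", "dissimilarity"]
            try:
                hc = regional.compare_groups(nat, farm, metric_name=f"beta_{facet}",
                                             group_labels=("natural", "farmland"))
            except DataError as exc:
                log.warning("skipping beta_%s contrast: %s", facet, exc)
                continue
            contrast_rows.append(hc)
        contrasts = pd.DataFrame([{
            "metric": h.metric_name, "group_a": h.group_labels[0],
            "group_b": h.group_labels[1], "t": h.t, "df": h.df, "p": h.p,
            "median_a": h.medians[0], "median_b": h.medians[1],
            "iqr_a": h.iqrs[0], "iqr_b": h.iqrs[1],
        } for h in contrast_rows])
        outputs["contrasts"] = out_dir / "contrasts.csv"
        _write_csv(contrasts, outputs["contrasts"])

        stage = "accumulation"
        curve_rows = []
        for label, sites in (
            ("farmland", cm.sites_by_habitat("farmland")),
            ("natural", cm.sites_by_habitat(*NATURAL_HABITATS)),
        ):
            ac = regional.accumulation_curve(cm, sites, mode="exact")
            for k, s in zip(ac.k, ac.expected_richness):
                curve_rows.append({"habitat_class": label, "k": int(k),
                                   "expected_richness": s})
        outputs["curve"] = out_dir / "curve.csv"
        _write_csv(pd.DataFrame(curve_rows), outputs["curve"])

        if cfg.grid is not None:
            stage = "complementarity"
            grid = read_grid_csv(cfg.grid)
            if cfg.replacements is not None:
                with open(cfg.replacements) as fh:
                    repl = yaml.safe_load(fh)
                grid = replace_cells(grid, repl)
            cells = cell_table(grid, phy)
            outputs["cells"] = out_dir / "cells.csv"
            cells.to_csv(outputs["cells"], float_format="%.12g")

        stage = "manifest"
        manifest = {
            "config_hash": cfg.config_hash(), "seed": cfg.seed,
            "row_counts": {name: int(pd.read_csv(p).shape[0])
                           for name, p in outputs.items()},
        }
        outputs["manifest"] = out_dir / "manifest.json"
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs


# ---------------------------------------------------------------------------
# In-memory full-pipeline summary used by the recovery checks
# ---------------------------------------------------------------------------

def homogenization_signature(ds, seed: int = 0, n_draws: int = 100,
                             n_starts: int = 4, max_iter: int = 150) -> dict:
    """Compare farmland vs natural alpha/beta/gamma on all three facets.

    Returns per-facet booleans for the homogenization signature (higher
    farmland alpha, lower farmland gamma than subsampled natural gamma,
    lower farmland beta) plus their conjunction.
    """
    import warnings as _w

    from .io import TraitTable

    cm, tt, phy = ds.cm, ds.tt, ds.phy
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        # one shared trait space over the observed species pool
        tt = TraitTable(data=tt.data.loc[cm.species_ids], kinds=tt.kinds,
                        units=tt.units)
        dm = gower_distance(tt)
        ts = nmds_embed(dm, k=3, n_starts=n_starts, max_iter=max_iter,
                        seed=seed + _SEED_NMDS)
        alpha = alpha_table(cm, ts, phy)
        natural_sites = set(cm.sites_by_habitat(*NATURAL_HABITATS))
        is_nat = alpha.site_id.isin(natural_sites)
        farm_sites = cm.sites_by_habitat("farmland")
        n_forest = min(7, len(cm.sites_by_habitat("forest")))
        n_sav = min(8, len(cm.sites_by_habitat("savannah")))
        out: dict = {"facets": {}}
        betas = {facet: beta_pairs_table(cm, facet, ts=ts, phy=phy)
                 for facet in ("taxonomic", "functional", "phylogenetic")}
        for facet, metric in (("taxonomic", "richness"),
                              ("functional", "fric"),
                              ("phylogenetic", "pd")):
            alpha_nat = float(np.nanmedian(alpha.loc[is_nat, metric]))
            alpha_farm = float(np.nanmedian(alpha.loc[~is_nat, metric]))
            gs = regional.subsample_gamma(
                cm, ts, phy, {"forest": n_forest, "savannah": n_sav},
                facet, n_draws=n_draws, seed=seed + _SEED_GAMMA)
            rec = assemblage_diversity(cm, ts, phy, farm_sites)
            gamma_farm = {"taxonomic": float(rec.richness),
                          "functional": rec.fric,
                          "phylogenetic": rec.pd}[facet]
            sub = betas[facet]
            beta_nat = float(np.nanmedian(
                sub.loc[sub.habitat_class.isin(NATURAL_HABITATS), "dissimilarity"]))
            beta_farm = float(np.nanmedian(
                sub.loc[sub.habitat_class == "farmland", "dissimilarity"]))
            out["facets"][facet] = {
                "alpha_natural": alpha_nat, "alpha_farmland": alpha_farm,
                "gamma_natural_median": gs.median, "gamma_farmland": gamma_farm,
                "beta_natural": beta_nat, "beta_farmland": beta_farm,
                "alpha_higher_in_farmland": alpha_farm > alpha_nat,
                "gamma_lower_in_farmland": gamma_farm < gs.median,
                "beta_lower_in_farmland": beta_farm < beta_nat,
            }
        out["signature"] = all(
            f["alpha_higher_in_farmland"] and f["gamma_lower_in_farmland"]
            and f["beta_lower_in_farmland"] for f in out["facets"].values())
    return out
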