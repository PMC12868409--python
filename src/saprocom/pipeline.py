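"""End-to-end orchestration of the deadwood community-assembly analysis.

Stage order: ingest (or simulate) -> trait preprocessing -> functional
and phylogenetic distance matrices -> blend-weight scan -> SES-MFPD at
the selected a -> four trend models (abundance, species number, species
richness, SES-MFPD) -> trait ablation -> compositional analysis
(filters, NMDS, conditional-inference tree, PERMANOVA) -> temporal
niches.  Every artifact is written as CSV/JSON into the output
directory together with a run log recording seeds and parameters.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import ablate_traits, scan_a
from .composition import bray_curtis, inference_tree, nmds, permanova
from .data_model import (assemblage_matrix,
                         read_community, summarize_overlap)
from .diversity import blend_distances, ses_mpd
from .niche import niche_summary
from .phylo import cophenetic_distance, graft_all, read_graft_list, read_newick, \
    write_newick
from .synthetic import SimulationConfig, simulate_dataset
from .traits import TraitSchema, gower_distance, preprocess_traits, \
    trait_correlations
from .trends import build_trend_frame, fit_additive_model, fit_richness_model, \
    morans_i_residuals

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    """Inputs plus analysis parameters for one pipeline run.

    Either ``synthetic`` is set (a :class:`SimulationConfig`) or all of
    the real-data paths are; analysis parameters default to the survey
    analysis conventions (a-grid step 0.025, blend exponent 2, 999
    randomizations/permutations, >=4 species per compositional
    assemblage, spruce year-0 excluded, >=3 individuals display filter,
    ablation threshold 0.03).
    """

    seed: int = 0
    synthetic: SimulationConfig | None = None
    community_path: str | None = None
    design_path: str | None = None
    traits_path: str | None = None
    schema_path: str | None = None
    newick_path: str | None = None
    graft_path: str | None = None
    sampling_years: tuple[int, ...] = ()
    missing_years: tuple[int, ...] = ()
    grid_step: float = 0.025
    blend_p: float = 2.0
    n_rand: int = 999
    n_perm: int = 999
    alpha: float = 0.05
    min_species: int = 4
    min_individuals_per_year: int = 3
    ablation_threshold: float = 0.03
    exclude_spruce_year0: bool = True
    nmds_starts: int = 20
    k_year: int = 10
    n_knots_spatial: int = 30
    ctree_min_leaf: int = 7

    def __post_init__(self):
        if self.synthetic is None and self.community_path is None:
            raise ValueError("either synthetic config or data paths required")
        for name in ("grid_step", "blend_p", "alpha", "ablation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in syn.items()})
        for key in ("sampling_years", "missing_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small synthetic configuration for a quick end-to-end run."""
    return PipelineConfig(
        seed=seed,
        synthetic=SimulationConfig(n_species=60, n_years=8, paper_design=False,
                                   n_logs_per_tree=7),
        n_rand=199, n_perm=199, nmds_starts=8, k_year=6, n_knots_spatial=8,
        ctree_min_leaf=5,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write all artifacts; returns the report dict."""
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    # ---- ingest -----------------------------------------------------------
    if config.synthetic is not None:
        tree, traits_raw, schema, design, community, truth = simulate_dataset(
            config.synthetic, config.seed)
        write_newick(tree, out / "tree.nwk")
        truth.to_json(out / "truth.json")
    else:
        design, community = read_community(
            config.community_path, config.design_path,
            sampling_years=config.sampling_years,
            missing_years=config.missing_years)
        traits_raw = pd.read_csv(config.traits_path, index_col=0)
        schema = TraitSchema.from_json(config.schema_path)
        tree = read_newick(config.newick_path)
        if config.graft_path:
            tree = graft_all(tree, read_graft_list(config.graft_path))
    design.to_csv(out / "design.csv")
    community.to_csv(out / "community.csv")
    schema.to_json(out / "schema.json")

    overlap = summarize_overlap(community, design)
    overlap.to_json(out / "overlap.json")
    report["overlap"] = {"total_species": overlap.total_species,
                         "total_individuals": overlap.total_individuals,
                         "shared_all": overlap.shared_all}

    # ---- traits & distances ----------------------------------------------
    traits = preprocess_traits(traits_raw, schema)
    traits.to_csv(out / "traits.csv")
    collin = trait_correlations(traits, schema)
    collin.vif.to_csv(out / "vif.csv", header=["vif"])
    report["max_vif"] = float(collin.vif.replace(np.inf, np.nan).max())

    species = sorted(set(community.species) & set(traits.index))
    traits = traits.loc[species]
    F = gower_distance(traits, schema)
    P = cophenetic_distance(tree, species)
    F.to_csv(out / "gower.csv")
    P.to_csv(out / "cophenetic.csv")

    sites = assemblage_matrix(community, design, min_species=2)
    sites = sites.loc[:, [c for c in sites.columns if c in species]]

    # ---- a-scan and SES at the selected blend ----------------------------
    scan = scan_a(sites, F, P, community, design, grid_step=config.grid_step,
                  p=config.blend_p, n_rand=config.n_rand, seed=config.seed,
                  k_year=config.k_year, n_knots_spatial=config.n_knots_spatial)
    scan.to_csv(out / "scan_a.csv")
    report["selected_a"] = scan.selected_a

    blend = blend_distances(F, P, a=scan.selected_a, p=config.blend_p)
    ses = ses_mpd(sites, blend, n_rand=config.n_rand, seed=config.seed)
    ses.to_csv(out / "ses_mfpd.csv")

    # ---- trend models -----------------------------------------------------
    frame = build_trend_frame(community, design, ses=ses)
    gam_kw = dict(k_year=config.k_year, n_knots_spatial=config.n_knots_spatial)
    fits = {
        "abundance": fit_additive_model(frame, "abundance",
                                        family="negative_binomial", **gam_kw),
        "n_species": fit_additive_model(frame, "n_species",
                                        family="negative_binomial", **gam_kw),
        "richness": fit_richness_model(frame, **gam_kw),
        "ses_mfpd": fit_additive_model(frame.dropna(subset=["ses"]), "ses",
                                       family="gaussian", **gam_kw),
    }
    report["models"] = {}
    for name, fit in fits.items():
        summ = fit.summary()
        report["models"][name] = {"adj_r2": summ["adj_r2"],
                                  "stars": summ["stars"]}
        with open(out / f"model_{name}.json", "w") as fh:
            json.dump(summ, fh, indent=2, default=float)
        if name == "ses_mfpd":
            data_used = frame.dropna(subset=["ses"])
        elif name == "richness":
            data_used = frame[frame["abundance"] > 0].assign(
                log_abundance=lambda d: np.log(d["abundance"].astype(float)))
        else:
            data_used = frame
        fit.prediction_grid(data_used).to_csv(out / f"pred_{name}.csv",
                                              index=False)
        moran = morans_i_residuals(fit.residuals,
                                   data_used[["E", "N"]].to_numpy())
        report["models"][name]["moran_p"] = moran.p_value

    # ---- trait ablation ---------------------------------------------------
    ablation = ablate_traits(sites, traits, schema, P, community, design,
                             a=scan.selected_a, p=config.blend_p,
                             n_rand=config.n_rand, seed=config.seed,
                             threshold=config.ablation_threshold, **gam_kw)
    ablation.to_csv(out / "ablation.csv")
    report["ablation"] = {"full_adj_r2": ablation.full_adj_r2,
                          "most_influential": ablation.most_influential}

    # ---- composition ------------------------------------------------------
    exclusions = {("spruce", 0)} if config.exclude_spruce_year0 else set()
    comp_sites = assemblage_matrix(community, design,
                                   min_species=config.min_species,
                                   exclusions=exclusions)
    D = bray_curtis(comp_sites)
    ord_res = nmds(D, k=2, n_starts=config.nmds_starts, seed=config.seed)
    ord_res.to_csv(out / "nmds_scores.csv")
    report["nmds_stress"] = ord_res.stress

    years = comp_sites.index.get_level_values("exposure_year").to_numpy()
    tree_of = dict(zip(design.logs["log_id"], design.logs["tree_species"]))
    tree_fac = pd.Series([tree_of[l] for l in
                          comp_sites.index.get_level_values("log_id")],
                         index=comp_sites.index)
    year_fac = pd.Series(years, index=comp_sites.index)
    perma = permanova(D, {"tree_species": tree_fac, "exposure_year": year_fac},
                      n_perm=config.n_perm, seed=config.seed)
    perma.to_csv(out / "permanova.csv")
    report["permanova"] = {
        t: {"r2": float(perma.table.loc[t, "r2"]),
            "p": float(perma.table.loc[t, "p_value"])}
        for t in ("tree_species", "exposure_year")}

    ctree = inference_tree(ord_res.scores["axis1"].to_numpy(), years,
                           alpha=config.alpha, min_leaf=config.ctree_min_leaf)
    ctree.to_json(out / "ctree.json")
    (out / "ctree.txt").write_text(ctree.render() + "\n")
    report["ctree_groups"] = [list(g) for g in ctree.leaf_year_groups()]

    # ---- temporal niches --------------------------------------------------
    niches = niche_summary(community, design,
                           min_individuals_per_year=config.min_individuals_per_year)
    niches.to_csv(out / "niche.csv")
    report["n_display_species"] = int(niches["display"].sum())

    report["runtime_s"] = round(time.time() - t0, 2)
    params = asdict(config)
    if config.synthetic is not None:
        params["synthetic"] = asdict(config.synthetic)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"report": report, "parameters": params}, fh, indent=2,
                  default=str)
    return report
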