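"""Temporal niche position and breadth per species.

The niche position of a species is its abundance-weighted mean year of
emergence over the whole survey; the abundance-weighted standard
deviation around that mean (population-weighted, no -1 correction — it
describes the dispersion of the observed individuals, not a sampling
estimator) is the temporal niche breadth.  A display filter marks
species with at least ``min_individuals_per_year`` individuals in some
year (default 3); the summary itself is computed for every species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CommunityTable, SurveyDesign

__all__ = ["niche_summary"]


def niche_summary(table: CommunityTable, design: SurveyDesign | None = None,
                  min_individuals_per_year: int = 3) -> pd.DataFrame:
    """Per-species niche position, breadth and tree-species associations.

    Returns a DataFrame indexed by species, sorted by weighted mean
    emergence year, with columns ``mean_year``, ``sd_year`` (niche
    breadth), ``total_individuals``, ``associations`` (subset of
    "B", "F", "S" when a design is given) and ``display`` (the
    visualization filter flag).
    """
    if len(table) == 0:
        raise ValueError("empty community table")
    rec = table.records
    per_year = (rec.groupby(["species_id", "exposure_year"])["count"].sum()
                .reset_index())
    rows = {}
    for sp, grp in per_year.groupby("species_id"):
        y = grp["exposure_year"].to_numpy(float)
        w = grp["count"].to_numpy(float)
        total = w.sum()
        mean = float((w * y).sum() / total)
        sd = float(np.sqrt((w * (y - mean) ** 2).sum() / total))
        rows[sp] = {
            "mean_year": mean,
            "sd_year": sd,
            "total_individuals": int(total),
            "display": bool((w >= min_individuals_per_year).any()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species_id"
    if design is not None:
        abbrev = {"beech": "B", "fir": "F", "spruce": "S"}
        tree_of = dict(zip(design.logs["log_id"], design.logs["tree_species"]))
        assoc = (rec.assign(tree=rec["log_id"].map(tree_of))
                 .groupby("species_id")["tree"]
                 .agg(lambda s: "".join(sorted({abbrev[t] for t in s}))))
        out["associations"] = assoc
    return out.sort_values("mean_year")
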