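"""Trait preprocessing, collinearity diagnostics and Gower distance.

Species traits mix continuous morphology (body length, wing length,
...), ordinal scores (hairiness classes) and categorical ecology
(feeding type, host-tree association).  A sidecar schema declares each
trait's type plus two preprocessing flags: standardize by body length
(size correction of linear measurements) and natural-log transform.
Gower distance handles the mixed types: continuous traits contribute
range-normalized absolute differences, categorical traits simple
mismatch, averaged over the traits observed for both species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTINUOUS, ORDINAL, CATEGORICAL = "continuous", "ordinal", "categorical"

__all__ = ["TraitSchema", "preprocess_traits", "trait_correlations",
           "CollinearityReport", "gower_distance"]


@dataclass
class TraitSchema:
    """Trait name -> type (+ preprocessing flags).

    ``types`` maps each trait column to ``continuous``, ``ordinal`` or
    ``categorical``; ``standardize_by_body_length`` and
    ``log_transform`` list trait names the respective flag applies to.
    """

    types: dict[str, str]
    standardize_by_body_length: tuple[str, ...] = ()
    log_transform: tuple[str, ...] = ()
    body_length_column: str = "body_length"

    def __post_init__(self):
        bad = {v for v in self.types.values()} - {CONTINUOUS, ORDINAL, CATEGORICAL}
        if bad:
            raise ValueError(f"unknown trait types: {sorted(bad)}")
        for name in (*self.standardize_by_body_length, *self.log_transform):
            if name not in self.types:
                raise ValueError(f"flagged trait {name!r} not in schema")

    @property
    def traits(self) -> list[str]:
        return list(self.types)

    def continuous_traits(self) -> list[str]:
        return [t for t, k in self.types.items() if k == CONTINUOUS]

    def drop(self, trait: str) -> "TraitSchema":
        """Schema without one trait (used by the trait-ablation loop)."""
        if trait not in self.types:
            raise KeyError(trait)
        types = {t: k for t, k in self.types.items() if t != trait}
        if not types:
            raise ValueError("cannot drop the last trait")
        return TraitSchema(
            types=types,
            standardize_by_body_length=tuple(
                t for t in self.standardize_by_body_length if t != trait),
            log_transform=tuple(t for t in self.log_transform if t != trait),
            body_length_column=self.body_length_column,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"types": self.types,
                       "standardize_by_body_length": list(self.standardize_by_body_length),
                       "log_transform": list(self.log_transform),
                       "body_length_column": self.body_length_column}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TraitSchema":
        with open(path) as fh:
            d = json.load(fh)
        return cls(types=d["types"],
                   standardize_by_body_length=tuple(d.get("standardize_by_body_length", ())),
                   log_transform=tuple(d.get("log_transform", ())),
                   body_length_column=d.get("body_length_column", "body_length"))


def preprocess_traits(raw: pd.DataFrame, schema: TraitSchema) -> pd.DataFrame:
    """Apply the schema's per-trait transformations, once each.

    Standardization by body length is applied before the log transform,
    so a trait carrying both flags becomes ``log(x / body_length)``.
    Raises on non-positive values under the log flag or missing /
    non-positive body length where standardization is requested.
    """
    df = raw.copy()
    if schema.standardize_by_body_length:
        bl = df[schema.body_length_column]
        if (bl <= 0).any() or bl.isna().any():
            raise ValueError("body length must be present and positive for standardization")
        for t in schema.standardize_by_body_length:
            df[t] = df[t] / bl
    for t in schema.log_transform:
        vals = df[t]
        if (vals <= 0).any():
            raise ValueError(f"non-positive value in {t!r} under log flag")
        df[t] = np.log(vals)
    return df


@dataclass(frozen=True)
class CollinearityReport:
    pearson_r: pd.DataFrame
    vif: pd.Series
    threshold: float
    excluded: tuple[str, ...] = ()

    @property
    def above_threshold(self) -> list[str]:
        return list(self.vif.index[self.vif > self.threshold])


def trait_correlations(traits: pd.DataFrame, schema: TraitSchema,
                       threshold: float = 5.0) -> CollinearityReport:
    """Pairwise Pearson r and VIF over the continuous traits.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from the least-squares regression
    of trait j on all other continuous traits (pairwise-complete r for
    the correlation matrix).  Constant traits have undefined r; they are
    excluded from the VIF computation and listed in ``excluded``.
    Perfectly collinear traits yield infinite VIF, reported as-is.
    """
    cont = [t for t in schema.continuous_traits() if t in traits.columns]
    if len(traits) < 3:
        raise ValueError("need at least 3 species")
    X = traits[cont].astype(float)
    constant = [t for t in cont if np.isclose(X[t].std(ddof=0), 0.0)]
    keep = [t for t in cont if t not in constant]
    r = X[keep].corr(method="pearson", min_periods=2)
    vifs = {}
    Z = X[keep].to_numpy()
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=0)
    for j, t in enumerate(keep):
        others = np.delete(Z, j, axis=1)
        y = Z[:, j]
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        r2 = 1.0 - resid @ resid / (y @ y)
        vifs[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return CollinearityReport(pearson_r=r, vif=pd.Series(vifs), threshold=threshold,
                              excluded=tuple(constant))


def gower_distance(traits: pd.DataFrame, schema: TraitSchema,
                   species_subset=None) -> pd.DataFrame:
    """Gower distance over mixed trait types, in [0, 1].

    Continuous and ordinal traits contribute |x_i - x_j| / range (ordinal
    traits are first rank-scaled to [0, 1]); categorical traits
    contribute 0/1 mismatch.  The distance is the mean contribution over
    traits non-missing in both species (pairwise deletion).  Ranges are
    taken over all species passed in ``traits`` — the full pool — so
    distances are comparable across assemblages.
    """
    sub = traits if species_subset is None else traits.loc[list(species_subset)]
    if len(sub) < 2:
        raise ValueError("need at least 2 species")
    n = len(sub)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for t, kind in schema.types.items():
        if t not in traits.columns:
            raise KeyError(f"trait {t!r} missing from table")
        col_full = traits[t]
        col = sub[t]
        avail = col.notna().to_numpy()
        both = np.outer(avail, avail)
        if kind == CATEGORICAL:
            vals = col.to_numpy(object)
            contrib = (vals[:, None] != vals[None, :]).astype(float)
        else:
            if kind == ORDINAL:
                # rank over the full pool, scaled to [0, 1]
                ranks = col_full.rank(method="average")
                ranks = (ranks - ranks.min()) / max(ranks.max() - ranks.min(), 1e-300)
                vals = ranks.loc[sub.index].to_numpy(float)
                rng = 1.0
            else:
                vals = col.to_numpy(float)
                rng = float(np.nanmax(col_full) - np.nanmin(col_full))
            if rng <= 0:
                contrib = np.zeros((n, n))
            else:
                contrib = np.abs(vals[:, None] - vals[None, :]) / rng
        contrib = np.where(both, np.nan_to_num(contrib), 0.0)
        num += contrib
        den += both.astype(float)
    if (den[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("species pair with zero jointly observed traits")
    D = num / den
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=sub.index, columns=sub.index)
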