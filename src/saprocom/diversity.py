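"""Functional-phylogenetic distance blending and the SES-MPD null model.

The blended distance FPDist(a, p) combines a functional (Gower) and a
phylogenetic (cophenetic) distance matrix, each rescaled by its own
maximum, as

    d_ij = (a * P_ij**p + (1 - a) * F_ij**p) ** (1/p)

so that a = 0 recovers the functional matrix and a = 1 the phylogenetic
one.  Assemblage-level dispersion is the mean pairwise distance (MPD)
over species present; habitat filtering is quantified as a standardized
effect size (SES) of observed MPD against a tip-shuffling null that
permutes species labels on the distance matrix while keeping assemblage
sizes fixed.  Negative SES indicates functional clustering.

Because a uniform label shuffle maps an assemblage of k species onto a
uniformly random k-subset of the pool, null draws are generated per
distinct assemblage size (marginally identical to full relabeling, and
much cheaper); an exhaustive mode enumerates all k-subsets for small
pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["BlendedDistance", "blend_distances", "mean_pairwise_distance",
           "ses_mpd", "SESResult", "make_null_draws"]


def make_null_draws(pool_size: int, sizes, n_rand: int,
                    seed: int | None) -> dict[int, np.ndarray]:
    """Pre-draw tip-shuffling null subsets (k -> n_rand x k index array).

    Sharing one set of draws across a grid of blended distance matrices
    (the a-scan) removes permutation noise from comparisons between
    grid points.
    """
    rng = np.random.default_rng(seed)
    draws = {}
    for k in sorted(set(int(s) for s in sizes)):
        if not 2 <= k <= pool_size:
            raise ValueError(f"assemblage size {k} incompatible with pool {pool_size}")
        subsets = np.empty((n_rand, k), dtype=int)
        for r in range(n_rand):
            subsets[r] = rng.choice(pool_size, size=k, replace=False)
        draws[k] = subsets
    return draws


@dataclass(frozen=True)
class BlendedDistance:
    """FPDist matrix with its provenance (a, p, rescaling maxima)."""

    matrix: pd.DataFrame
    a: float
    p: float
    func_max: float
    phylo_max: float

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)


def blend_distances(func_matrix: pd.DataFrame, phylo_matrix: pd.DataFrame,
                    a: float, p: float = 2.0) -> BlendedDistance:
    """Blend rescaled functional and phylogenetic distances with weight ``a``."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    if p <= 0:
        raise ValueError("p must be positive")
    if list(func_matrix.index) != list(func_matrix.columns):
        raise ValueError("functional matrix must be square with matching labels")
    if set(func_matrix.index) != set(phylo_matrix.index):
        raise ValueError("species sets of the two matrices differ")
    phylo_matrix = phylo_matrix.loc[func_matrix.index, func_matrix.index]
    F = func_matrix.to_numpy(float)
    P = phylo_matrix.to_numpy(float)
    fmax, pmax = F.max(), P.max()
    if fmax <= 0 or pmax <= 0:
        raise ValueError("all-zero source matrix cannot be rescaled")
    Fn, Pn = F / fmax, P / pmax
    M = (a * Pn ** p + (1.0 - a) * Fn ** p) ** (1.0 / p)
    np.fill_diagonal(M, 0.0)
    return BlendedDistance(
        matrix=pd.DataFrame(M, index=func_matrix.index, columns=func_matrix.columns),
        a=float(a), p=float(p), func_max=float(fmax), phylo_max=float(pmax))


def _as_array(distance) -> tuple[np.ndarray, list[str]]:
    if isinstance(distance, BlendedDistance):
        distance = distance.matrix
    return distance.to_numpy(float), list(distance.index)


def mean_pairwise_distance(assemblage_species, distance) -> float:
    """Mean distance over all unordered pairs of distinct species.

    Returns NaN (flagged missing) for assemblages with fewer than two
    species present in the matrix.
    """
    D, labels = _as_array(distance)
    pos = {s: i for i, s in enumerate(labels)}
    idx = [pos[s] for s in assemblage_species]
    if len(idx) < 2:
        return float("nan")
    sub = D[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def _mpd_of_subsets(D: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """MPD for each row of ``subsets`` (n_draws x k index matrix)."""
    k = subsets.shape[1]
    sub = D[subsets[:, :, None], subsets[:, None, :]]
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


@dataclass(frozen=True)
class SESResult:
    """Observed MPD with tip-shuffling null moments per assemblage."""

    table: pd.DataFrame  # index (log_id, exposure_year); columns below
    n_randomizations: int

    COLUMNS = ("mpd_obs", "null_mean", "null_sd", "ses", "n_species")

    @property
    def ses(self) -> pd.Series:
        return self.table["ses"]

    def valid(self) -> pd.DataFrame:
        """Rows with a defined SES (>= 2 species, non-degenerate null)."""
        return self.table[self.table["ses"].notna()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def ses_mpd(assemblages: pd.DataFrame, distance, n_rand: int = 999,
            seed: int | None = None, method: str = "sample",
            null_draws: dict[int, np.ndarray] | None = None) -> SESResult:
    """Standardized effect size of MPD under the tip-shuffling null.

    Parameters
    ----------
    assemblages : DataFrame
        Site x species count (or presence) matrix; index identifies the
        assemblage (conventionally a ``(log_id, exposure_year)``
        MultiIndex), columns are species present in ``distance``.
    distance : DataFrame or BlendedDistance
        Pairwise distances over the species pool (the null shuffles
        labels over this full pool).
    n_rand : int
        Number of null randomizations (ignored for ``method='exhaustive'``).
    seed : int
        Seed for the null draws; required for reproducibility.
    method : {'sample', 'exhaustive'}
        'exhaustive' enumerates every k-subset of the pool (small pools
        only) and weights them equally, which equals the average over
        all label permutations.

    MPD here is presence-based; assemblages with fewer than two species,
    or whose null has zero spread (e.g. the assemblage is the whole
    pool), get SES = NaN with the reason visible in the columns.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    D, labels = _as_array(distance)
    pos = {s: i for i, s in enumerate(labels)}
    unknown = set(assemblages.columns) - set(labels)
    if unknown:
        raise KeyError(f"species absent from distance matrix: {sorted(unknown)[:5]}")
    pool = len(labels)
    rng = np.random.default_rng(seed)

    members = {}
    for site in assemblages.index:
        present = assemblages.columns[assemblages.loc[site].to_numpy() > 0]
        members[site] = np.array([pos[s] for s in present], dtype=int)

    sizes = sorted({len(m) for m in members.values() if len(m) >= 2})
    null_moments: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if null_draws is not None and k in null_draws:
            subsets = null_draws[k]
        elif method == "exhaustive":
            if comb(pool, k) > 100_000:
                raise ValueError("exhaustive enumeration infeasible for this pool")
            subsets = np.array(list(combinations(range(pool), k)), dtype=int)
        elif method == "sample":
            subsets = np.empty((n_rand, k), dtype=int)
            for r in range(n_rand):
                subsets[r] = rng.choice(pool, size=k, replace=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        vals = _mpd_of_subsets(D, subsets)
        # exhaustive mode is the full permutation population -> ddof=0
        ddof = 0 if method == "exhaustive" else 1
        null_moments[k] = (float(vals.mean()), float(vals.std(ddof=ddof)))

    rows = []
    for site, idx in members.items():
        k = len(idx)
        obs = mean_pairwise_distance([labels[i] for i in idx], distance)
        if k < 2:
            rows.append((obs, np.nan, np.nan, np.nan, k))
            continue
        mu, sd = null_moments[k]
        degenerate = sd <= 1e-12 * max(1.0, abs(mu))
        ses = np.nan if degenerate else (obs - mu) / sd
        rows.append((obs, mu, sd, ses, k))
    table = pd.DataFrame(rows, index=assemblages.index, columns=list(SESResult.COLUMNS))
    return SESResult(table=table, n_randomizations=n_rand)
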