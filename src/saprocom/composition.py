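"""Compositional succession: ordination, PERMANOVA, year segmentation.

Assemblage turnover is quantified with Bray-Curtis dissimilarity,
ordinated by non-metric multidimensional scaling (best of several
random starts, then rotated to principal axes so axis 1 carries the
greatest score variance), partitioned with a sequential (adonis2-style)
PERMANOVA for tree species then exposure year, and segmented over years
with a conditional-inference tree on the first ordination axis: each
node performs a permutation-moment test of independence between score
and year, splits only while the adjusted p-value stays below alpha,
and (in the default ordered mode) chooses the best year cutpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "nmds", "OrdinationResult", "permanova",
           "PermanovaResult", "inference_tree", "SplitTree", "SplitNode"]


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1]."""
    X = matrix.to_numpy(float)
    if (X < 0).any():
        raise ValueError("negative counts")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero row")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class OrdinationResult:
    scores: pd.DataFrame     # site x k, principal-axis rotated
    stress: float            # Kruskal stress-1
    n_starts: int
    converged: bool

    def to_csv(self, path) -> None:
        self.scores.to_csv(path)


def nmds(dissimilarity: pd.DataFrame, k: int = 2, n_starts: int = 20,
         seed: int | None = None, max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS (SMACOF with isotonic regression), best of ``n_starts``.

    The winning configuration is centred and rotated to its principal
    axes, so axis-1 score variance >= axis-2 variance and downstream
    tests can use axis 1 as the main compositional gradient.  Stress is
    Kruskal's stress-1.
    """
    from sklearn.manifold import MDS

    D = dissimilarity.to_numpy(float)
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    kwargs = dict(n_components=k, n_init=n_starts, max_iter=max_iter, eps=1e-7,
                  random_state=int(np.random.default_rng(seed).integers(2**31 - 1)),
                  normalized_stress=True)
    try:
        mds = MDS(metric_mds=False, metric="precomputed", init="random",
                  **kwargs)
    except TypeError:  # older scikit-learn API
        mds = MDS(metric=False, dissimilarity="precomputed", **kwargs)
    Y = mds.fit_transform(D)
    stress = float(mds.stress_)
    converged = stress < 0.4  # degenerate fits approach stress-1 ~ 0.5
    Y = Y - Y.mean(axis=0)
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    Y = Y @ vt.T
    cols = [f"axis{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(Y, index=dissimilarity.index, columns=cols),
        stress=stress, n_starts=n_starts, converged=converged)


@dataclass(frozen=True)
class PermanovaResult:
    table: pd.DataFrame  # per term: df, ss, r2, pseudo_f, p_value (+ residual/total)
    n_permutations: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _hat(Xm: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Xm)
    return Q @ Q.T


def permanova(dissimilarity: pd.DataFrame, terms: dict[str, pd.Series],
              n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """Sequential distance-based multivariate ANOVA with free permutations.

    ``terms`` is an ordered mapping of term name to a factor over sites
    (e.g. tree species first, then exposure year); sums of squares are
    sequential in that order via the Gower-centred inner-product matrix
    G = -1/2 J D^2 J.  p-values count permuted pseudo-F statistics at
    least as large as the observed, with the +1 correction.
    """
    D = dissimilarity.to_numpy(float)
    n = D.shape[0]
    G = _gower_center(D)
    ss_total = float(np.trace(G))

    dummies, dfs = [], []
    for name, fac in terms.items():
        fac = pd.Series(fac)
        if fac.nunique() < 2:
            raise ValueError(f"term {name!r} is constant across sites")
        Z = pd.get_dummies(fac.astype(str), drop_first=True).to_numpy(float)
        dummies.append(Z)
        dfs.append(Z.shape[1])

    hats = []
    Xcur = np.ones((n, 1))
    hats.append(_hat(Xcur))
    for Z in dummies:
        Xcur = np.column_stack([Xcur, Z])
        hats.append(_hat(Xcur))
    H_full = hats[-1]
    df_res = n - int(round(np.trace(H_full)))

    def term_stats(Gm):
        ss_terms = [float(np.trace(hats[i + 1] @ Gm) - np.trace(hats[i] @ Gm))
                    for i in range(len(dummies))]
        ss_res = float(np.trace((np.eye(n) - H_full) @ Gm))
        fs = [(ss / df) / (ss_res / df_res) for ss, df in zip(ss_terms, dfs)]
        return ss_terms, ss_res, fs

    ss_terms, ss_res, f_obs = term_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dummies))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, f_perm = term_stats(G[np.ix_(perm, perm)])
        exceed += np.asarray(f_perm) >= np.asarray(f_obs)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for name, df, ss, f, pv in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": name, "df": df, "ss": ss, "r2": ss / ss_total,
                     "pseudo_f": f, "p_value": pv})
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "r2": ss_res / ss_total, "pseudo_f": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "r2": 1.0,
                 "pseudo_f": np.nan, "p_value": np.nan})
    return PermanovaResult(table=pd.DataFrame(rows).set_index("term"),
                           n_permutations=n_perm)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    J = np.eye(len(D)) - np.ones_like(D) / len(D)
    return J @ A @ J


# --------------------------------------------------------------------------
# conditional-inference tree on the first ordination axis

@dataclass
class SplitNode:
    """One node of the year-segmentation tree."""

    years: tuple[int, ...]
    n: int
    mean_score: float
    p_value: float | None = None
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"years": list(self.years), "n": self.n,
             "mean_score": self.mean_score}
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if not self.is_leaf:
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass(frozen=True)
class SplitTree:
    root: SplitNode
    alpha: float
    min_leaf: int

    def leaves(self) -> list[SplitNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def leaf_year_groups(self) -> list[tuple[int, ...]]:
        return [leaf.years for leaf in self.leaves()]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"alpha": self.alpha, "min_leaf": self.min_leaf,
                       "root": self.root.to_dict()}, fh, indent=2)

    def render(self) -> str:
        lines = []

        def walk(node, depth):
            pad = "  " * depth
            yrs = ",".join(map(str, node.years))
            if node.is_leaf:
                lines.append(f"{pad}leaf years={{{yrs}}} n={node.n} "
                             f"mean={node.mean_score:.3f}")
            else:
                lines.append(f"{pad}split years={{{yrs}}} p={node.p_value:.4g}")
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _independence_test(scores: np.ndarray, years: np.ndarray) -> float:
    """Permutation-moment quadratic test of score x year-factor independence.

    Linear statistic T_l = sum of scores in year level l; its exact
    permutation mean and covariance have closed forms, and the
    standardized quadratic form is referred to chi-square with
    df = rank(Cov).
    """
    levels, inv = np.unique(years, return_inverse=True)
    if len(levels) < 2:
        return 1.0
    n = len(scores)
    counts = np.bincount(inv).astype(float)
    T = np.bincount(inv, weights=scores)
    h_mean = scores.mean()
    h_var = scores.var(ddof=0)
    mu = counts * h_mean
    # Cov = n/(n-1) * Var(h) * (diag(counts) - counts counts' / n)
    C = (n / (n - 1.0)) * h_var * (np.diag(counts) - np.outer(counts, counts) / n)
    Cp = np.linalg.pinv(C, rcond=1e-10)
    stat = float((T - mu) @ Cp @ (T - mu))
    df = np.linalg.matrix_rank(C, tol=1e-10)
    if df == 0 or h_var == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def _split_statistic(scores: np.ndarray, left: np.ndarray) -> float:
    n = len(scores)
    nl = int(left.sum())
    h_var = scores.var(ddof=0)
    var = (n / (n - 1.0)) * h_var * nl * (1.0 - nl / n)
    if var <= 0:
        return -np.inf
    return abs(scores[left].sum() - nl * scores.mean()) / np.sqrt(var)


def _best_left_levels(scores: np.ndarray, years: np.ndarray, min_leaf: int,
                      ordered: bool):
    """Year levels forming the left child of the best binary partition.

    Ordered mode scans cutpoints (splits are contiguous year ranges);
    unordered mode enumerates every proper bipartition of the levels.
    Both maximize the standardized two-sample statistic subject to
    ``min_leaf`` observations per side.
    """
    uniq = np.sort(np.unique(years))
    n = len(scores)
    best, best_stat = None, -np.inf
    if ordered:
        candidates = [tuple(uniq[uniq <= cut]) for cut in uniq[:-1]]
    else:
        if len(uniq) > 15:
            raise ValueError("too many year levels for exhaustive bipartitions")
        candidates = []
        for mask in range(1, 1 << (len(uniq) - 1)):
            candidates.append(tuple(uniq[i] for i in range(len(uniq))
                                    if mask >> i & 1))
    for left_levels in candidates:
        left = np.isin(years, left_levels)
        nl = int(left.sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        stat = _split_statistic(scores, left)
        if stat > best_stat:
            best_stat, best = stat, left_levels
    return best


def inference_tree(scores, years, alpha: float = 0.05,
                   min_leaf: int = 7, ordered: bool = True) -> SplitTree:
    """Recursive year segmentation of the first ordination axis.

    At each node the independence of score and year (a factor) is
    tested with the permutation-moment quadratic statistic; if the
    p-value exceeds ``alpha`` the node becomes a leaf, otherwise the
    node splits at the year cutpoint with the largest standardized
    two-sample statistic, subject to ``min_leaf`` observations per
    side, and recursion continues.  Leaf year-groups partition the
    observed years into contiguous runs.
    """
    scores = np.asarray(scores, float)
    years = np.asarray(years, int)
    if len(scores) != len(years):
        raise ValueError("scores and years must align")
    if min_leaf > len(scores):
        raise ValueError("min_leaf larger than the number of observations")

    def grow(mask) -> SplitNode:
        s, yr = scores[mask], years[mask]
        node = SplitNode(years=tuple(int(v) for v in np.sort(np.unique(yr))),
                         n=len(s), mean_score=float(s.mean()))
        if len(np.unique(yr)) < 2 or len(s) < 2 * min_leaf:
            return node
        p = _independence_test(s, yr)
        node.p_value = p
        if p > alpha:
            return node
        left_levels = _best_left_levels(s, yr, min_leaf, ordered)
        if left_levels is None:
            return node
        in_left = np.isin(years, left_levels)
        left_mask = mask & in_left
        right_mask = mask & ~in_left
        node.left = grow(left_mask)
        node.right = grow(right_mask)
        return node

    root = grow(np.ones(len(scores), dtype=bool))
    return SplitTree(root=root, alpha=alpha, min_leaf=min_leaf)
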