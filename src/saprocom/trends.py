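"""Penalized additive trend models over years since deadwood exposure.

Each response (abundance, species number, species richness, SES-MFPD)
is modelled with the same structure: a tree-species fixed effect, one
penalized smooth of exposure year per tree species (cubic P-splines
times a group indicator, sum-to-zero constrained), and an isotropic
spatial smooth of the log coordinates (low-rank thin-plate-type radial
basis with unpenalized linear terms).  Counts use a negative-binomial
family with log link and dispersion theta estimated by alternating
profile likelihood; SES-MFPD uses a Gaussian identity family.  The
species-richness model adds log(abundance) as a fixed covariate, so a
flat year smooth there means species number is explained by abundance
alone (the more-individuals hypothesis).

Smoothing parameters are chosen by minimizing GCV of the working
penalized fit; effective degrees of freedom, Wald-type smooth tests and
an adjusted R-squared on the response scale are reported, and
predictions carry standard errors on the link scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.interpolate import BSpline

from .data_model import TREE_SPECIES, CommunityTable, SurveyDesign

__all__ = ["AdditiveModelFit", "fit_additive_model", "fit_richness_model",
           "build_trend_frame", "morans_i_residuals", "SpatialAutocorrResult",
           "significance_stars"]


# --------------------------------------------------------------------------
# basis construction

def _bspline_basis(x: np.ndarray, k: int, xmin: float, xmax: float,
                   degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with k functions on [xmin, xmax] and its knots."""
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis size {k} too small for degree {degree}")
    span = max(xmax - xmin, 1e-9)
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    t = np.r_[[xmin - 1e-9] * (degree + 1), interior, [xmax + 1e-9] * (degree + 1)]
    B = BSpline.design_matrix(np.clip(x, xmin, xmax), t, degree,
                              extrapolate=False).toarray()
    return B, t


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _nullspace_transform(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of the row vector(s) c."""
    c = np.atleast_2d(c)
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[c.shape[0]:].T


def _tps_eta(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


@dataclass
class _Term:
    name: str
    cols: slice
    penalty: np.ndarray | None   # in the term's own coordinates, None = unpenalized
    builder: object              # callable(new_data) -> columns


@dataclass
class _Design:
    X: np.ndarray
    terms: list[_Term]
    colnames: list[str]

    def penalties(self):
        """Full-size penalty matrix per penalized term."""
        p = self.X.shape[1]
        out = []
        for t in self.terms:
            if t.penalty is None:
                continue
            S = np.zeros((p, p))
            S[t.cols, t.cols] = t.penalty
            out.append((t.name, S))
        return out

    def build(self, new_data: pd.DataFrame) -> np.ndarray:
        return np.column_stack([t.builder(new_data) for t in self.terms])


def _build_design(data: pd.DataFrame, k_year: int, n_knots_spatial: int,
                  extra_linear: tuple[str, ...]) -> _Design:
    levels = [g for g in TREE_SPECIES if g in set(data["tree_species"])]
    if not levels:
        raise ValueError("no known tree species levels in data")
    year = data["exposure_year"].to_numpy(float)
    terms: list[_Term] = []
    blocks: list[np.ndarray] = []
    names: list[str] = []
    col = 0

    def add(name, cols_arr, colnames, penalty, builder):
        nonlocal col
        terms.append(_Term(name, slice(col, col + cols_arr.shape[1]), penalty, builder))
        blocks.append(cols_arr)
        names.extend(colnames)
        col += cols_arr.shape[1]

    add("intercept", np.ones((len(data), 1)), ["intercept"], None,
        lambda nd: np.ones((len(nd), 1)))

    # tree-species fixed effect (treatment coding, first level reference)
    for g in levels[1:]:
        ind = (data["tree_species"] == g).to_numpy(float)[:, None]
        add(f"tree[{g}]", ind, [f"tree[{g}]"], None,
            (lambda gg: lambda nd: (nd["tree_species"] == gg)
             .to_numpy(float)[:, None])(g))

    for name in extra_linear:
        v = data[name].to_numpy(float)[:, None]
        add(name, v, [name], None,
            (lambda nm: lambda nd: nd[nm].to_numpy(float)[:, None])(name))

    # per-tree-species smooth of exposure year (sum-to-zero constrained)
    for g in levels:
        mask = (data["tree_species"] == g).to_numpy(bool)
        xg = year[mask]
        kg = int(min(k_year, max(4, len(np.unique(xg)))))
        B, knots = _bspline_basis(year, kg, xg.min(), xg.max())
        c = B[mask].sum(axis=0)
        Z = _nullspace_transform(c)
        cols_arr = (B @ Z) * mask[:, None]
        S = Z.T @ _difference_penalty(kg) @ Z

        def builder(nd, g=g, knots=knots, Z=Z, lo=xg.min(), hi=xg.max()):
            x = np.clip(nd["exposure_year"].to_numpy(float), lo, hi)
            Bn = BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
            m = (nd["tree_species"] == g).to_numpy(float)
            return (Bn @ Z) * m[:, None]

        add(f"s(year):{g}", cols_arr,
            [f"s(year):{g}.{j}" for j in range(cols_arr.shape[1])], S, builder)

    # isotropic spatial smooth of (E, N)
    if n_knots_spatial > 0:
        coords = data[["E", "N"]].to_numpy(float)
        scale = coords.std(axis=0)
        scale[scale == 0] = 1.0
        zc = coords / scale
        uniq = np.unique(zc, axis=0)
        nk = int(min(n_knots_spatial, len(uniq)))
        if nk >= 3:
            from sklearn.cluster import KMeans

            if len(uniq) > nk:
                km = KMeans(n_clusters=nk, n_init=4, random_state=0).fit(uniq)
                knots_xy = km.cluster_centers_
            else:
                knots_xy = uniq
            lin = zc - zc.mean(axis=0)
            add("spatial_linear", lin, ["E.lin", "N.lin"], None,
                (lambda mu=zc.mean(axis=0), sc=scale:
                 lambda nd: nd[["E", "N"]].to_numpy(float) / sc - mu)())
            R = np.linalg.norm(zc[:, None, :] - knots_xy[None, :, :], axis=2)
            Phi = _tps_eta(R)
            cmean = Phi.mean(axis=0)
            Phi = Phi - cmean
            Om = _tps_eta(np.linalg.norm(
                knots_xy[:, None, :] - knots_xy[None, :, :], axis=2))
            w, V = np.linalg.eigh((Om + Om.T) / 2.0)
            S = (V * np.clip(w, 0.0, None)) @ V.T  # PSD part of the bending energy

            def sp_builder(nd, knots_xy=knots_xy, cmean=cmean, sc=scale):
                z = nd[["E", "N"]].to_numpy(float) / sc
                R = np.linalg.norm(z[:, None, :] - knots_xy[None, :, :], axis=2)
                return _tps_eta(R) - cmean

            add("s(E,N)", Phi, [f"s(E,N).{j}" for j in range(Phi.shape[1])],
                S, sp_builder)

    return _Design(X=np.column_stack(blocks), terms=terms, colnames=names)


# --------------------------------------------------------------------------
# families

class _Gaussian:
    name = "gaussian"

    @staticmethod
    def initialize(y):
        return y.astype(float)

    @staticmethod
    def link(mu):
        return mu

    @staticmethod
    def inverse(eta):
        return eta

    @staticmethod
    def weights(mu, theta):
        return np.ones_like(mu)

    @staticmethod
    def working(y, mu, eta):
        return eta + (y - mu)

    @staticmethod
    def deviance(y, mu, theta):
        return float(np.sum((y - mu) ** 2))


class _NegBin:
    name = "negative_binomial"

    @staticmethod
    def initialize(y):
        return y + 0.5

    @staticmethod
    def link(mu):
        return np.log(mu)

    @staticmethod
    def inverse(eta):
        return np.exp(np.clip(eta, -30, 30))

    @staticmethod
    def weights(mu, theta):
        return mu / (1.0 + mu / theta)

    @staticmethod
    def working(y, mu, eta):
        return eta + (y - mu) / mu

    @staticmethod
    def deviance(y, mu, theta):
        yp = np.where(y > 0, y, 1.0)
        term = np.where(y > 0, y * np.log(yp / mu), 0.0)
        term2 = (y + theta) * np.log((y + theta) / (mu + theta))
        return float(2.0 * np.sum(term - term2))

    @staticmethod
    def loglik(y, mu, theta):
        return float(np.sum(
            special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))))


_FAMILIES = {"gaussian": _Gaussian, "negative_binomial": _NegBin, "nb": _NegBin}


# --------------------------------------------------------------------------
# penalized IRLS

def _pirls(X, y, S_list, lam, family, theta, max_iter=50, tol=1e-8):
    n, p = X.shape
    S = sum(l * S for l, S in zip(lam, S_list)) if S_list else np.zeros((p, p))
    # scale-aware ridge keeps near-collinear bases (e.g. radial vs linear
    # spatial columns) numerically solvable without visible shrinkage
    S = S + 1e-8 * float(np.mean(np.sum(X * X, axis=0))) * np.eye(p)
    mu = family.initialize(y)
    eta = family.link(mu)
    dev = np.inf
    for _ in range(max_iter):
        w = family.weights(mu, theta)
        z = family.working(y, mu, eta)
        XtW = X.T * w
        A = XtW @ X + S
        beta = np.linalg.solve(A, XtW @ z)
        eta = X @ beta
        mu = family.inverse(eta)
        new_dev = family.deviance(y, mu, theta)
        if abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    w = family.weights(mu, theta)
    XtW = X.T * w
    XtWX = XtW @ X
    Ainv = np.linalg.inv(XtWX + S)
    F = Ainv @ XtWX
    edf = float(np.trace(F))
    return {"beta": beta, "mu": mu, "eta": eta, "dev": dev, "edf": edf,
            "F": F, "Ainv": Ainv, "w": w}


def _estimate_theta(y, mu, lo=1e-2, hi=1e4):
    def nll(log_theta):
        return -_NegBin.loglik(y, mu, np.exp(log_theta))

    res = optimize.minimize_scalar(nll, bounds=(np.log(lo), np.log(hi)),
                                   method="bounded")
    return float(np.exp(res.x))


# --------------------------------------------------------------------------
# public fit surface

@dataclass
class AdditiveModelFit:
    """Fitted penalized additive model.

    Holds coefficients, per-smooth effective degrees of freedom and
    Wald p-values, the adjusted R-squared on the response scale, the NB
    dispersion theta where applicable, and everything needed to predict
    with link-scale standard errors.
    """

    response: str
    family: str
    coef: np.ndarray
    cov: np.ndarray
    design: _Design
    fitted: np.ndarray
    y: np.ndarray
    edf_by_term: dict[str, float]
    edf_total: float
    adj_r2: float
    smooth_pvalues: dict[str, float]
    theta: float | None
    deviance: float
    gcv: float
    lam: dict[str, float]
    scale: float

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    def predict(self, new_data: pd.DataFrame, ci: float = 0.95) -> pd.DataFrame:
        """Mean prediction with a CI computed on the link scale.

        Columns absent from ``new_data`` that the model needs (spatial
        coordinates, extra covariates) must be supplied by the caller;
        `prediction_grid` fills them with training means.
        """
        Xn = self.design.build(new_data)
        eta = Xn @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xn, self.cov, Xn), 0.0))
        zq = stats.norm.ppf(0.5 + ci / 2.0)
        fam = _FAMILIES[self.family]
        return pd.DataFrame({
            "fit": fam.inverse(eta),
            "lower": fam.inverse(eta - zq * se),
            "upper": fam.inverse(eta + zq * se),
            "se_link": se,
        }, index=new_data.index)

    def prediction_grid(self, data: pd.DataFrame, n_points: int = 50) -> pd.DataFrame:
        """Year-grid predictions per tree species at average covariates."""
        frames = []
        for g in sorted(set(data["tree_species"])):
            sub = data[data["tree_species"] == g]
            years = np.linspace(sub["exposure_year"].min(),
                                sub["exposure_year"].max(), n_points)
            nd = pd.DataFrame({"exposure_year": years, "tree_species": g})
            for c in data.columns:
                if c not in nd.columns and pd.api.types.is_numeric_dtype(data[c]):
                    nd[c] = data[c].mean()
            pred = self.predict(nd)
            pred.insert(0, "tree_species", g)
            pred.insert(1, "exposure_year", years)
            frames.append(pred)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "adj_r2": self.adj_r2,
            "edf": self.edf_by_term,
            "smooth_pvalues": self.smooth_pvalues,
            "stars": {k: significance_stars(v)
                      for k, v in self.smooth_pvalues.items()},
            "theta": self.theta,
            "deviance": self.deviance,
            "lambda": self.lam,
        }


def significance_stars(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, . p<0.1."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def fit_additive_model(data: pd.DataFrame, response: str,
                       family: str = "negative_binomial",
                       extra_linear: tuple[str, ...] = (),
                       k_year: int = 10, n_knots_spatial: int = 30,
                       optimize_lambda: bool = True, lam_init=None,
                       criterion: str = "reml",
                       maxiter: int = 120) -> AdditiveModelFit:
    """Fit the standard trend-model structure to one response column.

    ``data`` needs columns ``response``, ``exposure_year``,
    ``tree_species``, ``E``, ``N`` plus any ``extra_linear`` covariates.
    Smoothing parameters (one per smooth) minimize a Laplace-approximate
    REML of the working penalized fit (default) or GCV
    (``criterion='gcv'``); set ``optimize_lambda=False`` to keep them
    at ``lam_init`` (or 1).
    """
    fam = _FAMILIES[family]
    y = data[response].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in response {response!r}; drop flagged rows first")
    if fam is _NegBin:
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negative-binomial family requires non-negative integers")
    design = _build_design(data, k_year=k_year, n_knots_spatial=n_knots_spatial,
                           extra_linear=extra_linear)
    X = design.X
    n = len(y)
    pen = design.penalties()
    S_list = [S for _, S in pen]
    pen_names = [nm for nm, _ in pen]

    theta = None
    if fam is _NegBin:
        # moment start for the dispersion, refined by profile likelihood below
        vr = max(y.var() - y.mean(), 1e-6)
        theta = float(np.clip(y.mean() ** 2 / vr, 0.05, 1e4))

    pen_ranks = [np.linalg.matrix_rank(S, tol=1e-9) for S in S_list]
    null_dim = X.shape[1] - sum(pen_ranks)

    def objective(log_lam, theta_):
        lam_ = np.exp(np.clip(log_lam, -18.0, 18.0))
        fit = _pirls(X, y, S_list, lam_, fam, theta_)
        if criterion == "gcv":
            return n * fit["dev"] / max(n - fit["edf"], 1e-3) ** 2
        # Laplace/working-model REML (negative restricted log-likelihood up
        # to constants): (n-M) log(D_pen) + log|X'WX + S| - sum r_b log(l_b)
        S = sum(l * Sb for l, Sb in zip(lam_, S_list))
        beta = fit["beta"]
        d_pen = fit["dev"] + float(beta @ S @ beta)
        XtWX = (X.T * fit["w"]) @ X
        sign, logdet = np.linalg.slogdet(
            XtWX + S + 1e-10 * np.eye(X.shape[1]))
        log_s_plus = float(np.dot(pen_ranks, np.clip(log_lam, -18.0, 18.0)))
        return ((n - null_dim) * np.log(max(d_pen, 1e-300))
                + logdet - log_s_plus)

    if lam_init is not None:
        log_lam = np.log(np.asarray(
            [lam_init[nm] for nm in pen_names] if isinstance(lam_init, dict)
            else lam_init, dtype=float))
    else:
        log_lam = np.zeros(len(S_list))
    cycles = 2 if fam is _NegBin else 1
    for _ in range(cycles):
        if optimize_lambda and S_list:
            # multi-start: Nelder-Mead on GCV can stall in a local optimum
            # for rough responses, so try light and heavy smoothing starts
            best = None
            starts = [log_lam, np.full_like(log_lam, 4.0)]
            for x0 in starts:
                res = optimize.minimize(objective, x0, args=(theta,),
                                        method="Nelder-Mead",
                                        options={"maxiter": maxiter,
                                                 "xatol": 0.05, "fatol": 1e-8})
                if best is None or res.fun < best.fun:
                    best = res
            log_lam = best.x
        if fam is _NegBin:
            fit = _pirls(X, y, S_list, np.exp(np.clip(log_lam, -18.0, 18.0)),
                         fam, theta)
            theta = _estimate_theta(y, fit["mu"])
    lam = np.exp(np.clip(log_lam, -18.0, 18.0))
    fit = _pirls(X, y, S_list, lam, fam, theta)
    gcv = n * fit["dev"] / max(n - fit["edf"], 1e-3) ** 2

    # per-term edf and Wald tests
    edf_by_term, pvals = {}, {}
    Fdiag = np.diag(fit["F"])
    scale = (fit["dev"] / max(n - fit["edf"], 1.0) if fam is _Gaussian else 1.0)
    cov = fit["Ainv"] * scale
    for t in design.terms:
        edf_t = float(Fdiag[t.cols].sum())
        edf_by_term[t.name] = edf_t
        if t.penalty is None or not t.name.startswith("s("):
            continue
        b = fit["beta"][t.cols]
        Vb = cov[t.cols, t.cols]
        # Wald test truncated to the effective rank: only the edf-many
        # best-determined directions enter the statistic, matching the
        # chi-square reference (full-rank inversion is anti-conservative)
        df = int(max(1, round(edf_t)))
        w, U = np.linalg.eigh((Vb + Vb.T) / 2.0)
        order = np.argsort(w)[::-1]
        w, U = w[order][:df], U[:, order][:, :df]
        proj = U.T @ b
        Tstat = float(np.sum(proj ** 2 / np.maximum(w, 1e-300)))
        pvals[t.name] = float(stats.chi2.sf(Tstat, df))

    mu = fit["mu"]
    ss_res = float(np.sum((y - mu) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        adj_r2 = 0.0
    else:
        adj_r2 = 1.0 - (ss_res / max(n - fit["edf"], 1.0)) / (ss_tot / (n - 1))

    return AdditiveModelFit(
        response=response, family=fam.name, coef=fit["beta"], cov=cov,
        design=design, fitted=mu, y=y, edf_by_term=edf_by_term,
        edf_total=fit["edf"], adj_r2=float(adj_r2), smooth_pvalues=pvals,
        theta=theta, deviance=fit["dev"], gcv=float(gcv),
        lam=dict(zip(pen_names, lam)), scale=float(scale))


def fit_richness_model(data: pd.DataFrame, **kwargs) -> AdditiveModelFit:
    """Species number controlled for abundance (more-individuals test).

    Adds natural-log abundance as a fixed covariate to the standard
    NB structure with species number as the response.  Zero-abundance
    rows are excluded (log undefined).
    """
    df = data.copy()
    if (df["abundance"] <= 0).any():
        df = df[df["abundance"] > 0]
    df["log_abundance"] = np.log(df["abundance"].to_numpy(float))
    return fit_additive_model(df, response="n_species",
                              family="negative_binomial",
                              extra_linear=("log_abundance",), **kwargs)


def build_trend_frame(table: CommunityTable, design: SurveyDesign,
                      ses=None) -> pd.DataFrame:
    """One row per (log, exposure year): abundance, species number, coords.

    If an SES result table is given, its ``ses`` column is joined as
    the functional-diversity response.
    """
    rec = table.records
    agg = rec.groupby(["log_id", "exposure_year"]).agg(
        abundance=("count", "sum"), n_species=("species_id", "nunique"))
    agg = agg.reset_index()
    meta = design.logs.set_index("log_id")
    agg["tree_species"] = agg["log_id"].map(meta["tree_species"])
    agg["E"] = agg["log_id"].map(meta["E"])
    agg["N"] = agg["log_id"].map(meta["N"])
    if ses is not None:
        tab = ses.table if hasattr(ses, "table") else ses
        agg = agg.join(tab["ses"], on=["log_id", "exposure_year"])
    return agg


# --------------------------------------------------------------------------
# residual spatial autocorrelation

@dataclass(frozen=True)
class SpatialAutocorrResult:
    """Moran's I on per-location mean residuals with inverse-distance weights."""

    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n_locations: int


def morans_i_residuals(residuals: np.ndarray, coordinates: np.ndarray
                       ) -> SpatialAutocorrResult:
    """Moran's I of model residuals with row-standardized 1/d weights.

    Residuals at repeated coordinates are first averaged per unique
    location; the analytic mean and variance under the normality
    assumption give a two-sided z-test.
    """
    residuals = np.asarray(residuals, float)
    coordinates = np.asarray(coordinates, float)
    if len(residuals) != len(coordinates):
        raise ValueError("one residual per coordinate row required")
    uniq, inv = np.unique(coordinates, axis=0, return_inverse=True)
    n = len(uniq)
    if n < 3:
        raise ValueError("need at least 3 unique locations")
    zres = np.zeros(n)
    for i in range(n):
        zres[i] = residuals[inv == i].mean()
    d = np.linalg.norm(uniq[:, None, :] - uniq[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    W = W / W.sum(axis=1, keepdims=True)
    z = zres - zres.mean()
    S0 = W.sum()
    I = (n / S0) * (z @ W @ z) / (z @ z)
    E = -1.0 / (n - 1)
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    var = ((n * n * S1 - n * S2 + 3.0 * S0 * S0)
           / ((n * n - 1.0) * S0 * S0)) - E * E
    zscore = (I - E) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return SpatialAutocorrResult(I=float(I), expected=float(E),
                                 variance=float(var), z=float(zscore),
                                 p_value=float(p), n_locations=n)
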