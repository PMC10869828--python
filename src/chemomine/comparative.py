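"""Phylogenetic comparative statistics.

Phylogenetic generalized least squares (pGLS) with Pagel's lambda, pairwise
gene-family-count correlation matrices, and trophic-level diet coding.

The phylogenetic covariance V has entries equal to the shared root-to-MRCA
path length of each species pair (Brownian motion expectation); Pagel's
transform multiplies the off-diagonal entries by lambda in [0, 1], which is
estimated by maximizing the restricted likelihood (REML, as in caper) with
Brent's method, or fixed. Coefficients come from GLS whitening; R-squared is
computed in whitened space against the whitened intercept-only model, and
the reported p-value is the overall F-test of the regression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lossstats import Phylo

__all__ = [
    "PGLSFit",
    "phylo_covariance",
    "pgls_fit",
    "family_count_correlations",
    "diet_from_trophic_level",
]

_LAMBDA_LO = 1e-6


@dataclass
class PGLSFit:
    """One phylogenetic regression: lambda, coefficients, fit statistics."""

    lambda_: float
    coefficients: pd.DataFrame  # index = term, columns = estimate, se, t, p
    r_squared: float
    f_stat: float
    f_pvalue: float
    n: int
    loglik: float
    lambda_mode: str
    terms: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.coefficients["estimate"]


def phylo_covariance(tree: Phylo, taxa: list[str]) -> np.ndarray:
    """Brownian covariance: V[i, j] = shared path length from root to MRCA."""
    idx = [tree.index_of(t) for t in taxa]
    depths = tree.depths()
    n = len(idx)
    V = np.zeros((n, n))
    pos = {node: k for k, node in enumerate(idx)}
    for i in range(n):
        V[i, i] = depths[idx[i]]
    # for each internal node, tip pairs split across different children share
    # exactly that node's depth
    for node in range(len(tree)):
        if tree.is_tip[node]:
            continue
        kids = tree.children[node]
        tipsets = []
        for c in kids:
            below = [d for d in ([c] + list(tree.descendants(c))) if tree.is_tip[d]]
            tipsets.append([pos[t] for t in below if t in pos])
        for a, b in itertools.combinations(range(len(tipsets)), 2):
            for i in tipsets[a]:
                for j in tipsets[b]:
                    V[i, j] = V[j, i] = depths[node]
    return V


def _pagel(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = V * lam
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _chol(Vl: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(Vl)
    except np.linalg.LinAlgError:
        # near-zero terminal branches make V numerically semi-definite
        jitter = 1e-10 * float(np.mean(np.diag(Vl)))
        return np.linalg.cholesky(Vl + jitter * np.eye(len(Vl)))


def _gls(y: np.ndarray, X: np.ndarray, Vl: np.ndarray):
    L = _chol(Vl)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet_V, Xw, yw


def _reml_loglik(y, X, V, lam) -> float:
    n, p = X.shape
    beta, rss, logdet_V, Xw, _ = _gls(y, X, _pagel(V, lam))
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / (n - p)
    sign, logdet_XtX = np.linalg.slogdet(Xw.T @ Xw)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1) + logdet_V + logdet_XtX
    )


def _ml_loglik(y, X, V, lam) -> float:
    n, p = X.shape
    beta, rss, logdet_V, _, _ = _gls(y, X, _pagel(V, lam))
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / n
    return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1) + logdet_V)


def _design_matrix(
    table: pd.DataFrame, predictors: list[str]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    for pred in predictors:
        col = table[pred]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(pred)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # treatment coding, lexicographic baseline
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{pred}[{lev}]")
    return np.column_stack(cols), names


def pgls_fit(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | str,
    tree: Phylo,
    lambda_mode: str | float = "reml",
) -> PGLSFit:
    """Fit a phylogenetic regression of ``response`` on ``predictors``.

    ``lambda_mode`` is "reml" (default, caper-style), "ml", or a fixed
    number in [0, 1]. The table index (or a ``species_id`` column) names the
    species; tree and table are pruned to their common species.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    if "species_id" in table.columns:
        table = table.set_index("species_id")
    tips = {tree.labels[i] for i in tree.tip_indices}
    common = [s for s in table.index if s in tips]
    if len(common) < 3:
        raise ValueError("need at least 3 species shared by tree and table")
    sub = table.loc[common, [response] + predictors].dropna()
    common = list(sub.index)
    if len(common) < 3:
        raise ValueError("need at least 3 species with complete data")
    y = sub[response].to_numpy(dtype=float)
    X, names = _design_matrix(sub, predictors)
    n, p = X.shape
    if n < p + 1:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    V = phylo_covariance(tree, common)
    diag = np.diag(V)
    if not np.allclose(diag, diag[0], rtol=1e-6):
        warnings.warn("tree is not ultrametric; proceeding with raw depths")

    if isinstance(lambda_mode, (int, float)):
        lam = float(lambda_mode)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("fixed lambda must be in [0, 1]")
        mode = "fixed"
        loglik = _reml_loglik(y, X, V, max(lam, 0.0))
    else:
        mode = str(lambda_mode).lower()
        objective = _reml_loglik if mode == "reml" else _ml_loglik
        res = optimize.minimize_scalar(
            lambda l: -objective(y, X, V, l),
            bounds=(_LAMBDA_LO, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(res.x)
        # guard the optimizer against flat boundaries
        for cand in (_LAMBDA_LO, 1.0):
            if objective(y, X, V, cand) > objective(y, X, V, lam) + 1e-9:
                lam = cand
        loglik = objective(y, X, V, lam)

    Vl = _pagel(V, lam if lam > 0 else 0.0)
    beta, rss, _, Xw, yw = _gls(y, X, Vl)
    sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)

    # whitened intercept-only model for TSS
    ones = np.ones((n, 1))
    _, tss, _, _, _ = _gls(y, ones, Vl)
    if tss <= 0:
        r2, f, f_p = 0.0, 0.0, 1.0
    else:
        r2 = max(0.0, 1.0 - rss / tss)
        df1 = p - 1
        df2 = n - p
        if df1 == 0:
            f, f_p = 0.0, 1.0
        else:
            f = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
            f_p = float(stats.f.sf(f, df1, df2))
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "p": pvals}, index=names
    )
    return PGLSFit(
        lambda_=lam,
        coefficients=coef,
        r_squared=float(r2),
        f_stat=float(f),
        f_pvalue=float(f_p),
        n=n,
        loglik=float(loglik),
        lambda_mode=mode,
        terms=names,
    )


OLFACTORY_FAMILIES = ("OR", "TAAR", "V1R", "V2R")
TASTE_FAMILIES = ("T1R", "T2R")


def family_count_correlations(
    repertoires: pd.DataFrame,
    tree: Phylo,
    lambda_mode: str | float = "reml",
    alpha: float = 0.05,
    include_aggregates: bool = True,
) -> pd.DataFrame:
    """Pairwise pGLS correlations between family counts across species.

    ``repertoires`` is species x family (complete-gene counts). Each ordered
    family pair is fit as count_y ~ count_x; R-squared is symmetric and
    reported once per unordered pair, with a significance flag at ``alpha``.
    The olfactory (OR+TAAR+V1R+V2R) vs taste (T1R+T2R) aggregate pair is
    appended when all six families are present. Pairs with fewer than three
    shared species are skipped with a warning.
    """
    df = repertoires.copy()
    if "species_id" in df.columns:
        df = df.set_index("species_id")
    families = list(df.columns)
    if include_aggregates and all(
        f in families for f in OLFACTORY_FAMILIES + TASTE_FAMILIES
    ):
        df["OLR"] = df[list(OLFACTORY_FAMILIES)].sum(axis=1)
        df["TR"] = df[list(TASTE_FAMILIES)].sum(axis=1)
        pairs = list(itertools.combinations(families, 2)) + [("OLR", "TR")]
    else:
        pairs = list(itertools.combinations(families, 2))
    rows = []
    for fx, fy in pairs:
        sub = df[[fx, fy]].dropna()
        if len(sub) < 3:
            warnings.warn(f"pair {fx}/{fy}: fewer than 3 shared species; skipped")
            continue
        try:
            fit = pgls_fit(sub, fy, [fx], tree, lambda_mode)
        except ValueError as exc:
            warnings.warn(f"pair {fx}/{fy}: {exc}; skipped")
            continue
        rows.append(
            dict(
                family_x=fx,
                family_y=fy,
                n=fit.n,
                lambda_=fit.lambda_,
                r_squared=fit.r_squared,
                p_value=fit.f_pvalue,
                significant=fit.f_pvalue < alpha,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_x", "family_y", "n", "lambda_", "r_squared",
            "p_value", "significant",
        ],
    )


def diet_from_trophic_level(t: float) -> str:
    """Trophic-level diet bins: <=2.19 herbivore, 2.2-2.79 omnivore,
    >=2.8 carnivore (values rounded half-up to two decimals first)."""
    if not np.isfinite(t) or t <= 0:
        raise ValueError("trophic level must be a positive number")
    from decimal import ROUND_HALF_UP, Decimal

    t = float(Decimal(repr(float(t))).quantize(Decimal("0.01"), ROUND_HALF_UP))
    if t <= 2.19:
        return "herbivore"
    if t <= 2.79:
        return "omnivore"
    return "carnivore"
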