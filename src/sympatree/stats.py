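"""Distance-matrix inference and model selection.

Simple Mantel tests correlate the lower triangles of two distance matrices
and assess significance by simultaneous row/column permutation of one
matrix; partial Mantel tests correlate the residuals of both triangles after
regressing out one or more conditioning matrices, permuting the residual
matrix (Legendre's residual-permutation scheme).  One-way ANOVA compares
phylogenetic structure across habitat groups, with compact letter displays
from pairwise Welch tests under a Holm correction.  Gaussian identity-link
GLMs are ranked by the small-sample Akaike criterion AICc over all predictor
subsets ("dredge"), and concordance (OLS slope + r-squared) checks agreement
between paired outcome vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StatsError",
    "MantelResult",
    "AnovaResult",
    "GLMFit",
    "log10_transform",
    "normality_check",
    "mantel",
    "partial_mantel",
    "anova_oneway",
    "fit_glm",
    "aicc",
    "dredge",
    "concordance",
]


class StatsError(ValueError):
    pass


def log10_transform(x) -> np.ndarray:
    """Common logarithm; non-positive values are a hard error (no epsilon)."""
    x = np.asarray(x, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise StatsError(f"non-positive value at position {bad[0]} (x={x[bad[0]]})")
    return np.log10(x)


def normality_check(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 with nonzero variance."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("constant vector")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int
    conditioners: int = 0


def _check_square(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise StatsError(f"{name} is not square")
    if M.shape[0] < 4:
        raise StatsError(f"{name} must have dimension >= 4")
    if not np.allclose(M, M.T):
        raise StatsError(f"{name} is not symmetric")
    if not np.allclose(np.diag(M), 0):
        raise StatsError(f"{name} has a nonzero diagonal")
    return M


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        raise StatsError("zero variance in a triangle vector")
    return float((xc @ yc) / den)


def _batch_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    den = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc @ yc) / den


def _perm_pvalue(r_obs: float, r_perm: np.ndarray, n_perm: int) -> float:
    exceed = np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    return float((1 + exceed) / (1 + n_perm))


def mantel(X, Y, n_perm: int = 9999, seed: Optional[int] = None) -> MantelResult:
    """Simple Mantel test (two-sided) between two distance matrices.

    r is the Pearson correlation of the n(n-1)/2 lower-triangle vectors; the
    p-value is (1 + #{|r*| >= |r|}) / (1 + n_perm) under simultaneous
    row/column permutation of ``Y``.  Deterministic under ``seed``.
    """
    X = _check_square(X, "X")
    Y = _check_square(Y, "Y")
    if X.shape != Y.shape:
        raise StatsError("X and Y have different dimensions")
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = X[iu], Y[iu]
    r = _corr(x, y)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = Y[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _batch_corr(yp, x)
    return MantelResult(r=r, p=_perm_pvalue(r, r_perm, n_perm), n_perm=n_perm, n=n)


def _residualize(v: np.ndarray, Z: np.ndarray, what: str) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ beta
    if resid.std() <= 1e-10 * max(v.std(), 1.0):
        raise StatsError(f"conditioners are collinear with {what}")
    return resid


def partial_mantel(
    X, Y, conditioners: Sequence, n_perm: int = 9999, seed: Optional[int] = None
) -> MantelResult:
    """Partial Mantel test of X vs Y given one or more conditioning matrices.

    Both triangle vectors are residualized on the conditioners' triangles
    (with intercept); r is the correlation of the residuals.  The p-value
    permutes the residuals of X as a symmetric matrix (rows and columns
    together), following the residual-permutation scheme.  With a single
    conditioner Z the statistic equals the closed-form first-order partial
    correlation (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2)).
    """
    if not conditioners:
        raise StatsError("at least one conditioning matrix is required")
    X = _check_square(X, "X")
    Y = _check_square(Y, "Y")
    Zs = [_check_square(Z, f"conditioner {k}") for k, Z in enumerate(conditioners)]
    for M in (Y, *Zs):
        if M.shape != X.shape:
            raise StatsError("matrices are not conformable")
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    Zt = np.column_stack([Z[iu] for Z in Zs])
    rx = _residualize(X[iu], Zt, "X")
    ry = _residualize(Y[iu], Zt, "Y")
    r = _corr(rx, ry)

    Rx = np.zeros((n, n))
    Rx[iu] = rx
    Rx = Rx + Rx.T
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    rxp = Rx[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _batch_corr(rxp, ry)
    return MantelResult(
        r=r, p=_perm_pvalue(r, r_perm, n_perm), n_perm=n_perm, n=n,
        conditioners=len(Zs),
    )


# ---------------------------------------------------------------------------
# ANOVA with compact letter display
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    groups: list[str]
    f: float
    df: tuple[int, int]
    p: float
    letters: dict[str, str]
    excluded: list[str] = field(default_factory=list)
    alpha: float = 0.05


def _compact_letters(groups: list[str], means: dict[str, float],
                     distinct: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups in the same letter class are not significantly different; every
    significantly different pair shares no letter.
    """
    order = sorted(groups, key=lambda g: -means[g])
    columns: list[set[str]] = [set(order)]
    for g1, g2 in itertools.combinations(order, 2):
        if frozenset((g1, g2)) not in distinct:
            continue
        for col in [c for c in columns if g1 in c and g2 in c]:
            columns.remove(col)
            c1, c2 = col - {g2}, col - {g1}
            for c in (c1, c2):
                if not any(c <= other for other in columns):
                    columns.append(c)
    # absorb redundant columns, then order letters by highest-mean member
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in order}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def anova_oneway(values, labels, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA across groups plus grouping letters.

    F = MS_between / MS_within; the letters come from all pairwise Welch
    t-tests with a Holm correction at ``alpha``.  Groups with a single value
    are reported in ``excluded`` and get no letter.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise StatsError("values and labels differ in length")
    group_names = list(pd.unique(labels))
    data = {g: values[labels == g] for g in group_names}
    excluded = [g for g in group_names if len(data[g]) < 2]
    kept = [g for g in group_names if len(data[g]) >= 2]
    if len(kept) < 2:
        raise StatsError("need at least two groups with >= 2 values")

    arrays = [data[g] for g in kept]
    grand = np.concatenate(arrays)
    n, k = len(grand), len(arrays)
    ssb = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = (k - 1, n - k)
    if ssw == 0 and ssb == 0:
        f, p = 0.0, 1.0
    elif ssw == 0:
        f, p = float("inf"), 0.0
    else:
        f = (ssb / df[0]) / (ssw / df[1])
        p = float(sps.f.sf(f, *df))

    pairs = list(itertools.combinations(kept, 2))
    if pairs and ssw > 0:
        pvals = np.array(
            [sps.ttest_ind(data[a], data[b], equal_var=False).pvalue for a, b in pairs]
        )
        pvals = np.nan_to_num(pvals, nan=1.0)
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        m = len(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        distinct = {frozenset(pair) for pair, q in zip(pairs, adj) if q < alpha}
    else:
        distinct = set()
    means = {g: data[g].mean() for g in kept}
    letters = _compact_letters(kept, means, distinct)
    return AnovaResult(groups=kept, f=float(f), df=df, p=p, letters=letters,
                       excluded=excluded, alpha=alpha)


# ---------------------------------------------------------------------------
# GLM, AICc, dredge, concordance
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    loglik: float
    coef: dict[str, float]
    k: int  # intercept + slopes + error variance
    n: int
    rss: float


def fit_glm(y, X=None, names: Optional[Sequence[str]] = None) -> GLMFit:
    """Gaussian identity-link GLM (ordinary least squares with ML loglik).

    ``X`` may be None (intercept-only model), a DataFrame, or a 2-d array
    with ``names``.  ``k`` counts intercept + slopes + the error variance.
    Collinear predictor columns raise an error naming the columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None or (hasattr(X, "shape") and np.asarray(X).size == 0):
        cols: list[str] = []
        mat = np.empty((n, 0))
    elif isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        cols = list(names) if names else [f"x{i}" for i in range(mat.shape[1])]
    design = np.column_stack([np.ones(n), mat])
    if n <= design.shape[1] + 1:
        raise StatsError("need n > k + 1 observations")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise StatsError(f"collinear predictor columns among {cols}")
    model = sm.OLS(y, design).fit()
    coef = {"intercept": float(model.params[0])}
    coef.update({c: float(b) for c, b in zip(cols, model.params[1:])})
    return GLMFit(loglik=float(model.llf), coef=coef, k=design.shape[1] + 1,
                  n=n, rss=float(model.ssr))


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike criterion: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise StatsError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def dredge(y, X: pd.DataFrame) -> pd.DataFrame:
    """Fit all 2^p predictor subsets (including the null model), rank by AICc.

    Returns one row per subset with predictors, k, log-likelihood, AICc,
    delta AICc and Akaike weights (summing to 1), sorted by AICc.
    """
    if not isinstance(X, pd.DataFrame):
        raise StatsError("X must be a DataFrame of candidate predictors")
    p = X.shape[1]
    if p > 12:
        raise StatsError("at most 12 candidate predictors")
    rows = []
    for size in range(p + 1):
        for subset in itertools.combinations(X.columns, size):
            fit = fit_glm(y, X[list(subset)] if subset else None)
            rows.append(
                {
                    "predictors": "+".join(subset) if subset else "(null)",
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aicc": aicc(fit.loglik, fit.k, fit.n),
                }
            )
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["weight"] = rel / rel.sum()
    return table


def concordance(x, y) -> tuple[float, float]:
    """OLS slope of y on x and squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need paired vectors with n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)
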