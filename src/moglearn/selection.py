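"""Three-stage feature selection: NB-Wald DGE, moderated-t, and LASSO.

Stage 1 tests count features (mRNA) with a per-feature negative-binomial
GLM and Wald test at p < 0.001.  Stage 2 tests methylation features with
an empirical-Bayes moderated t-statistic at p < 0.05.  Stage 3 fits
one-vs-rest L1-penalized least squares by cyclic coordinate descent

    min_beta  1/(2n) * sum_i (y_i - x_i beta)^2 + lambda * ||beta||_1

and keeps the union of nonzero-coefficient features across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from sklearn.model_selection import KFold

from .datatypes import OmicsMatrix

_DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# negative-binomial Wald differential expression
# ---------------------------------------------------------------------------

@dataclass
class DGEResult:
    """Per-feature NB-Wald test results; ``selected`` iff ``p_value < alpha``."""

    table: pd.DataFrame  # columns: log2_fold_change, wald_statistic, p_value, selected, all_zero
    alpha: float

    @property
    def selected_features(self) -> list:
        return self.table.index[self.table["selected"]].tolist()


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size normalization factors.

    The reference is the per-feature geometric mean over samples (features
    with any zero count are excluded); each sample's factor is the median
    ratio of its counts to the reference.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=0)
    if not positive.any():
        return np.ones(counts.shape[0])
    log_ref = np.log(counts[:, positive]).mean(axis=0)
    sf = np.exp(np.median(np.log(counts[:, positive]) - log_ref, axis=1))
    return sf / np.exp(np.mean(np.log(sf)))


def _mom_dispersion(q: np.ndarray, groups: np.ndarray, inv_sf_mean: float) -> float:
    """Pooled method-of-moments dispersion from size-factor-normalized counts.

    For NB counts, Var(k/s) ~= mu * E[1/s] + a * mu^2 within a group; solving
    for ``a`` and pooling across groups with df weights gives the estimate,
    floored at a tiny positive value.
    """
    num = 0.0
    den = 0.0
    for g in (0, 1):
        qg = q[groups == g]
        m = qg.mean()
        if m <= 0 or qg.size < 2:
            continue
        v = qg.var(ddof=1)
        df = qg.size - 1
        num += df * (v - m * inv_sf_mean) / (m * m)
        den += df
    alpha = num / den if den else 0.0
    return max(alpha, _DISPERSION_FLOOR)


def nb_wald_dge(
    counts: OmicsMatrix | pd.DataFrame,
    groups,
    alpha: float = 0.001,
) -> DGEResult:
    """Per-feature NB GLM Wald test of a binary group contrast.

    A log-link GLM with an intercept, a group indicator, and a
    library-size offset (median-of-ratios) is fitted per feature with a
    method-of-moments dispersion.  The Wald statistic is the group
    coefficient over its standard error, referred to N(0, 1) two-sided.

    All-zero features get ``p=1`` and are flagged, never selected.
    """
    df = counts.values if isinstance(counts, OmicsMatrix) else counts
    groups = np.asarray(groups).astype(int)
    if groups.size != df.shape[0]:
        raise ValueError("groups length must match number of samples")
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    for g in (0, 1):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    k = df.to_numpy(dtype=float)
    if not np.isfinite(k).all() or (k < 0).any():
        raise ValueError("counts must be finite and non-negative")

    sf = size_factors(k)
    offset = np.log(sf)
    inv_sf_mean = float(np.mean(1.0 / sf))
    design = np.column_stack([np.ones_like(groups, dtype=float), groups.astype(float)])

    log2fc = np.zeros(k.shape[1])
    wald = np.zeros(k.shape[1])
    pvals = np.ones(k.shape[1])
    all_zero = np.zeros(k.shape[1], dtype=bool)
    ln2 = np.log(2.0)
    for j in range(k.shape[1]):
        y = k[:, j]
        if y.sum() == 0:
            all_zero[j] = True
            continue
        disp = _mom_dispersion(y / sf, groups, inv_sf_mean)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y,
                    design,
                    family=sm.families.NegativeBinomial(alpha=disp),
                    offset=offset,
                ).fit()
            beta, se = fit.params[1], fit.bse[1]
        except Exception:  # non-convergence on degenerate features
            beta, se = 0.0, np.inf
        if not np.isfinite(se) or se == 0:
            log2fc[j] = beta / ln2
            continue
        z = beta / se
        log2fc[j] = beta / ln2
        wald[j] = z
        pvals[j] = 2.0 * stats.norm.sf(abs(z))

    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "wald_statistic": wald,
            "p_value": pvals,
            "all_zero": all_zero,
            "selected": (pvals < alpha) & ~all_zero,
        },
        index=df.columns,
    )
    return DGEResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # columns: effect, moderated_t, p_value, selected
    prior_df: float
    prior_var: float
    alpha: float

    @property
    def selected_features(self) -> list:
        return self.table.index[self.table["selected"]].tolist()


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the sample variances (log-scale).

    Returns ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the
    observed spread of log variances is no larger than expected from the
    chi-square sampling noise alone.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        prior_df = 2.0 * _trigamma_inverse(e_var)
        prior_var = np.exp(
            e_mean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)
        )
    else:
        prior_df = np.inf
        prior_var = np.exp(e_mean)
    return float(prior_df), float(prior_var)


def moderated_t_dm(
    methylation: OmicsMatrix | pd.DataFrame,
    groups,
    alpha: float = 0.05,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModeratedTResult:
    """Two-group moderated t-test per feature (empirical-Bayes shrinkage).

    Per-feature pooled residual variances are shrunk toward a prior fitted
    across features:  ``s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d)``; the
    moderated t is the mean difference over ``s_tilde * sqrt(1/n1 + 1/n2)``
    with ``d + d0`` degrees of freedom.  Passing ``prior_df=0`` recovers
    the ordinary two-sample t-test exactly.
    """
    df_values = methylation.values if isinstance(methylation, OmicsMatrix) else methylation
    groups = np.asarray(groups).astype(int)
    for g in (0, 1):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    X = df_values.to_numpy(dtype=float)
    n1 = int((groups == 0).sum())
    n2 = int((groups == 1).sum())
    df_resid = n1 + n2 - 2

    m1 = X[groups == 0].mean(axis=0)
    m2 = X[groups == 1].mean(axis=0)
    effect = m2 - m1
    ss = X[groups == 0].var(axis=0, ddof=1) * (n1 - 1) + X[groups == 1].var(
        axis=0, ddof=1
    ) * (n2 - 1)
    s2 = ss / df_resid

    if prior_df is None:
        est_df, est_var = _fit_f_dist(s2[s2 > 0], df_resid) if (s2 > 0).any() else (0.0, 1.0)
        d0 = est_df
        s02 = est_var if prior_var is None else prior_var
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, effect / scale, np.where(effect == 0, 0.0, np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero-variance, zero-effect features are uninformative
    p = np.where((scale == 0) & (effect == 0), 1.0, p)

    table = pd.DataFrame(
        {
            "effect": effect,
            "moderated_t": t,
            "p_value": p,
            "selected": p < alpha,
        },
        index=df_values.columns,
    )
    return ModeratedTResult(table=table, prior_df=d0, prior_var=s02, alpha=alpha)


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent
# ---------------------------------------------------------------------------

def soft_threshold(z: np.ndarray | float, lam: float):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    r = y - X @ beta
    n = y.size
    return float(r @ r / (2.0 * n) + lam * np.abs(beta).sum())


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    beta0: np.ndarray | None = None,
    callback=None,
) -> np.ndarray:
    """Cyclic coordinate descent with soft-thresholding.

    ``X`` is expected standardized (zero mean, unit variance per column);
    convergence is declared when no coefficient moves by more than ``tol``
    in a full sweep.  ``callback(beta)`` runs after every sweep (used by
    tests to assert the objective never increases).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    col_sq = (X * X).sum(axis=0) / n
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    r = y - X @ beta
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            old = beta[j]
            rho = (X[:, j] @ r) / n + col_sq[j] * old
            new = soft_threshold(rho, lam) / col_sq[j]
            if new != old:
                r += X[:, j] * (old - new)
                beta[j] = new
                max_change = max(max_change, abs(new - old))
        if callback is not None:
            callback(beta.copy())
        if max_change <= tol:
            break
    return beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero solution is optimal (KKT)."""
    n = X.shape[0]
    return float(np.abs(X.T @ y).max() / n)


def lasso_select(
    X: pd.DataFrame,
    labels,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
) -> list:
    """One-vs-rest LASSO selection: union of nonzero supports across classes.

    For every class, the 0/1 indicator response is fitted over a geometric
    lambda grid; the lambda minimizing ``cv_folds``-fold cross-validated
    squared error is chosen and the final fit's nonzero coefficients mark
    selected features.  Features with zero variance can never be selected.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("lasso_select requires at least two classes")
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    std = Xv.std(axis=0)
    nz = std > 0
    Xs = np.zeros_like(Xv)
    Xs[:, nz] = (Xv[:, nz] - mean[nz]) / std[nz]

    selected = np.zeros(Xv.shape[1], dtype=bool)
    rng = np.random.default_rng(seed)
    for cls in classes:
        y = (labels == cls).astype(float)
        y = y - y.mean()
        if lambda_grid is None:
            lmax = lambda_max(Xs, y)
            grid = np.geomspace(lmax, max(lmax * 0.01, 1e-10), n_lambda)
        else:
            grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        cv_err = np.zeros(len(grid))
        for train, test in kf.split(Xs):
            beta = None
            for gi, lam in enumerate(grid):
                beta = lasso_fit(Xs[train], y[train], lam, beta0=beta)
                resid = y[test] - Xs[test] @ beta
                cv_err[gi] += resid @ resid
        best = grid[int(np.argmin(cv_err))]
        beta = None
        for lam in grid:
            beta = lasso_fit(Xs, y, lam, beta0=beta)
            if lam <= best:
                break
        selected |= beta != 0
    selected &= nz
    return [f for f, s in zip(X.columns, selected) if s]


def selection_report(stages: dict) -> pd.DataFrame:
    """Per-layer feature counts at each pipeline stage (original / filtered /
    LASSO), mirroring the shape of a selection-summary table."""
    rows = []
    for layer, counts in stages.items():
        rows.append({"layer": layer, **counts})
    return pd.DataFrame(rows).set_index("layer")
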