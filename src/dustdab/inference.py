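"""High-dimensional inference: Lasso with cross-validated penalty and
debiased (desparsified) coefficient tests.

Model: y = X beta + Z gamma + eps with p (taxa) possibly comparable to n
and a low-dimensional unpenalized covariate block Z.  The penalized fit
minimizes (1/2n)||y - X beta - Z gamma||^2 + lambda ||beta||_1 with gamma
free.  Because Z is unpenalized, the fit is computed in Frisch-Waugh form:
X and y are residualized on [1, Z] and the Lasso runs on the residualized
design.

Each coefficient is then desparsified with a nodewise-Lasso relaxed
inverse covariance Theta:

    b = beta_hat + Theta X^T (y - X beta_hat) / n
    se_j = sigma_hat * sqrt((Theta Sigma Theta^T)_jj / n)

with Sigma = X^T X / n and sigma_hat from the Lasso residuals with a
degrees-of-freedom correction.  b_j / se_j is asymptotically standard
normal under H0: beta_j = 0, giving each taxon a test that controls for
all other taxa and the covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, ResultTable, SampleFrame, parse_lineage
from .preprocess import FilterSpec, StandardizedDesign, build_design

log = logging.getLogger("dustdab")

_KKT_TOL = 1e-6


class ConvergenceError(RuntimeError):
    pass


class CollinearityError(ValueError):
    pass


def _residualizer(Z: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis Q of span([1, Z]) for projection residuals."""
    ones = np.ones((n, 1))
    A = ones if Z is None or Z.size == 0 else np.hstack([ones, Z])
    Q, R = np.linalg.qr(A)
    keep = np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)).max(), 1.0)
    return Q[:, keep]


def residualize(design: StandardizedDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project X and y off the covariate block (plus intercept).

    Returns (X_tilde, y_tilde, Q) where Q is the orthonormal covariate
    basis; q = Q.shape[1] counts the unpenalized parameters.
    """
    n = design.n
    Q = _residualizer(design.Z, n)
    Xt = design.X - Q @ (Q.T @ design.X)
    yt = design.y - Q @ (Q.T @ design.y)
    return Xt, yt, Q


@dataclass
class LassoFit:
    """A penalized fit at a fixed regularizer on the residualized design."""

    beta: np.ndarray
    lambda_: float
    residuals: np.ndarray  # y_tilde - X_tilde beta
    n_unpenalized: int     # intercept + covariate columns projected out
    cv_lambdas: np.ndarray | None = None
    cv_errors: np.ndarray | None = None
    cv_fold_se: np.ndarray | None = None
    n_folds: int = 5
    fold_seed: int | None = None

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.beta))


def lambda_max(Xt: np.ndarray, yt: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |x_j^T y| / n."""
    n = Xt.shape[0]
    return float(np.max(np.abs(Xt.T @ yt)) / n) if Xt.size else 0.0


def _lasso_solve(Xt: np.ndarray, yt: np.ndarray, lam: float,
                 tol: float = 1e-10, max_iter: int = 100_000) -> np.ndarray:
    """Solve (1/2n)||y - X b||^2 + lam ||b||_1; exact least squares at lam=0."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        n, p = Xt.shape
        if p >= n:
            raise ValueError("lambda = 0 requires p < n (use a positive penalty)")
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        return beta
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=max_iter)
    model.fit(Xt, yt)
    if model.n_iter_ >= max_iter:
        raise ConvergenceError(
            f"coordinate descent hit {max_iter} iterations at lambda={lam:g}")
    return model.coef_.copy()


def check_kkt(Xt: np.ndarray, yt: np.ndarray, beta: np.ndarray,
              lam: float, tol: float = _KKT_TOL) -> bool:
    """Verify the Lasso stationarity conditions of a solution."""
    n = Xt.shape[0]
    g = Xt.T @ (yt - Xt @ beta) / n
    zero = beta == 0
    ok_zero = np.all(np.abs(g[zero]) <= lam + tol)
    ok_active = np.all(np.abs(g[~zero] - lam * np.sign(beta[~zero])) <= tol)
    return bool(ok_zero and ok_active)


def fit_lasso(design: StandardizedDesign, lam: float) -> LassoFit:
    """Penalized fit at a fixed lambda with the covariate block unpenalized."""
    Xt, yt, Q = residualize(design)
    beta = _lasso_solve(Xt, yt, lam)
    resid = yt - Xt @ beta
    return LassoFit(beta=beta, lambda_=lam, residuals=resid,
                    n_unpenalized=Q.shape[1])


def lambda_grid(lam_max: float, n_points: int = 100,
                decades: float = 3.0) -> np.ndarray:
    """Log-spaced grid from lambda_max down ``decades`` decades."""
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_points)


def choose_lambda(design: StandardizedDesign, n_folds: int = 5,
                  seed: int = 0, n_points: int = 100,
                  decades: float = 3.0) -> tuple[float, dict]:
    """Pick lambda by K-fold CV of held-out squared error.

    Folds are a seeded shuffled partition.  Within each training fold the
    covariate projection is refit; held-out predictions include the
    covariate part.  Returns the error-minimizing lambda plus the CV
    curve (grid, mean error, between-fold SE).
    """
    Xt, yt, _ = residualize(design)
    grid = lambda_grid(lambda_max(Xt, yt), n_points, decades)
    n = design.n
    if n < n_folds:
        raise ValueError(f"n={n} too small for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = np.empty((n_folds, len(grid)))
    X, y, Z = design.X, design.y, design.Z
    for k, (tr, te) in enumerate(kf.split(X)):
        Qtr = _residualizer(Z[tr] if Z.size else np.empty((len(tr), 0)), len(tr))
        Xtr = X[tr] - Qtr @ (Qtr.T @ X[tr])
        ytr = y[tr] - Qtr @ (Qtr.T @ y[tr])
        if np.allclose(ytr, ytr[0]):
            raise ValueError("degenerate fold: constant outcome after "
                             "projection; reseed the fold partition")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xtr, ytr, alphas=grid, tol=1e-4,
                                     max_iter=5000)
        # unpenalized covariate coefficients completing each path solution
        A_tr = np.hstack([np.ones((len(tr), 1)),
                          Z[tr] if Z.size else np.empty((len(tr), 0))])
        A_te = np.hstack([np.ones((len(te), 1)),
                          Z[te] if Z.size else np.empty((len(te), 0))])
        G, *_ = np.linalg.lstsq(A_tr, y[tr][:, None] - X[tr] @ coefs,
                                rcond=None)
        pred = X[te] @ coefs + A_te @ G
        errs[k] = np.mean((y[te][:, None] - pred) ** 2, axis=0)
    mean_err = errs.mean(axis=0)
    fold_se = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_err))
    info = {"grid": grid, "mean_error": mean_err, "fold_se": fold_se,
            "best_index": best, "n_folds": n_folds, "seed": seed}
    return float(grid[best]), info


def cv_fit(design: StandardizedDesign, n_folds: int = 5,
           seed: int = 0) -> LassoFit:
    """Cross-validate lambda, then refit on the full data."""
    lam, info = choose_lambda(design, n_folds=n_folds, seed=seed)
    fit = fit_lasso(design, lam)
    fit.cv_lambdas = info["grid"]
    fit.cv_errors = info["mean_error"]
    fit.cv_fold_se = info["fold_se"]
    fit.n_folds = n_folds
    fit.fold_seed = seed
    return fit


# ---------------------------------------------------------------------------
# nodewise regressions and the relaxed inverse covariance


def _nodewise_lambda_cv(Xmj: np.ndarray, xj: np.ndarray, n_folds: int,
                        seed: int, n_points: int = 10,
                        decades: float = 1.5) -> float:
    """Per-column CV for the nodewise penalty.

    The grid spans 1.5 decades below the column's lambda_max: nodewise
    penalties far below sqrt(log p / n) only slow convergence without
    improving the relaxed inverse, so the deep end of the main-fit grid
    is not revisited here.
    """
    n = len(xj)
    lmax = lambda_max(Xmj, xj - xj.mean())
    if lmax <= 0:
        return 0.0
    grid = np.geomspace(lmax, lmax * 10.0 ** (-decades), n_points)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = np.zeros((n_folds, n_points))
    for k, (tr, te) in enumerate(kf.split(Xmj)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xmj[tr], xj[tr], alphas=grid, tol=1e-3)
        pred = Xmj[te] @ coefs
        errs[k] = np.mean((xj[te][:, None] - pred) ** 2, axis=0)
    return float(grid[int(np.argmin(errs.mean(axis=0)))])


def nodewise_theta(X: np.ndarray, lambda_node: float | None = None,
                   n_folds: int = 5, seed: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Relaxed inverse covariance via per-column nodewise Lasso.

    For each column j, Lasso of x_j on the remaining columns gives
    gamma_j; tau_j^2 = x_j^T (x_j - X_{-j} gamma_j) / n; row j of Theta is
    (1, -gamma_j) / tau_j^2 placed in the right positions.  ``lambda_node``
    fixes one penalty for all columns (0 gives the exact matrix inverse
    when X has full column rank); ``None`` selects a per-column penalty by
    K-fold CV.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Theta = np.zeros((p, p))
    tau2 = np.empty(p)
    for j in range(p):
        xj = X[:, j]
        Xmj = np.delete(X, j, axis=1)
        lam = lambda_node
        if lam is None:
            lam = _nodewise_lambda_cv(Xmj, xj, n_folds, seed + j)
        gamma = _lasso_solve(Xmj, xj, lam, tol=1e-6) if lam > 0 else \
            np.linalg.lstsq(Xmj, xj, rcond=None)[0]
        resid = xj - Xmj @ gamma
        t2 = float(xj @ resid / n)
        if t2 < 1e-12:
            raise CollinearityError(
                f"nodewise residual variance ~ 0 for column {j}; "
                "taxon is (nearly) a linear combination of the others")
        tau2[j] = t2
        row = np.empty(p)
        row[j] = 1.0
        row[np.arange(p) != j] = -gamma
        Theta[j] = row / t2
    return Theta, np.sqrt(tau2)


# ---------------------------------------------------------------------------
# debiasing


@dataclass
class DebiasResult:
    """Desparsified coefficients with normal-theory tests."""

    b: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    sigma_hat: float
    support_size: int

    def ci(self, level: float = 0.95) -> np.ndarray:
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.b - zq * self.se, self.b + zq * self.se])


def debias_and_test(fit: LassoFit, Theta: np.ndarray,
                    Xt: np.ndarray, yt: np.ndarray) -> DebiasResult:
    """Desparsify a Lasso fit and test each coefficient.

    ``Xt``/``yt`` are the residualized design the fit was computed on.
    sigma_hat uses the df-corrected residual variance with
    df = n - support - q (q = unpenalized parameters projected out).
    """
    n = Xt.shape[0]
    resid = yt - Xt @ fit.beta
    b = fit.beta + Theta @ (Xt.T @ resid) / n
    Sigma = Xt.T @ Xt / n
    omega = np.einsum("ij,jk,ik->i", Theta, Sigma, Theta)
    df = n - fit.support_size - fit.n_unpenalized
    if df <= 0:
        raise ValueError(
            f"non-positive residual df (n={n}, support={fit.support_size}, "
            f"unpenalized={fit.n_unpenalized}); increase n or the penalty")
    sigma = float(np.sqrt(resid @ resid / df))
    se = sigma * np.sqrt(omega / n)
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return DebiasResult(b=b, se=se, z=z, p_values=p, sigma_hat=sigma,
                        support_size=fit.support_size)


def debiased_lasso(design: StandardizedDesign, seed: int = 0,
                   lambda_node: float | None = None,
                   n_folds: int = 5,
                   Theta: np.ndarray | None = None,
                   ) -> tuple[DebiasResult, LassoFit]:
    """CV-Lasso then desparsified inference on a standardized design.

    ``Theta`` may be supplied to reuse a nodewise estimate across repeated
    outcomes on the same predictor matrix (the nodewise step depends on X
    only).
    """
    Xt, yt, Q = residualize(design)
    fit = cv_fit(design, n_folds=n_folds, seed=seed)
    if Theta is None:
        Theta, _ = nodewise_theta(Xt, lambda_node=lambda_node,
                                  n_folds=n_folds, seed=seed)
    res = debias_and_test(fit, Theta, Xt, yt)
    return res, fit


# ---------------------------------------------------------------------------
# full pipeline


def run_differential_abundance(table: CountTable, frame: SampleFrame,
                               outcome: str, rank: str = "genus",
                               seed: int = 0,
                               filter_spec: FilterSpec | None = None,
                               season_sensitivity: bool = False,
                               lambda_node: float | None = None,
                               ) -> ResultTable:
    """Full chain: preprocess, CV-Lasso, nodewise debiasing, per-taxon tests.

    Returns one row per taxon surviving filtering.  Taxa constant after
    preprocessing are reported with NaN statistics.  The fixed 0.05
    convention sets the ``significant`` flag; a BH-FDR column ``q_value``
    is emitted for reference and never changes the flag.
    """
    design = build_design(table, frame, outcome, rank=rank,
                          filter_spec=filter_spec,
                          season_sensitivity=season_sensitivity)
    res, fit = debiased_lasso(design, seed=seed, lambda_node=lambda_node)
    log.info("run_differential_abundance[%s]: n=%d p=%d lambda=%.4g "
             "support=%d sigma=%.3f", outcome, design.n, design.p,
             fit.lambda_, fit.support_size, res.sigma_hat)

    ranks = [parse_lineage(s) for s in design.lineages]
    rows = pd.DataFrame({
        "taxon_id": design.taxon_ids,
        "phylum": [r[1] for r in ranks],
        "family": [r[4] for r in ranks],
        "genus": [r[5] for r in ranks],
        "coefficient": res.b,
        "se": res.se,
        "z": res.z,
        "p_value": res.p_values,
        "significant": res.p_values < 0.05,
    })
    rows["q_value"] = multipletests(res.p_values, method="fdr_bh")[1]
    if design.dropped_taxa:
        nan_rows = pd.DataFrame({
            "taxon_id": design.dropped_taxa,
            "phylum": "", "family": "", "genus": design.dropped_taxa,
            "coefficient": np.nan, "se": np.nan, "z": np.nan,
            "p_value": np.nan, "significant": False, "q_value": np.nan,
        })
        rows = pd.concat([rows, nan_rows], ignore_index=True)
    extra = {"lambda": fit.lambda_, "support_size": fit.support_size,
             "sigma_hat": res.sigma_hat, "n": design.n, "p": design.p,
             "seed": seed}
    return ResultTable(data=rows, outcome=outcome, extra=extra)
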