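"""Three-variable mediation path models with bootstrap inference.

The model decomposes the effect of an independent variable X (here: age) on
an outcome Y (a sentence-processing or memory measure) into a direct path
and an indirect path through a mediator M (a memory score, or an imaging
feature of one ROI), conditioning every regression on the same nuisance
covariates Z:

    a  : slope of X in        M ~ X + Z
    b  : slope of M in        Y ~ X + M + Z
    c' : slope of X in        Y ~ X + M + Z     (direct effect)
    c  : slope of X in        Y ~ X + Z         (total effect)
    ab : a * b                                  (indirect effect)

X, M, Y (and numeric covariates) are z-scored on the analysis sample so the
paths are standardized regression coefficients; with ordinary least squares
and identical covariates in all three models, c = c' + ab holds exactly.

Inference is by nonparametric bootstrap over participants with
bias-corrected (BC) percentile limits.  The p-value of each path is the
smallest alpha at which the BC bound excludes zero; one-tailed tests require
a declared direction for the indirect effect (``expected_sign_ab``), other
paths are tested in the direction of their point estimate.  Resamples where
a fit degenerates (constant column, rank-deficient design) are redrawn so
the number of bootstrap replicates stays fixed.

Estimation is plain OLS or iteratively reweighted least squares with Tukey
bisquare weights ("robust OLS"), selectable per model spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MediationSpec",
    "PathEstimates",
    "MediationResult",
    "fit_paths",
    "bootstrap_mediation",
    "sobel_test",
    "irls_bisquare",
]

_PATHS = ("a", "b", "c", "c_prime", "ab")


@dataclass(frozen=True)
class MediationSpec:
    """Configuration of one mediation model.

    Parameters
    ----------
    x, m, y:
        Column names of the independent variable, mediator, and outcome.
    covariates:
        Nuisance covariate column names; included (z-scored) in all three
        regressions.
    n_boot:
        Number of bootstrap resamples.
    alpha:
        Nominal level for the reported BC confidence interval.
    tails:
        ``"one"`` or ``"two"``.  One-tailed tests follow the declared
        direction for ab and the sign of the point estimate for other paths.
    expected_sign_ab:
        A-priori direction (+1 or -1) of the indirect effect for one-tailed
        testing; an estimate of the opposite sign yields p >= 0.5.
    robust:
        If True, each regression uses IRLS with Tukey bisquare weights
        instead of OLS.  (The exact c = c' + ab decomposition then no longer
        holds.)
    standardize_within_resample:
        Re-z-score within every bootstrap resample (standardization is part
        of the estimator).  If False, the full-sample scaling is reused.
    seed:
        Seed for the bootstrap resampling stream.
    """

    x: str
    m: str
    y: str
    covariates: tuple[str, ...] = ()
    n_boot: int = 5000
    alpha: float = 0.05
    tails: str = "one"
    expected_sign_ab: int = -1
    robust: bool = False
    standardize_within_resample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.expected_sign_ab not in (-1, 1):
            raise ValueError("expected_sign_ab must be -1 or +1")
        names = (self.x, self.m, self.y, *self.covariates)
        if len(set(names)) != len(names):
            raise ValueError(f"x, m, y and covariates must be distinct, got {names}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class PathEstimates:
    """Point estimates of the five standardized paths (plus OLS SEs)."""

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    se_a: float | None = None
    se_b: float | None = None
    n_used: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.c_prime, self.ab])


@dataclass(frozen=True)
class MediationResult:
    """Standardized path coefficients with bootstrap BC p-values."""

    beta_a: float
    beta_b: float
    beta_c: float
    beta_c_prime: float
    beta_ab: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    p_ab: float
    ci_ab: tuple[float, float]
    boot_ab_mean: float
    boot_ab_sd: float
    n_used: int
    n_boot_effective: int
    n_redrawn: int = 0
    spec: MediationSpec | None = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# basic numerics


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("cannot z-score a constant column")
    return (v - v.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def irls_bisquare(
    y: np.ndarray,
    X: np.ndarray,
    tuning: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Iteratively reweighted least squares with Tukey bisquare weights.

    Residuals are scaled by MAD/0.6745 (recomputed each iteration);
    observations beyond ``tuning`` rescaled units get weight exactly zero.
    Returns ``(coefficients, converged)``; on non-convergence the best
    iterate is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = _ols(y, X)
    converged = False
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = np.median(np.abs(resid)) / 0.6745
        if scale <= np.finfo(float).eps * max(1.0, np.abs(y).max()):
            return beta, True  # (near-)perfect fit
        u = resid / (tuning * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() <= X.shape[1]:
            break  # too few effective observations to continue
        sw = np.sqrt(w)
        new_beta = _ols(y * sw, X * sw[:, None])
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    if not converged:
        warnings.warn("IRLS did not converge; returning best iterate", RuntimeWarning)
    return beta, converged


def sobel_test(a: float, b: float, se_a: float, se_b: float) -> tuple[float, float]:
    """Sobel large-sample z test of the indirect effect ab.

    z = ab / sqrt(a^2 se_b^2 + b^2 se_a^2); two-tailed normal p-value.
    Serves as an asymptotic, bootstrap-free reference for the indirect test.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    if denom == 0:
        return 0.0, 1.0
    z = a * b / denom
    return float(z), float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# full-sample fit


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    return [names[i] for i in np.nonzero(bad)[0]]


def _prepare(data: pd.DataFrame, spec: MediationSpec) -> tuple[np.ndarray, ...]:
    cols = [spec.x, spec.m, spec.y, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not found in data: {missing}")
    df = data.loc[:, cols].apply(pd.to_numeric).dropna()
    n = len(df)
    if n < len(cols) + 2:
        raise ValueError(
            f"need at least {len(cols) + 2} complete rows, got {n} after listwise deletion"
        )
    arr = df.to_numpy(dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3:]


def _fit_single(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    robust: bool,
    want_se: bool = False,
    col_names: tuple[str, ...] = (),
) -> tuple[np.ndarray, float, float]:
    """Fit the three path regressions on z-scored arrays.

    Returns (paths[a,b,c,c',ab], se_a, se_b); SEs are OLS-based and NaN in
    robust mode unless computed.
    """
    n = x.size
    ones = np.ones(n)
    X1 = np.column_stack([ones, x, Z])  # M ~ X + Z
    X2 = np.column_stack([ones, x, m, Z])  # Y ~ X + M + Z
    names2 = ["intercept", *col_names]
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        bad = _collinear_columns(X2, names2)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = (lambda yy, XX: irls_bisquare(yy, XX)[0]) if robust else _ols
    b1 = fit(m, X1)
    b2 = fit(y, X2)
    b3 = fit(y, X1)
    a, b_path, c, c_prime = b1[1], b2[2], b3[1], b2[1]
    paths = np.array([a, b_path, c, c_prime, a * b_path])
    se_a = se_b = np.nan
    if want_se:
        r1 = m - X1 @ b1
        s1 = r1 @ r1 / (n - X1.shape[1])
        se_a = float(np.sqrt(s1 * np.linalg.inv(X1.T @ X1)[1, 1]))
        r2 = y - X2 @ b2
        s2 = r2 @ r2 / (n - X2.shape[1])
        se_b = float(np.sqrt(s2 * np.linalg.inv(X2.T @ X2)[2, 2]))
    return paths, se_a, se_b


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Point estimates of the five standardized paths on the full sample.

    x, m, y and covariates are z-scored on the complete-case analysis sample
    (listwise deletion).  Raises on rank-deficient designs, naming the
    collinear columns.
    """
    x, m, y, Z = _prepare(data, spec)
    x, m, y = _zscore(x), _zscore(m), _zscore(y)
    Z = np.column_stack([_zscore(Z[:, j]) for j in range(Z.shape[1])]) if Z.shape[1] else Z
    names = (spec.x, spec.m, *spec.covariates)
    paths, se_a, se_b = _fit_single(
        x, m, y, Z, spec.robust, want_se=not spec.robust, col_names=names
    )
    return PathEstimates(
        a=float(paths[0]),
        b=float(paths[1]),
        c=float(paths[2]),
        c_prime=float(paths[3]),
        ab=float(paths[4]),
        se_a=None if spec.robust else se_a,
        se_b=None if spec.robust else se_b,
        n_used=x.size,
    )


# ---------------------------------------------------------------------------
# batched bootstrap


def _batch_zscore(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score (B, n, k) along axis 1; flag resamples with any constant column."""
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    bad = (sd <= 0).any(axis=(1, 2))
    sd = np.where(sd <= 0, 1.0, sd)
    return (A - mu) / sd, bad


def _batch_solve(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched least squares via normal equations; flags ill-conditioned fits."""
    n = X.shape[1]
    Xt = X.transpose(0, 2, 1)
    G = Xt @ X
    h = (Xt @ y[..., None])[..., 0]
    # near-singularity check on the scale-free Gram (columns are z-scored)
    det = np.linalg.det(G / n)
    bad = ~np.isfinite(det) | (det < 1e-10)
    Gs = np.where(bad[:, None, None], np.eye(G.shape[1]), G)
    beta = np.linalg.solve(Gs, h[..., None])[..., 0]
    return beta, bad


def _boot_chunk_ols(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    idx: np.ndarray,
    standardize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit all three path models on a chunk of resamples (OLS only)."""
    B, n = idx.shape
    cols = np.stack([x, m, y], axis=1)[idx]  # (B, n, 3)
    Zb = Z[idx] if Z.shape[1] else np.empty((B, n, 0))
    if standardize:
        cols, bad1 = _batch_zscore(cols)
        if Zb.shape[2]:
            Zb, badz = _batch_zscore(Zb)
            bad1 |= badz
    else:
        bad1 = np.zeros(B, dtype=bool)
    xb, mb, yb = cols[:, :, 0], cols[:, :, 1], cols[:, :, 2]
    ones = np.ones((B, n, 1))
    X1 = np.concatenate([ones, xb[..., None], Zb], axis=2)
    X2 = np.concatenate([ones, xb[..., None], mb[..., None], Zb], axis=2)
    b1, bad_a = _batch_solve(X1, mb)
    b2, bad_b = _batch_solve(X2, yb)
    b3, bad_c = _batch_solve(X1, yb)
    theta = np.column_stack(
        [b1[:, 1], b2[:, 2], b3[:, 1], b2[:, 1], b1[:, 1] * b2[:, 2]]
    )
    bad = bad1 | bad_a | bad_b | bad_c | ~np.isfinite(theta).all(axis=1)
    return theta, bad


def _boot_loop_robust(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    idx: np.ndarray,
    standardize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    B = idx.shape[0]
    theta = np.full((B, 5), np.nan)
    bad = np.zeros(B, dtype=bool)
    for i in range(B):
        take = idx[i]
        xb, mb, yb, Zb = x[take], m[take], y[take], Z[take]
        try:
            if standardize:
                xb, mb, yb = _zscore(xb), _zscore(mb), _zscore(yb)
                if Zb.shape[1]:
                    Zb = np.column_stack([_zscore(Zb[:, j]) for j in range(Zb.shape[1])])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                theta[i], _, _ = _fit_single(xb, mb, yb, Zb, robust=True)
        except (ValueError, np.linalg.LinAlgError):
            bad[i] = True
    bad |= ~np.isfinite(theta).all(axis=1)
    return theta, bad


def _bc_pvalue(theta_hat: float, theta_star: np.ndarray, direction: int) -> float:
    """One-tailed BC bootstrap p-value by confidence-bound inversion.

    The p-value is the smallest alpha at which the bias-corrected percentile
    bound in the tested direction excludes zero (binary search to 1e-4).
    """
    B = theta_star.size
    prop = np.clip(np.mean(theta_star < theta_hat), 1.0 / (B + 1), B / (B + 1))
    z0 = norm.ppf(prop)

    def excludes_zero(alpha: float) -> bool:
        if direction < 0:
            q = norm.cdf(2.0 * z0 + norm.ppf(1.0 - alpha))
            return bool(np.quantile(theta_star, q) < 0.0)
        q = norm.cdf(2.0 * z0 + norm.ppf(alpha))
        return bool(np.quantile(theta_star, q) > 0.0)

    lo, hi = 1e-4, 1.0 - 1e-9
    if not excludes_zero(hi):
        return 1.0
    if excludes_zero(lo):
        return lo
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if excludes_zero(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _bc_interval(
    theta_hat: float, theta_star: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Two-sided bias-corrected percentile interval."""
    B = theta_star.size
    prop = np.clip(np.mean(theta_star < theta_hat), 1.0 / (B + 1), B / (B + 1))
    z0 = norm.ppf(prop)
    q_lo = norm.cdf(2.0 * z0 + norm.ppf(alpha / 2.0))
    q_hi = norm.cdf(2.0 * z0 + norm.ppf(1.0 - alpha / 2.0))
    return float(np.quantile(theta_star, q_lo)), float(np.quantile(theta_star, q_hi))


def _path_pvalue(
    theta_hat: float, theta_star: np.ndarray, spec: MediationSpec, is_ab: bool
) -> float:
    if spec.tails == "one":
        direction = spec.expected_sign_ab if is_ab else (1 if theta_hat >= 0 else -1)
        return float(_bc_pvalue(theta_hat, theta_star, direction))
    direction = 1 if theta_hat >= 0 else -1
    return float(min(1.0, 2.0 * _bc_pvalue(theta_hat, theta_star, direction)))


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit the path model and bootstrap bias-corrected p-values for all paths.

    Participants (rows) are the resampling unit.  Standardization is
    recomputed within each resample by default.  Resamples where any fit
    degenerates are redrawn to keep the number of replicates at
    ``spec.n_boot``; the run aborts if more than 10% of draws fail.
    Deterministic under ``spec.seed``.
    """
    x, m, y, Z = _prepare(data, spec)
    n = x.size
    est = fit_paths(data, spec)
    theta_hat = est.as_array()

    if not spec.standardize_within_resample:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
        if Z.shape[1]:
            Z = np.column_stack([_zscore(Z[:, j]) for j in range(Z.shape[1])])

    B = spec.n_boot
    rng = np.random.default_rng(spec.seed)
    max_fail = max(1, int(0.1 * B))
    chunk = max(1, min(B, int(2_000_000 // max(n, 1))))
    theta_star = np.empty((B, 5))
    filled = 0
    n_redrawn = 0
    while filled < B:
        need = min(chunk, B - filled)
        idx = rng.integers(0, n, size=(need, n))
        if spec.robust:
            th, bad = _boot_loop_robust(x, m, y, Z, idx, spec.standardize_within_resample)
        else:
            th, bad = _boot_chunk_ols(x, m, y, Z, idx, spec.standardize_within_resample)
        good = ~bad
        k = int(good.sum())
        theta_star[filled : filled + k] = th[good]
        filled += k
        n_redrawn += int(bad.sum())
        if n_redrawn > max_fail:
            raise RuntimeError(
                f"more than 10% of bootstrap resamples failed ({n_redrawn} of >= {B}); "
                "check for near-constant or collinear columns"
            )

    p = [
        _path_pvalue(theta_hat[i], theta_star[:, i], spec, is_ab=(i == 4))
        for i in range(5)
    ]
    ci_ab = _bc_interval(theta_hat[4], theta_star[:, 4], spec.alpha)
    return MediationResult(
        beta_a=float(theta_hat[0]),
        beta_b=float(theta_hat[1]),
        beta_c=float(theta_hat[2]),
        beta_c_prime=float(theta_hat[3]),
        beta_ab=float(theta_hat[4]),
        p_a=p[0],
        p_b=p[1],
        p_c=p[2],
        p_c_prime=p[3],
        p_ab=p[4],
        ci_ab=ci_ab,
        boot_ab_mean=float(theta_star[:, 4].mean()),
        boot_ab_sd=float(theta_star[:, 4].std(ddof=1)),
        n_used=n,
        n_boot_effective=B,
        n_redrawn=n_redrawn,
        spec=spec,
    )
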