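"""Statistical machinery for the campus depression analysis.

Everything here follows the reporting conventions of mainstream social
science software (SPSS-style): tie-corrected asymptotic Mann-Whitney U
without continuity correction, chi-square tests of independence with
adjusted standardized residuals (ASR) for post hoc cell inspection, Wald
log-scale confidence intervals for 2x2 odds ratios, and principal-component
factoring with Kaiser-normalised varimax followed by promax (oblique)
rotation, plus the KMO and Bartlett sphericity adequacy diagnostics.

The rank-based and contingency statistics are written out explicitly (they
need specific tie/variant conventions); scipy supplies the reference
distributions and rank primitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "ContingencyResult",
    "OddsRatioResult",
    "FactorAnalysisResult",
    "mann_whitney",
    "chi_square_independence",
    "odds_ratio_2x2",
    "spearman",
    "pearson",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "promax",
    "pc_factor_promax",
]


class StatsError(ValueError):
    """Raised for invalid statistical inputs (empty samples, zero margins...)."""


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    """Tie-corrected asymptotic Mann-Whitney U test.

    ``U`` is the statistic of the first sample; ``U_min`` the smaller of the
    two (both conventions appear in the literature).  ``z`` uses the
    tie-corrected variance without continuity correction and ``p_two_tailed``
    is the two-sided normal tail probability.
    """

    U: float
    U_min: float
    z: float
    p_two_tailed: float
    group_means: tuple[float, float]
    n1: int
    n2: int


def mann_whitney(x, y) -> MannWhitneyResult:
    """Mann-Whitney U with midranks for ties and asymptotic two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (x, y) pairs with x > y, ties half
    u2 = n1 * n2 - u1
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    else:  # pragma: no cover - n1, n2 >= 1 implies n >= 2
        var = 0.0
    if var <= 0:  # all observations tied
        z = 0.0
        p = 1.0
    else:
        z = (u1 - mu) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(
        U=float(u1),
        U_min=float(min(u1, u2)),
        z=float(z),
        p_two_tailed=float(min(p, 1.0)),
        group_means=(float(x.mean()), float(y.mean())),
        n1=n1,
        n2=n2,
    )


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    """Chi-square independence test with adjusted standardized residuals."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    asr: np.ndarray


def chi_square_independence(table) -> ContingencyResult:
    """Pearson chi-square on an r x c count table with per-cell ASR.

    The adjusted standardized residual of cell (i, j) is
    ``(O - E) / sqrt(E * (1 - row_i/N) * (1 - col_j/N))``; |ASR| > 2 flags
    the cells driving a significant overall test.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError("table must be at least 2x2")
    if (obs < 0).any():
        raise StatsError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise StatsError("all row and column margins must be positive")
    n = obs.sum()
    expected = np.outer(row, col) / n
    chi2 = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = sps.chi2.sf(chi2, df)
    rp = row / n
    cp = col / n
    denom = np.sqrt(expected * (1.0 - rp[:, None]) * (1.0 - cp[None, :]))
    asr = (obs - expected) / denom
    return ContingencyResult(
        observed=obs, expected=expected, chi2=float(chi2), df=int(df), p=float(p), asr=asr
    )


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with Wald (log-scale normal) 95% confidence interval."""

    or_value: float
    ci_low: float
    ci_high: float


def odds_ratio_2x2(table, haldane: bool = False, z_crit: float = 1.96) -> OddsRatioResult:
    """OR = ad/bc with CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

    With ``haldane=True`` a 0.5 continuity correction is added to every cell,
    allowing zero cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("odds ratio requires a 2x2 table")
    if haldane:
        t = t + 0.5
    if (t <= 0).any():
        raise StatsError("all four cells must be positive (or pass haldane=True)")
    a, b = t[0]
    c, d = t[1]
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(or_value) - z_crit * se)
    hi = np.exp(np.log(or_value) + z_crit * se)
    return OddsRatioResult(or_value=float(or_value), ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho on pairwise-complete data, two-tailed p via the t approximation.

    Returns ``(nan, nan)`` when fewer than 3 complete pairs remain or either
    vector is constant.
    """
    x, y = _pairwise_complete(x, y)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r on pairwise-complete data, two-tailed p."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Factor-analysis diagnostics
# ---------------------------------------------------------------------------

def kmo(corr) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image (partial) correlations from the scaled inverse of R.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise StatsError("correlation matrix is singular; KMO undefined") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d
    off = ~np.eye(p, dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr, n: int) -> tuple[float, int, float]:
    """Bartlett test that R = I: chi2 = -(n-1-(2p+5)/6) ln det R, df = p(p-1)/2."""
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise StatsError("correlation matrix not positive definite; Bartlett undefined")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Principal-component factoring with promax rotation
# ---------------------------------------------------------------------------

def varimax(loadings, normalize: bool = True, tol: float = 1e-10, max_iter: int = 1000):
    """Orthogonal varimax rotation, Kaiser-normalised by default.

    Returns the rotated loading matrix and the orthogonal rotation matrix.
    """
    A = np.asarray(loadings, dtype=float).copy()
    p, k = A.shape
    if k < 2:
        return A, np.eye(k)
    if normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        grad = A.T @ (L**3 - L * (L**2).sum(axis=0) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    L = A @ R
    if normalize:
        L = L * h[:, None]
    return L, R


def promax(loadings, kappa: float = 4.0, normalize: bool = True):
    """Promax oblique rotation: varimax, then an |L|^kappa target fit.

    Returns the oblique pattern matrix and the factor correlation matrix.
    With ``kappa=1`` the target equals the varimax solution, so the pattern
    reproduces varimax exactly.
    """
    V, _ = varimax(loadings, normalize=normalize)
    k = V.shape[1]
    if k < 2:
        return V.copy(), np.eye(k)
    target = np.sign(V) * np.abs(V) ** kappa
    # least-squares oblique transformation toward the target
    Q, *_ = np.linalg.lstsq(V, target, rcond=None)
    # rescale columns so the implied factors have unit variance
    d = np.diag(np.linalg.inv(Q.T @ Q))
    Q = Q * np.sqrt(d)
    pattern = V @ Q
    qinv = np.linalg.inv(Q)
    phi = qinv @ qinv.T
    return pattern, phi


@dataclass(frozen=True)
class FactorAnalysisResult:
    """Principal-component factoring with promax rotation and diagnostics."""

    eigenvalues: np.ndarray
    n_retained: int
    pattern_matrix: np.ndarray
    factor_correlations: np.ndarray
    variance_explained_pct: np.ndarray
    communalities: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float

    def assignment(self) -> np.ndarray:
        """Index of the max-|loading| factor for each variable."""
        return np.abs(self.pattern_matrix).argmax(axis=1)


def pc_factor_promax(
    data,
    retain: int | None = None,
    kappa: float = 4.0,
    n_obs: int | None = None,
    is_corr: bool = False,
) -> FactorAnalysisResult:
    """Principal-component factor analysis with promax (oblique) rotation.

    Parameters
    ----------
    data
        An (n, p) observation matrix, or a p x p correlation matrix if
        ``is_corr`` (then ``n_obs`` must be given for Bartlett).
    retain
        Number of factors to keep; ``None`` applies the Kaiser eigenvalue > 1
        rule to the correlation-matrix spectrum.
    kappa
        Promax power (4 is the common default).

    Notes
    -----
    Initial loadings are eigenvectors scaled by sqrt(eigenvalue); a
    Kaiser-normalised varimax precedes the promax step.  Factor columns are
    sign-flipped so the largest-magnitude loading in each column is positive
    (rotation sign is arbitrary; tests need determinism).
    """
    X = np.asarray(data, dtype=float)
    if is_corr:
        corr = X
        if n_obs is None:
            raise StatsError("n_obs required when passing a correlation matrix")
        n = n_obs
    else:
        n, p = X.shape
        if np.any(np.nanstd(X, axis=0) == 0):
            raise StatsError("data contains constant columns")
        corr = np.corrcoef(X, rowvar=False)
    p = corr.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    k = int((eigvals > 1.0).sum()) if retain is None else int(retain)
    if k < 1:
        raise StatsError("retention rule kept zero factors; specify retain explicitly")
    loadings = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0, None))
    pattern, phi = promax(loadings, kappa=kappa)
    # deterministic sign convention per factor column
    for j in range(pattern.shape[1]):
        i = np.abs(pattern[:, j]).argmax()
        if pattern[i, j] < 0:
            pattern[:, j] = -pattern[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    communalities = (loadings**2).sum(axis=1)
    variance_pct = eigvals[:k] / p * 100.0
    kmo_val = kmo(corr)
    b_chi2, b_df, b_p = bartlett_sphericity(corr, n)
    return FactorAnalysisResult(
        eigenvalues=eigvals,
        n_retained=k,
        pattern_matrix=pattern,
        factor_correlations=phi,
        variance_explained_pct=variance_pct,
        communalities=communalities,
        kmo=kmo_val,
        bartlett_chi2=b_chi2,
        bartlett_df=b_df,
        bartlett_p=b_p,
    )
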