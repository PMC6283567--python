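"""Null-model fitting, p-values, permutation procedures and corrections.

The logistic null model (intercept plus optional covariates such as
principal components) supplies fitted means for every statistic.  Analytic
significance uses the 1-df chi-square score test for burden scores and a
mixture-of-chi-squares tail (characteristic-function inversion with a
four-moment fallback) for the SKAT/SKAT-O/PODKAT quadratic forms.
Empirical significance uses an adaptive permutation procedure; the
stratification-preserving variant permutes case labels by Fisher's
noncentral hypergeometric sampling with per-individual disease odds taken
from the covariate-only null model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, optimize, stats

from . import assoc
from .assoc import (
    PositionKernel,
    WeightSpec,
    cast_scores,
    compute_weights,
    podkat_kernel,
    skat_Q,
    weighted_sum_scores,
)

__all__ = [
    "NullModel",
    "ScoreTestResult",
    "PermutationPlan",
    "TestResult",
    "SeparationError",
    "fit_null",
    "score_test",
    "mixture_chisq_sf",
    "skat_pvalue",
    "skato_pvalue",
    "podkat_pvalue",
    "adaptive_permutation",
    "stratified_permutation",
    "pca_model_correction",
    "pca_permutation_correction",
    "run_test",
    "METHODS",
    "MODEL_CORRECTABLE",
]

DEFAULT_RHO_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation of the phenotype by covariates."""


@dataclass
class NullModel:
    """Fitted logistic null model logit P(Y=1|Z) = a0 + a'Z."""

    alpha: np.ndarray  # coefficients, intercept first
    mu: np.ndarray  # fitted means, in (0, 1)
    Z: np.ndarray  # design matrix including the intercept column
    converged: bool = True

    @property
    def has_covariates(self) -> bool:
        return self.Z.shape[1] > 1

    def disease_odds(self, literal_exp_probability: bool = False) -> np.ndarray:
        """Per-individual odds of disease exp(a0 + a'Z_i).

        ``literal_exp_probability`` instead exponentiates the fitted
        probability itself (a published variant of the weight definition;
        the odds form is the default).
        """
        if literal_exp_probability:
            return np.exp(self.mu)
        return self.mu / (1.0 - self.mu)


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def fit_null(
    y: np.ndarray,
    Z: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NullModel:
    """Maximum-likelihood logistic fit of the covariate-only null model.

    Without covariates the fit is closed form (mu = mean(y)).  With
    covariates, iteratively reweighted least squares; separation (fitted
    log-odds diverging) raises :class:`SeparationError` — this is the
    regime where covariates fully explain the phenotype and no correction
    is possible.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("phenotype is constant; null model undefined")
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        mu = np.full(n, ybar)
        a0 = math.log(ybar / (1.0 - ybar))
        return NullModel(alpha=np.array([a0]), mu=mu, Z=np.ones((n, 1)))

    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    D = np.column_stack([np.ones(n), Z])
    beta = np.zeros(D.shape[1])
    beta[0] = math.log(ybar / (1.0 - ybar))
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        if np.max(np.abs(eta)) > 15.0:
            # odds beyond e^15: some fitted probabilities are numerically
            # 0/1, the hallmark of (quasi-)separation
            raise SeparationError(
                "fitted log-odds diverged: covariates (quasi-)separate the phenotype"
            )
        mu = _expit(eta)
        grad = D.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = D.T @ (D * w[:, None])
        step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        beta = beta + step
    else:
        eta = D @ beta
        mu = _expit(eta)
        if np.max(np.abs(D.T @ (y - mu))) > 1e-6:
            raise SeparationError("IRLS failed to converge; likely separation")
    mu = _expit(D @ beta)
    return NullModel(alpha=beta, mu=mu, Z=D, converged=converged)


@dataclass
class ScoreTestResult:
    """Score statistic U, its variance V, Q = U^2/V and the 1-df p-value."""

    U: float
    V: float
    Q: float
    p: float
    degenerate: bool = False


def score_test(S: np.ndarray, y: np.ndarray, null: NullModel) -> ScoreTestResult:
    """Logistic score test of a burden score against the phenotype.

    Without covariates, V is the product of the phenotype and score sums of
    squares over N-1; with covariates, the standard variance of the score
    with the covariate effects projected out under the null weights.
    A constant score is degenerate: p is defined as 1.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    n = S.size
    resid = y - null.mu
    U = float(S @ resid)
    if not null.has_covariates:
        Sc = S - S.mean()
        V = float(resid @ resid) * float(Sc @ Sc) / (n - 1.0)
    else:
        w = null.mu * (1.0 - null.mu)
        Zw = null.Z * w[:, None]
        ZtWZ = null.Z.T @ Zw
        b = Zw.T @ S
        coef, *_ = np.linalg.lstsq(ZtWZ, b, rcond=None)
        V = float(S @ (w * S) - b @ coef)
    if V <= 0.0:
        return ScoreTestResult(U=U, V=V, Q=0.0, p=1.0, degenerate=True)
    Q = U * U / V
    return ScoreTestResult(U=U, V=V, Q=Q, p=float(stats.chi2.sf(Q, df=1)))


# ---------------------------------------------------------------------------
# Mixture of chi-squares tail


def _liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Moment-matching constants (muQ, sigmaQ, df, delta, muX, sigmaX)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    sigmaQ = math.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = math.sqrt(df)
    return c1, sigmaQ, df, delta, df + delta, math.sqrt(2.0) * a


def _liu_sf_vec(lambdas: np.ndarray, q) -> np.ndarray:
    """Four-moment (Liu-type) approximation to P(sum l_k chi2_1 > q)."""
    muQ, sigmaQ, df, delta, muX, sigmaX = _liu_params(lambdas)
    x = (np.asarray(q, dtype=float) - muQ) / sigmaQ * sigmaX + muX
    if delta > 0:
        return stats.ncx2.sf(x, df, delta)
    return stats.chi2.sf(x, df)


def _liu_sf(lambdas: np.ndarray, q: float) -> float:
    return float(_liu_sf_vec(lambdas, q))


def mixture_chisq_sf(lambdas: np.ndarray, q: float, atol: float = 1e-6) -> float:
    """Upper tail of a positively weighted sum of 1-df chi-squares.

    Numerical inversion of the characteristic function (Imhof's integral),
    with a four-moment approximation as fallback when the inversion fails
    to deliver a probability within tolerance.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("mixture requires at least one positive eigenvalue")
    # normalize the scale so that scaled problems are bitwise identical
    s = lam.max()
    lam = lam / s
    q = q / s
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1))

    def integrand(u: float) -> float:
        lu = lam * u
        theta = 0.5 * np.arctan(lu).sum() - 0.5 * q * u
        rho = np.exp(0.25 * np.log1p(lu * lu).sum())
        return math.sin(theta) / (u * rho)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=500, epsabs=atol / 10)
        p = 0.5 + val / math.pi
        if err < 1e-4 and -1e-6 <= p <= 1.0 + 1e-6:
            return float(min(max(p, 0.0), 1.0))
    except Exception:  # pragma: no cover - inversion failure path
        pass
    return min(max(_liu_sf(lam, q), 0.0), 1.0)


def _mixture_quantile_liu(lambdas: np.ndarray, upper_p: float) -> float:
    """Moment-matched quantile of the mixture at upper-tail probability."""
    lam = np.asarray(lambdas, dtype=float)
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    s1 = c3 / c2**1.5
    df = 1.0 / s1**2 if s1 > 0 else 1e8
    xq = stats.chi2.isf(upper_p, df)
    return float((xq - df) / math.sqrt(2.0 * df) * math.sqrt(2.0 * c2) + c1)


# ---------------------------------------------------------------------------
# Kernel (variance-component) analytic p-values


def _adjusted_half_kernel(B: np.ndarray, null: NullModel) -> np.ndarray:
    """V^(1/2) (I - Z (Z'VZ)^-1 Z'V) B, with V the null phenotype variance.

    Without covariates the variance uses the sample (N-1 divisor)
    convention, N/(N-1) mu(1-mu): this matches both the burden score-test
    variance and the exact second moment of the label-permutation null, so
    analytic and permutation p-values agree on small samples.
    """
    n = null.mu.size
    v = null.mu * (1.0 - null.mu)
    if not null.has_covariates:
        v = v * (n / (n - 1.0))
    Z = null.Z
    Zv = Z * v[:, None]
    coef, *_ = np.linalg.lstsq(Z.T @ Zv, Zv.T @ B, rcond=None)
    return np.sqrt(v)[:, None] * (B - Z @ coef)


def _half_kernel_eigenvalues(B: np.ndarray, null: NullModel) -> np.ndarray:
    G = _adjusted_half_kernel(B, null)
    lam = np.linalg.eigvalsh(G.T @ G)
    lam = lam[lam > max(lam.max(initial=0.0) * 1e-10, 0.0)]
    return lam[::-1]


def _perm_moments_quadform(M: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of Q = ||M'r||^2 under uniform permutation
    of the (centered) residual vector r, for column-centered M.

    Derived combinatorially from the pattern decomposition of
    E[r_i r_j r_k r_l] under sampling without replacement; verified against
    exhaustive enumeration.
    """
    n = M.shape[0]
    d = (M * M).sum(axis=1)
    t1 = float(d.sum())
    K = M.T @ M
    t2 = float((K * K).sum())
    d2 = float((d * d).sum())
    mu2 = float((r**2).sum())
    mu4 = float((r**4).sum())
    n2 = n * (n - 1.0)
    n3 = n2 * (n - 2.0)
    n4 = n3 * (n - 3.0)
    eq = t1 * mu2 / (n - 1.0)
    eq2 = (
        d2 * mu4 / n
        + (t1 * t1 - d2) * (mu2 * mu2 - mu4) / n2
        + 2.0 * (t2 - d2) * (mu2 * mu2 - mu4) / n2
        + 4.0 * d2 * mu4 / n2
        + (2.0 * (-t1 * t1 + 2.0 * d2) + (8.0 * d2 - 4.0 * t2))
        * (2.0 * mu4 - mu2 * mu2)
        / n3
        + (t1 * t1 + 2.0 * t2 - 6.0 * d2) * (3.0 * mu2 * mu2 - 6.0 * mu4) / n4
    )
    return eq, eq2 - eq * eq


def _perm_adjusted_Q(
    B: np.ndarray, y: np.ndarray, null: NullModel, Q: float, lam: np.ndarray
) -> float:
    """Map the observed quadratic form onto the asymptotic mixture scale.

    Without covariates the reference null is the label-permutation law; its
    exact mean and variance differ from the chi-square mixture's on small
    samples (binary phenotypes are less kurtotic than Gaussian residuals).
    The statistic is location/scale matched before the mixture tail is
    evaluated; the correction vanishes as N grows.
    """
    if null.has_covariates or y.size < 5 or lam.size < 2:
        # one-dimensional kernels are already exactly the score test's
        # 1-df chi-square; rescaling would only distort that equality
        return Q
    r = np.asarray(y, dtype=float) - null.mu
    M = B - B.mean(axis=0)
    eq, vq = _perm_moments_quadform(M, r)
    var_mix = 2.0 * float((lam**2).sum())
    if vq <= 0 or var_mix <= 0:
        return Q
    return float(lam.sum() + (Q - eq) * math.sqrt(var_mix / vq))


def _rho_half_matrix(p: int, rho: float) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    a = math.sqrt(1.0 - rho)
    b = (math.sqrt(1.0 - rho + p * rho) - a) / p
    return a * np.eye(p) + b * np.ones((p, p))


#: exact-resampling bounds: enumerate the permutation null completely when
#: the sample is this small (the asymptotic mixture tail is unreliable for
#: binary phenotypes at such sizes).
EXACT_ENUM_MAX_N = 25
EXACT_ENUM_MAX_SUBSETS = 300_000


def _case_subset_scores(B: np.ndarray, n1: int) -> np.ndarray | None:
    """Score vectors M'r for every assignment of n1 case labels.

    Returns an (n_subsets, P) array, or None when enumeration is too
    large.  M is the column-centered half kernel, so M'r = M'z with z the
    case indicator (the constant part cancels).
    """
    from itertools import combinations

    n = B.shape[0]
    if n > EXACT_ENUM_MAX_N or math.comb(n, n1) > EXACT_ENUM_MAX_SUBSETS:
        return None
    M = B - B.mean(axis=0)
    subsets = np.fromiter(
        (i for comb in combinations(range(n), n1) for i in comb),
        dtype=np.int64,
    ).reshape(-1, n1)
    # S[s] = sum over the case subset of M rows
    return M[subsets].sum(axis=1)


def _exact_kernel_sf(B: np.ndarray, y: np.ndarray, Q: float) -> float | None:
    """Exact permutation tail of Q = ||B'(y - ybar)||^2 for small samples."""
    n1 = int(np.asarray(y).sum())
    S = _case_subset_scores(B, n1)
    if S is None:
        return None
    qs = (S * S).sum(axis=1)
    return float((qs >= Q - 1e-12).mean())


def skat_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    null: NullModel,
    weights: np.ndarray | None = None,
    rho: float = 0.0,
) -> tuple[float, float]:
    """Analytic SKAT p-value: Davies tail of Q_rho.  Returns (p, Q)."""
    X = np.asarray(X, dtype=float)
    p_var = X.shape[1]
    w = np.ones(p_var) if weights is None else np.asarray(weights, dtype=float)
    Q = skat_Q(X, y, null.mu, w, rho)
    B = X * w
    if rho > 0:
        B = B @ _rho_half_matrix(p_var, rho)
    if not null.has_covariates:
        p_exact = _exact_kernel_sf(B, y, Q)
        if p_exact is not None:
            return p_exact, Q
    lam = _half_kernel_eigenvalues(B, null)
    return mixture_chisq_sf(lam, _perm_adjusted_Q(B, y, null, Q, lam)), Q


def podkat_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    null: NullModel,
    kernel: PositionKernel,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Analytic PODKAT p-value via the same mixture tail.  Returns (p, Q)."""
    X = np.asarray(X, dtype=float)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    Q = assoc.podkat_Q(X, y, null.mu, w, kernel)
    B = (X * w) @ kernel.A
    if not null.has_covariates:
        p_exact = _exact_kernel_sf(B, y, Q)
        if p_exact is not None:
            return p_exact, Q
    lam = _half_kernel_eigenvalues(B, null)
    return mixture_chisq_sf(lam, _perm_adjusted_Q(B, y, null, Q, lam)), Q


def skato_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    null: NullModel,
    weights: np.ndarray | None = None,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
) -> tuple[float, float]:
    """Optimal-rho SKAT (SKAT-O) p-value.

    The minimum p over the rho grid is recalibrated through the
    one-dimensional mixture representation Q_rho = (1-rho) kappa +
    tau(rho) eta0, integrating the conditional tail over the burden
    direction eta0 ~ chi2_1.  Returns (p, min-p over the grid).
    """
    X = np.asarray(X, dtype=float)
    n, p_var = X.shape
    w = np.ones(p_var) if weights is None else np.asarray(weights, dtype=float)
    rhos = np.array([min(r, 0.999) for r in rho_grid])
    if p_var == 1:
        p, Q = skat_pvalue(X, y, null, w, rho=0.0)
        return p, p

    if not null.has_covariates:
        exact = _skato_exact(X, y, null, w, rhos)
        if exact is not None:
            return exact

    # Per-rho analytic p-values.
    lam_by_rho = []
    p_by_rho = np.empty(rhos.size)
    q_by_rho = np.empty(rhos.size)
    for i, r in enumerate(rhos):
        B = (X * w) @ _rho_half_matrix(p_var, r)
        lam = _half_kernel_eigenvalues(B, null)
        lam_by_rho.append(lam)
        q_raw = skat_Q(X, y, null.mu, w, r)
        q_by_rho[i] = _perm_adjusted_Q(B, y, null, q_raw, lam)
        p_by_rho[i] = mixture_chisq_sf(lam, q_by_rho[i])
    T = float(p_by_rho.min())

    # Null decomposition in the adjusted genotype space.
    Zt = _adjusted_half_kernel(X * w, null)  # n x p
    zbar = Zt.mean(axis=1)
    zz = float(zbar @ zbar)
    if zz <= 0:
        return T, T
    cof = (zbar @ Zt) / zz  # length p
    Z1 = zbar[:, None] * cof[None, :]
    Z2 = Zt - Z1
    K2 = Z2.T @ Z2
    lam = np.linalg.eigvalsh(K2)
    lam = lam[lam > max(lam.max(initial=0.0) * 1e-10, 0.0)]
    if lam.size == 0:
        return T, T
    var_zeta = 4.0 * float(((Z1.T @ Z1) * K2).sum())
    mu_q = lam.sum()
    var_q = 2.0 * (lam**2).sum() + var_zeta
    tau = p_var**2 * rhos * zz + (1.0 - rhos) * (cof**2).sum() * zz

    qmin = np.array(
        [_mixture_quantile_liu(lam_by_rho[i], T) for i in range(rhos.size)]
    )
    scale = math.sqrt(2.0 * (lam**2).sum()) / math.sqrt(var_q)

    # Outer integral over the burden direction eta0 ~ chi2_1, evaluated on
    # a dense grid after the substitution x = t^2 (which absorbs the
    # chi2_1 density singularity at 0 into 2*phi(t)).  The conditional
    # kappa tail uses the four-moment approximation; the characteristic-
    # function inversion is reserved for the per-rho p-values above.
    t = np.linspace(0.0, math.sqrt(40.0), 2_001)
    x = t * t
    with np.errstate(divide="ignore"):
        m = np.min((qmin[:, None] - tau[:, None] * x[None, :]) / (1.0 - rhos)[:, None], axis=0)
    q_adj = (m - mu_q) * scale + mu_q
    ok = (m > 0) & (q_adj > 0)
    Fk = np.zeros_like(x)
    Fk[ok] = 1.0 - np.clip(_liu_sf_vec(lam, q_adj[ok]), 0.0, 1.0)
    val = np.trapezoid(Fk * 2.0 * stats.norm.pdf(t), t)
    p = 1.0 - val
    # Sanity bounds: the combined p cannot beat the best grid point and is
    # at worst the Bonferroni bound over the grid.
    p = min(max(p, T), min(1.0, T * rhos.size))
    return float(p), T


def _skato_exact(
    X: np.ndarray,
    y: np.ndarray,
    null: NullModel,
    w: np.ndarray,
    rhos: np.ndarray,
) -> tuple[float, float] | None:
    """Exact small-sample SKAT-O: permutation law of the min-p statistic
    over the complete enumeration of case-label assignments."""
    B = X * w
    n1 = int(np.asarray(y).sum())
    S = _case_subset_scores(B, n1)
    if S is None:
        return None
    lam_by_rho = [
        _half_kernel_eigenvalues(B @ _rho_half_matrix(B.shape[1], r), null)
        for r in rhos
    ]
    norm2 = (S * S).sum(axis=1)
    tot2 = S.sum(axis=1) ** 2
    s_obs = w * (X.T @ (np.asarray(y, dtype=float) - null.mu))
    minp_all = np.ones(S.shape[0])
    minp_obs = 1.0
    for i, r in enumerate(rhos):
        q_all = (1.0 - r) * norm2 + r * tot2
        minp_all = np.minimum(minp_all, _liu_sf_vec(lam_by_rho[i], q_all))
        q_obs = (1.0 - r) * float(s_obs @ s_obs) + r * float(s_obs.sum() ** 2)
        minp_obs = min(minp_obs, _liu_sf(lam_by_rho[i], q_obs))
    p = float((minp_all <= minp_obs + 1e-12).mean())
    return p, minp_obs


# ---------------------------------------------------------------------------
# Permutation machinery


@dataclass(frozen=True)
class PermutationPlan:
    """Adaptive permutation parameters.

    ``alpha`` is the significance threshold the procedure resolves against,
    ``precision`` the target coefficient of variation of the p estimate;
    permutations stop early once either the precision is reached or the
    one-sided 99% lower confidence bound of the p estimate exceeds alpha.
    """

    alpha: float = 0.01
    precision: float = 0.2
    max_permutations: int | None = None
    min_permutations: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.precision < 1.0:
            raise ValueError("alpha and precision must lie in (0, 1)")

    @property
    def budget(self) -> int:
        if self.max_permutations is not None:
            return self.max_permutations
        return int(round(10.0 / self.alpha))


def adaptive_permutation(
    stat_fn: Callable[[np.ndarray], float],
    y: np.ndarray,
    plan: PermutationPlan,
    rng: np.random.Generator,
    label_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
) -> tuple[float, int]:
    """Adaptive permutation p-value of an observed statistic.

    ``stat_fn`` maps a label vector to the statistic (larger = more
    extreme).  Labels are plain permutations of ``y`` unless a
    ``label_sampler`` (e.g. the stratified resampler) is supplied.  The
    estimate is (b+1)/(m+1) with b the count of permuted statistics at or
    above the observed one.
    """
    y = np.asarray(y)
    stat0 = stat_fn(y)
    if not np.isfinite(stat0):
        raise ValueError("observed statistic is not finite")
    z99 = stats.norm.isf(0.01)
    b = 0
    m = 0
    check_every = 10
    budget = plan.budget
    while m < budget:
        y_perm = label_sampler(rng) if label_sampler is not None else rng.permutation(y)
        t = stat_fn(y_perm)
        if t >= stat0 - 1e-12:
            b += 1
        m += 1
        if m >= plan.min_permutations and m % check_every == 0:
            p_hat = (b + 1) / (m + 1)
            if (1.0 - p_hat) / (m * p_hat) <= plan.precision**2:
                break
            se = math.sqrt(p_hat * (1.0 - p_hat) / m)
            if p_hat - z99 * se > plan.alpha:
                break
    return (b + 1) / (m + 1), m


def stratified_permutation(
    theta: np.ndarray,
    n1: int,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> np.ndarray:
    """One draw of case labels from the multivariate Fisher's noncentral
    hypergeometric law with odds weights ``theta`` and exactly ``n1`` cases.

    Sampling is exact: independent Bernoulli draws with odds proportional
    to theta (globally tuned so the expected total equals n1) conditioned
    on the total, which is the definition of the law.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("disease odds must be positive")
    n = theta.size
    if not 0 < n1 < n:
        raise ValueError("n1 must lie strictly between 0 and N")
    lt = np.log(theta)

    def excess(s: float) -> float:
        return float(_expit(lt + s).sum()) - n1

    s = optimize.brentq(excess, -60.0, 60.0)
    pi = _expit(lt + s)
    batch = 64
    for _ in range(max_tries // batch + 1):
        draws = rng.random((batch, n)) < pi
        totals = draws.sum(axis=1)
        hit = np.flatnonzero(totals == n1)
        if hit.size:
            return draws[hit[0]].astype(np.int8)
    raise RuntimeError("conditional Bernoulli rejection sampling did not converge")


# ---------------------------------------------------------------------------
# Method registry and dispatch

#: method name -> (family, weighting scheme or None, permutation-only flag)
METHODS: dict[str, tuple[str, str | None, bool]] = {
    "cast": ("burden_cast", None, False),
    "sum": ("burden", "uniform", False),
    "wsum_maftot": ("burden", "invsd_maf_total", False),
    "wsum_betamaftot": ("burden", "beta_maf_total", False),
    "wsum_mafctrl": ("burden", "invsd_maf_controls", True),
    "asum": ("burden_asum", None, True),
    "kbac": ("kbac", None, True),
    "skat": ("skat", "uniform", False),
    "skat_maftot": ("skat", "invsd_maf_total", False),
    "skat_betamaftot": ("skat", "beta_maf_total", False),
    "skato": ("skato", "uniform", False),
    "skato_maftot": ("skato", "invsd_maf_total", False),
    "skato_betamaftot": ("skato", "beta_maf_total", False),
    "podkat": ("podkat", "uniform", False),
    "doestrare": ("doestrare", None, True),
}

#: methods whose statistic is representable in the logistic regression and
#: whose weights do not depend on the case/control split: eligible for the
#: PCA model (M1) correction.
MODEL_CORRECTABLE = frozenset(
    name
    for name, (family, scheme, perm_only) in METHODS.items()
    if not perm_only and scheme != "invsd_maf_controls"
)


@dataclass
class TestResult:
    """Outcome of one gene-level association test."""

    method: str
    statistic: float
    p: float
    permutations: int = 0
    correction: str = "none"


def _fixed_weights(scheme: str | None, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    spec = WeightSpec(scheme=scheme or "uniform")
    return compute_weights(spec, X, y)


def _make_stat_fn(
    method: str,
    X: np.ndarray,
    null: NullModel,
    positions: np.ndarray | None,
    gene_length: float | None,
    asum_alpha: float = 0.10,
    podkat_radius: float = 1_000.0,
    kbac_exclude_wildtype: bool = False,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
) -> Callable[[np.ndarray], float]:
    """Build the permutation statistic for a method, precomputing whatever
    does not depend on the label vector."""
    family, scheme, _ = METHODS[method]
    X = np.asarray(X, dtype=float)
    mu = null.mu

    if family == "burden_cast":
        S = cast_scores(X)
        return lambda y: score_test(S, y, null).Q
    if family == "burden" and scheme != "invsd_maf_controls":
        w = _fixed_weights(scheme, X, np.zeros(X.shape[0]))
        S = weighted_sum_scores(X, w)
        return lambda y: score_test(S, y, null).Q
    if family == "burden":  # control-MAF weights: recomputed per permutation

        def stat_wctrl(y: np.ndarray) -> float:
            w = compute_weights(WeightSpec("invsd_maf_controls"), X, y)
            return score_test(weighted_sum_scores(X, w), y, null).Q

        return stat_wctrl
    if family == "burden_asum":

        def stat_asum(y: np.ndarray) -> float:
            signs = assoc.asum_signs(X, y, mu, marginal_alpha=asum_alpha)
            return score_test(weighted_sum_scores(X, signs), y, null).Q

        return stat_asum
    if family == "kbac":
        _, first, inv = np.unique(X, axis=0, return_index=True, return_inverse=True)
        n_tot = np.bincount(inv).astype(np.int64)
        wild = X[first].sum(axis=1) == 0
        use = ~wild if kbac_exclude_wildtype else np.ones(n_tot.size, dtype=bool)
        n = X.shape[0]
        # Hypergeometric upper-tail lookups are cached per case count; the
        # case count is invariant across permutations, so the table is
        # built once per distinct n1 seen.
        cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

        def stat_kbac(y: np.ndarray) -> float:
            n1 = int(y.sum())
            n0 = n - n1
            tab = cache.get(n1)
            if tab is None:
                tab = _kbac_sf_table(n, n_tot, n1)
                cache[n1] = tab
            offsets, sf_flat = tab
            nc = np.bincount(inv, weights=y, minlength=n_tot.size).astype(np.int64)
            w = sf_flat[offsets + nc]
            diff = nc / n1 - (n_tot - nc) / n0
            return float((w[use] * diff[use]).sum() ** 2)

        return stat_kbac
    if family == "doestrare":
        if positions is None or gene_length is None:
            raise ValueError("doestrare requires variant positions and gene length")
        y0 = np.zeros(X.shape[0])
        pre = assoc.doestrare_precompute(X, y0, positions, gene_length)

        def stat_doe(y: np.ndarray) -> float:
            y = np.asarray(y, dtype=float)
            m1 = X.T @ y
            m0 = pre.allele_totals - m1
            p = assoc.DoEstRarePrecompute(
                grid=pre.grid,
                density_cols=pre.density_cols,
                allele_totals=pre.allele_totals,
                n_cases=int(y.sum()),
                n_controls=int(y.size - y.sum()),
            )
            return assoc._doestrare_from_counts(p, m1, m0)

        return stat_doe
    if family in ("skat", "skato"):
        w = _fixed_weights(scheme, X, np.zeros(X.shape[0]))
        if family == "skat":
            return lambda y: skat_Q(X, y, mu, w, rho=0.0)

        # SKAT-O permutation statistic: minus the minimum analytic p over
        # the rho grid (larger = more extreme); eigenvalues are fixed.
        rhos = [min(r, 0.999) for r in rho_grid]
        lam_by_rho = [
            _half_kernel_eigenvalues((X * w) @ _rho_half_matrix(X.shape[1], r), null)
            for r in rhos
        ]

        def stat_skato(y: np.ndarray) -> float:
            # moment-matched tails: only the rank of the min-p matters here
            ps = [
                _liu_sf(lam_by_rho[i], skat_Q(X, y, mu, w, rhos[i]))
                for i in range(len(rhos))
            ]
            return -min(ps)

        return stat_skato
    if family == "podkat":
        w = _fixed_weights(scheme, X, np.zeros(X.shape[0]))
        kern = podkat_kernel(positions, podkat_radius)
        return lambda y: assoc.podkat_Q(X, y, mu, w, kern)
    raise ValueError(f"unknown method {method!r}")


def _kbac_sf_table(n: int, n_tot: np.ndarray, n1: int):
    """Per-class hypergeometric upper-tail lookup for fixed margins."""
    offsets = np.concatenate([[0], np.cumsum(n_tot + 1)])[:-1].astype(np.int64)
    parts = [stats.hypergeom.sf(np.arange(nl + 1) - 1, n, nl, n1) for nl in n_tot]
    return offsets, np.concatenate(parts)


def _analytic_result(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    null: NullModel,
    positions: np.ndarray | None,
    gene_length: float | None,
    podkat_radius: float,
    rho_grid: tuple[float, ...],
    correction: str,
) -> TestResult:
    family, scheme, _ = METHODS[method]
    if family == "burden_cast":
        res = score_test(cast_scores(X), y, null)
        return TestResult(method, res.Q, res.p, 0, correction)
    if family == "burden":
        w = _fixed_weights(scheme, X, y)
        res = score_test(weighted_sum_scores(X, w), y, null)
        return TestResult(method, res.Q, res.p, 0, correction)
    w = _fixed_weights(scheme, X, y)
    if family == "skat":
        p, Q = skat_pvalue(X, y, null, w, rho=0.0)
        return TestResult(method, Q, p, 0, correction)
    if family == "skato":
        p, T = skato_pvalue(X, y, null, w, rho_grid)
        return TestResult(method, T, p, 0, correction)
    if family == "podkat":
        kern = podkat_kernel(positions, podkat_radius)
        p, Q = podkat_pvalue(X, y, null, kern, w)
        return TestResult(method, Q, p, 0, correction)
    raise ValueError(f"method {method!r} has no analytic route")


def run_test(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    positions: np.ndarray | None = None,
    gene_length: float | None = None,
    Z: np.ndarray | None = None,
    correction: str = "none",
    plan: PermutationPlan | None = None,
    rng: np.random.Generator | int | None = None,
    use_permutation: bool | None = None,
    asum_alpha: float = 0.10,
    podkat_radius: float = 1_000.0,
    kbac_exclude_wildtype: bool = False,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
    literal_exp_probability: bool = False,
) -> TestResult:
    """Run one association test on a rare-variant genotype matrix.

    ``correction`` is ``"none"`` (no covariates), ``"pca_model"``
    (covariates in the null model, analytic significance) or ``"pca_perm"``
    (covariate-only null model plus stratification-preserving adaptive
    permutation).  Permutation-only methods under ``"none"`` use plain
    adaptive permutation.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    family, scheme, perm_only = METHODS[method]
    y = np.asarray(y, dtype=np.int8)
    if correction not in ("none", "pca_model", "pca_perm"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction != "none" and Z is None:
        raise ValueError("corrections require covariates Z")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    plan = plan or PermutationPlan()

    if correction == "pca_model":
        if method not in MODEL_CORRECTABLE:
            raise ValueError(
                f"{method!r} is not representable in the covariate-adjusted "
                "regression; use the permutation correction"
            )
        null = fit_null(y, Z)
        return _analytic_result(
            method, X, y, null, positions, gene_length, podkat_radius, rho_grid,
            correction,
        )

    null = fit_null(y, Z if correction == "pca_perm" else None)
    permute = perm_only if use_permutation is None else use_permutation
    if correction == "pca_perm":
        permute = True
    if not permute:
        return _analytic_result(
            method, X, y, null, positions, gene_length, podkat_radius, rho_grid,
            correction,
        )

    stat_fn = _make_stat_fn(
        method, X, null, positions, gene_length,
        asum_alpha=asum_alpha, podkat_radius=podkat_radius,
        kbac_exclude_wildtype=kbac_exclude_wildtype, rho_grid=rho_grid,
    )
    sampler = None
    if correction == "pca_perm" and null.has_covariates:
        theta = null.disease_odds(literal_exp_probability)
        n1 = int(y.sum())
        sampler = lambda r: stratified_permutation(theta, n1, r)
    p, m = adaptive_permutation(stat_fn, y, plan, rng, label_sampler=sampler)
    return TestResult(method, float(stat_fn(y)), p, m, correction)


def pca_model_correction(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    Z_pcs: np.ndarray,
    positions: np.ndarray | None = None,
    gene_length: float | None = None,
    **kwargs,
) -> TestResult:
    """Covariate-in-model (M1) correction: PCs enter the logistic null."""
    return run_test(
        method, X, y, positions, gene_length, Z=Z_pcs, correction="pca_model", **kwargs
    )


def pca_permutation_correction(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    Z_pcs: np.ndarray,
    plan: PermutationPlan | None = None,
    rng: np.random.Generator | int | None = None,
    positions: np.ndarray | None = None,
    gene_length: float | None = None,
    **kwargs,
) -> TestResult:
    """Stratification-preserving permutation correction (M0 + Fisher's
    noncentral hypergeometric label resampling)."""
    return run_test(
        method, X, y, positions, gene_length, Z=Z_pcs, correction="pca_perm",
        plan=plan, rng=rng, **kwargs
    )
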