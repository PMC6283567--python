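"""Gene-based rare-variant association statistics and MAF weighting systems.

All statistics are pure functions of a rare-variant genotype matrix X
(individuals x variants, minor-allele counts), the phenotype vector Y and,
where needed, null-model fitted means and variant positions.  P-values are
computed in :mod:`rarestrat.inference`.

Statistic families
------------------
Burden tests (CAST, Sum, wSum, aSum) collapse the gene into one genetic
score per individual and rely on a logistic score test.  Variance-component
tests (SKAT, SKAT-O) use the quadratic form Q_rho = (Y-mu)' X W R_rho W X'
(Y-mu), with R_rho interpolating between the SKAT (rho=0) and burden
(rho=1) kernels.  KBAC compares multi-site genotype frequencies between
cases and controls with hypergeometric-tail weights.  The position tests
are PODKAT (SKAT with a triangular position-proximity kernel) and DoEstRare
(integrated absolute difference of frequency-scaled allele-position
densities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "WeightSpec",
    "MultiSiteGenotypeTable",
    "PositionKernel",
    "cast_scores",
    "weighted_sum_scores",
    "compute_weights",
    "asum_signs",
    "kbac_statistic",
    "skat_Q",
    "podkat_kernel",
    "podkat_Q",
    "doestrare_statistic",
]

log = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("uniform", "beta_maf_total", "invsd_maf_total", "invsd_maf_controls")


@dataclass(frozen=True)
class WeightSpec:
    """A MAF-based variant weighting system.

    Schemes
    -------
    uniform:
        w_j = 1.
    beta_maf_total:
        w_j = Beta(a1, a2) density at the total-sample MAF estimate
        (defaults a1=1, a2=25, so w_j = 25 (1 - MAF_j)^24).
    invsd_maf_total:
        w_j = 1 / sqrt(N MAF_j (1 - MAF_j)) with the total-sample plug-in
        MAF; columns monomorphic in the sample get weight 0 (logged).
    invsd_maf_controls:
        same form but with the control-only pseudo-count estimator
        MAF0_j = (sum of control allele counts + 1) / (2 N0 + 2), which is
        always in (0, 1) so the weight is always finite.
    """

    scheme: str = "uniform"
    a1: float = 1.0
    a2: float = 25.0

    def __post_init__(self) -> None:
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")


def control_maf(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pseudo-count MAF estimator in controls: (sum X_ij + 1) / (2 N0 + 2)."""
    Y = np.asarray(Y)
    ctrl = Y == 0
    n0 = int(ctrl.sum())
    if n0 < 1:
        raise ValueError("control-based weights require at least one control")
    return (np.asarray(X, dtype=float)[ctrl].sum(axis=0) + 1.0) / (2.0 * n0 + 2.0)


def compute_weights(spec: WeightSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-variant nonnegative weights under the requested scheme."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if spec.scheme == "uniform":
        return np.ones(p)
    if spec.scheme == "beta_maf_total":
        maf = X.mean(axis=0) / 2.0
        return stats.beta.pdf(maf, spec.a1, spec.a2)
    if spec.scheme == "invsd_maf_total":
        maf = X.mean(axis=0) / 2.0
        w = np.zeros(p)
        ok = (maf > 0) & (maf < 1)
        if not ok.all():
            log.info("invsd_maf_total: %d monomorphic columns get weight 0", (~ok).sum())
        w[ok] = 1.0 / np.sqrt(n * maf[ok] * (1.0 - maf[ok]))
        return w
    maf0 = control_maf(X, Y)
    return 1.0 / np.sqrt(n * maf0 * (1.0 - maf0))


def cast_scores(X: np.ndarray) -> np.ndarray:
    """CAST collapsing score: 1 if the individual carries any rare allele."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("CAST requires at least one rare variant column")
    return (X.sum(axis=1) >= 1).astype(np.float64)


def weighted_sum_scores(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-sum burden score S_i = sum_j w_j X_ij."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != X.shape[1]:
        raise ValueError("weight length must equal the number of variants")
    return X @ w


def asum_signs(
    X: np.ndarray,
    Y: np.ndarray,
    mu_hat: np.ndarray,
    marginal_alpha: float = 0.10,
) -> np.ndarray:
    """Adaptive-sum sign vector: -1 for marginally significant protective variants.

    Each variant receives a single-marker score test; variants whose test is
    significant at ``marginal_alpha`` *and* enriched in controls (negative
    score) are flagged protective and weighted -1 in the burden score.
    """
    if not 0.0 < marginal_alpha < 1.0:
        raise ValueError("marginal_alpha must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    resid = Y - mu_hat
    U = X.T @ resid
    ssq_y = float(resid @ resid)
    Xc = X - X.mean(axis=0)
    V = ssq_y * (Xc * Xc).sum(axis=0) / (n - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    pvals = stats.chi2.sf(Q, df=1)
    signs = np.ones(X.shape[1])
    signs[(pvals < marginal_alpha) & (U < 0)] = -1.0
    return signs


@dataclass
class MultiSiteGenotypeTable:
    """Distinct multi-site genotype classes with case/control counts."""

    class_index: np.ndarray  # (N,) class id per individual
    n_cases: np.ndarray  # (L+1,) count of each class among cases
    n_controls: np.ndarray  # (L+1,)
    weights: np.ndarray  # (L+1,) hypergeometric upper-tail weights
    is_wildtype: np.ndarray  # (L+1,) bool, True for the all-zero genotype


def kbac_statistic(
    X: np.ndarray, Y: np.ndarray, exclude_wildtype: bool = False
) -> tuple[float, MultiSiteGenotypeTable]:
    """KBAC statistic with hypergeometric kernel weights.

    Individuals are grouped by their full multi-site genotype vector.  Each
    class l is weighted by the upper-tail hypergeometric probability
    P(H >= n_l^1) with H ~ Hypergeometric(N, N_l, N1), and the statistic is
    the squared weighted sum of case/control frequency differences over all
    classes (including the wild-type class by default, as the formula
    prints; ``exclude_wildtype`` restricts the sum to carrier classes).
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    n1 = int(Y.sum())
    n0 = int(Y.size - n1)
    if n1 < 1 or n0 < 1:
        raise ValueError("KBAC requires at least one case and one control")
    _, inv = np.unique(X, axis=0, return_inverse=True)
    L1 = int(inv.max()) + 1
    n_tot = np.bincount(inv, minlength=L1).astype(np.int64)
    n_case = np.bincount(inv, weights=Y, minlength=L1).astype(np.int64)
    n_ctrl = n_tot - n_case
    w = stats.hypergeom.sf(n_case - 1, Y.size, n_tot, n1)
    wild = np.array([not X[np.flatnonzero(inv == l)[0]].any() for l in range(L1)])
    use = ~wild if exclude_wildtype else np.ones(L1, dtype=bool)
    diff = n_case / n1 - n_ctrl / n0
    stat = float((w[use] * diff[use]).sum() ** 2)
    table = MultiSiteGenotypeTable(
        class_index=inv, n_cases=n_case, n_controls=n_ctrl, weights=w, is_wildtype=wild
    )
    return stat, table


def skat_Q(
    X: np.ndarray,
    Y: np.ndarray,
    mu_hat: np.ndarray,
    weights: np.ndarray,
    rho: float = 0.0,
) -> float:
    """SKAT-family quadratic form Q_rho = (Y-mu)' X W R_rho W X' (Y-mu)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    resid = np.asarray(Y, dtype=float) - np.asarray(mu_hat, dtype=float)
    s = np.asarray(weights, dtype=float) * (X.T @ resid)
    return float((1.0 - rho) * (s @ s) + rho * s.sum() ** 2)


@dataclass
class PositionKernel:
    """Triangular position-proximity matrix with tolerance radius (bp)."""

    A: np.ndarray
    radius: float


def podkat_kernel(positions: np.ndarray, radius: float = 1_000.0) -> PositionKernel:
    """PODKAT proximity matrix A_jj' = max(1 - d_jj'/radius, 0)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = np.asarray(positions, dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    A = np.clip(1.0 - d / radius, 0.0, None)
    return PositionKernel(A=A, radius=radius)


def podkat_Q(
    X: np.ndarray,
    Y: np.ndarray,
    mu_hat: np.ndarray,
    weights: np.ndarray,
    kernel: PositionKernel,
) -> float:
    """PODKAT statistic Q = (Y-mu)' X W A A' W X' (Y-mu) = ||A' W X'(Y-mu)||^2."""
    X = np.asarray(X, dtype=float)
    if kernel.A.shape[0] != X.shape[1]:
        raise ValueError("kernel dimension must equal the number of variants")
    resid = np.asarray(Y, dtype=float) - np.asarray(mu_hat, dtype=float)
    s = np.asarray(weights, dtype=float) * (X.T @ resid)
    u = kernel.A.T @ s
    return float(u @ u)


# ---------------------------------------------------------------------------
# DoEstRare


def silverman_bandwidth(positions: np.ndarray, counts: np.ndarray) -> float:
    """Silverman's rule on the allele-position sample (positions weighted by
    allele counts).  Falls back to 1 bp for degenerate samples."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 1:
        return 1.0
    mean = (counts * positions).sum() / total
    var = (counts * (positions - mean) ** 2).sum() / max(total - 1.0, 1.0)
    sd = np.sqrt(var)
    if sd <= 0:
        return 1.0
    return float(0.9 * sd * total ** (-0.2))


@dataclass
class DoEstRarePrecompute:
    """Quantities reused across permutations of the DoEstRare statistic."""

    grid: np.ndarray
    density_cols: np.ndarray  # (grid, P) per-variant Gaussian kernel columns
    allele_totals: np.ndarray  # (P,) total minor-allele count per variant
    n_cases: int
    n_controls: int


def doestrare_precompute(
    X: np.ndarray,
    Y: np.ndarray,
    positions: np.ndarray,
    gene_length: float,
    bandwidth: float | None = None,
    grid_points: int = 1_024,
) -> DoEstRarePrecompute:
    pos = np.asarray(positions, dtype=float)
    if gene_length < pos.max(initial=1.0):
        raise ValueError("gene_length must cover every variant position")
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=0)
    if bandwidth is None:
        # Pooled-sample bandwidth: permutation-invariant by construction.
        bandwidth = silverman_bandwidth(pos, totals)
    grid = np.linspace(1.0, float(gene_length), grid_points)
    z = (grid[:, None] - pos[None, :]) / bandwidth
    cols = np.exp(-0.5 * z * z) / (bandwidth * np.sqrt(2.0 * np.pi))
    n1 = int(np.asarray(Y).sum())
    return DoEstRarePrecompute(
        grid=grid,
        density_cols=cols,
        allele_totals=totals,
        n_cases=n1,
        n_controls=int(np.asarray(Y).size - n1),
    )


def _doestrare_from_counts(
    pre: DoEstRarePrecompute, m1: np.ndarray, m0: np.ndarray
) -> float:
    n1, n0 = pre.n_cases, pre.n_controls
    maf0 = (m0 + 1.0) / (2.0 * n0 + 2.0)
    w = stats.binom.cdf(m1, 2 * n1, maf0)
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    p1 = float((w * m1).sum() / (2.0 * n1) / wsum)
    p0 = float((w * m0).sum() / (2.0 * n0) / wsum)
    t1 = m1.sum()
    t0 = m0.sum()
    f1 = pre.density_cols @ m1 / t1 if t1 > 0 else np.zeros_like(pre.grid)
    f0 = pre.density_cols @ m0 / t0 if t0 > 0 else np.zeros_like(pre.grid)
    return float(np.trapezoid(np.abs(p1 * f1 - p0 * f0), pre.grid))


def doestrare_statistic(
    X: np.ndarray,
    Y: np.ndarray,
    positions: np.ndarray,
    gene_length: float,
    bandwidth: float | None = None,
    grid_points: int = 1_024,
) -> float:
    """DoEstRare statistic: integral over the gene of
    ``|p1 f1(pos) - p0 f0(pos)|``.

    ``f1``/``f0`` are Gaussian kernel density estimates of the rare-allele
    position distributions of cases and controls; ``p1``/``p0`` are the
    binomial-tail-weighted average allele frequencies.  A group carrying no
    rare allele contributes the zero function.
    """
    pre = doestrare_precompute(X, Y, positions, gene_length, bandwidth, grid_points)
    Y = np.asarray(Y, dtype=float)
    Xf = np.asarray(X, dtype=float)
    m1 = Xf.T @ Y
    m0 = pre.allele_totals - m1
    return _doestrare_from_counts(pre, m1, m0)
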