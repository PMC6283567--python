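"""Population-structure estimation on common variants.

LD pruning, ancestry-style principal component analysis, and the
Weir & Cockerham (1984) multi-locus fixation index for two populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "FstEstimate", "ld_prune", "pca_genotypes", "wc_fst"]

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Principal components of a genotype matrix.

    ``coordinates`` are per-individual scores (N x K), mean-zero per
    component; ``eigenvalues`` non-increasing; ``loadings`` per-variant
    weights (P_used x K); ``variants_used`` indexes into the input columns.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    variants_used: np.ndarray


@dataclass
class FstEstimate:
    """Weir-Cockerham theta with its ratio-of-sums components."""

    theta: float
    sum_a: float
    sum_abc: float
    n_loci: int


def ld_prune(
    G: np.ndarray,
    ref_maf: np.ndarray | None = None,
    maf_min: float = 0.05,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept column indices.

    Variants failing ``maf_min`` (on ``ref_maf`` when given, else on the
    sample frequency of ``G``) are removed first.  Within each window of
    ``window`` surviving variants, pairs with squared Pearson correlation at
    or above ``r2_max`` are resolved by dropping the lower-MAF member; the
    window then slides by ``step``.
    """
    G = np.asarray(G, dtype=np.float64)
    n, p = G.shape
    if ref_maf is None:
        f = G.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
    else:
        maf = np.asarray(ref_maf, dtype=float)
        if maf.shape[0] != p:
            raise ValueError("ref_maf length must match variant count")
    candidates = np.flatnonzero(maf >= maf_min)
    keep = np.ones(candidates.size, dtype=bool)
    sd = G[:, candidates].std(axis=0)
    keep &= sd > 0  # monomorphic-in-sample columns carry no LD information

    start = 0
    while start < candidates.size:
        live = np.flatnonzero(keep[start : start + window]) + start
        if live.size > 1:
            sub = G[:, candidates[live]]
            r = np.corrcoef(sub, rowvar=False)
            r2 = r * r
            for ii in range(live.size):
                if not keep[live[ii]]:
                    continue
                for jj in range(ii + 1, live.size):
                    if not keep[live[jj]]:
                        continue
                    if r2[ii, jj] >= r2_max:
                        # drop the lower-MAF member of the conflicting pair
                        if maf[candidates[live[ii]]] >= maf[candidates[live[jj]]]:
                            keep[live[jj]] = False
                        else:
                            keep[live[ii]] = False
                            break
        if start + window >= candidates.size:
            break
        start += step
    return candidates[keep]


def pca_genotypes(G: np.ndarray, K: int = 2) -> PCAResult:
    """Ancestry PCA of a genotype matrix (individuals x variants).

    Columns are centered by twice the sample allele frequency and scaled by
    the binomial standard deviation sqrt(2 p (1-p)), the normalization used
    by ancestry-PCA programs.  Monomorphic columns are dropped (logged).
    The sign of each component is fixed so its largest-magnitude loading is
    positive.
    """
    G = np.asarray(G, dtype=np.float64)
    n, p = G.shape
    if n < K + 1 or p < K:
        raise ValueError("not enough individuals or variants for the requested K")
    freq = G.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    if not poly.all():
        log.info("pca_genotypes: dropping %d monomorphic columns", (~poly).sum())
    used = np.flatnonzero(poly)
    if used.size < K:
        raise ValueError("fewer polymorphic variants than requested components")
    f = freq[used]
    M = (G[:, used] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    M -= M.mean(axis=0)  # guard: exact column centering
    if min(M.shape) > 400 and K < min(M.shape) - 1:
        # truncated SVD for large panels; fixed start vector keeps the
        # decomposition deterministic
        from scipy.sparse.linalg import svds

        U, S, Vt = svds(M, k=K, v0=np.ones(M.shape[1]) / np.sqrt(M.shape[1]))
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order]
    else:
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
    coords = U[:, :K] * S[:K]
    loadings = Vt[:K].T
    # deterministic sign: largest |loading| positive per component
    for k in range(K):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            coords[:, k] = -coords[:, k]
    eigenvalues = (S[:K] ** 2) / (n - 1)
    return PCAResult(
        coordinates=coords,
        eigenvalues=eigenvalues,
        loadings=loadings,
        variants_used=used,
    )


def wc_fst(G: np.ndarray, pop_labels: np.ndarray) -> FstEstimate:
    """Weir & Cockerham (1984) theta for two populations from genotypes.

    Per-locus variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are computed
    from genotype counts, and aggregated as the ratio of sums
    ``theta = sum(a) / sum(a + b + c)`` across loci.
    """
    G = np.asarray(G, dtype=np.float64)
    labels = np.asarray(pop_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two populations are required")
    masks = [labels == g for g in groups]
    ns = np.array([m.sum() for m in masks], dtype=float)
    if (ns < 2).any():
        raise ValueError("each population needs at least two individuals")

    r = 2.0
    n1, n2 = ns
    ga, gb = G[masks[0]], G[masks[1]]
    p1 = ga.mean(axis=0) / 2.0
    p2 = gb.mean(axis=0) / 2.0
    h1 = (ga == 1).mean(axis=0)  # observed heterozygosity
    h2 = (gb == 1).mean(axis=0)

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    sum_a = float(a[poly].sum())
    sum_abc = float((a + b + c)[poly].sum())
    if poly.sum() == 0 or sum_abc == 0.0:
        raise ValueError("F_ST undefined: no polymorphic loci")
    return FstEstimate(
        theta=sum_a / sum_abc, sum_a=sum_a, sum_abc=sum_abc, n_loci=int(poly.sum())
    )
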