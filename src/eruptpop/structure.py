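"""Between-population differentiation: Weir-Cockerham FST, genotype PCA,
and binomial-mixture admixture estimation by EM.

FST follows Weir & Cockerham (1984): per-site variance components a
(between populations), b (between individuals within populations) and c
(within individuals), combined multi-locus as a ratio of sums.  Negative
estimates are admissible and preserved.  A Hudson-style estimator is
included as a cross-check, not as the default.

PCA uses Patterson normalisation (centre by 2p, scale by sqrt(2p(1-p)))
with mean imputation of missing dosages after centring; the sign of each
axis is fixed by making its largest-magnitude loading positive.

Admixture maximises sum_ij log Binomial(g_ij | 2, sum_k q_ik p_jk) by plain
EM block updates from multiple random starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.special import xlogy

from .genio import MISSING, GenotypeMatrix

_EPS = 1e-9


# -- Weir-Cockerham FST ------------------------------------------------------


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham (1984) variance components a, b, c.

    Parameters are per-site arrays over r populations (last axis):
    sample sizes in individuals ``n``, alt-allele frequencies ``p`` and
    observed heterozygote proportions ``h``.  Shapes broadcast as
    ``(..., r)``; returns arrays of shape ``(...,)``.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[-1]
    if r < 2:
        raise ValueError("need >= 2 populations")
    nbar = n.mean(axis=-1)
    nsum = n.sum(axis=-1)
    nc = (nsum - (n**2).sum(axis=-1) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=-1) / nsum
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=-1) / nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


@dataclass
class FstResult:
    fst: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_site_fst: np.ndarray
    site_ids: list[str]


def weir_cockerham_fst(matrix: GenotypeMatrix, pop_labels) -> FstResult:
    """Multi-locus Weir-Cockerham FST with per-site components.

    ``pop_labels`` assigns each sample (row) to a population; sites are
    analysed when every population has >= 2 called individuals there.
    The multi-locus estimate is the ratio of sums sum(a)/sum(a+b+c).
    """
    labels = np.asarray(list(pop_labels))
    if len(labels) != matrix.n_samples:
        raise ValueError("pop_labels length must match samples")
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    d = matrix.dosages
    n = np.empty((matrix.n_sites, len(pops)))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for k, pop in enumerate(pops):
        sub = d[labels == pop]
        called = sub != MISSING
        nk = called.sum(axis=0).astype(float)
        n[:, k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(nk > 0, np.where(called, sub, 0).sum(axis=0) / (2 * nk), np.nan)
            h[:, k] = np.where(nk > 0, ((sub == 1) & called).sum(axis=0) / nk, np.nan)
    usable = (n >= 2).all(axis=1)
    if not usable.any():
        raise ValueError("no site with >= 2 called individuals in every population")
    a, b, c = wc_components(n[usable], p[usable], h[usable])
    denom = a + b + c
    total = denom.sum()
    if total == 0:
        raise ValueError("no variance at analyzable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom != 0, a / denom, np.nan)
    ids = [sid for sid, u in zip(matrix.site_ids, usable) if u]
    return FstResult(
        fst=float(a.sum() / total), a=a, b=b, c=c, per_site_fst=per_site, site_ids=ids
    )


def hudson_fst(matrix: GenotypeMatrix, pop_labels) -> float:
    """Hudson (1992) two-population FST, ratio-of-sums; cross-check estimator."""
    labels = np.asarray(list(pop_labels))
    pops = sorted(set(labels))
    if len(pops) != 2:
        raise ValueError("Hudson estimator is two-population")
    num_sum = den_sum = 0.0
    stats = []
    for pop in pops:
        sub = matrix.dosages[labels == pop]
        called = sub != MISSING
        nk = 2 * called.sum(axis=0).astype(float)
        ak = np.where(called, sub, 0).sum(axis=0).astype(float)
        stats.append((nk, ak))
    (n1, a1), (n2, a2) = stats
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2 = a1[ok] / n1[ok], a2[ok] / n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1[ok] - 1) - p2 * (1 - p2) / (n2[ok] - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num_sum, den_sum = num.sum(), den.sum()
    if den_sum == 0:
        raise ValueError("no between-population diversity")
    return float(num_sum / den_sum)


# -- PCA ---------------------------------------------------------------------


@dataclass
class PcaResult:
    coordinates: np.ndarray  # (individuals, axes)
    explained_variance: np.ndarray
    loadings: np.ndarray  # (sites, axes)
    sample_ids: list[str]


def pca_genotypes(matrix: GenotypeMatrix, n_axes: int = 10) -> PcaResult:
    """Genotype PCA with Patterson normalisation.

    Columns are centred by 2p and scaled by sqrt(2p(1-p)); missing dosages
    are mean-imputed (zero after centring).  Eigendecomposition of the
    individual x individual covariance; deterministic up to the sign fix.
    """
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 individuals")
    d = matrix.dosages.astype(float)
    called = matrix.dosages != MISSING
    alt, tot = matrix.allele_counts()
    poly = (alt > 0) & (alt < tot) & (tot >= 2)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic sites")
    d = d[:, poly]
    called = called[:, poly]
    p = alt[poly] / tot[poly].astype(float)
    x = np.where(called, d, 2 * p[None, :]) - 2 * p[None, :]
    x /= np.sqrt(2 * p * (1 - p))[None, :]
    m = x.shape[1]
    cov = x @ x.T / m
    w, v = eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(n_axes, matrix.n_samples - 1)
    w, v = np.clip(w[:k], 0, None), v[:, :k]
    coords = v * np.sqrt(np.maximum(w, 0))[None, :]
    loadings = x.T @ v
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
            v[:, j] *= -1
    return PcaResult(
        coordinates=coords,
        explained_variance=w,
        loadings=loadings,
        sample_ids=list(matrix.sample_ids),
    )


# -- admixture EM ------------------------------------------------------------


@dataclass
class AdmixtureFit:
    Q: np.ndarray  # (individuals, K) ancestry fractions
    P: np.ndarray  # (sites, K) ancestral allele frequencies
    loglik_trace: np.ndarray
    converged: bool
    K: int
    sample_ids: list[str]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _admixture_loglik(g, mask, Q, P) -> float:
    f = np.clip(Q @ P.T, _EPS, 1 - _EPS)
    ll = xlogy(g, f) + xlogy(2 - g, 1 - f) + np.where(g == 1, np.log(2.0), 0.0)
    return float(np.where(mask, ll, 0.0).sum())


def admixture_em(
    matrix: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    n_starts: int = 10,
) -> AdmixtureFit:
    """Binomial-mixture admixture fit (ancestry fractions Q, ancestral
    frequencies P) by EM from ``n_starts`` random starts; best kept.

    The log-likelihood trace of the kept run is non-decreasing; convergence
    is declared when the per-iteration gain drops below ``tol``.
    """
    if not (1 <= K <= matrix.n_samples):
        raise ValueError("K must satisfy 1 <= K <= individuals")
    g = matrix.dosages.astype(float)
    mask = matrix.dosages != MISSING
    g = np.where(mask, g, 0.0)
    l_i = mask.sum(axis=1).astype(float)
    if (l_i == 0).any():
        raise ValueError("individual with no called genotypes")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_starts if K > 1 else 1)):
        Q = rng.dirichlet(np.ones(K), size=matrix.n_samples)
        P = rng.uniform(0.05, 0.95, size=(matrix.n_sites, K))
        trace = [_admixture_loglik(g, mask, Q, P)]
        converged = False
        for _it in range(max_iter):
            F = np.clip(Q @ P.T, _EPS, 1 - _EPS)
            A = np.where(mask, g / F, 0.0)
            B = np.where(mask, (2.0 - g) / (1.0 - F), 0.0)
            # expected allele-origin counts
            Q_new = Q * (A @ P + B @ (1.0 - P)) / (2.0 * l_i[:, None])
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            a_jk = P * (A.T @ Q)
            b_jk = (1.0 - P) * (B.T @ Q)
            P_new = np.clip(a_jk / np.clip(a_jk + b_jk, _EPS, None), _EPS, 1 - _EPS)
            Q, P = Q_new, P_new
            trace.append(_admixture_loglik(g, mask, Q, P))
            if trace[-1] - trace[-2] < tol:
                converged = True
                break
        fit = AdmixtureFit(
            Q=Q, P=P, loglik_trace=np.asarray(trace), converged=converged,
            K=K, sample_ids=list(matrix.sample_ids),
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best
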