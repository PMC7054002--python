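"""Phylogenetic signal: Pagel's λ, Blomberg's K, and multivariate K_mult.

All three statistics ask how much of the variation among species tracks
the phylogeny, against the benchmark of Brownian motion (BM) along the
tree:

* λ scales the expected between-species covariances: λ=0 is a star
  phylogeny (no signal), λ=1 the full BM structure.  It is estimated by
  maximising the multivariate-normal likelihood of the tip values, with
  the phylogenetic mean and the BM rate profiled out analytically so the
  search is one-dimensional; significance comes from a likelihood-ratio
  test against λ=0.
* K compares the observed ratio of trait variance to
  phylogenetically-whitened variance against its BM expectation, so
  K ≈ 1 under BM, K < 1 when close relatives resemble each other less
  than expected, and K > 1 when variance accumulates among clades.
* K_mult is the multivariate generalisation (Euclidean norms in trait
  space take the place of squares) and reduces exactly to K at p=1.
  K and K_mult are tested by permuting values across tips.

Estimates operate on one value (or vector) per tip — species means in the
reference design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .trees import PhyloCov, PhyloTree, lambda_transform

__all__ = [
    "SignalResult",
    "pagel_lambda",
    "blomberg_k",
    "k_mult",
    "permutation_test",
]


@dataclass
class SignalResult:
    """A phylogenetic-signal estimate with its significance test."""

    statistic: str  # "lambda" | "K" | "Kmult"
    estimate: float
    pvalue: float | None = None
    loglik: float | None = None  # at the optimum (lambda only)
    loglik0: float | None = None  # at lambda = 0 (lambda only)
    n_perm: int | None = None
    seed: int | None = None
    n: int | None = None

    def summary(self) -> str:
        name = {"lambda": "Pagel's lambda", "K": "Blomberg's K", "Kmult": "K_mult"}[
            self.statistic
        ]
        s = f"{name} = {self.estimate:.4f}"
        if self.pvalue is not None:
            s += f"  (p = {self.pvalue:.4g}"
            if self.n_perm:
                s += f", {self.n_perm} permutations, seed {self.seed}"
            s += ")"
        if self.loglik is not None:
            s += f"  [lnL = {self.loglik:.3f}, lnL(lambda=0) = {self.loglik0:.3f}]"
        return s


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _align(tree_or_cov, values) -> tuple[PhyloCov, np.ndarray, list[str]]:
    """Order tip values against the tree's covariance matrix."""
    if isinstance(values, pd.Series):
        taxa = list(values.index)
        y = values.to_numpy(dtype=float)
    elif isinstance(values, dict):
        taxa = list(values)
        y = np.array([values[t] for t in taxa], dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        taxa = None
    if isinstance(tree_or_cov, PhyloTree):
        C = tree_or_cov.covariance(taxa)
    else:
        C = tree_or_cov if taxa is None else tree_or_cov.reorder(taxa)
    if taxa is None:
        taxa = list(C.taxa)
    if len(y) != len(C.taxa):
        raise ValueError(f"{len(y)} values for {len(C.taxa)} tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite tip values")
    return C, y, taxa


def _chol(C: np.ndarray) -> np.ndarray:
    """Cholesky factor with a single jitter retry on failure."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C) / C.shape[0]
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


def _profile_loglik(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile MVN log-likelihood with mean a*1 and covariance s2*C.

    Returns (loglik, a_hat, s2_hat); the phylogenetic mean and the BM rate
    are profiled in closed form.
    """
    n = len(y)
    L = _chol(C)
    ones = np.ones(n)
    w = np.linalg.solve(L, ones)
    z = np.linalg.solve(L, y)
    denom = w @ w  # 1' C^-1 1
    a_hat = (w @ z) / denom
    r = z - a_hat * w
    s2 = (r @ r) / n
    if s2 <= 0 or not np.isfinite(s2):
        raise ValueError("zero variance: trait is constant across tips")
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(ll), float(a_hat), float(s2)


def gls_mean(C: PhyloCov | np.ndarray, y: np.ndarray) -> float:
    """Phylogenetic (GLS) mean of tip values: the BM root-state estimate."""
    M = C.matrix if isinstance(C, PhyloCov) else np.asarray(C, float)
    L = _chol(M)
    w = np.linalg.solve(L, np.ones(len(y)))
    z = np.linalg.solve(L, np.asarray(y, float))
    return float((w @ z) / (w @ w))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def pagel_lambda(
    tree: PhyloTree | PhyloCov,
    tip_values,
    xtol: float = 1e-6,
) -> SignalResult:
    """Maximum-likelihood Pagel's λ on [0, 1] with a likelihood-ratio p-value.

    The MVN likelihood of the tip values under covariance σ²·C(λ) is
    profiled over the phylogenetic mean and rate, leaving a bounded scalar
    search in λ; endpoints are checked explicitly so boundary optima
    (λ̂ = 0 or 1) are exact.  p is the χ²(1 df) tail of the likelihood
    ratio against λ = 0.
    """
    C, y, _ = _align(tree, tip_values)
    if len(y) < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: trait is constant across tips")

    def nll(lam: float) -> float:
        return -_profile_loglik(lambda_transform(C, lam).matrix, y)[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": xtol})
    candidates = [(0.0, -nll(0.0)), (1.0, -nll(1.0)), (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = -nll(0.0)
    if not np.isfinite(ll_hat):
        raise ValueError("non-finite likelihood")
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        statistic="lambda",
        estimate=lam_hat,
        pvalue=p,
        loglik=ll_hat,
        loglik0=ll0,
        n=len(y),
    )


def _k_stat(Cinv: np.ndarray, trC: float, y: np.ndarray) -> float:
    """Blomberg's K given a precomputed C^-1 (vectorised over permutations)."""
    n = y.shape[-1]
    ones = np.ones(n)
    s1 = ones @ Cinv @ ones
    Cy = y @ Cinv  # works for 1-d and (B, n)
    a = (Cy @ ones) / s1
    if y.ndim == 1:
        r = y - a
        num = r @ r
        den = y @ Cy - 2 * a * (Cy @ ones) + a**2 * s1
    else:
        r = y - a[:, None]
        num = (r * r).sum(axis=1)
        den = (y * Cy).sum(axis=1) - 2 * a * (Cy @ ones) + a**2 * s1
    expectation = (trC - n / s1) / (n - 1)
    return (num / den) / expectation


def blomberg_k(
    tree: PhyloTree | PhyloCov,
    tip_values,
    n_perm: int | None = None,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K; a tip-permutation p-value is attached when requested.

    K = [(y-â1)'(y-â1) / (y-â1)'C⁻¹(y-â1)] / [(tr C - n/(1'C⁻¹1)) / (n-1)]
    with â the phylogenetic GLS mean.
    """
    C, y, _ = _align(tree, tip_values)
    if len(y) < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: trait is constant across tips")
    Cinv = _inv(C.matrix)
    k = float(_k_stat(Cinv, float(np.trace(C.matrix)), y))
    result = SignalResult(statistic="K", estimate=k, n=len(y))
    if n_perm is not None:
        result.pvalue = permutation_test("K", C, y, n_perm=n_perm, seed=seed)
        result.n_perm, result.seed = n_perm, seed
    return result


def _inv(C: np.ndarray) -> np.ndarray:
    L = _chol(C)
    Linv = np.linalg.solve(L, np.eye(C.shape[0]))
    return Linv.T @ Linv


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() <= 0:
        raise ValueError("rank-deficient covariance matrix")
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def _kmult_stat(
    Cinv: np.ndarray, Cinv_sqrt: np.ndarray, trC: float, Y: np.ndarray
) -> float:
    """K_mult for an (n, p) tip matrix with precomputed factors of C."""
    n = Y.shape[0]
    ones = np.ones(n)
    s1 = ones @ Cinv @ ones
    a = (ones @ Cinv @ Y) / s1  # phylogenetic mean vector, length p
    R = Y - a
    num = (R * R).sum()
    Z = Cinv_sqrt @ R
    den = (Z * Z).sum()
    expectation = (trC - n / s1) / (n - 1)
    return float((num / den) / expectation)


def k_mult(
    tree: PhyloTree | PhyloCov,
    tip_matrix,
    n_perm: int | None = None,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal K_mult (reduces to K at p=1).

    Numerator: summed squared Euclidean distances of tip vectors to the
    phylogenetic mean vector.  Denominator: the same after premultiplying
    the centred tip matrix by the inverse square root of C (from its
    eigendecomposition).  The ratio is divided by the univariate BM
    expectation term.
    """
    if isinstance(tip_matrix, pd.DataFrame):
        values = pd.Series(range(len(tip_matrix)), index=tip_matrix.index)
        C, _, taxa = _align(tree, values)
        Y = tip_matrix.to_numpy(dtype=float)
    else:
        Y = np.asarray(tip_matrix, dtype=float)
        C = tree.covariance() if isinstance(tree, PhyloTree) else tree
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != len(C.taxa):
        raise ValueError(f"{Y.shape[0]} rows for {len(C.taxa)} tips")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 tips")
    Cinv = _inv(C.matrix)
    Cinv_sqrt = _inv_sqrt(C.matrix)
    k = _kmult_stat(Cinv, Cinv_sqrt, float(np.trace(C.matrix)), Y)
    result = SignalResult(statistic="Kmult", estimate=k, n=Y.shape[0])
    if n_perm is not None:
        result.pvalue = permutation_test("Kmult", C, Y, n_perm=n_perm, seed=seed)
        result.n_perm, result.seed = n_perm, seed
    return result


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    stat: str,
    tree: PhyloTree | PhyloCov,
    data,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Tip-permutation p-value for K or K_mult.

    Values are shuffled across tips n_perm times with the given seed and
    p = (1 + #{permuted >= observed}) / (n_perm + 1).  Deterministic given
    the seed; n_perm < 99 is refused (resolution floor of ~0.01).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    C = tree.covariance() if isinstance(tree, PhyloTree) else tree
    rng = np.random.default_rng(seed)
    Cinv = _inv(C.matrix)
    trC = float(np.trace(C.matrix))
    if stat == "K":
        if isinstance(data, pd.Series):
            data = data.reindex(C.taxa).to_numpy(dtype=float)
        y = np.asarray(data, dtype=float)
        obs = float(_k_stat(Cinv, trC, y))
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        stats_perm = _k_stat(Cinv, trC, perms)
    elif stat == "Kmult":
        Y = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Cinv_sqrt = _inv_sqrt(C.matrix)
        obs = _kmult_stat(Cinv, Cinv_sqrt, trC, Y)
        stats_perm = np.array(
            [
                _kmult_stat(Cinv, Cinv_sqrt, trC, Y[rng.permutation(Y.shape[0])])
                for _ in range(n_perm)
            ]
        )
    else:
        raise ValueError("stat must be 'K' or 'Kmult'")
    return float((1 + np.sum(stats_perm >= obs)) / (n_perm + 1))
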