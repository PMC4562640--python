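"""Phylogenetic-signal statistics and distance-matrix (Mantel) tests.

Three complementary per-trait statistics:

* **Blomberg's K** — ratio of the observed mean-squared trait deviation to
  its phylogenetically expected counterpart, scaled so K = 1 under
  Brownian motion; K < 1 means less resemblance among relatives than BM
  predicts, K > 1 more.  Significance by tip-shuffling randomisation.
* **Pagel's λ** — the multiplier on the shared-history (off-diagonal)
  entries of the BM covariance that maximises the Gaussian likelihood;
  λ = 0 is a star phylogeny, λ = 1 is BM.  Significance by a likelihood
  ratio test against λ = 0.
* **Moran's I** — spatial-autocorrelation statistic with phylogenetic
  proximity weights (here 1/patristic distance); expectation −1/(n−1)
  under randomisation.

Mantel tests ask the matrix-level question: are pairwise patristic
distances correlated with pairwise trait distances?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloTree, transform_covariance

__all__ = [
    "SignalResult",
    "MantelResult",
    "blomberg_k",
    "blomberg_k_pvalue",
    "pagel_lambda_ml",
    "moran_i",
    "euclidean_trait_distance",
    "mantel_test",
    "phylo_signal",
]


@dataclass(frozen=True)
class SignalResult:
    trait_name: str
    n: int
    k_stat: float
    p_k: float
    lambda_hat: float
    p_lambda: float
    moran_i: float
    p_i: float
    n_rand: int
    seed: Optional[int]


@dataclass(frozen=True)
class MantelResult:
    trait_name: str
    z_stat: float
    p: float
    n_perm: int
    seed: Optional[int]


def _align(tree: PhyloTree, x) -> np.ndarray:
    """Trait values in the tree's tip order; requires data for every tip."""
    if isinstance(x, pd.Series):
        missing = set(tree.tip_labels) - set(x.index)
        if missing:
            raise KeyError(f"no trait value for tips: {sorted(missing)}")
        v = x.reindex(tree.tip_labels).to_numpy(dtype=float)
    else:
        v = np.asarray(x, dtype=float)
        if v.shape != (tree.n_tips,):
            raise ValueError("trait vector length does not match number of tips")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite trait value")
    return v


def _check_variance(v: np.ndarray) -> None:
    if v.size < 3:
        raise ValueError("need at least 3 species with data")
    if np.allclose(v, v[0]):
        raise ValueError("trait is constant: signal undefined")


# ---------------------------------------------------------------------------
# Blomberg's K


def _k_from_cov(v: np.ndarray, cinv: np.ndarray, tr_c: float) -> float:
    n = v.size
    one = np.ones(n)
    denom = one @ cinv @ one
    ahat = (one @ cinv @ v) / denom
    dev = v - ahat
    mse0 = (dev @ dev) / (n - 1)
    mse = (dev @ cinv @ dev) / (n - 1)
    expected = (tr_c - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(tree: PhyloTree, x) -> float:
    """Blomberg's K for a continuous trait on a rooted tree."""
    v = _align(tree, x)
    _check_variance(v)
    c = tree.covariance().to_numpy()
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    return _k_from_cov(v, cinv, float(np.trace(c)))


def blomberg_k_pvalue(
    tree: PhyloTree, x, n_rand: int = 999, seed: Optional[int] = None
) -> tuple[float, float]:
    """(K, one-tailed randomisation p) — tip values shuffled across tips.

    p = (1 + #{K_perm >= K_obs}) / (n_rand + 1); small p means relatives
    resemble each other more than random placement allows.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    v = _align(tree, x)
    _check_variance(v)
    c = tree.covariance().to_numpy()
    cinv = np.linalg.inv(c)
    tr_c = float(np.trace(c))
    k_obs = _k_from_cov(v, cinv, tr_c)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        if _k_from_cov(rng.permutation(v), cinv, tr_c) >= k_obs:
            hits += 1
    return k_obs, (1 + hits) / (n_rand + 1)


# ---------------------------------------------------------------------------
# Pagel's λ by profile maximum likelihood


def _profile_loglik_lambda(v: np.ndarray, c: pd.DataFrame, lam: float) -> float:
    from .models import gls_profile_loglik  # local import avoids cycle at import time

    cl = transform_covariance(c, "lambda", lam) if lam != 1.0 else c
    try:
        ll, _, _ = gls_profile_loglik(v, cl.to_numpy())
    except np.linalg.LinAlgError:
        return -np.inf
    return ll


def pagel_lambda_ml(tree: PhyloTree, x) -> tuple[float, float, float]:
    """ML estimate of Pagel's λ with an LRT against λ = 0.

    Returns (lambda_hat, loglik, p_lambda).  The profile likelihood over
    λ ∈ [0, 1] (mean and rate profiled analytically by GLS) is scanned on
    a grid and refined by bounded scalar optimisation; the p-value is the
    upper χ²₁ tail of 2·(ℓ(λ̂) − ℓ(0)), set to 1 when λ̂ = 0.
    """
    v = _align(tree, x)
    _check_variance(v)
    c = tree.covariance()

    grid = np.linspace(0.0, 1.0, 51)
    lls = np.array([_profile_loglik_lambda(v, c, g) for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_loglik_lambda(v, c, g),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat, ll_hat = float(res.x), float(-res.fun)
    # keep the grid point if refinement did not beat it
    if lls[i] > ll_hat:
        lam_hat, ll_hat = float(grid[i]), float(lls[i])
    if abs(lam_hat) < 1e-8:
        lam_hat = 0.0
    ll0 = _profile_loglik_lambda(v, c, 0.0)
    lr = max(2.0 * (ll_hat - ll0), 0.0)
    p = 1.0 if lam_hat == 0.0 else float(stats.chi2.sf(lr, df=1))
    return lam_hat, ll_hat, min(max(p, np.nextafter(0, 1)), 1.0)


# ---------------------------------------------------------------------------
# Moran's I with inverse-patristic-distance weights


def _moran_stat(v: np.ndarray, w: np.ndarray) -> float:
    n = v.size
    dev = v - v.mean()
    num = dev @ w @ dev
    den = dev @ dev
    return float(n / w.sum() * num / den)


def moran_i(
    tree: PhyloTree, x, n_rand: int = 999, seed: Optional[int] = None
) -> tuple[float, float]:
    """Moran's I with weights w[i,j] = 1/PD[i,j] and a one-tailed
    randomisation test for positive phylogenetic autocorrelation."""
    v = _align(tree, x)
    _check_variance(v)
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    d = tree.cophenetic_distances().to_numpy()
    off = ~np.eye(len(v), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("zero patristic distance between distinct tips")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    i_obs = _moran_stat(v, w)
    rng = np.random.default_rng(seed)
    hits = sum(_moran_stat(rng.permutation(v), w) >= i_obs for _ in range(n_rand))
    return i_obs, (1 + hits) / (n_rand + 1)


# ---------------------------------------------------------------------------
# distance matrices and the Mantel test


def euclidean_trait_distance(x: pd.Series) -> pd.DataFrame:
    """|x_i − x_j| for a single trait, as a labelled symmetric matrix."""
    v = x.to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite trait value")
    d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=x.index, columns=x.index)


def mantel_test(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    n_perm: int = 999,
    seed: Optional[int] = None,
    trait_name: str = "",
) -> MantelResult:
    """One-tailed permutation Mantel test between two distance matrices.

    The statistic is the raw cross-product z = Σ_{i<j} m1[i,j]·m2[i,j];
    each permutation relabels the rows and columns of m2 simultaneously.
    """
    if list(m1.index) != list(m2.index) or list(m1.columns) != list(m2.columns):
        raise ValueError("distance matrices must share labels and order")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 species for a Mantel test")
    a = m1.to_numpy(dtype=float)
    b = m2.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    z_obs = float(a[iu] @ b[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        bp = b[np.ix_(p, p)]
        if float(a[iu] @ bp[iu]) >= z_obs:
            hits += 1
    return MantelResult(
        trait_name=trait_name,
        z_stat=z_obs,
        p=(1 + hits) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# convenience: all three signal statistics at once


def phylo_signal(
    tree: PhyloTree,
    x: pd.Series,
    trait_name: str = "",
    n_rand: int = 999,
    seed: Optional[int] = None,
) -> SignalResult:
    """K, λ and Moran's I with their tests, on one trait/tree pair."""
    rng = np.random.default_rng(seed)
    seed_k, seed_i = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    k, p_k = blomberg_k_pvalue(tree, x, n_rand=n_rand, seed=seed_k)
    lam, _, p_lam = pagel_lambda_ml(tree, x)
    i_stat, p_i = moran_i(tree, x, n_rand=n_rand, seed=seed_i)
    return SignalResult(
        trait_name=trait_name,
        n=tree.n_tips,
        k_stat=k,
        p_k=p_k,
        lambda_hat=lam,
        p_lambda=p_lam,
        moran_i=i_stat,
        p_i=p_i,
        n_rand=n_rand,
        seed=seed,
    )
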