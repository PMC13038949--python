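"""Phylogenetic signal (Blomberg's K) and trait-table PCA.

Blomberg's K compares the observed ratio of the trait's mean squared
error (around the phylogenetically corrected GLS mean) to the MSE under
the tree's variance-covariance structure, against the expectation of that
ratio under Brownian motion:

    K = [ MSE0 / MSE ]_obs / [ (tr C - n / sum(C^-1)) / (n - 1) ]

with C the phylogenetic covariance matrix (shared branch lengths).  K is
about 1 for Brownian traits, below 1 when close relatives resemble each
other less than Brownian motion predicts, above 1 when they resemble each
other more.  Significance comes from permuting trait values across tips
(one-sided toward high K by default, the phytools convention).

Coded discrete characters (e.g. perianth merosity classes) are accepted
as integer columns and treated as continuous, which mirrors common
practice but is an approximation worth keeping in mind when interpreting
K for few-state characters.

The PCA is an ordinary PCA on standardized trait columns (unit-variance
scaling, eigendecomposition of the correlation structure) with a
deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "KResult",
    "PcaResult",
    "phylo_vcv",
    "blomberg_k",
    "k_permutation_test",
    "trait_pca",
]


@dataclass
class KResult:
    trait: str
    k_stat: float
    p_value: float
    n_perm: int
    seed: int
    alternative: str  # "greater" or "two-sided"


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # traits x axes, orthonormal columns
    variance_fraction: np.ndarray
    scores: pd.DataFrame  # tips x axes


def phylo_vcv(tree: Phylogeny) -> np.ndarray:
    """Phylogenetic covariance matrix: C[i,j] = shared root-to-MRCA path."""
    n = tree.n_tips
    C = np.zeros((n, n))
    for node in range(tree.n_nodes):
        if tree.parent[node] < 0:
            continue
        tips = tree.clade_tips(node)
        idx = np.array(tips)
        C[np.ix_(idx, idx)] += tree.edge_length[node]
    return C


def _k_parts(tree: Phylogeny):
    C = phylo_vcv(tree)
    n = tree.n_tips
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix "
                         "(duplicate zero-length tips?)") from exc
    one = np.ones(n)
    w = Cinv @ one
    denom = one @ w
    expected = (np.trace(C) - n / denom) / (n - 1)
    return Cinv, w, denom, expected, n


def _k_from_parts(x: np.ndarray, Cinv, w, denom, expected, n) -> np.ndarray:
    """Vectorized K for trait matrix x of shape (n,) or (n, B)."""
    X = np.atleast_2d(x.T).T  # (n, B)
    ahat = (w @ X) / denom
    R = X - ahat  # residuals around the GLS mean
    mse0 = (R * R).sum(axis=0) / (n - 1)
    mse = np.einsum("ib,ij,jb->b", R, Cinv, R) / (n - 1)
    if np.any(mse <= 0):
        raise ValueError("degenerate trait: phylogenetic MSE is zero")
    out = (mse0 / mse) / expected
    return out if x.ndim > 1 else float(out[0])


def blomberg_k(tree: Phylogeny, trait: np.ndarray) -> float:
    """Blomberg's K for one continuous trait (one value per tip)."""
    x = np.asarray(trait, dtype=float)
    if tree.n_tips < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if x.shape != (tree.n_tips,):
        raise ValueError("need one trait value per tip")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    return _k_from_parts(x, *_k_parts(tree))


def k_permutation_test(tree: Phylogeny, trait: np.ndarray, n_perm: int = 1000,
                       seed: int = 0, trait_name: str = "trait",
                       alternative: str = "greater") -> KResult:
    """Permutation test for phylogenetic signal.

    Shuffles trait values across tips; ``p = (1 + #{K_perm >= K_obs}) /
    (n_perm + 1)`` for the one-sided (high-K) test.  ``alternative=
    "two-sided"`` uses |log K| as the discrepancy instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(trait, dtype=float)
    parts = _k_parts(tree)
    k_obs = blomberg_k(tree, x)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)], axis=1)
    k_perm = _k_from_parts(perms, *parts)
    if alternative == "greater":
        ge = int((k_perm >= k_obs).sum())
    else:
        ge = int((np.abs(np.log(k_perm)) >= abs(np.log(k_obs))).sum())
    p = (1 + ge) / (n_perm + 1)
    return KResult(trait=trait_name, k_stat=float(k_obs), p_value=p,
                   n_perm=n_perm, seed=seed, alternative=alternative)


def trait_pca(table: pd.DataFrame) -> PcaResult:
    """Ordinary PCA on standardized trait columns.

    Columns are centered and scaled to unit (sample) variance; axes are
    ordered by decreasing explained variance; each loading vector's
    largest-magnitude entry is made positive so signs are deterministic.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 tips")
    if table.isna().any().any():
        raise ValueError("trait table contains missing values")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance trait(s): {list(table.columns[zero])}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    frac = var / var.sum()
    loadings = Vt.T  # traits x axes, orthonormal
    for j in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            U[:, j] *= -1
    scores = U * s
    axes = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=table.columns, columns=axes),
        variance_fraction=frac,
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
    )
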