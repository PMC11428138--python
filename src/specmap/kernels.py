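"""Anisotropic diffusion kernels and Markov transition matrices.

Given a batch of low-dimensional samples ``Z`` the pipeline is

    scale_matrix -> gaussian_kernel -> anisotropic_kernel
                 -> row_normalize (row-stochastic ``M``)
                 -> symmetrize    (spectrum-preserving ``M_sym``)

followed by an eigendecomposition of ``M_sym`` from which the spectral
gap ``sigma_k = lambda_{k-1} - lambda_k`` and implied time scales are
read off.  All matrices are dense; batches are assumed to hold at most a
few thousand samples.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateKernelError, DegenerateScaleError

__all__ = [
    "KernelConfig",
    "MarkovModel",
    "scale_matrix",
    "adaptive_radii",
    "gaussian_kernel",
    "anisotropic_kernel",
    "row_normalize",
    "symmetrize",
    "spectrum",
    "spectral_gap",
    "implied_timescales",
    "build_markov_model",
]


@dataclasses.dataclass(frozen=True)
class KernelConfig:
    """Parameters of the anisotropic diffusion kernel.

    Attributes
    ----------
    alpha : float
        Anisotropic diffusion constant in [0, 1].  ``alpha = 1/2``
        yields the construction whose limiting generator is the
        backward Fokker-Planck operator under the free energy of the
        reduced coordinates; ``alpha = 0`` gives the normalized graph
        Laplacian and ``alpha = 1`` the Laplace-Beltrami limit.
    r : float
        Neighborhood fraction in [0, 1] controlling the adaptive scale:
        0 uses nearest-neighbor radii, 1 farthest-neighbor radii.
    eps_floor : float
        Lower bound applied to the scale matrix to guard against
        duplicated samples.
    """

    alpha: float = 0.5
    r: float = 0.65
    eps_floor: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r}")
        if not self.eps_floor > 0:
            raise ValueError("eps_floor must be positive")


@dataclasses.dataclass
class MarkovModel:
    """A data-driven Markov model over one batch of reduced samples."""

    K: np.ndarray
    M: np.ndarray
    M_sym: np.ndarray
    eigenvalues: np.ndarray  # sorted descending, lambda_0 ~ 1
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    sigma: float
    k_states: int
    config: KernelConfig

    @property
    def timescales(self) -> np.ndarray:
        return implied_timescales(self.eigenvalues)


def _as_samples(Z: np.ndarray) -> np.ndarray:
    """Coerce to an (m, d) sample matrix; 1-D input becomes a column."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z


def _neighbor_rank(m: int, r: float) -> int:
    """Rank (1-based, self excluded) of the neighbor defining the radius."""
    rank = int(np.ceil(r * (m - 1)))
    return min(max(rank, 1), m - 1)


def adaptive_radii(Z: np.ndarray, r: float):
    """Per-sample neighborhood radii eta_r and the realizing neighbor index.

    Returns ``(eta, nbr, D2)`` where ``eta[i]`` is the distance from
    ``Z[i]`` to its ceil(r*(m-1))-th nearest neighbor, ``nbr[i]`` the
    index of that neighbor (ties broken by sample index) and ``D2`` the
    full squared-distance matrix, reused downstream.
    """
    Z = _as_samples(Z)
    m = Z.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 samples for adaptive scales, got {m}")
    D2 = squareform(pdist(Z, metric="sqeuclidean"))
    D = np.sqrt(D2)
    rank = _neighbor_rank(m, r)
    D_masked = D.copy()
    np.fill_diagonal(D_masked, np.inf)
    order = np.argsort(D_masked, axis=1, kind="stable")
    nbr = order[:, rank - 1]
    eta = D_masked[np.arange(m), nbr]
    return eta, nbr, D2


def scale_matrix(
    Z: np.ndarray, r: float, eps_floor: float = 1e-12
) -> np.ndarray:
    """Adaptive scale matrix eps_ij = eta_r(z_i) * eta_r(z_j).

    Raises
    ------
    DegenerateScaleError
        If more than half of the samples have a zero neighborhood
        radius (duplicate-dominated batch).
    """
    eta, _, _ = adaptive_radii(Z, r)
    n_zero = int(np.sum(eta == 0.0))
    if n_zero > 0.5 * eta.size:
        raise DegenerateScaleError(
            f"{n_zero}/{eta.size} samples have zero neighborhood radius"
        )
    eps = np.outer(eta, eta)
    np.maximum(eps, eps_floor, out=eps)
    return eps


def gaussian_kernel(Z: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """g_ij = exp(-||z_i - z_j||^2 / eps_ij)."""
    Z = _as_samples(Z)
    D2 = squareform(pdist(Z, metric="sqeuclidean"))
    return np.exp(-D2 / eps)


def anisotropic_kernel(g: np.ndarray, alpha: float) -> np.ndarray:
    """K_ij = g_ij / (rho_i * rho_j)^alpha with rho_i = sum_j g_ij."""
    rho = g.sum(axis=1)
    if alpha == 0.0:
        return g.copy()
    return g / np.outer(rho, rho) ** alpha


def row_normalize(K: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix M_ij = K_ij / sum_j K_ij."""
    d = K.sum(axis=1)
    if np.any(d <= 0.0):
        raise DegenerateKernelError("kernel has a non-positive row sum")
    return K / d[:, None]


def symmetrize(K: np.ndarray) -> np.ndarray:
    """Symmetrized transition matrix M_sym,ij = K_ij / sqrt(d_i d_j).

    Shares its eigenvalues with ``row_normalize(K)``; the conjugation
    by sqrt(d) maps one to the other.
    """
    d = K.sum(axis=1)
    if np.any(d <= 0.0):
        raise DegenerateKernelError("kernel has a non-positive row sum")
    s = np.sqrt(d)
    return K / np.outer(s, s)


def spectrum(M_sym: np.ndarray, n_top: Optional[int] = None, method: str = "auto"):
    """Eigenvalues (descending) and orthonormal eigenvectors of M_sym.

    Parameters
    ----------
    n_top : int, optional
        If given, only the ``n_top`` largest eigenpairs are computed
        (cheaper for large batches).
    method : {"auto", "dense", "arpack"}
        "auto" uses a dense subset solver for small matrices and ARPACK
        for large ones when ``n_top`` is small.
    """
    M_sym = np.asarray(M_sym, dtype=float)
    m = M_sym.shape[0]
    if n_top is None or n_top >= m:
        w, V = scipy.linalg.eigh(M_sym)
        return w[::-1], V[:, ::-1]
    if method == "auto":
        method = "arpack" if (m > 1200 and n_top < 10) else "dense"
    if method == "arpack":
        try:
            w, V = scipy.sparse.linalg.eigsh(M_sym, k=n_top, which="LA")
            order = np.argsort(w)[::-1]
            return w[order], V[:, order]
        except scipy.sparse.linalg.ArpackError:  # pragma: no cover
            pass
    w, V = scipy.linalg.eigh(M_sym, subset_by_index=[m - n_top, m - 1])
    return w[::-1], V[:, ::-1]


def spectral_gap(eigenvalues: np.ndarray, k: int) -> float:
    """sigma_k = lambda_{k-1} - lambda_k for metastable-state count k."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if k < 1:
        raise IndexError(f"k must be >= 1, got {k}")
    if eigenvalues.size < k + 1:
        raise IndexError(
            f"need at least {k + 1} eigenvalues for k={k}, got {eigenvalues.size}"
        )
    return float(eigenvalues[k - 1] - eigenvalues[k])


def implied_timescales(eigenvalues: np.ndarray) -> np.ndarray:
    """t_k = -1 / log(lambda_k); infinite at lambda = 1, NaN for lambda <= 0."""
    lam = np.asarray(eigenvalues, dtype=float)
    t = np.full_like(lam, np.nan)
    pos = lam > 0.0
    # clip tiny overshoots above 1 coming from finite-precision eigensolves
    lam_c = np.clip(lam, None, 1.0)
    with np.errstate(divide="ignore"):
        t[pos] = -1.0 / np.log(lam_c[pos])
    return t


def build_markov_model(
    Z: np.ndarray,
    k_states: int = 2,
    config: Optional[KernelConfig] = None,
    n_top: Optional[int] = None,
) -> MarkovModel:
    """Run the full kernel pipeline on one batch of reduced samples."""
    if config is None:
        config = KernelConfig()
    Z = _as_samples(Z)
    eps = scale_matrix(Z, config.r, config.eps_floor)
    g = gaussian_kernel(Z, eps)
    K = anisotropic_kernel(g, config.alpha)
    M = row_normalize(K)
    M_sym = symmetrize(K)
    w, V = spectrum(M_sym, n_top=n_top)
    sigma = spectral_gap(w, k_states)
    return MarkovModel(
        K=K, M=M, M_sym=M_sym, eigenvalues=w, eigenvectors=V,
        sigma=sigma, k_states=k_states, config=config,
    )
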