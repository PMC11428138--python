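"""Training of the target mapping by stochastic spectral-gap ascent.

The mapping ``z = f_w(x)`` (linear by default, optionally a small
feed-forward network) is optimized with Adam so that the spectral gap
``sigma_k = lambda_{k-1} - lambda_k`` of the batch Markov transition
matrix built on the mapped samples is maximal.

The gradient of ``sigma`` with respect to the mapped batch is computed
analytically: eigenvalue perturbation ``d lambda = psi^T dM_sym psi``
chained through the symmetrized normalization, the density
normalization, the Gaussian kernel and the adaptive scale matrix
(including the dependence of the neighborhood radii on the samples).
It is validated against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import kernels
from .exceptions import (
    DegenerateScaleError,
    NonImprovingWarning,
    TrainingDivergedError,
)

__all__ = [
    "TargetMapping",
    "TrainConfig",
    "map_samples",
    "spectral_gap_objective",
    "sigma_and_grad",
    "train",
    "select_r",
]


@dataclasses.dataclass
class TargetMapping:
    """Parametric map from feature space to the reduced space.

    ``kind`` is "linear" (z = Xs W) or "mlp" (one tanh hidden layer).
    Inputs are standardized with frozen per-feature statistics; outputs
    are affinely rescaled to [0, 1] over the training set (a monotone
    transform that leaves the spectral gap unchanged).
    """

    kind: str
    weights: List[np.ndarray]
    mean: np.ndarray
    scale: np.ndarray
    out_min: np.ndarray
    out_range: np.ndarray

    @property
    def n_in(self) -> int:
        return self.weights[0].shape[0]

    @property
    def d(self) -> int:
        return self.weights[-1].shape[-1] if self.kind == "mlp" else self.weights[0].shape[1]

    def forward(self, Xs: np.ndarray) -> np.ndarray:
        """Apply the raw map to already-standardized inputs."""
        if self.kind == "linear":
            return Xs @ self.weights[0]
        W1, b1, W2, b2 = self.weights
        return np.tanh(Xs @ W1 + b1) @ W2 + b2

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize, map, and rescale to the stored [0, 1] range."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean) / self.scale
        Z = self.forward(Xs)
        return (Z - self.out_min) / self.out_range

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "weights": [w.tolist() for w in self.weights],
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "out_min": self.out_min.tolist(),
            "out_range": self.out_range.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TargetMapping":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            out_min=np.asarray(d["out_min"], dtype=float),
            out_range=np.asarray(d["out_range"], dtype=float),
        )


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the spectral-gap ascent."""

    d: int = 1
    k_states: int = 2
    epochs: int = 100
    batch_size: int = 2000
    learning_rate: float = 1e-3
    r: float = 0.65
    alpha: float = 0.5
    eps_floor: float = 1e-12
    seed: int = 0
    architecture: str = "linear"  # or "mlp"
    hidden: int = 16
    degenerate_gap: float = 1e-6  # skip batches with sigma below this
    # small weights speed up direction search: sigma is scale-invariant
    # in w, so Adam's ~lr-sized coordinate steps rotate a short weight
    # vector much faster than a unit-norm one
    init_scale: float = 0.03

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.architecture not in ("linear", "mlp"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def kernel_config(self) -> kernels.KernelConfig:
        return kernels.KernelConfig(
            alpha=self.alpha, r=self.r, eps_floor=self.eps_floor
        )


def map_samples(mapping: TargetMapping, X) -> np.ndarray:
    """Row-wise application of the mapping; time order preserved."""
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    if values.shape[1] != mapping.n_in:
        raise ValueError(
            f"mapping expects {mapping.n_in} features, got {values.shape[1]}"
        )
    return mapping.transform(values)


def spectral_gap_objective(
    Z: np.ndarray, k_states: int, config: Optional[kernels.KernelConfig] = None
) -> float:
    """Spectral gap of the batch Markov model (value only)."""
    model = kernels.build_markov_model(
        Z, k_states=k_states, config=config, n_top=k_states + 1
    )
    return model.sigma


def sigma_and_grad(
    Z: np.ndarray,
    k_states: int,
    config: Optional[kernels.KernelConfig] = None,
) -> Tuple[float, np.ndarray]:
    """Spectral gap of a batch and its gradient with respect to the batch.

    Returns ``(sigma, dsigma/dZ)`` with ``dsigma/dZ`` of the same shape
    as ``Z``.  The chain runs through eps(Z) as well, i.e. the adaptive
    radii are differentiated, not frozen.
    """
    if config is None:
        config = kernels.KernelConfig()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    m = Z.shape[0]
    alpha = config.alpha

    eta, nbr, D2 = kernels.adaptive_radii(Z, config.r)
    n_zero = int(np.sum(eta == 0.0))
    if n_zero > 0.5 * m:
        raise DegenerateScaleError(
            f"{n_zero}/{m} samples have zero neighborhood radius"
        )
    eps_raw = np.outer(eta, eta)
    floored = eps_raw < config.eps_floor
    eps = np.maximum(eps_raw, config.eps_floor)

    g = np.exp(-D2 / eps)
    rho = g.sum(axis=1)
    K = g / np.outer(rho, rho) ** alpha if alpha != 0.0 else g
    d = K.sum(axis=1)
    sd = np.sqrt(d)
    M_sym = K / np.outer(sd, sd)

    w, V = kernels.spectrum(M_sym, n_top=k_states + 1)
    sigma = float(w[k_states - 1] - w[k_states])
    psi_a = V[:, k_states - 1]
    psi_b = V[:, k_states]

    # d sigma / d M_sym
    S = np.outer(psi_a, psi_a) - np.outer(psi_b, psi_b)
    # back through M_sym = K / sqrt(d_i d_j)
    c = np.sum(S * M_sym, axis=1)
    A = S / np.outer(sd, sd) - (c / d)[:, None]
    # back through K = g / (rho_i rho_j)^alpha
    if alpha != 0.0:
        e = np.sum((A + A.T) * K, axis=1)
        B = A / np.outer(rho, rho) ** alpha - alpha * (e / rho)[:, None]
    else:
        B = A
    # back through g = exp(-D2/eps)
    C = -B * g / eps  # d sigma / d D2
    E = B * g * D2 / eps**2  # d sigma / d eps
    E[floored] = 0.0  # floor is flat

    # D2 path: d sigma/d z_p = 2 sum_q (C_pq + C_qp)(z_p - z_q)
    Wsym = C + C.T
    dZ = 2.0 * (Wsym.sum(axis=1)[:, None] * Z - Wsym @ Z)

    # eps path: eps_pq = eta_p eta_q, eta_p realized by neighbor nbr[p]
    G = np.sum((E + E.T) * eta[None, :], axis=1)
    safe = eta > 0
    U = np.zeros_like(Z)
    U[safe] = (Z[safe] - Z[nbr[safe]]) / eta[safe, None]
    np.add.at(dZ, np.arange(m), G[:, None] * U)
    np.subtract.at(dZ, nbr, G[:, None] * U)

    return sigma, dZ


class _Adam:
    """Minimal Adam optimizer over a list of arrays (ascent: pass -grad)."""

    def __init__(self, params: List[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, gr, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * gr
            v *= b2
            v += (1 - b2) * gr**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_mapping(n: int, cfg: TrainConfig, rng) -> List[np.ndarray]:
    if cfg.architecture == "linear":
        return [cfg.init_scale * rng.standard_normal((n, cfg.d)) / np.sqrt(n)]
    h = cfg.hidden
    return [
        rng.standard_normal((n, h)) / np.sqrt(n),
        np.zeros(h),
        cfg.init_scale * rng.standard_normal((h, cfg.d)) / np.sqrt(h),
        np.zeros(cfg.d),
    ]


def _forward_backward(
    weights: List[np.ndarray], Xs: np.ndarray, dZ: np.ndarray, kind: str
) -> List[np.ndarray]:
    """Gradient of sigma w.r.t. the weights given dsigma/dZ."""
    if kind == "linear":
        return [Xs.T @ dZ]
    W1, b1, W2, b2 = weights
    H = np.tanh(Xs @ W1 + b1)
    dW2 = H.T @ dZ
    db2 = dZ.sum(axis=0)
    dH = dZ @ W2.T
    dpre = dH * (1.0 - H**2)
    dW1 = Xs.T @ dpre
    db1 = dpre.sum(axis=0)
    return [dW1, db1, dW2, db2]


def train(
    X,
    cfg: TrainConfig,
    initial_weights: Optional[List[np.ndarray]] = None,
) -> Tuple[TargetMapping, Dict]:
    """Stochastic spectral-gap maximization over permuted mini-batches.

    Per epoch the sample order is permuted, full batches of
    ``cfg.batch_size`` are mapped forward and the spectral gap of every
    batch Markov model is ascended with Adam.  The returned mapping
    carries the weights of the epoch with the best mean batch sigma.
    """
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    T, n = values.shape
    batch_size = min(cfg.batch_size, T)
    if batch_size < cfg.k_states + 2:
        raise ValueError("batch_size too small for the requested k_states")

    mean = values.mean(axis=0)
    scale = values.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Xs = (values - mean) / scale

    rng = np.random.default_rng(cfg.seed)
    if initial_weights is not None:
        weights = [np.array(w, dtype=float) for w in initial_weights]
    else:
        weights = _init_mapping(n, cfg, rng)
    opt = _Adam(weights, cfg.learning_rate)
    kcfg = cfg.kernel_config

    history: Dict = {
        "sigma": [], "epoch_mean": [], "skipped": 0, "best_epoch": -1,
        "best_sigma": -np.inf, "improved": True,
    }
    best_weights = [w.copy() for w in weights]

    n_batches = T // batch_size
    for epoch in range(cfg.epochs):
        perm = rng.permutation(T)
        epoch_sigmas = []
        for b in range(n_batches):
            idx = perm[b * batch_size : (b + 1) * batch_size]
            Xb = Xs[idx]
            if cfg.architecture == "linear":
                Zb = Xb @ weights[0]
            else:
                W1, b1, W2, b2 = weights
                Zb = np.tanh(Xb @ W1 + b1) @ W2 + b2
            try:
                sigma, dZ = sigma_and_grad(Zb, cfg.k_states, kcfg)
            except DegenerateScaleError:
                history["skipped"] += 1
                continue
            if sigma < cfg.degenerate_gap:
                # near-degenerate pair: eigenvector gradient unstable
                history["skipped"] += 1
                epoch_sigmas.append(sigma)
                history["sigma"].append(sigma)
                continue
            grads = _forward_backward(weights, Xb, dZ, cfg.architecture)
            if not all(np.all(np.isfinite(g)) for g in grads):
                raise TrainingDivergedError(
                    f"non-finite gradient at epoch {epoch}, batch {b}"
                )
            opt.step([-g for g in grads])  # ascent
            epoch_sigmas.append(sigma)
            history["sigma"].append(sigma)
        if epoch_sigmas:
            em = float(np.mean(epoch_sigmas))
        else:
            em = np.nan
        history["epoch_mean"].append(em)
        if np.isfinite(em) and em > history["best_sigma"]:
            history["best_sigma"] = em
            history["best_epoch"] = epoch
            best_weights = [w.copy() for w in weights]

    if (
        len(history["epoch_mean"]) > 1
        and np.isfinite(history["epoch_mean"][0])
        and history["best_sigma"] <= history["epoch_mean"][0] + 1e-12
    ):
        history["improved"] = False
        warnings.warn(
            "spectral gap did not improve over training", NonImprovingWarning
        )

    Z_full = (
        Xs @ best_weights[0]
        if cfg.architecture == "linear"
        else np.tanh(Xs @ best_weights[0] + best_weights[1]) @ best_weights[2]
        + best_weights[3]
    )
    out_min = Z_full.min(axis=0)
    out_range = Z_full.max(axis=0) - out_min
    out_range = np.where(out_range < 1e-12, 1.0, out_range)
    mapping = TargetMapping(
        kind=cfg.architecture,
        weights=best_weights,
        mean=mean,
        scale=scale,
        out_min=out_min,
        out_range=out_range,
    )
    return mapping, history


def select_r(
    X,
    cfg: TrainConfig,
    r_grid: Sequence[float],
    budget_epochs: int = 10,
) -> float:
    """Pick the neighborhood fraction with the largest converged gap.

    Short-budget training is run per grid point; ties go to the
    smaller r.
    """
    best_r = None
    best_sigma = -np.inf
    for r in sorted(r_grid):
        cfg_r = dataclasses.replace(cfg, r=float(r), epochs=budget_epochs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonImprovingWarning)
            _, hist = train(X, cfg_r)
        if hist["best_sigma"] > best_sigma:
            best_sigma = hist["best_sigma"]
            best_r = float(r)
    return best_r
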