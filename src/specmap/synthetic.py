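"""Ground-truth generators: overdamped Langevin dynamics on toy
potentials, high-dimensional liftings with fast noise directions, and
discrete toy processes (telegraph signals, Markov chains).

Every generator is seeded and cheap enough to run inside the test
suite, so no external trajectory data is ever required.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

try:  # optional: pure-python fallback below is correct but slow
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Potential",
    "LangevinConfig",
    "LiftConfig",
    "double_well",
    "harmonic",
    "sum_potential",
    "mueller_like_2d",
    "simulate_langevin",
    "lift",
    "telegraph",
    "toy_chain",
]


@dataclasses.dataclass(frozen=True)
class Potential:
    """Analytic potential: value, gradient, dimensionality.

    ``value`` and ``grad`` accept arrays of shape (..., dim) for
    dim > 1, or plain scalars/arrays for dim == 1.
    """

    name: str
    dim: int
    value: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]


def double_well(h: float = 5.0) -> Potential:
    """U(z) = h (z^2 - 1)^2: minima at z = +-1, barrier U(0) = h."""

    def value(z):
        z = np.asarray(z, dtype=float)
        return h * (z**2 - 1.0) ** 2

    def grad(z):
        z = np.asarray(z, dtype=float)
        return 4.0 * h * z * (z**2 - 1.0)

    return Potential(name=f"double_well(h={h})", dim=1, value=value, grad=grad)


def harmonic(kappa: float = 1.0, center: float = 0.0) -> Potential:
    """U(z) = kappa/2 (z - center)^2."""

    def value(z):
        z = np.asarray(z, dtype=float)
        return 0.5 * kappa * (z - center) ** 2

    def grad(z):
        z = np.asarray(z, dtype=float)
        return kappa * (z - center)

    return Potential(name=f"harmonic(kappa={kappa})", dim=1, value=value, grad=grad)


def sum_potential(*parts: Potential) -> Potential:
    """Separable product-space potential U(z) = sum_i U_i(z_i).

    Each part must be one-dimensional; the result acts on vectors whose
    components are the parts' coordinates (e.g. slow double well plus a
    fast harmonic degree of freedom).
    """
    if any(p.dim != 1 for p in parts):
        raise ValueError("sum_potential combines one-dimensional parts only")
    d = len(parts)

    def value(z):
        z = np.asarray(z, dtype=float)
        return sum(p.value(z[..., i]) for i, p in enumerate(parts))

    def grad(z):
        z = np.asarray(z, dtype=float)
        return np.stack(
            [np.asarray(p.grad(z[..., i])) for i, p in enumerate(parts)], axis=-1
        )

    name = "+".join(p.name for p in parts)
    return Potential(name=name, dim=d, value=value, grad=grad)


# Mueller-Brown-style parameters, scaled so barriers are a few k_BT.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0]) * 0.02
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def mueller_like_2d(scale: float = 1.0) -> Potential:
    """A 2-D multi-basin potential in the Mueller-Brown family."""

    def value(z):
        z = np.asarray(z, dtype=float)
        x, y = z[..., 0], z[..., 1]
        u = np.zeros_like(x)
        for A, a, b, c, x0, y0 in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            u = u + A * np.exp(
                a * (x - x0) ** 2 + b * (x - x0) * (y - y0) + c * (y - y0) ** 2
            )
        return scale * u

    def grad(z):
        z = np.asarray(z, dtype=float)
        x, y = z[..., 0], z[..., 1]
        gx = np.zeros_like(x)
        gy = np.zeros_like(y)
        for A, a, b, c, x0, y0 in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            e = A * np.exp(
                a * (x - x0) ** 2 + b * (x - x0) * (y - y0) + c * (y - y0) ** 2
            )
            gx = gx + e * (2.0 * a * (x - x0) + b * (y - y0))
            gy = gy + e * (b * (x - x0) + 2.0 * c * (y - y0))
        return scale * np.stack([gx, gy], axis=-1)

    return Potential(name="mueller_like_2d", dim=2, value=value, grad=grad)


@dataclasses.dataclass(frozen=True)
class LangevinConfig:
    """Overdamped Langevin (Euler-Maruyama) simulation parameters.

    The update rule is
        z' = z - D grad U(z) dt + sqrt(2 D dt / beta) xi,  xi ~ N(0, 1)
    whose stationary law is the Boltzmann density exp(-beta U).
    """

    potential: Potential
    beta: float = 1.0
    dt: float = 1e-3
    n_steps: int = 100_000
    seed: int = 0
    D: float = 1.0
    z0: Optional[Sequence[float]] = None
    thin: int = 1
    bound: float = 1e3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def _em_loop_python(z0, drift, amp, noise, thin, bound, grad):
    n = noise.shape[0]
    d = z0.size
    out = np.empty((n // thin, d))
    z = z0.copy()
    j = 0
    for t in range(n):
        z = z - drift * grad(z) + amp * noise[t]
        if np.any(np.abs(z) > bound):
            raise FloatingPointError(
                f"trajectory diverged (|z| > {bound}) at step {t}; reduce dt"
            )
        if (t + 1) % thin == 0:
            out[j] = z
            j += 1
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _em_loop_dw(z0, h, drift, amp, noise, thin, bound):  # pragma: no cover
        n = noise.shape[0]
        out = np.empty(n // thin)
        z = z0
        j = 0
        for t in range(n):
            g = 4.0 * h * z * (z * z - 1.0)
            z = z - drift * g + amp * noise[t, 0]
            if abs(z) > bound:
                return out[:0]
            if (t + 1) % thin == 0:
                out[j] = z
                j += 1
        return out

    @numba.njit(cache=False)
    def _em_loop_dw_harm(z0, h, kappa, drift, amp, noise, thin, bound):  # pragma: no cover
        n = noise.shape[0]
        out = np.empty((n // thin, 2))
        x = z0[0]
        y = z0[1]
        j = 0
        for t in range(n):
            gx = 4.0 * h * x * (x * x - 1.0)
            gy = kappa * y
            x = x - drift * gx + amp * noise[t, 0]
            y = y - drift * gy + amp * noise[t, 1]
            if abs(x) > bound or abs(y) > bound:
                return out[:0]
            if (t + 1) % thin == 0:
                out[j, 0] = x
                out[j, 1] = y
                j += 1
        return out


def _fast_path(cfg: LangevinConfig):
    """Match cfg.potential against the numba-specialized integrators."""
    if not _HAVE_NUMBA:
        return None
    name = cfg.potential.name
    if name.startswith("double_well(") and cfg.potential.dim == 1:
        h = float(name.split("=")[1].rstrip(")"))
        return ("dw", (h,))
    if cfg.potential.dim == 2 and "+" in name:
        left, right = name.split("+", 1)
        if left.startswith("double_well(") and right.startswith("harmonic("):
            h = float(left.split("=")[1].rstrip(")"))
            kappa = float(right.split("=")[1].rstrip(")"))
            return ("dw_harm", (h, kappa))
    return None


def simulate_langevin(cfg: LangevinConfig) -> np.ndarray:
    """Integrate overdamped Langevin dynamics; returns thinned positions.

    Output shape is ``(n_steps // thin,)`` for 1-D potentials and
    ``(n_steps // thin, dim)`` otherwise.  Reproducible under
    ``cfg.seed``; raises ``FloatingPointError`` if the trajectory
    leaves ``[-bound, bound]`` (step size too large).
    """
    d = cfg.potential.dim
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((cfg.n_steps, d))
    drift = cfg.D * cfg.dt
    amp = np.sqrt(2.0 * cfg.D * cfg.dt / cfg.beta)
    if cfg.z0 is None:
        z0 = np.zeros(d)
    else:
        z0 = np.asarray(cfg.z0, dtype=float).reshape(d)

    fast = _fast_path(cfg)
    if fast is not None:
        kind, params = fast
        if kind == "dw":
            out = _em_loop_dw(z0[0], params[0], drift, amp, noise, cfg.thin, cfg.bound)
            if out.size == 0 and cfg.n_steps // cfg.thin > 0:
                raise FloatingPointError("trajectory diverged; reduce dt")
            return out
        if kind == "dw_harm":
            out = _em_loop_dw_harm(
                z0, params[0], params[1], drift, amp, noise, cfg.thin, cfg.bound
            )
            if out.shape[0] == 0 and cfg.n_steps // cfg.thin > 0:
                raise FloatingPointError("trajectory diverged; reduce dt")
            return out

    grad = cfg.potential.grad
    if d == 1:
        g1 = lambda z: np.asarray([float(grad(z[0]))])  # noqa: E731
        out = _em_loop_python(z0, drift, amp, noise, cfg.thin, cfg.bound, g1)
        return out[:, 0]
    out = _em_loop_python(
        z0, drift, amp, noise, cfg.thin, cfg.bound,
        lambda z: np.asarray(grad(z), dtype=float),
    )
    return out


@dataclasses.dataclass(frozen=True)
class LiftConfig:
    """High-dimensional lifting of a slow trajectory.

    The lifted features are ``X = z A_slow^T + sum_f u_f A_fast^T + noise``
    with orthonormal mixing columns; the fast modes ``u_f`` are OU
    processes whose relaxation times are far below the slow process.
    """

    n_features: int = 10
    n_fast: int = 3
    tau_fast: float = 0.05
    fast_amplitude: float = 1.0
    noise_amplitude: float = 0.01
    seed: int = 0


def _ou_trajectory(n: int, dt: float, tau: float, amp: float, rng) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck path with stationary sd amp."""
    from scipy.signal import lfilter

    phi = np.exp(-dt / tau)
    innov_sd = amp * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n)
    driving = innov_sd * eps
    driving[0] = amp * eps[0]  # start in the stationary law
    return lfilter([1.0], [1.0, -phi], driving)


def lift(z: np.ndarray, cfg: LiftConfig, dt: float = 1.0):
    """Embed a slow trajectory into cfg.n_features dimensions.

    Returns ``(X, truth)`` where ``truth`` records the slow signal and
    mixing directions for parameter-recovery tests.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    T, d = z.shape
    if cfg.n_features < d + cfg.n_fast:
        raise ValueError(
            f"n_features={cfg.n_features} too small for d={d} slow + "
            f"{cfg.n_fast} fast modes"
        )
    rng = np.random.default_rng(cfg.seed)
    # random orthonormal columns via QR
    G = rng.standard_normal((cfg.n_features, d + cfg.n_fast))
    Q, _ = np.linalg.qr(G)
    A_slow = Q[:, :d]
    A_fast = Q[:, d : d + cfg.n_fast]
    U = np.column_stack(
        [
            _ou_trajectory(T, dt, cfg.tau_fast, cfg.fast_amplitude, rng)
            for _ in range(cfg.n_fast)
        ]
    ) if cfg.n_fast else np.zeros((T, 0))
    X = z @ A_slow.T
    if cfg.n_fast:
        X = X + U @ A_fast.T
    if cfg.noise_amplitude > 0:
        X = X + cfg.noise_amplitude * rng.standard_normal(X.shape)
    truth = {"z": z, "A_slow": A_slow, "A_fast": A_fast, "fast": U}
    return X, truth


def _telegraph_loop(u: np.ndarray, p01: float, p10: float) -> np.ndarray:
    labels = np.empty(u.size, dtype=np.int64)
    s = 0
    for t in range(u.size):
        if s == 0:
            if u[t] < p01:
                s = 1
        else:
            if u[t] < p10:
                s = 0
        labels[t] = s
    return labels


if _HAVE_NUMBA:
    _telegraph_loop = numba.njit(cache=False)(_telegraph_loop)


def telegraph(k1: float, k2: float, n: int, dt: float = 1.0, seed: int = 0) -> np.ndarray:
    """Two-state jump process sampled at interval dt.

    State 0 leaves with rate k1, state 1 with rate k2; exact
    per-interval switching probabilities 1 - exp(-k dt).
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return _telegraph_loop(u, 1.0 - np.exp(-k1 * dt), 1.0 - np.exp(-k2 * dt))


def toy_chain(P: np.ndarray, n: int, seed: int = 0, s0: int = 0) -> np.ndarray:
    """Sample a discrete Markov chain with row-stochastic matrix P."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("P rows must sum to 1")
    if np.any(P < 0):
        raise ValueError("P must be nonnegative")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    s = s0
    for t in range(n):
        s = int(np.searchsorted(cum[s], u[t]))
        out[t] = s
    return out
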