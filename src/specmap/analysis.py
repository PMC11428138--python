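"""Post-hoc physics along learned coordinates.

Free-energy profiles and landscapes by Boltzmann inversion, minimum
free-energy paths, the Bayes test for Markovianity of a 1-D coordinate,
coordinate-dependent diffusion coefficients with the diffusion-corrected
free energy, and mean first-passage times with block-bootstrap
confidence intervals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .exceptions import DisconnectedEndpointsError, SpecmapWarning
from .partitioning import TS_LABEL

__all__ = [
    "FreeEnergyProfile",
    "FreeEnergyLandscape",
    "MarkovianityProfile",
    "DiffusionProfile",
    "MFPTEstimate",
    "free_energy_profile",
    "free_energy_landscape",
    "min_free_energy_path",
    "markovianity_profile",
    "diffusion_profile",
    "diffusion_corrected_F",
    "mfpt",
]


@dataclasses.dataclass
class FreeEnergyProfile:
    """1-D potential of mean force, min-shifted to zero, in k_BT units."""

    centers: np.ndarray
    F: np.ndarray  # NaN on unpopulated bins
    counts: np.ndarray
    beta: float
    edges: np.ndarray


@dataclasses.dataclass
class FreeEnergyLandscape:
    """2-D potential of mean force on a rectangular bin grid."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    F: np.ndarray  # shape (nx, ny), NaN on unpopulated bins
    counts: np.ndarray
    beta: float


@dataclasses.dataclass
class MarkovianityProfile:
    """Bayes-test profile p(ts|z) with its maximum p*."""

    centers: np.ndarray
    p_ts_given_z: np.ndarray
    p_star: float
    ts: Tuple[float, float]
    degenerate: bool = False


@dataclasses.dataclass
class DiffusionProfile:
    """Coordinate-dependent diffusion coefficients from short-lag MSD."""

    centers: np.ndarray
    D: np.ndarray  # NaN on masked bins
    counts: np.ndarray
    lags: np.ndarray  # lag times used for the regression (time units)


@dataclasses.dataclass
class MFPTEstimate:
    """Mean first-passage time for one direction with bootstrap CI."""

    direction: Tuple[int, int]
    lags: np.ndarray  # lag values in frames
    mfpt_per_lag: np.ndarray  # time units
    plateau_lag: int
    plateau: float
    ci: Tuple[float, float]
    n_boot: int


def free_energy_profile(
    z: np.ndarray,
    bins: int = 50,
    beta: float = 1.0,
    range: Optional[Tuple[float, float]] = None,
) -> FreeEnergyProfile:
    """F(z) = -ln(p(z)) / beta from a histogram, min-shifted to zero."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty trajectory")
    counts, edges = np.histogram(z, bins=bins, range=range)
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the requested range")
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / counts.sum() / np.diff(edges)
    F = np.full(bins, np.nan)
    populated = counts > 0
    F[populated] = -np.log(density[populated]) / beta
    F -= np.nanmin(F)
    return FreeEnergyProfile(centers=centers, F=F, counts=counts, beta=beta, edges=edges)


def free_energy_landscape(
    Z: np.ndarray,
    bins: int = 50,
    beta: float = 1.0,
    range=None,
) -> FreeEnergyLandscape:
    """2-D Boltzmann inversion; ``Z`` is (T, 2)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError("Z must have shape (T, 2)")
    counts, xe, ye = np.histogram2d(Z[:, 0], Z[:, 1], bins=bins, range=range)
    area = np.outer(np.diff(xe), np.diff(ye))
    density = counts / counts.sum() / area
    F = np.full_like(counts, np.nan)
    populated = counts > 0
    F[populated] = -np.log(density[populated]) / beta
    F -= np.nanmin(F)
    return FreeEnergyLandscape(
        x_centers=0.5 * (xe[:-1] + xe[1:]),
        y_centers=0.5 * (ye[:-1] + ye[1:]),
        F=F,
        counts=counts,
        beta=beta,
    )


def min_free_energy_path(
    landscape: FreeEnergyLandscape,
    start: Tuple[int, int],
    end: Tuple[int, int],
) -> Dict[str, np.ndarray]:
    """Least-cost path between two bins of a 2-D landscape.

    Dijkstra on the 8-connected graph of populated bins with edge cost
    equal to the mean free energy of the two endpoint bins.  Returns the
    path as bin indices, the free energy along it and the barrier (path
    maximum).
    """
    F = landscape.F
    nx, ny = F.shape
    populated = np.isfinite(F)
    for p, name in ((start, "start"), (end, "end")):
        if not (0 <= p[0] < nx and 0 <= p[1] < ny) or not populated[p]:
            raise DisconnectedEndpointsError(f"{name} bin {p} is not populated")
    node = -np.ones(F.shape, dtype=int)
    idx = np.argwhere(populated)
    node[populated] = np.arange(idx.shape[0])
    rows, cols, weights = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, j in idx:
        for di, dj in offsets:
            ii, jj = i + di, j + dj
            if 0 <= ii < nx and 0 <= jj < ny and populated[ii, jj]:
                rows.append(node[i, j])
                cols.append(node[ii, jj])
                weights.append(0.5 * (F[i, j] + F[ii, jj]))
    graph = coo_matrix(
        (weights, (rows, cols)), shape=(idx.shape[0], idx.shape[0])
    ).tocsr()
    s, e = node[start], node[end]
    dist, pred = dijkstra(graph, indices=s, return_predecessors=True)
    if not np.isfinite(dist[e]):
        raise DisconnectedEndpointsError(
            f"no populated-bin path between {start} and {end}"
        )
    chain = [e]
    while chain[-1] != s:
        chain.append(pred[chain[-1]])
    chain.reverse()
    path = idx[chain]
    F_path = F[path[:, 0], path[:, 1]]
    return {"path": path, "F": F_path, "barrier": float(F_path.max()), "cost": float(dist[e])}


def _transition_path_masks(z: np.ndarray, a: float, b: float):
    """Frames on directional transition paths through the interval [a, b].

    A frame inside (a, b) is on a forward (backward) transition path if
    the trajectory entered the interval from below a (above b) and next
    leaves it above b (below a).
    """
    n = z.size
    region = np.where(z < a, 0, np.where(z > b, 2, 1))
    idx = np.arange(n)
    outside = region != 1
    last_out = np.where(outside, idx, -1)
    np.maximum.accumulate(last_out, out=last_out)
    next_out = np.where(outside, idx, n)
    next_out = np.minimum.accumulate(next_out[::-1])[::-1]
    valid = (~outside) & (last_out >= 0) & (next_out < n)
    prev_code = region[np.clip(last_out, 0, n - 1)]
    next_code = region[np.clip(next_out, 0, n - 1)]
    tp_fwd = valid & (prev_code == 0) & (next_code == 2)
    tp_bwd = valid & (prev_code == 2) & (next_code == 0)
    return tp_fwd, tp_bwd


def markovianity_profile(
    z: np.ndarray,
    ts: Tuple[float, float],
    bins: int = 50,
    range: Optional[Tuple[float, float]] = None,
) -> MarkovianityProfile:
    """Bayes estimate of p(ts|z) and its maximum p*.

    ``ts = (a, b)`` bounds the transition region.  A frame belongs to
    the ts ensemble when it lies on a directional transition path
    through [a, b]; p(ts|z) = p(z|ts) p(ts) / p(z) is evaluated per
    histogram bin and averaged over the two (equivalent, by detailed
    balance) directions.  For overdamped Markovian dynamics
    p* = max_z p(ts|z) = 1/4; memory pushes p* below 1/4.
    """
    z = np.asarray(z, dtype=float).ravel()
    a, b = ts
    if not a < b:
        raise ValueError("ts interval must satisfy a < b")
    counts, edges = np.histogram(z, bins=bins, range=range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    inside = (z >= a) & (z <= b)
    if inside.all():
        warnings.warn(
            "every frame lies inside the ts interval; p(ts|z) is degenerate",
            SpecmapWarning,
        )
        p = np.where(counts > 0, 1.0, np.nan)
        return MarkovianityProfile(centers, p, 1.0, (a, b), degenerate=True)
    if not inside.any():
        warnings.warn("trajectory never visits the ts interval", SpecmapWarning)
        p = np.where(counts > 0, 0.0, np.nan)
        return MarkovianityProfile(centers, p, 0.0, (a, b))
    tp_fwd, tp_bwd = _transition_path_masks(z, a, b)
    cf, _ = np.histogram(z[tp_fwd], bins=edges)
    cb, _ = np.histogram(z[tp_bwd], bins=edges)
    p = np.full(bins, np.nan)
    populated = counts > 0
    p[populated] = 0.5 * (cf[populated] + cb[populated]) / counts[populated]
    p_star = float(np.nanmax(p)) if populated.any() else 0.0
    return MarkovianityProfile(centers, p, p_star, (a, b))


def diffusion_profile(
    z: np.ndarray,
    dt: float,
    bins: int = 50,
    lags: Sequence[int] = (1, 2, 3, 4, 5),
    range: Optional[Tuple[float, float]] = None,
    min_count: int = 50,
) -> DiffusionProfile:
    """D(z) from the short-lag growth of conditional squared displacements.

    Per bin b, D(b) is the slope of <(z(t+tau) - z(t))^2 | z(t) in b>/2
    against tau over the lag window (ordinary least squares with
    intercept).  Bins with fewer than ``min_count`` conditioning samples
    at any lag are masked.
    """
    z = np.asarray(z, dtype=float).ravel()
    lags = np.asarray(sorted(lags), dtype=int)
    if lags.size < 2:
        raise ValueError("need at least 2 lags for the regression")
    if lags[0] < 1:
        raise ValueError("lags must be >= 1 frame")
    _, edges = np.histogram(z, bins=bins, range=range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(z, edges) - 1, 0, bins - 1)
    msd = np.full((bins, lags.size), np.nan)
    counts = np.zeros((bins, lags.size), dtype=int)
    for i, lag in enumerate(lags):
        disp2 = (z[lag:] - z[:-lag]) ** 2
        origin = which[: z.size - lag]
        sums = np.bincount(origin, weights=disp2, minlength=bins)
        cnt = np.bincount(origin, minlength=bins)
        ok = cnt > 0
        msd[ok, i] = sums[ok] / cnt[ok]
        counts[:, i] = cnt
    tau = lags * dt
    D = np.full(bins, np.nan)
    X = np.column_stack([tau, np.ones_like(tau)])
    for bq in np.nonzero(np.all(counts >= min_count, axis=1))[0]:
        slope, _ = np.linalg.lstsq(X, msd[bq] / 2.0, rcond=None)[0]
        if slope >= 0:
            D[bq] = slope
    return DiffusionProfile(
        centers=centers, D=D, counts=counts.min(axis=1), lags=tau
    )


def diffusion_corrected_F(
    F: FreeEnergyProfile,
    D: DiffusionProfile,
    beta: Optional[float] = None,
    ref_bin: Optional[int] = None,
) -> Tuple[FreeEnergyProfile, float]:
    """F_D(z) = F(z) - ln(D(z)/D_0)/beta and its mean deviation from F.

    ``D_0`` is the diffusion coefficient at ``ref_bin`` (default: the
    minimum-F bin among bins with a valid D), conventionally the first
    metastable state.  Returns the corrected profile (min-shifted) and
    mean |F_D - F| over jointly valid bins.
    """
    if F.centers.shape != D.centers.shape or not np.allclose(F.centers, D.centers):
        raise ValueError("F and D must be computed on identical bins")
    beta = F.beta if beta is None else beta
    valid = np.isfinite(F.F) & np.isfinite(D.D)
    if not valid.any():
        raise ValueError("no bin carries both F and D")
    if ref_bin is None:
        cand = np.where(valid, F.F, np.inf)
        ref_bin = int(np.argmin(cand))
    if not valid[ref_bin]:
        raise ValueError(f"reference bin {ref_bin} has no valid D")
    D0 = D.D[ref_bin]
    FD = np.full_like(F.F, np.nan)
    FD[valid] = F.F[valid] - np.log(D.D[valid] / D0) / beta
    FD -= np.nanmin(FD)
    discrepancy = float(np.nanmean(np.abs(FD[valid] - F.F[valid])))
    profile = FreeEnergyProfile(
        centers=F.centers.copy(), F=FD, counts=F.counts.copy(),
        beta=beta, edges=F.edges.copy(),
    )
    return profile, discrepancy


def _mean_first_passage_frames(sub: np.ndarray, i: int, j: int) -> float:
    """Mean frames until first visit of j, averaged over frames in i."""
    idx_j = np.flatnonzero(sub == j)
    pos_i = np.flatnonzero(sub == i)
    if idx_j.size == 0 or pos_i.size == 0:
        return np.inf
    nxt = np.searchsorted(idx_j, pos_i, side="left")
    ok = nxt < idx_j.size
    if not ok.any():
        return np.inf
    return float(np.mean(idx_j[nxt[ok]] - pos_i[ok]))


def mfpt(
    labels: np.ndarray,
    dt: float = 1.0,
    lags: Optional[Sequence[int]] = None,
    n_boot: int = 200,
    block: Optional[int] = None,
    ci_level: float = 0.95,
    plateau_rtol: float = 0.05,
    seed: int = 0,
) -> Dict[Tuple[int, int], MFPTEstimate]:
    """MFPTs between core states by direct transition counting.

    ``labels`` holds per-frame state labels with ``-1`` marking the
    transition-state ensemble (excluded from the cores).  For each lag
    the trajectory is subsampled and the mean time to first reach the
    target core, averaged over source-core frames, is recorded; the
    plateau is the first lag at which successive estimates agree within
    ``plateau_rtol``.  CIs come from a block bootstrap at the plateau
    lag (default block length 10x the plateau MFPT, in frames).
    """
    labels = np.asarray(labels)
    states = np.unique(labels[labels != TS_LABEL])
    if states.size < 2:
        raise ValueError("need at least two core states")
    if lags is None:
        lags = [1, 2, 5, 10, 20, 50, 100]
    lags = np.asarray(sorted(set(int(l) for l in lags)), dtype=int)
    rng = np.random.default_rng(seed)

    # pass 1: lag curves and plateaus for every direction
    results = {}
    for i in states:
        for j in states:
            if i == j:
                continue
            per_lag = np.empty(lags.size)
            for q, lag in enumerate(lags):
                sub = labels[::lag]
                per_lag[q] = _mean_first_passage_frames(sub, i, j) * lag * dt
            plateau_idx = lags.size - 1
            for q in range(lags.size - 1):
                if not np.isfinite(per_lag[q]) or per_lag[q] == 0:
                    continue
                if abs(per_lag[q + 1] - per_lag[q]) / per_lag[q] < plateau_rtol:
                    plateau_idx = q + 1
                    break
            results[(int(i), int(j))] = (
                per_lag, int(lags[plateau_idx]), float(per_lag[plateau_idx])
            )

    # blocks must dwarf the slowest passage time or the joins between
    # resampled blocks fabricate transitions and bias the MFPT down
    finite_plateaus = [p for _, _, p in results.values() if np.isfinite(p)]
    if block is not None:
        L = block
    elif finite_plateaus:
        L = int(min(max(20 * max(finite_plateaus) / dt, 100), labels.size // 5))
    else:
        L = max(labels.size // 5, 1)

    out: Dict[Tuple[int, int], MFPTEstimate] = {}
    n = labels.size
    n_blocks = int(np.ceil(n / L))
    starts_max = max(n - L, 1)
    for (i, j), (per_lag, plateau_lag, plateau) in results.items():
        if not np.isfinite(plateau):
            out[(i, j)] = MFPTEstimate(
                direction=(i, j), lags=lags, mfpt_per_lag=per_lag,
                plateau_lag=plateau_lag, plateau=np.inf,
                ci=(np.inf, np.inf), n_boot=0,
            )
            continue
        boot = np.empty(n_boot)
        for bq in range(n_boot):
            starts = rng.integers(0, starts_max, size=n_blocks)
            resampled = np.concatenate([labels[s : s + L] for s in starts])[:n]
            boot[bq] = (
                _mean_first_passage_frames(resampled[::plateau_lag], i, j)
                * plateau_lag
                * dt
            )
        lo_q = 0.5 * (1 - ci_level)
        finite = boot[np.isfinite(boot)]
        if finite.size:
            ci = (
                float(np.quantile(finite, lo_q)),
                float(np.quantile(finite, 1 - lo_q)),
            )
        else:
            ci = (np.inf, np.inf)
        out[(i, j)] = MFPTEstimate(
            direction=(i, j), lags=lags, mfpt_per_lag=per_lag,
            plateau_lag=plateau_lag, plateau=plateau, ci=ci, n_boot=n_boot,
        )
    return out
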