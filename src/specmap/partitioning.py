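"""Kinetic coarse-graining of Markov transition matrices.

The row-stochastic matrix of a batch is propagated until its rows stop
changing (each sample's row then approximates its sink distribution),
the rows are merged into metastable groups, and samples whose top two
sink probabilities are within an ambiguity threshold form the
transition-state (TS) ensemble, labeled ``-1``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse.linalg
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import KReductionWarning

__all__ = [
    "Partition",
    "TS_LABEL",
    "propagate",
    "coarse_grain",
    "merge_batches",
    "fit_boundary",
]

TS_LABEL = -1


@dataclasses.dataclass
class Partition:
    """Per-sample metastable assignment with sink probabilities."""

    labels: np.ndarray  # int, TS_LABEL for transition-state samples
    sink_probs: np.ndarray  # (m, k) rows summing to 1
    k_states: int
    delta: float
    t_used: int  # propagation steps actually applied

    @property
    def states(self) -> np.ndarray:
        """Hard state assignment ignoring the TS relabeling."""
        return np.argmax(self.sink_probs, axis=1)

    @property
    def ts_mask(self) -> np.ndarray:
        return self.labels == TS_LABEL


def propagate(M: np.ndarray, t: int) -> np.ndarray:
    """M^t by repeated squaring; stays row-stochastic."""
    M = np.asarray(M, dtype=float)
    if t < 1:
        raise ValueError("t must be >= 1")
    return np.linalg.matrix_power(M, t)


def _ward_rows(rows: np.ndarray, k: int) -> np.ndarray:
    """Ward agglomeration of matrix rows into k groups (0-based labels)."""
    if rows.shape[0] <= k:
        return np.arange(rows.shape[0])
    link = linkage(rows, method="ward")
    return fcluster(link, t=k, criterion="maxclust") - 1


def _top_eigenvalues(M: np.ndarray, n_top: int) -> np.ndarray:
    """Largest real eigenvalue parts of a stochastic matrix, descending."""
    m = M.shape[0]
    if m <= 600 or n_top >= m - 2:
        w = np.linalg.eigvals(M).real
    else:
        try:
            w = scipy.sparse.linalg.eigs(
                M, k=n_top, which="LM", return_eigenvectors=False
            ).real
        except scipy.sparse.linalg.ArpackError:  # pragma: no cover
            w = np.linalg.eigvals(M).real
    return np.sort(w)[::-1][:n_top]


def _plateau_time(M: np.ndarray, k_states: int, t_auto: int) -> int:
    """Propagation time killing fast modes but preserving the slow ones.

    Uses the geometric mean of the implied time scales of the slowest
    retained mode (lambda_{k-1}) and the fastest discarded one
    (lambda_k); with genuine time scale separation any t in between
    works, and the log-midpoint is the robust choice.
    """
    lam = np.clip(_top_eigenvalues(M, k_states + 1), 0.0, 1.0 - 1e-15)
    lam_slow, lam_fast = lam[k_states - 1], lam[k_states]
    t_slow = t_auto if lam_slow <= 0 else min(-1.0 / np.log(lam_slow), t_auto)
    t_fast = 1.0 if lam_fast <= 0 else min(-1.0 / np.log(lam_fast), t_auto)
    return int(np.clip(round(np.sqrt(t_slow * t_fast)), 1, t_auto))


def coarse_grain(
    M: np.ndarray,
    k_states: int = 2,
    t_auto: int = 2**20,
    delta: float = 0.1,
    t: Optional[int] = None,
) -> Partition:
    """Sink-based kinetic partition of the samples behind ``M``.

    The chain is propagated for ``t`` steps (by default an automatic
    choice between the fast and slow implied time scales, capped at
    ``t_auto``) so each row approximates its sink distribution.  Rows
    of the propagated matrix are grouped by Ward's method; per-sample
    sink probabilities are the row mass aggregated over each group.
    Samples whose two largest sink probabilities differ by less than
    ``delta`` are labeled TS.
    """
    M = np.asarray(M, dtype=float)
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if t is None:
        t = _plateau_time(M, k_states, t_auto)
    P = propagate(M, t)
    groups = _ward_rows(P, k_states)
    # aggregate row mass per group
    sink = np.zeros((M.shape[0], k_states))
    for c in range(k_states):
        cols = groups == c
        if np.any(cols):
            sink[:, c] = P[:, cols].sum(axis=1)
    distinct = np.unique(np.round(P, 8), axis=0).shape[0]
    labels = np.argmax(sink, axis=1)
    order = np.sort(sink, axis=1)
    ambiguous = (order[:, -1] - order[:, -2]) < delta
    labels[ambiguous] = TS_LABEL
    if distinct < k_states:
        warnings.warn(
            f"only {distinct} distinct row-clusters found for k={k_states}; "
            "all samples are maximally ambiguous",
            KReductionWarning,
        )
        labels[:] = TS_LABEL
    return Partition(
        labels=labels, sink_probs=sink, k_states=k_states, delta=delta, t_used=t
    )


def merge_batches(
    partitions: Sequence[Partition],
    centroids: Sequence[np.ndarray],
    k_states: int,
) -> List[np.ndarray]:
    """Merge per-batch partitions into consistent global labels.

    ``centroids[b]`` holds one reduced-space centroid per local state of
    batch ``b`` (shape ``(k_b, d)``).  All centroids are agglomerated by
    Ward's method into ``k_states`` global clusters and each batch's
    labels are relabeled through its centroids; TS labels pass through.
    """
    if len(partitions) != len(centroids):
        raise ValueError("one centroid set per partition required")
    cents = [np.atleast_2d(np.asarray(c, dtype=float)) for c in centroids]
    stacked = np.vstack(cents)
    if stacked.shape[0] < k_states:
        raise ValueError(
            f"{stacked.shape[0]} centroids cannot form {k_states} clusters"
        )
    global_of = _ward_rows(stacked, k_states)
    out: List[np.ndarray] = []
    offset = 0
    for part, c in zip(partitions, cents):
        k_b = c.shape[0]
        lut = global_of[offset : offset + k_b]
        offset += k_b
        labels = part.labels.copy()
        core = labels != TS_LABEL
        labels[core] = lut[labels[core]]
        out.append(labels)
    return out


@dataclasses.dataclass
class Boundary:
    """Fitted state-boundary classifier over a 2-D reduced space."""

    predict: callable
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_labels: np.ndarray


def fit_boundary(
    Z: np.ndarray,
    labels: np.ndarray,
    grid: int = 200,
    C: float = 10.0,
    gamma: str = "scale",
) -> Boundary:
    """Maximum-margin (RBF) classifier separating the non-TS states.

    Inputs are standardized before fitting so the boundary is invariant
    under affine rescaling of the CVs.  Returns a callable evaluator
    plus a grid-sampled label field for contour plotting.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError("fit_boundary requires 2-D reduced samples")
    core = labels != TS_LABEL
    classes = np.unique(labels[core])
    if classes.size < 2:
        raise ValueError("need at least two non-TS classes to fit a boundary")
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
    clf.fit(Z[core], labels[core])

    gx = np.linspace(Z[:, 0].min(), Z[:, 0].max(), grid)
    gy = np.linspace(Z[:, 1].min(), Z[:, 1].max(), grid)
    XX, YY = np.meshgrid(gx, gy)
    GL = clf.predict(np.column_stack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    return Boundary(predict=clf.predict, grid_x=gx, grid_y=gy, grid_labels=GL)
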