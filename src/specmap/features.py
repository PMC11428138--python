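"""Feature construction from coordinates and per-feature kinetic scoring.

Features are pairwise Euclidean distances between selected atoms
(lexicographic pair order ``(k, l)`` with ``k > l``), plus the smoothed
fraction-of-native-contacts descriptor.  Each raw feature can also be
scored by the spectral gap of the Markov model built on that feature
alone, and per-residue importances are obtained by summing pair gaps.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import kernels
from .exceptions import (
    DegenerateScaleError,
    EmptyContactSpecError,
    InvalidSelectionError,
)

__all__ = [
    "FeatureMatrix",
    "ContactSpec",
    "pair_order",
    "pairwise_distances",
    "build_contact_spec",
    "fraction_native_contacts",
    "feature_spectral_gaps",
    "residue_importance",
]


@dataclasses.dataclass
class FeatureMatrix:
    """Time-ordered sample-by-feature matrix at uniform spacing ``dt``."""

    values: np.ndarray
    dt: float = 1.0
    names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a T x n matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 time-ordered samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.names is None:
            self.names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must match feature count")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def pair_order(n_atoms: int) -> List[Tuple[int, int]]:
    """All index pairs (k, l), k > l, in lexicographic (k, l) order."""
    return [(k, l) for k in range(1, n_atoms) for l in range(k)]


def pairwise_distances(
    coords: np.ndarray,
    selection: Optional[Sequence[int]] = None,
    dt: float = 1.0,
) -> FeatureMatrix:
    """Pairwise Euclidean distances between selected atoms per frame.

    Parameters
    ----------
    coords : (T, N, 3) array
        Cartesian positions, nanometers.
    selection : sequence of int, optional
        Atom indices (0-based); defaults to all atoms.

    Returns a FeatureMatrix with ``N_sel (N_sel - 1) / 2`` columns named
    ``d_<k>_<l>`` in lexicographic ``(k, l)``, ``k > l`` order, where
    the indices refer to positions within the selection.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (T, N, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain NaN or Inf")
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int), :]
    N = coords.shape[1]
    if N < 2:
        raise InvalidSelectionError(f"need at least 2 atoms, got {N}")
    pairs = pair_order(N)
    ks = np.array([p[0] for p in pairs])
    ls = np.array([p[1] for p in pairs])
    diff = coords[:, ks, :] - coords[:, ls, :]
    dists = np.sqrt(np.einsum("tpc,tpc->tp", diff, diff))
    names = [f"d_{k}_{l}" for k, l in pairs]
    return FeatureMatrix(values=dists, dt=dt, names=names)


@dataclasses.dataclass
class ContactSpec:
    """Native-contact definition: pairs, reference distances, smoothing."""

    pairs: List[Tuple[int, int]]
    x0: np.ndarray  # reference (folded) distances, nm
    alpha_c: float = 50.0  # 1/nm
    gamma: float = 1.5
    cutoff: float = 0.8  # nm
    min_seq_sep: int = 3

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        if len(self.pairs) != self.x0.size:
            raise ValueError("pairs and x0 must have the same length")
        if len(self.pairs) == 0:
            raise EmptyContactSpecError("contact spec has no pairs")
        if self.alpha_c <= 0:
            raise ValueError("alpha_c must be positive")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if np.any(self.x0 >= self.cutoff):
            raise ValueError("all reference distances must be below the cutoff")

    @property
    def n(self) -> int:
        return len(self.pairs)


def build_contact_spec(
    reference: np.ndarray,
    residue_ids: Sequence[int],
    cutoff: float = 0.8,
    min_seq_sep: int = 3,
    alpha_c: float = 50.0,
    gamma: float = 1.5,
) -> ContactSpec:
    """Native contacts from a reference structure.

    A pair (k, l) is native when its reference distance is strictly
    below ``cutoff`` (nm) and the residue separation is strictly
    greater than ``min_seq_sep``.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2 or reference.shape[1] != 3:
        raise ValueError("reference must have shape (N, 3)")
    if not np.all(np.isfinite(reference)):
        raise ValueError("reference contains NaN or Inf")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residue_ids = np.asarray(residue_ids, dtype=int)
    if residue_ids.size != reference.shape[0]:
        raise ValueError("residue_ids must match the number of atoms")
    pairs: List[Tuple[int, int]] = []
    x0: List[float] = []
    for k, l in pair_order(reference.shape[0]):
        if abs(int(residue_ids[k]) - int(residue_ids[l])) <= min_seq_sep:
            continue
        d = float(np.linalg.norm(reference[k] - reference[l]))
        if d < cutoff:
            pairs.append((k, l))
            x0.append(d)
    if not pairs:
        raise EmptyContactSpecError(
            "no pairs below the cutoff with sufficient sequence separation"
        )
    return ContactSpec(
        pairs=pairs, x0=np.asarray(x0), alpha_c=alpha_c, gamma=gamma,
        cutoff=cutoff, min_seq_sep=min_seq_sep,
    )


def fraction_native_contacts(x: np.ndarray, spec: ContactSpec) -> np.ndarray:
    """Smoothed fraction of native contacts q in (0, 1).

    q = (1/n) sum_pairs 1 / (1 + exp(alpha_c (x - gamma x0))); ``x`` is
    a single frame (n,) or a trajectory (T, n) ordered like
    ``spec.pairs``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != spec.n:
        raise ValueError(
            f"expected {spec.n} pair distances per frame, got {x.shape[-1]}"
        )
    arg = spec.alpha_c * (x - spec.gamma * spec.x0)
    # clip to keep exp finite; the sigmoid saturates anyway
    q = 1.0 / (1.0 + np.exp(np.clip(arg, -500.0, 500.0)))
    return q.mean(axis=-1)


def feature_spectral_gaps(
    X: FeatureMatrix,
    k_states: int = 2,
    config: Optional[kernels.KernelConfig] = None,
    n_batches: int = 5,
    batch_size: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Spectral gap of each raw feature used as a 1-D reduced coordinate.

    For every feature, Markov models are built on ``n_batches`` random
    sample batches and their spectral gaps averaged.  Features that are
    constant within every batch get NaN (undefined gap) rather than an
    exception.
    """
    if config is None:
        config = kernels.KernelConfig()
    rng = np.random.default_rng(seed)
    T = X.T
    if batch_size is None:
        batch_size = min(T, 1000)
    batch_size = min(batch_size, T)
    batches = [
        rng.choice(T, size=batch_size, replace=False) for _ in range(n_batches)
    ]
    out = np.full(X.n, np.nan)
    for j in range(X.n):
        col = X.values[:, j]
        gaps = []
        for idx in batches:
            z = col[idx]
            if np.ptp(z) == 0.0:
                continue
            try:
                model = kernels.build_markov_model(
                    z, k_states=k_states, config=config, n_top=k_states + 1
                )
            except DegenerateScaleError:
                continue
            gaps.append(model.sigma)
        if gaps:
            out[j] = float(np.mean(gaps))
    return out


def residue_importance(
    sigma_pairs: Dict[Tuple[int, int], float],
    n_residues: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Per-residue importance r_k = sum_l sigma_kl.

    ``sigma_pairs`` maps residue-index pairs to per-pair spectral gaps;
    NaN entries are skipped.  Returns raw and max-normalized scores.
    """
    if n_residues is None:
        n_residues = 1 + max(max(p) for p in sigma_pairs)
    r = np.zeros(n_residues)
    for (k, l), s in sigma_pairs.items():
        if not np.isfinite(s):
            continue
        r[k] += s
        r[l] += s
    rmax = r.max()
    normalized = r / rmax if rmax > 0 else r.copy()
    return {"raw": r, "normalized": normalized}
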