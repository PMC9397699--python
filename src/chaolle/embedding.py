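"""Phase-space reconstruction: lag by mutual information, dimension by FNN.

A scalar series x_t is delay-embedded into vectors
``[x_s, x_{s+lag}, ..., x_{s+(dim-1)*lag}]`` (Takens reconstruction).
The lag is chosen at the first local minimum of the lagged mutual
information, the dimension as the smallest embedding at which the false
nearest neighbor fraction drops below a threshold (Kennel criteria).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "Trajectory",
    "mutual_information_curve",
    "select_lag",
    "false_nearest_fraction",
    "select_dimension",
    "delay_embed",
]


@dataclass
class EmbeddingParams:
    """Embedding parameters and their search ceilings.

    ``max_lag`` and ``max_dim`` cap the mutual-information and FNN searches;
    these two ceilings are the free parameters the metaheuristic optimizers
    tune. ``lag``/``dim`` hold the selected values once known (may stay None
    until selection has run).
    """

    lag: int | None = None
    dim: int | None = None
    max_lag: int = 10
    max_dim: int = 3
    n_bins: int = 16
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    fnn_frac_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.max_lag < 2 or self.max_dim < 2:
            raise ValueError("max_lag and max_dim must both be >= 2")
        if self.lag is not None and not 1 <= self.lag <= self.max_lag:
            raise ValueError("lag must lie in [1, max_lag]")
        if self.dim is not None and not 2 <= self.dim <= self.max_dim:
            raise ValueError("dim must lie in [2, max_dim]")


@dataclass
class Trajectory:
    """Delay-embedded phase-space points for one scalar signal."""

    points: np.ndarray          # (N - (dim-1)*lag, dim)
    source_length: int
    lag: int
    dim: int

    def __post_init__(self) -> None:
        expected = self.source_length - (self.dim - 1) * self.lag
        if self.points.shape != (expected, self.dim):
            raise ValueError(
                f"trajectory shape {self.points.shape} inconsistent with "
                f"N={self.source_length}, lag={self.lag}, dim={self.dim}")

    def __len__(self) -> int:
        return self.points.shape[0]


def mutual_information_curve(x: np.ndarray, max_lag: int,
                             n_bins: int = 16) -> np.ndarray:
    """Lagged mutual information MI(lag) in bits, for lag = 1..max_lag.

    MI is estimated from an equal-width 2-D histogram of (x_t, x_{t+lag})
    over the range of x, so the curve is invariant under affine transforms
    of the signal. Values are non-negative up to estimator bias.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= max_lag + n_bins:
        raise ValueError(f"series of length {len(x)} too short for max_lag={max_lag} "
                         f"with {n_bins} bins")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series has zero entropy; MI undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    # digitize once; lagged pairing reuses the bin indices
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)

    mi = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = idx[:-lag], idx[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        pa = joint.sum(axis=1)
        pb = joint.sum(axis=0)
        nz = joint > 0
        denom = np.outer(pa, pb)[nz]
        mi[lag - 1] = float(np.sum(joint[nz] * np.log2(joint[nz] / denom)))
    return mi


def select_lag(mi_curve: np.ndarray) -> int:
    """First local minimum of the MI curve; global argmin as fallback.

    Returns a lag in [1, len(mi_curve)] (1-based, matching MI(lag)).
    """
    mi_curve = np.asarray(mi_curve, dtype=float)
    if mi_curve.size == 0:
        raise ValueError("empty MI curve")
    for k in range(1, len(mi_curve) - 1):
        if mi_curve[k - 1] > mi_curve[k] < mi_curve[k + 1]:
            return k + 1
    return int(np.argmin(mi_curve)) + 1


def delay_embed(x: np.ndarray, lag: int, dim: int) -> Trajectory:
    """Takens delay embedding of a scalar series."""
    x = np.asarray(x, dtype=float)
    n_rows = len(x) - (dim - 1) * lag
    if n_rows <= 0:
        raise ValueError(
            f"series of length {len(x)} too short for lag={lag}, dim={dim}; "
            f"need N > (dim-1)*lag = {(dim - 1) * lag}")
    cols = [x[k * lag: k * lag + n_rows] for k in range(dim)]
    return Trajectory(np.column_stack(cols), len(x), lag, dim)


def _nearest_neighbors(points: np.ndarray, theiler: int,
                       exclude_zero: bool = False,
                       ref: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean nearest neighbor per reference point, excluding
    |i-j| <= theiler.

    ``ref`` restricts the reference points (rows) whose neighbor is sought;
    candidates always span the full trajectory. With ``exclude_zero``
    coincident points (distance exactly 0) are also skipped. Ties break
    toward the smallest index. Returns (indices, distances) aligned with
    ``ref``; index -1 where no admissible neighbor exists.

    For the trajectory sizes this package works with (hundreds to a few
    thousand points) a full distance matrix with the Theiler band masked
    out beats a KD-tree that must over-query past the band, so brute force
    is used below a size threshold.
    """
    n = len(points)
    if ref is None:
        ref = np.arange(n)
    if n <= 4000:
        from scipy.spatial.distance import cdist
        D = cdist(points[ref], points)
        for row, r in enumerate(ref):
            D[row, max(0, r - theiler): r + theiler + 1] = np.inf
        if exclude_zero:
            D[D == 0.0] = np.inf
        nn_idx = np.argmin(D, axis=1)
        nn_dist = D[np.arange(len(ref)), nn_idx]
        bad = ~np.isfinite(nn_dist)
        nn_idx[bad] = -1
        return nn_idx, nn_dist

    tree = cKDTree(points)
    # enough candidates to skip the Theiler band plus exact duplicates
    k = min(n, 2 * theiler + 8)
    nn_idx = np.full(len(ref), -1, dtype=int)
    nn_dist = np.full(len(ref), np.inf)
    pending = np.arange(len(ref))
    while len(pending):
        dist, idx = tree.query(points[ref[pending]], k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        ok = np.abs(idx - ref[pending][:, None]) > theiler
        if exclude_zero:
            ok &= dist > 0.0
        found = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        rows = np.where(found)[0]
        sel = pending[rows]
        nn_dist[sel] = dist[rows, first[rows]]
        nn_idx[sel] = idx[rows, first[rows]]
        pending = pending[~found]
        if k == n:
            break
        k = min(n, k * 2)
    return nn_idx, nn_dist


def false_nearest_fraction(x: np.ndarray, lag: int, dim: int,
                           rtol: float = 15.0, atol: float = 2.0,
                           theiler: int | None = None,
                           max_ref: int = 512) -> float:
    """Fraction of nearest neighbors at dimension ``dim`` that are false.

    A neighbor pair is false (Kennel criteria) if adding the (dim+1)-th
    delay coordinate stretches it by more than ``rtol`` relative to its
    distance at dimension ``dim``, or moves it beyond ``atol`` times the
    attractor size (std of the series). Neighbors closer than the Theiler
    window (default: the lag itself) are excluded as temporally correlated.
    """
    x = np.asarray(x, dtype=float)
    if theiler is None:
        theiler = lag
    needed = (dim + 1 - 1) * lag + 2 * (theiler + 1)
    if len(x) <= needed:
        raise ValueError(
            f"series of length {len(x)} too short for FNN at dim={dim}, "
            f"lag={lag}: need > (dim)*lag + 2*(theiler+1) = {needed} samples")
    traj_hi = delay_embed(x, lag, dim + 1)
    pts_hi = traj_hi.points
    pts_lo = pts_hi[:, :dim]          # dim-embedding restricted to shared rows
    n = len(pts_hi)
    if n < 2 * (theiler + 1):
        raise ValueError("too few embedded points beyond the Theiler window")

    ref = np.arange(0, n, max(1, int(np.ceil(n / max_ref))))
    nn_idx, nn_dist = _nearest_neighbors(pts_lo, theiler, ref=ref)
    valid = nn_idx >= 0
    if not valid.any():
        raise ValueError("no admissible neighbor pairs for FNN")
    attractor_size = x.std()
    extra = np.abs(pts_hi[ref, dim] - pts_hi[nn_idx, dim])
    dist_hi = np.sqrt(nn_dist ** 2 + extra ** 2)
    d = nn_dist[valid]
    e = extra[valid]
    hi = dist_hi[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_false = np.where(d > 0, e / np.where(d > 0, d, 1.0) > rtol, False)
    # coincident points: false only if the new coordinate separates them
    # beyond the attractor-size criterion
    size_false = np.where(d > 0, hi / attractor_size > atol,
                          e / attractor_size > atol)
    return float(np.mean(ratio_false | size_false))


def select_dimension(x: np.ndarray, lag: int, max_dim: int,
                     fnn_frac_threshold: float = 0.01,
                     rtol: float = 15.0, atol: float = 2.0,
                     theiler: int | None = None) -> int:
    """Smallest dim in [2, max_dim] whose FNN fraction is below threshold.

    Returns ``max_dim`` when the fraction never drops below the threshold
    (noise-like signals never unfold).
    """
    for dim in range(2, max_dim + 1):
        frac = false_nearest_fraction(x, lag, dim, rtol=rtol, atol=atol,
                                      theiler=theiler)
        if frac <= fnn_frac_threshold:
            return dim
    return max_dim
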