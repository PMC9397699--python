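"""Largest Lyapunov exponent from the average-log-divergence curve.

For every point of a delay-embedded trajectory the nearest neighbor outside
a Theiler window is found; the pairs' Euclidean separation is tracked over
i = 0..max_steps and averaged in the log:

    D(i) = (1/j) * sum_j ln Q_j(i)

For a chaotic signal D(i) grows linearly at rate gamma_1 * dt before the
pair distances saturate at the attractor size; the largest Lyapunov
exponent is the least-squares slope of D over the pre-saturation range,
divided by the sampling interval dt.

``LLEFeatureExtractor`` wraps the full per-signal pipeline — mutual-
information lag selection, FNN dimension selection, embedding, divergence
fit — as a scikit-learn transformer turning an epoch set into a
(n_epochs, n_channels) feature matrix. ``_SignalMemo`` holds the
per-signal intermediate results (MI curve, FNN fractions, exponents per
(lag, dim) cell) that the pipeline's feature cache reuses when an
optimizer sweeps the search ceilings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import embedding as emb
from .embedding import EmbeddingParams, Trajectory, _nearest_neighbors
from .preprocess import EpochSet

__all__ = [
    "DivergenceCurve",
    "LLEResult",
    "divergence_curve",
    "largest_lyapunov",
    "lle_feature",
    "LLEFeatureExtractor",
]


@dataclass
class DivergenceCurve:
    """Mean log pair-separation per divergence step."""

    steps: np.ndarray           # step indices i with at least one pair
    mean_log_dist: np.ndarray   # <ln Q_j(i)> over contributing pairs
    n_pairs: np.ndarray         # pairs contributing per step
    dt: float                   # seconds per sample
    extent: float               # attractor extent (max coordinate range)

    def __post_init__(self) -> None:
        if np.any(self.n_pairs <= 0):
            raise ValueError("every reported step needs at least one pair")
        if not np.all(np.isfinite(self.mean_log_dist)):
            raise ValueError("non-finite mean log distance")


@dataclass
class LLEResult:
    """Largest Lyapunov exponent with its fit diagnostics."""

    lle: float                  # nats per second (per iteration when dt=1)
    fit_range: tuple[int, int]  # (i_start, i_end) inclusive, in step units
    r2: float
    curve: DivergenceCurve


def divergence_curve(traj: Trajectory, theiler: int | None = None,
                     max_steps: int = 100, dt: float = 1.0,
                     max_pairs: int = 512) -> DivergenceCurve:
    """Track nearest-neighbor pair separations along the trajectory.

    Pairs with zero initial separation are excluded (their log distance is
    undefined). At most ``max_pairs`` reference points (an even stride over
    the trajectory) seed pairs; the slope estimate is an average over pairs
    and is insensitive to this cap.
    """
    pts = traj.points
    n = len(pts)
    if theiler is None:
        theiler = traj.lag
    if n < theiler + 10:
        raise ValueError(f"trajectory of {n} points too short beyond "
                         f"theiler={theiler}")
    ref = np.arange(0, n, max(1, int(np.ceil(n / max_pairs))))
    nn_idx, nn_dist = _nearest_neighbors(pts, theiler, exclude_zero=True,
                                         ref=ref)
    valid = (nn_idx >= 0) & np.isfinite(nn_dist)
    base = ref[valid]
    if base.size == 0:
        raise ValueError(
            f"no admissible neighbor pairs (theiler={theiler}, n={n})")
    partner = nn_idx[valid]
    extent = float(np.max(pts.max(axis=0) - pts.min(axis=0)))

    # Fix the pair population to pairs that survive the whole horizon, so
    # the per-step mean always averages the same pairs; otherwise pairs
    # near the end of the record drop out as i grows and the changing
    # composition biases the curve (severely so for transient signals).
    max_steps = min(max_steps, n - 1)
    horizon = max_steps
    while horizon > 3:
        keep = (base + horizon < n) & (partner + horizon < n)
        if keep.sum() >= min(10, base.size):
            break
        horizon //= 2
    keep = (base + horizon < n) & (partner + horizon < n)
    if not keep.any():
        raise ValueError(
            f"no neighbor pairs survive a {horizon}-step horizon "
            f"(theiler={theiler}, n={n})")
    base, partner = base[keep], partner[keep]

    offsets = np.arange(horizon + 1)
    diffs = pts[base[:, None] + offsets[None, :]] \
        - pts[partner[:, None] + offsets[None, :]]
    D = np.sqrt(np.sum(diffs * diffs, axis=-1))       # (n_pairs, steps+1)
    pos = D > 0
    counts = pos.sum(axis=0)
    keep_steps = counts > 0
    with np.errstate(divide="ignore"):
        logs = np.where(pos, np.log(np.where(pos, D, 1.0)), 0.0)
    means = logs.sum(axis=0)[keep_steps] / counts[keep_steps]
    return DivergenceCurve(offsets[keep_steps], means,
                           counts[keep_steps].astype(int), dt, extent)


def _auto_fit_range(curve: DivergenceCurve,
                    saturation_frac: float = 0.5) -> tuple[int, int]:
    """Steps before the mean pair distance saturates.

    Pair separations cannot exceed the attractor size, so the log-divergence
    curve flattens at a plateau; the linear fit must stop before that. The
    fit ends at the first step where the curve has closed ``saturation_frac``
    of the gap between its initial value and its plateau (curve maximum,
    itself capped by the attractor extent). For flat or decaying curves the
    gap is ~0 and the rule keeps the earliest 3 steps, where the local slope
    equals the exponent.
    """
    y = curve.mean_log_dist
    plateau = min(float(y.max()), np.log(curve.extent))
    threshold = y[0] + saturation_frac * (plateau - y[0])
    above = np.where(y > threshold)[0]
    end = above[0] - 1 if above.size else len(curve.steps) - 1
    end = max(end, 2)  # keep at least 3 points
    return int(curve.steps[0]), int(curve.steps[end])


def largest_lyapunov(curve: DivergenceCurve,
                     fit_range: tuple[int, int] | None = None,
                     saturation_frac: float = 0.5) -> LLEResult:
    """Least-squares slope of the divergence curve over the fit range."""
    if fit_range is None:
        fit_range = _auto_fit_range(curve, saturation_frac)
    i0, i1 = fit_range
    mask = (curve.steps >= i0) & (curve.steps <= i1)
    xs = curve.steps[mask].astype(float)
    ys = curve.mean_log_dist[mask]
    if xs.size < 3:
        raise ValueError(f"fit range {fit_range} covers fewer than 3 steps")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate fit: zero variance in step index")
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LLEResult(float(slope) / curve.dt, (int(i0), int(i1)),
                     float(np.clip(r2, 0.0, 1.0)), curve)


def lle_feature(signal: np.ndarray, params: EmbeddingParams,
                dt: float = 1.0, max_steps: int = 100) -> float:
    """Scalar LLE feature of one signal: MI lag -> FNN dim -> embed -> fit."""
    signal = np.asarray(signal, dtype=float)
    try:
        mi = emb.mutual_information_curve(signal, params.max_lag, params.n_bins)
        lag = emb.select_lag(mi)
    except ValueError as exc:
        raise ValueError(f"lag selection failed: {exc}") from exc
    try:
        dim = emb.select_dimension(signal, lag, params.max_dim,
                                   params.fnn_frac_threshold,
                                   params.fnn_rtol, params.fnn_atol)
    except ValueError as exc:
        raise ValueError(f"dimension selection failed: {exc}") from exc
    try:
        traj = emb.delay_embed(signal, lag, dim)
        curve = divergence_curve(traj, theiler=lag, max_steps=max_steps, dt=dt)
        return largest_lyapunov(curve).lle
    except ValueError as exc:
        raise ValueError(f"divergence estimation failed: {exc}") from exc


class _SignalMemo:
    """Per-signal cache of lag/dimension selections and LLE values.

    The selected lag is a pure function of the MI curve prefix, the
    selected dimension of (lag, max_dim), and the LLE of (lag, dim) — so
    sweeping the two ceilings revisits a small set of distinct cells.
    """

    def __init__(self, x: np.ndarray, params: EmbeddingParams, dt: float,
                 max_steps: int):
        self.x = np.asarray(x, dtype=float)
        self.params = params
        self.dt = dt
        self.max_steps = max_steps
        self._mi: np.ndarray | None = None
        self._lag_by_ceiling: dict[int, int] = {}
        self._fnn: dict[tuple[int, int], float] = {}
        self._dim_by_key: dict[tuple[int, int], int] = {}
        self._lle: dict[tuple[int, int], float] = {}

    def _mi_curve(self, max_lag: int) -> np.ndarray:
        if self._mi is None or len(self._mi) < max_lag:
            self._mi = emb.mutual_information_curve(self.x, max_lag,
                                                    self.params.n_bins)
        return self._mi[:max_lag]

    def lag(self, max_lag: int) -> int:
        if max_lag not in self._lag_by_ceiling:
            self._lag_by_ceiling[max_lag] = emb.select_lag(self._mi_curve(max_lag))
        return self._lag_by_ceiling[max_lag]

    def _fnn_frac(self, lag: int, dim: int) -> float:
        key = (lag, dim)
        if key not in self._fnn:
            p = self.params
            self._fnn[key] = emb.false_nearest_fraction(
                self.x, lag, dim, rtol=p.fnn_rtol, atol=p.fnn_atol)
        return self._fnn[key]

    def dim(self, lag: int, max_dim: int) -> int:
        key = (lag, max_dim)
        if key not in self._dim_by_key:
            chosen = max_dim
            for d in range(2, max_dim + 1):
                if self._fnn_frac(lag, d) <= self.params.fnn_frac_threshold:
                    chosen = d
                    break
            self._dim_by_key[key] = chosen
        return self._dim_by_key[key]

    def feature(self, max_lag: int, max_dim: int) -> float:
        lag = self.lag(max_lag)
        dim = self.dim(lag, max_dim)
        key = (lag, dim)
        if key not in self._lle:
            traj = emb.delay_embed(self.x, lag, dim)
            curve = divergence_curve(traj, theiler=lag,
                                     max_steps=self.max_steps, dt=self.dt)
            self._lle[key] = largest_lyapunov(curve).lle
        return self._lle[key]


class LLEFeatureExtractor(BaseEstimator, TransformerMixin):
    """Turn labeled epochs into per-channel LLE features.

    Parameters
    ----------
    max_lag, max_dim : int
        Search ceilings for the mutual-information lag and the FNN embedding
        dimension; the "traditional" configuration is (10, 3).
    n_bins : int
        Histogram bins for the MI estimate.
    fnn_rtol, fnn_atol, fnn_frac_threshold : float
        Kennel FNN criteria and acceptance threshold.
    max_steps : int
        Divergence-tracking horizon in samples.
    time_unit : {"sample", "second"}
        Whether the exponent is reported per sample (dt = 1) or per second
        (dt = 1/fs, requires an :class:`EpochSet` input).

    ``transform`` accepts an :class:`EpochSet` or a raw
    (n_epochs, n_channels, n_samples) array and returns an
    (n_epochs, n_channels) matrix of exponents.
    """

    def __init__(self, max_lag: int = 10, max_dim: int = 3, n_bins: int = 16,
                 fnn_rtol: float = 15.0, fnn_atol: float = 2.0,
                 fnn_frac_threshold: float = 0.01, max_steps: int = 100,
                 time_unit: str = "sample"):
        self.max_lag = max_lag
        self.max_dim = max_dim
        self.n_bins = n_bins
        self.fnn_rtol = fnn_rtol
        self.fnn_atol = fnn_atol
        self.fnn_frac_threshold = fnn_frac_threshold
        self.max_steps = max_steps
        self.time_unit = time_unit

    def _params(self) -> EmbeddingParams:
        return EmbeddingParams(max_lag=self.max_lag, max_dim=self.max_dim,
                               n_bins=self.n_bins, fnn_rtol=self.fnn_rtol,
                               fnn_atol=self.fnn_atol,
                               fnn_frac_threshold=self.fnn_frac_threshold)

    def fit(self, X, y=None):
        if self.time_unit not in ("sample", "second"):
            raise ValueError("time_unit must be 'sample' or 'second'")
        self._params()  # validates ceilings
        self.n_channels_in_ = (X.data.shape[1] if isinstance(X, EpochSet)
                               else np.asarray(X).shape[1])
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_channels_in_"):
            self.fit(X)
        if isinstance(X, EpochSet):
            data, fs = X.data, X.fs
        else:
            data, fs = np.asarray(X, dtype=float), None
        if data.ndim != 3:
            raise ValueError("expected (epochs, channels, samples) input")
        dt = 1.0
        if self.time_unit == "second":
            if fs is None:
                raise ValueError("time_unit='second' requires an EpochSet "
                                 "with a sampling rate")
            dt = 1.0 / fs
        params = self._params()
        out = np.empty(data.shape[:2])
        for e in range(data.shape[0]):
            for c in range(data.shape[1]):
                out[e, c] = lle_feature(data[e, c], params, dt=dt,
                                        max_steps=self.max_steps)
        return out
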