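"""End-to-end pipelines: traditional LLE vs optimizer-tuned (OLLE) variants.

Three pipeline variants mirror the comparison of interest:

* ``traditional`` — embedding search ceilings fixed at (max lag 10,
  max dimension 3);
* ``wd`` — the per-class ceilings are tuned by the Intelligent Water Drop
  optimizer over the integer grid;
* ``ctw`` — the ceilings are tuned by the chaotic Tug-of-War optimizer.

The optimization objective is the four-parameter vector
theta = (max_lag_open, max_dim_open, max_lag_fist, max_dim_fist): each
class's epochs are embedded under its own ceilings, per-channel LLE
features are extracted, and the fitness is either 1 - cross-validated
accuracy or a cheap Fisher-ratio surrogate (1 / (1 + J)).

Leakage control: epochs are split once into an optimizer-search partition
and a held-out partition; the optimizer's fitness only ever sees search
epochs, and the reported accuracy is always measured on the held-out
epochs. Per-signal feature memoization makes repeated fitness evaluations
cheap, since lag/dimension selection under different ceilings lands on few
distinct (lag, dim) cells; cached integer cells do not consume optimizer
budget.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from .classify import GRBFParams
from .embedding import EmbeddingParams
from .lyapunov import _SignalMemo
from .optimizers import IWDConfig, SearchSpace, TWConfig, optimize
from .preprocess import EpochSet, bandpass_filter, select_channels

__all__ = [
    "PipelineConfig",
    "RunReport",
    "FeatureCache",
    "fitness_from_params",
    "run_offline",
    "report_table",
]

METHODS = ("traditional", "wd", "ctw")

#: ceiling bounds of the four-parameter search: lags in [2, 100],
#: dimensions in [2, 60]
LAG_BOUNDS = (2, 100)
DIM_BOUNDS = (2, 60)
TRADITIONAL_CEILINGS = (10, 3)


@dataclass
class PipelineConfig:
    """Everything one offline run needs; reproducible from (config, seed)."""

    method: str = "traditional"
    band: tuple[float, float] = (8.0, 15.0)
    filter_order: int = 6
    channels: tuple[str, ...] | None = None      # None: keep all channels
    # classifier
    C: float = 1.0
    tau: float = 2.0
    sigma: float | None = None                   # None: median heuristic
    n_repeats: int = 100
    cv_folds: int = 5
    screen_alpha: float = 0.05
    # optimizer
    fitness_kind: str = "fisher"                 # "fisher" | "cv"
    max_evaluations: int = 10_000
    fitness_epochs_per_class: int = 32
    holdout_frac: float = 0.3
    map_id: str = "logistic"
    # embedding
    n_bins: int = 16
    fnn_frac_threshold: float = 0.01
    max_steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.fitness_kind not in ("fisher", "cv"):
            raise ValueError("fitness_kind must be 'fisher' or 'cv'")


@dataclass
class RunReport:
    """Outcome of one offline pipeline run."""

    method: str
    mean_accuracy: float
    accuracies: list[float]
    selected_ceilings: dict          # {"open": [lag, dim], "fist": [lag, dim]}
    screen: dict                     # per-channel {"t":, "p":, "kept":}
    n_fitness_evaluations: int
    eval_history: list
    seed: int
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


class FeatureCache:
    """Per-signal LLE feature memos for one epoch set.

    ``features(indices, ceilings_by_class)`` extracts the per-channel LLE
    feature matrix for the requested epochs, embedding each epoch under its
    class's (max_lag, max_dim) ceilings. Epochs whose signals cannot be
    embedded at the selected parameters are skipped; if more than 20% of
    the requested epochs drop out the extraction fails.
    """

    def __init__(self, epochs: EpochSet, config: PipelineConfig):
        self.epochs = epochs
        self.config = config
        self._memos: dict[tuple[int, int], _SignalMemo] = {}

    def _memo(self, ep: int, ch: int) -> _SignalMemo:
        key = (ep, ch)
        if key not in self._memos:
            params = EmbeddingParams(
                max_lag=max(LAG_BOUNDS[1], TRADITIONAL_CEILINGS[0]),
                max_dim=max(DIM_BOUNDS[1], TRADITIONAL_CEILINGS[1]),
                n_bins=self.config.n_bins,
                fnn_frac_threshold=self.config.fnn_frac_threshold)
            self._memos[key] = _SignalMemo(self.epochs.data[ep, ch], params,
                                           dt=1.0,
                                           max_steps=self.config.max_steps)
        return self._memos[key]

    def features(self, indices, ceilings_by_class: dict,
                 max_skip_frac: float = 0.2):
        """Label-free feature rows: every epoch is embedded under BOTH
        classes' ceilings and the per-channel features are concatenated
        (open-ceiling block first). Extracting under the epoch's own
        class ceilings only would require the label at prediction time —
        a leak that turns any class-dependent feature scale into fake
        accuracy."""
        indices = np.asarray(indices, dtype=int)
        n_ch = self.epochs.data.shape[1]
        settings = [tuple(ceilings_by_class[0]), tuple(ceilings_by_class[1])]
        if settings[0] == settings[1]:
            settings = settings[:1]
        rows, labels, kept = [], [], []
        skipped = []
        for ep in indices:
            try:
                row = [self._memo(ep, ch).feature(max_lag, max_dim)
                       for (max_lag, max_dim) in settings
                       for ch in range(n_ch)]
            except ValueError:
                skipped.append(ep)
                continue
            rows.append(row)
            labels.append(int(self.epochs.labels[ep]))
            kept.append(ep)
        if len(skipped) > max_skip_frac * len(indices):
            raise ValueError(
                f"{len(skipped)}/{len(indices)} epochs infeasible under "
                f"ceilings {ceilings_by_class}; first offenders {skipped[:5]}")
        return np.asarray(rows), np.asarray(labels, dtype=int), np.asarray(kept)


def _validate_theta(theta) -> tuple[tuple[int, int], tuple[int, int]]:
    t = np.round(np.asarray(theta, dtype=float)).astype(int)
    if t.shape != (4,):
        raise ValueError("theta must be a 4-vector "
                         "(max_lag_open, max_dim_open, max_lag_fist, max_dim_fist)")
    for lag in (t[0], t[2]):
        if not LAG_BOUNDS[0] <= lag <= LAG_BOUNDS[1]:
            raise ValueError(f"max lag {lag} outside {LAG_BOUNDS}")
    for dim in (t[1], t[3]):
        if not DIM_BOUNDS[0] <= dim <= DIM_BOUNDS[1]:
            raise ValueError(f"max dim {dim} outside {DIM_BOUNDS}")
    return (int(t[0]), int(t[1])), (int(t[2]), int(t[3]))


def _fisher_ratio(X: np.ndarray, y: np.ndarray) -> float:
    """Summed per-feature Fisher discriminant ratio between the classes."""
    a, b = X[y == 0], X[y == 1]
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0) + b.var(axis=0) + 1e-12
    return float(np.sum(num / den))


def fitness_from_params(theta, cache: FeatureCache, indices,
                        config: PipelineConfig) -> float:
    """Cost of one ceiling 4-vector on the given (search) epochs.

    Returns ``1 - cv_accuracy`` or the Fisher surrogate ``1 / (1 + J)``,
    both minimized, both bounded by (0, 1].
    """
    open_c, fist_c = _validate_theta(theta)
    X, y, _ = cache.features(indices, {0: open_c, 1: fist_c})
    if len(np.unique(y)) < 2:
        return 1.0
    if config.fitness_kind == "fisher":
        return 1.0 / (1.0 + _fisher_ratio(X, y))
    sigma = config.sigma or clf.median_heuristic_sigma(X)
    acc = clf.cross_validated_accuracy(
        X, y, k=config.cv_folds, C=config.C,
        params=GRBFParams(sigma, config.tau), seed=config.seed)
    return 1.0 - acc


def _search_ceilings(cache: FeatureCache, search_idx, config: PipelineConfig):
    """Run the configured optimizer over theta; returns ceilings + history."""
    rng = np.random.default_rng(config.seed)
    sub = []
    labels = cache.epochs.labels
    for cls in (0, 1):
        cls_idx = np.asarray(search_idx)[labels[search_idx] == cls]
        take = min(len(cls_idx), config.fitness_epochs_per_class)
        sub.extend(rng.choice(cls_idx, size=take, replace=False))
    sub = np.sort(np.array(sub))

    def cost(theta):
        try:
            return fitness_from_params(theta, cache, sub, config)
        except ValueError:
            return 1.0  # infeasible cell

    lo = [LAG_BOUNDS[0], DIM_BOUNDS[0]] * 2
    hi = [LAG_BOUNDS[1], DIM_BOUNDS[1]] * 2
    space = SearchSpace(np.array(lo, dtype=float), np.array(hi, dtype=float),
                        integer_mask=np.ones(4, dtype=bool))
    if config.method == "wd":
        iwd = IWDConfig(max_evaluations=config.max_evaluations,
                        max_iterations=10 ** 9, seed=config.seed)
        res = optimize(cost, space, method="iwd", config=iwd)
    else:
        tw = TWConfig(max_evaluations=config.max_evaluations,
                      seed=config.seed, map_id=config.map_id,
                      cache_rounded=True)
        res = optimize(cost, space, method="ctw", config=tw)
    open_c, fist_c = _validate_theta(res.best_x)
    return open_c, fist_c, res


def _feature_names(channel_names, ceilings: dict) -> list[str]:
    """Column names of the concatenated feature table."""
    settings = [tuple(ceilings[0]), tuple(ceilings[1])]
    if settings[0] == settings[1]:
        return [f"{ch}" for ch in channel_names]
    return [f"{ch}[{tag}]" for tag, s in zip(("open", "fist"), settings)
            for ch in channel_names]


def _screen_channels(X: np.ndarray, y: np.ndarray, channel_names,
                     alpha: float) -> dict:
    """Paired t-test per feature column: open vs fist epoch features.

    Epochs are paired by within-class order (the generator and segmenter
    produce matched counts); unequal counts are truncated to the shorter
    class. Columns advance only when p < alpha; if no column survives,
    all are kept (flagged), since classification needs at least one input.
    """
    a_all, b_all = X[y == 0], X[y == 1]
    n = min(len(a_all), len(b_all))
    screen = {}
    any_kept = False
    for ch, name in enumerate(channel_names):
        try:
            t, p = clf.paired_feature_ttest(a_all[:n, ch], b_all[:n, ch])
        except ValueError:
            t, p = 0.0, 1.0
        kept = bool(p < alpha)
        any_kept |= kept
        screen[name] = {"t": float(t), "p": float(p), "kept": kept}
    if not any_kept:
        for name in screen:
            screen[name]["kept"] = True
            screen[name]["forced"] = True
    return screen


def run_offline(config: PipelineConfig, epochs: EpochSet) -> RunReport:
    """Execute one full pipeline variant and report averaged accuracy."""
    if len(np.unique(epochs.labels)) < 2:
        raise ValueError("pipeline.run_offline: epochs must contain both classes")
    try:
        if config.channels is not None:
            epochs = select_channels(epochs, list(config.channels))
        epochs = bandpass_filter(epochs, *config.band,
                                 order=config.filter_order)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {exc}") from exc

    rng = np.random.default_rng(config.seed)
    # stratified search/holdout partition: the optimizer and all model
    # training see only the search epochs; accuracy is measured on holdout
    search_idx, holdout_idx = [], []
    for cls in np.unique(epochs.labels):
        idx = np.where(epochs.labels == cls)[0]
        rng.shuffle(idx)
        n_hold = max(1, int(round(config.holdout_frac * len(idx))))
        holdout_idx.extend(idx[:n_hold])
        search_idx.extend(idx[n_hold:])
    search_idx = np.sort(np.array(search_idx))
    holdout_idx = np.sort(np.array(holdout_idx))

    cache = FeatureCache(epochs, config)
    if config.method == "traditional":
        open_c = fist_c = TRADITIONAL_CEILINGS
        history, n_evals = [], 0
    else:
        try:
            open_c, fist_c, res = _search_ceilings(cache, search_idx, config)
            history, n_evals = res.history, res.n_evaluations
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'optimize' failed: {exc}") from exc

    ceilings = {0: open_c, 1: fist_c}
    try:
        X_tr, y_tr, _ = cache.features(search_idx, ceilings)
        X_ho, y_ho, _ = cache.features(holdout_idx, ceilings)
    except ValueError as exc:
        raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc

    names = _feature_names(epochs.channel_names, ceilings)
    screen = _screen_channels(X_tr, y_tr, names, config.screen_alpha)
    keep = [k for k, name in enumerate(names) if screen[name]["kept"]]
    X_tr, X_ho = X_tr[:, keep], X_ho[:, keep]

    accuracies = []
    for rep in range(config.n_repeats):
        tr, _, _ = clf.split_70_25_5(y_tr, seed=config.seed + 1000 + rep)
        sigma = config.sigma or clf.median_heuristic_sigma(X_tr[tr])
        model = clf.train_smsvm(X_tr[tr], y_tr[tr], C=config.C,
                                params=GRBFParams(sigma, config.tau))
        accuracies.append(float(np.mean(model.predict(X_ho) == y_ho)))

    cfg_dict = asdict(config)
    return RunReport(
        method=config.method,
        mean_accuracy=float(np.mean(accuracies)),
        accuracies=accuracies,
        selected_ceilings={"open": list(open_c), "fist": list(fist_c)},
        screen=screen,
        n_fitness_evaluations=n_evals,
        eval_history=[list(h) for h in history[-50:]],
        seed=config.seed,
        config=cfg_dict,
    )


def report_table(reports) -> pd.DataFrame:
    """Comparison table: one column per run, rows lag/dimension/accuracy."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    if any(not r.accuracies for r in reports):
        raise ValueError("report with empty accuracy list")
    cols = {}
    for r in reports:
        lag = "{}|{}".format(r.selected_ceilings["open"][0],
                             r.selected_ceilings["fist"][0])
        dim = "{}|{}".format(r.selected_ceilings["open"][1],
                             r.selected_ceilings["fist"][1])
        cols[r.method] = {
            "max_selected_lag (open|fist)": lag,
            "max_selected_dimension (open|fist)": dim,
            "mean_accuracy": round(r.mean_accuracy, 4),
        }
    return pd.DataFrame(cols)
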