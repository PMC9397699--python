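"""Population metaheuristics for the embedding-ceiling search.

Three optimizers are provided behind one ``optimize`` front end:

* **Tug-of-War (TW)** — candidate solutions are teams with fitness-derived
  weights in [1, 2]; lighter teams are pulled toward heavier ones with an
  acceleration proportional to the weight difference, plus a decaying
  random perturbation.
* **Chaotic Tug-of-War (CTW)** — identical dynamics, but the stochastic
  perturbation is driven by iterates of a 1-D chaotic map (ergodic and
  non-repeating) into which the pair's normalized fitness difference is
  folded.
* **Intelligent Water Drops (IWD)** — a layered-graph swarm: one layer per
  decision variable, nodes are candidate values; drops prefer low-soil
  edges, gain velocity on them, and erode soil locally and along the
  iteration-best path globally.

All methods are capped by a hard budget of cost-function evaluations
(default 10,000) enforced by a counting wrapper, and are reproducible from
a seed. Minimization is the convention throughout; classification fitness
is passed as (1 - accuracy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chaotic_maps import ChaoticMap, ChaoticMapSpec

__all__ = [
    "SearchSpace", "Team", "TWConfig", "IWDConfig", "OptimizeResult",
    "tw_initialize", "tw_weights", "tw_step", "ctw_step",
    "optimize", "iwd_optimize",
    "BENCHMARK_FUNCTIONS", "benchmark_suite",
]


@dataclass
class SearchSpace:
    """A box [lb, ub] in R^d, with optional integer coordinates.

    Integer coordinates are searched continuously by TW/CTW and rounded
    only when the fitness is evaluated; IWD searches their grid natively.
    """

    lb: np.ndarray
    ub: np.ndarray
    integer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape or np.any(self.lb >= self.ub):
            raise ValueError("need lb < ub elementwise")
        if self.integer_mask is None:
            self.integer_mask = np.zeros(self.lb.shape, dtype=bool)
        else:
            self.integer_mask = np.asarray(self.integer_mask, dtype=bool)
            if self.integer_mask.shape != self.lb.shape:
                raise ValueError("integer_mask shape mismatch")

    @property
    def dim(self) -> int:
        return self.lb.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def round_integers(self, x: np.ndarray) -> np.ndarray:
        if not self.integer_mask.any():
            return x
        out = np.array(x, dtype=float)
        out[..., self.integer_mask] = np.round(out[..., self.integer_mask])
        return out


@dataclass
class Team:
    """One candidate solution of the Tug-of-War population."""

    position: np.ndarray
    fitness: float = math.inf
    weight: float = 1.5


@dataclass
class TWConfig:
    """Tug-of-War / chaotic Tug-of-War settings.

    ``alpha`` is the geometric decay base of the perturbation scale
    (scale at iteration k is ``alpha**k * beta`` times the box width) and
    ``beta`` its initial magnitude; neither has a published value, so the
    defaults were chosen for stable convergence on the standard benchmark
    suite. ``mu`` is the friction coefficient of the pulling force (it
    cancels between force and inertia for the max-pull convention but is
    kept for fidelity to the update equations). ``dt`` is the step time;
    values below 1 damp the summed pair pulls, which is what keeps a
    20-team population from overshooting.
    """

    n_teams: int = 20
    alpha: float = 0.996
    beta: float = 0.6
    mu: float = 1.0
    dt: float = 0.3
    max_evaluations: int = 10_000
    seed: int = 0
    map_id: str | None = None          # CTW only
    map_x0: float = 0.7
    mix_fitness: bool = False          # fold |F_i - F_j| into the map state
    cache_rounded: bool = False        # memoize integer cells
    count_cached: bool = False         # budget cached hits as evaluations

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.max_evaluations < self.n_teams:
            raise ValueError("max_evaluations must be at least n_teams")


@dataclass
class IWDConfig:
    """Intelligent Water Drops settings (classic parameterization)."""

    n_drops: int = 20
    max_iterations: int = 500
    a_v: float = 1.0
    b_v: float = 0.01
    c_v: float = 1.0
    a_s: float = 1.0
    b_s: float = 0.01
    c_s: float = 1.0
    init_soil: float = 10_000.0
    init_velocity: float = 4.0
    rho_local: float = 0.9
    rho_global: float = 0.9
    eps_soil: float = 1e-4
    p_explore: float = 0.1             # uniform node choice fraction
    max_evaluations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_local", "rho_global"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


class BudgetExhausted(Exception):
    """Raised internally when the evaluation budget is spent."""


class _BudgetedFitness:
    """Counting (and optionally caching) wrapper around a cost function.

    Non-finite fitness values are recorded as +inf (worst) with a warning.
    When ``cache_key`` is set, repeated evaluations of the same rounded
    cell return the memo; by default those hits do not consume budget.
    """

    def __init__(self, fn, max_evaluations: int, space: SearchSpace,
                 cache_rounded: bool = False, count_cached: bool = False):
        self.fn = fn
        self.max_evaluations = max_evaluations
        self.space = space
        self.n_evaluations = 0
        self.best_f = math.inf
        self.best_x: np.ndarray | None = None
        self.history: list[tuple[int, float]] = []
        self._cache: dict | None = {} if cache_rounded else None
        self.count_cached = count_cached

    def __call__(self, x: np.ndarray) -> float:
        x = self.space.round_integers(np.asarray(x, dtype=float))
        key = None
        if self._cache is not None:
            key = tuple(np.round(x, 12))
            if key in self._cache and not self.count_cached:
                return self._cache[key]
        if self.n_evaluations >= self.max_evaluations:
            raise BudgetExhausted
        f = float(self.fn(x))
        if not math.isfinite(f):
            warnings.warn(f"non-finite fitness at {x}; treated as worst")
            f = math.inf
        self.n_evaluations += 1
        if f < self.best_f:
            self.best_f = f
            self.best_x = x.copy()
        self.history.append((self.n_evaluations, self.best_f))
        if key is not None:
            self._cache[key] = f
        return f


@dataclass
class OptimizeResult:
    best_x: np.ndarray
    best_f: float
    history: list[tuple[int, float]] = field(repr=False, default_factory=list)
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# Tug-of-War


def tw_initialize(space: SearchSpace, n_teams: int,
                  seed: int | np.random.Generator = 0) -> list[Team]:
    """Uniform random positions in the box: X = LB + rand * (UB - LB)."""
    if n_teams < 2:
        raise ValueError("need at least 2 teams")
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    r = rng.random((n_teams, space.dim))
    return [Team(space.lb + r[i] * (space.ub - space.lb)) for i in range(n_teams)]


def tw_weights(fitnesses, minimize: bool = True) -> np.ndarray:
    """Affine map of fitness onto [1, 2]: best team 2, worst team 1."""
    f = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite fitness values")
    if not minimize:
        f = -f
    best, worst = f.min(), f.max()
    if best == worst:
        return np.full(f.shape, 1.5)
    return (f - worst) / (best - worst) + 1.0


def _pair_noise_tw(rng: np.random.Generator):
    def noise(n: int) -> np.ndarray:
        return rng.random((n, n))
    return noise


def _pair_noise_ctw(map_state: ChaoticMap, fitnesses: np.ndarray,
                    mix_fitness: bool):
    f = np.asarray(fitnesses, dtype=float)
    span = np.ptp(f[np.isfinite(f)]) if np.isfinite(f).any() else 0.0

    def noise(n: int) -> np.ndarray:
        out = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                mix = None
                if mix_fitness and span > 0:
                    mix = abs(f[i] - f[j]) / span
                out[i, j] = map_state.next_value(mix)
        return out
    return noise


def _tw_candidates(positions: np.ndarray, weights: np.ndarray,
                   space: SearchSpace, config: TWConfig, iteration: int,
                   pair_noise) -> np.ndarray:
    """One generation of candidate positions from the pairwise pull update.

    For each ordered pair (i, j): g_ij = X_j - X_i, the pulling force is
    F_p = max(W_i, W_j) * mu, the resultant on team i is F_r = F_p - W_i*mu
    (zero when i is the heavier side), and a_ij = g_ij * F_r / (W_i * mu).
    The candidate displacement sums 0.5 * a_ij * dt^2 plus the perturbation
    term scaled by alpha^k * beta * (UB - LB), with the per-pair noise
    stream mapped onto [-1, 1].
    """
    n, d = positions.shape
    W = weights
    # F_r / (W_i mu) = max(0, W_j - W_i) / W_i  (mu cancels)
    rel = np.maximum(0.0, W[None, :] - W[:, None]) / W[:, None]
    g = positions[None, :, :] - positions[:, None, :]       # g[i, j] = Xj - Xi
    pull = 0.5 * config.dt ** 2 * np.sum(rel[:, :, None] * g, axis=1)
    scale = (config.alpha ** iteration) * config.beta * (space.ub - space.lb)
    noise = pair_noise(n)                                    # (n, n) in (0, 1)
    # Center by the matrix mean and rescale to the spread of uniform noise:
    # chaotic maps driven by fitness differences have input-dependent means
    # (coherent drift) and map-dependent spread (uncontrolled step size);
    # standardizing makes every noise stream step-size equivalent to the
    # plain uniform one. A constant stream keeps factor 1 and centers to 0.
    std = noise.std()
    factor = (1.0 / np.sqrt(12.0)) / std if std > 0 else 1.0
    pert = np.sum(2.0 * (noise - noise.mean()) * factor, axis=1)[:, None] \
        * scale[None, :] / n
    return space.clamp(positions + pull + pert)


def tw_step(teams: list[Team], space: SearchSpace, config: TWConfig,
            rng: np.random.Generator, iteration: int = 0) -> np.ndarray:
    """Candidate next-generation positions for the plain TW update."""
    positions = np.array([t.position for t in teams])
    weights = np.array([t.weight for t in teams])
    return _tw_candidates(positions, weights, space, config, iteration,
                          _pair_noise_tw(rng))


def ctw_step(teams: list[Team], space: SearchSpace, config: TWConfig,
             map_state: ChaoticMap, iteration: int = 0) -> np.ndarray:
    """Candidate positions with the chaotic perturbation stream."""
    positions = np.array([t.position for t in teams])
    weights = np.array([t.weight for t in teams])
    fitnesses = np.array([t.fitness for t in teams])
    return _tw_candidates(positions, weights, space, config, iteration,
                          _pair_noise_ctw(map_state, fitnesses,
                                          config.mix_fitness))


def _run_tw(fitness, space: SearchSpace, config: TWConfig,
            chaotic: bool) -> None:
    rng = np.random.default_rng(config.seed)
    map_state = None
    if chaotic:
        map_id = config.map_id or "logistic"
        map_state = ChaoticMap(ChaoticMapSpec(map_id, x0=config.map_x0))
    teams = tw_initialize(space, config.n_teams, rng)
    try:
        for t in teams:
            t.fitness = fitness(t.position)
        iteration = 0
        while True:
            fitnesses = np.array([t.fitness for t in teams])
            if not np.all(np.isfinite(fitnesses)):
                # failed evaluations rank strictly worst
                finite = fitnesses[np.isfinite(fitnesses)]
                worst = finite.max() + max(np.ptp(finite), 1.0) \
                    if finite.size else 1.0
                fitnesses = np.where(np.isfinite(fitnesses), fitnesses, worst)
            weights = tw_weights(fitnesses)
            for t, w in zip(teams, weights):
                t.weight = float(w)
            if chaotic:
                candidates = ctw_step(teams, space, config, map_state,
                                      iteration)
            else:
                candidates = tw_step(teams, space, config, rng, iteration)
            for t, cand in zip(teams, candidates):
                f = fitness(cand)
                if f <= t.fitness:  # greedy per-team replacement
                    t.position, t.fitness = cand, f
            iteration += 1
    except BudgetExhausted:
        return


def _run_random(fitness, space: SearchSpace, seed: int) -> None:
    rng = np.random.default_rng(seed)
    try:
        while True:
            x = space.lb + rng.random(space.dim) * (space.ub - space.lb)
            fitness(x)
    except BudgetExhausted:
        return


def _grid_layers(space: SearchSpace, n_candidates: int = 101) -> list[np.ndarray]:
    """Candidate values per coordinate: the integer grid for integer
    coordinates, an odd equispaced grid (which includes the box center)
    otherwise."""
    layers = []
    for k in range(space.dim):
        if space.integer_mask[k]:
            layers.append(np.arange(math.ceil(space.lb[k]),
                                    math.floor(space.ub[k]) + 1, dtype=float))
        else:
            layers.append(np.linspace(space.lb[k], space.ub[k], n_candidates))
    return layers


def optimize(fitness_fn, space: SearchSpace, method: str = "ctw",
             config: TWConfig | IWDConfig | None = None) -> OptimizeResult:
    """Minimize ``fitness_fn`` over the box with the chosen method.

    ``method`` is one of ``tw``, ``ctw``, ``iwd``, ``random``. At most
    ``config.max_evaluations`` cost-function calls are made; the result
    history records ``(evaluation_index, best_so_far)``.
    """
    if method in ("tw", "ctw"):
        config = config or TWConfig()
        budget = _BudgetedFitness(fitness_fn, config.max_evaluations, space,
                                  config.cache_rounded, config.count_cached)
        _run_tw(budget, space, config, chaotic=(method == "ctw"))
    elif method == "iwd":
        config = config or IWDConfig()
        budget = _BudgetedFitness(fitness_fn, config.max_evaluations, space)
        layers = _grid_layers(space)
        _run_iwd(budget, layers, config)
    elif method == "random":
        config = config or TWConfig()
        budget = _BudgetedFitness(fitness_fn, config.max_evaluations, space)
        _run_random(budget, space, config.seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    if budget.best_x is None:
        raise RuntimeError("no successful fitness evaluation")
    return OptimizeResult(budget.best_x, budget.best_f, budget.history,
                          budget.n_evaluations)


# ---------------------------------------------------------------------------
# Intelligent Water Drops


def _iwd_probabilities(soil: np.ndarray, eps: float) -> np.ndarray:
    g = soil - soil.min() if soil.min() < 0 else soil
    w = 1.0 / (eps + g)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        return np.full(soil.shape, 1.0 / soil.size)
    return w / total


def _run_iwd(fitness, layers: list[np.ndarray], config: IWDConfig) -> None:
    rng = np.random.default_rng(config.seed)
    soil = [np.full(len(lay), config.init_soil) for lay in layers]
    n_layers = len(layers)
    try:
        for _ in range(config.max_iterations):
            iter_best_f = math.inf
            iter_best_path: list[int] | None = None
            iter_best_soil = 0.0
            for _ in range(config.n_drops):
                vel = config.init_velocity
                drop_soil = 0.0
                path = []
                for lay in range(n_layers):
                    if rng.random() < config.p_explore:
                        # sustained uniform exploration: soil dynamics alone
                        # are pure visitation feedback and would lock the
                        # search onto the first cells drops happen to visit
                        node = int(rng.integers(len(soil[lay])))
                    else:
                        p = _iwd_probabilities(soil[lay], config.eps_soil)
                        node = int(rng.choice(len(p), p=p))
                    path.append(node)
                    s = soil[lay][node]
                    vel += config.a_v / (config.b_v + config.c_v * s * s)
                    t = 1.0 / max(vel, 1e-12)
                    delta = config.a_s / (config.b_s + config.c_s * t * t)
                    soil[lay][node] = ((1.0 - config.rho_local) * s
                                       - config.rho_local * delta)
                    drop_soil += delta
                x = np.array([layers[lay][k] for lay, k in enumerate(path)])
                f = fitness(x)
                if f < iter_best_f:
                    iter_best_f, iter_best_path = f, path
                    iter_best_soil = drop_soil
            if iter_best_path is not None:
                # global reinforcement as exponential relaxation toward a
                # negative soil target: monotone attraction regardless of
                # the edge's current soil (the multiplicative classic form
                # repels still-high-soil nodes, including a late-found
                # optimum)
                target = 2.0 * iter_best_soil / max(n_layers, 1)
                for lay, node in enumerate(iter_best_path):
                    soil[lay][node] = ((1.0 - config.rho_global)
                                       * soil[lay][node]
                                       - config.rho_global * target)
    except BudgetExhausted:
        return


def iwd_optimize(fitness_fn, layered_candidates: list[np.ndarray],
                 config: IWDConfig | None = None) -> OptimizeResult:
    """Minimize a fitness over an explicit layered candidate grid.

    ``layered_candidates`` holds one array of candidate values per decision
    variable; each completed drop path costs one fitness evaluation.
    """
    config = config or IWDConfig()
    layers = [np.asarray(lay, dtype=float) for lay in layered_candidates]
    if any(len(lay) == 0 for lay in layers):
        raise ValueError("every layer needs at least one candidate")
    lb = np.array([lay.min() for lay in layers])
    ub = np.array([lay.max() + 1e-9 for lay in layers])
    space = SearchSpace(lb - 1e-9, ub)
    budget = _BudgetedFitness(fitness_fn, config.max_evaluations, space)
    _run_iwd(budget, layers, config)
    if budget.best_x is None:
        raise RuntimeError("no successful fitness evaluation")
    return OptimizeResult(budget.best_x, budget.best_f, budget.history,
                          budget.n_evaluations)


# ---------------------------------------------------------------------------
# benchmark harness


def _sphere(x):
    return float(np.sum(x ** 2))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2
                        + (1.0 - x[:-1]) ** 2))


def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x ** 2 - 10.0 * np.cos(2 * np.pi * x)))


def _ackley(x):
    d = x.size
    return float(-20.0 * np.exp(-0.2 * np.sqrt(np.sum(x ** 2) / d))
                 - np.exp(np.sum(np.cos(2 * np.pi * x)) / d) + 20.0 + np.e)


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x ** 2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _schwefel_222(x):
    return float(np.sum(np.abs(x)) + np.prod(np.abs(x)))


def _levy(x):
    w = 1.0 + (x - 1.0) / 4.0
    term1 = np.sin(np.pi * w[0]) ** 2
    term3 = (w[-1] - 1.0) ** 2 * (1.0 + np.sin(2 * np.pi * w[-1]) ** 2)
    mid = np.sum((w[:-1] - 1.0) ** 2
                 * (1.0 + 10.0 * np.sin(np.pi * w[:-1] + 1.0) ** 2))
    return float(term1 + mid + term3)


def _zakharov(x):
    i = np.arange(1, x.size + 1)
    s = np.sum(0.5 * i * x)
    return float(np.sum(x ** 2) + s ** 2 + s ** 4)


def _sum_squares(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(i * x ** 2))


def _michalewicz(x):
    i = np.arange(1, x.size + 1)
    return float(-np.sum(np.sin(x) * np.sin(i * x ** 2 / np.pi) ** 20))


#: name -> (function, (lb, ub) per coordinate, global minimum value in 2-D)
BENCHMARK_FUNCTIONS = {
    "sphere": (_sphere, (-5.12, 5.12), 0.0),
    "rosenbrock": (_rosenbrock, (-2.048, 2.048), 0.0),
    "rastrigin": (_rastrigin, (-5.12, 5.12), 0.0),
    "ackley": (_ackley, (-32.768, 32.768), 0.0),
    "griewank": (_griewank, (-600.0, 600.0), 0.0),
    "schwefel_222": (_schwefel_222, (-10.0, 10.0), 0.0),
    "levy": (_levy, (-10.0, 10.0), 0.0),
    "zakharov": (_zakharov, (-5.0, 10.0), 0.0),
    "sum_squares": (_sum_squares, (-10.0, 10.0), 0.0),
    "michalewicz": (_michalewicz, (0.0, np.pi), -1.8013034),
}


def benchmark_suite(methods=("tw", "ctw", "iwd", "random"),
                    functions=tuple(BENCHMARK_FUNCTIONS),
                    reps: int = 20, budget: int = 10_000, d: int = 2,
                    seed: int = 0, map_id: str = "logistic") -> pd.DataFrame:
    """Median and IQR of final best error per (method, function).

    Error is ``best_f - f_min`` (non-negative for functions whose global
    minimum is known exactly). Rows are methods, columns functions, with a
    two-level (median, iqr) column index.
    """
    records = {}
    for method in methods:
        for fname in functions:
            fn, (lo, hi), fmin = BENCHMARK_FUNCTIONS[fname]
            errs = []
            for rep in range(reps):
                if method in ("tw", "ctw", "random"):
                    cfg = TWConfig(max_evaluations=budget, seed=seed + rep,
                                   map_id=map_id)
                else:
                    cfg = IWDConfig(max_evaluations=budget, seed=seed + rep,
                                    max_iterations=10 ** 9)
                space = SearchSpace(np.full(d, lo), np.full(d, hi))
                res = optimize(fn, space, method=method, config=cfg)
                errs.append(res.best_f - fmin)
            errs = np.asarray(errs)
            if errs.size:
                med = float(np.median(errs))
                iqr = float(np.percentile(errs, 75) - np.percentile(errs, 25))
            else:
                med = iqr = math.nan
            records[(method, fname)] = (med, iqr)
    idx = pd.MultiIndex.from_tuples(records, names=["method", "function"])
    df = pd.DataFrame([records[k] for k in idx], index=idx,
                      columns=["median_error", "iqr_error"])
    if reps == 0:
        return df.iloc[0:0]
    return df
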