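"""Synthetic reference signals and two-class motor-imagery surrogate epochs.

Two families of generators live here:

* canonical dynamical systems (logistic and Henon maps, the Lorenz flow,
  a pure sinusoid, a damped oscillator) with independently computable
  largest Lyapunov exponents, used as ground truth for the divergence-curve
  estimator; and
* a labeled two-class epoch generator that emulates event-related
  desynchronization (ERD): an alpha-band carrier whose post-cue amplitude
  drops in the "fist" class, mixed with a class-dependent chaotic component
  and 1/f noise.

The oracle :func:`lle_oracle` computes exponents from system Jacobians
(analytic derivative averages for 1-D maps, Benettin tangent-vector
renormalization for multi-dimensional systems); it never touches the
trajectory-divergence estimator it validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet

__all__ = [
    "ChaoticSystemSpec",
    "ERDConfig",
    "simulate_map_series",
    "lle_oracle",
    "generate_erd_epochs",
]

_SYSTEMS = ("logistic", "henon", "lorenz", "sine", "damped_oscillator")

_DEFAULT_PARAMS = {
    "logistic": {"r": 4.0},
    "henon": {"a": 1.4, "b": 0.3},
    "lorenz": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "dt": 0.01},
    "sine": {"freq": 1.0, "dt": 0.01},
    "damped_oscillator": {"omega": 2 * np.pi, "zeta_damp": 0.2, "dt": 0.01},
}

_DEFAULT_STATE = {
    "logistic": [0.3],
    "henon": [0.1, 0.1],
    "lorenz": [1.0, 1.0, 1.0],
    "sine": [0.0, 1.0],
    "damped_oscillator": [1.0, 0.0],
}


@dataclass
class ChaoticSystemSpec:
    """Specification of one deterministic test system.

    ``parameters`` missing entries fall back to canonical defaults
    (logistic r=4; Henon a=1.4, b=0.3; Lorenz sigma=10, rho=28, beta=8/3).
    The damped oscillator is x'' = -2*zeta_damp*omega*x' - omega^2*x, whose
    largest Lyapunov exponent is the real part of the slow eigenvalue,
    -zeta_damp*omega for the underdamped case.
    """

    system_id: str
    parameters: dict = field(default_factory=dict)
    initial_state: list[float] | None = None
    n_samples: int = 1000
    transient_discard: int = 0

    def __post_init__(self) -> None:
        if self.system_id not in _SYSTEMS:
            raise ValueError(f"unknown system {self.system_id!r}; choose from {_SYSTEMS}")
        self.parameters = {**_DEFAULT_PARAMS[self.system_id], **self.parameters}
        if self.initial_state is None:
            self.initial_state = list(_DEFAULT_STATE[self.system_id])
        self.initial_state = [float(v) for v in self.initial_state]
        if self.n_samples <= self.transient_discard:
            raise ValueError("n_samples must exceed transient_discard")
        if self.transient_discard < 0:
            raise ValueError("transient_discard must be non-negative")
        if self.system_id == "logistic" and not 0.0 < self.initial_state[0] < 1.0:
            raise ValueError("logistic initial state must lie in (0, 1)")
        if self.system_id in ("lorenz", "sine", "damped_oscillator") \
                and self.parameters["dt"] <= 0:
            raise ValueError("dt must be positive")

    @property
    def dt(self) -> float:
        """Time per output sample: 1 for maps, integrator dt for flows."""
        return float(self.parameters.get("dt", 1.0))


def _check_finite(x: np.ndarray, system: str, step: int) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"{system} orbit diverged to non-finite values at step {step}")


def _iterate_map(spec: ChaoticSystemSpec):
    """Yield successive full states of a discrete map."""
    p = spec.parameters
    x = np.asarray(spec.initial_state, dtype=float)
    for k in range(spec.n_samples):
        yield x
        with np.errstate(over="ignore", invalid="ignore"):
            if spec.system_id == "logistic":
                x = np.array([p["r"] * x[0] * (1.0 - x[0])])
            else:  # henon
                x = np.array([1.0 - p["a"] * x[0] ** 2 + p["b"] * x[1], x[0]])
        _check_finite(x, spec.system_id, k + 1)


def _flow_rhs(system_id: str, p: dict):
    if system_id == "lorenz":
        def rhs(x):
            return np.array([
                p["sigma"] * (x[1] - x[0]),
                x[0] * (p["rho"] - x[2]) - x[1],
                x[0] * x[1] - p["beta"] * x[2],
            ])
    elif system_id == "sine":
        # harmonic oscillator: a genuinely neutral (limit-cycle-like) orbit
        w = 2 * np.pi * p["freq"]

        def rhs(x):
            return np.array([x[1], -w ** 2 * x[0]])
    else:  # damped_oscillator
        w, z = p["omega"], p["zeta_damp"]

        def rhs(x):
            return np.array([x[1], -2 * z * w * x[1] - w ** 2 * x[0]])
    return rhs


def _flow_jacobian(system_id: str, p: dict):
    if system_id == "lorenz":
        def jac(x):
            return np.array([
                [-p["sigma"], p["sigma"], 0.0],
                [p["rho"] - x[2], -1.0, -x[0]],
                [x[1], x[0], -p["beta"]],
            ])
    elif system_id == "sine":
        w = 2 * np.pi * p["freq"]
        J = np.array([[0.0, 1.0], [-w ** 2, 0.0]])

        def jac(x):
            return J
    else:
        w, z = p["omega"], p["zeta_damp"]
        J = np.array([[0.0, 1.0], [-w ** 2, -2 * z * w]])

        def jac(x):
            return J
    return jac


def _rk4_step(rhs, x, dt):
    k1 = rhs(x)
    k2 = rhs(x + 0.5 * dt * k1)
    k3 = rhs(x + 0.5 * dt * k2)
    k4 = rhs(x + dt * k3)
    return x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_map_series(spec: ChaoticSystemSpec) -> np.ndarray:
    """Simulate the system and return its scalar observable.

    Maps yield their first coordinate; flows are integrated with fixed-step
    RK4 and yield x(t). For the sine system the observable is
    sin(2*pi*freq*t) exactly. The first ``transient_discard`` samples are
    dropped; output length is ``n_samples - transient_discard``.
    Fully deterministic: no RNG is involved.
    """
    p = spec.parameters
    if spec.system_id in ("logistic", "henon"):
        series = np.array([s[0] for s in _iterate_map(spec)])
    elif spec.system_id == "sine":
        t = np.arange(spec.n_samples) * p["dt"]
        series = np.sin(2 * np.pi * p["freq"] * t)
    else:
        rhs = _flow_rhs(spec.system_id, p)
        x = np.asarray(spec.initial_state, dtype=float)
        out = np.empty(spec.n_samples)
        for k in range(spec.n_samples):
            out[k] = x[0]
            x = _rk4_step(rhs, x, p["dt"])
            _check_finite(x, spec.system_id, k + 1)
        series = out
    return series[spec.transient_discard:]


def lle_oracle(spec: ChaoticSystemSpec, n_steps: int = 100_000) -> float:
    """Largest Lyapunov exponent from system Jacobians.

    * 1-D maps: orbit average of ln|f'(x_t)| (nats per iteration).
    * Henon and flows: Benettin scheme — evolve one tangent vector alongside
      the orbit, renormalizing each step and averaging the log growth
      (nats per iteration for maps, nats per time unit for flows).
    """
    p = spec.parameters
    if spec.system_id == "logistic":
        r = p["r"]
        x = spec.initial_state[0]
        burn = 1000
        total = 0.0
        for k in range(burn + n_steps):
            d = abs(r * (1.0 - 2.0 * x))
            if d == 0.0 or not np.isfinite(d):
                raise FloatingPointError("non-finite or zero derivative on logistic orbit")
            if k >= burn:
                total += np.log(d)
            x = r * x * (1.0 - x)
        return total / n_steps

    if spec.system_id == "henon":
        a, b = p["a"], p["b"]
        x = np.asarray(spec.initial_state, dtype=float)
        v = np.array([1.0, 0.0])
        burn = 1000
        total = 0.0
        for k in range(burn + n_steps):
            J = np.array([[-2 * a * x[0], b], [1.0, 0.0]])
            x = np.array([1.0 - a * x[0] ** 2 + b * x[1], x[0]])
            _check_finite(x, "henon", k)
            v = J @ v
            norm = np.linalg.norm(v)
            if norm == 0.0 or not np.isfinite(norm):
                raise FloatingPointError("tangent vector collapsed on Henon orbit")
            if k >= burn:
                total += np.log(norm)
            v /= norm
        return total / n_steps

    # flows: Benettin with RK4 on state + tangent
    dt = p["dt"]
    rhs = _flow_rhs(spec.system_id, p)
    jac = _flow_jacobian(spec.system_id, p)
    x = np.asarray(spec.initial_state, dtype=float)
    v = np.zeros_like(x)
    v[0] = 1.0
    burn = min(n_steps // 10, 5000)
    total = 0.0
    for k in range(burn + n_steps):
        def tangent_rhs(w, x=x):
            return jac(x) @ w
        v = _rk4_step(tangent_rhs, v, dt)
        x = _rk4_step(rhs, x, dt)
        _check_finite(x, spec.system_id, k)
        norm = np.linalg.norm(v)
        if norm == 0.0 or not np.isfinite(norm):
            raise FloatingPointError(f"tangent vector collapsed on {spec.system_id} orbit")
        if k >= burn:
            total += np.log(norm)
        v /= norm
    return total / (n_steps * dt)


# ---------------------------------------------------------------------------
# two-class ERD/ERS surrogate epochs


@dataclass
class ERDConfig:
    """Configuration of the two-class synthetic epoch generator.

    Each epoch is an alpha-band sinusoidal carrier (random frequency in
    ``alpha_band``, random phase) plus a chaotic alpha component: a
    logistic-map series with class-dependent growth rate ``chaotic_r``,
    generated at ``chaotic_rate`` iterations per second, resampled to
    ``fs`` and amplitude-modulated onto its own alpha-band carrier so it
    survives the downstream band-pass filter. The ERD envelope (factor 1
    before the cue, ``1 - erd_depth`` after it, 100 ms linear ramp, fist
    class only) multiplies carrier and chaotic component jointly — the
    whole alpha rhythm desynchronizes, so post-cue alpha power scales by
    ``(1 - erd_depth)^2``. Seeded 1/f pink noise is added on top,
    unattenuated.

    ``fs`` defaults to 512 Hz — a fabricated but typical BCI-amplifier rate;
    no recording montage or rate is implied by the task itself.
    """

    n_epochs_per_class: int = 100
    fs: float = 512.0
    epoch_span: tuple[float, float] = (200.0, 2500.0)
    channels: tuple[str, ...] = ("C3", "CP5")
    alpha_band: tuple[float, float] = (8.0, 13.0)
    erd_depth: float = 0.5
    chaotic_mix: tuple[float, float] = (0.8, 0.8)   # (open, fist) weights
    chaotic_r: tuple[float, float] = (3.9, 3.6)     # (open, fist) logistic r
    chaotic_rate: float = 64.0                      # map iterations per second
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.fs < 100:
            raise ValueError("fs must be at least 100 Hz")
        if self.n_epochs_per_class < 1:
            raise ValueError("n_epochs_per_class must be positive")
        if np.isscalar(self.chaotic_mix):
            self.chaotic_mix = (float(self.chaotic_mix),) * 2
        if np.isscalar(self.chaotic_r):
            self.chaotic_r = (float(self.chaotic_r),) * 2


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero at DC
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def _logistic_component(rng: np.random.Generator, r: float, n_out: int,
                        fs: float, gen_rate: float = 64.0) -> np.ndarray:
    """Logistic-map series generated at ``gen_rate`` Hz, resampled to fs.

    Linear interpolation onto the epoch's sample grid band-limits the
    series to roughly the generation rate while preserving the map's
    chaotic irregularity on the ~1/gen_rate timescale.
    """
    n_gen = int(np.ceil(n_out * gen_rate / fs)) + 2
    x = rng.uniform(0.05, 0.95)
    for _ in range(50):  # discard transient
        x = r * x * (1.0 - x)
    series = np.empty(n_gen)
    for k in range(n_gen):
        series[k] = x
        x = r * x * (1.0 - x)
    series -= series.mean()
    sd = series.std()
    if sd > 0:
        series /= sd
    t_out = np.arange(n_out) / fs
    t_gen = np.arange(n_gen) / gen_rate
    return np.interp(t_out, t_gen, series)


def generate_erd_epochs(config: ERDConfig) -> EpochSet:
    """Generate ``2 * n_epochs_per_class`` labeled epochs.

    Epochs 0..n-1 are class "open" (label 0), the rest "fist" (label 1).
    Each channel's stream is seeded independently from ``(seed, channel
    name)``, so requesting the channels in a different order permutes the
    channel axis but never changes any channel's content.
    """
    pre_ms, post_ms = config.epoch_span
    n_samples = int(round((pre_ms + post_ms) * config.fs / 1000.0))
    n_total = 2 * config.n_epochs_per_class
    cue = int(round(pre_ms * config.fs / 1000.0))
    ramp = int(round(0.100 * config.fs))

    data = np.empty((n_total, len(config.channels), n_samples))
    labels = np.concatenate([
        np.zeros(config.n_epochs_per_class, dtype=int),
        np.ones(config.n_epochs_per_class, dtype=int),
    ])
    t = np.arange(n_samples) / config.fs

    for ch_idx, ch_name in enumerate(config.channels):
        # independent, order-invariant stream per channel
        ch_key = int.from_bytes(ch_name.encode(), "little") % (2 ** 31)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, ch_key]))
        for ep in range(n_total):
            cls = labels[ep]
            freq = rng.uniform(*config.alpha_band)
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.sin(2 * np.pi * freq * t + phase)

            envelope = np.ones(n_samples)
            if cls == 1 and config.erd_depth > 0:
                target = 1.0 - config.erd_depth
                end = min(cue + ramp, n_samples)
                envelope[cue:end] = np.linspace(1.0, target, end - cue,
                                                endpoint=False)
                envelope[end:] = target

            chaotic = _logistic_component(rng, config.chaotic_r[cls],
                                          n_samples, config.fs,
                                          config.chaotic_rate)
            freq2 = rng.uniform(*config.alpha_band)
            phase2 = rng.uniform(0, 2 * np.pi)
            comp = (config.chaotic_mix[cls] * chaotic
                    * np.sin(2 * np.pi * freq2 * t + phase2))
            noise = _pink_noise(rng, n_samples) * config.noise_sigma
            data[ep, ch_idx] = (carrier + comp) * envelope + noise

    return EpochSet(data, labels, config.fs, list(config.channels),
                    window=(pre_ms, post_ms))
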