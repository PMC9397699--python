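"""The twelve 1-D chaotic maps used to drive the chaotic Tug-of-War search.

Each map is iterated as an autonomous dynamical system on (0, 1); maps whose
natural range is [-1, 1] (Chebyshev, iterative, sinus-type variants) are
min-max normalized into (0, 1) so every map can serve interchangeably as a
stochastic-surrogate stream. The dozen — Chebyshev, circle, Gauss/mouse,
intermittency, iterative, Liebovitch, logistic, piecewise, sine, Singer,
sinusoidal, tent — is the canonical set of the chaotic-metaheuristics
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MAP_IDS", "ChaoticMapSpec", "ChaoticMap", "chaotic_map_sequence"]

_EPS = 1e-12


def _chebyshev(x, p):      # natural range [-1, 1]
    return np.cos(p["a"] * np.arccos(2 * x - 1)) * 0.5 + 0.5


def _circle(x, p):
    return np.mod(x + p["b"] - p["a"] / (2 * np.pi) * np.sin(2 * np.pi * x), 1.0)


def _gauss_mouse(x, p):
    # exponential Gauss/mouse form on the shifted variable x + b; the
    # frac(1/x) form is numerically degenerate (rational orbits die at 0)
    return np.exp(-p["a"] * (x + p["b"]) ** 2)


def _intermittency(x, p):
    P, eps = p["P"], p["eps"]
    if x <= P:
        m = 2.0
        c = (1.0 - eps - P) / P ** m
        return eps + x + c * x ** m
    return (x - P) / (1.0 - P)


def _iterative(x, p):      # natural range [-1, 1]
    return abs(np.sin(p["a"] * np.pi / (2 * x - 1 if x != 0.5 else _EPS)))


def _liebovitch(x, p):
    d1, d2 = p["d1"], p["d2"]
    a = d2 / d1 * (1.0 - (d2 - d1))
    b = (1.0 / (d2 - 1.0)) * ((d2 - 1.0) - d1 * (d2 - d1))
    if x <= d1:
        return a * x
    if x <= d2:
        return (x - d1) / (d2 - d1) * 0.999
    return 1.0 - b * (1.0 - x)


def _logistic(x, p):
    return p["r"] * x * (1.0 - x)


def _piecewise(x, p):
    P = p["P"]
    if x < P:
        return x / P
    if x < 0.5:
        return (x - P) / (0.5 - P)
    if x < 1.0 - P:
        return (1.0 - P - x) / (0.5 - P)
    return (1.0 - x) / P


def _sine(x, p):
    return p["a"] / 4.0 * np.sin(np.pi * x)


def _singer(x, p):
    return p["mu"] * (7.86 * x - 23.31 * x ** 2 + 28.75 * x ** 3
                      - 13.302875 * x ** 4)


def _sinusoidal(x, p):
    return p["a"] * x ** 2 * np.sin(np.pi * x)


def _tent(x, p):
    return x / 0.7 if x < 0.7 else 10.0 / 3.0 * (1.0 - x)


_MAPS = {
    "chebyshev": (_chebyshev, {"a": 4.0}),
    "circle": (_circle, {"a": 0.5, "b": 0.2}),
    "gauss_mouse": (_gauss_mouse, {"a": 4.9, "b": -0.5}),
    "intermittency": (_intermittency, {"P": 0.5, "eps": 1e-3}),
    "iterative": (_iterative, {"a": 0.7}),
    "liebovitch": (_liebovitch, {"d1": 0.3, "d2": 0.7}),
    "logistic": (_logistic, {"r": 4.0}),
    "piecewise": (_piecewise, {"P": 0.4}),
    "sine": (_sine, {"a": 4.0}),
    "singer": (_singer, {"mu": 1.07}),
    "sinusoidal": (_sinusoidal, {"a": 2.3}),
    "tent": (_tent, {}),
}

MAP_IDS = tuple(_MAPS)


@dataclass
class ChaoticMapSpec:
    """One named map with its state and parameters."""

    map_id: str
    x0: float = 0.7
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.map_id not in _MAPS:
            raise ValueError(f"unknown map {self.map_id!r}; choose from {MAP_IDS}")
        if not 0.0 < self.x0 < 1.0:
            raise ValueError("x0 must lie in (0, 1)")
        fn, defaults = _MAPS[self.map_id]
        self.parameters = {**defaults, **self.parameters}


class ChaoticMap:
    """Stateful iterator over one chaotic map, clipped into (0, 1).

    ``next_value(mix=...)`` returns the next iterate; an optional ``mix``
    in [0, 1) is folded additively (mod 1) into the state before iterating,
    which is how fitness differences drive the chaotic search factor.
    """

    def __init__(self, spec: ChaoticMapSpec):
        self.spec = spec
        self._fn, _ = _MAPS[spec.map_id]
        self.state = float(spec.x0)
        self._eps = _EPS

    def next_value(self, mix: float | None = None) -> float:
        x = self.state
        if mix is not None:
            x = (x + float(mix)) % 1.0
        eps = self._eps
        x = float(self._fn(min(max(x, eps), 1.0 - eps), self.spec.parameters))
        x = min(max(x, eps), 1.0 - eps)
        self.state = x
        return x


def chaotic_map_sequence(spec: ChaoticMapSpec, n: int,
                         cycle_check: int = 64) -> np.ndarray:
    """Iterate the map ``n`` times from its seed state.

    Raises if the orbit collapses onto a fixed point or a short cycle
    (period <= ``cycle_check``) within the first iterates; such seeds
    (e.g. the logistic map started exactly on its fixed point 0.75)
    cannot drive an ergodic search.
    """
    m = ChaoticMap(spec)
    out = np.empty(n)
    for k in range(n):
        out[k] = m.next_value()
    probe = out[: min(n, 4 * cycle_check)]
    if len(probe) >= 2 * cycle_check:
        for period in range(1, cycle_check + 1):
            if np.allclose(probe[period:2 * cycle_check],
                           probe[:2 * cycle_check - period], atol=1e-12):
                raise ValueError(
                    f"{spec.map_id} orbit from x0={spec.x0} collapsed to a "
                    f"period-{period} cycle; choose a different x0")
    return out
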