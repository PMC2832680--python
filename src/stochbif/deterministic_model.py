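"""Deterministic auto-activating switch: steady states and the S-shaped
bifurcation diagram.

A single gene activated by an external signal ``s`` and by its own protein
product ``P`` is described by

    dP/dt = basal + vmax * (s P)^n / (K^n + (s P)^n) - gamma * P

with a basal production rate, a maximal regulated production ``vmax``, a
Hill activation function of the combined input ``s P`` with half-saturation
``K`` and coefficient ``n``, and first-order decay ``gamma``.  For suitable
parameters the steady-state curve versus ``s`` is S-shaped: one low and one
high stable state coexist over an intermediate signal range, separated by
an unstable state, and the range is bounded by two saddle-node (fold)
bifurcation points.

This module provides the deterministic counterpart against which the
stochastic (population-level) bifurcation estimates of the rest of the
package can be interpreted: the diagram it draws is what a noiseless
bistable switch would look like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SwitchParams",
    "SteadyState",
    "BifurcationDiagram",
    "steady_states",
    "bifurcation_diagram",
]

STABLE = "stable"
UNSTABLE = "unstable"


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the auto-activator (all rates per unit time).

    ``basal``: basal production; ``vmax``: maximal additional regulated
    production; ``K``: half-saturation of activation (in units of the
    combined signal ``s * P``); ``n``: Hill coefficient; ``gamma``:
    first-order degradation/dilution rate.
    """

    basal: float
    vmax: float
    K: float
    n: float = 2.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("basal", "vmax", "K", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    @property
    def p_max(self) -> float:
        """Upper bound on any steady state: production never exceeds
        ``basal + vmax``."""
        return (self.basal + self.vmax) / self.gamma


@dataclass(frozen=True)
class SteadyState:
    value: float
    stability: str  # STABLE or UNSTABLE


def _rate(p_vals, s: float, p: SwitchParams):
    """dP/dt at protein level(s) ``p_vals`` and signal ``s``."""
    p_vals = np.asarray(p_vals, dtype=float)
    u = np.maximum(s * p_vals, 0.0)
    hill = np.where(u > 0, u ** p.n / (p.K ** p.n + u ** p.n), 0.0)
    return p.basal + p.vmax * hill - p.gamma * p_vals


def _rate_derivative(p_val: float, s: float, p: SwitchParams) -> float:
    """d(dP/dt)/dP at a point, for stability classification."""
    u = s * p_val
    if u <= 0:
        dhill = 0.0
    else:
        un = u ** p.n
        kn = p.K ** p.n
        dhill = p.n * kn * un / (u * (kn + un) ** 2)
    return p.vmax * dhill * s - p.gamma


def steady_states(s: float, p: SwitchParams,
                  n_scan: int = 4096) -> list[SteadyState]:
    """All steady states of the switch at signal level ``s``.

    Roots of ``dP/dt = 0`` on ``[0, p_max]`` are located by a dense sign
    scan followed by bisection (``brentq``) in each bracketing interval;
    stability is the sign of the rate derivative at the root (negative →
    stable).  A bistable switch yields three roots ordered
    stable–unstable–stable.
    """
    if s < 0:
        raise ValueError("signal level s must be non-negative")
    upper = p.p_max * (1.0 + 1e-9) + 1e-12
    grid = np.linspace(0.0, upper, n_scan)
    rates = _rate(grid, s, p)
    roots: list[float] = []
    for i in range(n_scan - 1):
        a, b = rates[i], rates[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(
                lambda x: float(_rate(x, s, p)), grid[i], grid[i + 1],
                xtol=1e-12, rtol=1e-14)))
    if rates[-1] == 0.0:
        roots.append(float(grid[-1]))
    states = [
        SteadyState(
            value=root,
            stability=(STABLE if _rate_derivative(root, s, p) < 0
                       else UNSTABLE),
        )
        for root in roots
    ]
    return sorted(states, key=lambda st: st.value)


@dataclass
class BifurcationDiagram:
    """Steady-state branches over a signal grid plus fold points."""

    s_values: np.ndarray
    #: per grid point, the sorted steady states at that signal level
    states: list[list[SteadyState]]
    #: signal levels where the root count changes (saddle-node folds)
    fold_points: list[float]

    def root_counts(self) -> np.ndarray:
        return np.array([len(st) for st in self.states])


def bifurcation_diagram(s_grid: Sequence[float], p: SwitchParams,
                        n_scan: int = 4096,
                        fold_tol: float = 1e-9) -> BifurcationDiagram:
    """Sweep the signal grid and locate saddle-node bifurcation points.

    The number of steady states as a function of ``s`` changes 1 → 3 → 1
    for bistable parameters; each grid interval across which the count
    changes is refined by bisection on ``s`` (to ``fold_tol`` absolute) and
    the bracket midpoint reported as a fold point.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or s_grid.size < 2:
        raise ValueError("s_grid must be a 1-D grid with >= 2 points")
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")

    states = [steady_states(float(s), p, n_scan=n_scan) for s in s_grid]
    counts = [len(st) for st in states]

    fold_points: list[float] = []
    for i in range(len(s_grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = float(s_grid[i]), float(s_grid[i + 1])
        c_lo = counts[i]
        while hi - lo > fold_tol:
            mid = 0.5 * (lo + hi)
            if len(steady_states(mid, p, n_scan=n_scan)) == c_lo:
                lo = mid
            else:
                hi = mid
        fold_points.append(0.5 * (lo + hi))

    return BifurcationDiagram(
        s_values=s_grid, states=states, fold_points=fold_points)
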