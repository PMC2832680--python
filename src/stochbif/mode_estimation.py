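"""Density mode (peak) detection and the mode-estimation-plus-EM pipeline.

The detector smooths the histogram with a wide running average, estimates
first and second derivatives with centred finite differences of the same
width, and accepts a positive-to-negative first-derivative crossing as a mode
only when the curvature there is convincingly negative (``d2 <= theta``).
Small bumps have small curvature near their peak, so the threshold
suppresses them while keeping genuine subpopulation peaks of any size.

A combined product criterion ``d1 * d2 <= theta`` is also available
(``criterion="product"``), motivated by small bumps having both small first
and small second derivatives near a mode.  At the crossing, however, the
first derivative is by construction close to zero, so the product scales
with the discretisation phase of the crossing rather than with peak
strength, and with the default ``theta`` it rejects unambiguous strong
modes; the curvature rule is therefore the default.

Counts are normalised to a per-10,000-events scale before smoothing, which
makes the detector — and therefore ``theta`` — invariant to the number of
events collected.

In the ME+EM pipeline (:func:`fit_me_em`) one Gaussian component is pinned
at each detected mode and a single EM run fits only the weights and
variances, with means held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_data import ChannelHistogram
from .mixture_em import (
    DEFAULT_INIT_SD,
    DEFAULT_UNIFORM_WEIGHT,
    FitResult,
    GaussianComponent,
    MixtureModel,
    fit_em,
)

__all__ = [
    "ModeSet",
    "smooth_counts",
    "central_difference",
    "detect_modes",
    "fit_me_em",
]

#: Default smoothing window / derivative span, in channels.
DEFAULT_WINDOW = 71
#: Default combined-derivative acceptance threshold (per-10,000-events
#: scale); more negative is stricter.
DEFAULT_THETA = -2e-4


@dataclass
class ModeSet:
    """Detected density modes plus the smoothed/derivative series behind
    them (all on the counts-per-10,000-events scale)."""

    modes: list[int]
    smoothed: np.ndarray
    d1: np.ndarray
    d2: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def smooth_counts(counts: np.ndarray, window: int = DEFAULT_WINDOW,
                  total: int | None = None) -> np.ndarray:
    """Centred running average of a count vector, normalised per 10⁴ events.

    Near the edges the window truncates to the available channels and the
    average renormalises accordingly, so a constant input stays constant.

    Parameters
    ----------
    total
        Event count used for the per-10,000 normalisation; defaults to
        ``counts.sum()``.  Passing the original total lets CV folds share a
        scale, but the default makes the output invariant to rescaling all
        counts.
    """
    counts = np.asarray(counts, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 3 or window > counts.size:
        raise ValueError(
            f"window must be in [3, {counts.size}], got {window}")
    if total is None:
        total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has zero total count")
    scaled = counts * (1e4 / total)
    kernel = np.ones(window)
    sums = np.convolve(scaled, kernel, mode="same")
    norms = np.convolve(np.ones_like(scaled), kernel, mode="same")
    return sums / norms


def central_difference(series: np.ndarray, span: int = DEFAULT_WINDOW
                       ) -> np.ndarray:
    """Wide centred finite-difference derivative estimate.

    ``d[c] = (series[c + h] - series[c - h]) / (2 h)`` with
    ``h = (span - 1) / 2``; positions within ``h`` of either edge are
    undefined and filled with zero (they are never eligible as modes).
    """
    series = np.asarray(series, dtype=float)
    if span % 2 == 0:
        raise ValueError(f"span must be odd, got {span}")
    if span >= series.size:
        raise ValueError("span must be smaller than the series length")
    h = (span - 1) // 2
    d = np.zeros_like(series)
    if h == 0:
        raise ValueError("span must be >= 3")
    d[h:-h] = (series[2 * h:] - series[:-2 * h]) / (2.0 * h)
    return d


def detect_modes(h: ChannelHistogram, window: int = DEFAULT_WINDOW,
                 theta: float = DEFAULT_THETA,
                 criterion: str = "curvature") -> ModeSet:
    """Detect density modes of a histogram.

    A candidate is the last channel ``c`` with ``d1(c) > 0`` followed by
    ``d1(c+1) <= 0`` (a positive-to-negative crossing of the smoothed first
    derivative).  It is accepted iff ``d2(c) <= theta``
    (``criterion="curvature"``, default) or the combined criterion
    ``d1(c) * d2(c) <= theta`` holds (``criterion="product"``).  The reported mode
    location is the argmax of the smoothed series over ``{c, c+1}``.

    Channels whose derivative estimates are edge-truncated are never
    eligible.  An empty mode list is a legitimate outcome.
    """
    if criterion not in ("product", "curvature"):
        raise ValueError("criterion must be 'product' or 'curvature'")
    smoothed = smooth_counts(h.counts, window=window)
    d1 = central_difference(smoothed, span=window)
    d2 = central_difference(d1, span=window)
    half = (window - 1) // 2
    n = smoothed.size

    modes: list[int] = []
    # Eligible indices: both d1 and d2 defined at c and c+1.
    lo = 2 * half
    hi = n - 2 * half - 1  # last index with d2 defined; need c+1 <= hi
    for i in range(lo, hi):
        if d1[i] > 0 and d1[i + 1] <= 0:
            value = d1[i] * d2[i] if criterion == "product" else d2[i]
            if value <= theta:
                peak = i if smoothed[i] >= smoothed[i + 1] else i + 1
                modes.append(peak + 1)  # to 1-based channel
    return ModeSet(modes=modes, smoothed=smoothed, d1=d1, d2=d2)


def fit_me_em(h: ChannelHistogram, window: int = DEFAULT_WINDOW,
              theta: float = DEFAULT_THETA,
              seed: int | None = None,
              uniform_weight: float = DEFAULT_UNIFORM_WEIGHT,
              **fit_kwargs) -> FitResult:
    """Mode-estimation-plus-EM fit: one Gaussian per detected mode, means
    pinned at the mode locations, a single EM run for weights and variances.

    ``seed`` is accepted for interface symmetry with the other fitting
    routines; the pipeline is deterministic.

    Raises
    ------
    ValueError
        If no modes are detected — callers should fall back to
        ``fit_em_restarts`` with one component.
    """
    mode_set = detect_modes(h, window=window, theta=theta)
    if mode_set.n_modes == 0:
        raise ValueError(
            "no modes detected; fall back to fit_em_restarts with "
            "n_components=1"
        )
    k = mode_set.n_modes
    w = (1.0 - uniform_weight) / k
    init = MixtureModel(
        components=tuple(
            GaussianComponent(mean=float(m), sd=DEFAULT_INIT_SD, weight=w)
            for m in mode_set.modes
        ),
        uniform_weight=uniform_weight,
        n_channels=h.n_channels,
    )
    return fit_em(h, k, init=init, fix_means=True, **fit_kwargs)
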