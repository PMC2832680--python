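"""Conditional mixture model of a bistable dose response, fit by EM.

Instead of fitting a separate mixture at every inducer concentration, the
conditional mixture model (CEM) makes the dependence on the concentration
``g`` explicit and fits one model per biological replicate jointly across
all concentrations:

* the low- and high-subpopulation means are affine in ``g``
  (``mu = a + b * g``);
* the subpopulation standard deviations are independent of ``g``;
* the low subpopulation's mixture weight equals the full Gaussian mass
  (``1 - uniform_weight``, i.e. 0.98) below a threshold concentration ``g0``
  and decays exponentially at rate ``r`` above it, the high subpopulation
  taking up the remainder.

The threshold-exponential weight form encodes the switch phenomenology —
exclusively low-expressing cells below ``g0``, a high subpopulation that
abruptly appears and then dominates — and prevents the degenerate solution
in which a concentration-independent high component "captures" low cells at
small ``g`` and drags its mean curve down onto the low branch.

A single EM run suffices in practice; restarts do not improve the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

from .flow_data import ChannelHistogram
from .mixture_em import (
    DEFAULT_UNIFORM_WEIGHT,
    GaussianComponent,
    MixtureModel,
    mixture_loglik,
)

__all__ = [
    "ConditionalMixtureModel",
    "CEMFitResult",
    "weight_low",
    "predict_mixture",
    "fit_cem",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Variance floor (squared channels) shared with the unconditional EM.
_VARIANCE_FLOOR = 1.0


@dataclass(frozen=True)
class ConditionalMixtureModel:
    """Two-branch conditional mixture: parameters as functions of dose.

    Attributes
    ----------
    a_low, b_low
        Intercept (channels) and slope (channels per %gal) of the low
        subpopulation mean.
    a_high, b_high
        Same for the high subpopulation.
    sigma_low, sigma_high
        Concentration-independent subpopulation sds, channels.
    g0
        Threshold concentration (%gal) below which the population is
        entirely low-expressing.
    r
        Exponential decay rate (per %gal) of the low weight above ``g0``.
    """

    a_low: float
    b_low: float
    a_high: float
    b_high: float
    sigma_low: float
    sigma_high: float
    g0: float
    r: float
    uniform_weight: float = DEFAULT_UNIFORM_WEIGHT
    n_channels: int = 1024

    def __post_init__(self) -> None:
        if not (self.sigma_low > 0 and self.sigma_high > 0):
            raise ValueError("sigma_low and sigma_high must be positive")
        if self.r < 0:
            raise ValueError("decay rate r must be non-negative")
        if self.g0 < 0:
            raise ValueError("threshold g0 must be non-negative")
        if not 0.0 <= self.uniform_weight < 1.0:
            raise ValueError("uniform_weight must be in [0, 1)")

    @property
    def gaussian_mass(self) -> float:
        return 1.0 - self.uniform_weight

    def mean_low(self, g) -> np.ndarray | float:
        return self.a_low + self.b_low * np.asarray(g, dtype=float)

    def mean_high(self, g) -> np.ndarray | float:
        return self.a_high + self.b_high * np.asarray(g, dtype=float)


def weight_low(g, model: ConditionalMixtureModel):
    """Low-subpopulation mixture weight at concentration(s) ``g``.

    Equals the full Gaussian mass (0.98 by default) for ``g <= g0`` and
    decays exponentially at rate ``r`` above the threshold.  The high
    weight is the Gaussian mass minus this value.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("concentration must be non-negative")
    w = model.gaussian_mass * np.exp(
        -model.r * np.maximum(g - model.g0, 0.0))
    return float(w) if w.ndim == 0 else w


def predict_mixture(model: ConditionalMixtureModel, g: float) -> MixtureModel:
    """Evaluate the conditional model at one concentration.

    Returns the implied snapshot mixture: low and high Gaussians at their
    predicted means/weights plus the fixed uniform outlier component.  A
    branch whose weight is exactly zero (the high branch at ``g <= g0``) is
    represented with a vanishing but positive weight so the snapshot remains
    a valid mixture; its mass is numerically irrelevant.
    """
    w_low = weight_low(g, model)
    w_high = model.gaussian_mass - w_low
    tiny = 1e-300
    comps = [
        GaussianComponent(mean=float(model.mean_low(g)),
                          sd=model.sigma_low, weight=max(w_low, tiny)),
        GaussianComponent(mean=float(model.mean_high(g)),
                          sd=model.sigma_high, weight=max(w_high, tiny)),
    ]
    # MixtureModel sorts by mean; weight bookkeeping must still sum to one.
    excess = (max(w_low, tiny) + max(w_high, tiny)) - model.gaussian_mass
    if excess > 0:  # absorb the tiny padding into the larger weight
        big = max(range(2), key=lambda i: comps[i].weight)
        comps[big] = replace(comps[big], weight=comps[big].weight - excess)
    return MixtureModel(
        components=tuple(comps),
        uniform_weight=model.uniform_weight,
        n_channels=model.n_channels,
    )


@dataclass
class CEMFitResult:
    """Outcome of a conditional-mixture EM fit (one replicate)."""

    model: ConditionalMixtureModel
    loglik: float
    mean_nll: float
    n_iterations: int
    converged: bool


def _total_loglik(model: ConditionalMixtureModel,
                  histograms: list[ChannelHistogram]) -> tuple[float, float]:
    loglik = 0.0
    total = 0
    for h in histograms:
        ll, _ = mixture_loglik(predict_mixture(model, h.concentration), h)
        loglik += ll
        total += h.total
    return loglik, -loglik / total


#: Floor applied to branch weights inside the M-step weight objective.
#: The threshold-exponential form assigns the high branch exactly zero
#: weight below g0, which would make the objective -inf whenever any event
#: carries high responsibility there (inevitable on the first iteration,
#: when responsibilities come from flat weights and outliers sit under the
#: high component at every dose).  An infinitesimal leak keeps the search
#: well posed; once the E-step uses the thresholded curve, responsibilities
#: below g0 are exactly zero and the floor is inert.
_WEIGHT_FLOOR = 1e-12


def _weight_objective(g: np.ndarray, s_low: np.ndarray, s_high: np.ndarray,
                      gaussian_mass: float, g0: float, r: float) -> float:
    """Responsibility-weighted log-likelihood of the weight curve,
    ``sum_j s_low[j] * log w_low(g_j) + s_high[j] * log w_high(g_j)``,
    with branch weights floored at :data:`_WEIGHT_FLOOR`."""
    w_low = gaussian_mass * np.exp(-r * np.maximum(g - g0, 0.0))
    w_high = gaussian_mass - w_low
    log_low = np.log(np.maximum(w_low, _WEIGHT_FLOOR))
    log_high = np.log(np.maximum(w_high, _WEIGHT_FLOOR))
    return float(np.dot(s_low, log_low) + np.dot(s_high, log_high))


def _golden_refine(fun, lo: float, hi: float, x0: float,
                   n_iter: int = 40) -> float:
    """Golden-section maximisation of ``fun`` on [lo, hi], returning the
    better of the interior optimum and the starting point ``x0``."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    x = c if fc >= fd else d
    return x if fun(x) > fun(x0) else x0


def _fit_weight_curve(g: np.ndarray, s_low: np.ndarray, s_high: np.ndarray,
                      gaussian_mass: float, g0_current: float,
                      r_current: float, r_max: float,
                      n_grid: int = 50) -> tuple[float, float]:
    """Maximise the weight log-likelihood over (g0, r).

    Coarse grid search (linear in g0, log-spaced in r plus r = 0) followed
    by alternating golden-section refinement of each coordinate; the update
    is accepted only if it improves on the current (g0, r), preserving EM
    ascent.
    """
    g_max = float(np.max(g))
    g0_grid = np.linspace(0.0, g_max, n_grid)
    r_grid = np.concatenate(
        [[0.0], np.logspace(math.log10(max(1e-2, 1.0 / max(g_max, 1e-12))),
                            math.log10(r_max), n_grid - 1)])

    def q(g0, r):
        return _weight_objective(g, s_low, s_high, gaussian_mass, g0, r)

    # Vectorised grid evaluation.
    g0m, rm = np.meshgrid(g0_grid, r_grid, indexing="ij")
    w_low = gaussian_mass * np.exp(
        -rm[..., None] * np.maximum(g[None, None, :] - g0m[..., None], 0.0))
    w_high = gaussian_mass - w_low
    log_low = np.log(np.maximum(w_low, _WEIGHT_FLOOR))
    log_high = np.log(np.maximum(w_high, _WEIGHT_FLOOR))
    obj = log_low @ s_low + log_high @ s_high
    best_flat = int(np.argmax(obj))
    i, j = np.unravel_index(best_flat, obj.shape)
    g0_best, r_best = float(g0_grid[i]), float(r_grid[j])

    # Local refinement, one coordinate at a time.
    for _ in range(3):
        lo = g0_grid[max(i - 1, 0)]
        hi = g0_grid[min(i + 1, n_grid - 1)]
        g0_best = _golden_refine(lambda x: q(x, r_best), lo, hi, g0_best)
        r_lo = r_grid[max(j - 1, 0)]
        r_hi = r_grid[min(j + 1, n_grid - 1)]
        r_best = _golden_refine(lambda x: q(g0_best, x), r_lo, r_hi, r_best)

    # EM-ascent guard: never move to a worse weight curve.
    if q(g0_best, r_best) < q(g0_current, r_current):
        return g0_current, r_current
    return g0_best, r_best


def _wls_affine(g_per_obs: np.ndarray, y: np.ndarray, w: np.ndarray,
                fallback: tuple[float, float]) -> tuple[float, float]:
    """Weighted least squares of y on g: returns (intercept, slope)."""
    sw = w.sum()
    if sw <= 0:
        return fallback
    gbar = float(np.dot(w, g_per_obs) / sw)
    ybar = float(np.dot(w, y) / sw)
    sgg = float(np.dot(w, (g_per_obs - gbar) ** 2))
    if sgg <= 0:
        return ybar, 0.0
    sgy = float(np.dot(w, (g_per_obs - gbar) * (y - ybar)))
    slope = sgy / sgg
    return ybar - slope * gbar, slope


def fit_cem(replicate_data: Iterable[ChannelHistogram] |
            Mapping[float, ChannelHistogram],
            seed: int | None = None,
            max_iter: int = 1000, tol: float = 1e-8,
            r_max: float = 1e4,
            uniform_weight: float = DEFAULT_UNIFORM_WEIGHT,
            init: ConditionalMixtureModel | None = None) -> CEMFitResult:
    """Fit the conditional mixture model to one replicate's dose series.

    Parameters
    ----------
    replicate_data
        Histograms of a single replicate at three or more distinct
        concentrations (affine means plus the two-parameter weight curve
        need at least three design points).
    seed
        Accepted for interface symmetry; the single-run fit is
        deterministic.
    r_max
        Upper bound of the decay-rate search grid, per %gal.
    init
        Optional starting model.  The default follows the standard recipe:
        constant means of 200 (low) and 700 (high) channels, sds of 50, and
        a flat first E-step with both branch weights at half the Gaussian
        mass — the threshold-exponential weight curve is first fitted in
        the first M-step and used thereafter.

    Notes
    -----
    The M-step fits the affine mean coefficients by responsibility-weighted
    least squares of channel on concentration, the variances by the
    responsibility-weighted mean squared residual (floored at one squared
    channel), and (g0, r) by grid search plus golden-section refinement of
    the responsibility-weighted weight log-likelihood, accepting only
    improving steps — so the total log-likelihood is non-decreasing across
    iterations.
    """
    if isinstance(replicate_data, Mapping):
        histograms = [replicate_data[g] for g in sorted(replicate_data)]
    else:
        histograms = sorted(replicate_data, key=lambda h: h.concentration)
    if not histograms:
        raise ValueError("no histograms supplied")
    concentrations = [h.concentration for h in histograms]
    if len(set(concentrations)) < 3:
        raise ValueError(
            "fit_cem needs histograms at >= 3 distinct concentrations; got "
            f"{sorted(set(concentrations))}"
        )
    n_channels = histograms[0].n_channels
    for h in histograms:
        if h.n_channels != n_channels:
            raise ValueError("histograms disagree on channel count")
        if h.total <= 0:
            raise ValueError(
                f"histogram at g={h.concentration} has zero total count")

    g = np.array(concentrations, dtype=float)          # (J,)
    counts = np.stack([h.counts for h in histograms]).astype(float)  # (J, C)
    channels = np.arange(1, n_channels + 1, dtype=float)             # (C,)
    total_events = counts.sum()
    gaussian_mass = 1.0 - uniform_weight
    log_unif = (math.log(uniform_weight / n_channels)
                if uniform_weight > 0 else -np.inf)

    if init is None:
        model = ConditionalMixtureModel(
            a_low=200.0, b_low=0.0, a_high=700.0, b_high=0.0,
            sigma_low=50.0, sigma_high=50.0,
            g0=float(np.max(g)), r=0.0,
            uniform_weight=uniform_weight, n_channels=n_channels,
        )
        flat_first_weights = True
    else:
        model = init
        flat_first_weights = False

    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # --- E-step ---------------------------------------------------
        mu_low = model.mean_low(g)[:, None]    # (J, 1)
        mu_high = model.mean_high(g)[:, None]
        if flat_first_weights and n_iter == 1:
            w_low = np.full_like(g, gaussian_mass / 2.0)
        else:
            w_low = weight_low(g, model)
        w_high = gaussian_mass - w_low

        z_low = (channels[None, :] - mu_low) / model.sigma_low
        z_high = (channels[None, :] - mu_high) / model.sigma_high
        with np.errstate(divide="ignore"):
            log_joint = np.stack([
                np.where(w_low[:, None] > 0,
                         np.log(np.maximum(w_low, 1e-300))[:, None]
                         - math.log(model.sigma_low)
                         - 0.5 * (_LOG_2PI + z_low ** 2), -np.inf),
                np.where(w_high[:, None] > 0,
                         np.log(np.maximum(w_high, 1e-300))[:, None]
                         - math.log(model.sigma_high)
                         - 0.5 * (_LOG_2PI + z_high ** 2), -np.inf),
                np.full((len(g), n_channels), log_unif),
            ])  # (3, J, C)
        log_norm = logsumexp(log_joint, axis=0)        # (J, C)
        resp = np.exp(log_joint - log_norm[None])      # (3, J, C)

        # --- M-step ---------------------------------------------------
        w_obs_low = resp[0] * counts                   # (J, C)
        w_obs_high = resp[1] * counts

        g_per_obs = np.broadcast_to(g[:, None], w_obs_low.shape).ravel()
        y = np.broadcast_to(channels[None, :], w_obs_low.shape).ravel()

        a_low, b_low = _wls_affine(
            g_per_obs, y, w_obs_low.ravel(), (model.a_low, model.b_low))
        a_high, b_high = _wls_affine(
            g_per_obs, y, w_obs_high.ravel(), (model.a_high, model.b_high))

        res_low = (channels[None, :] - (a_low + b_low * g[:, None])) ** 2
        res_high = (channels[None, :] - (a_high + b_high * g[:, None])) ** 2
        s_low_tot = w_obs_low.sum()
        s_high_tot = w_obs_high.sum()
        var_low = ((w_obs_low * res_low).sum() / s_low_tot
                   if s_low_tot > 0 else model.sigma_low ** 2)
        var_high = ((w_obs_high * res_high).sum() / s_high_tot
                    if s_high_tot > 0 else model.sigma_high ** 2)
        sigma_low = math.sqrt(max(var_low, _VARIANCE_FLOOR))
        sigma_high = math.sqrt(max(var_high, _VARIANCE_FLOOR))

        s_low = w_obs_low.sum(axis=1)                  # (J,)
        s_high = w_obs_high.sum(axis=1)
        if flat_first_weights and n_iter == 1:
            # No current (g0, r) yet: seed the guard with the grid best.
            g0_cur, r_cur = float(np.max(g)), 0.0
        else:
            g0_cur, r_cur = model.g0, model.r
        g0, r = _fit_weight_curve(
            g, s_low, s_high, gaussian_mass, g0_cur, r_cur, r_max)

        model = ConditionalMixtureModel(
            a_low=a_low, b_low=b_low, a_high=a_high, b_high=b_high,
            sigma_low=sigma_low, sigma_high=sigma_high,
            g0=g0, r=r,
            uniform_weight=uniform_weight, n_channels=n_channels,
        )

        loglik_new, _ = _total_loglik(model, histograms)
        if (np.isfinite(loglik)
                and abs(loglik_new - loglik) <= tol * abs(loglik)):
            loglik = loglik_new
            converged = True
            break
        loglik = loglik_new

    loglik, mean_nll = _total_loglik(model, histograms)
    return CEMFitResult(
        model=model, loglik=loglik, mean_nll=mean_nll,
        n_iterations=n_iter, converged=converged,
    )
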