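"""Gaussian-plus-uniform mixture density estimation on binned histograms.

Each fluorescence histogram is modelled as a mixture of ``K`` Gaussian
components (the cell subpopulations, in log-intensity channel coordinates)
plus one uniform component over the channel support whose weight is held
fixed (default 0.02) to absorb outliers — debris, carry-over between samples,
doublets.  The Gaussian weights share the remaining mass.

Fitting is expectation-maximisation on the binned counts: every event in
channel ``c`` contributes the density evaluated at the bin centre ``c``.
Because the bins are narrow relative to any credible subpopulation spread
(sd of tens of channels), bin-centre evaluation is indistinguishable from
bin-integrated probabilities.

Local optima are handled by random restarts (:func:`fit_em_restarts`); a
component whose variance collapses below a floor of one squared channel is
eliminated, since a Gaussian focussed on a single channel does not represent
a real subpopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .flow_data import ChannelHistogram

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "FitResult",
    "mixture_loglik",
    "fit_em",
    "fit_em_restarts",
    "random_init",
]

#: Fixed mixture weight of the uniform outlier component.
DEFAULT_UNIFORM_WEIGHT = 0.02
#: Initial Gaussian standard deviation, in channels.
DEFAULT_INIT_SD = 50.0
#: Variance floor (squared channels) below which a component is eliminated.
DEFAULT_VARIANCE_FLOOR = 1.0

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian subpopulation: mean and sd in channels, mixture weight."""

    mean: float
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class MixtureModel:
    """Gaussian components plus a fixed-weight uniform outlier component.

    Components are kept sorted by ascending mean.  The uniform component is
    supported on ``[1, n_channels]``; its weight plus the Gaussian weights
    must sum to one.
    """

    components: tuple[GaussianComponent, ...]
    uniform_weight: float = DEFAULT_UNIFORM_WEIGHT
    n_channels: int = 1024

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        means = [c.mean for c in comps]
        if means != sorted(means):
            comps = tuple(sorted(comps, key=lambda c: c.mean))
        object.__setattr__(self, "components", comps)
        total = self.uniform_weight + sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def log_density(self, c) -> np.ndarray:
        """Log mixture density at (real-valued) channel coordinates ``c``."""
        c = np.atleast_1d(np.asarray(c, dtype=float))
        parts = []
        if self.uniform_weight > 0:
            parts.append(np.full_like(
                c, math.log(self.uniform_weight / self.n_channels)))
        for comp in self.components:
            z = (c - comp.mean) / comp.sd
            parts.append(
                math.log(comp.weight) - math.log(comp.sd)
                - 0.5 * (_LOG_2PI + z * z)
            )
        if not parts:
            raise ValueError("empty mixture (no components, no uniform mass)")
        return logsumexp(np.stack(parts, axis=0), axis=0)

    def density(self, c) -> np.ndarray:
        return np.exp(self.log_density(c))


@dataclass
class FitResult:
    """Outcome of one mixture fit.

    ``mean_nll`` is the per-event negative log-likelihood in nats,
    ``-loglik / total event count`` — the goodness-of-fit score used for
    cross-replicate comparison.
    """

    model: MixtureModel
    loglik: float
    mean_nll: float
    n_iterations: int
    converged: bool
    n_restarts_used: int = 1
    eliminated_components: int = 0
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def mixture_loglik(model: MixtureModel, h: ChannelHistogram
                   ) -> tuple[float, float]:
    """Total log-likelihood and per-event NLL of a histogram under a model.

    Densities are evaluated at bin centres (integer channels).  With a
    positive uniform weight the density is bounded away from zero, so no
    channel can contribute ``-inf``.
    """
    if model.n_channels != h.n_channels:
        raise ValueError(
            f"model support ({model.n_channels} channels) does not match "
            f"histogram ({h.n_channels} channels)"
        )
    total = h.total
    if total <= 0:
        raise ValueError("histogram has zero total count")
    occupied = np.nonzero(h.counts)[0]
    logdens = model.log_density(occupied + 1.0)
    loglik = float(np.dot(h.counts[occupied], logdens))
    return loglik, -loglik / total


def random_init(h: ChannelHistogram, n_components: int,
                rng: np.random.Generator,
                init_sd: float = DEFAULT_INIT_SD,
                uniform_weight: float = DEFAULT_UNIFORM_WEIGHT) -> MixtureModel:
    """Random initial mixture for one EM restart.

    Component means are drawn uniformly between the lowest and highest
    occupied channel; sds start at ``init_sd``; Gaussian weights share the
    non-uniform mass equally.
    """
    lo, hi = _occupied_range(h)
    means = np.sort(rng.uniform(lo, hi, size=n_components))
    w = (1.0 - uniform_weight) / n_components
    return MixtureModel(
        components=tuple(
            GaussianComponent(mean=float(m), sd=init_sd, weight=w)
            for m in means
        ),
        uniform_weight=uniform_weight,
        n_channels=h.n_channels,
    )


def _occupied_range(h: ChannelHistogram) -> tuple[float, float]:
    occupied = np.nonzero(h.counts)[0]
    if occupied.size == 0:
        raise ValueError("histogram has zero total count")
    return float(occupied[0] + 1), float(occupied[-1] + 1)


def _default_init(h: ChannelHistogram, n_components: int,
                  uniform_weight: float) -> MixtureModel:
    """Deterministic fallback initialisation: means at evenly spaced
    quantile positions between the occupied extremes."""
    lo, hi = _occupied_range(h)
    qs = (np.arange(n_components) + 0.5) / n_components
    means = lo + qs * (hi - lo)
    w = (1.0 - uniform_weight) / n_components
    return MixtureModel(
        components=tuple(
            GaussianComponent(mean=float(m), sd=DEFAULT_INIT_SD, weight=w)
            for m in means
        ),
        uniform_weight=uniform_weight,
        n_channels=h.n_channels,
    )


def fit_em(h: ChannelHistogram, n_components: int,
           init: MixtureModel | None = None,
           max_iter: int = 500, tol: float = 1e-8,
           fix_means: bool = False,
           variance_floor: float = DEFAULT_VARIANCE_FLOOR,
           uniform_weight: float = DEFAULT_UNIFORM_WEIGHT) -> FitResult:
    """Fit a Gaussian-plus-uniform mixture to one histogram by EM.

    Parameters
    ----------
    h
        Histogram with positive total count.
    n_components
        Number of Gaussian components ``K`` (>= 1); must not exceed the
        number of occupied channels.
    init
        Optional starting mixture; its uniform weight overrides
        ``uniform_weight``.  Without it a deterministic evenly-spaced
        initialisation is used.
    fix_means
        Hold the component means fixed (mode-estimation-plus-EM pipeline);
        only weights and variances are updated.
    variance_floor
        A component whose fitted variance falls below this floor (squared
        channels) is eliminated and the remaining Gaussian weights are
        renormalised to the non-uniform mass.

    Returns
    -------
    FitResult
        The mean log-likelihood is non-decreasing over iterations (standard
        EM ascent); convergence is declared when the relative change in
        total log-likelihood drops below ``tol``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    total = h.total
    if total <= 0:
        raise ValueError("histogram has zero total count")
    n_occupied = int(np.count_nonzero(h.counts))
    if n_components > n_occupied:
        raise ValueError(
            f"n_components={n_components} exceeds the {n_occupied} occupied "
            "channels"
        )
    if init is not None:
        if init.n_components != n_components:
            raise ValueError("init has a different number of components")
        if init.n_channels != h.n_channels:
            raise ValueError("init support does not match histogram")
        uniform_weight = init.uniform_weight
    else:
        init = _default_init(h, n_components, uniform_weight)

    n_channels = h.n_channels
    occupied = np.nonzero(h.counts)[0]
    counts = h.counts[occupied].astype(float)
    channels = occupied + 1.0  # bin centres

    gaussian_mass = 1.0 - uniform_weight
    means = init.means.copy()
    sds = init.sds.copy()
    weights = init.weights.copy()

    log_unif = (
        math.log(uniform_weight / n_channels)
        if uniform_weight > 0 else -np.inf
    )

    trace: list[float] = []
    eliminated = 0
    converged = False
    n_iter = 0
    loglik = -np.inf

    for n_iter in range(1, max_iter + 1):
        # E-step: log joint of each component at every occupied channel.
        z = (channels[None, :] - means[:, None]) / sds[:, None]
        log_joint = (
            np.log(weights)[:, None] - np.log(sds)[:, None]
            - 0.5 * (_LOG_2PI + z * z)
        )
        if uniform_weight > 0:
            log_joint = np.vstack(
                [np.full((1, channels.size), log_unif), log_joint])
        log_norm = logsumexp(log_joint, axis=0)
        loglik_new = float(np.dot(counts, log_norm))
        trace.append(loglik_new)

        resp = np.exp(log_joint - log_norm[None, :])  # (1?+K, C)
        gauss_resp = resp[1:] if uniform_weight > 0 else resp

        # M-step.
        nk = gauss_resp @ counts  # effective events per component
        nk_total = nk.sum()
        if nk_total <= 0:
            means = np.empty(0)
            sds = np.empty(0)
            weights = np.empty(0)
            eliminated += len(nk)
            break
        new_weights = gaussian_mass * nk / nk_total
        if not fix_means:
            with np.errstate(invalid="ignore", divide="ignore"):
                new_means = (gauss_resp @ (counts * channels)) / nk
            new_means = np.where(nk > 0, new_means, means)
        else:
            new_means = means
        sq = (channels[None, :] - new_means[:, None]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            new_vars = (gauss_resp * sq[...]) @ counts / nk
        new_vars = np.where(nk > 0, new_vars, 0.0)

        # Variance-floor elimination: a component collapsing onto a single
        # channel is removed and the Gaussian mass renormalised.
        keep = (new_vars >= variance_floor) & (nk > 0)
        if not np.all(keep):
            eliminated += int(np.count_nonzero(~keep))
            new_means = new_means[keep]
            new_vars = new_vars[keep]
            new_weights = new_weights[keep]
            if new_weights.size == 0:
                means = np.empty(0)
                sds = np.empty(0)
                weights = np.empty(0)
                break
            new_weights = gaussian_mass * new_weights / new_weights.sum()

        means = new_means
        sds = np.sqrt(new_vars)
        weights = new_weights

        if (np.isfinite(loglik)
                and abs(loglik_new - loglik) <= tol * abs(loglik)):
            loglik = loglik_new
            converged = True
            break
        loglik = loglik_new

    if means.size == 0:
        # All components eliminated: degenerate pure-uniform model.
        model = MixtureModel(
            components=(), uniform_weight=1.0, n_channels=n_channels)
        loglik, mean_nll = mixture_loglik(model, h)
        return FitResult(
            model=model, loglik=loglik, mean_nll=mean_nll,
            n_iterations=n_iter, converged=True,
            eliminated_components=eliminated, loglik_trace=trace,
        )

    order = np.argsort(means)
    model = MixtureModel(
        components=tuple(
            GaussianComponent(
                mean=float(means[i]), sd=float(sds[i]),
                weight=float(weights[i]))
            for i in order
        ),
        uniform_weight=uniform_weight,
        n_channels=n_channels,
    )
    loglik, mean_nll = mixture_loglik(model, h)
    return FitResult(
        model=model, loglik=loglik, mean_nll=mean_nll,
        n_iterations=n_iter, converged=converged,
        eliminated_components=eliminated, loglik_trace=trace,
    )


def fit_em_restarts(h: ChannelHistogram, n_components: int,
                    n_restarts: int = 100,
                    seed: int | np.random.SeedSequence | None = None,
                    **fit_kwargs) -> FitResult:
    """Best-of-``n_restarts`` EM fits from random initialisations.

    Each restart draws its initial component means uniformly between the
    lowest and highest occupied channel.  Restarts use independent
    substreams spawned from one root seed, so increasing ``n_restarts``
    extends the restart list without reshuffling earlier restarts.  Ties in
    final log-likelihood are broken by the lowest restart index.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(n_restarts)
    uniform_weight = fit_kwargs.get("uniform_weight", DEFAULT_UNIFORM_WEIGHT)
    best: FitResult | None = None
    for child in children:
        rng = np.random.default_rng(child)
        init = random_init(h, n_components, rng,
                           uniform_weight=uniform_weight)
        result = fit_em(h, n_components, init=init, **fit_kwargs)
        if best is None or result.loglik > best.loglik:
            best = result
    assert best is not None
    best.n_restarts_used = n_restarts
    return best
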