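"""Cross-validated choice of the number of Gaussian mixture components.

Starting from one component, the candidate ``K + 1``-component model is
accepted only when 10-fold cross-validation says it predicts held-out events
significantly better than the ``K``-component model: the mean (across folds)
held-out per-event log-likelihood must exceed the ``K`` model's mean by more
than ``alpha`` times the across-fold standard deviation of the ``K + 1``
scores.  Both candidates are scored on the same folds.  The search stops at
the first rejection or at ``k_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .flow_data import ChannelHistogram
from .mixture_em import fit_em_restarts, mixture_loglik

__all__ = ["CVDecision", "split_folds", "select_num_components"]


@dataclass
class CVDecision:
    """Trace of the cross-validated component-count search."""

    chosen_k: int
    per_k_fold_scores: dict[int, list[float]]
    per_k_mean: dict[int, float]
    per_k_sd: dict[int, float]
    alpha: float
    n_folds: int = 10


def split_folds(h: ChannelHistogram, n_folds: int = 10,
                seed: int | np.random.SeedSequence | None = None
                ) -> list[tuple[ChannelHistogram, ChannelHistogram]]:
    """Randomly partition the *events* of a histogram into CV folds.

    Every event is assigned to exactly one test fold uniformly at random
    (equivalently, each channel's count is split multinomially across
    folds), so per fold train + test reproduce the original counts
    channel-wise and the test folds sum to the original histogram.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    total = h.total
    if total < n_folds:
        raise ValueError(
            f"histogram has {total} events, fewer than n_folds={n_folds}")
    rng = np.random.default_rng(seed)
    # (n_channels, n_folds) multinomial split of each channel's count.
    test_counts = rng.multinomial(h.counts, np.full(n_folds, 1.0 / n_folds))
    folds = []
    for j in range(n_folds):
        test = test_counts[:, j]
        train = h.counts - test
        folds.append((
            replace(h, counts=train),
            replace(h, counts=test),
        ))
    return folds


def _cv_scores(folds, n_components: int, restarts: int,
               seeds: list[np.random.SeedSequence], **fit_kwargs
               ) -> list[float]:
    """Held-out mean per-event log-likelihood for each fold."""
    scores = []
    for (train, test), fold_seed in zip(folds, seeds):
        if test.total == 0 or train.total == 0:
            raise ValueError("empty CV fold; too few events for n_folds")
        fit = fit_em_restarts(train, n_components, n_restarts=restarts,
                              seed=fold_seed, **fit_kwargs)
        _, mean_nll = mixture_loglik(fit.model, test)
        scores.append(-mean_nll)
    return scores


def select_num_components(h: ChannelHistogram, alpha: float = 1.0,
                          k_max: int = 6, n_folds: int = 10,
                          restarts: int = 100,
                          seed: int | np.random.SeedSequence | None = None,
                          **fit_kwargs) -> CVDecision:
    """Choose the number of Gaussian components by 10-fold cross-validation.

    Parameters
    ----------
    alpha
        Stringency multiplier: ``K + 1`` is accepted iff
        ``mean(K+1) - mean(K) > alpha * sd(K+1)`` where mean/sd are taken
        across folds of the held-out per-event log-likelihood.  Larger
        ``alpha`` is stricter, so the chosen ``K`` is non-increasing in it.
    restarts
        EM restarts per fold fit (the final full-data fit, done by the
        caller, conventionally uses the same count).

    Notes
    -----
    The comparator is the ``K`` model's cross-validation mean on the same
    folds (not its training score), which makes the comparison symmetric
    between the two candidate orders.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    fold_seed, fit_root = root.spawn(2)
    folds = split_folds(h, n_folds=n_folds, seed=fold_seed)
    fit_seeds = fit_root.spawn(k_max * n_folds)

    def seeds_for(k: int) -> list[np.random.SeedSequence]:
        return fit_seeds[(k - 1) * n_folds:k * n_folds]

    per_k_scores: dict[int, list[float]] = {}
    per_k_mean: dict[int, float] = {}
    per_k_sd: dict[int, float] = {}

    def evaluate(k: int) -> None:
        scores = _cv_scores(folds, k, restarts, seeds_for(k), **fit_kwargs)
        per_k_scores[k] = scores
        per_k_mean[k] = float(np.mean(scores))
        per_k_sd[k] = float(np.std(scores, ddof=1))

    evaluate(1)
    chosen = 1
    while chosen < k_max:
        candidate = chosen + 1
        evaluate(candidate)
        gain = per_k_mean[candidate] - per_k_mean[chosen]
        if gain > alpha * per_k_sd[candidate]:
            chosen = candidate
        else:
            break

    return CVDecision(
        chosen_k=chosen,
        per_k_fold_scores=per_k_scores,
        per_k_mean=per_k_mean,
        per_k_sd=per_k_sd,
        alpha=alpha,
        n_folds=n_folds,
    )
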