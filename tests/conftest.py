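"""Shared fixtures: seeded synthetic histograms for the estimator tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from stochbif import ChannelHistogram, default_paper_spec


def sample_mixture_histogram(rng, components, n_events=30_000,
                             outlier_frac=0.02, n_channels=1024,
                             concentration=0.0):
    """Draw a histogram from Gaussian components plus uniform outliers.

    ``components`` is a list of (weight, mean, sd); weights are renormalised
    over the non-outlier mass.  Events are rounded to integer channels and
    clipped to the instrument rails, like the real acquisition.
    """
    n_out = rng.binomial(n_events, outlier_frac)
    weights = np.array([w for w, _, _ in components], dtype=float)
    weights = weights / weights.sum()
    per_comp = rng.multinomial(n_events - n_out, weights)
    parts = [
        rng.normal(mu, sd, size=k)
        for (_, mu, sd), k in zip(components, per_comp)
    ]
    parts.append(rng.uniform(1, n_channels, size=n_out))
    values = np.concatenate(parts)
    channels = np.clip(np.rint(values), 1, n_channels).astype(np.int64)
    counts = np.bincount(channels, minlength=n_channels + 1)[1:]
    return ChannelHistogram(counts=counts, concentration=concentration)


@pytest.fixture
def unimodal_histogram():
    """One Gaussian subpopulation (mean 300, sd 50) plus 2% outliers."""
    rng = np.random.default_rng(2024)
    return sample_mixture_histogram(rng, [(1.0, 300.0, 50.0)])


@pytest.fixture
def bimodal_histogram():
    """Well-separated low/high subpopulations (250/700) plus 2% outliers."""
    rng = np.random.default_rng(2025)
    return sample_mixture_histogram(
        rng, [(0.5, 250.0, 40.0), (0.5, 700.0, 80.0)])


def scaled_study_spec(seed, events_per_condition=8_000,
                      pregrowths=("gal",)):
    """The default study design scaled down for test runtime: the same
    ground truth and acquisition model on a 9-level subset of the dose
    series with fewer events per condition."""
    concentrations = (0.0, 0.0022, 0.0038, 0.0050, 0.0066, 0.0087,
                      0.0115, 0.0174, 0.080)
    return dataclasses.replace(
        default_paper_spec(seed=seed),
        events_per_condition=events_per_condition,
        pregrowths=pregrowths,
        concentrations=concentrations,
    )
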