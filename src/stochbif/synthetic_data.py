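"""Synthetic flow-cytometry datasets with the structure of a bistable
galactose dose–response experiment.

The generator emulates the statistical shape of the yeast galactose-switch
assay: for every (pregrowth, replicate, concentration) condition it draws
events from a two-Gaussian-plus-uniform mixture in log-intensity channel
space whose parameters follow a ground-truth conditional mixture model —
an affine high-subpopulation mean that grows with concentration, a low
weight that is flat below a threshold and decays exponentially above it,
and 2% uniform outliers.  Events are thinned by an independent Bernoulli
"scatter gate", rounded to integer channels, clipped to the instrument
rails, and binned.

A Gaussian in channel coordinates corresponds to a lognormal intensity
distribution, the standard phenomenology for stochastic gene expression.
Replicate-to-replicate biological variability is emulated by jittering both
mean intercepts once per (pregrowth, replicate); pregrowth history enters
only by scaling the weight-curve threshold (the raffinose-start transition
occurs over a slightly higher concentration range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conditional_mixture import ConditionalMixtureModel, weight_low
from .flow_data import ChannelHistogram, ChannelTransform, Dataset

__all__ = [
    "SyntheticSpec",
    "default_paper_spec",
    "default_truth",
    "generate_dataset",
    "EVENT_LOW",
    "EVENT_HIGH",
    "EVENT_OUTLIER",
]

#: Dose series of the emulated experiment (%w/v galactose): the 17
#: analysed concentrations of the galactose-switch assay.
DEFAULT_CONCENTRATIONS = (
    0.0, 0.0015, 0.0022, 0.0033, 0.0038, 0.0043, 0.0050, 0.0057, 0.0066,
    0.0076, 0.0087, 0.0100, 0.0115, 0.0132, 0.0174, 0.020, 0.080,
)

# Integer labels attached to generated events.
EVENT_LOW, EVENT_HIGH, EVENT_OUTLIER = 0, 1, 2


def default_truth() -> ConditionalMixtureModel:
    """Ground-truth generative parameters for the default synthetic study.

    Values chosen to produce dose-response trajectories like the real
    experiment: a near-flat low branch around channel 150, a high branch
    rising from ~550 to ~870 channels over the dose range, larger spread in
    the high subpopulation, and a low weight that collapses above a
    threshold of 0.003 %gal.
    """
    return ConditionalMixtureModel(
        a_low=150.0, b_low=500.0,
        a_high=550.0, b_high=4000.0,
        sigma_low=40.0, sigma_high=80.0,
        g0=0.003, r=150.0,
        uniform_weight=0.02, n_channels=1024,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus acquisition parameters for the generator.

    Attributes
    ----------
    truth
        Generative conditional mixture model (per-condition component
        parameters and weights as functions of concentration).
    events_per_condition
        Events acquired per condition before gating.
    gate_fraction
        Probability that an event survives the scatter gate, independent of
        its fluorescence.
    replicate_jitter_sd
        Standard deviation (channels) of the Gaussian offset added to both
        mean intercepts, drawn once per (pregrowth, replicate).
    raf_threshold_scale
        Multiplier applied to the weight threshold ``g0`` under raffinose
        pregrowth.
    """

    truth: ConditionalMixtureModel = field(default_factory=default_truth)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 4
    pregrowths: tuple[str, ...] = ("gal", "raf")
    events_per_condition: int = 60_000
    gate_fraction: float = 0.5
    replicate_jitter_sd: float = 10.0
    raf_threshold_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_condition <= 0:
            raise ValueError("events_per_condition must be positive")
        if not 0.0 < self.gate_fraction <= 1.0:
            raise ValueError("gate_fraction must be in (0, 1]")
        conc = tuple(float(g) for g in self.concentrations)
        if len(set(conc)) != len(conc):
            raise ValueError("concentrations must be distinct")
        if any(g < 0 for g in conc):
            raise ValueError("concentrations must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_jitter_sd < 0:
            raise ValueError("replicate_jitter_sd must be non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(
            self, "pregrowths", tuple(sorted(set(self.pregrowths))))


def default_paper_spec(seed: int = 0) -> SyntheticSpec:
    """The default study conditions: 17 concentrations, 4 replicates per
    pregrowth, 60,000 events per condition, ~50% gating."""
    return SyntheticSpec(seed=seed)


def _replicate_truth(spec: SyntheticSpec, pregrowth: str,
                     jitter: float) -> ConditionalMixtureModel:
    truth = spec.truth
    g0 = truth.g0 * (spec.raf_threshold_scale if pregrowth == "raf" else 1.0)
    return replace(truth, a_low=truth.a_low + jitter,
                   a_high=truth.a_high + jitter, g0=g0)


def _simulate_condition(rng: np.random.Generator,
                        truth: ConditionalMixtureModel,
                        g: float, spec: SyntheticSpec
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one condition's events.

    Returns (integer channels of all events, component labels, gate mask).
    """
    n = spec.events_per_condition
    w_low = weight_low(g, truth)
    w_high = truth.gaussian_mass - w_low
    labels = rng.choice(
        3, size=n, p=[w_low, w_high, truth.uniform_weight])
    values = np.empty(n)
    low = labels == EVENT_LOW
    high = labels == EVENT_HIGH
    out = labels == EVENT_OUTLIER
    values[low] = rng.normal(truth.mean_low(g), truth.sigma_low,
                             size=int(low.sum()))
    values[high] = rng.normal(truth.mean_high(g), truth.sigma_high,
                              size=int(high.sum()))
    values[out] = rng.uniform(1.0, truth.n_channels, size=int(out.sum()))
    kept = rng.random(n) < spec.gate_fraction
    channels = np.clip(np.rint(values), 1, truth.n_channels).astype(np.int64)
    return channels, labels, kept


def generate_dataset(spec: SyntheticSpec, return_labels: bool = False):
    """Generate a full synthetic dataset from a :class:`SyntheticSpec`.

    Fully reproducible given ``spec.seed``: the root seed spawns one
    substream per (pregrowth, replicate) for the intercept jitter and one
    per condition for the event draws, keyed by the sorted condition order.

    Parameters
    ----------
    return_labels
        If true, also return a mapping from condition key to a dict with
        the pre-gate event ``channels``, component ``labels``
        (:data:`EVENT_LOW` / :data:`EVENT_HIGH` / :data:`EVENT_OUTLIER`),
        and the gate ``kept`` mask — the generator's own ground truth for
        calibration checks.
    """
    transform = ChannelTransform(n_channels=spec.truth.n_channels)
    dataset = Dataset(transform=transform)
    labelled: dict[tuple[str, str, float], dict[str, np.ndarray]] = {}

    root = np.random.SeedSequence(spec.seed)
    replicate_keys = [
        (pg, str(rep + 1))
        for pg in spec.pregrowths
        for rep in range(spec.n_replicates)
    ]
    n_conditions = len(replicate_keys) * len(spec.concentrations)
    streams = root.spawn(len(replicate_keys) + n_conditions)
    jitter_streams = streams[:len(replicate_keys)]
    condition_streams = streams[len(replicate_keys):]

    idx = 0
    for (pg, rep), jitter_ss in zip(replicate_keys, jitter_streams):
        jitter_rng = np.random.default_rng(jitter_ss)
        jitter = jitter_rng.normal(0.0, spec.replicate_jitter_sd)
        truth = _replicate_truth(spec, pg, jitter)
        for g in spec.concentrations:
            rng = np.random.default_rng(condition_streams[idx])
            idx += 1
            channels, labels, kept = _simulate_condition(rng, truth, g, spec)
            counts = np.bincount(channels[kept],
                                 minlength=truth.n_channels + 1)[1:]
            dataset.add(ChannelHistogram(
                counts=counts, concentration=g,
                replicate_id=rep, pregrowth=pg,
            ))
            if return_labels:
                labelled[(pg, rep, g)] = {
                    "channels": channels, "labels": labels, "kept": kept,
                }
    if return_labels:
        return dataset, labelled
    return dataset
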