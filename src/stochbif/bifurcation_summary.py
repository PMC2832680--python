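"""Assembling the stochastic bifurcation structure and cross-method /
cross-replicate evaluation.

The stochastic bifurcation structure of a noisy switch summarises, as a
function of the control parameter (here the galactose concentration), four
things: the number of distinguishable subpopulations, their locations
(Gaussian means, in channels), their within-subpopulation variability
(Gaussian sds), and the fraction of the population in each.  Any fitted
mixture — per-concentration EM or ME+EM fits, or a conditional mixture
evaluated along the dose axis — can be reduced to this structure.

Evaluation utilities compare fitting methods against biological replicates:
per-event negative log-likelihood on the fitting replicate ("training") and
on the other replicates of the same pregrowth ("testing"), and a
decomposition of landmark-location variability into a between-replicate
(biological) and a between-method component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_data import ChannelHistogram, Dataset
from .mixture_em import MixtureModel, mixture_loglik
from .conditional_mixture import (
    ConditionalMixtureModel,
    predict_mixture,
    weight_low,
)

__all__ = [
    "BifurcationStructure",
    "SubpopulationSnapshot",
    "VariabilityReport",
    "extract_structure",
    "train_test_nll",
    "variability_decomposition",
    "default_landmarks",
    "landmark_location",
    "landmark_table",
    "fit_all_methods",
]

#: Minimum CEM low-branch weight for the low subpopulation to be reported.
DEFAULT_LOW_REPORT_THRESHOLD = 0.01


@dataclass(frozen=True)
class SubpopulationSnapshot:
    """Subpopulation summary at one concentration."""

    n_subpops: int
    locations: tuple[float, ...]
    spreads: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.locations) == len(self.spreads)
                == len(self.fractions) == self.n_subpops):
            raise ValueError("snapshot list lengths disagree with n_subpops")
        if self.n_subpops and abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to one")


@dataclass
class BifurcationStructure:
    """Per-concentration subpopulation summaries, keyed by concentration."""

    snapshots: dict[float, SubpopulationSnapshot]

    def concentrations(self) -> list[float]:
        return sorted(self.snapshots)

    def __getitem__(self, g: float) -> SubpopulationSnapshot:
        return self.snapshots[g]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.concentrations():
            snap = self.snapshots[g]
            for i in range(snap.n_subpops):
                rows.append({
                    "concentration": g,
                    "subpopulation": i,
                    "location": snap.locations[i],
                    "spread": snap.spreads[i],
                    "fraction": snap.fractions[i],
                })
        return pd.DataFrame(rows)


def _snapshot_from_mixture(model: MixtureModel,
                           drop_low: bool = False) -> SubpopulationSnapshot:
    comps = list(model.components)
    if drop_low and len(comps) > 1:
        comps = comps[1:]
    wsum = sum(c.weight for c in comps)
    return SubpopulationSnapshot(
        n_subpops=len(comps),
        locations=tuple(c.mean for c in comps),
        spreads=tuple(c.sd for c in comps),
        fractions=tuple(c.weight / wsum for c in comps),
    )


def extract_structure(
    fits: Mapping[float, MixtureModel] | ConditionalMixtureModel,
    low_report_threshold: float = DEFAULT_LOW_REPORT_THRESHOLD,
    concentrations: Sequence[float] | None = None,
) -> BifurcationStructure:
    """Reduce fitted mixtures to the stochastic bifurcation structure.

    Parameters
    ----------
    fits
        Either a mapping from concentration to a fitted snapshot mixture
        (EM / ME+EM), or a conditional mixture model, in which case
        ``concentrations`` selects where to evaluate it and the low
        subpopulation is reported only where its weight exceeds
        ``low_report_threshold`` (the weight curve never reaches zero, so a
        cutoff stands in for "the low subpopulation has disappeared").

    Subpopulation fractions are the Gaussian weights renormalised over the
    reported components (by the full Gaussian mass, 0.98, when nothing is
    dropped), so they always sum to one.
    """
    snapshots: dict[float, SubpopulationSnapshot] = {}
    if isinstance(fits, ConditionalMixtureModel):
        if concentrations is None:
            raise ValueError(
                "concentrations are required to evaluate a conditional model")
        for g in concentrations:
            drop_low = weight_low(g, fits) <= low_report_threshold
            snapshots[float(g)] = _snapshot_from_mixture(
                predict_mixture(fits, g), drop_low=drop_low)
    else:
        for g, model in fits.items():
            snapshots[float(g)] = _snapshot_from_mixture(model)
    return BifurcationStructure(snapshots=snapshots)


# --------------------------------------------------------------------------
# Train/test evaluation across replicates
# --------------------------------------------------------------------------

FittedModel = Mapping[float, MixtureModel] | ConditionalMixtureModel


def _mean_nll(model: FittedModel, h: ChannelHistogram) -> float:
    if isinstance(model, ConditionalMixtureModel):
        snapshot = predict_mixture(model, h.concentration)
    else:
        snapshot = model[h.concentration]
    _, mean_nll = mixture_loglik(snapshot, h)
    return mean_nll


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                  n_resamples: int = 1000,
                  level: float = 0.95) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def train_test_nll(
    models: Mapping[tuple[str, str, str], FittedModel],
    dataset: Dataset,
    seed: int | None = None,
    n_resamples: int = 1000,
) -> pd.DataFrame:
    """Training and testing per-event NLL for every fitted model.

    Parameters
    ----------
    models
        Mapping from ``(method, pregrowth, replicate_id)`` to the fitted
        model for that replicate (a concentration→mixture mapping for the
        per-condition methods, or a conditional mixture model).
    dataset
        The histograms the models were fit to.  All replicates of a
        pregrowth must share the same concentrations.

    Returns
    -------
    pandas.DataFrame
        One row per (method, pregrowth, replicate, split) with the mean
        per-event NLL — averaged over conditions (training: the model's own
        replicate; testing: every other replicate of the same pregrowth) —
        plus a 95% percentile-bootstrap confidence interval over conditions
        (seeded, ``n_resamples`` resamples).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (method, pregrowth, replicate_id), model in sorted(models.items()):
        concentrations = dataset.concentrations(pregrowth, replicate_id)
        others = [r for r in dataset.replicates(pregrowth)
                  if r != replicate_id]
        for other in others:
            conc_other = dataset.concentrations(pregrowth, other)
            if conc_other != concentrations:
                raise ValueError(
                    f"replicates {replicate_id} and {other} of pregrowth "
                    f"{pregrowth} measured different concentrations"
                )
        train_scores = np.array([
            _mean_nll(model, dataset.get(pregrowth, replicate_id, g))
            for g in concentrations
        ])
        test_scores = np.array([
            _mean_nll(model, dataset.get(pregrowth, other, g))
            for other in others
            for g in concentrations
        ])
        for split, scores in (("train", train_scores),
                              ("test", test_scores)):
            if scores.size == 0:
                continue
            lo, hi = _bootstrap_ci(scores, rng, n_resamples=n_resamples)
            rows.append({
                "method": method,
                "pregrowth": pregrowth,
                "replicate": replicate_id,
                "split": split,
                "mean_nll": float(scores.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n_conditions": int(scores.size),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Variability decomposition (methods vs. biological replicates)
# --------------------------------------------------------------------------


@dataclass
class VariabilityReport:
    """Per-landmark decomposition of location variability.

    ``bio_sd`` — sd across replicates of the method-averaged location
    (biological variability); ``method_sd`` — sd across methods of the
    replicate-averaged location (methodological variability).  Sample sds
    (n − 1 denominator).
    """

    landmarks: tuple[str, ...]
    bio_sd: np.ndarray
    method_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "landmark": self.landmarks,
            "bio_sd": self.bio_sd,
            "method_sd": self.method_sd,
        })


def variability_decomposition(
    locations: np.ndarray,
    methods: Sequence[str] | None = None,
    replicates: Sequence[str] | None = None,
    landmarks: Sequence[str] | None = None,
) -> VariabilityReport:
    """Split landmark-location variability into replicate and method parts.

    Parameters
    ----------
    locations
        Array of shape (n_methods, n_replicates, n_landmarks) of estimated
        landmark locations (channels).  Every cell must be present (finite);
        a missing estimate is an error naming the offending cell.
    """
    locations = np.asarray(locations, dtype=float)
    if locations.ndim != 3:
        raise ValueError(
            "locations must have shape (n_methods, n_replicates, "
            "n_landmarks)")
    n_methods, n_replicates, n_landmarks = locations.shape
    methods = list(methods) if methods is not None else [
        f"method{i}" for i in range(n_methods)]
    replicates = list(replicates) if replicates is not None else [
        str(i + 1) for i in range(n_replicates)]
    landmarks = tuple(landmarks) if landmarks is not None else tuple(
        f"P{i + 1}" for i in range(n_landmarks))
    missing = np.argwhere(~np.isfinite(locations))
    if missing.size:
        m, r, p = missing[0]
        raise ValueError(
            f"missing location estimate for method={methods[m]}, "
            f"replicate={replicates[r]}, landmark={landmarks[p]}"
        )
    # Biological: average over methods, sd across replicates.
    bio_sd = np.std(locations.mean(axis=0), axis=0, ddof=1)
    # Methodological: average over replicates, sd across methods.
    method_sd = np.std(locations.mean(axis=1), axis=0, ddof=1)
    return VariabilityReport(
        landmarks=landmarks, bio_sd=bio_sd, method_sd=method_sd)


# --------------------------------------------------------------------------
# Landmarks and the three-method fitting pipeline
# --------------------------------------------------------------------------

#: Landmark = (name, concentration, branch); branch in {"low", "high"}.
Landmark = tuple[str, float, str]


def default_landmarks(concentrations: Sequence[float]) -> list[Landmark]:
    """The four default landmark subpopulations along the dose axis.

    P1 — the low (and only) subpopulation at the lowest concentration;
    P2/P3 — the low/high subpopulations at an intermediate concentration
    where both coexist (the 11th level of the full dose series, otherwise
    the middle level); P4 — the high (and only) subpopulation at the
    highest concentration.
    """
    conc = sorted(concentrations)
    if len(conc) < 3:
        raise ValueError("need at least 3 concentrations for landmarks")
    mid = conc[10] if len(conc) >= 11 else conc[len(conc) // 2]
    return [
        ("P1", conc[0], "low"),
        ("P2", mid, "low"),
        ("P3", mid, "high"),
        ("P4", conc[-1], "high"),
    ]


def landmark_location(structure: BifurcationStructure, g: float,
                      branch: str) -> float:
    """Location (channels) of the requested branch at concentration ``g``.

    With two or more subpopulations the low branch is the lowest-location
    component and the high branch the highest.  A single subpopulation is
    "the only subpopulation" and serves as either branch.  Returns NaN when
    no snapshot exists at ``g`` or it is empty.
    """
    if branch not in ("low", "high"):
        raise ValueError("branch must be 'low' or 'high'")
    snap = structure.snapshots.get(float(g))
    if snap is None or snap.n_subpops == 0:
        return float("nan")
    locations = sorted(snap.locations)
    return locations[0] if branch == "low" else locations[-1]


def landmark_table(
    structures: Mapping[tuple[str, str], BifurcationStructure],
    landmarks: Sequence[Landmark],
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Assemble the (methods × replicates × landmarks) location array.

    ``structures`` maps ``(method, replicate_id)`` to the extracted
    structure.  Returns the array plus the method, replicate and landmark
    labels (sorted, so the layout is deterministic); missing estimates are
    NaN and will be rejected by :func:`variability_decomposition`.
    """
    methods = sorted({k[0] for k in structures})
    replicates = sorted({k[1] for k in structures})
    names = [lm[0] for lm in landmarks]
    out = np.full((len(methods), len(replicates), len(landmarks)), np.nan)
    for (method, replicate), structure in structures.items():
        i = methods.index(method)
        j = replicates.index(replicate)
        for k, (_, g, branch) in enumerate(landmarks):
            out[i, j, k] = landmark_location(structure, g, branch)
    return out, methods, replicates, names


def fit_all_methods(
    dataset: Dataset,
    pregrowth: str,
    seed: int | np.random.SeedSequence | None = None,
    restarts: int = 100,
    k_max: int = 6,
    alpha: float = 1.0,
    n_folds: int = 10,
    window: int = 71,
    theta: float = -2e-4,
    em_concentrations: Sequence[float] | None = None,
) -> dict[tuple[str, str, str], FittedModel]:
    """Fit all three estimators to every replicate of one pregrowth.

    Per replicate: "em" — per-concentration mixtures with the component
    count chosen by cross-validation and the final fit from ``restarts``
    random restarts; "me+em" — mode detection then a single fixed-means EM
    run (falling back to a one-component EM fit when no mode is found);
    "cem" — the conditional mixture over the whole dose series.

    ``em_concentrations`` optionally restricts the per-concentration
    methods to a subset of the dose series (the conditional fit always uses
    all concentrations).

    Returns the ``(method, pregrowth, replicate_id) -> model`` mapping
    consumed by :func:`train_test_nll`.
    """
    from .conditional_mixture import fit_cem
    from .mixture_em import fit_em_restarts
    from .mode_estimation import fit_me_em
    from .model_selection import select_num_components

    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    models: dict[tuple[str, str, str], FittedModel] = {}
    replicates = dataset.replicates(pregrowth)
    if not replicates:
        raise ValueError(f"no replicates with pregrowth {pregrowth!r}")
    rep_seeds = root.spawn(len(replicates))
    for replicate, rep_seed in zip(replicates, rep_seeds):
        all_conc = dataset.concentrations(pregrowth, replicate)
        conc = (list(em_concentrations) if em_concentrations is not None
                else all_conc)
        conc_seeds = rep_seed.spawn(2 * len(conc))
        em_fits: dict[float, MixtureModel] = {}
        me_fits: dict[float, MixtureModel] = {}
        for idx, g in enumerate(conc):
            h = dataset.get(pregrowth, replicate, g)
            decision = select_num_components(
                h, alpha=alpha, k_max=k_max, n_folds=n_folds,
                restarts=restarts, seed=conc_seeds[2 * idx])
            em_fits[g] = fit_em_restarts(
                h, decision.chosen_k, n_restarts=restarts,
                seed=conc_seeds[2 * idx + 1]).model
            try:
                me_fits[g] = fit_me_em(h, window=window, theta=theta).model
            except ValueError:
                me_fits[g] = fit_em_restarts(
                    h, 1, n_restarts=restarts,
                    seed=conc_seeds[2 * idx + 1]).model
        cem = fit_cem([dataset.get(pregrowth, replicate, g)
                       for g in all_conc])
        models[("em", pregrowth, replicate)] = em_fits
        models[("me+em", pregrowth, replicate)] = me_fits
        models[("cem", pregrowth, replicate)] = cem.model
    return models
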