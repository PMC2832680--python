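"""Bifurcation-structure extraction, train/test scoring, variability."""

import dataclasses

import numpy as np
import pytest

from stochbif import (
    ChannelHistogram,
    Dataset,
    GaussianComponent,
    MixtureModel,
    default_truth,
    extract_structure,
    landmark_location,
    train_test_nll,
    variability_decomposition,
    weight_low,
)
from stochbif.bifurcation_summary import default_landmarks


def _two_component_model(w_low=0.49):
    return MixtureModel(components=(
        GaussianComponent(150.0, 40.0, w_low),
        GaussianComponent(700.0, 80.0, 0.98 - w_low),
    ))


class TestExtractStructure:
    def test_single_gaussian_full_fraction(self):
        m = MixtureModel(
            components=(GaussianComponent(300.0, 50.0, 0.98),))
        structure = extract_structure({0.0: m})
        snap = structure[0.0]
        assert snap.n_subpops == 1
        assert snap.fractions == (1.0,)
        assert snap.locations == (300.0,)

    def test_equal_weights_renormalised_to_half(self):
        structure = extract_structure({0.01: _two_component_model()})
        snap = structure[0.01]
        assert snap.fractions == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_fractions_always_sum_to_one(self):
        structure = extract_structure(
            {0.0: _two_component_model(0.9), 0.02: _two_component_model(0.1)})
        for g in structure.concentrations():
            assert sum(structure[g].fractions) == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_cem_low_branch_dropped_below_threshold(self):
        truth = default_truth()
        # Find a dose where the low weight falls below the 0.01 cutoff.
        g_hidden = truth.g0 + 6.0 / truth.r   # w_low ~ 0.98 e^-6 ~ 0.0024
        g_visible = truth.g0 + 0.5 / truth.r
        assert weight_low(g_hidden, truth) < 0.01 < weight_low(
            g_visible, truth)
        structure = extract_structure(
            truth, concentrations=[g_visible, g_hidden])
        assert structure[g_visible].n_subpops == 2
        assert structure[g_hidden].n_subpops == 1
        # The surviving subpopulation is the high branch.
        assert structure[g_hidden].locations[0] == pytest.approx(
            float(truth.mean_high(g_hidden)))


class TestTrainTestNll:
    def _dataset_and_models(self, jitter):
        rng = np.random.default_rng(50)
        ds = Dataset()
        gs = (0.0, 0.0087, 0.08)
        models = {}
        for rep, offset in (("1", 0.0), ("2", jitter)):
            fits = {}
            for g in gs:
                mu = 300.0 + offset + 2000 * g
                events = np.clip(
                    np.rint(rng.normal(mu, 50, 4_000)), 1, 1024).astype(int)
                counts = np.bincount(events, minlength=1025)[1:]
                ds.add(ChannelHistogram(counts=counts, concentration=g,
                                        replicate_id=rep, pregrowth="gal"))
                fits[g] = MixtureModel(components=(
                    GaussianComponent(mu, 50.0, 0.98),))
            models[("em", "gal", rep)] = fits
        return ds, models

    def test_training_score_equals_direct_evaluation(self):
        from stochbif import mixture_loglik
        ds, models = self._dataset_and_models(jitter=30.0)
        table = train_test_nll(models, ds, seed=0, n_resamples=50)
        row = table[(table.replicate == "1") & (table.split == "train")]
        direct = np.mean([
            mixture_loglik(models[("em", "gal", "1")][g],
                           ds.get("gal", "1", g))[1]
            for g in ds.concentrations("gal", "1")
        ])
        assert row.mean_nll.iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_identical_replicates_equal_train_test(self):
        ds, models = self._dataset_and_models(jitter=30.0)
        # Overwrite replicate 2 with replicate 1's exact histograms.
        for g in ds.concentrations("gal", "1"):
            ds.histograms[("gal", "2", g)] = dataclasses.replace(
                ds.get("gal", "1", g), replicate_id="2")
        models[("em", "gal", "2")] = models[("em", "gal", "1")]
        table = train_test_nll(models, ds, seed=0, n_resamples=50)
        for rep in ("1", "2"):
            sub = table[table.replicate == rep]
            tr = sub[sub.split == "train"].mean_nll.iloc[0]
            te = sub[sub.split == "test"].mean_nll.iloc[0]
            assert te == pytest.approx(tr, abs=1e-9)

    def test_jittered_replicates_train_below_test(self):
        ds, models = self._dataset_and_models(jitter=30.0)
        table = train_test_nll(models, ds, seed=0, n_resamples=50)
        tr = table[table.split == "train"].mean_nll.mean()
        te = table[table.split == "test"].mean_nll.mean()
        assert tr < te

    def test_ci_brackets_point_estimate(self):
        ds, models = self._dataset_and_models(jitter=30.0)
        table = train_test_nll(models, ds, seed=1, n_resamples=500)
        assert np.all(table.ci_low <= table.mean_nll + 1e-12)
        assert np.all(table.ci_high >= table.mean_nll - 1e-12)


class TestVariabilityDecomposition:
    def test_all_equal_gives_zero(self):
        locations = np.full((3, 4, 2), 123.0)
        report = variability_decomposition(locations)
        assert np.all(report.bio_sd == 0)
        assert np.all(report.method_sd == 0)

    def test_replicate_only_variation(self):
        # Constant across methods, replicates at {100, 110, 120, 130}.
        reps = np.array([100.0, 110.0, 120.0, 130.0])
        locations = np.broadcast_to(
            reps[None, :, None], (3, 4, 1)).copy()
        report = variability_decomposition(locations)
        assert report.method_sd[0] == pytest.approx(0.0, abs=1e-12)
        assert report.bio_sd[0] == pytest.approx(np.std(reps, ddof=1),
                                                 rel=1e-12)
        assert report.bio_sd[0] == pytest.approx(12.909944, abs=1e-5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(51)
        locations = rng.normal(500, 20, size=(3, 4, 4))
        report = variability_decomposition(locations)
        for lm in range(4):
            rep_means = [locations[:, j, lm].mean() for j in range(4)]
            meth_means = [locations[i, :, lm].mean() for i in range(3)]
            assert report.bio_sd[lm] == pytest.approx(
                np.std(rep_means, ddof=1), abs=1e-12)
            assert report.method_sd[lm] == pytest.approx(
                np.std(meth_means, ddof=1), abs=1e-12)

    def test_missing_cell_named_in_error(self):
        locations = np.full((2, 2, 2), 100.0)
        locations[1, 0, 1] = np.nan
        with pytest.raises(ValueError, match="method1.*replicate=1.*P2"):
            variability_decomposition(locations)


class TestLandmarks:
    def test_default_landmarks_use_extremes_and_middle(self):
        conc = sorted(np.linspace(0, 0.08, 17))
        lms = default_landmarks(conc)
        names = [name for name, _, _ in lms]
        assert names == ["P1", "P2", "P3", "P4"]
        assert lms[0][1] == conc[0] and lms[3][1] == conc[-1]
        assert lms[1][1] == conc[10] == lms[2][1]

    def test_landmark_location_branches(self):
        structure = extract_structure({0.01: _two_component_model()})
        assert landmark_location(structure, 0.01, "low") == 150.0
        assert landmark_location(structure, 0.01, "high") == 700.0
        assert np.isnan(landmark_location(structure, 0.05, "low"))
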