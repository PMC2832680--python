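"""Gaussian-plus-uniform mixture EM: likelihood, fitting, restarts."""

import math

import numpy as np
import pytest

from stochbif import (
    ChannelHistogram,
    GaussianComponent,
    MixtureModel,
    fit_em,
    fit_em_restarts,
    mixture_loglik,
    random_init,
)

from conftest import sample_mixture_histogram


def _hist_from_channels(channels, n_channels=1024, concentration=0.0):
    counts = np.bincount(np.asarray(channels), minlength=n_channels + 1)[1:]
    return ChannelHistogram(counts=counts, concentration=concentration)


class TestMixtureLoglik:
    def test_point_mass_closed_form(self):
        # All events at the component mean: per-event density is
        # 0.02/1024 + 0.98 / (sd * sqrt(2 pi)).
        sd = 37.0
        model = MixtureModel(
            components=(GaussianComponent(mean=400.0, sd=sd, weight=0.98),))
        h = _hist_from_channels([400] * 250)
        loglik, mean_nll = mixture_loglik(model, h)
        expected = math.log(0.02 / 1024 + 0.98 / (sd * math.sqrt(2 * math.pi)))
        assert loglik == pytest.approx(250 * expected, rel=1e-12)
        assert mean_nll == pytest.approx(-expected, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        channels = np.clip(
            np.rint(rng.normal(300, 30, 2000)), 1, 1024).astype(int)
        h1 = _hist_from_channels(channels)
        h2 = _hist_from_channels(channels + 100)
        m1 = MixtureModel(
            components=(GaussianComponent(300.0, 30.0, 0.98),))
        m2 = MixtureModel(
            components=(GaussianComponent(400.0, 30.0, 0.98),))
        assert mixture_loglik(m1, h1)[0] == pytest.approx(
            mixture_loglik(m2, h2)[0], rel=1e-12)

    def test_matches_event_by_event_brute_force(self):
        rng = np.random.default_rng(6)
        channels = rng.integers(1, 1025, size=10)
        h = _hist_from_channels(channels)
        model = MixtureModel(components=(
            GaussianComponent(200.0, 40.0, 0.5),
            GaussianComponent(650.0, 90.0, 0.48),
        ))
        brute = sum(
            math.log(
                0.02 / 1024
                + sum(
                    c.weight / (c.sd * math.sqrt(2 * math.pi))
                    * math.exp(-0.5 * ((ch - c.mean) / c.sd) ** 2)
                    for c in model.components
                )
            )
            for ch in channels
        )
        assert mixture_loglik(model, h)[0] == pytest.approx(brute, abs=1e-10)

    def test_support_mismatch_rejected(self):
        model = MixtureModel(
            components=(GaussianComponent(10.0, 2.0, 0.98),), n_channels=64)
        with pytest.raises(ValueError):
            mixture_loglik(model, _hist_from_channels([5], n_channels=1024))


class TestMixtureModelInvariants:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MixtureModel(components=(GaussianComponent(100.0, 10.0, 0.5),))

    def test_components_sorted_by_mean(self):
        m = MixtureModel(components=(
            GaussianComponent(700.0, 10.0, 0.49),
            GaussianComponent(100.0, 10.0, 0.49),
        ))
        assert list(m.means) == sorted(m.means)


class TestFitEM:
    def test_single_component_recovers_moments(self):
        # Pure Gaussian events (no outlier contamination): the fitted
        # component must match the sample moments once the expected uniform
        # mass is discounted.
        rng = np.random.default_rng(7)
        events = np.clip(
            np.rint(rng.normal(300, 50, 50_000)), 1, 1024).astype(int)
        h = _hist_from_channels(events)
        fit = fit_em(h, 1)
        # Count-weighted sample moments after removing the expected uniform
        # outlier mass from every channel.
        channels = np.arange(1, 1025, dtype=float)
        weights = h.counts - h.total * 0.02 / 1024
        weights = np.clip(weights, 0, None)
        mean = np.average(channels, weights=weights)
        sd = math.sqrt(np.average((channels - mean) ** 2, weights=weights))
        comp = fit.model.components[0]
        assert comp.mean == pytest.approx(mean, abs=2.0)
        assert comp.sd == pytest.approx(sd, abs=2.0)

    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(8)
        h = sample_mixture_histogram(
            rng, [(0.5, 250.0, 40.0), (0.5, 700.0, 80.0)])
        fit = fit_em(h, 2)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-10 * abs(fit.loglik))

    def test_weight_conservation_after_fit(self):
        rng = np.random.default_rng(9)
        h = sample_mixture_histogram(
            rng, [(0.5, 250.0, 40.0), (0.5, 700.0, 80.0)])
        fit = fit_em(h, 2)
        total = fit.model.uniform_weight + fit.model.weights.sum()
        assert total == pytest.approx(1.0, abs=1e-9)
        assert fit.model.weights.sum() == pytest.approx(0.98, abs=1e-9)

    def test_point_mass_component_eliminated(self):
        h = _hist_from_channels([512] * 1000)
        fit = fit_em(h, 1)
        assert fit.eliminated_components == 1
        assert fit.model.n_components == 0
        assert fit.model.uniform_weight == 1.0

    def test_too_many_components_rejected(self):
        h = _hist_from_channels([100, 100, 200])
        with pytest.raises(ValueError, match="occupied"):
            fit_em(h, 3)

    def test_mean_nll_definition(self):
        rng = np.random.default_rng(10)
        h = sample_mixture_histogram(rng, [(1.0, 300.0, 50.0)],
                                     n_events=5_000)
        fit = fit_em(h, 1)
        assert fit.mean_nll == pytest.approx(-fit.loglik / h.total, rel=1e-12)

    def test_fix_means_holds_means(self):
        rng = np.random.default_rng(11)
        h = sample_mixture_histogram(
            rng, [(0.5, 250.0, 40.0), (0.5, 700.0, 80.0)])
        init = MixtureModel(components=(
            GaussianComponent(240.0, 50.0, 0.49),
            GaussianComponent(710.0, 50.0, 0.49),
        ))
        fit = fit_em(h, 2, init=init, fix_means=True)
        assert tuple(fit.model.means) == (240.0, 710.0)


class TestRestarts:
    def test_bimodal_recovery_within_five_channels(self):
        rng = np.random.default_rng(12)
        h = sample_mixture_histogram(
            rng, [(0.49, 250.0, 40.0), (0.49, 700.0, 80.0)],
            n_events=30_000)
        fit = fit_em_restarts(h, 2, n_restarts=20, seed=0)
        assert fit.model.means[0] == pytest.approx(250, abs=5)
        assert fit.model.means[1] == pytest.approx(700, abs=5)

    def test_best_of_restarts_beats_each_restart(self, bimodal_histogram):
        best = fit_em_restarts(bimodal_histogram, 2, n_restarts=8, seed=3)
        root = np.random.SeedSequence(3)
        for child in root.spawn(8):
            rng = np.random.default_rng(child)
            init = random_init(bimodal_histogram, 2, rng)
            single = fit_em(bimodal_histogram, 2, init=init)
            assert best.loglik >= single.loglik - 1e-9

    def test_single_restart_equals_seeded_fit(self, bimodal_histogram):
        res = fit_em_restarts(bimodal_histogram, 2, n_restarts=1, seed=11)
        child = np.random.SeedSequence(11).spawn(1)[0]
        init = random_init(bimodal_histogram, 2,
                           np.random.default_rng(child))
        direct = fit_em(bimodal_histogram, 2, init=init)
        assert res.loglik == direct.loglik
        assert np.array_equal(res.model.means, direct.model.means)

    def test_restarts_escape_bad_initialisation(self, bimodal_histogram):
        bad_init = MixtureModel(components=(
            GaussianComponent(1.0, 50.0, 0.49),
            GaussianComponent(1.5, 50.0, 0.49),
        ))
        bad = fit_em(bimodal_histogram, 2, init=bad_init)
        good = fit_em_restarts(bimodal_histogram, 2, n_restarts=20, seed=0)
        assert good.loglik >= bad.loglik


class TestReferenceOracle:
    """With the uniform component switched off, our EM and an independent
    reference Gaussian-mixture implementation must find the same optimum."""

    def _sample(self):
        rng = np.random.default_rng(42)
        events = np.concatenate([
            rng.normal(250, 40, 2_500), rng.normal(700, 80, 2_500)])
        return np.clip(np.rint(events), 1, 1024).astype(int)

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_sklearn_gmm(self, k):
        sklearn = pytest.importorskip("sklearn.mixture")
        channels = self._sample()
        h = _hist_from_channels(channels)
        ours = fit_em_restarts(h, k, n_restarts=10, seed=0,
                               uniform_weight=0.0, tol=1e-12, max_iter=2000)
        gm = sklearn.GaussianMixture(
            k, n_init=10, tol=1e-10, max_iter=2000, reg_covar=1e-10,
            random_state=0).fit(channels.astype(float).reshape(-1, 1))
        ref_mean_ll = gm.score(channels.astype(float).reshape(-1, 1))
        assert -ours.mean_nll == pytest.approx(ref_mean_ll, abs=1e-4)
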