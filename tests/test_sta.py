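"""Spike-triggered statistics: raw moments, denoising, fantope subspaces."""

import numpy as np
import pytest

from lnlncascade.data import build_design_matrix
from lnlncascade.metrics import subspace_overlap
from lnlncascade.simulate import (
    GroundTruthSpec,
    SubunitSpec,
    generate_white_noise_bars,
    make_ground_truth_model,
    sample_poisson_spikes,
)
from lnlncascade.sta import (
    STCSubspace,
    compute_sta,
    compute_stc,
    regularized_sta,
    regularized_stc,
    significant_stc_eigenvectors,
    suggested_sta_penalties,
)


def _ln_cell(threshold_sd=2.0, gain=0.5, theta=1.0, n_bars=12, n_lags=8):
    spec = GroundTruthSpec(
        subunits=[SubunitSpec(center_um=6 * 55.5, threshold_sd=threshold_sd)],
        gain=gain, theta=theta, n_bars=n_bars, n_lags=n_lags)
    return make_ground_truth_model(spec), spec


def _simulate(model, spec, duration_s, seed):
    stim = generate_white_noise_bars(duration_s=duration_s,
                                     n_bars=spec.n_bars, seed=seed)
    dm = build_design_matrix(stim, spec.n_lags, dtype=np.float32)
    train = sample_poisson_spikes(model, stim, design=dm, seed=seed + 1)
    return dm, dm.align_counts(train.counts)


def _cos(a, b):
    return abs(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestComputeSTA:
    def test_single_spike_returns_that_row(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 10))
        counts = np.zeros(30)
        counts[17] = 1
        stats = compute_sta(X, counts)
        np.testing.assert_allclose(stats.sta, X[17], rtol=1e-6)

    def test_zero_spikes_rejected(self):
        with pytest.raises(ValueError):
            compute_sta(np.ones((5, 3)), np.zeros(5))

    def test_ln_cell_sta_aligns_with_filter(self):
        """Stein consistency: the STA of an LN cell points along its filter."""
        model, spec = _ln_cell()
        dm, y = _simulate(model, spec, 2000.0, seed=21)   # 2e5 bins
        stats = compute_sta(dm.X, y)
        assert _cos(stats.sta, model.filters[0]) >= 0.9

    def test_stimulus_independent_rate_gives_null_sta(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50_000, 24))
        counts = rng.poisson(0.2, 50_000)
        stats = compute_sta(X, counts)
        # expected noise norm is sqrt(N / n_spikes)
        assert np.linalg.norm(stats.sta) < 3.0 * np.sqrt(24 / stats.n_spikes)

    def test_sta_alignment_improves_with_data(self):
        """Mean |cos| to the true filter grows monotonically with n."""
        model, spec = _ln_cell()
        means = []
        for n_bins in (1_000, 10_000, 100_000):
            cosines = []
            for seed in range(10):
                dm, y = _simulate(model, spec, n_bins / 100.0, seed=100 + seed)
                stats = compute_sta(dm.X, y)
                cosines.append(_cos(stats.sta, model.filters[0]))
            means.append(np.mean(cosines))
        assert means[0] < means[1] < means[2]


class TestComputeSTC:
    def test_spike_every_bin_recovers_prior_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100_000, 40))
        stats = compute_stc(X, np.ones(100_000))
        dev = np.linalg.norm(stats.stc - np.eye(40), ord=2)
        assert dev < 0.05

    def test_single_spike_centered_stc_is_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 6))
        counts = np.zeros(20)
        counts[4] = 2
        stats = compute_stc(X, counts)
        np.testing.assert_allclose(stats.stc, np.zeros((6, 6)), atol=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 12))
        counts = rng.poisson(0.5, 500)
        stats = compute_stc(X, counts)
        np.testing.assert_allclose(stats.stc, stats.stc.T, atol=1e-10)

    def test_two_subunit_expansive_eigenvectors_span_filters(self):
        """Eigenvectors above the noise bulk span the pathway filters."""
        spec = GroundTruthSpec(
            subunits=[SubunitSpec(center_um=3 * 55.5, threshold_sd=3.0),
                      SubunitSpec(center_um=9 * 55.5, threshold_sd=3.0)],
            gain=0.5, theta=2.0, n_bars=12, n_lags=8)
        model = make_ground_truth_model(spec)
        dm, y = _simulate(model, spec, 1500.0, seed=31)
        stats = compute_stc(dm.X, y)
        lam, Q = np.linalg.eigh(stats.stc)
        top2 = Q[:, np.argsort(lam)[-2:]]
        assert subspace_overlap(top2, model.filters.T) >= 0.85


class TestRegularizedSTA:
    def test_zero_weights_identity(self):
        rng = np.random.default_rng(5)
        sta = rng.standard_normal(24)
        out = regularized_sta(sta, (6, 4), 0.0, 0.0)
        np.testing.assert_array_equal(out, sta)

    def test_dominant_l1_returns_zero(self):
        rng = np.random.default_rng(6)
        sta = rng.standard_normal(24)
        out = regularized_sta(sta, (6, 4), 1e3, 0.0, tol=1e-8, max_iter=1000)
        np.testing.assert_allclose(out, np.zeros(24), atol=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            regularized_sta(np.ones(6), (2, 3), -0.1, 0.0)

    def test_short_recording_denoising_beats_raw(self):
        """With limited data the denoised STA is closer to the true filter."""
        model, spec = _ln_cell(gain=0.15, theta=2.5)   # sparse-firing regime
        dm, y = _simulate(model, spec, 180.0, seed=41)  # 3 simulated minutes
        stats = compute_sta(dm.X, y)
        g1, gn = suggested_sta_penalties(stats.n_spikes,
                                         (spec.n_bars, spec.n_lags))
        denoised = regularized_sta(stats.sta, (spec.n_bars, spec.n_lags),
                                   g1, gn)
        raw_cos = _cos(stats.sta, model.filters[0])
        reg_cos = _cos(denoised, model.filters[0])
        assert reg_cos > raw_cos

    def test_long_recording_reaches_high_fidelity(self):
        model, spec = _ln_cell(gain=0.15, theta=2.5)
        dm, y = _simulate(model, spec, 2400.0, seed=43)  # 40 simulated minutes
        stats = compute_sta(dm.X, y)
        assert _cos(stats.sta, model.filters[0]) > 0.9


class TestRegularizedSTC:
    def test_unregularized_matches_eigendecomposition(self):
        """gamma=0 fantope maximizer is the top-d projector of the raw STC."""
        rng = np.random.default_rng(7)
        M = rng.standard_normal((30, 12))
        C = M.T @ M / 30
        res = regularized_stc(C, d=2)
        lam, Q = np.linalg.eigh(C)
        raw_top = Q[:, np.argsort(lam)[-2:]]
        assert subspace_overlap(res.eigenvectors, raw_top) >= 0.99

    @pytest.mark.parametrize("gamma_nuc,d", [(0.0, 1), (0.05, 2), (0.2, 3)])
    def test_fantope_feasibility(self, gamma_nuc, d):
        rng = np.random.default_rng(8)
        M = rng.standard_normal((40, 12))
        C = M.T @ M / 40
        res = regularized_stc(C, d=d, gamma_nuc=gamma_nuc, shape=(4, 3))
        lam = np.linalg.eigvalsh(res.X_hat)
        assert lam.min() >= -1e-6 and lam.max() <= 1 + 1e-6
        assert abs(np.trace(res.X_hat) - d) < 1e-6
        # returned eigenvectors are orthonormal
        np.testing.assert_allclose(res.eigenvectors.T @ res.eigenvectors,
                                   np.eye(d), atol=1e-8)

    def test_limited_data_regularization_beats_raw(self):
        """Structured penalties recover the subunit span from short data."""
        spec = GroundTruthSpec(
            subunits=[SubunitSpec(center_um=3 * 55.5, threshold_sd=3.0),
                      SubunitSpec(center_um=9 * 55.5, threshold_sd=3.0)],
            gain=0.15, theta=2.5, n_bars=12, n_lags=8)   # ~1.7 spikes/s
        model = make_ground_truth_model(spec)
        raw_overlaps, reg_overlaps = [], []
        for seed in (50, 51, 52, 53, 54):
            dm, y = _simulate(model, spec, 600.0, seed=seed)  # 10 sim. minutes
            stats = compute_stc(dm.X, y)
            lam, Q = np.linalg.eigh(stats.stc)
            raw_overlaps.append(subspace_overlap(Q[:, np.argsort(lam)[-2:]],
                                                 model.filters.T))
            res = regularized_stc(stats.stc, d=2, gamma_nuc=0.1,
                                  shape=(spec.n_bars, spec.n_lags),
                                  max_iter=200)
            reg_overlaps.append(subspace_overlap(res.eigenvectors,
                                                 model.filters.T))
        assert np.mean(reg_overlaps) > np.mean(raw_overlaps)

    def test_suppressive_option_negates_objective(self):
        # one direction with variance below the bulk
        lam = np.ones(10)
        lam[0] = 0.1
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        C = (Q * lam) @ Q.T
        res = regularized_stc(C, d=1, suppressive=True)
        assert _cos(res.eigenvectors[:, 0], Q[:, 0]) > 0.99

    def test_asymmetric_rejected(self):
        C = np.eye(4)
        C[0, 1] = 0.2
        with pytest.raises(ValueError):
            regularized_stc(C, d=1)


class TestSignificantEigenvectors:
    def test_ln_cell_has_significant_expansive_direction(self):
        model, spec = _ln_cell(threshold_sd=3.0, gain=0.5, theta=2.0)
        dm, y = _simulate(model, spec, 1000.0, seed=60)
        lam, Q, mask = significant_stc_eigenvectors(dm.X, y, n_shifts=30,
                                                    seed=0)
        assert mask.any()
        top = Q[:, np.argmax(np.where(mask, lam, -np.inf))]
        assert _cos(top, model.filters[0]) > 0.8

    def test_stimulus_independent_counts_have_none(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((30_000, 20))
        counts = rng.poisson(0.3, 30_000)
        _, _, mask = significant_stc_eigenvectors(X, counts, n_shifts=30,
                                                  seed=1)
        assert mask.sum() == 0


class TestSTCSubspaceEstimator:
    def test_fit_transform_shapes(self):
        model, spec = _ln_cell()
        dm, y = _simulate(model, spec, 300.0, seed=71)
        est = STCSubspace(d=3, filter_shape=(spec.n_bars, spec.n_lags))
        Z = est.fit(dm.X, y).transform(dm.X[:100])
        assert Z.shape == (100, 3)
        assert est.eigenvalues_.shape == (3,)
        assert est.sta_.size == dm.n_features
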