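"""CSP eigenstructure, STFT band power, and fusion contracts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from medeeg import (EpochArray, FeatureTable, csp_features, fit_csp, fuse,
                    stft_band_power, stft_order_by_variance)
from medeeg.features import SpatialFilterBank, channel_groups


def _epochs(data: np.ndarray, labels) -> EpochArray:
    n = data.shape[0]
    return EpochArray(data=data, labels=np.asarray(labels), fs=128.0,
                      source=[("S", "NONMED", 1)] * n)


def _axis_toy() -> EpochArray:
    """Two-channel epochs whose normalized class covariances are exactly
    diag(0.8, 0.2) (meditation) and diag(0.2, 0.8)."""
    n = 256
    t = np.arange(n)
    s1 = np.sqrt(2.0) * np.cos(2 * np.pi * 4 * t / n)   # unit power, orthogonal
    s2 = np.sqrt(2.0) * np.cos(2 * np.pi * 8 * t / n)
    a = np.stack([np.sqrt(0.8) * s1, np.sqrt(0.2) * s2])
    b = np.stack([np.sqrt(0.2) * s1, np.sqrt(0.8) * s2])
    data = np.stack([a, a, b, b])
    return _epochs(data, [1, 1, 0, 0])


class TestCSPFit:
    def test_analytic_two_channel_eigenvalues_and_axes(self):
        bank = fit_csp(_axis_toy(), n_pairs=1)
        np.testing.assert_allclose(bank.eigvals_A, [0.8, 0.2], atol=1e-10)
        # filters are coordinate axes up to sign/scale
        for row in bank.W:
            ratio = np.min(np.abs(row)) / np.max(np.abs(row))
            assert ratio < 1e-8

    def test_identical_classes_give_half_eigenvalues(self):
        toy = _axis_toy()
        sym = _epochs(toy.data[[0, 1, 0, 1]], [1, 1, 0, 0])
        bank = fit_csp(sym, n_pairs=1)
        np.testing.assert_allclose(bank.eigvals_A, 0.5, atol=1e-10)

    def test_whitening_identity_and_eigenvalue_conservation(self, unit_cohort):
        from medeeg import concatenate_epochs, filter_and_epoch
        pool = concatenate_epochs([filter_and_epoch(r) for r in unit_cohort[:6]])
        bank = fit_csp(pool, n_pairs=2)
        mask = pool.labels == 1
        from medeeg.features import _mean_normalized_cov
        c_c = (_mean_normalized_cov(pool.data[mask])
               + _mean_normalized_cov(pool.data[~mask]))
        np.testing.assert_allclose(bank.W_full @ c_c @ bank.W_full.T,
                                   np.eye(pool.n_channels), atol=1e-8)
        # class-A and class-B eigenvalues are complementary
        s_a = bank.W_full @ _mean_normalized_cov(pool.data[mask]) @ bank.W_full.T
        s_b = bank.W_full @ _mean_normalized_cov(pool.data[~mask]) @ bank.W_full.T
        np.testing.assert_allclose(np.diag(s_a) + np.diag(s_b), 1.0, atol=1e-8)
        np.testing.assert_allclose(np.diag(s_a), bank.eigvals_A, atol=1e-8)

    @pytest.mark.parametrize("n_ch", [3, 4])
    def test_extreme_variance_ratios_match_brute_force(self, n_ch):
        """The top/bottom CSP eigenvalues equal the max/min of the Rayleigh
        ratio w'C_A w / w'(C_A + C_B)w over unit vectors (random search +
        local refinement), within 1%."""
        rng = np.random.default_rng(42)
        data = rng.standard_normal((40, n_ch, 128)) * \
            (0.3 + rng.random((40, n_ch, 1)))
        ep = _epochs(data, [1] * 20 + [0] * 20)
        bank = fit_csp(ep, n_pairs=1)
        from medeeg.features import _mean_normalized_cov
        c_a = _mean_normalized_cov(ep.data[:20])
        c_c = c_a + _mean_normalized_cov(ep.data[20:])

        def ratio(w):
            return (w @ c_a @ w) / (w @ c_c @ w)

        cands = rng.standard_normal((4000, n_ch))
        vals = np.einsum("ij,jk,ik->i", cands, c_a, cands) / \
            np.einsum("ij,jk,ik->i", cands, c_c, cands)
        hi = minimize(lambda w: -ratio(w), cands[np.argmax(vals)],
                      method="Nelder-Mead").fun * -1
        lo = minimize(ratio, cands[np.argmin(vals)], method="Nelder-Mead").fun
        assert abs(bank.eigvals_A[0] - hi) <= 0.01 * hi
        assert abs(bank.eigvals_A[-1] - lo) <= 0.01 * max(lo, 1e-3)

    def test_mne_csp_agrees_on_extreme_eigenvalues(self):
        """Independent route: mne's CSP on per-epoch trace-normalized data
        finds the same extreme class-A variance shares."""
        import warnings

        from mne.decoding import CSP as MneCSP
        rng = np.random.default_rng(1)
        data = rng.standard_normal((60, 4, 128)) * \
            (0.3 + rng.random((60, 4, 1)))
        # pre-normalize epochs so both implementations see the same scale
        data /= np.sqrt(np.einsum("ecs,ecs->e", data, data))[:, None, None]
        labels = np.array([1] * 30 + [0] * 30)
        ep = _epochs(data, labels)
        bank = fit_csp(ep, n_pairs=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mne_csp = MneCSP(n_components=4, norm_trace=False,
                             transform_into="csp_space")
            mne_csp.fit(data, labels)
        from medeeg.features import _mean_normalized_cov
        c_a = _mean_normalized_cov(ep.data[:30])
        c_c = c_a + _mean_normalized_cov(ep.data[30:])
        mne_ratios = []
        for w in mne_csp.filters_:
            mne_ratios.append((w @ c_a @ w) / (w @ c_c @ w))
        assert abs(max(mne_ratios) - bank.eigvals_A[0]) < 0.02
        assert abs(min(mne_ratios) - bank.eigvals_A[-1]) < 0.02

    def test_single_class_rejected(self):
        toy = _axis_toy()
        with pytest.raises(ValueError):
            fit_csp(_epochs(toy.data, [1, 1, 1, 1]), n_pairs=1)


class TestCSPFeatures:
    def test_toy_projected_variances(self):
        bank = SpatialFilterBank(W_full=np.eye(2), eigvals_A=np.array([0.9, 0.1]),
                                 n_pairs=1)
        data = np.stack([np.stack([np.sqrt(3) * np.ones(4) * [1, -1, 1, -1],
                                   np.ones(4) * [1, 1, -1, -1]])])
        ft = csp_features(_epochs(data, [1]), bank)
        np.testing.assert_allclose(ft.X[0], [np.log(0.75), np.log(0.25)],
                                   atol=1e-12)

    def test_equal_variances_give_log_half(self):
        bank = SpatialFilterBank(W_full=np.eye(2), eigvals_A=np.array([0.9, 0.1]),
                                 n_pairs=1)
        data = np.stack([np.stack([np.ones(4) * [1, -1, 1, -1],
                                   np.ones(4) * [1, 1, -1, -1]])])
        ft = csp_features(_epochs(data, [1]), bank)
        np.testing.assert_allclose(ft.X[0], np.log(0.5), atol=1e-12)

    def test_global_scale_invariance(self, unit_cohort):
        from medeeg import filter_and_epoch
        ep = filter_and_epoch(unit_cohort[0])
        bank = SpatialFilterBank(W_full=np.eye(ep.n_channels),
                                 eigvals_A=np.linspace(1, 0, ep.n_channels),
                                 n_pairs=2)
        scaled = EpochArray(data=7.5 * ep.data, labels=ep.labels, fs=ep.fs,
                            source=ep.source)
        np.testing.assert_allclose(csp_features(ep, bank).X,
                                   csp_features(scaled, bank).X, atol=1e-10)

    def test_zero_variance_epoch_identified(self):
        bank = SpatialFilterBank(W_full=np.eye(2), eigvals_A=np.array([1.0, 0.0]),
                                 n_pairs=1)
        data = np.zeros((2, 2, 16))
        data[0] += 1e-3 * np.random.default_rng(0).standard_normal((2, 16))
        with pytest.raises(ValueError, match="1"):
            csp_features(_epochs(data, [1, 0]), bank)


class TestSTFT:
    def test_pure_alpha_tone_dominates(self):
        t = np.arange(256) / 128.0
        data = np.sin(2 * np.pi * 10 * t)[None, None, :]
        ft = stft_band_power(_epochs(data, [1]), n_groups=1)
        theta, alpha = np.exp(ft.X[0])
        assert alpha > theta
        assert alpha / (alpha + theta) >= 0.90

    def test_white_noise_band_ratio_matches_bandwidths(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((600, 1, 256))
        ft = stft_band_power(_epochs(data, [0] * 600), n_groups=1)
        power = np.exp(ft.X)
        ratio = power[:, 0].mean() / power[:, 1].mean()
        assert abs(ratio - 4.0 / 5.0) < 0.05  # theta 4 Hz wide, alpha 5 Hz

    def test_log_power_shift_under_scaling(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((5, 4, 256))
        base = stft_band_power(_epochs(data, [0] * 5)).X
        scaled = stft_band_power(_epochs(3.0 * data, [0] * 5)).X
        np.testing.assert_allclose(scaled - base, np.log(9.0), atol=1e-10)

    def test_zero_epoch_guard(self):
        with pytest.raises(ValueError):
            stft_band_power(_epochs(np.zeros((1, 2, 256)), [0]))

    def test_empty_band_reports_minimum_window(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 2, 256))
        with pytest.raises(ValueError, match="window"):
            stft_band_power(_epochs(data, [0, 0]), bands=((4.2, 4.6),),
                            window_length=1.0, n_groups=2)

    def test_channel_groups_partition(self):
        groups = channel_groups(22, 4)
        assert len(groups) == 4
        np.testing.assert_array_equal(np.concatenate(groups), np.arange(22))


class TestFusion:
    def _table(self, n_rows, n_cols, prefix, seed=0):
        rng = np.random.default_rng(seed)
        return FeatureTable(X=rng.standard_normal((n_rows, n_cols)),
                            labels=np.tile([0, 1], n_rows // 2),
                            feature_names=[f"{prefix}{i}" for i in range(n_cols)])

    def test_six_plus_eight_is_fourteen(self):
        fused = fuse(self._table(10, 6, "csp"), self._table(10, 8, "stft"))
        assert fused.n_features == 14

    def test_empty_stft_is_identity(self):
        csp = self._table(10, 6, "csp")
        empty = FeatureTable(X=np.empty((10, 0)), labels=csp.labels.copy(),
                             feature_names=[])
        fused = fuse(csp, empty)
        np.testing.assert_array_equal(fused.X, csp.X)
        assert fused.feature_names == csp.feature_names

    def test_cap_keeps_all_csp_columns_first(self):
        csp = self._table(10, 10, "csp")
        stft = self._table(10, 10, "stft", seed=1)
        fused = fuse(csp, stft, cap=14)
        assert fused.n_features == 14
        np.testing.assert_array_equal(fused.X[:, :10], csp.X)
        assert fused.feature_names[:10] == csp.feature_names

    def test_truncation_keeps_highest_variance_stft_columns(self):
        csp = self._table(40, 10, "csp")
        rng = np.random.default_rng(2)
        stft_x = rng.standard_normal((40, 6)) * np.array([1, 10, 1, 20, 1, 30])
        stft = FeatureTable(X=stft_x, labels=csp.labels.copy(),
                            feature_names=[f"s{i}" for i in range(6)])
        fused = fuse(csp, stft, cap=14)
        assert fused.n_features == 14
        # room for 4 STFT columns: the three scaled-up ones must survive
        kept = set(fused.feature_names[10:])
        assert {"s5", "s3", "s1"} <= kept and len(kept) == 4

    def test_precomputed_order_is_respected(self):
        csp = self._table(10, 12, "csp")
        stft = self._table(10, 4, "stft", seed=3)
        order = np.array([2, 0, 1, 3])
        fused = fuse(csp, stft, cap=14, stft_order=order)
        assert fused.feature_names[12:] == ["stft0", "stft2"]

    def test_label_mismatch_rejected(self):
        a = self._table(10, 3, "csp")
        b = self._table(10, 3, "stft")
        b.labels = 1 - b.labels
        with pytest.raises(ValueError):
            fuse(a, b)

    def test_variance_order_deterministic(self):
        t = self._table(30, 5, "s", seed=9)
        np.testing.assert_array_equal(stft_order_by_variance(t),
                                      stft_order_by_variance(t))
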