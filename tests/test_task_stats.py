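"""Trial averaging, permutation nulls, corrections and significance calls."""

import numpy as np
import pytest
from scipy import stats

import dynconn as dc
from dynconn.connectivity import WindowIndex
from dynconn.network_ica import ComponentSet, WhiteningRecord, _upper_edges


def make_components(X, n_subjects, n_trials, n_windows):
    """Wrap a (nic, Ns*T*W) matrix as a ComponentSet with canonical index."""
    nic = X.shape[0]
    sids = np.repeat([f"s{i:02d}" for i in range(n_subjects)], n_trials * n_windows)
    trials = np.tile(np.repeat(np.arange(n_trials), n_windows), n_subjects)
    wins = np.tile(np.arange(n_windows), n_subjects * n_trials)
    idx = WindowIndex(
        subject_ids=sids, trials=trials, windows=wins,
        centres=np.arange(n_windows, dtype=float),
    )
    rec = WhiteningRecord(
        transform=np.zeros((nic, 1)), back_projection=np.zeros((1, nic)),
        mean=np.zeros(1), explained_variance_ratio=np.ones(nic) / nic,
    )
    comp = ComponentSet(
        X=X, A=np.zeros((3, nic)), edge_index=_upper_edges(3),
        region_labels=["a", "b", "c"], whitening=rec, seed=0, window_index=idx,
    )
    return comp, idx


class TestTrialAverage:
    def test_constant_stays_constant(self):
        X = np.full((2, 3 * 4 * 5), 7.5)
        comp, idx = make_components(X, 3, 4, 5)
        xbar = dc.trial_average(comp, idx)
        assert np.allclose(xbar.data, 7.5)

    def test_opposite_trials_cancel(self):
        W = 5
        trial = np.arange(1.0, W + 1)
        X = np.concatenate([trial, -trial])[None, :]
        comp, idx = make_components(X, 1, 2, W)
        xbar = dc.trial_average(comp, idx)
        assert np.allclose(xbar.data, 0.0)

    def test_planted_boxcar_depth_recovered(self):
        """Boxcar of depth d + per-trial noise: peak within 3 sd of d."""
        rng = np.random.default_rng(0)
        Ns, T, W, d, sd = 8, 10, 9, 0.5, 0.3
        shape = np.zeros(W)
        shape[3:6] = d
        X = np.tile(shape, Ns * T)[None, :] + sd * rng.standard_normal((1, Ns * T * W))
        comp, idx = make_components(X, Ns, T, W)
        xbar = dc.trial_average(comp, idx)
        assert abs(xbar.data[4, 0] - d) < 3 * sd / np.sqrt(Ns * T)

    def test_missing_windows_rejected(self):
        X = np.zeros((1, 10))
        comp, idx = make_components(X, 1, 2, 5)
        idx.windows = idx.windows.copy()
        idx.windows[3] = 4  # duplicate a window, lose one
        with pytest.raises(ValueError):
            dc.trial_average(comp, idx)


class TestFlipCounts:
    @pytest.mark.parametrize("n,expected", [(15, 6435), (19, 92378), (4, 6)])
    def test_counts(self, n, expected):
        assert dc.count_flip_realisations(n) == expected

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            dc.count_flip_realisations(1)


class TestSignflipNull:
    def test_exhaustive_realisation_count(self):
        rng = np.random.default_rng(1)
        Ns, T, W = 6, 2, 3
        X = rng.standard_normal((2, Ns * T * W))
        comp, idx = make_components(X, Ns, T, W)
        null = dc.signflip_null(comp, idx, mode="exhaustive")
        assert null.n_realisations == dc.count_flip_realisations(Ns) == 20

    def test_identical_subjects_symmetric_about_zero(self):
        """Equal-split flips of identical per-subject averages centre on 0."""
        Ns, T, W = 4, 1, 3
        v = np.array([1.0, 2.0, 3.0])
        X = np.tile(v, Ns * T)[None, :]
        comp, idx = make_components(X, Ns, T, W)
        null = dc.signflip_null(comp, idx, mode="exhaustive")
        # every realisation flips exactly half: (2 - 2) v / 4 = 0
        assert np.allclose(null.samples, 0.0)
        assert np.allclose(null.samples.mean(axis=0), 0.0)

    def test_null_matches_sham_dataset_spread(self):
        """No task-locked signal: flip-null spread is indistinguishable from
        the spread of the genuine trial average across fresh null datasets
        (two-sample KS, p > 0.01)."""
        Ns, T, W = 8, 6, 4
        rng = np.random.default_rng(2)
        X = rng.standard_normal((1, Ns * T * W))
        comp, idx = make_components(X, Ns, T, W)
        null = dc.signflip_null(comp, idx, mode="exhaustive")
        flips = null.samples[:, 2, 0]
        xbars = []
        for _ in range(500):
            Xf = rng.standard_normal((1, Ns * T * W))
            compf, idxf = make_components(Xf, Ns, T, W)
            xbars.append(dc.trial_average(compf, idxf).data[2, 0])
        assert stats.ks_2samp(flips, np.array(xbars)).pvalue > 0.01

    def test_sampled_mode_seeded(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1, 6 * 2 * 3))
        comp, idx = make_components(X, 6, 2, 3)
        n1 = dc.signflip_null(comp, idx, mode="sampled", n_realisations=50, seed=7)
        n2 = dc.signflip_null(comp, idx, mode="sampled", n_realisations=50, seed=7)
        assert np.array_equal(n1.samples, n2.samples)

    def test_exhaustive_cap_advises_sampling(self):
        rng = np.random.default_rng(4)
        Ns = 8
        X = rng.standard_normal((1, Ns * 1 * 2))
        comp, idx = make_components(X, Ns, 1, 2)
        with pytest.raises(ValueError, match="sampled"):
            dc.signflip_null(comp, idx, mode="exhaustive", cap=10)


class TestShamOnsetNull:
    def test_realisation_count(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((1, 4 * 6 * 3))
        comp, idx = make_components(X, 4, 6, 3)
        null = dc.shamonset_null(comp, idx, n_realisations=600, seed=0)
        assert null.n_realisations == 600

    def test_constant_signal_zero_spread(self):
        X = np.full((2, 3 * 4 * 5), 4.2)
        comp, idx = make_components(X, 3, 4, 5)
        null = dc.shamonset_null(comp, idx, n_realisations=100, seed=0)
        assert np.allclose(null.samples, 4.2)
        assert null.samples.std() < 1e-12

    def test_boxcar_inflates_null_beyond_sampling_noise(self):
        """Sham epochs hit the boxcar at random phases, so the null spread at
        the peak exceeds the locked average's sampling noise."""
        rng = np.random.default_rng(6)
        Ns, T, W, d, sd = 6, 8, 9, 0.6, 0.05
        shape = np.zeros(W)
        shape[3:6] = d
        X = np.tile(shape, Ns * T)[None, :] + sd * rng.standard_normal((1, Ns * T * W))
        comp, idx = make_components(X, Ns, T, W)
        null = dc.shamonset_null(comp, idx, n_realisations=500, seed=1)
        locked_sampling_sd = sd / np.sqrt(Ns * T)
        assert null.samples[:, 4, 0].std() > locked_sampling_sd


class TestAnalyticCorrections:
    @pytest.mark.parametrize(
        "n_windows,shift,width,expected",
        [(49, 0.5, 6, 8), (75, 0.5, 6, 12), (1, 6, 6, 2)],
    )
    def test_temporal_dof(self, n_windows, shift, width, expected):
        assert dc.temporal_dof(n_windows, shift, width) == expected

    @pytest.mark.parametrize(
        "alpha,nc,ndof,expected,digits",
        [(0.05, 10, 8, 0.0003, 1), (0.05, 10, 12, 0.0002, 1), (0.05, 1, 1, 0.025, 3)],
    )
    def test_corrected_threshold(self, alpha, nc, ndof, expected, digits):
        got = dc.corrected_threshold(alpha, nc, ndof)
        # compare at the printed precision (1 significant figure)
        from math import floor, log10

        scale = 10 ** (floor(log10(abs(got))) - digits + 1)
        assert round(got / scale) * scale == pytest.approx(expected)

    def test_corrected_threshold_monotone(self):
        base = dc.corrected_threshold(0.05, 10, 8)
        assert dc.corrected_threshold(0.05, 11, 8) < base
        assert dc.corrected_threshold(0.05, 10, 9) < base

    @pytest.mark.parametrize(
        "Bw,delta,expected,decimals",
        [(17, 6, 0.1, 1), (26, 6, 0.08, 2)],
    )
    def test_sigma_r_paper_values(self, Bw, delta, expected, decimals):
        est = dc.sigma_r(Bw, delta)
        assert round(est.sigma_r, decimals) == expected
        assert est.dof == Bw * delta

    def test_sigma_r_inverse_sqrt_scaling(self):
        assert dc.sigma_r(17, 24).sigma_r == pytest.approx(
            dc.sigma_r(17, 6).sigma_r / 2
        )


class TestTestComponents:
    def _null_from(self, samples, kind="sham_onset"):
        return dc.NullDistribution(samples=samples, kind=kind)

    def test_inside_envelopes_not_significant(self):
        rng = np.random.default_rng(7)
        W, nic = 5, 3
        xbar = dc.TrialAverage(data=np.zeros((W, nic)), time_axis=np.arange(W, dtype=float))
        nulls = [
            self._null_from(rng.standard_normal((400, W, nic)), "sign_flip"),
            self._null_from(rng.standard_normal((400, W, nic)), "sham_onset"),
        ]
        report = dc.test_components(xbar, nulls, alpha_corrected=0.05)
        assert not report.significant.any()

    def test_requires_escape_from_both_nulls(self):
        rng = np.random.default_rng(8)
        W, nic = 4, 2
        data = np.zeros((W, nic))
        data[2, 0] = 10.0  # escapes the narrow null only
        xbar = dc.TrialAverage(data=data, time_axis=np.arange(W, dtype=float))
        narrow = self._null_from(0.1 * rng.standard_normal((400, W, nic)), "sign_flip")
        wide = self._null_from(100 * rng.standard_normal((400, W, nic)), "sham_onset")
        report = dc.test_components(xbar, [narrow, wide], alpha_corrected=0.05)
        assert not report.significant.any()
        report2 = dc.test_components(xbar, [narrow], alpha_corrected=0.05)
        assert report2.significant[0] and not report2.significant[1]
        assert report2.significant_timepoints[0].tolist() == [2.0]

    def test_opposite_sign_subjects_cancel(self):
        """Modulation with opposite sign in half the subjects never reaches
        significance: the trial average cancels while the flip null widens."""
        rng = np.random.default_rng(9)
        Ns, T, W = 8, 6, 7
        shape = np.zeros(W)
        shape[2:5] = 1.0
        X = np.empty((1, Ns * T * W))
        block = T * W
        for s in range(Ns):
            sign = 1.0 if s < Ns // 2 else -1.0
            X[0, s * block : (s + 1) * block] = (
                np.tile(sign * shape, T) + 0.05 * rng.standard_normal(block)
            )
        comp, idx = make_components(X, Ns, T, W)
        xbar = dc.trial_average(comp, idx)
        nulls = [
            dc.signflip_null(comp, idx, mode="exhaustive"),
            dc.shamonset_null(comp, idx, n_realisations=400, seed=0),
        ]
        report = dc.test_components(xbar, nulls, alpha_corrected=0.01)
        assert not report.significant.any()

    def test_extreme_bound_warning_logged(self, caplog):
        rng = np.random.default_rng(10)
        xbar = dc.TrialAverage(data=np.zeros((3, 1)), time_axis=np.arange(3.0))
        null = self._null_from(rng.standard_normal((50, 3, 1)))
        import logging

        with caplog.at_level(logging.WARNING, logger="dynconn.task_stats"):
            dc.test_components(xbar, [null], alpha_corrected=0.001)
        assert any("extreme" in r.message for r in caplog.records)

    def test_type_one_error_controlled_on_null_components(self):
        """Constructed null datasets: <= 5% of component-tests flagged."""
        flagged = total = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            Ns, T, W, nic = 10, 8, 6, 4
            X = rng.standard_normal((nic, Ns * T * W))
            comp, idx = make_components(X, Ns, T, W)
            xbar = dc.trial_average(comp, idx)
            alpha_c = dc.corrected_threshold(0.05, nic, dc.temporal_dof(W, 2, 6))
            nulls = [
                dc.signflip_null(comp, idx, mode="exhaustive"),
                dc.shamonset_null(comp, idx, n_realisations=1000, seed=rep),
            ]
            report = dc.test_components(xbar, nulls, alpha_c)
            flagged += int(report.significant.sum())
            total += nic
        assert flagged / total <= 0.05
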