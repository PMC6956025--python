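import numpy as np
import pytest

import eogclean as ec
from eogclean import (Montage, Recording, frontal_correlations,
                      identify_eog_components, mean_abs_frontal_weights, tukey_flag)
from eogclean.ica import ICADecomposition


def brute_force_fence(values):
    """Oracle: Tukey fence with linearly interpolated order statistics."""
    v = np.sort(np.asarray(values, float))
    n = v.size

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    thr = q3 + 1.5 * (q3 - q1)
    return thr, {i for i, x in enumerate(values) if x > thr}


class TestTukeyFlag:
    @pytest.mark.parametrize("values", [
        [1.0, 2.0, 3.0, 4.0, 100.0],
        [0.1] * 7 + [1.0],
        [5.0, 5.0, 5.0, 5.0, 5.0],
        [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8],
    ])
    def test_matches_brute_force_oracle(self, values):
        thr, flagged = tukey_flag(np.array(values))
        thr_o, flagged_o = brute_force_fence(values)
        assert thr == pytest.approx(thr_o)
        assert flagged == flagged_o

    def test_known_threshold(self):
        thr, flagged = tukey_flag(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert thr == pytest.approx(7.0)  # Q3=4, Q1=2 under the linear rule
        assert flagged == {4}

    def test_equal_values_flag_nothing(self):
        thr, flagged = tukey_flag(np.full(6, 2.5))
        assert thr == pytest.approx(2.5)
        assert flagged == set()  # strict inequality

    def test_too_few_components(self):
        with pytest.raises(ValueError, match="manual"):
            tukey_flag(np.array([1.0, 2.0, 3.0]))


class TestFrontalWeights:
    def test_absolute_then_mean(self):
        A = np.array([[1.0, 0.0], [-3.0, 0.0], [9.9, 0.0]])
        np.testing.assert_allclose(mean_abs_frontal_weights(A, [0, 1]), [2.0, 0.0])

    def test_single_channel(self):
        A = np.array([[-4.0], [1.0]])
        np.testing.assert_allclose(mean_abs_frontal_weights(A, [0]), [4.0])

    def test_empty_indices(self):
        with pytest.raises(ValueError):
            mean_abs_frontal_weights(np.eye(2), [])


def _fake_decomp(A, S, fs=200.0, labels=None):
    W = np.linalg.pinv(A)
    return ICADecomposition(A=A, W=W, S=S, mean=np.zeros(A.shape[0]),
                            whitener=W, converged=True, n_iter=1, seed=0,
                            fs=fs, labels=labels or [])


class TestFrontalCorrelations:
    def test_identical_series_gives_one(self, rng):
        S = rng.standard_normal((2, 500))
        data = np.vstack([S[0], rng.standard_normal(500), rng.standard_normal(500)])
        rec = Recording(data=data, fs=100.0, labels=["Fp1", "Fp2", "O1"])
        d = _fake_decomp(rng.standard_normal((3, 2)), S)
        R = frontal_correlations(d, rec, Montage(frontal=["Fp1", "Fp2"]))
        assert R[0, 0] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        S = rng.standard_normal((2, 500))
        data = rng.standard_normal((2, 500))
        rec1 = Recording(data=data, fs=100.0, labels=["Fp1", "Fp2"])
        rec2 = Recording(data=7.0 * data, fs=100.0, labels=["Fp1", "Fp2"])
        mon = Montage(frontal=["Fp1", "Fp2"])
        d1 = _fake_decomp(np.eye(2), S)
        d2 = _fake_decomp(np.eye(2), 3.0 * S)
        np.testing.assert_allclose(frontal_correlations(d1, rec1, mon),
                                   frontal_correlations(d2, rec2, mon), atol=1e-12)

    def test_orthogonal_sinusoids(self):
        t = np.arange(1000) / 100.0  # integer number of 1 Hz periods
        S = np.vstack([np.cos(2 * np.pi * t), np.sin(3 * 2 * np.pi * t)])
        data = np.vstack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        rec = Recording(data=data, fs=100.0, labels=["Fp1", "Fp2"])
        d = _fake_decomp(np.eye(2), S)
        R = frontal_correlations(d, rec, Montage(frontal=["Fp1", "Fp2"]))
        assert abs(R[0, 0]) < 1e-6  # sin vs cos

    def test_zero_variance_warns_and_reports_zero(self, rng):
        S = np.vstack([np.zeros(500), rng.standard_normal(500)])
        rec = Recording(data=rng.standard_normal((2, 500)), fs=100.0,
                        labels=["Fp1", "Fp2"])
        d = _fake_decomp(np.eye(2), S)
        with pytest.warns(UserWarning, match="zero-variance"):
            R = frontal_correlations(d, rec, Montage(frontal=["Fp1", "Fp2"]))
        assert (R[:, 0] == 0).all()


class TestIdentifyProperties:
    def _random_report(self, rng, perm=None, scale=1.0):
        n_ch, n_comp, n = 6, 5, 2000
        A = rng.standard_normal((n_ch, n_comp))
        A[:2, 0] *= 6.0  # one frontally dominant component
        S = rng.standard_normal((n_comp, n))
        if perm is not None:
            A = A[:, perm]
            S = S[perm]
        data = scale * (A @ S)
        A = A * scale
        labels = ["Fp1", "Fp2", "C3", "C4", "O1", "O2"]
        rec = Recording(data=data, fs=100.0, labels=labels)
        d = _fake_decomp(A, S, labels=labels)
        return identify_eog_components(d, rec, Montage(frontal=["Fp1", "Fp2"]))

    def test_component_permutation_permutes_flags(self):
        rng = np.random.default_rng(7)
        base = self._random_report(rng)
        rng = np.random.default_rng(7)
        perm = [4, 3, 2, 1, 0]
        permuted = self._random_report(rng, perm=perm)
        expected = tuple(sorted(perm.index(j) for j in base.flagged))
        assert permuted.flagged == expected

    def test_global_rescaling_preserves_flags(self):
        rng = np.random.default_rng(9)
        base = self._random_report(rng)
        rng = np.random.default_rng(9)
        scaled = self._random_report(rng, scale=250.0)
        assert scaled.flagged == base.flagged


class TestIdentifyEndToEnd:
    def test_blink_component_is_flagged_exactly(self, blink_dataset, montage):
        """With one blink source injected, exactly its carrier is flagged."""
        from scipy import signal as sps

        ds = blink_dataset
        rec_p = ec.preprocess(ds.contaminated)
        d = ec.fit_infomax(rec_p, seed=ds.seed, tol=1e-6)
        rep = identify_eog_components(d, rec_p, montage)
        sos = sps.butter(4, [1, 47], btype="bandpass", fs=rec_p.fs, output="sos")
        vf = sps.sosfiltfilt(sos, ds.veog)
        corr = [abs(np.corrcoef(vf, s)[0, 1]) for s in d.S]
        carrier = int(np.argmax(corr))
        assert corr[carrier] > 0.9
        assert rep.flagged == (carrier,)

    def test_both_ocular_sources_flagged(self, montage):
        """Strong blink and gaze-shift activity yield two flagged components."""
        from scipy import signal as sps

        seed = 1
        pure = ec.gen_pure_eeg(seed=seed)
        veog, heog, _ = ec.gen_eog_sources(duration_s=120.0,
                                           saccade_rate_per_min=10.0,
                                           saccade_amp_uV=(250.0, 450.0),
                                           seed=seed)
        contam = ec.contaminate(pure, veog, heog, ec.veog_propagation(19),
                                ec.heog_propagation(19))
        rec_p = ec.preprocess(contam)
        d = ec.fit_infomax(rec_p, seed=seed, tol=1e-6)
        rep = identify_eog_components(d, rec_p, montage)
        sos = sps.butter(4, [1, 47], btype="bandpass", fs=rec_p.fs, output="sos")
        vj = int(np.argmax([abs(np.corrcoef(sps.sosfiltfilt(sos, veog), s)[0, 1])
                            for s in d.S]))
        hj = int(np.argmax([abs(np.corrcoef(sps.sosfiltfilt(sos, heog), s)[0, 1])
                            for s in d.S]))
        assert vj != hj
        assert vj in rep.flagged
        assert hj in rep.flagged
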