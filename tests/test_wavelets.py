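import numpy as np
import pytest

from eogclean import (clean_component_selective, dwt_multilevel,
                      highpass_reconstruct, idwt_multilevel, reject_clean,
                      wica_clean_component)
from eogclean.peaks import ArtifactWindows


class TestTransformCore:
    @pytest.mark.parametrize("length", [200, 137, 224, 40])
    def test_perfect_reconstruction(self, length, rng):
        x = rng.standard_normal(length)
        d = dwt_multilevel(x)
        np.testing.assert_allclose(idwt_multilevel(d), x, atol=1e-8)

    @pytest.mark.parametrize("length", [200, 137, 224])
    def test_energy_conservation(self, length, rng):
        x = rng.standard_normal(length)
        d = dwt_multilevel(x)
        assert d.energy() == pytest.approx(np.sum(x ** 2), rel=1e-6)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        dx, dy = dwt_multilevel(x), dwt_multilevel(y)
        dxy = dwt_multilevel(x + y)
        for cx, cy, cxy in zip(dx.details + [dx.approx], dy.details + [dy.approx],
                               dxy.details + [dxy.approx]):
            np.testing.assert_allclose(cxy, cx + cy, atol=1e-8)

    def test_too_short_segment(self):
        with pytest.raises(ValueError, match="32"):
            dwt_multilevel(np.ones(20), levels=5)

    def test_coefficient_labels(self, rng):
        d = dwt_multilevel(rng.standard_normal(200))
        assert d.labels() == ["D1", "D2", "D3", "D4", "D5", "A5"]
        assert d.coeff("D1") is d.details[0]
        assert d.coeff("A") is d.approx
        with pytest.raises(KeyError):
            d.coeff("D9")


class TestHighpass:
    def test_zero_in_zero_out(self):
        d = dwt_multilevel(np.zeros(200))
        assert np.abs(highpass_reconstruct(d)).max() == 0.0

    def test_low_frequency_probe_removed(self):
        t = np.arange(200) / 200.0
        x = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz falls in the discarded bands
        out = highpass_reconstruct(dwt_multilevel(x))
        assert np.sqrt(np.mean(out ** 2)) < 0.15 * np.sqrt(np.mean(x ** 2))

    def test_high_frequency_probe_kept(self):
        t = np.arange(200) / 200.0
        x = np.sin(2 * np.pi * 30.0 * t)  # 30 Hz lies in the retained D2 band
        out = highpass_reconstruct(dwt_multilevel(x))
        assert np.sqrt(np.mean(out ** 2)) > 0.85 * np.sqrt(np.mean(x ** 2))

    def test_keep_everything_is_identity(self, rng):
        x = rng.standard_normal(200)
        d = dwt_multilevel(x)
        out = highpass_reconstruct(d, keep=("D1", "D2", "D3", "D4", "D5", "A5"))
        np.testing.assert_allclose(out, x, atol=1e-8)

    def test_empty_keep_rejected(self, rng):
        d = dwt_multilevel(rng.standard_normal(200))
        with pytest.raises(ValueError):
            highpass_reconstruct(d, keep=())


class TestSelectiveClean:
    def test_empty_windows_identity(self, rng):
        y = rng.standard_normal(2000)
        w = ArtifactWindows(intervals=(), n_samples=2000)
        out = clean_component_selective(y, w, fs=200.0)
        assert (out == y).all()

    def test_untouched_outside_windows(self, rng):
        y = rng.standard_normal(2000)
        w = ArtifactWindows(intervals=((600, 800),), n_samples=2000)
        out = clean_component_selective(y, w, fs=200.0)
        assert (out[:600] == y[:600]).all()
        assert (out[800:] == y[800:]).all()
        assert not (out[600:800] == y[600:800]).all()

    def test_full_window_matches_highpass_interior(self, rng):
        y = rng.standard_normal(600)
        w = ArtifactWindows(intervals=((0, 600),), n_samples=600)
        out = clean_component_selective(y, w, fs=200.0)
        direct = highpass_reconstruct(dwt_multilevel(y))
        # compare away from boundaries and crossfades
        np.testing.assert_allclose(out[100:500], direct[100:500], atol=0.2)

    def test_no_amplification_outside_windows(self, rng):
        y = rng.standard_normal(4000)
        w = ArtifactWindows(intervals=((1000, 1200), (2500, 2700)), n_samples=4000)
        out = clean_component_selective(y, w, fs=200.0)
        outside = ~w.mask()
        assert np.abs(out[outside]).max() <= np.abs(y[outside]).max()

    def test_length_mismatch(self, rng):
        w = ArtifactWindows(intervals=((0, 10),), n_samples=100)
        with pytest.raises(ValueError):
            clean_component_selective(rng.standard_normal(50), w, fs=200.0)


class TestWica:
    def test_sub_threshold_series_unchanged(self, rng):
        y = rng.standard_normal(1000)
        # verify the premise: with a 3x threshold scale no coefficient crosses
        d = dwt_multilevel(y)
        sigma = np.median(np.abs(d.details[0])) / 0.6745
        thr = 3.0 * np.sqrt(2 * np.log(y.size)) * sigma
        top = max(np.abs(np.concatenate(d.details + [d.approx])).max(), 0.0)
        assert top < thr
        out = wica_clean_component(y, threshold_scale=3.0)
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_large_spike_suppressed(self, rng):
        y = rng.normal(0.0, 10.0, 2000)
        y[1000] += 500.0
        out = wica_clean_component(y)
        assert abs(out[1000]) < 0.2 * 500.0

    def test_zero_series(self):
        out = wica_clean_component(np.zeros(500))
        assert np.abs(out).max() == 0.0


class TestRejectClean:
    def test_identities(self, rng):
        from eogclean import Recording, fit_infomax, gen_ica_toy

        _, _, X = gen_ica_toy(3, 6000, seed=9)
        rec = Recording(data=X, fs=100.0, labels=["a", "b", "c"])
        d = fit_infomax(rec, seed=9)
        np.testing.assert_allclose(reject_clean(d, set()).data, X, atol=1e-6)
        only_mean = reject_clean(d, {0, 1, 2}).data
        np.testing.assert_allclose(only_mean, np.tile(d.mean[:, None], (1, 6000)),
                                   atol=1e-9)
        one = reject_clean(d, {2}).data
        np.testing.assert_allclose(one, X - np.outer(d.A[:, 2], d.S[2]), atol=1e-6)
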