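import numpy as np
import pytest

from eogclean import (Recording, center_whiten, fit_infomax, gen_ica_toy,
                      reconstruct, sources)


def amari_error(P):
    """Distance of |P| from a scaled permutation matrix (0 = perfect)."""
    P = np.abs(P)
    m = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return (rows.sum() + cols.sum()) / (2 * m * (m - 1))


class TestCenterWhiten:
    def test_output_is_white(self, rng):
        x = rng.standard_normal((4, 4)) @ rng.standard_normal((4, 5000))
        z, K, mu = center_whiten(x)
        cov = z @ z.T / (z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(z.shape[0]), atol=1e-8)
        assert np.abs(z.mean(axis=1)).max() < 1e-10

    def test_whitener_orthogonal_for_white_input(self, rng):
        # whiten once to obtain an exactly-white sample, then whiten again
        z0, _, _ = center_whiten(rng.standard_normal((5, 8000)))
        _, K, _ = center_whiten(z0)
        np.testing.assert_allclose(K @ K.T, np.eye(K.shape[0]), atol=1e-6)

    def test_constant_channel_rejected(self, rng):
        x = rng.standard_normal((3, 1000))
        x[1] = 2.5
        with pytest.raises(ValueError, match="zero variance"):
            center_whiten(x)

    def test_duplicated_channel_rejected(self, rng):
        x = rng.standard_normal((3, 1000))
        x = np.vstack([x, x[0]])
        with pytest.raises(ValueError, match="rank"):
            center_whiten(x)

    def test_average_referenced_deficiency_allowed(self, rng):
        x = rng.standard_normal((4, 2000))
        x -= x.mean(axis=0)
        z, K, mu = center_whiten(x)
        assert z.shape[0] == 3  # one dimension dropped


class TestInfomax:
    @pytest.fixture(scope="class")
    def toy_fit(self):
        S, A, X = gen_ica_toy(3, 20000, seed=0)
        return S, A, X, fit_infomax(X, seed=0)

    def test_source_recovery(self, toy_fit):
        """Each Laplacian source matches a recovered component at |r| > 0.95."""
        S, A, X, d = toy_fit
        C = np.abs(np.corrcoef(np.vstack([S, d.S]))[:3, 3:])
        taken = set()
        for i in range(3):
            j = int(np.argmax(C[i]))
            assert C[i, j] > 0.95
            assert j not in taken
            taken.add(j)

    def test_mixing_unmixing_inverse(self, toy_fit):
        _, _, X, d = toy_fit
        np.testing.assert_allclose(d.A @ d.W, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(d.W @ d.A, np.eye(3), atol=1e-8)

    def test_amari_separation(self, toy_fit):
        S, A, X, d = toy_fit
        assert amari_error(d.W @ A) < 0.1

    def test_reconstruction_identity(self, toy_fit):
        _, _, X, d = toy_fit
        np.testing.assert_allclose(d.A @ d.S + d.mean[:, None], X, atol=1e-6)

    def test_unit_variance_and_sign_convention(self, toy_fit):
        _, _, _, d = toy_fit
        np.testing.assert_allclose(d.S.std(axis=1), 1.0, atol=1e-10)
        for j in range(d.n_components):
            assert d.A[np.argmax(np.abs(d.A[:, j])), j] > 0

    def test_deterministic_given_seed(self):
        _, _, X = gen_ica_toy(3, 6000, seed=2)
        d1 = fit_infomax(X, seed=11)
        d2 = fit_infomax(X, seed=11)
        np.testing.assert_allclose(d1.S, d2.S, atol=1e-12)
        np.testing.assert_allclose(d1.A, d2.A, atol=1e-12)

    def test_cross_check_against_fastica(self):
        """Independent implementation recovers the same sources."""
        from sklearn.decomposition import FastICA

        S, A, X = gen_ica_toy(3, 20000, seed=5)
        ours = fit_infomax(X, seed=5).S
        theirs = FastICA(n_components=3, random_state=0,
                         whiten="unit-variance").fit_transform(X.T).T
        C = np.abs(np.corrcoef(np.vstack([ours, theirs]))[:3, 3:])
        assert (C.max(axis=1) > 0.95).all()


class TestSourcesReconstruct:
    @pytest.fixture(scope="class")
    def fitted(self):
        _, _, X = gen_ica_toy(3, 8000, seed=1)
        rec = Recording(data=X, fs=100.0, labels=["a", "b", "c"])
        return rec, fit_infomax(rec, seed=1)

    def test_sources_of_training_data(self, fitted):
        rec, d = fitted
        np.testing.assert_allclose(sources(d, rec), d.S, atol=1e-10)

    def test_sources_of_mean_are_zero(self, fitted):
        rec, d = fitted
        flat = np.tile(d.mean[:, None], (1, 50))
        assert np.abs(d.W @ (flat - d.mean[:, None])).max() < 1e-12

    def test_channel_mismatch(self, fitted, rng):
        _, d = fitted
        with pytest.raises(ValueError, match="channels"):
            sources(d, rng.standard_normal((5, 100)))

    def test_reject_single_component_is_linear(self, fitted):
        rec, d = fitted
        out = reconstruct(d, d.S, reject={1})
        expected = rec.data - np.outer(d.A[:, 1], d.S[1])
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_reject_out_of_range(self, fitted):
        _, d = fitted
        with pytest.raises(IndexError):
            reconstruct(d, d.S, reject={7})

    def test_modification_is_local(self, fitted):
        rec, d = fitted
        S_mod = d.S.copy()
        S_mod[0, 100:200] += 5.0
        out = reconstruct(d, S_mod)
        diff = np.abs(out.data - rec.data).max(axis=0)
        assert diff[100:200].min() > 0
        assert diff[:100].max() < 1e-9
        assert diff[200:].max() < 1e-9
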