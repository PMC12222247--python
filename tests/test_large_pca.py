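"""Streaming series-wide PCA vs direct in-memory oracles."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from grainfluor.assembly import MultispectralImage
from grainfluor.large_pca import (
    AccumulatedStats,
    accumulate_statistics,
    dominant_component,
    finalize_pca,
    iter_score_arrays,
    project_all_scores,
    project_scores,
    score_bounds,
    score_to_8bit,
)
from grainfluor.synthetic import default_endmembers

C = 11


def _image_from_pixels(X):
    """Wrap an (n, 11) pixel table as a 1 x n image with full mask."""
    X = np.asarray(X, float)
    img = MultispectralImage(X[None, :, :])
    mask = np.ones((1, X.shape[0]), bool)
    return img, mask


def _random_series(rng, n_images=4, n_pixels=300):
    series = []
    for _ in range(n_images):
        X = rng.gamma(2.0, 50.0, size=(n_pixels, C))
        series.append(_image_from_pixels(X))
    return series


def _direct_pca(series):
    """Independent oracle: dense PCA of the concatenated pixel table."""
    X = np.vstack([img.data[mask] for img, mask in series])
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    return X, eigval[order], eigvec[:, order]


class TestAccumulate:
    def test_statistics_are_additive(self, rng):
        series = _random_series(rng, n_images=2, n_pixels=100)
        parts = [AccumulatedStats.from_image(img, m) for img, m in series]
        total = accumulate_statistics(series)
        assert total.n_pixels == 200
        assert np.allclose(total.crossprod,
                           parts[0].crossprod + parts[1].crossprod)
        assert np.allclose(total.sum_vector,
                           parts[0].sum_vector + parts[1].sum_vector)

    def test_order_invariance(self, rng):
        series = _random_series(rng, n_images=5)
        a = accumulate_statistics(series)
        b = accumulate_statistics(series[::-1])
        assert np.allclose(a.crossprod, b.crossprod, rtol=1e-10)
        assert np.allclose(a.sum_vector, b.sum_vector, rtol=1e-10)

    def test_single_image_crossprod_matches_dense(self, rng):
        X = rng.uniform(0, 1000, (500, C))
        img, mask = _image_from_pixels(X)
        stats = AccumulatedStats.from_image(img, mask)
        assert np.allclose(stats.crossprod, X.T @ X, rtol=1e-12)

    def test_merge_associativity(self, rng):
        series = _random_series(rng, n_images=3)
        parts = [AccumulatedStats.from_image(img, m) for img, m in series]
        left = (parts[0] + parts[1]) + parts[2]
        right = parts[0] + (parts[1] + parts[2])
        assert np.allclose(left.crossprod, right.crossprod, rtol=1e-10)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            accumulate_statistics([])


class TestFinalize:
    def test_rank_one_data_explained_by_first_component(self, rng):
        direction = rng.uniform(0.1, 1.0, C)
        t = rng.normal(0, 5, 400)
        X = 100.0 + np.outer(t, direction)
        model = finalize_pca(
            AccumulatedStats.from_image(*_image_from_pixels(X)))
        assert model.explained[0] == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.abs(model.eigenvalues[1:])
                      < 1e-8 * model.eigenvalues[0])

    def test_matches_direct_pca_oracle(self, rng):
        series = _random_series(rng, n_images=4, n_pixels=1250)
        model = finalize_pca(accumulate_statistics(series))
        _, eigval, eigvec = _direct_pca(series)
        assert np.allclose(model.eigenvalues, eigval, rtol=1e-8)
        for k in range(C):
            dot = abs(model.loadings[:, k] @ eigvec[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_pca(self, rng):
        from sklearn.decomposition import PCA

        series = _random_series(rng, n_images=3, n_pixels=700)
        X = np.vstack([img.data[m] for img, m in series])
        model = finalize_pca(accumulate_statistics(series))
        sk = PCA(svd_solver="full").fit(X)
        assert np.allclose(model.eigenvalues, sk.explained_variance_,
                           rtol=1e-8)
        assert np.allclose(model.explained / 100.0,
                           sk.explained_variance_ratio_, atol=1e-10)

    def test_isotropic_data_spreads_variance_evenly(self):
        rng = np.random.default_rng(2024)
        X = rng.normal(0, 1, (100_000, C))
        model = finalize_pca(
            AccumulatedStats.from_image(*_image_from_pixels(X)))
        # each explained share ~ 100/11 %; eigenvalue sampling error is
        # O(sqrt(2/n)) ~ 0.45%, so 0.25 percentage points is ~3 SE
        assert np.all(np.abs(model.explained - 100.0 / C) < 0.25)

    def test_variance_conservation(self, rng):
        series = _random_series(rng)
        stats = accumulate_statistics(series)
        model = finalize_pca(stats)
        X = np.vstack([img.data[m] for img, m in series])
        trace = np.cov(X, rowvar=False, ddof=1).trace()
        assert model.eigenvalues.sum() == pytest.approx(trace, rel=1e-10)
        assert model.explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_loadings_orthonormal(self, rng):
        model = finalize_pca(accumulate_statistics(_random_series(rng)))
        assert np.allclose(model.loadings.T @ model.loadings,
                           np.eye(C), atol=1e-8)

    def test_sign_convention_largest_entry_negative(self, rng):
        model = finalize_pca(accumulate_statistics(_random_series(rng)))
        for k in range(C):
            j = np.argmax(np.abs(model.loadings[:, k]))
            assert model.loadings[j, k] < 0

    def test_intensity_loading_all_negative_on_brightness_data(self, rng):
        """When channels co-vary through a shared per-pixel brightness
        factor — the usual situation for fluorescence counts — the
        first loading is an intensity contrast and the sign convention
        makes all its entries negative."""
        spectrum = rng.uniform(0.2, 1.0, C)
        brightness = rng.gamma(2.0, 500.0, 3000)
        X = np.outer(brightness, spectrum)
        X += rng.normal(0, 0.05 * X.mean(), X.shape)
        model = finalize_pca(
            AccumulatedStats.from_image(*_image_from_pixels(X)))
        assert np.all(model.loadings[:, 0] < 0)

    def test_too_few_pixels_rejected(self):
        stats = AccumulatedStats(1, np.zeros(C), np.zeros((C, C)), 1)
        with pytest.raises(ValueError):
            finalize_pca(stats)

    def test_endmember_contrasts_recovered(self, rng):
        """With three spectrally distinct fluorophores and 2% noise,
        the top-3 loading subspace contains every centered
        endmember-difference direction to within 5 degrees."""
        ems = default_endmembers()
        W = np.stack([e.channel_weights for e in ems])      # (3, 11)
        A = rng.uniform(0, 3000, (20_000, 3))               # abundances
        X = A @ W
        X += rng.normal(0, 0.02 * X.mean(), X.shape)
        model = finalize_pca(
            AccumulatedStats.from_image(*_image_from_pixels(X)))
        top3 = model.loadings[:, :3]
        for i in range(3):
            for j in range(i + 1, 3):
                diff = (W[i] - W[j])[:, None]
                angle = np.degrees(subspace_angles(top3, diff)[0])
                assert angle < 5.0


class TestScores:
    def test_mean_spectrum_scores_zero(self, rng):
        series = _random_series(rng)
        model = finalize_pca(accumulate_statistics(series))
        img = MultispectralImage(model.mean[None, None, :])
        mask = np.ones((1, 1), bool)
        for k in range(C):
            s = project_scores(img, mask, model, k)
            assert s.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_score_variance_equals_eigenvalue(self, rng):
        series = _random_series(rng, n_images=4, n_pixels=800)
        model = finalize_pca(accumulate_statistics(series))
        scores = np.vstack([
            project_all_scores(img, m, model) for img, m in series
        ])
        var = scores.var(axis=0, ddof=1)
        assert np.allclose(var, model.eigenvalues, rtol=1e-6)

    def test_scores_of_distinct_components_uncorrelated(self, rng):
        series = _random_series(rng, n_images=4, n_pixels=800)
        model = finalize_pca(accumulate_statistics(series))
        scores = np.vstack([
            project_all_scores(img, m, model) for img, m in series
        ])
        cov = np.cov(scores, rowvar=False, ddof=1)
        off = cov - np.diag(np.diag(cov))
        scale = np.sqrt(np.outer(model.eigenvalues, model.eigenvalues))
        assert np.all(np.abs(off) / scale < 1e-6)

    def test_component_out_of_range(self, rng):
        series = _random_series(rng, n_images=1)
        model = finalize_pca(accumulate_statistics(series))
        with pytest.raises(ValueError, match="out of range"):
            project_scores(*series[0], model, component=C)

    def test_values_nan_outside_roi(self, rng):
        X = rng.uniform(0, 100, (10, C))
        img = MultispectralImage(X[None, :, :])
        mask = np.zeros((1, 10), bool)
        mask[0, :5] = True
        model = finalize_pca(accumulate_statistics([(img, mask)]))
        s = project_scores(img, mask, model, 0)
        assert np.all(np.isfinite(s.values[0, :5]))
        assert np.all(np.isnan(s.values[0, 5:]))

    def test_score_stream_matches_projection(self, rng):
        series = _random_series(rng, n_images=2, n_pixels=50)
        model = finalize_pca(accumulate_statistics(series))
        streamed = np.concatenate(
            list(iter_score_arrays(series, model, 1)))
        direct = np.vstack([
            project_all_scores(img, m, model) for img, m in series
        ])[:, 1]
        assert np.allclose(streamed, direct)


class TestEightBit:
    def _model(self, rng):
        return finalize_pca(accumulate_statistics(_random_series(rng)))

    def test_zero_score_maps_to_mid_gray(self, rng):
        from grainfluor.large_pca import ScoreImage

        model = self._model(rng)
        s = ScoreImage(component=0, values=np.zeros((2, 2)))
        gray, _ = score_to_8bit(s, model)
        assert np.all(gray == 128)

    def test_scores_beyond_spread_clip(self, rng):
        from grainfluor.large_pca import ScoreImage

        model = self._model(rng)
        hi = 10.0 * np.sqrt(model.eigenvalues[0])
        s = ScoreImage(component=0, values=np.full((2, 2), hi))
        gray, _ = score_to_8bit(s, model)
        assert np.all(gray == 255)

    def test_bounds_common_across_images(self, rng):
        from grainfluor.large_pca import ScoreImage

        model = self._model(rng)
        s1 = ScoreImage(component=2, values=rng.normal(0, 1, (3, 3)))
        s2 = ScoreImage(component=2, values=rng.normal(0, 5, (3, 3)))
        _, b1 = score_to_8bit(s1, model)
        _, b2 = score_to_8bit(s2, model)
        assert b1 == b2 == score_bounds(model, 2)

    def test_zero_eigenvalue_with_scores_rejected(self, rng):
        from grainfluor.large_pca import PcaModel, ScoreImage

        model = self._model(rng)
        model.eigenvalues = model.eigenvalues.copy()
        model.eigenvalues[0] = 0.0
        s = ScoreImage(component=0, values=np.ones((2, 2)))
        with pytest.raises(ValueError, match="eigenvalue"):
            score_to_8bit(s, model)

    def test_model_json_round_trip(self, rng, tmp_path):
        from grainfluor import io as gio
        from grainfluor.large_pca import PcaModel

        model = self._model(rng)
        gio.write_json(tmp_path / "m.json", model.to_dict())
        back = PcaModel.from_dict(gio.read_json(tmp_path / "m.json"))
        assert np.allclose(back.loadings, model.loadings)
        assert np.allclose(back.eigenvalues, model.eigenvalues)
        assert back.channels == model.channels


def test_dominant_component_identifies_spectral_contrast(rng):
    """A series dominated by red-emission variance puts its red
    contrast on component 1, found by loading energy."""
    ems = default_endmembers()
    W = np.stack([e.channel_weights for e in ems])
    A = rng.uniform(0, 1, (5000, 3)) * np.array([8000.0, 500.0, 500.0])
    X = A @ W + rng.normal(0, 5, (5000, C))
    model = finalize_pca(
        AccumulatedStats.from_image(*_image_from_pixels(X)))
    k = dominant_component(model, ("BLr", "GRr", "U2r"))
    assert k == 0
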