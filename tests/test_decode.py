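import numpy as np
import pandas as pd
import pytest

from barrel4.decode import (
    FeatureMatrix,
    _solve_shrunk,
    ensemble_curve,
    featurize,
    loo_cv,
    oddball_single_cell,
    train_linear_decoder,
)
from barrel4.metrics import van_rossum


def toy_features(n_per_class=10, p=6, sep=4.0, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, noise, (n_per_class, p))
    x1 = rng.normal(0.0, noise, (n_per_class, p))
    x1[:, 0] += sep
    x = np.vstack([x0, x1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return FeatureMatrix(x, y, ensemble=tuple(range(p)), bin_ms=10.0, window=(0, 60))


def raster_frame(records):
    return pd.DataFrame(records, columns=["trial", "neuron", "t_ms", "label"])


class TestFeaturize:
    def test_single_spike_lands_in_bin(self):
        df = raster_frame([(0, 7, 25.0, 0), (0, 7, 25.0, 1)])
        fm = featurize(df, ensemble=[7], bin_ms=10.0, window=(0.0, 100.0))
        row = fm.x[0]
        assert row[2] == 1.0 and row.sum() == 1.0

    def test_doubling_bin_width_halves_columns(self):
        df = raster_frame([(0, 1, 5.0, 0), (0, 1, 5.0, 1)])
        narrow = featurize(df, [1], bin_ms=10.0, window=(0.0, 100.0))
        wide = featurize(df, [1], bin_ms=20.0, window=(0.0, 100.0))
        assert narrow.x.shape[1] == 2 * wide.x.shape[1]

    def test_feature_sums_conserve_spike_counts(self):
        rng = np.random.default_rng(0)
        rows = [
            (t, int(n), float(rng.uniform(0, 100)), lab)
            for lab in (0, 1)
            for t in range(3)
            for n in rng.integers(0, 4, 10)
        ]
        df = raster_frame(rows)
        fm = featurize(df, [0, 1, 2, 3], bin_ms=10.0, window=(0.0, 100.0))
        assert fm.x.sum() == len(df)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            featurize(raster_frame([]), [], 10.0, (0.0, 100.0))


class TestLinearDecoder:
    def test_separable_classes_zero_training_error(self):
        fm = toy_features(sep=10.0)
        dec = train_linear_decoder(fm)
        assert np.array_equal(dec.predict(fm.x), fm.y)

    def test_single_class_rejected(self):
        fm = toy_features()
        bad = FeatureMatrix(fm.x[:10], fm.y[:10], fm.ensemble, fm.bin_ms, fm.window)
        with pytest.raises(ValueError):
            train_linear_decoder(bad)

    def test_full_shrinkage_is_nearest_class_mean(self):
        fm = toy_features(sep=1.0, seed=3)
        dec = train_linear_decoder(fm, lam=1.0)
        mu0, mu1 = dec.mu0, dec.mu1
        d0 = ((fm.x - mu0) ** 2).sum(axis=1)
        d1 = ((fm.x - mu1) ** 2).sum(axis=1)
        assert np.array_equal(dec.predict(fm.x), (d1 < d0).astype(int))

    def test_woodbury_solve_matches_dense(self):
        """The n x n dual solve equals the explicit p x p regularized solve."""
        rng = np.random.default_rng(4)
        xc = rng.normal(size=(12, 30))
        d = rng.normal(size=30)
        lam = 0.05
        got = _solve_shrunk(xc, d, lam, "shrinkage")
        n = xc.shape[0]
        sigma = xc.T @ xc / n
        c_bar = np.trace(sigma) / sigma.shape[0]
        reg = (1 - lam) * sigma + lam * c_bar * np.eye(30)
        assert np.allclose(got, np.linalg.solve(reg, d), atol=1e-8)

    def test_additive_mode_matches_dense(self):
        rng = np.random.default_rng(5)
        xc = rng.normal(size=(8, 20))
        d = rng.normal(size=20)
        got = _solve_shrunk(xc, d, 0.05, "additive")
        reg = xc.T @ xc / 8 + 0.05 * np.eye(20)
        assert np.allclose(got, np.linalg.solve(reg, d), atol=1e-8)


class TestLooCv:
    def test_separable_toy_zero_error(self):
        res = loo_cv(toy_features(sep=10.0), n_permutations=0)
        assert res.error == 0.0

    def test_one_fold_per_trial(self):
        fm = toy_features(n_per_class=5)
        res = loo_cv(fm, n_permutations=0)
        assert res.predictions.size == 10

    def test_permutation_null_centred_at_chance(self):
        fm = toy_features(sep=10.0, n_per_class=10)
        res = loo_cv(fm, n_permutations=100, seed=1)
        se = res.null_errors.std(ddof=1) / np.sqrt(res.null_errors.size)
        assert res.null_mean == pytest.approx(0.5, abs=max(3 * se, 0.06))

    def test_identical_distributions_near_chance(self):
        errs = [
            loo_cv(toy_features(sep=0.0, seed=s), n_permutations=0).error for s in range(20)
        ]
        assert 0.3 < np.mean(errs) < 0.7

    def test_too_few_trials_rejected(self):
        fm = toy_features(n_per_class=1)
        with pytest.raises(ValueError):
            loo_cv(fm)

    def test_noise_features_do_not_help(self):
        """Appending pure-noise columns never lowers the average error
        beyond sampling noise (regularization sanity)."""
        deltas = []
        for s in range(50):
            fm = toy_features(n_per_class=8, p=10, sep=1.5, seed=s)
            base = loo_cv(fm, n_permutations=0).error
            rng = np.random.default_rng(1000 + s)
            x_aug = np.hstack([fm.x, rng.normal(size=(fm.x.shape[0], 10))])
            aug = FeatureMatrix(x_aug, fm.y, fm.ensemble, fm.bin_ms, fm.window)
            deltas.append(loo_cv(aug, n_permutations=0).error - base)
        assert np.mean(deltas) > -0.02


class TestEnsembleCurve:
    def _raster(self, informative, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lab in (0, 1):
            for t in range(8):
                for n in range(12):
                    n_spk = rng.poisson(2.0 + (4.0 if informative and lab else 0.0))
                    for _ in range(n_spk):
                        rows.append((t, n, float(rng.uniform(0, 100)), lab))
        return raster_frame(rows)

    def test_oversized_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_curve({"g": [self._raster(True)]}, sizes=[50], population=12, n_null=0)

    def test_uninformative_rasters_near_chance(self):
        df = self._raster(informative=False)
        out = ensemble_curve(
            {"g": [df]}, sizes=[4], n_permutations=6, population=12,
            window=(0.0, 100.0), seed=0, n_null=0,
        )
        assert 0.25 < out["error"].mean() < 0.75

    def test_informative_rasters_beat_chance(self):
        df = self._raster(informative=True)
        out = ensemble_curve(
            {"g": [df]}, sizes=[8], n_permutations=6, population=12,
            window=(0.0, 100.0), seed=0, n_null=0,
        )
        assert out["error"].mean() < 0.35

    def test_seeded_reproducibility(self):
        df = self._raster(True)
        kw = dict(sizes=[4], n_permutations=3, population=12, window=(0.0, 100.0),
                  seed=7, n_null=0)
        assert ensemble_curve({"g": [df]}, **kw).equals(ensemble_curve({"g": [df]}, **kw))


class TestOddballSingleCell:
    def test_identical_responses_all_zero(self):
        df = raster_frame([(t, 0, 30.0 + t, 0) for t in range(4)]).drop(columns="label")
        out = oddball_single_cell(df, df, neurons=[0], window=(0.0, 100.0))
        row = out.iloc[0]
        assert row["d_rate"] == 0.0
        assert row["d_first_ms"] == 0.0
        assert row["vr_dissimilarity"] >= 0.0

    def test_extra_spike_shifts_rate_by_one(self):
        reg = raster_frame([(t, 0, 30.0, 0) for t in range(4)]).drop(columns="label")
        odd = raster_frame(
            [(t, 0, tm, 0) for t in range(4) for tm in (30.0, 60.0)]
        ).drop(columns="label")
        out = oddball_single_cell(reg, odd, neurons=[0], window=(0.0, 100.0))
        assert out.iloc[0]["d_rate"] == pytest.approx(1.0)

    def test_dissimilarity_equals_mean_pairwise_distance(self):
        reg = raster_frame([(0, 3, 20.0, 0), (1, 3, 25.0, 0)]).drop(columns="label")
        odd = raster_frame([(0, 3, 70.0, 0), (1, 3, 75.0, 0)]).drop(columns="label")
        out = oddball_single_cell(reg, odd, neurons=[3], window=(0.0, 100.0))
        expected = np.mean(
            [van_rossum([a], [b]) for a in (20.0, 25.0) for b in (70.0, 75.0)]
        )
        assert out.iloc[0]["vr_dissimilarity"] == pytest.approx(expected, rel=1e-9)
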