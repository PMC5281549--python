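"""Voxel screening and ARD regression: oracles, sparsity, determinism."""

import numpy as np
import pandas as pd
import pytest

from dreamdecode.config import ArdSettings
from dreamdecode.decoding import (
    fit_ard,
    predict_features,
    select_voxels,
    train_decoder_bank,
)
from dreamdecode.preprocess import SampleSet, make_block_samples
from dreamdecode.simulate import make_encoding_model, make_feature_tables, \
    simulate_perception_session

from conftest import clean_sim


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def _sparse_problem(n=200, p=50, true=(3, 17, 41), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    w[list(true)] = [2.0, -1.5, 1.0]
    y = X @ w + noise * rng.standard_normal(n)
    return X, y, w


class TestSelectVoxels:
    def test_exact_match_voxel_wins(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = X[:, 3].copy()
        assert select_voxels(X, y, 1).tolist() == [3]

    def test_absolute_ranking_prefers_strong_anticorrelation(self):
        rng = np.random.default_rng(1)
        n = 200
        z = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([-0.9 * y + 0.44 * z, 0.5 * y + 0.87 * z, rng.normal(size=n)])
        sel = select_voxels(X, y, 1, use_abs=True)
        assert sel.tolist() == [0]
        sel_signed = select_voxels(X, y, 1, use_abs=False)
        assert sel_signed.tolist() == [1]

    def test_matches_brute_force_ranking_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 50))
        y = rng.normal(size=100)
        for k in (1, 7, 23, 50):
            got = select_voxels(X, y, k)
            # independent oracle: full corrcoef sort
            r = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(50)])
            expect = np.sort(np.argsort(-r, kind="stable")[:k])
            np.testing.assert_array_equal(got, expect)

    def test_zero_variance_voxels_excluded(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        X[:, 2] = 5.0
        sel = select_voxels(X, rng.normal(size=40), 4)
        assert 2 not in sel.tolist()

    def test_constant_target_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            select_voxels(rng.normal(size=(20, 3)), np.ones(20), 1)


class TestFitArd:
    def test_noiseless_sparse_truth_matches_ols_oracle(self):
        X, y, w_true = _sparse_problem()
        Xh, yh, _ = _sparse_problem(seed=99)
        yh = Xh @ w_true
        w, info = fit_ard(_standardize(X), (y - y.mean()) / y.std())
        # de-standardised prediction on held-out data
        pred = ((Xh - X.mean(0)) / X.std(0)) @ w * y.std() + y.mean()
        oracle = Xh[:, [3, 17, 41]] @ np.linalg.lstsq(
            X[:, [3, 17, 41]], y, rcond=None
        )[0]
        assert np.corrcoef(pred, yh)[0, 1] >= 0.999
        assert np.corrcoef(pred, oracle)[0, 1] >= 0.999
        mass = np.abs(w[[3, 17, 41]]).sum() / np.abs(w).sum()
        assert mass >= 0.9

    def test_pure_noise_target_gives_null_heldout_r(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(40):
            X = rng.standard_normal((60, 20))
            y = rng.standard_normal(60)
            w, _ = fit_ard(_standardize(X), (y - y.mean()) / max(y.std(), 1e-12))
            Xh = rng.standard_normal((60, 20))
            yh = rng.standard_normal(60)
            pred = Xh @ w
            if pred.std() > 0:
                rs.append(np.corrcoef(pred, yh)[0, 1])
        rs = np.array(rs)
        assert abs(rs.mean()) < 2 * rs.std() / np.sqrt(len(rs)) + 0.05

    def test_single_voxel_identity(self):
        rng = np.random.default_rng(6)
        y = rng.normal(2.0, 3.0, size=50)
        X = y[:, None].copy()
        w, _ = fit_ard(_standardize(X), (y - y.mean()) / y.std())
        assert abs(w[0] - 1.0) < 1e-6

    def test_oracle_equivalence_dense_truth(self):
        rng = np.random.default_rng(7)
        n, p = 120, 30
        X = rng.standard_normal((n, p))
        w_true = rng.standard_normal(p)
        y = X @ w_true
        Z, ys = _standardize(X), (y - y.mean()) / y.std()
        w, _ = fit_ard(Z, ys)
        w_ols = np.linalg.lstsq(Z, ys, rcond=None)[0]
        Xh = rng.standard_normal((80, p))
        Zh = (Xh - X.mean(0)) / X.std(0)
        assert np.corrcoef(Zh @ w, Zh @ w_ols)[0, 1] >= 0.999

    def test_sparsity_not_increasing_with_noise(self):
        active = []
        for noise in (0.05, 0.5, 2.0):
            X, y, _ = _sparse_problem(noise=noise, seed=8)
            w, _ = fit_ard(_standardize(X), (y - y.mean()) / y.std())
            active.append(int(np.count_nonzero(w)))
        assert active[2] <= active[0] + 2

    def test_deterministic(self):
        X, y, _ = _sparse_problem(noise=0.3, seed=9)
        w1, _ = fit_ard(_standardize(X), (y - y.mean()) / y.std())
        w2, _ = fit_ard(_standardize(X), (y - y.mean()) / y.std())
        np.testing.assert_array_equal(w1, w2)

    def test_nonfinite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_ard(X, np.ones(10))

    def test_agrees_with_sklearn_ard_crosscheck(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y, _ = _sparse_problem(n=150, p=50, noise=0.5, seed=10)
        Z, ys = _standardize(X), (y - y.mean()) / y.std()
        w, _ = fit_ard(Z, ys)
        ref = sklearn.ARDRegression(fit_intercept=False).fit(Z, ys)
        Xh = np.random.default_rng(11).standard_normal((100, 50))
        assert np.corrcoef(Xh @ w, Xh @ ref.coef_)[0, 1] >= 0.98


@pytest.fixture(scope="module")
def clean_training():
    # exact closure needs (a) at least as many voxels per ROI as total
    # latent feature dimensions, so the encoding map is invertible, and
    # (b) clearly more training samples than screened voxels
    cfg = clean_sim(
        n_train_categories=25,
        exemplars_per_category=8,
        units_per_layer=15,
        n_voxels_per_roi={"V1": 40, "FFA": 40},
    )
    tables = make_feature_tables(cfg)
    model = make_encoding_model(cfg, tables)
    runs = simulate_perception_session(cfg, tables, model, "train")
    test_runs = simulate_perception_session(cfg, tables, model, "test")
    train_ss = make_block_samples(runs, "perception", cfg.hemodynamic_shift_volumes)
    test_ss = make_block_samples(test_runs, "perception", cfg.hemodynamic_shift_volumes)
    return cfg, tables, train_ss, test_ss


class TestDecoderBank:
    def test_bank_covers_all_units(self, clean_training):
        cfg, tables, train_ss, _ = clean_training
        bank = train_decoder_bank(train_ss, tables[0], "V1", 20)
        assert len(bank) + len(bank.skipped_units) == cfg.units_per_layer

    def test_noiseless_closure_on_preferred_layer(self, clean_training):
        """Decoders recover the presented features almost exactly when the
        generator's nuisance chain is disabled (the simulator closure)."""
        cfg, tables, train_ss, test_ss = clean_training
        rows = test_ss.sample_meta["exemplar"].to_numpy(int)
        for layer, roi in ((0, "V1"), (1, "FFA")):
            bank = train_decoder_bank(train_ss, tables[layer], roi, 40)
            decoded = predict_features(bank, test_ss)
            truth = tables[layer].values[rows]
            for j in range(truth.shape[1]):
                r = np.corrcoef(decoded[:, j], truth[:, j])[0, 1]
                assert r >= 0.999

    def test_prediction_is_affine(self, clean_training):
        cfg, tables, train_ss, test_ss = clean_training
        bank = train_decoder_bank(train_ss, tables[0], "V1", 20)
        d = predict_features(bank, test_ss)
        mean_sample = SampleSet(
            X=test_ss.X.mean(axis=0, keepdims=True),
            labels=[test_ss.labels[0]],
            sample_meta=test_ss.sample_meta.iloc[:1],
            roi_masks=test_ss.roi_masks,
            mode="single",
        )
        d_mean = predict_features(bank, mean_sample)
        np.testing.assert_allclose(d_mean[0], d.mean(axis=0), atol=1e-8)

    def test_zero_pattern_predicts_destandardised_bias(self, clean_training):
        cfg, tables, train_ss, test_ss = clean_training
        bank = train_decoder_bank(train_ss, tables[0], "V1", 20)
        zero = SampleSet(
            X=np.zeros((1, test_ss.X.shape[1])),
            labels=[("x",)],
            sample_meta=test_ss.sample_meta.iloc[:1],
            roi_masks=test_ss.roi_masks,
            mode="single",
        )
        d = predict_features(bank, zero)
        for j, u in enumerate(bank.unit_ids):
            dec = bank.decoders[u]
            expect = (
                (-dec.train_voxel_mean / dec.train_voxel_sd) @ dec.weights
                * dec.train_target_sd
                + dec.train_target_mean
            )
            assert abs(d[0, j] - expect) < 1e-8

    def test_voxel_dimension_mismatch_rejected(self, clean_training):
        cfg, tables, train_ss, test_ss = clean_training
        bank = train_decoder_bank(train_ss, tables[0], "V1", 20)
        bad = SampleSet(
            X=np.zeros((2, 7)),
            labels=[("x",), ("y",)],
            sample_meta=pd.DataFrame({"i": [0, 1]}),
            roi_masks={"V1": np.arange(7)},
            mode="single",
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_features(bank, bad)

    def test_label_feature_mismatch_detected_before_training(self, clean_training):
        cfg, tables, train_ss, _ = clean_training
        broken = SampleSet(
            X=train_ss.X,
            labels=[("wrong",)] * train_ss.n_samples,
            sample_meta=train_ss.sample_meta,
            roi_masks=train_ss.roi_masks,
            mode="single",
        )
        with pytest.raises(ValueError, match="does not match"):
            train_decoder_bank(broken, tables[0], "V1", 20)

    def test_constant_unit_skipped_and_logged(self, clean_training, caplog):
        import dataclasses

        cfg, tables, train_ss, _ = clean_training
        t = tables[0]
        vals = t.values.copy()
        vals[:, 0] = 3.14
        t2 = dataclasses.replace(t, values=vals)
        bank = train_decoder_bank(train_ss, t2, "V1", 20)
        assert str(t.unit_ids[0]) in bank.skipped_units
        decoded = predict_features(bank, train_ss)
        assert np.all(np.isnan(decoded[:, 0]))
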