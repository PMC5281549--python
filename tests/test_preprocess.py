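"""Preprocessing: nuisance regression, despiking, baseline, windowing."""

import numpy as np
import pandas as pd
import pytest

from dreamdecode.config import VC
from dreamdecode.preprocess import (
    SampleSet,
    average_dream_samples_by_category,
    despike,
    make_block_samples,
    make_dream_samples,
    normalize_dream_baseline,
    preprocess_block_runs,
    regress_out_nuisance,
)
from dreamdecode.simulate import (
    Event,
    RunTimeSeries,
    make_encoding_model,
    make_feature_tables,
    simulate_dream_session,
    simulate_perception_session,
)

from conftest import clean_sim, tiny_sim


def _run(data, tr=3.0, events=None, nuisance=None, run_id="r0"):
    T, V = data.shape
    if nuisance is None:
        rng = np.random.default_rng(0)
        nuisance = np.column_stack(
            [np.arange(T, dtype=float), np.cumsum(rng.normal(0, 0.02, (T, 6)), axis=0)]
        )
    return RunTimeSeries(
        data=data,
        nuisance=nuisance,
        events=events or [],
        roi_masks={"V1": np.arange(V), VC: np.arange(V)},
        tr_seconds=tr,
        run_id=run_id,
    )


class TestNuisanceRegression:
    def test_trend_voxel_residual_zero(self):
        T = 40
        data = np.column_stack([3.0 * np.arange(T) + 5.0, np.ones(T)])
        run = _run(data)
        out = regress_out_nuisance(run, include_constant=True)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_residual_orthogonal_to_all_regressors(self):
        rng = np.random.default_rng(1)
        run = _run(rng.normal(size=(60, 15)))
        out = regress_out_nuisance(run, include_constant=True)
        X = np.column_stack([np.ones(60), run.nuisance])
        # normalise columns so the tolerance is scale-free
        Xn = X / np.linalg.norm(X, axis=0)
        assert np.max(np.abs(Xn.T @ out.data)) < 1e-8

    def test_matches_explicit_hat_matrix_projection(self):
        rng = np.random.default_rng(2)
        run = _run(rng.normal(size=(50, 8)))
        out = regress_out_nuisance(run, include_constant=True)
        X = np.column_stack([np.ones(50), run.nuisance])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        expected = (np.eye(50) - H) @ run.data
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        T = 30
        nuis = np.column_stack(
            [np.arange(T, dtype=float), rng.normal(size=(T, 5)), np.arange(T, dtype=float)]
        )
        run = _run(rng.normal(size=(T, 4)), nuisance=nuis)
        with pytest.raises(ValueError, match="motion6"):
            regress_out_nuisance(run, include_constant=True)


# hand-built 20-value series: mean/SD computed once, the single 10-SD spike
# clipped to the mean+3SD bound, every other value untouched
_SPIKE_SERIES = np.array(
    [1.0, 2.0, 1.5, 0.5, 1.0, 2.5, 1.0, 1.5, 2.0, 0.5,
     1.5, 1.0, 2.0, 1.5, 0.5, 1.0, 30.0, 1.5, 1.0, 2.0]
)


class TestDespike:
    def test_constant_series_unchanged(self):
        run = _run(np.full((10, 3), 7.0))
        out = despike(run)
        np.testing.assert_array_equal(out.data, run.data)

    def test_hand_computed_spike_clipping(self):
        y = _SPIKE_SERIES
        mean, sd = y.mean(), y.std()
        run = _run(y[:, None])
        out = despike(run, k_sd=3.0)
        expected = y.copy()
        expected[16] = mean + 3.0 * sd  # the only value beyond the bound
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-12)
        assert np.sum(out.data[:, 0] != y) == 1

    def test_output_within_preclip_bounds(self):
        rng = np.random.default_rng(4)
        data = rng.standard_t(df=2, size=(200, 10))
        run = _run(data)
        out = despike(run, k_sd=3.0)
        z = (out.data - data.mean(axis=0)) / data.std(axis=0)
        assert np.max(np.abs(z)) <= 3.0 + 1e-12


class TestBaselineNormalization:
    def _dream_run(self):
        # 40 volumes, awakening at volume 38; baseline window 60-90 s before
        # = volumes [8, 18); baseline mean 100, pre-awakening value 103
        data = np.full((40, 2), 100.0)
        data[35:38] = 103.0
        return _run(data), 38

    def test_known_offset_fixture(self):
        run, A = self._dream_run()
        out = normalize_dream_baseline(run, A)
        np.testing.assert_allclose(out.data[35:38], 3.0, atol=1e-12)
        np.testing.assert_allclose(out.data[8:18], 0.0, atol=1e-12)

    def test_baseline_window_mean_zero(self):
        rng = np.random.default_rng(5)
        run = _run(rng.normal(100, 5, size=(40, 6)))
        out = normalize_dream_baseline(run, 38)
        np.testing.assert_allclose(out.data[8:18].mean(axis=0), 0.0, atol=1e-10)

    def test_constant_run_all_zeros(self):
        run = _run(np.full((40, 3), 42.0))
        out = normalize_dream_baseline(run, 38)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_divide_mode_percent_change(self):
        run, A = self._dream_run()
        out = normalize_dream_baseline(run, A, mode="divide")
        np.testing.assert_allclose(out.data[35:38], 3.0, atol=1e-12)  # 3% of 100

    def test_window_outside_run_rejected(self):
        run, _ = self._dream_run()
        with pytest.raises(ValueError):
            normalize_dream_baseline(run, 10)


def _dream_fixture(n=6, T=40, V=4, tr=3.0):
    rng = np.random.default_rng(6)
    runs, recs = [], []
    for i in range(n):
        runs.append(_run(rng.normal(size=(T, V)), tr=tr, run_id=f"d{i}"))
        recs.append(
            {"awakening_id": i, "run": f"d{i}", "volume": 38,
             "labels": "a;b" if i % 2 else "a", "sleep_stage_eligible": True}
        )
    return runs, pd.DataFrame(recs)


class TestDreamSamples:
    def test_offset_zero_is_last_three_preawakening_volumes(self):
        runs, reports = _dream_fixture()
        ss = make_dream_samples(runs, reports)
        np.testing.assert_allclose(ss.X[0], runs[0].data[35:38].mean(axis=0))
        assert ss.n_samples == len(reports)
        assert ss.mode == "multi"

    def test_offset_shifts_by_whole_volumes(self):
        runs, reports = _dream_fixture()
        a = make_dream_samples(runs, reports, window_center_offset_s=3.0)
        np.testing.assert_allclose(a.X[0], runs[0].data[36:39].mean(axis=0))

    def test_out_of_bounds_windows_dropped(self):
        runs, reports = _dream_fixture()
        # lengthen one run so a far-future window survives only there
        rng = np.random.default_rng(8)
        runs[0] = _run(rng.normal(size=(60, 4)), run_id="d0")
        ss = make_dream_samples(runs, reports, window_center_offset_s=30.0)
        assert ss.n_samples == 1
        assert ss.sample_meta["run"].tolist() == ["d0"]

    def test_no_post_awakening_volumes_at_nonpositive_offset(self):
        runs, reports = _dream_fixture()
        for off in (0.0, -3.0, -6.0):
            n = int(round(9.0 / 3.0))
            shift = int(round(off / 3.0))
            assert 38 + shift <= 38  # window end never passes the awakening

    def test_stage_ineligible_awakenings_excluded(self):
        runs, reports = _dream_fixture()
        reports.loc[0, "sleep_stage_eligible"] = False
        ss = make_dream_samples(runs, reports)
        assert ss.n_samples == len(reports) - 1


class TestCategoryAveraging:
    def test_shared_category_rows_averaged(self):
        runs, reports = _dream_fixture(n=4)
        ss = make_dream_samples(runs, reports)
        single = average_dream_samples_by_category(ss)
        # categories: 'a' in all 4 awakenings, 'b' in awakenings 1 and 3
        assert [ls[0] for ls in single.labels] == ["a", "b"]
        np.testing.assert_allclose(single.X[0], ss.X.mean(axis=0))
        np.testing.assert_allclose(single.X[1], ss.X[[1, 3]].mean(axis=0))

    def test_unique_single_labels_reorder_input(self):
        runs, reports = _dream_fixture(n=3)
        reports["labels"] = ["c", "a", "b"]
        ss = make_dream_samples(runs, reports)
        single = average_dream_samples_by_category(ss)
        assert [ls[0] for ls in single.labels] == ["a", "b", "c"]
        np.testing.assert_allclose(single.X[0], ss.X[1])

    def test_output_count_equals_base_category_count(self):
        # the study-scale property: as many averaged samples as base synsets
        for n_base in (26, 16):
            rng = np.random.default_rng(n_base)
            n = 4 * n_base
            runs, recs = [], []
            cats = [f"s{i:02d}" for i in range(n_base)]
            for i in range(n):
                runs.append(_run(rng.normal(size=(40, 3)), run_id=f"d{i}"))
                labels = {cats[i % n_base], cats[(i * 7 + 3) % n_base]}
                recs.append(
                    {"awakening_id": i, "run": f"d{i}", "volume": 38,
                     "labels": ";".join(sorted(labels)), "sleep_stage_eligible": True}
                )
            ss = make_dream_samples(runs, pd.DataFrame(recs))
            single = average_dream_samples_by_category(ss)
            assert single.n_samples == n_base


class TestBlockSamples:
    def test_training_session_sample_count(self):
        cfg = tiny_sim(
            n_train_categories=150, exemplars_per_category=8, units_per_layer=4,
            n_layers=1, invariance_profile=(0.5,),
            n_voxels_per_roi={"V1": 5, "FFA": 5},
        )
        tables = make_feature_tables(cfg)
        model = make_encoding_model(cfg, tables)
        runs = simulate_perception_session(cfg, tables, model, "train")
        ss = preprocess_block_runs(runs, "perception", 1)
        assert ss.n_samples == 1200

    def test_test_session_category_averaging(self):
        cfg = tiny_sim()
        tables = make_feature_tables(cfg)
        model = make_encoding_model(cfg, tables)
        runs = simulate_perception_session(cfg, tables, model, "test")
        ss = preprocess_block_runs(runs, "perception", 1, average_by_category=True)
        assert ss.n_samples == cfg.n_test_categories

    def test_pipeline_order_is_nuisance_then_despike(self):
        # a large spike inflates the regression fit; the two orders differ,
        # and the composed pipeline uses nuisance -> despike
        rng = np.random.default_rng(7)
        data = rng.normal(size=(40, 3))
        data[20, 0] += 50.0
        ev = [Event(onset=5, duration=3, labels=("x",), kind="stimulus", exemplar=0)]
        run = _run(data, events=ev)
        a = despike(regress_out_nuisance(run, include_constant=True))
        b = regress_out_nuisance(despike(run), include_constant=True)
        assert not np.allclose(a.data, b.data)
        ss = preprocess_block_runs([run], "perception", 0)
        np.testing.assert_allclose(ss.X[0], a.data[5:8].mean(axis=0))


class TestSampleSetInvariants:
    def test_single_mode_requires_one_label(self):
        with pytest.raises(ValueError):
            SampleSet(
                X=np.zeros((1, 2)),
                labels=[("a", "b")],
                sample_meta=pd.DataFrame({"i": [0]}),
                roi_masks={"V1": np.arange(2)},
                mode="single",
            )

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            SampleSet(
                X=np.array([[np.nan, 0.0]]),
                labels=[("a",)],
                sample_meta=pd.DataFrame({"i": [0]}),
                roi_masks={"V1": np.arange(2)},
                mode="single",
            )
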