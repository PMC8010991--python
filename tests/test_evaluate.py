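import numpy as np
import pandas as pd
import pytest

from leafspec.errors import DegenerateDataError, InvalidParameterError
from leafspec.evaluate import (
    FittedPipeline,
    ensemble_predict,
    evaluate_pipeline,
    grid_search,
    residual_table,
    summarize,
)
from leafspec.pls import PLSRModel

from .conftest import as_spectra, planted_band_data


@pytest.fixture(scope="module")
def planted_spectra():
    X, y = planted_band_data(n=100, p=60, seed=40)
    return as_spectra(X), y


class TestEvaluatePipeline:
    def test_record_count_and_determinism(self, planted_spectra):
        sm, y = planted_spectra
        a = evaluate_pipeline(sm, y, "raw", "none", n_rep=6, seed=3, max_ncomp=5)
        b = evaluate_pipeline(sm, y, "raw", "none", n_rep=6, seed=3, max_ncomp=5)
        assert len(a.records) == 6
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_repetition_reproducible_in_isolation(self, planted_spectra):
        # rep r depends only on (seed, r): a shorter run reproduces a prefix
        sm, y = planted_spectra
        a = evaluate_pipeline(sm, y, "raw", "none", n_rep=5, seed=3, max_ncomp=5)
        b = evaluate_pipeline(sm, y, "raw", "none", n_rep=2, seed=3, max_ncomp=5)
        pd.testing.assert_frame_equal(a.records.iloc[:2], b.records)

    def test_splits_disjoint_exhaustive(self, planted_spectra):
        from leafspec.evaluate import _rep_rng, _split

        sm, y = planted_spectra
        n = sm.n_samples
        for rep in range(10):
            cal, val = _split(n, 0.8, _rep_rng(7, rep))
            assert len(np.intersect1d(cal, val)) == 0
            assert len(cal) + len(val) == n
            np.testing.assert_array_equal(np.sort(np.r_[cal, val]), np.arange(n))

    def test_high_snr_fixture_validates_well(self, planted_spectra):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=10, seed=1, max_ncomp=5)
        assert summarize(d)["r2_val_mean"] >= 0.9

    def test_selector_runs_inside_loop(self, planted_spectra):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "smc", n_rep=4, seed=2, max_ncomp=5)
        assert d.masks[: len(d.records)].any(axis=1).all()
        assert (d.records["n_selected"] < sm.n_bands).all()

    def test_zeroing_never_selected_validation_bands_is_noop(self, planted_spectra):
        # the fitted model must not touch unselected bands of validation rows
        from leafspec.evaluate import _rep_rng, _split

        sm, y = planted_spectra
        for seed in (5, 6):
            d = evaluate_pipeline(sm, y, "raw", "smc", n_rep=1, seed=seed,
                                  max_ncomp=5)
            never = ~d.masks[0]
            assert never.any()  # fixture has plenty of noise bands
            _, val = _split(sm.n_samples, 0.8, _rep_rng(seed, 0))
            zeroed = sm.copy()
            zeroed.values[np.ix_(val, np.where(never)[0])] = 0.0
            d2 = evaluate_pipeline(zeroed, y, "raw", "smc", n_rep=1, seed=seed,
                                   max_ncomp=5)
            pd.testing.assert_frame_equal(d.records, d2.records)

    def test_tiny_partition_rejected(self, planted_spectra):
        sm, y = planted_spectra
        with pytest.raises(InvalidParameterError):
            evaluate_pipeline(sm.take(range(10)), y[:10], "raw", "none",
                              n_rep=2, frac_cal=0.9)


class TestSummarize:
    def test_constant_records_collapse(self, planted_spectra):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=3, seed=1, max_ncomp=3)
        d.records[["r2_cal", "rmse_cal", "r2_val", "rmse_val"]] = 0.5
        s = summarize(d)
        assert s["r2_val_mean"] == s["r2_val_min"] == s["r2_val_max"] == 0.5

    def test_mean_matches_recomputation_and_percentiles_bracket_median(
        self, planted_spectra
    ):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=8, seed=2, max_ncomp=5)
        s = summarize(d)
        ok = d.records[~d.records["failed"]]
        assert s["r2_val_mean"] == pytest.approx(ok["r2_val"].mean(), abs=1e-12)
        med = ok["r2_val"].median()
        assert s["r2_val_p2.5"] <= med <= s["r2_val_p97.5"]

    def test_all_failed_rejected(self, planted_spectra):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=2, seed=1, max_ncomp=3)
        d.records["failed"] = True
        with pytest.raises(DegenerateDataError):
            summarize(d)


class TestGridSearch:
    def test_single_cell_grid(self, planted_spectra):
        sm, y = planted_spectra
        table, best, _ = grid_search(sm, y, ["raw"], ["none"], n_rep=3, seed=1,
                                     max_ncomp=4)
        assert best == ("raw", "none") and len(table) == 1

    def test_shared_splits_across_cells(self, planted_spectra):
        sm, y = planted_spectra
        _, _, dists = grid_search(sm, y, ["raw", "snv"], ["none"], n_rep=4,
                                  seed=9, max_ncomp=4)
        h1 = dists[("raw", "none")].records["split_hash"]
        h2 = dists[("snv", "none")].records["split_hash"]
        pd.testing.assert_series_equal(h1, h2)

    def test_signal_destroying_preprocessing_ranks_below_raw(self):
        # response rides on a per-sample offset: the 2nd derivative erases it
        rng = np.random.default_rng(41)
        offsets = rng.standard_normal(80)
        X = offsets[:, None] + rng.standard_normal((80, 60)) * 0.01
        y = offsets + rng.standard_normal(80) * 0.01
        table, best, _ = grid_search(as_spectra(X), y, ["raw", "d2"], ["none"],
                                     n_rep=5, seed=2, max_ncomp=4)
        assert best == ("raw", "none")
        t = table.set_index("method")
        assert t.loc["raw", "r2_val_mean"] > t.loc["d2", "r2_val_mean"]

    def test_empty_grid_rejected(self, planted_spectra):
        sm, y = planted_spectra
        with pytest.raises(InvalidParameterError):
            grid_search(sm, y, [], ["none"], n_rep=2, seed=0)


def _constant_pipeline(value: float, p: int) -> FittedPipeline:
    model = PLSRModel(
        x_mean=np.zeros(p), y_mean=value,
        x_weights=np.zeros((p, 1)), x_loadings=np.zeros((p, 1)),
        y_loadings=np.zeros(1), x_scores=np.zeros((1, 1)),
        regression_vector=np.zeros(p), n_components=1, training_dims=(2, p),
    )
    return FittedPipeline("raw", 15, 2, np.ones(p, dtype=bool), model)


class TestEnsemble:
    def test_identical_models_have_zero_sd(self, planted_spectra):
        sm, _ = planted_spectra
        p = sm.n_bands
        mean, sd = ensemble_predict(
            [_constant_pipeline(2.0, p), _constant_pipeline(2.0, p)], sm
        )
        np.testing.assert_array_equal(sd, 0.0)
        np.testing.assert_array_equal(mean, 2.0)

    def test_two_model_mean_and_sd(self, planted_spectra):
        sm, _ = planted_spectra
        p = sm.n_bands
        mean, sd = ensemble_predict(
            [_constant_pipeline(1.0, p), _constant_pipeline(3.0, p)], sm
        )
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_ensemble_tracks_measured_values_on_high_snr_fixture(
        self, planted_spectra
    ):
        from leafspec.pls import fit_stats

        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=10, seed=4, max_ncomp=5)
        mean, _ = ensemble_predict(d.pipelines, sm)
        r2, _ = fit_stats(y, mean)
        assert r2 >= 0.9

    def test_single_model_rejected(self, planted_spectra):
        sm, _ = planted_spectra
        with pytest.raises(InvalidParameterError):
            ensemble_predict([_constant_pipeline(1.0, sm.n_bands)], sm)


class TestResiduals:
    def test_examples(self):
        t = residual_table([1.0, 2.0], [0.7, 2.0], [0.1, 0.2])
        assert t["residual"].tolist() == pytest.approx([0.3, 0.0])
        assert "predicted_sd" in t.columns

    def test_calibration_residuals_center_near_zero(self, planted_spectra):
        sm, y = planted_spectra
        d = evaluate_pipeline(sm, y, "raw", "none", n_rep=6, seed=6, max_ncomp=5)
        mean, sd = ensemble_predict(d.pipelines, sm)
        t = residual_table(y, mean, sd)
        assert abs(t["residual"].mean()) < 0.05 * y.std()
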