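"""Cleaning pipeline: outlier rules, the 10% screen, both imputers."""

import numpy as np
import pandas as pd
import pytest

from pci_traj import apply_missingness, generate_cohort
from pci_traj.config import SimConfig
from pci_traj.panel import LongitudinalPanel
from pci_traj.preprocessing import (
    filter_outliers,
    impute_cross_sectional,
    impute_longitudinal,
    screen_missingness,
)


class TestFilterOutliers:
    def test_age_over_200_set_missing_and_logged(self):
        df = pd.DataFrame({"age": [65.0, 210.0], "heart_rate": [80.0, 90.0]})
        out, log = filter_outliers(df)
        assert np.isnan(out.loc[1, "age"])
        assert len(log) == 1 and log[0]["rule"] == "age > 200"

    def test_negative_vital_set_missing(self):
        df = pd.DataFrame({"heart_rate": [-5.0, 70.0], "mean_bp": [80.0, -1.0]})
        out, log = filter_outliers(df)
        assert np.isnan(out.loc[0, "heart_rate"]) and np.isnan(out.loc[1, "mean_bp"])
        assert {e["rule"] for e in log} == {"negative vital sign"}

    def test_negative_urine_output_set_missing(self):
        df = pd.DataFrame({"urine_output": [-10.0, 500.0]})
        out, log = filter_outliers(df)
        assert np.isnan(out.loc[0, "urine_output"]) and len(log) == 1

    def test_in_range_identity(self):
        df = pd.DataFrame({"age": [65.0], "heart_rate": [80.0], "urine_output": [900.0]})
        out, log = filter_outliers(df)
        pd.testing.assert_frame_equal(out, df)
        assert log == []


class TestScreenMissingness:
    @staticmethod
    def _table(missing_count: int, n: int = 1000) -> pd.DataFrame:
        col = np.ones(n)
        col[:missing_count] = np.nan
        return pd.DataFrame({"x": col, "full": np.ones(n)})

    def test_strictly_above_threshold_dropped(self):
        rep = screen_missingness(self._table(101))  # 10.1%
        assert "x" in rep.dropped

    def test_at_or_below_threshold_kept(self):
        rep = screen_missingness(self._table(99))  # 9.9%
        assert "x" in rep.kept
        rep = screen_missingness(self._table(100))  # exactly 10%: strict ">"
        assert "x" in rep.kept

    def test_forced_drop_regardless_of_completeness(self):
        df = pd.DataFrame({"ph": [7.3] * 98 + [np.nan] * 2, "x": np.ones(100)})
        rep = screen_missingness(df)
        assert "ph" in rep.forced_drop and "ph" not in rep.kept

    def test_partition_property(self, default_cohort):
        _, cohort, _ = default_cohort
        df = cohort.select_dtypes("number")
        rep = screen_missingness(df)
        all_vars = sorted(rep.kept + rep.dropped + rep.forced_drop)
        assert all_vars == sorted(df.columns)

    def test_row_order_invariance(self):
        df = self._table(80)
        rep1 = screen_missingness(df)
        rep2 = screen_missingness(df.sample(frac=1, random_state=0))
        assert rep1.kept == rep2.kept and rep1.dropped == rep2.dropped

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_missingness(pd.DataFrame({"x": []}))


def _single_var_panel(series_rows: np.ndarray, mask_rows: np.ndarray) -> LongitudinalPanel:
    vals = series_rows[:, :, None]
    mask = mask_rows[:, :, None]
    return LongitudinalPanel(vals, mask, ["v"])


class TestImputeLongitudinal:
    def test_no_missing_is_identity(self):
        rows = np.random.default_rng(0).normal(size=(5, 10))
        panel = _single_var_panel(rows, np.ones((5, 10), dtype=bool))
        out = impute_longitudinal(panel)
        np.testing.assert_array_equal(out.values, panel.values)

    def test_linear_series_recovered_exactly(self):
        vals = np.tile(np.arange(1.0, 11.0), (3, 1))
        mask = np.ones((3, 10), dtype=bool)
        mask[0, 4] = False  # day 5 hidden in an exactly linear series
        panel = _single_var_panel(vals.copy(), mask)
        out = impute_longitudinal(panel)
        assert out.values[0, 4, 0] == pytest.approx(5.0, abs=1e-6)
        assert out.mask.all()

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 10))
        mask = rng.random((20, 10)) > 0.3
        mask[:, 0] = True
        panel = _single_var_panel(vals.copy(), mask)
        out = impute_longitudinal(panel)
        np.testing.assert_array_equal(out.values[:, :, 0][mask], vals[mask])

    def test_fully_missing_series_falls_back_to_day_means(self):
        vals = np.vstack([np.arange(10.0) + 1, np.arange(10.0) + 3, np.zeros(10)])
        mask = np.ones((3, 10), dtype=bool)
        mask[2] = False
        panel = _single_var_panel(vals, mask)
        out = impute_longitudinal(panel)
        np.testing.assert_allclose(out.values[2, :, 0], np.arange(10.0) + 2)

    def test_error_decreases_with_missing_rate(self):
        """On MCAR data the imputation RMSE is monotone in the missing rate
        in expectation (averaged over seeds)."""
        cfg = SimConfig(n_patients=60, seed=0, miss_rates={})
        _, base = generate_cohort(cfg)
        errs = {0.1: [], 0.4: []}
        for rate in errs:
            for seed in range(20):
                holey = apply_missingness(base, {"bun": rate}, seed=seed)
                filled = impute_longitudinal(holey)
                j = base.var_index("bun")
                hidden = base.mask[:, :, j] & ~holey.mask[:, :, j]
                if hidden.any():
                    err = filled.values[:, :, j][hidden] - base.values[:, :, j][hidden]
                    errs[rate].append(np.sqrt(np.mean(err**2)))
        assert np.mean(errs[0.1]) < np.mean(errs[0.4])


class TestImputeCrossSectional:
    def test_complete_table_gives_identical_copies(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = impute_cross_sectional(df, m=3, seed=0)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, df)

    def test_duplicate_column_imputed_from_pure_node(self):
        x = np.repeat([0.0, 10.0, 20.0, 30.0], 12)
        y = x.copy()
        y[5] = np.nan
        df = pd.DataFrame({"x": x, "y": y})
        out = impute_cross_sectional(df, m=3, seed=1)
        for t in out:
            assert t.loc[5, "y"] == 0.0  # the donor leaf is pure in y

    def test_observed_cells_identical_across_imputations(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        df.loc[rng.choice(50, 8, replace=False), "a"] = np.nan
        obs = df["a"].notna()
        out = impute_cross_sectional(df, m=4, seed=0)
        for t in out:
            assert not t.isna().any().any()
            np.testing.assert_array_equal(t.loc[obs, "a"], df.loc[obs, "a"])

    def test_rmse_close_to_oracle_regression(self):
        """Donor-draw CART imputation error stays within 1.5x the oracle
        residual RMSE on data with a known linear generator (a donor draw
        adds one residual's worth of noise on top of the oracle's)."""
        rng = np.random.default_rng(7)
        n = 600
        x = np.round(rng.normal(size=n), 1)
        noise = rng.normal(0, 0.5, size=n)
        y = 2.0 * x + noise
        df = pd.DataFrame({"x": x, "y": y})
        miss = rng.choice(n, int(0.1 * n), replace=False)
        df.loc[miss, "y"] = np.nan
        out = impute_cross_sectional(df, m=5, seed=0)
        imp = np.mean([t.loc[miss, "y"].to_numpy() for t in out], axis=0)
        rmse = np.sqrt(np.mean((imp - (2.0 * x[miss] + noise[miss])) ** 2))
        oracle = 0.5  # residual SD of the generator
        assert rmse <= 1.5 * oracle

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_cross_sectional(df, seed=0)
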