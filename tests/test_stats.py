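"""Benefit decomposition, accuracy metrics, outlier and pattern statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsim.stats import (
    accuracy_metrics,
    compute_benefits,
    detect_outliers,
    fisher_z_compare,
    ks_normality,
    pattern_projection,
    metrics_table,
)


def srt_frame(triples: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    rows = []
    for lid, (a, b, c) in triples.items():
        rows += [(lid, "S0N0", a), (lid, "S0N90", b), (lid, "S0mN90m", c)]
    return pd.DataFrame(rows, columns=["id", "condition", "srt_db"])


class TestBenefits:
    def test_worked_example(self):
        out = compute_benefits(srt_frame({"a": (-6.0, -12.0, -9.0)}))
        row = out.iloc[0]
        assert row["SRM"] == pytest.approx(6.0)
        assert row["BRM"] == pytest.approx(3.0)
        assert row["BEL"] == pytest.approx(3.0)

    def test_equal_srts_zero_benefits(self):
        out = compute_benefits(srt_frame({"a": (-5.0, -5.0, -5.0)}))
        assert (out[["SRM", "BRM", "BEL"]].iloc[0] == 0.0).all()

    @given(st.tuples(st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20)))
    @settings(max_examples=50, deadline=None)
    def test_additivity_identity(self, triple):
        out = compute_benefits(srt_frame({"a": triple}))
        row = out.iloc[0]
        assert row["SRM"] == pytest.approx(row["BEL"] + row["BRM"], abs=1e-9)

    def test_missing_condition_dropped_with_reason(self):
        df = srt_frame({"a": (-6.0, -12.0, -9.0)})
        df = pd.concat([df, pd.DataFrame([("b", "S0N0", -3.0)], columns=df.columns)])
        out = compute_benefits(df)
        assert list(out["id"]) == ["a"]
        assert out.attrs["dropped"][0][0] == "b"


class TestAccuracyMetrics:
    def test_perfect_prediction(self):
        m = accuracy_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.bias_db, m.rmse_db) == (1.0, 0.0, 0.0)

    def test_constant_shift(self):
        m = accuracy_metrics([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.bias_db == pytest.approx(-2.0)
        assert m.rmse_db == pytest.approx(2.0)

    def test_hand_computed_small_set(self):
        measured, predicted = [0.0, 2.0, 4.0], [1.0, 2.0, 5.0]
        m = accuracy_metrics(measured, predicted)
        err = np.array(measured) - np.array(predicted)
        assert m.bias_db == pytest.approx(err.mean())
        assert m.rmse_db == pytest.approx(np.sqrt((err**2).mean()))
        assert m.r2 == pytest.approx(np.corrcoef(measured, predicted)[0, 1] ** 2)
        assert m.rmse_db >= abs(m.bias_db)

    def test_zero_variance_flagged(self):
        m = accuracy_metrics([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert not m.r2_defined


class TestFisherZ:
    def test_equal_correlations_p_one(self):
        assert fisher_z_compare(0.5, 100, 0.5, 100) == pytest.approx(1.0)

    def test_symmetry(self):
        p1 = fisher_z_compare(0.3, 50, 0.6, 80)
        p2 = fisher_z_compare(0.6, 80, 0.3, 50)
        assert p1 == pytest.approx(p2)

    def test_large_cohort_improvement_significant(self):
        """R^2 0.57 -> 0.74 at n=738 per condition is a significant gain."""
        p = fisher_z_compare(np.sqrt(0.57), 738, np.sqrt(0.74), 738)
        assert p < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.5, 100)
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 10, 0.5, 10)


class TestOutliers:
    def test_single_gross_error_flagged(self):
        idx = detect_outliers([0.0, 0.0, 0.0, 0.0, 10.0])
        assert list(idx) == [4]

    def test_constant_sample_no_outliers(self):
        assert detect_outliers([2.0] * 8).size == 0

    def test_gaussian_flag_rate_near_theoretical(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(1000)
        rate = detect_outliers(x).size / x.size
        assert rate == pytest.approx(0.007, abs=0.008)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            detect_outliers([1.0, 2.0, 3.0])


class TestKSWorkflow:
    def test_gaussian_usually_passes(self):
        rng = np.random.default_rng(7)
        passes = sum(ks_normality(rng.standard_normal(500)) > 0.05 for _ in range(100))
        assert passes >= 90

    def test_outlier_screen_two_step(self):
        """Gross outliers break normality; removing them restores it."""
        rng = np.random.default_rng(11)
        clean = rng.standard_normal(300)
        contaminated = np.concatenate([clean, [9.0, -8.5, 10.0, 8.0, -9.5]])
        assert ks_normality(contaminated) < 0.05
        keep = np.delete(contaminated, detect_outliers(contaminated))
        assert ks_normality(keep) > 0.05


class TestPatternProjection:
    @staticmethod
    def benefit_frame(group_means: dict[str, float], n: int = 25, sd: float = 0.5, seed: int = 0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in group_means.items():
            for i in range(n):
                v = rng.normal(mu, sd, size=3)
                rows.append((f"{g}{i}", g, v[0], v[1], v[2]))
        return pd.DataFrame(rows, columns=["id", "group", "SRM", "BRM", "BEL"])

    def test_identical_group_data_all_none(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 0.5, (25, 3))
        rows = [(f"{g}{i}", g, *x[i]) for g in ("NH", "N3") for i in range(25)]
        bm = pd.DataFrame(rows, columns=["id", "group", "SRM", "BRM", "BEL"])
        out = pattern_projection(bm, bm.copy())
        assert set(out["outcome"]) == {"none"}
        assert out.attrs["match_fraction"] == 1.0

    def test_shared_shift_is_both_greater(self):
        bm = self.benefit_frame({"NH": 3.0, "N3": 0.0}, seed=3)
        bp = self.benefit_frame({"NH": 3.0, "N3": 0.0}, seed=4)
        out = pattern_projection(bm, bp)
        assert set(out["outcome"]) == {"both"}
        assert set(out["direction"]) == {"greater"}
        assert set(out["code"]) == {"B+"}

    def test_measured_only_is_type_two(self):
        bm = self.benefit_frame({"NH": 3.0, "N3": 0.0}, seed=5)
        bp = self.benefit_frame({"NH": 0.0, "N3": 0.0}, seed=6)
        out = pattern_projection(bm, bp)
        assert set(out["outcome"]) == {"measured_only"}

    def test_predicted_only_is_type_one(self):
        bm = self.benefit_frame({"NH": 0.0, "N3": 0.0}, seed=7)
        bp = self.benefit_frame({"NH": 0.0, "N3": 3.0}, seed=8)
        out = pattern_projection(bm, bp)
        assert set(out["outcome"]) == {"predicted_only"}
        assert set(out["direction"]) == {"smaller"}  # NH mean below N3

    def test_small_groups_excluded(self):
        bm = self.benefit_frame({"NH": 0.0, "N3": 0.0}, n=25, seed=9)
        tiny = self.benefit_frame({"N4": 0.0}, n=2, seed=10)
        out = pattern_projection(pd.concat([bm, tiny]), pd.concat([bm, tiny]))
        assert "N4" in out.attrs["excluded_groups"]
        assert not set(out["group_a"]) & {"N4"}

    def test_self_consistency_predicted_equals_measured(self):
        bm = self.benefit_frame({"NH": 4.0, "N2": 2.0, "N4": 0.0}, seed=11)
        out = pattern_projection(bm, bm.copy())
        sig = out[out["outcome"] != "none"]
        assert (sig["outcome"] == "both").all()
        assert out.attrs["match_fraction"] == 1.0


def test_metrics_table_layout():
    rng = np.random.default_rng(5)
    ids = [f"l{i}" for i in range(12)]
    rows_m, rows_p = [], []
    for i, lid in enumerate(ids):
        base = rng.normal(-6, 2)
        for cond, off in (("S0N0", 0.0), ("S0N90", -6.0), ("S0mN90m", -3.0)):
            rows_m.append((lid, cond, base + off + rng.normal(0, 0.3)))
            rows_p.append((lid, cond, base + off))
    m = pd.DataFrame(rows_m, columns=["id", "condition", "srt_db"])
    p = pd.DataFrame(rows_p, columns=["id", "condition", "srt_db"])
    table = metrics_table(m, p)
    assert list(table.index) == ["R2", "bias_db", "rmse_db"]
    assert set(table.columns) == {"S0N0", "S0N90", "S0mN90m", "SRM", "BRM", "BEL"}
    assert table.loc["R2", "S0N0"] > 0.9
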