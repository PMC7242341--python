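"""Multiscale curves, AUC reduction and the four-cell region ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegrqa.features import FEATURE_COLUMNS
from eegrqa.stats import (
    curve_auc, heatmap_table, multiscale_group_curve, one_way_anova,
    region_anova, subject_sensor_auc,
)
from eegrqa.montage import STANDARD_1020, CT_SENSORS


def make_table(values_by_subject, measure="SampE", sensors=STANDARD_1020):
    """Long-format feature table from {subject: (group, band->value fn)}."""
    rows = []
    for subject, (group, fn) in values_by_subject.items():
        for sensor in sensors:
            region = "CT" if sensor in CT_SENSORS else "nonCT"
            for b in range(7):
                rows.append((subject, group, sensor, region, b,
                             0.0, 0.0, measure, fn(sensor, b)))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


class TestMultiscaleCurve:
    def test_identical_subjects_zero_ci(self):
        table = make_table({
            "a": ("case", lambda s, b: b + 1.0),
            "b": ("case", lambda s, b: b + 1.0),
        })
        c = multiscale_group_curve(table, "SampE", "C3", "case")
        np.testing.assert_allclose(c.band_means, np.arange(7) + 1.0)
        np.testing.assert_allclose(c.ci_half_width, 0.0)
        assert (c.n_per_band == 2).all()

    def test_single_subject_curve(self):
        table = make_table({"a": ("case", lambda s, b: 2.0 * b)})
        c = multiscale_group_curve(table, "SampE", "Fz", "case")
        np.testing.assert_allclose(c.band_means, 2.0 * np.arange(7))
        np.testing.assert_allclose(c.ci_half_width, 0.0)

    def test_ci_is_1p96_sem(self):
        gen = np.random.default_rng(5)
        vals = {f"s{i}": ("case", lambda s, b, v=gen.standard_normal(7): v[b])
                for i in range(6)}
        table = make_table(vals)
        c = multiscale_group_curve(table, "SampE", "O1", "case")
        sub = table[(table.sensor == "O1")]
        for b in range(7):
            x = sub[sub.band_index == b]["value"].to_numpy()
            assert c.ci_half_width[b] == pytest.approx(
                1.96 * x.std(ddof=1) / np.sqrt(len(x))
            )

    def test_sampling_distribution_recovers_population_mean(self):
        """Cohort means land within 3 SEM of the population mean per band."""
        gen = np.random.default_rng(42)
        mu = np.array([1, 2, 3, 4, 5, 6, 7], dtype=float)
        hits = trials = 0
        for _ in range(30):
            vals = {
                f"s{i}": ("case",
                          lambda s, b, v=mu + gen.standard_normal(7): v[b])
                for i in range(20)
            }
            c = multiscale_group_curve(make_table(vals), "SampE", "C3", "case")
            sem = 1.0 / np.sqrt(20)
            hits += int(np.all(np.abs(c.band_means - mu) <= 3 * sem))
            trials += 1
        assert hits / trials >= 0.95

    def test_empty_band_raises(self):
        table = make_table({"a": ("case", lambda s, b: np.nan if b == 3 else 1.0),
                            "b": ("case", lambda s, b: np.nan if b == 3 else 1.0)})
        with pytest.raises(ValueError, match=r"\[3\]"):
            multiscale_group_curve(table, "SampE", "C3", "case")


class TestCurveAuc:
    def test_constant_curve(self):
        assert curve_auc(np.full(7, 3.0)) == pytest.approx(18.0)

    def test_single_trapezoid(self):
        assert curve_auc(np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_hand_computed(self):
        assert curve_auc(np.array([1.0, 3.0, 2.0])) == pytest.approx(4.5)

    def test_interior_missing_interpolated(self):
        assert curve_auc(np.array([1.0, np.nan, 3.0])) == pytest.approx(
            curve_auc(np.array([1.0, 2.0, 3.0]))
        )

    def test_terminal_missing_truncates(self):
        assert curve_auc(np.array([np.nan, 1.0, 1.0])) == pytest.approx(1.0)

    def test_rejects_sparse_curve(self):
        with pytest.raises(ValueError):
            curve_auc(np.array([np.nan, 1.0, np.nan]))

    def test_linearity(self, rng):
        v = rng.standard_normal(7)
        w = rng.standard_normal(7)
        assert curve_auc(2.0 * v + 3.0 * w) == pytest.approx(
            2.0 * curve_auc(v) + 3.0 * curve_auc(w)
        )


class TestOneWayAnova:
    def test_equal_cells_give_null_f(self):
        cells = [np.array([1.0, 2.0, 3.0])] * 4
        res = one_way_anova(cells)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df_between == 3

    def test_two_group_hand_computation(self):
        res = one_way_anova([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_matches_scipy_f_oneway(self, rng):
        cells = [rng.standard_normal(n) + mu
                 for n, mu in [(8, 0.0), (12, 0.5), (9, -0.2), (15, 0.1)]]
        res = one_way_anova(cells)
        ref_f, ref_p = sps.f_oneway(*cells)
        assert res.F == pytest.approx(ref_f)
        assert res.p == pytest.approx(ref_p)

    def test_ss_decomposition_identity(self, rng):
        for _ in range(20):
            cells = [rng.standard_normal(int(rng.integers(3, 20))) for _ in range(4)]
            res = one_way_anova(cells)
            assert res.ss_total == pytest.approx(
                res.ss_between + res.ss_within, rel=1e-9
            )

    def test_f_invariant_under_shift_and_scale(self, rng):
        cells = [rng.standard_normal(10) for _ in range(4)]
        f0 = one_way_anova(cells).F
        assert one_way_anova([c + 5.0 for c in cells]).F == pytest.approx(f0)
        assert one_way_anova([3.0 * c for c in cells]).F == pytest.approx(f0)

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0]),
                           np.array([3.0, 3.0]), np.array([4.0, 4.0])])


class TestRegionAnova:
    def test_cells_and_means(self):
        table = make_table({
            "a": ("case", lambda s, b: 1.0 if s in CT_SENSORS else 2.0),
            "b": ("contrast", lambda s, b: 3.0 if s in CT_SENSORS else 4.0),
            "c": ("case", lambda s, b: 1.5 if s in CT_SENSORS else 2.5),
            "d": ("contrast", lambda s, b: 3.5 if s in CT_SENSORS else 4.5),
        })
        summary = region_anova(table, "SampE")
        assert set(summary.cells) == {
            ("case", "CT"), ("case", "nonCT"), ("contrast", "CT"), ("contrast", "nonCT")
        }
        assert len(summary.cells[("case", "CT")]) == 2 * 7   # 2 subjects x 7 CT sensors
        assert summary.cell_means[("case", "CT")] == pytest.approx(6 * 1.25)
        assert summary.anova.df_between == 3

    def test_empty_cell_named_in_error(self):
        table = make_table({"a": ("case", lambda s, b: 1.0)})
        with pytest.raises(ValueError, match="contrast"):
            region_anova(table, "SampE")

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 under the null stays near nominal."""
        gen = np.random.default_rng(314)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            cells = [gen.standard_normal(15) for _ in range(4)]
            rejections += one_way_anova(cells).p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestHeatmap:
    def test_constant_auc_cohort(self):
        table = make_table({"a": ("case", lambda s, b: 1.0),
                            "b": ("contrast", lambda s, b: 1.0)})
        hm = heatmap_table(table, "SampE")
        assert len(hm) == 38
        np.testing.assert_allclose(hm["mean_auc"], 6.0)
        assert set(hm["group"]) == {"case", "contrast"}

    def test_cell_values_match_groupby_oracle(self, rng):
        gen = np.random.default_rng(8)
        table = make_table({
            f"s{i}": (g, lambda s, b, o=gen.standard_normal(): o + b)
            for i, g in enumerate(["case", "contrast"] * 3)
        })
        hm = heatmap_table(table, "SampE")
        auc = subject_sensor_auc(table, "SampE")
        ref = auc.groupby(["group", "sensor"])["auc"].mean()
        for _, row in hm.iterrows():
            assert row["mean_auc"] == pytest.approx(ref[(row["group"], row["sensor"])])

    def test_missing_sensor_errors_unless_allowed(self):
        table = make_table({"a": ("case", lambda s, b: 1.0),
                            "b": ("contrast", lambda s, b: 1.0)},
                           sensors=[s for s in STANDARD_1020 if s != "O2"])
        with pytest.raises(ValueError, match="O2"):
            heatmap_table(table, "SampE")
        hm = heatmap_table(table, "SampE", allow_missing=True)
        assert len(hm) == 36
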