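"""Measured-vs-predicted map comparison and penetration summaries."""

import numpy as np
import pandas as pd
import pytest

from tectomap.compare import (
    PenetrationSummary,
    columnar_summary,
    compare_orientation_to_concentric,
    penetration_concentric_test,
)
from tectomap.geometry import concentric_from_angles
from tectomap.maps import AxialMap


def axial(angle, amp=0.02):
    angle = np.asarray(angle, dtype=float)
    return AxialMap(angle, np.full_like(angle, amp), np.ones_like(angle, bool))


@pytest.fixture()
def smooth_angle_field(rng):
    from scipy.ndimage import gaussian_filter

    re = gaussian_filter(rng.standard_normal((30, 30)), 4)
    im = gaussian_filter(rng.standard_normal((30, 30)), 4)
    return np.rad2deg(np.arctan2(im, re)) / 2 % 180


class TestCompareMaps:
    def test_identical_maps(self, smooth_angle_field):
        m = axial(smooth_angle_field)
        cmp_ = compare_orientation_to_concentric(m, m, min_mean_response=0.001)
        assert cmp_.circ_corr == pytest.approx(1.0)
        assert cmp_.diff_histogram[8:10].sum() == cmp_.n_pixels  # all in [-10, 10)
        assert cmp_.median_abs_diff_deg == 0.0

    def test_ninety_degree_rotation_concentrates_at_edges(self, smooth_angle_field):
        m = axial(smooth_angle_field)
        r = axial((smooth_angle_field + 90) % 180)
        cmp_ = compare_orientation_to_concentric(m, r, min_mean_response=0.001)
        # differences sit at the +/-90 edges (float rounding can land on either)
        assert cmp_.diff_histogram[0] + cmp_.diff_histogram[-1] == cmp_.n_pixels
        assert cmp_.median_abs_diff_deg == pytest.approx(90.0)

    def test_correlation_symmetric_histogram_flips(self, smooth_angle_field, rng):
        a = axial(smooth_angle_field)
        b = axial((smooth_angle_field + rng.normal(0, 15, smooth_angle_field.shape)) % 180)
        c1 = compare_orientation_to_concentric(a, b, min_mean_response=0.001)
        c2 = compare_orientation_to_concentric(b, a, min_mean_response=0.001)
        assert c1.circ_corr == pytest.approx(c2.circ_corr)
        interior = slice(1, -1)  # the +90 tie-break bin cannot flip
        assert np.array_equal(c1.diff_histogram[interior], c2.diff_histogram[interior][::-1])

    def test_histogram_counts_sum_to_n(self, smooth_angle_field, rng):
        a = axial(smooth_angle_field)
        b = axial(rng.uniform(0, 180, smooth_angle_field.shape))
        cmp_ = compare_orientation_to_concentric(a, b, min_mean_response=0.001)
        assert cmp_.diff_histogram.sum() == cmp_.n_pixels

    def test_response_filter_is_monotone(self, smooth_angle_field, rng):
        a = axial(smooth_angle_field, amp=0.02)
        b = axial(rng.uniform(0, 180, smooth_angle_field.shape))
        per_cond = rng.uniform(0, 0.02, (4,) + smooth_angle_field.shape)
        ns = []
        for thr in [0.001, 0.005, 0.01]:
            cmp_ = compare_orientation_to_concentric(
                a, b, min_mean_response=thr, per_condition=per_cond
            )
            ns.append(cmp_.n_pixels)
        assert ns[0] >= ns[1] >= ns[2]

    def test_strict_filter_requires_every_condition(self, smooth_angle_field):
        a = axial(smooth_angle_field)
        b = axial(smooth_angle_field)
        per_cond = np.full((4,) + smooth_angle_field.shape, 0.01)
        per_cond[2, :10] = 0.001  # one weak condition knocks out those rows
        strict = compare_orientation_to_concentric(
            a, b, min_mean_response=0.005, per_condition=per_cond, filter_mode="all"
        )
        lenient = compare_orientation_to_concentric(
            a, b, min_mean_response=0.005, per_condition=per_cond, filter_mode="any"
        )
        assert strict.n_pixels == 20 * 30
        assert lenient.n_pixels == 30 * 30

    def test_insufficient_overlap_raises(self):
        m = axial(np.array([[10.0, 20.0], [30.0, 40.0]]))
        with pytest.raises(ValueError, match="insufficient overlap"):
            compare_orientation_to_concentric(m, m)

    def test_permutation_p_small_for_matching_maps(self, smooth_angle_field):
        m = axial(smooth_angle_field)
        cmp_ = compare_orientation_to_concentric(
            m, m, min_mean_response=0.001, n_permutations=99, seed=0
        )
        assert cmp_.p_value == pytest.approx(1 / 100)


class TestPenetrationConcentric:
    def test_exact_concentric_summaries_give_corr_one(self, rng):
        summaries = []
        for i in range(12):
            az = rng.uniform(5, 50)
            el = rng.uniform(-20, 30)
            ang = float(concentric_from_angles(az, el))
            summaries.append(PenetrationSummary(f"p{i}", ang, 0.05, 6, az, el))
        table, corr = penetration_concentric_test(summaries)
        assert corr == pytest.approx(1.0)
        assert np.allclose(table["diff_deg"], 0.0, atol=1e-9)

    def test_constant_predictor_flagged_degenerate(self):
        # receptive fields on the temporal horizontal axis all predict vertical
        summaries = [
            PenetrationSummary(f"p{i}", 90.0, 0.05, 6, az, 0.0)
            for i, az in enumerate([10.0, 20.0, 30.0, 40.0])
        ]
        table, corr = penetration_concentric_test(summaries)
        assert np.allclose(table["predicted_deg"], 90.0)
        assert corr is None
        assert table.attrs.get("degenerate_predictor")

    def test_missing_rf_raises(self):
        with pytest.raises(ValueError, match="receptive-field"):
            penetration_concentric_test([PenetrationSummary("p0", 10.0, 0.1, 4)])


class TestColumnarSummary:
    def make_table(self, prefs_by_pen, n_trials=4, amp=20.0):
        rows = []
        dirs = np.arange(0.0, 360, 45)
        for pen, prefs in prefs_by_pen.items():
            for u, pref in enumerate(prefs):
                oris = (dirs + 90) % 180
                rates = 3.0 + amp * np.exp(np.cos(2 * np.deg2rad(oris - pref)) - 1)
                for t in range(n_trials):
                    for d, r in zip(dirs, rates):
                        rows.append(
                            {
                                "penetration_id": pen,
                                "unit_id": f"{pen}u{u}",
                                "direction_deg": d,
                                "trial_index": t,
                                "response": r,
                                "baseline": 3.0,
                            }
                        )
        return pd.DataFrame(rows)

    def test_perfectly_columnar_ensemble(self):
        table = self.make_table(
            {"a": [0.0] * 6, "b": [45.0] * 6, "c": [90.0] * 6, "d": [135.0] * 6}
        )
        pen, shuffle, _ = columnar_summary(table, n_shuffles=999, seed=2)
        assert np.allclose(pen["circ_var"], 0.0, atol=1e-12)
        assert shuffle.p_value == pytest.approx(1 / 1000)

    def test_unresponsive_units_are_excluded(self):
        strong = self.make_table({"a": [0.0] * 3, "b": [90.0] * 3})
        weak = self.make_table({"a": [45.0]}, amp=0.5)  # evoked under 2 Hz
        weak["unit_id"] = "a_weak"
        pen, _, _ = columnar_summary(pd.concat([strong, weak]), n_shuffles=99, seed=0)
        assert int(pen.loc[pen.penetration_id == "a", "n_units"].iloc[0]) == 3

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            columnar_summary(pd.DataFrame(), n_shuffles=10, seed=0)
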