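"""Direction tuning curves, selectivity indices and von Mises fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tectomap.tuning import (
    DirectionTuning,
    collapse_directions,
    direction_selectivity_index,
    direction_to_grating_orientation,
    fit_von_mises,
    orientation_gradient,
    orientation_index,
    preferred_orientation_vector,
    trials_to_tuning,
)

DIRS8 = np.arange(0.0, 360.0, 45.0)


def make_tuning(responses, directions=DIRS8):
    responses = np.asarray(responses, dtype=float)
    return DirectionTuning(
        directions=np.asarray(directions, float),
        mean_response=responses,
        sem=np.zeros_like(responses),
        n_trials=np.full(responses.size, 2),
    )


def trial_frame(direction_responses, n_trials=2, baseline=0.0):
    rows = []
    for d, r in direction_responses.items():
        for t in range(n_trials):
            rows.append(
                {"direction_deg": d, "trial_index": t, "response": r, "baseline": baseline}
            )
    return pd.DataFrame(rows)


class TestTrialsToTuning:
    def test_flat_five_hz_included(self):
        df = trial_frame({d: 5.0 for d in DIRS8})
        t, included, evoked = trials_to_tuning(df)
        assert np.allclose(t.mean_response, 5.0)
        assert np.allclose(t.sem, 0.0)
        assert included and evoked == pytest.approx(5.0)

    def test_one_hz_over_baseline_excluded(self):
        df = trial_frame({d: 1.0 for d in DIRS8}, baseline=0.0)
        _, included, evoked = trials_to_tuning(df, min_evoked_hz=2.0)
        assert not included
        assert evoked == pytest.approx(1.0)

    def test_single_trial_sem_zero(self):
        df = trial_frame({d: 4.0 for d in DIRS8}, n_trials=1)
        t, _, _ = trials_to_tuning(df)
        assert np.allclose(t.sem, 0.0)

    def test_sem_from_trials(self):
        rows = [
            {"direction_deg": d, "trial_index": i, "response": r, "baseline": 0.0}
            for d in DIRS8
            for i, r in enumerate([4.0, 6.0])
        ]
        t, _, _ = trials_to_tuning(pd.DataFrame(rows))
        assert np.allclose(t.mean_response, 5.0)
        assert np.allclose(t.sem, np.std([4, 6], ddof=1) / np.sqrt(2))


class TestCollapseDirections:
    def test_average_and_max_of_opposing_pair(self):
        t = make_tuning([8, 0, 0, 0, 2, 0, 0, 0])
        _, avg = collapse_directions(t, "average")
        _, mx = collapse_directions(t, "max")
        assert avg[0] == pytest.approx(5.0)
        assert mx[0] == pytest.approx(8.0)

    def test_eight_direction_hand_pairing(self):
        t = make_tuning([8, 5, 2, 5, 8, 5, 2, 5])
        phi, R = collapse_directions(t, "average")
        assert np.allclose(phi, [0, 45, 90, 135])
        assert np.allclose(R, [8, 5, 2, 5])

    def test_unpaired_directions_raise(self):
        t = make_tuning([1, 2, 3, 4], directions=[0, 45, 90, 180])
        with pytest.raises(ValueError, match="unpaired"):
            collapse_directions(t)


class TestOrientationIndex:
    def test_worked_values(self):
        assert orientation_index([0, 90], [10, 0]) == pytest.approx(1.0)
        assert orientation_index([0, 45, 90, 135], [3, 3, 3, 3]) == pytest.approx(0.0)
        assert orientation_index([0, 45, 90, 135], [8, 5, 2, 5]) == pytest.approx(0.6)

    def test_unresponsive_raises(self):
        with pytest.raises(ValueError, match="unresponsive"):
            orientation_index([0, 45, 90, 135], [0, 0, 0, 0])

    @settings(derandomize=True, max_examples=40)
    @given(scale=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, scale):
        R = np.array([8, 5, 2, 5], dtype=float)
        assert orientation_index([0, 45, 90, 135], scale * R) == pytest.approx(0.6)


class TestDSI:
    def test_worked_values(self):
        single = make_tuning([10, 0, 0, 0, 0, 0, 0, 0])
        dsi, flag = direction_selectivity_index(single)
        assert dsi == pytest.approx(1.0) and flag
        flat = make_tuning([3.0] * 8)
        dsi, flag = direction_selectivity_index(flat)
        assert dsi == pytest.approx(0.0, abs=1e-12) and not flag
        two = make_tuning([10, 0, 0, 0, 5, 0, 0, 0])
        dsi, _ = direction_selectivity_index(two)
        assert dsi == pytest.approx(1 / 3)

    @settings(derandomize=True, max_examples=40)
    @given(scale=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, scale):
        t = make_tuning(scale * np.array([10, 1, 0, 2, 5, 0, 1, 0.5]))
        ref = make_tuning([10, 1, 0, 2, 5, 0, 1, 0.5])
        assert direction_selectivity_index(t)[0] == pytest.approx(
            direction_selectivity_index(ref)[0]
        )


class TestPreferredOrientationVector:
    def test_single_nonzero_orientation(self):
        assert preferred_orientation_vector([0, 45, 90, 135], [0, 7, 0, 0]) == pytest.approx(45)

    def test_symmetric_tuning_prefers_axis(self):
        assert preferred_orientation_vector([0, 45, 90, 135], [8, 5, 2, 5]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_matches_complex_sum_oracle(self, rng):
        phi = np.array([0, 45, 90, 135], dtype=float)
        for _ in range(25):
            R = rng.uniform(0, 10, 4)
            vec = np.sum(R * np.exp(2j * np.deg2rad(phi)))
            if abs(vec) < 1e-9:
                continue
            expected = np.rad2deg(np.angle(vec)) / 2 % 180
            assert preferred_orientation_vector(phi, R) == pytest.approx(expected, abs=1e-12)

    def test_rotation_equivariance(self):
        phi = np.array([0, 45, 90, 135], dtype=float)
        R = np.array([8, 5, 2, 5], dtype=float)
        # relabel all orientations by +45 degrees: preference follows
        rotated = preferred_orientation_vector((phi + 45) % 180, R)
        assert rotated == pytest.approx(45.0, abs=1e-9)


class TestVonMisesFit:
    @staticmethod
    def model(phi, phi0, amp=1.0, base=0.5):
        return base + amp * np.exp(np.cos(2 * np.deg2rad(phi - phi0)) - 1)

    def test_noiseless_recovery(self):
        phi = np.arange(0, 180, 22.5)
        fit = fit_von_mises(phi, self.model(phi, 73.0))
        assert abs(fit.phi_preferred_deg - 73.0) < 0.5
        assert fit.amplitude == pytest.approx(1.0, rel=1e-3)
        assert fit.reliable

    def test_flat_data_flagged(self):
        phi = np.arange(0, 180, 45.0)
        fit = fit_von_mises(phi, np.full(4, 2.0))
        assert fit.amplitude == 0.0
        assert not fit.reliable

    def test_noisy_recovery_median_under_five_degrees(self):
        rng = np.random.default_rng(21)
        phi = np.arange(0, 180, 22.5)
        errs = []
        for _ in range(200):
            phi0 = rng.uniform(0, 180)
            y = self.model(phi, phi0) + rng.normal(0, 0.1, phi.size)
            fit = fit_von_mises(phi, y)
            d = abs((fit.phi_preferred_deg - phi0 + 90) % 180 - 90)
            errs.append(d)
        assert np.median(errs) < 5.0


class TestOrientationGradient:
    def test_constant_and_linear(self):
        assert orientation_gradient([(0, 40), (100, 40), (200, 40)]) == 0
        assert orientation_gradient([(0, 0), (100, 10), (200, 20)]) == pytest.approx(10)

    def test_wrap_across_180(self):
        # 170 -> 10 is a 20-degree axial step
        assert orientation_gradient([(0, 170), (100, 10)]) == pytest.approx(20)

    def test_duplicate_positions_raise(self):
        with pytest.raises(ValueError, match="invalid track"):
            orientation_gradient([(0, 10), (0, 20)])


def test_direction_to_grating_orientation_convention():
    # upward-drifting grating (90 deg motion) is horizontal (0 deg)
    assert direction_to_grating_orientation(90.0) == 0.0
    assert direction_to_grating_orientation(270.0) == 0.0
    assert direction_to_grating_orientation(0.0) == 90.0
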