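"""Vector tuning geometry, preference scores, receptive fields, locus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cicada_dh import (
    infer_injection_locus,
    preference_score,
    rf_area,
    rf_size,
    standardize_angles,
    tuning_vector,
)
from cicada_dh.config import BASIS_ANGLES_CARDINAL
from cicada_dh.errors import ExcludedCell, FormatError


def amps(heat=0.0, mech=0.0, cold=0.0):
    return {"heat": heat, "mechanical": mech, "cold": cold}


class TestTuningVector:
    def test_equal_trimodal_cell_has_zero_magnitude(self):
        tv = tuning_vector(amps(1, 1, 1))
        assert tv.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_heat_only_cell_points_at_90(self):
        tv = tuning_vector(amps(heat=1.0))
        assert tv.angle_deg == pytest.approx(90.0, abs=1e-9)
        assert tv.magnitude == pytest.approx(3.0)  # normalized by mean 1/3

    @pytest.mark.parametrize(
        "modality,angle", [("heat", 90.0), ("mechanical", 210.0), ("cold", 330.0)]
    )
    def test_single_modality_recovers_basis_angle(self, modality, angle):
        tv = tuning_vector({**amps(), modality: 2.0})
        assert tv.angle_deg == pytest.approx(angle, abs=1e-9)

    def test_two_to_one_mixture_geometry(self):
        # normalized (2,1,0): sum = (-sqrt(3)/2, 3/2) -> 120 deg, sqrt(3)
        tv = tuning_vector(amps(heat=2.0, mech=1.0))
        assert tv.angle_deg == pytest.approx(120.0, abs=1e-9)
        assert tv.magnitude == pytest.approx(math.sqrt(3.0), abs=1e-12)

    def test_scale_invariance(self):
        a = tuning_vector(amps(2.0, 0.7, 0.3))
        b = tuning_vector(amps(20.0, 7.0, 3.0))
        assert a.angle_deg == pytest.approx(b.angle_deg)
        assert a.magnitude == pytest.approx(b.magnitude)

    def test_basis_unit_vectors_sum_to_zero(self):
        x = sum(math.cos(math.radians(a)) for a in BASIS_ANGLES_CARDINAL.values())
        y = sum(math.sin(math.radians(a)) for a in BASIS_ANGLES_CARDINAL.values())
        assert abs(x) < 1e-12 and abs(y) < 1e-12

    def test_all_zero_amplitudes_excluded(self):
        with pytest.raises(ExcludedCell):
            tuning_vector(amps())

    def test_angle_recovery_under_noise(self):
        """Measured-amplitude jitter moves recovered angles by < 10 deg SD."""
        rng = np.random.default_rng(0)
        angles = []
        for _ in range(200):
            # heat-tuned cell: the off-modality amplitudes are noise peaks
            a = amps(heat=2.0 + 0.05 * rng.standard_normal(),
                     mech=abs(rng.normal(0, 0.05)) + 0.05,
                     cold=abs(rng.normal(0, 0.05)) + 0.05)
            angles.append(tuning_vector(a).angle_deg)
        rad = np.radians(angles)
        R = np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad)))
        circ_sd = math.degrees(math.sqrt(-2 * math.log(R)))
        assert circ_sd < 10.0
        assert abs(standardize_angles(np.degrees(np.angle(np.mean(np.exp(1j * rad)))), 90.0)) < 5.0


class TestStandardizeAngles:
    def test_equivalent_angles_map_together(self):
        assert standardize_angles(1.0, 0.0) == pytest.approx(1.0)
        assert standardize_angles(-359.0, 0.0) == pytest.approx(1.0)

    def test_full_turn_is_zero(self):
        assert standardize_angles(360.0, 0.0) == pytest.approx(0.0)

    def test_range_is_half_open(self):
        assert standardize_angles(180.0, 0.0) == pytest.approx(180.0)
        assert standardize_angles(180.0001, 0.0) == pytest.approx(-179.9999)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-720, 720, allow_nan=False),
        st.floats(0, 360, allow_nan=False),
        st.integers(-3, 3),
    )
    def test_modular_invariance(self, angle, ref, k):
        a = standardize_angles(angle, ref)
        b = standardize_angles(angle + 360.0 * k, ref)
        assert a == pytest.approx(b, abs=1e-6)
        assert -180.0 < a <= 180.0 or a == pytest.approx(180.0)


class TestPreferenceScore:
    def test_formula(self):
        np.testing.assert_allclose(preference_score([2.0, 1.0, 0.0]), [0.5, 0.0, -0.5])

    def test_equal_amplitudes_score_zero(self):
        np.testing.assert_allclose(preference_score([1.3, 1.3, 1.3]), [0.0, 0.0, 0.0])

    def test_upper_bound_two_thirds(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.uniform(0, 5, 3)
            if a.max() == 0:
                continue
            assert preference_score(a).max() <= 2.0 / 3.0 + 1e-12

    def test_all_zero_flagged(self):
        with pytest.raises(ExcludedCell):
            preference_score([0.0, 0.0, 0.0])


class TestReceptiveField:
    def test_full_grid_both_trials_is_16(self):
        rf = rf_size(np.ones((2, 4, 4), dtype=bool))
        assert rf.size == 16.0
        assert rf.area_mm2 == pytest.approx(60.0)

    def test_empty_grid_is_zero(self):
        assert rf_size(np.zeros((2, 4, 4), dtype=bool)).size == 0.0

    def test_trial_counts_average(self):
        g = np.zeros((2, 4, 4), dtype=bool)
        g[0].flat[:4] = True
        g[1].flat[:2] = True
        assert rf_size(g).size == pytest.approx(3.0)

    def test_worked_area_example(self):
        # 4 responsive sites on the 4x4 grid over 225 mm^2 -> 15 mm^2
        assert rf_area(4) == pytest.approx(15.0)
        assert rf_area(0) == 0.0

    def test_wrong_grid_shape_rejected(self):
        with pytest.raises(FormatError):
            rf_size(np.ones((2, 3, 4), dtype=bool))

    def test_recovery_from_generator(self, detection_run):
        """Measured RF size matches the injected disc within one site."""
        from cicada_dh import build_response_table
        from cicada_dh.tuning import rf_from_calls

        traces, timeline, rois, truth, dffset = detection_run
        calls = build_response_table(dffset, timeline)
        rf = rf_from_calls(calls[calls["kind"] == "stimulus"])
        rf_lt = rf[rf["family"] == "static_LT"].set_index("cell_id")
        tr = truth.responses
        g = tr[tr["family"] == "static_LT"]
        errs = []
        for cid, gg in g.groupby("cell_id"):
            true_size = gg.groupby("trial_index").size().mean()
            errs.append(abs(rf_lt.loc[cid, "size"] - true_size))
        assert np.mean(errs) <= 1.0
        assert np.max(errs) <= 1.0


class TestLocusInference:
    def _refs(self, seed=0):
        rng = np.random.default_rng(seed)
        return {c: rng.normal(100.0 * c + 50.0, 25.0, 200) for c in range(4)}, rng

    def test_identity_match(self):
        refs, rng = self._refs()
        est = infer_injection_locus(rng.normal(250.0, 25.0, 50), refs)
        assert est.locus_col == 2 and not est.low_confidence

    def test_mixture_spreads_over_both_columns(self):
        refs, rng = self._refs(1)
        mix = np.concatenate([rng.normal(250, 25, 25), rng.normal(350, 25, 25)])
        est = infer_injection_locus(mix, refs)
        assert {2, 3} <= set(est.spread_cols)

    def test_uniform_responders_low_confidence(self):
        refs, rng = self._refs(2)
        est = infer_injection_locus(rng.uniform(0, 400, 50), refs)
        assert est.low_confidence

    def test_too_few_responders_gives_no_estimate(self):
        refs, _ = self._refs(3)
        est = infer_injection_locus([100.0, 110.0], refs)
        assert est.locus_col is None and est.low_confidence
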