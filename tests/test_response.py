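"""Responder rule, family assignment, calibration, capsaicin classification."""

import numpy as np
import pandas as pd
import pytest

from cicada_dh import (
    assign_family_response,
    calibrate_thresholds,
    capsaicin_responder,
    detect_ligand_response,
    detect_response,
)
from cicada_dh.errors import AssignmentError, CalibrationError, WindowOutOfRange


def trace_with_peak(peak, sigma, n=200, onset=100, seed=0):
    """Noise of SD ``sigma`` with a single-frame peak at ``onset``."""
    rng = np.random.default_rng(seed)
    tr = rng.normal(0.0, sigma, n) if sigma else np.zeros(n)
    tr[onset] = peak
    return tr


class TestResponderRule:
    @pytest.mark.parametrize(
        "peak,sigma,expected",
        [
            (2.0, 0.05, True),   # 2.0 > 1.25 and > 6*0.05
            (1.0, 0.05, False),  # fails the 1.25 amplitude criterion
            (1.5, 0.30, False),  # 6 sigma = 1.8 exceeds the peak
        ],
    )
    def test_threshold_arithmetic(self, peak, sigma, expected):
        # exact sigma: feed a synthetic noise window with the stated SD
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(30)
        noise = (noise - noise.mean()) / noise.std(ddof=1) * sigma
        tr = np.zeros(140)
        tr[70:100] = noise
        tr[100] = peak
        call = detect_response(tr, 100.0)
        assert call.noise_sigma == pytest.approx(sigma, rel=1e-9)
        assert call.peak_amp == pytest.approx(peak)
        assert call.responder is expected

    def test_window_out_of_range(self):
        with pytest.raises(WindowOutOfRange):
            detect_response(np.zeros(50), 10.0)  # noise window would start < 0

    def test_exclude_mask_removes_prior_response(self):
        tr = np.zeros(200)
        tr[80:90] = 3.0  # a previous event's transient inside the noise window
        tr[100] = 2.0
        mask = np.zeros(200, dtype=bool)
        mask[80:90] = True
        noisy = detect_response(tr, 100.0)
        masked = detect_response(tr, 100.0, exclude_mask=mask)
        assert masked.noise_sigma < noisy.noise_sigma
        assert masked.responder

    def test_monotonic_in_amplitude(self):
        """Raising the injected amplitude never flips responder -> non."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            sigma = rng.uniform(0.0, 0.4)
            amp = rng.uniform(0.0, 3.0)
            tr = trace_with_peak(amp, sigma, seed=int(rng.integers(1 << 30)))
            base = detect_response(tr, 100.0)
            tr2 = tr.copy()
            tr2[100] += rng.uniform(0.1, 2.0)
            bigger = detect_response(tr2, 100.0)
            assert bigger.responder or not base.responder


class TestLigandWindow:
    def test_slow_transient_needs_wide_window(self):
        # transient peaking 80 s after onset, amplitude 2.0
        t = np.arange(400.0)
        onset = 100.0
        tr = 2.0 * np.exp(-((t - onset - 80.0) ** 2) / (2 * 15.0**2))
        assert detect_ligand_response(tr, onset).responder
        assert not detect_response(tr, onset).responder  # 5 s window misses it

    def test_cells_without_receptor_stay_silent(self, ligand_archetype_run):
        """False-positive rate of ligand detection over non-expressed ligands."""
        planted, traces, timeline, truth, dffset = ligand_archetype_run
        from cicada_dh import build_response_table

        table = build_response_table(dffset, timeline)
        lig = table[table["kind"] == "ligand"]
        pos = truth.responder_pairs()
        is_pos = np.array(
            [(c, e) in pos for c, e in zip(lig["cell_id"], lig["event_index"])]
        )
        fp_rate = lig.loc[~is_pos, "responder"].mean()
        assert fp_rate <= 0.01
        assert lig.loc[is_pos, "responder"].mean() >= 0.95


class TestFamilyAssignment:
    def _calls(self, family, flags):
        return pd.DataFrame(
            {
                "cell_id": "a",
                "family": family,
                "block": "pre",
                "trial_index": range(len(flags)),
                "responder": flags,
                "peak_amp": [1.0 + f for f in flags],
            }
        )

    def test_brush_two_of_three(self):
        out = assign_family_response(self._calls("brush", [True, True, False]))
        assert bool(out["responder"].iloc[0])

    def test_brush_one_of_three_fails(self):
        out = assign_family_response(self._calls("brush", [True, False, False]))
        assert not bool(out["responder"].iloc[0])

    def test_thermal_single_hit_suffices(self):
        out = assign_family_response(self._calls("heat", [False, True]))
        assert bool(out["responder"].iloc[0])

    def test_missing_family_raises(self):
        with pytest.raises(AssignmentError):
            assign_family_response(self._calls("heat", [True]), families=["heat", "cold"])

    def test_max_peak_across_trials(self):
        calls = self._calls("static_LT", [True, True])
        calls["peak_amp"] = [1.4, 2.6]
        out = assign_family_response(calls)
        assert out["max_peak"].iloc[0] == pytest.approx(2.6)


class TestCalibration:
    def _annotated(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        peaks = rng.uniform(0, 3.0, n)
        sig = rng.uniform(0.0, 0.4, n)
        labels = (peaks > 1.25) & (peaks > 6 * sig)
        return pd.DataFrame({"peak_amp": peaks, "noise_sigma": sig, "label": labels})

    def test_recovers_published_thresholds(self):
        """Annotations generated under (1.25, 6) give back (1.25, 6)."""
        cal = calibrate_thresholds(
            self._annotated(), np.arange(0.75, 2.01, 0.25), np.arange(3, 10)
        )
        assert cal.amp_threshold == pytest.approx(1.25)
        assert cal.sigma_mult == pytest.approx(6.0)
        assert cal.sensitivity == 1.0 and cal.specificity == 1.0

    def test_specificity_weight_favors_specificity(self):
        # overlapping classes: mislabel 10% of items
        ann = self._annotated(seed=1)
        rng = np.random.default_rng(2)
        flip = rng.random(len(ann)) < 0.10
        ann.loc[flip, "label"] = ~ann.loc[flip, "label"]
        cal = calibrate_thresholds(ann, np.arange(0.5, 2.51, 0.25), np.arange(2, 11))
        assert cal.specificity >= cal.sensitivity

    def test_auc_equals_pair_counting(self):
        ann = self._annotated(n=200, seed=3)
        cal = calibrate_thresholds(ann, [1.25], [6.0])
        pos = ann.loc[ann["label"], "peak_amp"].to_numpy()
        neg = ann.loc[~ann["label"], "peak_amp"].to_numpy()
        gt = np.sum(pos[:, None] > neg[None, :])
        eq = np.sum(pos[:, None] == neg[None, :])
        brute = (gt + 0.5 * eq) / (pos.size * neg.size)
        assert cal.auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        ann = self._annotated()
        ann["label"] = True
        with pytest.raises(CalibrationError):
            calibrate_thresholds(ann, [1.25], [6.0])


class TestCapsaicin:
    def _flat(self, level_pre, level_post, inj=400.0, n=800):
        tr = np.empty(n)
        tr[: int(inj)] = level_pre
        tr[int(inj):] = level_post
        return tr

    def test_175_percent_is_responder(self):
        call = capsaicin_responder(self._flat(0.20, 0.35), 400.0)
        assert call.responder
        assert call.pre_mean == pytest.approx(0.20)
        assert call.post_mean == pytest.approx(0.35)

    def test_125_percent_is_not(self):
        assert not capsaicin_responder(self._flat(0.20, 0.25), 400.0).responder

    def test_zero_pre_activity_is_indeterminate(self):
        call = capsaicin_responder(self._flat(0.0, 0.5), 400.0)
        assert call.indeterminate and not call.responder

    def test_windows_exclude_blind_interval(self):
        # huge activity only inside the 30 s blind spot must not matter
        tr = self._flat(0.2, 0.2)
        tr[380:420] = 50.0
        call = capsaicin_responder(tr, 400.0)
        assert call.pre_mean == pytest.approx(0.2)
        assert call.post_mean == pytest.approx(0.2)

    def test_recovery_on_population(self, capsaicin_run):
        """Planted 2x-activity cells are found; quiet cells are not flagged."""
        cells, traces, timeline, truth, dffset = capsaicin_run
        from cicada_dh.response import capsaicin_calls

        calls = capsaicin_calls(dffset, timeline)
        direct = np.array([c.capsaicin_direct for c in cells])
        resp = calls["capsaicin_responder"].to_numpy()
        assert resp[direct].mean() >= 0.9
        assert resp[~direct].mean() <= 0.05
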