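"""Generator invariants: determinism, kernel shape, noise, sensitization."""

import numpy as np
import pytest
from scipy import stats

from cicada_dh import build_response_table, preprocess_traces
from cicada_dh.errors import ConfigError
from cicada_dh.synth import (
    CellSpec,
    KernelParams,
    ProtocolConfig,
    build_protocol,
    generate_annotations,
    generate_experiment,
)


QUIET = dict(spontaneous_rate_hz=0.0)


class TestProtocol:
    def test_grid_covers_all_sites_each_trial(self):
        tl = build_protocol(ProtocolConfig())
        for fam in ("static_LT", "static_HT"):
            for block in ("pre", "post"):
                evs = tl.select(family=fam, block=block)
                for trial in (0, 1):
                    sites = {(e.grid_row, e.grid_col) for e in evs if e.trial_index == trial}
                    assert len(sites) == 16

    def test_brush_repeats_60s_apart(self):
        tl = build_protocol(ProtocolConfig())
        onsets = [e.onset_s for e in tl.select(family="brush", block="pre")]
        assert len(onsets) == 3
        np.testing.assert_allclose(np.diff(onsets), 60.0)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ConfigError):
            generate_experiment(1, ProtocolConfig(), duration_s=100.0)


class TestDeterminism:
    def test_same_seed_gives_identical_traces(self):
        proto = ProtocolConfig(include_ligands=False, include_capsaicin=False,
                               include_grid=False)
        a, _, _, _ = generate_experiment(5, proto, seed=12)
        b, _, _, _ = generate_experiment(5, proto, seed=12)
        np.testing.assert_array_equal(a.F, b.F)

    def test_different_seeds_differ(self):
        proto = ProtocolConfig(include_ligands=False, include_capsaicin=False,
                               include_grid=False)
        a, _, _, _ = generate_experiment(5, proto, seed=12)
        b, _, _, _ = generate_experiment(5, proto, seed=13)
        assert not np.array_equal(a.F, b.F)


class TestTraceModel:
    def test_zero_mech_cell_silent_at_static_events(self):
        proto = ProtocolConfig(include_dynamic=False, include_thermal=False,
                               include_capsaicin=False, include_ligands=False)
        cell = CellSpec(heat_amp=2.0, lt_amp=0.0, ht_amp=0.0, **QUIET)
        _, tl, _, truth = generate_experiment([cell], proto, seed=0)
        assert len(truth.responses) == 0

    def test_noise_only_segments_average_to_zero(self):
        proto = ProtocolConfig(include_dynamic=False, include_thermal=False,
                               include_grid=False, include_capsaicin=False,
                               include_ligands=False)
        cell = CellSpec(**QUIET)
        _, _, _, truth = generate_experiment(
            [cell], proto, seed=1, keep_dff_true=True, duration_s=2000.0
        )
        seg = truth.dff_true[0]
        se = seg.std(ddof=1) / np.sqrt(seg.size)
        assert abs(seg.mean()) <= 3 * se

    def test_event_triggered_average_shape(self):
        """ETA peaks right after onset and decays below 10% within 5 taus."""
        kp = KernelParams(noise_sd=0.02)
        proto = ProtocolConfig(include_dynamic=False, include_grid=False,
                               include_capsaicin=False, include_ligands=False,
                               n_heat=2, n_cold=0)
        cell = CellSpec(heat_amp=2.0, **QUIET)
        _, tl, _, truth = generate_experiment([cell], proto, kernel=kp, seed=2,
                                              keep_dff_true=True)
        dff = truth.dff_true[0]
        onsets = [int(e.onset_s) for e in tl.select(family="heat")]
        eta = np.mean([dff[o : o + 12] for o in onsets], axis=0)
        peak_at = int(np.argmax(eta))
        assert peak_at <= int(np.ceil(kp.rise_tau_s)) + 1  # within a frame of the rise
        five_tau = int(np.ceil(5 * kp.decay_tau_s))
        assert eta[five_tau:].max() < 0.1 * eta[peak_at]

    def test_bleach_decays_raw_fluorescence(self):
        proto = ProtocolConfig(include_dynamic=False, include_thermal=False,
                               include_grid=False, include_capsaicin=False,
                               include_ligands=False)
        kp = KernelParams(noise_sd=0.0, bleach_fraction_per_h=0.2)
        traces, _, _, _ = generate_experiment(
            [CellSpec(**QUIET)], proto, kernel=kp, seed=0, duration_s=3600.0
        )
        t_last = (traces.n_frames - 1) / traces.frame_rate_hz
        expected = traces.F[0, 0] * 0.8 ** (t_last / 3600.0)
        assert traces.F[0, -1] == pytest.approx(expected, rel=1e-9)

    def test_detection_flags_injected_lt_events(self, detection_run):
        """>= 95% of injected 2.0 dF/F static responses are detected."""
        traces, timeline, rois, truth, dffset = detection_run
        table = build_response_table(dffset, timeline)
        stim = table[table["kind"] == "stimulus"]
        pos = truth.responder_pairs()
        is_pos = np.array(
            [(c, e) in pos for c, e in zip(stim["cell_id"], stim["event_index"])]
        )
        assert is_pos.sum() >= 500
        assert stim.loc[is_pos, "responder"].mean() >= 0.95


class TestSensitization:
    def test_lt_gain_recovered_from_peaks(self):
        """Post/pre LT peak ratio across cells recovers the planted gain."""
        rng = np.random.default_rng(0)
        proto = ProtocolConfig(include_dynamic=False, include_thermal=False,
                               include_ligands=False, n_grid_trials=1)
        gain = 1.8
        cells = [
            CellSpec(lt_amp=2.0, ht_amp=2.0, lt_gain=gain,
                     rf_center=(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5)),
                     rf_radius=1.2)
            for _ in range(100)
        ]
        traces, tl, _, truth = generate_experiment(cells, proto, seed=21)
        dffset = preprocess_traces(traces)
        table = build_response_table(dffset, tl)
        lt = table[(table["family"] == "static_LT")].merge(
            truth.responses[["cell_id", "event_index", "amplitude"]],
            on=["cell_id", "event_index"],
        )  # only sites inside the RF (injected responses)
        ratios = []
        for cid, g in lt.groupby("cell_id"):
            pre = g.loc[g["block"] == "pre", "peak_amp"]
            post = g.loc[g["block"] == "post", "peak_amp"]
            if len(pre) and len(post):
                ratios.append(post.mean() / pre.mean())
        assert len(ratios) >= 50
        assert np.mean(ratios) == pytest.approx(gain, rel=0.15)


class TestAnnotations:
    def _run(self):
        proto = ProtocolConfig(include_capsaicin=False, include_ligands=False,
                               include_dynamic=False, include_thermal=False,
                               n_grid_trials=1)
        rng = np.random.default_rng(1)
        cells = [
            CellSpec(lt_amp=2.0, ht_amp=2.0,
                     rf_center=(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5)))
            for _ in range(20)
        ]
        return generate_experiment(cells, proto, seed=8)

    def test_zero_noise_labels_equal_truth(self):
        traces, tl, _, truth = self._run()
        ann = generate_annotations(traces, tl, truth, 0.0)
        assert (ann["label"] == ann["true_responder"]).all()

    def test_output_size_is_cells_times_events(self):
        traces, tl, _, truth = self._run()
        ann = generate_annotations(traces, tl, truth, 0.0)
        n_events = sum(1 for e in tl if e.kind != "injection")
        assert len(ann) == traces.n_cells * n_events

    def test_flip_rate_within_binomial_ci(self):
        traces, tl, _, truth = self._run()
        ann = generate_annotations(traces, tl, truth, 0.05, seed=2)
        flipped = (ann["label"] != ann["true_responder"]).mean()
        n = len(ann)
        lo, hi = stats.binom.interval(0.99, n, 0.05)
        assert lo / n <= flipped <= hi / n
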