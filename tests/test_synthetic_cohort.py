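"""Generator checks: IPFM beat timing, rendering contracts, cohort layout."""

import numpy as np
import pandas as pd
import pytest

from facepulse import synthetic_cohort as sc
from facepulse.chromophore_separation import RGBTrace


class TestIPFM:
    def test_unmodulated_integrator_is_metronome(self):
        p = sc.IPFMParams(t0=0.8, a_lf=0.0, a_hf=0.0, phi_lf=0.0, phi_hf=0.0)
        beats = sc.generate_beat_train(p, 8.0, seed=0)
        assert np.allclose(beats, 0.8 * np.arange(1, len(beats) + 1), atol=1e-9)
        assert np.allclose(np.diff(beats) * 1000, 800.0)

    def test_tachogram_spectrum_peaks_at_modulation_frequency(self):
        p = sc.IPFMParams(t0=1.0, a_lf=0.0, a_hf=0.1, f_hf=0.25, phi_lf=0.0, phi_hf=0.0)
        beats = sc.generate_beat_train(p, 300.0, seed=1)
        rr = np.diff(beats) * 1000
        # independent oracle: nearest-sample tachogram + plain FFT
        t = beats[1:]
        grid = np.arange(t[0], t[-1], 0.25)
        tach = np.interp(grid, t, rr)
        tach -= tach.mean()
        freqs = np.fft.rfftfreq(len(tach), 0.25)
        power = np.abs(np.fft.rfft(tach)) ** 2
        assert abs(freqs[np.argmax(power)] - 0.25) < 0.01

    @pytest.mark.parametrize(
        "params",
        [
            sc.IPFMParams(t0=0.8, a_lf=0.1, a_hf=0.1),
            sc.IPFMParams(t0=1.0, a_lf=0.3, a_hf=0.2, f_lf=0.05, f_hf=0.35),
            sc.IPFMParams(t0=0.6, a_lf=0.0, a_hf=0.4),
        ],
    )
    def test_long_run_mean_rr_equals_t0(self, params):
        beats = sc.generate_beat_train(params, 300.0, seed=3)
        mean_rr = np.mean(np.diff(beats)) * 1000
        assert abs(mean_rr - 1000 * params.t0) / (1000 * params.t0) < 0.01

    def test_rejects_nonpositive_modulation(self):
        with pytest.raises(ValueError, match="A_LF \\+ A_HF"):
            sc.IPFMParams(t0=0.8, a_lf=0.6, a_hf=0.4)

    def test_rejects_too_short_duration(self):
        with pytest.raises(ValueError, match="duration"):
            sc.generate_beat_train(sc.IPFMParams(t0=1.0), 1.5, seed=0)

    def test_lf_hf_band_power_monotone_in_amplitude_ratio(self):
        """LF/HF tachogram band power must track the A_LF/A_HF knob."""
        ratios = []
        for a_lf, a_hf in [(0.05, 0.15), (0.10, 0.10), (0.15, 0.05)]:
            p = sc.IPFMParams(
                t0=0.9, a_lf=a_lf, f_lf=0.1, a_hf=a_hf, f_hf=0.25,
                phi_lf=0.3, phi_hf=1.1,
            )
            beats = sc.generate_beat_train(p, 300.0, seed=5)
            t = beats[1:]
            rr = np.diff(beats) * 1000
            grid = np.arange(t[0], t[-1], 0.25)
            tach = np.interp(grid, t, rr)
            tach -= tach.mean()
            freqs = np.fft.rfftfreq(len(tach), 0.25)
            power = np.abs(np.fft.rfft(tach)) ** 2
            lf = power[(freqs >= 0.04) & (freqs < 0.15)].sum()
            hf = power[(freqs >= 0.15) & (freqs < 0.40)].sum()
            ratios.append(lf / hf)
        assert ratios[0] < ratios[1] < ratios[2]


class TestRender:
    def test_frame_count_contract(self):
        rp = sc.RenderParams()
        trace = sc.render_rgb_trace(np.array([1.0, 2.0]), rp, 10.0, seed=0)
        assert trace.n_frames == round(10.0 * rp.frame_rate)

    def test_empty_beats_noiseless_trace_is_constant_modulo_drift(self):
        rp = sc.RenderParams(noise_sd=0.0, shade_modulation=0.0, melanin_drift=0.0)
        trace = sc.render_rgb_trace(np.empty(0), rp, 10.0, seed=0)
        assert np.allclose(trace.samples, trace.samples[0])

    def test_rejects_beats_outside_duration(self):
        with pytest.raises(ValueError, match="within"):
            sc.render_rgb_trace(np.array([5.0, 12.0]), sc.RenderParams(), 10.0, seed=0)

    def test_rejects_non_unit_hb_direction(self):
        with pytest.raises(ValueError, match="unit"):
            sc.RenderParams(hb_direction=(1.0, 1.0, 0.0))

    def test_rgb_values_in_unit_interval(self):
        beats = sc.generate_beat_train(sc.IPFMParams(), 30.0, seed=2)
        trace = sc.render_rgb_trace(beats, sc.RenderParams(), 30.0, seed=2)
        assert isinstance(trace, RGBTrace)
        assert trace.samples.min() > 0 and trace.samples.max() <= 1


class TestSessions:
    def test_session_structure_and_determinism(self, tiny_cohort_config):
        seq = np.random.SeedSequence([1, 2])
        s1 = sc.generate_session(tiny_cohort_config, "TD01", "TD", seq)
        s2 = sc.generate_session(
            tiny_cohort_config, "TD01", "TD", np.random.SeedSequence([1, 2])
        )
        assert set(s1.conditions) == set(sc.CLIP_NAMES)
        for clip in sc.CLIP_NAMES:
            a, b = s1.conditions[clip], s2.conditions[clip]
            np.testing.assert_array_equal(a.baseline.beats, b.baseline.beats)
            np.testing.assert_array_equal(
                a.clip_segment.trace.samples, b.clip_segment.trace.samples
            )
            assert np.all(np.diff(a.clip_segment.beats) > 0)

    def test_zero_effect_means_identical_parameter_distributions(self, tiny_cohort_config):
        s = sc.generate_session(
            tiny_cohort_config, "ASD01", "ASD", np.random.SeedSequence([4, 0])
        )
        for cond in s.conditions.values():
            assert cond.baseline.params.a_lf == cond.clip_segment.params.a_lf
            assert cond.baseline.params.t0 == cond.clip_segment.params.t0

    def test_group_effect_shifts_clip_parameters_only(self):
        config = sc.CohortConfig(
            group_effects={"ASD": {"happy": (0.0, -0.05, 0.0)}}, master_seed=0
        )
        s = sc.generate_session(config, "ASD01", "ASD", np.random.SeedSequence(9), render=False)
        happy = s.conditions["happy"]
        assert happy.clip_segment.params.a_lf == pytest.approx(
            max(0.0, happy.baseline.params.a_lf - 0.05)
        )
        neutral = s.conditions["neutral"]
        assert neutral.clip_segment.params.a_lf == neutral.baseline.params.a_lf

    def test_asd_lf_suppression_lowers_cohort_mean_delta_lf_hf(self):
        """Monte-Carlo: an A_LF-lowering effect during social clips must
        depress the ASD group's mean LF/HF change from baseline."""
        from facepulse.feature_pipeline import feature_table_from_cohort

        config = sc.CohortConfig(
            n_td=26,
            n_asd=26,
            group_effects={
                "ASD": {c: (0.0, -0.05, 0.0) for c in ("happy", "fear", "sad")}
            },
            master_seed=21,
        )
        cohort = sc.generate_cohort(config, render=False)
        table = feature_table_from_cohort(cohort, from_truth=True)
        social = [f"lf_hf_fft_{c}" for c in ("happy", "fear", "sad")]
        mean_delta = table.groupby("group")[social].mean().mean(axis=1)
        assert mean_delta["ASD"] < mean_delta["TD"]


class TestCohortIO:
    def test_write_cohort_layout_and_roundtrip(self, tmp_path):
        config = sc.CohortConfig(
            n_td=21,
            n_asd=17,
            clip_durations={c: 12.0 for c in sc.CLIP_NAMES},
            baseline_duration=8.0,
            master_seed=5,
        )
        cohort = sc.generate_cohort(config, render=True)
        manifest = sc.write_cohort(cohort, tmp_path)
        assert len(manifest) == 38 * 12
        assert manifest["group"].value_counts().to_dict() == {"TD": 21 * 12, "ASD": 17 * 12}
        assert (
            manifest.drop_duplicates("participant")["group"].value_counts().to_dict()
            == {"TD": 21, "ASD": 17}
        )
        row = manifest.iloc[0]
        trace = sc.read_trace(tmp_path / row["path"], frame_rate=row["frame_rate"])
        original = cohort[0].conditions[row["condition"]]
        seg = original.baseline if row["segment"] == "baseline" else original.clip_segment
        np.testing.assert_array_equal(trace.samples, seg.trace.samples)

    def test_manifest_collision_is_an_error(self, tmp_path):
        config = sc.CohortConfig(
            n_td=1, n_asd=1,
            clip_durations={c: 5.0 for c in sc.CLIP_NAMES},
            baseline_duration=5.0, master_seed=6,
        )
        cohort = sc.generate_cohort(config, render=True)
        sc.write_cohort(cohort, tmp_path)
        with pytest.raises(FileExistsError):
            sc.write_cohort(cohort, tmp_path)

    def test_byte_identical_output_under_fixed_master_seed(self, tmp_path):
        config = sc.CohortConfig(
            n_td=1, n_asd=1,
            clip_durations={c: 5.0 for c in sc.CLIP_NAMES},
            baseline_duration=5.0, master_seed=6,
        )
        m1 = sc.write_cohort(sc.generate_cohort(config, render=True), tmp_path / "a")
        sc.write_cohort(sc.generate_cohort(config, render=True), tmp_path / "b")
        for name in [*m1["path"], "manifest.csv"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
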