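"""Token synthesis, cue manipulation, and acoustic measurement."""

import numpy as np
import pytest

from stressmmn import (
    ConstraintError,
    CueManipulation,
    CueMeasurement,
    DataError,
    WordSpec,
    apply_cue_manipulation,
    cue_change_table,
    measure_cues,
    standard_word,
    synthesize_word,
)
from stressmmn.stimuli import REF_RMS, SyllableSpec, _autocorr_f0

F0_TOL = 0.01  # relative
DB_TOL = 0.2
MS_TOL = 1000.0 / 44100.0  # one sample


class TestSynthesisAndMeasurement:
    def test_standard_token_reproduces_spec_cues(self, std_measured):
        _, _, _, (m1, m2) = std_measured
        assert m1.f0_hz == pytest.approx(210.53, rel=F0_TOL)
        assert m1.intensity_db == pytest.approx(73.0, abs=DB_TOL)
        assert m1.syllable_duration_ms == pytest.approx(176.0, abs=MS_TOL)
        assert m2.f0_hz == pytest.approx(222.22, rel=F0_TOL)
        assert m2.intensity_db == pytest.approx(71.0, abs=DB_TOL)
        assert m2.syllable_duration_ms == pytest.approx(282.0, abs=MS_TOL)

    def test_first_syllable_deviant_cues(self, deviant_measured):
        _, (d1, _) = deviant_measured["pitch_syll1"]
        assert d1.f0_hz == pytest.approx(231.88, rel=F0_TOL)
        _, (d1, _) = deviant_measured["intensity_syll1"]
        assert d1.intensity_db == pytest.approx(79.0, abs=DB_TOL)
        _, (d1, _) = deviant_measured["duration_syll1"]
        assert d1.syllable_duration_ms == pytest.approx(220.0, abs=0.01)

    @pytest.mark.parametrize("dtype", [
        "pitch_syll1", "intensity_syll1", "duration_syll1",
        "pitch_syll2", "intensity_syll2", "duration_syll2",
    ])
    def test_round_trip_reproduces_requested_change_only(
        self, std_measured, deviant_measured, dtype
    ):
        """Manipulate -> synthesize -> measure recovers the one requested cue
        change and leaves the other two cues unchanged within tolerance."""
        _, _, _, std = std_measured
        _, dev = deviant_measured[dtype]
        target = int(dtype[-1]) - 1
        cue = dtype.rsplit("_", 1)[0]
        s, d = std[target], dev[target]
        expected = {
            "pitch": (1.10, 0.0, 1.0),
            "intensity": (1.0, 6.0, 1.0),
            "duration": (1.0, 0.0, 1.7),
        }[cue]
        assert d.f0_hz / s.f0_hz == pytest.approx(expected[0], rel=F0_TOL)
        assert d.intensity_db - s.intensity_db == pytest.approx(expected[1], abs=DB_TOL)
        assert d.vowel_duration_ms / s.vowel_duration_ms == pytest.approx(
            expected[2], rel=0.01
        )
        # untouched syllable is bit-identical in spec terms
        other_s, other_d = std[1 - target], dev[1 - target]
        assert other_d.f0_hz == pytest.approx(other_s.f0_hz, rel=1e-6)
        assert other_d.syllable_duration_ms == other_s.syllable_duration_ms

    def test_intensity_increase_scales_rms_closed_form(self, std_measured, deviant_measured):
        """+6 dB multiplies the target syllable's RMS by 10^(6/20)."""
        spec, wave, segments, _ = std_measured
        dspec, _ = deviant_measured["intensity_syll1"]
        dwave, dsegments = synthesize_word(dspec)
        fs = spec.sample_rate_hz
        n1 = int(round(176.0 * fs / 1000.0))
        rms = np.sqrt(np.mean(wave[:n1] ** 2))
        drms = np.sqrt(np.mean(dwave[:n1] ** 2))
        assert drms / rms == pytest.approx(10 ** (6 / 20), rel=1e-6)

    def test_doubling_durations_doubles_sample_count(self):
        spec = standard_word()
        doubled = WordSpec(
            tuple(
                SyllableSpec(
                    s.f0_hz,
                    s.intensity_db,
                    2 * s.duration_ms,
                    (2 * s.vowel_interval_ms[0], 2 * s.vowel_interval_ms[1]),
                )
                for s in spec.syllables
            )
        )
        w1, _ = synthesize_word(spec)
        w2, _ = synthesize_word(doubled)
        assert abs(len(w2) - 2 * len(w1)) <= 1

    def test_pure_pulse_train_f0(self):
        fs = 44100
        x = np.zeros(fs // 5)
        x[np.round(np.arange(0, len(x) - 1, fs / 200.0)).astype(int)] = 1.0
        f0, voiced = _autocorr_f0(x, fs)
        assert voiced
        assert f0 == pytest.approx(200.0, rel=F0_TOL)

    def test_halved_amplitude_drops_6db(self, std_measured):
        _, wave, segments, (m1, _) = std_measured
        h1, _ = measure_cues(0.5 * wave, segments)
        assert m1.intensity_db - h1.intensity_db == pytest.approx(6.02, abs=0.1)

    def test_unvoiced_span_flags_no_f0(self):
        fs = 44100
        rng = np.random.default_rng(0)
        wave = rng.standard_normal(int(0.5 * fs)) * REF_RMS
        segments = [
            (0.0, 250.0, "syll1"), (0.0, 100.0, "vowel1"),
            (250.0, 500.0, "syll2"), (300.0, 400.0, "vowel2"),
        ]
        m1, m2 = measure_cues(wave, segments, fs)
        assert not m1.voiced and not m2.voiced
        assert np.isnan(m1.f0_hz)

    def test_synthesis_deterministic(self):
        w1, _ = synthesize_word(standard_word())
        w2, _ = synthesize_word(standard_word())
        assert np.array_equal(w1, w2)


class TestManipulationContracts:
    def test_duration_math_from_vowel_prolongation(self):
        spec = standard_word()
        out = apply_cue_manipulation(spec, CueManipulation.duration(1))
        assert out.syllables[0].duration_ms == pytest.approx(176 + 0.7 * 62.86)
        assert out.syllables[0].duration_ms == pytest.approx(220.0, abs=0.01)
        # consonant span unchanged
        assert (
            out.syllables[0].duration_ms - out.syllables[0].vowel_duration_ms
            == pytest.approx(176.0 - 62.86)
        )

    def test_identity_manipulation_rejected(self):
        with pytest.raises(ConstraintError, match="exactly one cue"):
            CueManipulation(1)

    def test_double_manipulation_rejected(self):
        with pytest.raises(ConstraintError):
            CueManipulation(1, pitch_ratio=1.1, intensity_delta_db=6.0)

    def test_invalid_target_syllable_rejected(self):
        with pytest.raises(ConstraintError):
            CueManipulation(3, pitch_ratio=1.1)

    def test_zero_duration_vowel_rejected(self):
        with pytest.raises(ConstraintError):
            SyllableSpec(210.0, 73.0, 176.0, (50.0, 50.0))

    def test_aliasing_prone_spec_rejected(self):
        with pytest.raises(ConstraintError):
            WordSpec(
                (
                    SyllableSpec(300.0, 73.0, 176.0, (0.0, 60.0)),
                    SyllableSpec(300.0, 71.0, 282.0, (100.0, 180.0)),
                ),
                sample_rate_hz=1000,
            )

    def test_other_fields_bit_identical(self):
        spec = standard_word()
        out = apply_cue_manipulation(spec, CueManipulation.pitch(2))
        assert out.syllables[0] == spec.syllables[0]
        assert out.syllables[1].intensity_db == spec.syllables[1].intensity_db
        assert out.syllables[1].duration_ms == spec.syllables[1].duration_ms


class TestCueChangeTable:
    def test_printed_duration_increases(self):
        first = cue_change_table(
            CueMeasurement(210.53, 73.0, 176.0, 62.86),
            CueMeasurement(210.53, 73.0, 220.0, 106.86),
        )
        second = cue_change_table(
            CueMeasurement(222.22, 71.0, 282.0, 81.43),
            CueMeasurement(222.22, 71.0, 339.0, 138.43),
        )
        assert first.duration_percent == 25
        assert second.duration_percent == 20

    def test_printed_pitch_increase(self):
        change = cue_change_table(
            CueMeasurement(210.53, 73.0, 176.0, 62.86),
            CueMeasurement(231.88, 73.0, 176.0, 62.86),
        )
        assert change.pitch_percent == 10

    def test_identity_measurements(self):
        m = CueMeasurement(210.53, 73.0, 176.0, 62.86)
        change = cue_change_table(m, m)
        assert (change.pitch_percent, change.intensity_delta_db, change.duration_percent) == (
            0, 0.0, 0,
        )

    def test_zero_standard_rejected(self):
        with pytest.raises(DataError):
            cue_change_table(
                CueMeasurement(float("nan"), 73.0, 176.0, 62.0),
                CueMeasurement(231.0, 73.0, 176.0, 62.0),
            )
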