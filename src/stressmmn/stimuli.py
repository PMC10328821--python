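"""Parametric two-syllable word synthesis, stress-cue manipulation and measurement.

A word token is described by a :class:`WordSpec` (per-syllable fundamental
frequency, RMS intensity, duration, and the vowel interval within the
syllable).  Synthesis is a glottal-pulse train through two fixed formant
resonators for the vowel, plus a deterministic inharmonic band of high
partials for the consonantal remainder — crude as speech, but with exactly
measurable ground-truth cues and no text-to-speech dependency.

The three stress-cue manipulations mirror the study design: syllable pitch
x1.10, syllable intensity +6 dB, vowel duration x1.7 (consonants untouched).
Intensity is expressed in dB re a fixed reference RMS of 1e-5 full scale
(so 100 dB corresponds to unit RMS); the absolute dB values of the token
table are matched by construction of the spec, not by SPL calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import ConstraintError, DataError

#: dB reference: intensity_db = 20*log10(rms / REF_RMS).
REF_RMS = 1e-5

#: Fixed formant resonators (Hz, bandwidth Hz) applied to the voiced source.
FORMANTS = ((500.0, 80.0), (1500.0, 120.0))

#: Deterministic inharmonic partials used for consonant spans (Hz).
_CONSONANT_PARTIALS = (
    1913.0, 2203.0, 2531.0, 2897.0, 3301.0, 3643.0,
    4021.0, 4409.0, 4801.0, 5171.0, 5557.0, 5923.0,
)
_CONSONANT_LEVEL = 0.3  # consonant RMS relative to vowel RMS before scaling

OFFSET_RAMP_MS = 5.0
F0_SEARCH_HZ = (75.0, 400.0)
VOICING_THRESHOLD = 0.5


@dataclass(frozen=True)
class SyllableSpec:
    f0_hz: float
    intensity_db: float
    duration_ms: float
    vowel_interval_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ConstraintError("syllable duration must be positive")
        start, end = self.vowel_interval_ms
        if not (0.0 <= start < end <= self.duration_ms):
            raise ConstraintError(
                "vowel interval must be a non-empty span inside the syllable"
            )
        if self.f0_hz <= 0:
            raise ConstraintError("f0 must be positive")

    @property
    def vowel_duration_ms(self) -> float:
        start, end = self.vowel_interval_ms
        return end - start


@dataclass(frozen=True)
class WordSpec:
    syllables: tuple[SyllableSpec, SyllableSpec]
    sample_rate_hz: int = 44100

    def __post_init__(self) -> None:
        nyquist = self.sample_rate_hz / 2.0
        for syll in self.syllables:
            if syll.f0_hz >= self.sample_rate_hz / 4.0:
                raise ConstraintError("f0 must stay below sample_rate / 4")
        if max(f for f, _ in FORMANTS) + max(b for _, b in FORMANTS) >= nyquist:
            raise ConstraintError("formants above Nyquist for this sample rate")


def standard_word(sample_rate_hz: int = 44100) -> WordSpec:
    """The neutral (unstressed) token.

    Cue values per syllable: 210.53 Hz / 73 dB / 176 ms and
    222.22 Hz / 71 dB / 282 ms.  Vowel spans (62.86 and 81.43 ms) are
    back-solved so that a x1.7 vowel prolongation yields syllable durations
    of 220 ms (+25%) and 339 ms (+20%) respectively.
    """
    return WordSpec(
        syllables=(
            SyllableSpec(210.53, 73.0, 176.0, (0.0, 62.86)),
            SyllableSpec(222.22, 71.0, 282.0, (100.0, 181.43)),
        ),
        sample_rate_hz=sample_rate_hz,
    )


@dataclass(frozen=True)
class CueManipulation:
    """Exactly one active cue change on exactly one syllable."""

    target_syllable: int  # 1 or 2
    pitch_ratio: float = 1.0
    intensity_delta_db: float = 0.0
    duration_factor: float = 1.0  # applied to the vowel span only

    def __post_init__(self) -> None:
        if self.target_syllable not in (1, 2):
            raise ConstraintError("target_syllable must be 1 or 2")
        if self.pitch_ratio <= 0 or self.duration_factor <= 0:
            raise ConstraintError("ratios/factors must be positive")
        active = [self.pitch_ratio != 1.0, self.intensity_delta_db != 0.0,
                  self.duration_factor != 1.0]
        if sum(active) != 1:
            raise ConstraintError(
                "exactly one cue must differ from identity (no active cue or "
                "multiple active cues rejected)"
            )

    @classmethod
    def pitch(cls, target_syllable: int, ratio: float = 1.10) -> "CueManipulation":
        return cls(target_syllable, pitch_ratio=ratio)

    @classmethod
    def intensity(cls, target_syllable: int, delta_db: float = 6.0) -> "CueManipulation":
        return cls(target_syllable, intensity_delta_db=delta_db)

    @classmethod
    def duration(cls, target_syllable: int, factor: float = 1.7) -> "CueManipulation":
        return cls(target_syllable, duration_factor=factor)

    @classmethod
    def for_deviant(cls, deviant_type: str) -> "CueManipulation":
        """Default manipulation for a deviant label like ``"pitch_syll2"``."""
        cue, position = deviant_type.rsplit("_", 1)
        target = int(position[-1])
        return {"pitch": cls.pitch, "intensity": cls.intensity,
                "duration": cls.duration}[cue](target)


def apply_cue_manipulation(spec: WordSpec, manip: CueManipulation) -> WordSpec:
    """Return a new spec with the single requested cue change applied."""
    idx = manip.target_syllable - 1
    syll = spec.syllables[idx]
    if manip.pitch_ratio != 1.0:
        syll = replace(syll, f0_hz=syll.f0_hz * manip.pitch_ratio)
    elif manip.intensity_delta_db != 0.0:
        syll = replace(syll, intensity_db=syll.intensity_db + manip.intensity_delta_db)
    else:
        start, end = syll.vowel_interval_ms
        grown = (end - start) * manip.duration_factor
        syll = replace(
            syll,
            duration_ms=syll.duration_ms - (end - start) + grown,
            vowel_interval_ms=(start, start + grown),
        )
    syllables = list(spec.syllables)
    syllables[idx] = syll
    return replace(spec, syllables=tuple(syllables))


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _resonator_sos(fs: float) -> np.ndarray:
    sections = []
    for freq, bw in FORMANTS:
        r = np.exp(-np.pi * bw / fs)
        theta = 2 * np.pi * freq / fs
        # unit-gain-at-resonance two-pole section
        b0 = (1 - r) * np.sqrt(1 + r * r - 2 * r * np.cos(2 * theta))
        sections.append([b0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r])
    return np.array(sections)


def _synthesize_syllable(syll: SyllableSpec, fs: int, n_samples: int) -> np.ndarray:
    vowel_a = int(round(syll.vowel_interval_ms[0] * fs / 1000.0))
    vowel_b = int(round(syll.vowel_interval_ms[1] * fs / 1000.0))
    vowel_b = min(vowel_b, n_samples)

    # voiced source: impulse train at f0 within the vowel span
    source = np.zeros(n_samples)
    period = fs / syll.f0_hz
    positions = vowel_a + np.round(np.arange(0, vowel_b - vowel_a - 1e-9, period)).astype(int)
    positions = positions[positions < vowel_b]
    source[positions] = 1.0
    voiced = sps.sosfilt(_resonator_sos(fs), source)

    # deterministic unvoiced consonant band outside the vowel span
    t = np.arange(n_samples) / fs
    band = np.zeros(n_samples)
    for i, freq in enumerate(_CONSONANT_PARTIALS):
        band += np.sin(2 * np.pi * freq * t + 0.37 * i * i)
    mask = np.ones(n_samples, dtype=bool)
    mask[vowel_a:vowel_b] = False
    vowel_rms = np.sqrt(np.mean(voiced[vowel_a:vowel_b] ** 2))
    if mask.any():
        band_rms = np.sqrt(np.mean(band[mask] ** 2))
        band *= _CONSONANT_LEVEL * vowel_rms / band_rms
        voiced[mask] += band[mask]

    rms = np.sqrt(np.mean(voiced**2))
    target = REF_RMS * 10.0 ** (syll.intensity_db / 20.0)
    return voiced * (target / rms)


def synthesize_word(spec: WordSpec) -> tuple[np.ndarray, list[tuple[float, float, str]]]:
    """Synthesize a word token.

    Returns the mono waveform and segment annotations
    ``(start_ms, end_ms, label)`` with labels ``syll1/vowel1/syll2/vowel2``.
    Syllable boundaries sit on a cumulative-rounded sample grid so that
    scaling all durations scales the total sample count proportionally
    (within one sample).  A 5 ms cosine offset ramp is applied at word end.
    """
    fs = spec.sample_rate_hz
    cum = np.cumsum([0.0] + [s.duration_ms for s in spec.syllables])
    bounds = np.round(cum * fs / 1000.0).astype(int)
    wave = np.zeros(bounds[-1])
    segments: list[tuple[float, float, str]] = []
    for i, syll in enumerate(spec.syllables):
        n = bounds[i + 1] - bounds[i]
        wave[bounds[i]:bounds[i + 1]] = _synthesize_syllable(syll, fs, n)
        offset = cum[i]
        segments.append((offset, offset + syll.duration_ms, f"syll{i + 1}"))
        va, vb = syll.vowel_interval_ms
        segments.append((offset + va, offset + vb, f"vowel{i + 1}"))

    n_ramp = min(int(round(OFFSET_RAMP_MS * fs / 1000.0)), len(wave))
    if n_ramp > 1:
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_ramp)))
        wave[-n_ramp:] *= ramp
    return wave, segments


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueMeasurement:
    f0_hz: float
    intensity_db: float
    syllable_duration_ms: float
    vowel_duration_ms: float
    voiced: bool = True


def _autocorr_f0(x: np.ndarray, fs: float) -> tuple[float, bool]:
    """F0 by normalized autocorrelation peak, searched in 75-400 Hz."""
    x = x - np.mean(x)
    if np.max(np.abs(x)) <= 0:
        return float("nan"), False
    lag_min = int(np.floor(fs / F0_SEARCH_HZ[1]))
    lag_max = int(np.ceil(fs / F0_SEARCH_HZ[0]))
    if lag_max >= len(x):
        return float("nan"), False
    full = np.correlate(x, x, mode="full")
    acf = full[len(x) - 1:]
    acf = acf / acf[0]
    # a fractional-sample period splits the autocorrelation peak across two
    # adjacent lags, so peak-pick and threshold on the 3-lag sum and read the
    # lag off the local centroid
    lags = np.arange(lag_min, lag_max + 1)
    score = acf[lags - 1] + acf[lags] + acf[lags + 1]
    k = int(lags[np.argmax(score)])
    if score[k - lag_min] < VOICING_THRESHOLD:
        return float("nan"), False
    neighborhood = np.clip(acf[k - 1:k + 2], 0.0, None)
    if neighborhood.sum() == 0:
        return float("nan"), False
    lag = float(np.dot([k - 1, k, k + 1], neighborhood) / neighborhood.sum())
    return fs / lag, True


def measure_cues(
    wave: np.ndarray,
    segments: Sequence[tuple[float, float, str]],
    sample_rate_hz: int = 44100,
) -> tuple[CueMeasurement, CueMeasurement]:
    """Measure pitch, intensity and durations of both syllables.

    F0 comes from the autocorrelation peak over the annotated vowel span,
    intensity is 20*log10(RMS/REF_RMS) over the whole syllable, durations
    are read from the annotations.  An unvoiced or silent vowel span yields
    a "no F0" flag rather than an error.
    """
    spans = {label: (a, b) for a, b, label in segments}
    for needed in ("syll1", "vowel1", "syll2", "vowel2"):
        if needed not in spans:
            raise DataError(f"missing segment annotation '{needed}'")
    fs = sample_rate_hz
    out = []
    for i in (1, 2):
        sa, sb = spans[f"syll{i}"]
        va, vb = spans[f"vowel{i}"]
        syll = wave[int(round(sa * fs / 1000)):int(round(sb * fs / 1000))]
        vowel = wave[int(round(va * fs / 1000)):int(round(vb * fs / 1000))]
        if syll.size == 0 or vowel.size == 0:
            raise DataError(f"empty segment span for syllable {i}")
        f0, voiced = _autocorr_f0(vowel, fs)
        rms = np.sqrt(np.mean(syll**2))
        intensity = 20.0 * np.log10(rms / REF_RMS) if rms > 0 else float("-inf")
        out.append(
            CueMeasurement(
                f0_hz=f0,
                intensity_db=intensity,
                syllable_duration_ms=sb - sa,
                vowel_duration_ms=vb - va,
                voiced=voiced,
            )
        )
    return out[0], out[1]


@dataclass(frozen=True)
class CueChange:
    pitch_percent: int
    intensity_delta_db: float
    duration_percent: int


def cue_change_table(standard: CueMeasurement, deviant: CueMeasurement) -> CueChange:
    """Per-cue standard-to-deviant change (pitch/duration % rounded, dB delta)."""
    if not standard.f0_hz or standard.syllable_duration_ms == 0:
        raise DataError("standard cue values must be non-zero")
    if not (np.isfinite(standard.f0_hz) and np.isfinite(deviant.f0_hz)):
        raise DataError("both measurements must be finite")
    return CueChange(
        pitch_percent=int(round(100.0 * (deviant.f0_hz / standard.f0_hz - 1.0))),
        intensity_delta_db=deviant.intensity_db - standard.intensity_db,
        duration_percent=int(
            round(100.0 * (deviant.syllable_duration_ms / standard.syllable_duration_ms - 1.0))
        ),
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_wav(path: str, wave: np.ndarray, sample_rate_hz: int = 44100) -> None:
    """Write PCM 16-bit WAV (clipping guarded)."""
    scaled = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (scaled * 32767).astype(np.int16))


def write_segments(path: str, segments: Sequence[tuple[float, float, str]]) -> None:
    """Plain-text label file: start_ms, end_ms, label per line."""
    with open(path, "w") as fh:
        fh.write("start_ms\tend_ms\tlabel\n")
        for a, b, label in segments:
            fh.write(f"{a:.3f}\t{b:.3f}\t{label}\n")
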