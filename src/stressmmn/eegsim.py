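"""Synthetic oddball EEG generator.

Simulates multichannel recordings (Fz, FCz, Cz and the two mastoids M1/M2,
nose reference implicit) in which every stimulus evokes a stereotyped
response and every deviant additionally carries a Gaussian MMN whose
frontocentral negativity inverts polarity at the mastoids.  Broadband
1/f-shaped noise and occasional high-amplitude transients (for exercising
threshold-based epoch rejection) complete the picture.

Amplitude convention
--------------------
Group/subject amplitudes are calibrated in *measured* units: an injected
amplitude ``A`` is defined as the mean amplitude the analysis pipeline
reads out of the 70%-of-peak MMN window at mastoid-referenced FCz.  Since
the window-mean of a unit-peak Gaussian over its 70% window is ~0.8926,
the underlying Gaussian peak is scaled by the inverse of that gain
(computed exactly on the analysis sample grid).  This makes the noiseless
injected-vs-recovered identity exact and lets group means be set directly
to published window-mean values.  ``ErpTemplateSpec.amplitude_mode="peak"``
switches to the raw convention where ``A`` is the Gaussian trough itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigError, DataError
from .paradigm import DEVIANT_TYPES, STANDARD, EventSequence

CHANNELS = ("Fz", "FCz", "Cz", "M1", "M2")
SFREQ = 500.0

#: nose-referenced scalp weights of the frontocentral component topography
SCALP_WEIGHTS = {"Fz": 0.8, "FCz": 1.0, "Cz": 0.9}

#: onset of the physical deviation within the word, per deviant type (ms)
DEVIATION_ONSETS_MS = {
    "pitch_syll1": 0.0,
    "intensity_syll1": 0.0,
    "duration_syll1": 50.0,
    "pitch_syll2": 175.0,
    "intensity_syll2": 175.0,
    "duration_syll2": 225.0,
}

#: default peak-search range relative to deviation onset (ms)
SEARCH_OFFSET_MS = (100.0, 350.0)
WINDOW_THRESHOLD = 0.7

TEMPLATE_N_SAMPLES = 300  # 0..598 ms at 500 Hz


@dataclass(frozen=True)
class GroupParams:
    """Per-group true MMN amplitude distribution for the six deviant cells."""

    label: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for t in DEVIANT_TYPES:
            if t not in self.means or t not in self.sds:
                raise ConfigError(f"missing cell parameters for deviant type {t!r}")
            if self.sds[t] < 0:
                raise ConfigError("cell SDs must be >= 0")

    @classmethod
    def from_position_marginals(
        cls,
        label: str,
        syll1_mean: float,
        syll1_sd: float,
        syll2_mean: float,
        syll2_sd: float,
    ) -> "GroupParams":
        """Build cell parameters from position marginals with zero cue offsets."""
        means, sds = {}, {}
        for t in DEVIANT_TYPES:
            first = t.endswith("syll1")
            means[t] = syll1_mean if first else syll2_mean
            sds[t] = syll1_sd if first else syll2_sd
        return cls(label, means, sds)


def german_defaults() -> GroupParams:
    return GroupParams.from_position_marginals("German", -1.62, 1.81, -3.53, 1.80)


def slavic_defaults() -> GroupParams:
    return GroupParams.from_position_marginals("Slavic", -2.35, 1.28, -3.30, 1.88)


@dataclass(frozen=True)
class ErpTemplateSpec:
    """Shape parameters of the simulated event-locked responses.

    The standard response is a P1/N1/P2 triplet of Gaussians (invented
    plumbing creating realistic component overlap; it cancels in difference
    waves).  The MMN is a Gaussian of width ``mmn_width_ms`` peaking
    ``mmn_peak_lag_ms`` after the deviation onset of the deviant type, split
    across channels so that FCz carries ``kappa*P`` and each mastoid
    ``-(1-kappa)*P`` of the (signed) peak ``P`` in nose-referenced space;
    mastoid-referenced FCz then carries the full component.
    """

    standard_components: tuple[tuple[float, float, float], ...] = (
        (1.0, 50.0, 20.0),   # P1: amplitude uV, latency ms, width ms
        (-2.0, 100.0, 20.0),
        (1.5, 200.0, 20.0),
    )
    mmn_peak_lag_ms: float = 195.0
    mmn_width_ms: float = 25.0
    deviation_onsets_ms: tuple[tuple[str, float], ...] = tuple(DEVIATION_ONSETS_MS.items())
    kappa: float = 0.7
    amplitude_mode: str = "window_mean"  # or "peak"

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa <= 1.0:
            raise ConfigError("kappa must be in (0, 1]")
        if self.amplitude_mode not in ("window_mean", "peak"):
            raise ConfigError("amplitude_mode must be 'window_mean' or 'peak'")

    @property
    def onsets(self) -> dict[str, float]:
        return dict(self.deviation_onsets_ms)


@dataclass(frozen=True)
class NoiseSpec:
    """Spectrally shaped noise plus rejectable artifact transients."""

    exponent: float = 1.0  # 1/f^alpha
    rms_uv: float = 10.0
    artifact_fraction: float = 0.05
    artifact_amplitude_uv: float = 150.0
    artifact_duration_ms: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rms_uv < 0:
            raise ConfigError("noise RMS must be >= 0")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ConfigError("artifact fraction must be in [0, 1]")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with stimulus markers."""

    ch_names: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # [channels x samples], uV
    markers: list[tuple[str, int]]
    reference: str = "nose"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise DataError("data must be [channels x samples]")
        n = self.data.shape[1]
        for label, sample in self.markers:
            if not 0 <= sample < n:
                raise DataError(f"marker {label!r} at sample {sample} out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# amplitudes and templates
# ---------------------------------------------------------------------------

def draw_subject_amplitudes(
    params: GroupParams, n_subjects: int, seed: int
) -> np.ndarray:
    """Draw [subject x 6 cells] true amplitudes ~ Normal(mean, SD), cells independent.

    Column order follows :data:`stressmmn.paradigm.DEVIANT_TYPES`.
    """
    if n_subjects < 1:
        raise DataError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.array([params.means[t] for t in DEVIANT_TYPES])
    sds = np.array([params.sds[t] for t in DEVIANT_TYPES])
    return means + sds * rng.standard_normal((n_subjects, len(DEVIANT_TYPES)))


def template_times_ms(sfreq: float = SFREQ) -> np.ndarray:
    return np.arange(TEMPLATE_N_SAMPLES) * 1000.0 / sfreq


@lru_cache(maxsize=64)
def _window_gain(onset_ms: float, lag_ms: float, width_ms: float, sfreq: float) -> float:
    """Window-mean of a unit-peak Gaussian over its own 70%-of-peak window.

    Computed with the same window-determination code the analysis pipeline
    uses, on the same sample grid, so the calibration is exact by
    construction.
    """
    from .mmn_stats import find_mmn_window  # local import avoids a cycle

    times = template_times_ms(sfreq)
    mu = onset_ms + lag_ms
    trace = -np.exp(-0.5 * ((times - mu) / width_ms) ** 2)
    window = find_mmn_window(
        trace,
        times,
        significant=np.ones_like(times, dtype=bool),
        search_range_ms=(onset_ms + SEARCH_OFFSET_MS[0], onset_ms + SEARCH_OFFSET_MS[1]),
        threshold_fraction=WINDOW_THRESHOLD,
    )
    inside = (times >= window.start_ms) & (times <= window.end_ms)
    return float(-np.mean(trace[inside]))


def mmn_gain(deviant_type: str, spec: ErpTemplateSpec, sfreq: float = SFREQ) -> float:
    """Measured-amplitude / Gaussian-peak ratio for one deviant type."""
    onset = spec.onsets[deviant_type]
    return _window_gain(onset, spec.mmn_peak_lag_ms, spec.mmn_width_ms, sfreq)


def make_erp_template(
    condition: str,
    amplitude: float,
    spec: ErpTemplateSpec,
    sfreq: float = SFREQ,
) -> np.ndarray:
    """Per-channel event-locked waveform (0-600 ms) for one condition.

    ``condition`` is ``"standard"`` or one of the six deviant types; the
    deviant template is the standard template plus the MMN term.
    """
    if condition != STANDARD and condition not in spec.onsets:
        raise DataError(f"unknown condition label {condition!r}")
    times = template_times_ms(sfreq)
    out = np.zeros((len(CHANNELS), TEMPLATE_N_SAMPLES))

    for amp, lat, width in spec.standard_components:
        shape = amp * np.exp(-0.5 * ((times - lat) / width) ** 2)
        for c, name in enumerate(CHANNELS):
            out[c] += SCALP_WEIGHTS.get(name, 0.0) * shape

    if condition != STANDARD:
        onset = spec.onsets[condition]
        peak = amplitude
        if spec.amplitude_mode == "window_mean":
            peak = amplitude / mmn_gain(condition, spec, sfreq)
        mu = onset + spec.mmn_peak_lag_ms
        shape = np.exp(-0.5 * ((times - mu) / spec.mmn_width_ms) ** 2)
        for c, name in enumerate(CHANNELS):
            if name in ("M1", "M2"):
                out[c] += -(1.0 - spec.kappa) * peak * shape
            else:
                out[c] += SCALP_WEIGHTS[name] * spec.kappa * peak * shape
    return out


def deviant_search_ranges(
    spec: ErpTemplateSpec, offsets_ms: tuple[float, float] = SEARCH_OFFSET_MS
) -> dict[str, tuple[float, float]]:
    """Peak-search range per deviant type: deviation onset + offsets."""
    return {t: (on + offsets_ms[0], on + offsets_ms[1]) for t, on in spec.onsets.items()}


def simulate_cohort_traces(
    groups: list[GroupParams],
    n_subjects_per_group: int,
    spec: ErpTemplateSpec,
    noise_rms_uv: float,
    seed: int,
    exponent: float = 1.0,
    sfreq: float = SFREQ,
) -> tuple[dict[str, np.ndarray], list[str], list[str], np.ndarray]:
    """Subject-level analysis-channel difference waves for a whole cohort.

    Emulates the mastoid-referenced FCz difference wave each subject would
    contribute after averaging (MMN term plus residual 1/f noise at
    ``noise_rms_uv``), bypassing the continuous-recording stage.  This is
    the scale at which cohort-level Monte Carlo runs; the continuous chain
    is exercised separately by :func:`simulate_recording`.

    Returns ``(traces, subjects, group_labels, amplitudes)`` with
    ``traces[deviant_type]`` of shape [n_total_subjects x 300] and
    ``amplitudes`` of shape [n_total_subjects x 6].
    """
    times = template_times_ms(sfreq)
    rng = np.random.default_rng(seed)
    all_amps, subjects, labels = [], [], []
    for gi, params in enumerate(groups):
        amps = draw_subject_amplitudes(
            params, n_subjects_per_group, int(rng.integers(2**31))
        )
        all_amps.append(amps)
        subjects += [f"{params.label}_{i + 1:02d}" for i in range(n_subjects_per_group)]
        labels += [params.label] * n_subjects_per_group
    amplitudes = np.vstack(all_amps)
    n_total = amplitudes.shape[0]

    traces: dict[str, np.ndarray] = {}
    for ti, dtype in enumerate(DEVIANT_TYPES):
        mu = spec.onsets[dtype] + spec.mmn_peak_lag_ms
        shape = np.exp(-0.5 * ((times - mu) / spec.mmn_width_ms) ** 2)
        peaks = amplitudes[:, ti]
        if spec.amplitude_mode == "window_mean":
            peaks = peaks / mmn_gain(dtype, spec, sfreq)
        noise = shaped_noise(
            rng, n_total, TEMPLATE_N_SAMPLES, exponent, noise_rms_uv, sfreq
        )
        traces[dtype] = peaks[:, None] * shape[None, :] + noise
    return traces, subjects, labels, amplitudes


# ---------------------------------------------------------------------------
# continuous recording
# ---------------------------------------------------------------------------

def shaped_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    exponent: float,
    rms_uv: float,
    sfreq: float = SFREQ,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^exponent, exact per-channel RMS."""
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * weights, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped * (rms_uv / rms)


def simulate_recording(
    events: EventSequence,
    amplitudes: dict[str, float],
    template_spec: ErpTemplateSpec,
    noise: NoiseSpec,
    sfreq: float = SFREQ,
    pad_s: float = 1.0,
) -> Recording:
    """Render one subject's continuous recording for an event sequence.

    ``amplitudes`` maps each deviant type occurring in the sequence to the
    subject's true MMN amplitude.  Event-locked templates are summed into
    the continuous trace (overlap adds linearly), then shaped noise and
    artifact transients are added.  Deterministic under ``noise.rng_seed``.
    """
    present = {lab for lab in events.labels if lab != STANDARD}
    missing = present - set(amplitudes)
    if missing:
        raise DataError(f"no amplitude provided for deviant types {sorted(missing)}")

    n_lead = int(round(pad_s * sfreq))
    marker_samples = n_lead + np.round(events.onsets_ms * sfreq / 1000.0).astype(int)
    n_samples = int(marker_samples[-1]) + TEMPLATE_N_SAMPLES + n_lead

    templates = {STANDARD: make_erp_template(STANDARD, 0.0, template_spec, sfreq)}
    for t in present:
        templates[t] = make_erp_template(t, amplitudes[t], template_spec, sfreq)

    rng = np.random.default_rng(noise.rng_seed)
    data = shaped_noise(rng, len(CHANNELS), n_samples, noise.exponent, noise.rms_uv, sfreq)
    for label, sample in zip(events.labels, marker_samples):
        data[:, sample:sample + TEMPLATE_N_SAMPLES] += templates[label]

    # artifact transients: half-cosine lobe on one random channel
    n_art = int(round(noise.artifact_duration_ms * sfreq / 1000.0))
    lobe = noise.artifact_amplitude_uv * np.sin(np.linspace(0, np.pi, n_art))
    hit = rng.random(len(marker_samples)) < noise.artifact_fraction
    channels = rng.integers(0, len(CHANNELS), size=len(marker_samples))
    for sample, is_hit, ch in zip(marker_samples, hit, channels):
        if is_hit:
            data[ch, sample:sample + n_art] += lobe[: max(0, n_samples - sample)]

    markers = [(lab, int(s)) for lab, s in zip(events.labels, marker_samples)]
    return Recording(CHANNELS, sfreq, data, markers)
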