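"""Preprocessing chain: FIR bandpass, mastoid re-reference, epoching, rejection.

The filter follows the published design: Kaiser-windowed linear-phase FIR,
0.1-45 Hz, order 9056, beta 5.6533, passband ripple 0.001 (-60 dB),
transition bandwidth 0.2 Hz at 500 Hz sampling.  Filtering is one-pass
with group-delay compensation (the common ERP-toolbox convention), which
preserves the designed magnitude response exactly.  Epochs span -100 to
600 ms around each marker (half-open grid, 350 samples at 500 Hz), are
baseline-corrected to [-100, 0) ms, and are rejected when the within-epoch
peak-to-peak range exceeds 100 uV on any channel ("amplitude change" read
as peak-to-peak; strictly-above rejects).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .eegsim import Recording
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

MASTOIDS = ("M1", "M2")
MASTOID_REFERENCE = "average mastoids"


@dataclass(frozen=True)
class FilterSpec:
    band_hz: tuple[float, float] = (0.1, 45.0)
    order: int = 9056
    kaiser_beta: float = 5.6533
    max_passband_ripple: float = 0.001
    transition_bw_hz: float = 0.2
    sample_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.order % 2 != 0:
            raise ConfigError("filter order must be even (symmetric linear phase)")
        lo, hi = self.band_hz
        nyq = self.sample_rate_hz / 2.0
        if not 0.0 < lo < hi < nyq:
            raise ConfigError("band edges must lie within (0, Nyquist)")
        if hi + self.transition_bw_hz >= nyq:
            raise ConfigError("band edge incompatible with transition width")


def design_bandpass_fir(spec: FilterSpec) -> np.ndarray:
    """Design the bandpass as the difference of two DC-normalized lowpasses.

    Both lowpasses are Kaiser designs with sum(h) = 1, so the bandpass has
    an exact spectral zero at DC; the -6 dB points sit on the band edges
    with the Kaiser transition (~0.2 Hz at this order/beta) either side.
    Returns ``order + 1`` symmetric coefficients.
    """
    lo, hi = spec.band_hz
    numtaps = spec.order + 1
    window = ("kaiser", spec.kaiser_beta)
    h_hi = sps.firwin(numtaps, hi, window=window, fs=spec.sample_rate_hz)
    h_lo = sps.firwin(numtaps, lo, window=window, fs=spec.sample_rate_hz)
    return h_hi - h_lo


def filter_response_db(coeffs: np.ndarray, freqs_hz: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Magnitude response in dB at the requested frequencies."""
    _, h = sps.freqz(coeffs, worN=2 * np.pi * np.asarray(freqs_hz) / sample_rate_hz)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def apply_filter(rec: Recording, coeffs: np.ndarray) -> Recording:
    """One-pass convolution with group-delay compensation and reflect padding.

    The output is time-aligned with the input (markers unchanged), so a
    marker at sample ``s`` still maps to t = 0 of its epoch.
    """
    order = len(coeffs) - 1
    if rec.n_samples <= len(coeffs):
        raise DataError(
            f"recording ({rec.n_samples} samples) must be longer than the filter "
            f"({len(coeffs)} taps)"
        )
    half = order // 2
    padded = np.pad(rec.data, ((0, 0), (half, order - half)), mode="reflect")
    out = np.empty_like(rec.data)
    for c in range(rec.data.shape[0]):
        out[c] = sps.oaconvolve(padded[c], coeffs, mode="valid")
    return replace(rec, data=out, markers=list(rec.markers))


def rereference(
    rec: Recording,
    target_channels: tuple[str, ...] | None = None,
    ref_channels: tuple[str, str] = MASTOIDS,
) -> Recording:
    """Subtract the mastoid average from every target (non-mastoid) channel.

    Calling this twice is rejected: once the reference bookkeeping says
    "average mastoids" a second subtraction would silently change nothing
    meaningful (the mastoid channels keep their original values so the
    operation is not idempotent in general).
    """
    if rec.reference == MASTOID_REFERENCE:
        raise DataError("recording is already mastoid-referenced")
    for ch in ref_channels:
        if ch not in rec.ch_names:
            raise DataError(f"missing mastoid channel {ch!r}")
    if target_channels is None:
        target_channels = tuple(ch for ch in rec.ch_names if ch not in ref_channels)
    idx = {ch: i for i, ch in enumerate(rec.ch_names)}
    ref = np.mean([rec.data[idx[ch]] for ch in ref_channels], axis=0)
    data = rec.data.copy()
    for ch in target_channels:
        data[idx[ch]] -= ref
    return replace(rec, data=data, markers=list(rec.markers), reference=MASTOID_REFERENCE)


@dataclass
class EpochSet:
    """Event-locked, baseline-corrected segments with a rejection mask."""

    data: np.ndarray  # [epochs x channels x samples], uV
    times_ms: np.ndarray
    labels: list[str]
    ch_names: tuple[str, ...]
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    rejected: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.labels), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def retention_fraction(self) -> float:
        if self.n_epochs == 0:
            return float("nan")
        return 1.0 - float(np.mean(self.rejected))

    def retained(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            self.data[keep],
            self.times_ms,
            [l for l, k in zip(self.labels, keep) if k],
            self.ch_names,
            self.baseline_ms,
        )

    # -- on-disk container: raw float64 + CSV index + JSON metadata -------

    def save(self, prefix: str) -> None:
        np.save(prefix + "_data.npy", self.data)
        with open(prefix + "_index.csv", "w") as fh:
            fh.write("epoch,label,rejected\n")
            for i, (label, rej) in enumerate(zip(self.labels, self.rejected)):
                fh.write(f"{i},{label},{int(rej)}\n")
        meta = {
            "times_ms": self.times_ms.tolist(),
            "ch_names": list(self.ch_names),
            "baseline_ms": list(self.baseline_ms),
        }
        with open(prefix + "_meta.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, prefix: str) -> "EpochSet":
        data = np.load(prefix + "_data.npy")
        labels, rejected = [], []
        with open(prefix + "_index.csv") as fh:
            next(fh)
            for line in fh:
                _, label, rej = line.strip().split(",")
                labels.append(label)
                rejected.append(bool(int(rej)))
        with open(prefix + "_meta.json") as fh:
            meta = json.load(fh)
        return cls(
            data,
            np.array(meta["times_ms"]),
            labels,
            tuple(meta["ch_names"]),
            tuple(meta["baseline_ms"]),
            np.array(rejected, dtype=bool),
        )


def extract_epochs(
    rec: Recording,
    window_ms: tuple[float, float] = (-100.0, 600.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut half-open ``[window_ms[0], window_ms[1])`` epochs around each marker.

    At 500 Hz and the default window this yields exactly 350 samples with
    t = 0 aligned to the marker sample.  The per-channel mean over the
    baseline interval (half-open, default [-100, 0) ms) is subtracted.
    Markers without full window support are dropped with a logged warning.
    """
    fs = rec.sfreq
    start = int(round(window_ms[0] * fs / 1000.0))
    stop = int(round(window_ms[1] * fs / 1000.0))
    n_samp = stop - start
    times = (np.arange(n_samp) + start) * 1000.0 / fs

    base = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if not base.any():
        raise ConfigError("baseline interval contains no samples")

    data, labels = [], []
    n_dropped = 0
    for label, sample in rec.markers:
        a, b = sample + start, sample + stop
        if a < 0 or b > rec.n_samples:
            n_dropped += 1
            continue
        epoch = rec.data[:, a:b].copy()
        epoch -= epoch[:, base].mean(axis=1, keepdims=True)
        data.append(epoch)
        labels.append(label)
    if n_dropped:
        logger.warning("dropped %d marker(s) too close to the recording edge", n_dropped)
    if not data:
        raise DataError("no marker has full window support within the recording")
    return EpochSet(np.stack(data), times, labels, rec.ch_names, baseline_ms)


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Flag epochs whose peak-to-peak range exceeds the threshold on any channel.

    A range of exactly ``threshold_uv`` is retained (strictly "above"
    rejects).  Retained data are never altered.
    """
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # [epochs x channels]
    rejected = (ptp > threshold_uv).any(axis=1)
    return EpochSet(
        epochs.data,
        epochs.times_ms,
        list(epochs.labels),
        epochs.ch_names,
        epochs.baseline_ms,
        rejected,
    )
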