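"""Condition averaging, difference waves, and grand averaging."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .paradigm import STANDARD
from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class SubjectErps:
    """Per-condition mean waveforms [channels x samples] for one subject."""

    subject: str
    group: str
    erps: dict[str, np.ndarray]
    counts: dict[str, int]
    times_ms: np.ndarray
    ch_names: tuple[str, ...]


@dataclass
class DifferenceWaves:
    """Deviant-minus-standard waveforms per deviant type for one subject."""

    subject: str
    group: str
    diffs: dict[str, np.ndarray]
    times_ms: np.ndarray
    ch_names: tuple[str, ...]


def average_by_condition(
    epochs: EpochSet, subject: str = "s0", group: str = ""
) -> SubjectErps:
    """Arithmetic mean over retained epochs, per condition label."""
    retained = epochs.retained()
    erps: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for condition in dict.fromkeys(epochs.labels):  # preserve first-seen order
        mask = np.array([l == condition for l in retained.labels])
        if not mask.any():
            raise DataError(f"no retained epochs for condition {condition!r}")
        erps[condition] = retained.data[mask].mean(axis=0)
        counts[condition] = int(mask.sum())
    return SubjectErps(subject, group, erps, counts, retained.times_ms, retained.ch_names)


def difference_waves(erps: SubjectErps) -> DifferenceWaves:
    """Subtract the (single) standard ERP from every deviant ERP."""
    if STANDARD not in erps.erps:
        raise DataError("standard condition missing; cannot form difference waves")
    standard = erps.erps[STANDARD]
    diffs = {
        cond: wave - standard for cond, wave in erps.erps.items() if cond != STANDARD
    }
    if not diffs:
        logger.warning("subject %s has no deviant conditions", erps.subject)
    return DifferenceWaves(erps.subject, erps.group, diffs, erps.times_ms, erps.ch_names)


def grand_average(items: list) -> "SubjectErps | DifferenceWaves":
    """Unweighted mean across subjects of ERPs or difference waves."""
    if not items:
        raise DataError("grand average of an empty list")
    first = items[0]
    waves_attr = "erps" if isinstance(first, SubjectErps) else "diffs"
    times = first.times_ms
    conditions = list(getattr(first, waves_attr))
    for item in items[1:]:
        if not np.array_equal(item.times_ms, times):
            raise DataError("time axes differ across subjects")
        if list(getattr(item, waves_attr)) != conditions:
            raise DataError("condition sets differ across subjects")
    averaged = {}
    for cond in conditions:
        stacked = np.stack([getattr(it, waves_attr)[cond] for it in items])
        # element-wise sort fixes the summation order, making the mean
        # bit-identical under any permutation of the subject list
        stacked.sort(axis=0)
        averaged[cond] = stacked.mean(axis=0)
    if isinstance(first, SubjectErps):
        counts = {c: len(items) for c in conditions}
        return SubjectErps("grand", "", averaged, counts, times, first.ch_names)
    return DifferenceWaves("grand", "", averaged, times, first.ch_names)


def waves_to_frame(items: list) -> "pd.DataFrame":
    """Long-format export (subject, group, condition, channel, time_ms, amplitude_uV)."""
    import pandas as pd

    rows = []
    for item in items:
        waves = item.erps if isinstance(item, SubjectErps) else item.diffs
        for condition, wave in waves.items():
            for c, ch in enumerate(item.ch_names):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": item.subject,
                            "group": item.group,
                            "condition": condition,
                            "channel": ch,
                            "time_ms": item.times_ms,
                            "amplitude_uV": wave[c],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def mastoid_referenced_trace(
    wave: np.ndarray,
    ch_names: tuple[str, ...],
    channel: str = "FCz",
    mastoids: tuple[str, str] = ("M1", "M2"),
) -> np.ndarray:
    """Analysis trace: one channel re-referenced to the average of the mastoids."""
    idx = {ch: i for i, ch in enumerate(ch_names)}
    for ch in (channel, *mastoids):
        if ch not in idx:
            raise DataError(f"channel {ch!r} not present")
    return wave[idx[channel]] - 0.5 * (wave[idx[mastoids[0]]] + wave[idx[mastoids[1]]])
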