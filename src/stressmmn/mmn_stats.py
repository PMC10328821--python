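"""MMN detection and quantification.

The deviance response is verified without peak-picking circularity: a
sample-wise one-sample t-test across subjects runs over the whole 0-600 ms
epoch, corrected with Benjamini-Hochberg FDR (the family is the 300
samples of one deviant type; types are corrected separately).  Only after
a significant negativity is confirmed is the analysis window set, per
deviant type, from the all-subject grand-average difference wave: the most
negative sample within the significant region (and a configurable search
range around the expected deviation latency) is the peak, and the window
runs between the linearly interpolated 70%-of-peak crossings either side.
Mean amplitude over that window in each subject's difference wave is the
quantity carried into group statistics.

Windows must be determined on the whole sample's grand average, never per
group; the high-level entry point :func:`quantify_mmn` enforces this by
construction (it takes the full cohort and splits groups only after the
windows are fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .paradigm import split_deviant_label

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.05
DEFAULT_THRESHOLD_FRACTION = 0.7


def bh_fdr(pvalues: np.ndarray, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class RunningTestResult:
    """Per-sample one-sample t-test with FDR flags, aligned to ``times_ms``."""

    times_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    test_mask: np.ndarray  # samples belonging to the tested window
    q: float


def running_ttest(
    waves: np.ndarray,
    times_ms: np.ndarray,
    q: float = DEFAULT_Q,
    test_range_ms: tuple[float, float] = (0.0, 600.0),
) -> RunningTestResult:
    """Sample-wise two-sided one-sample t-test across subjects against zero.

    ``waves`` is [subjects x samples] at the analysis channel.  BH-FDR is
    applied jointly across all samples inside ``test_range_ms`` (half-open).
    Samples with zero across-subject variance get p = 1 with a warning.
    """
    waves = np.asarray(waves, dtype=float)
    if waves.ndim != 2 or waves.shape[0] < 3:
        raise DataError("running t-test needs [subjects x samples] with >= 3 subjects")
    mask = (times_ms >= test_range_ms[0]) & (times_ms < test_range_ms[1])
    t_full = np.full(len(times_ms), np.nan)
    p_full = np.full(len(times_ms), np.nan)
    sig = np.zeros(len(times_ms), dtype=bool)

    sub = waves[:, mask]
    res = stats.ttest_1samp(sub, 0.0, axis=0)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d sample(s) with zero across-subject variance; p set to 1",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    t_full[mask] = t
    p_full[mask] = p
    sig[mask] = bh_fdr(p, q)
    return RunningTestResult(times_ms, t_full, p_full, sig, mask, q)


@dataclass(frozen=True)
class MmnWindow:
    """Analysis window for one deviant type; ``found=False`` means "no MMN"."""

    deviant_type: str
    found: bool
    peak_latency_ms: float = float("nan")
    peak_amplitude_uv: float = float("nan")
    start_ms: float = float("nan")
    end_ms: float = float("nan")


def _interp_crossing(t_in: float, v_in: float, t_out: float, v_out: float, thr: float) -> float:
    if v_in == v_out:
        return t_in
    return t_out + (thr - v_out) / (v_in - v_out) * (t_in - t_out)


def find_mmn_window(
    grand_trace: np.ndarray,
    times_ms: np.ndarray,
    significant: np.ndarray,
    search_range_ms: tuple[float, float],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    deviant_type: str = "",
) -> MmnWindow:
    """Locate the MMN peak and its 70%-of-peak window on a grand difference wave.

    The peak is the most negative sample within significant & search-range
    samples.  Window bounds are the linear-interpolated crossings of
    ``threshold_fraction * peak`` moving outward from the peak, restricted
    to the contiguous significant region containing the peak (only samples
    at least as negative as the threshold are ever averaged).  With a
    multi-lobed negativity only the lobe containing the peak is used.
    Returns an explicit "no MMN" result when no significant negative sample
    exists in the search range.
    """
    trace = np.asarray(grand_trace, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    in_search = (times_ms >= search_range_ms[0]) & (times_ms <= search_range_ms[1])
    candidates = in_search & significant & (trace < 0)
    if not candidates.any():
        return MmnWindow(deviant_type, found=False)

    idx = np.flatnonzero(candidates)
    peak = idx[np.argmin(trace[idx])]
    peak_value = trace[peak]
    thr = threshold_fraction * peak_value  # negative

    # contiguous significant region containing the peak
    sig_lo = peak
    while sig_lo > 0 and significant[sig_lo - 1]:
        sig_lo -= 1
    sig_hi = peak
    while sig_hi < len(trace) - 1 and significant[sig_hi + 1]:
        sig_hi += 1

    lo = peak
    while lo > sig_lo and trace[lo - 1] <= thr:
        lo -= 1
    if lo > sig_lo and trace[lo - 1] > thr:
        start = _interp_crossing(times_ms[lo], trace[lo], times_ms[lo - 1], trace[lo - 1], thr)
    else:
        start = times_ms[lo]

    hi = peak
    while hi < sig_hi and trace[hi + 1] <= thr:
        hi += 1
    if hi < sig_hi and trace[hi + 1] > thr:
        end = _interp_crossing(times_ms[hi], trace[hi], times_ms[hi + 1], trace[hi + 1], thr)
    else:
        end = times_ms[hi]

    return MmnWindow(
        deviant_type,
        found=True,
        peak_latency_ms=float(times_ms[peak]),
        peak_amplitude_uv=float(peak_value),
        start_ms=float(start),
        end_ms=float(end),
    )


def analysis_windows(
    diff_traces: dict[str, np.ndarray],
    times_ms: np.ndarray,
    search_ranges_ms: dict[str, tuple[float, float]],
    q: float = DEFAULT_Q,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> tuple[dict[str, MmnWindow], dict[str, RunningTestResult]]:
    """Run the detection chain per deviant type on the full cohort.

    ``diff_traces`` maps deviant type to the [subjects x samples] matrix of
    analysis-channel difference waves of *all* subjects.
    """
    windows: dict[str, MmnWindow] = {}
    tests: dict[str, RunningTestResult] = {}
    for dtype, waves in diff_traces.items():
        test = running_ttest(waves, times_ms, q=q)
        grand = np.mean(waves, axis=0)
        windows[dtype] = find_mmn_window(
            grand,
            times_ms,
            test.significant,
            search_ranges_ms[dtype],
            threshold_fraction,
            deviant_type=dtype,
        )
        tests[dtype] = test
    return windows, tests


def extract_mean_amplitude(
    diff_traces: dict[str, np.ndarray],
    times_ms: np.ndarray,
    windows: dict[str, MmnWindow],
    subjects: list[str],
    groups: list[str],
) -> pd.DataFrame:
    """Subject x deviant-type mean amplitudes over each type's window.

    Returns the balanced long-format amplitude table
    (subject, group, cue, position, mean_amplitude_uv).  Deviant types
    whose window is a "no MMN" result are skipped with a logged notice.
    """
    rows = []
    for dtype, waves in diff_traces.items():
        window = windows[dtype]
        if not window.found:
            logger.info("no MMN window for %s; cells skipped", dtype)
            continue
        if window.start_ms < times_ms[0] or window.end_ms > times_ms[-1]:
            raise DataError(f"window for {dtype} lies outside the epoch")
        inside = (times_ms >= window.start_ms) & (times_ms <= window.end_ms)
        if not inside.any():
            raise DataError(f"window for {dtype} contains no samples")
        cue, position = split_deviant_label(dtype)
        means = np.asarray(waves)[:, inside].mean(axis=1)
        for subject, group, value in zip(subjects, groups, means):
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "cue": cue,
                    "position": position,
                    "mean_amplitude_uv": float(value),
                }
            )
    return pd.DataFrame(rows)


def quantify_mmn(
    diff_traces: dict[str, np.ndarray],
    times_ms: np.ndarray,
    search_ranges_ms: dict[str, tuple[float, float]],
    subjects: list[str],
    groups: list[str],
    q: float = DEFAULT_Q,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> tuple[pd.DataFrame, dict[str, MmnWindow], dict[str, RunningTestResult]]:
    """Full-cohort MMN quantification: windows then per-subject amplitudes.

    Windows are fixed from the all-subject grand average before any group
    split; per-group window determination is impossible through this path.
    """
    windows, tests = analysis_windows(
        diff_traces, times_ms, search_ranges_ms, q, threshold_fraction
    )
    table = extract_mean_amplitude(diff_traces, times_ms, windows, subjects, groups)
    return table, windows, tests


def windows_to_frame(windows: dict[str, MmnWindow]) -> pd.DataFrame:
    """Windows as a tidy frame for CSV export."""
    return pd.DataFrame(
        [
            {
                "deviant_type": w.deviant_type,
                "found": w.found,
                "peak_latency_ms": w.peak_latency_ms,
                "peak_amplitude_uv": w.peak_amplitude_uv,
                "start_ms": w.start_ms,
                "end_ms": w.end_ms,
            }
            for w in windows.values()
        ]
    )


def running_tests_to_frame(tests: dict[str, RunningTestResult]) -> pd.DataFrame:
    """Running-test traces as a tidy frame (deviant_type, time_ms, t, p, significant)."""
    frames = []
    for dtype, res in tests.items():
        mask = res.test_mask
        frames.append(
            pd.DataFrame(
                {
                    "deviant_type": dtype,
                    "time_ms": res.times_ms[mask],
                    "t": res.t[mask],
                    "p": res.p[mask],
                    "significant": res.significant[mask],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
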