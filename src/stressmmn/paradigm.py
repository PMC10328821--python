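"""Multi-feature oddball sequence generation and validation.

An oddball session presents a frequent "standard" token interleaved with six
rare deviant types (stress cue: pitch / intensity / duration, crossed with
stressed syllable: first / second).  The session is organised in blocks.
Two ordering constraints hold: every block opens with a standard, and at
least one standard separates any two deviants.  The silent gap between a
stimulus offset and the next onset (ISI) is jittered uniformly.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConstraintError, DataError

STANDARD = "standard"

#: Fixed deviant order; also fixes the BrainVision marker codes S2..S7.
DEVIANT_TYPES = (
    "pitch_syll1",
    "intensity_syll1",
    "duration_syll1",
    "pitch_syll2",
    "intensity_syll2",
    "duration_syll2",
)

#: Marker code map used in .vmrk export ("S 1" = standard, "S 2".."S 7" deviants).
MARKER_CODES = {STANDARD: 1, **{d: i + 2 for i, d in enumerate(DEVIANT_TYPES)}}
CODE_LABELS = {v: k for k, v in MARKER_CODES.items()}


def split_deviant_label(label: str) -> tuple[str, str]:
    """Split e.g. ``"pitch_syll2"`` into ``("pitch", "syll2")``."""
    cue, position = label.rsplit("_", 1)
    return cue, position


@dataclass(frozen=True)
class ParadigmConfig:
    """Session layout parameters.

    Defaults reproduce the study paradigm: 10 blocks of 312 standards and
    18 deviants per type (108 deviants/block), i.e. 3,120 standards (74%)
    and 1,080 deviants in total, with offset-to-onset ISI drawn uniformly
    from [330, 630] ms around a 480 ms mean.  ``stimulus_duration_ms`` is
    the length of the standard token (176 + 282 ms syllables) and is used
    to convert ISIs into onset times.
    """

    n_blocks: int = 10
    standards_per_block: int = 312
    deviants_per_type_per_block: int = 18
    deviant_types: tuple[str, ...] = DEVIANT_TYPES
    isi_range_ms: tuple[float, float] = (330.0, 630.0)
    stimulus_duration_ms: float = 458.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConstraintError("n_blocks must be >= 1")
        if self.standards_per_block < 0 or self.deviants_per_type_per_block < 0:
            raise ConstraintError("counts must be >= 0")
        lo, hi = self.isi_range_ms
        if lo > hi:
            raise ConstraintError("isi_range_ms must satisfy low <= high")
        if self.stimulus_duration_ms <= 0:
            raise ConstraintError("stimulus_duration_ms must be positive")

    @property
    def deviants_per_block(self) -> int:
        return self.deviants_per_type_per_block * len(self.deviant_types)

    @property
    def events_per_block(self) -> int:
        return self.standards_per_block + self.deviants_per_block


@dataclass
class EventSequence:
    """Ordered stimulus labels with onset times and block membership."""

    labels: list[str]
    onsets_ms: np.ndarray
    blocks: np.ndarray
    stimulus_duration_ms: float = 458.0

    def __post_init__(self) -> None:
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=float)
        self.blocks = np.asarray(self.blocks, dtype=int)
        n = len(self.labels)
        if len(self.onsets_ms) != n or len(self.blocks) != n:
            raise DataError("labels, onsets_ms and blocks must have equal length")
        if n > 1 and not np.all(np.diff(self.onsets_ms) > 0):
            raise DataError("onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.labels)

    def isis_ms(self) -> np.ndarray:
        """Offset-to-onset gaps between consecutive events."""
        return np.diff(self.onsets_ms) - self.stimulus_duration_ms

    def count_violations(self) -> int:
        """Number of ordering-constraint violations (0 for generator output)."""
        violations = 0
        prev_block = None
        prev_deviant = False
        for label, block in zip(self.labels, self.blocks):
            is_deviant = label != STANDARD
            if block != prev_block:
                if is_deviant:  # block must open with a standard
                    violations += 1
                prev_block = block
            elif prev_deviant and is_deviant:  # deviant directly after deviant
                violations += 1
            prev_deviant = is_deviant
        return violations

    # -- text round-trip ---------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["label\tblock\tonset_ms"]
        for label, block, onset in zip(self.labels, self.blocks, self.onsets_ms):
            lines.append(f"{label}\t{block}\t{onset:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, stimulus_duration_ms: float = 458.0) -> "EventSequence":
        labels, blocks, onsets = [], [], []
        reader = io.StringIO(text)
        header = reader.readline()
        if not header.startswith("label"):
            raise DataError("missing TSV header 'label\\tblock\\tonset_ms'")
        for line in reader:
            line = line.strip()
            if not line:
                continue
            label, block, onset = line.split("\t")
            labels.append(label)
            blocks.append(int(block))
            onsets.append(float(onset))
        return cls(labels, np.array(onsets), np.array(blocks), stimulus_duration_ms)

    def to_vmrk_entries(self, sample_rate_hz: float = 500.0, start_index: int = 2) -> list[str]:
        """BrainVision marker lines ``Mk<n>=Stimulus,S <k>,<pos>,1,0`` (1-based)."""
        entries = []
        for i, (label, onset) in enumerate(zip(self.labels, self.onsets_ms)):
            code = MARKER_CODES[label]
            sample = int(round(onset * sample_rate_hz / 1000.0))
            entries.append(f"Mk{i + start_index}=Stimulus,S {code},{sample + 1},1,0")
        return entries


@dataclass
class SequenceSummary:
    n_standards: int
    n_deviants: int
    per_type_counts: dict[str, int]
    percent_standards: int
    mean_isi_ms: float
    mean_isi_defined: bool
    constraint_violations: int


def _deviant_positions(rng: np.random.Generator, n_events: int, n_deviants: int) -> np.ndarray:
    """Uniform draw of ``n_deviants`` pairwise non-adjacent positions in 1..n_events-1.

    Uses the stars-and-bars bijection: a sorted subset {y_1 < ... < y_k} of
    {1..n_events-k} maps to x_i = y_i + (i - 1), which enumerates exactly the
    non-adjacent subsets of {1..n_events-1} (position 0 stays a standard).
    """
    population = n_events - n_deviants  # size of {1..n_events-k}
    if n_deviants > 0 and population < n_deviants:
        raise ConstraintError("too few standards to separate all deviants")
    y = np.sort(rng.choice(np.arange(1, population + 1), size=n_deviants, replace=False))
    return y + np.arange(n_deviants)


def generate_session(config: ParadigmConfig) -> EventSequence:
    """Generate a constrained oddball session.

    Each block holds exactly ``standards_per_block`` standards and
    ``deviants_per_type_per_block`` deviants of every type, opens with a
    standard, and never places two deviants back to back.  Deviant
    positions are drawn uniformly over all constraint-satisfying layouts;
    deviant identities are a random permutation of the balanced type
    multiset.  ISIs are continuous-uniform over ``isi_range_ms``.
    """
    n_types = len(config.deviant_types)
    k = config.deviants_per_block
    if k > 0 and config.standards_per_block < n_types * config.deviants_per_type_per_block + 1:
        raise ConstraintError(
            "standards_per_block must be >= deviants_per_type_per_block * "
            f"{n_types} + 1 (got {config.standards_per_block} standards for {k} deviants)"
        )
    rng = np.random.default_rng(config.rng_seed)
    m = config.events_per_block

    labels: list[str] = []
    blocks: list[int] = []
    for block in range(config.n_blocks):
        block_labels = [STANDARD] * m
        positions = _deviant_positions(rng, m, k)
        identities = rng.permutation(
            np.repeat(np.arange(n_types), config.deviants_per_type_per_block)
        )
        for pos, ident in zip(positions, identities):
            block_labels[pos] = config.deviant_types[ident]
        labels.extend(block_labels)
        blocks.extend([block] * m)

    n_total = len(labels)
    isis = rng.uniform(*config.isi_range_ms, size=max(n_total - 1, 0))
    onsets = np.zeros(n_total)
    if n_total > 1:
        onsets[1:] = np.cumsum(config.stimulus_duration_ms + isis)
    return EventSequence(labels, onsets, np.array(blocks), config.stimulus_duration_ms)


def summarize_sequence(seq: EventSequence) -> SequenceSummary:
    """Exhaustive tally of a sequence with rounded standard percentage."""
    if seq.n_events == 0:
        raise DataError("cannot summarize an empty sequence")
    counts = Counter(seq.labels)
    n_standards = counts.pop(STANDARD, 0)
    n_deviants = seq.n_events - n_standards
    isis = seq.isis_ms()
    defined = isis.size > 0
    return SequenceSummary(
        n_standards=n_standards,
        n_deviants=n_deviants,
        per_type_counts=dict(counts),
        percent_standards=int(round(100.0 * n_standards / seq.n_events)),
        mean_isi_ms=float(np.mean(isis)) if defined else float("nan"),
        mean_isi_defined=defined,
        constraint_violations=seq.count_violations(),
    )
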