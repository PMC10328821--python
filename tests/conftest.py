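"""Shared fixtures: small simulated sessions and measured stimulus tokens.

Everything is generated programmatically; expensive objects are module- or
session-scoped so the suite stays fast.
"""

import numpy as np
import pytest

from stressmmn import (
    CueManipulation,
    DEVIANT_TYPES,
    ErpTemplateSpec,
    NoiseSpec,
    ParadigmConfig,
    apply_cue_manipulation,
    generate_session,
    measure_cues,
    simulate_recording,
    standard_word,
    synthesize_word,
)


@pytest.fixture(scope="session")
def paper_session():
    """Full 10-block session with the study's paradigm defaults."""
    return generate_session(ParadigmConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_config():
    """One short block, feasible but tight, for quick generation tests."""
    return ParadigmConfig(
        n_blocks=1, standards_per_block=40, deviants_per_type_per_block=2, rng_seed=3
    )


@pytest.fixture(scope="session")
def std_measured():
    """Measured cues of the neutral token."""
    spec = standard_word()
    wave, segments = synthesize_word(spec)
    return spec, wave, segments, measure_cues(wave, segments)


@pytest.fixture(scope="session")
def deviant_measured(std_measured):
    """Measured cues of all six single-cue deviant tokens."""
    spec = std_measured[0]
    out = {}
    for dtype in DEVIANT_TYPES:
        manip = CueManipulation.for_deviant(dtype)
        dspec = apply_cue_manipulation(spec, manip)
        wave, segments = synthesize_word(dspec)
        out[dtype] = (dspec, measure_cues(wave, segments))
    return out


@pytest.fixture(scope="session")
def noiseless_recording():
    """Noiseless single-subject recording: 1 tight block, A = -3 uV everywhere."""
    seq = generate_session(
        ParadigmConfig(
            n_blocks=1, standards_per_block=40, deviants_per_type_per_block=1, rng_seed=5
        )
    )
    spec = ErpTemplateSpec()
    amplitudes = {t: -3.0 for t in DEVIANT_TYPES}
    noise = NoiseSpec(rms_uv=0.0, artifact_fraction=0.0, rng_seed=0)
    return seq, spec, amplitudes, simulate_recording(seq, amplitudes, spec, noise)
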