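# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `stressmmn`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Oddball sequence generation

A session consists of `n_blocks` blocks, each holding
`standards_per_block` neutral tokens and `deviants_per_type_per_block`
tokens of each of six deviant types (cue ∈ {pitch, intensity, duration} ×
position ∈ {first, second syllable}). Defaults: 10 blocks × (312 + 6×18),
i.e. 3,120 standards (74%) and 1,080 deviants. Two ordering constraints
hold: each block opens with a standard, and at least one standard follows
every deviant (equivalently, no two deviants are adjacent).

Deviant positions are drawn **uniformly over all constraint-satisfying
layouts** via the stars-and-bars bijection: a sorted k-subset
{y₁<…<y_k} ⊆ {1..m−k} maps to xᵢ = yᵢ + (i−1), which enumerates exactly
the pairwise non-adjacent subsets of {1..m−1} (slot 0 stays a standard).
We chose this closed-form sampler over re-shuffling with rejection
because, at 108 deviants among 420 slots, the probability that an
unconstrained shuffle satisfies the adjacency constraint is vanishingly
small — rejection sampling would effectively never terminate — while the
bijection is exact, uniform and O(k log k). Deviant identities are a
random permutation of the balanced type multiset, independently per block.

The inter-stimulus interval (offset-to-onset) is continuous-uniform on
[330, 630] ms (mean 480 ms); the distribution shape is a modeling choice,
as only the range and mean are prescribed, and it is configurable. Onset
times add the stimulus duration (458 ms = 176 + 282 ms syllables) to each
gap; intervals are quantized to the sample grid only at synthesis time.

## Stimulus synthesis and measurement

Tokens are parametric, not TTS: each syllable is a glottal-pulse train at
a flat F0 through two fixed formant resonators (500 Hz / 80 Hz BW,
1500 Hz / 120 Hz BW), with the consonantal remainder filled by a
deterministic inharmonic band of twelve high partials at 30% of the vowel
RMS. This trades phonetic realism for *exact, measurable ground truth*:
every cue the pipeline measures is a direct function of the spec, and
synthesis is deterministic (no RNG anywhere in the module).

Intensity is expressed as dB re a fixed reference RMS of 1e-5 full scale
(100 dB ≡ unit RMS), so the token table's absolute dB values are matched
by construction rather than by SPL calibration, and +6 dB manipulations
land below full scale in 16-bit WAV output.

The three manipulations act on the parametric source: pitch multiplies F0
by 1.10 (regeneration, not waveform-domain PSOLA — exact and
artifact-free), intensity adds 6 dB to the syllable gain, and duration
multiplies **only the vowel span** by 1.7, leaving consonants untouched.
Default vowel spans (62.86 ms and 81.43 ms) are back-solved so the ×1.7
vowel prolongation produces syllable-level increases of 176→220 ms (+25%)
and 282→339 ms (+20%). Where the cited per-syllable percentages and the
printed millisecond values disagree in the source material, the
millisecond values win, since they are self-consistent.

F0 measurement uses the normalized autocorrelation over the annotated
vowel span, searched between 75 and 400 Hz. Because a fractional-sample
period splits the autocorrelation peak across two adjacent lags, peak
picking and the voicing decision use the 3-lag sum (threshold 0.5), and
the lag is read off the local 3-point centroid; unvoiced or silent spans
return an explicit "no F0" flag. A 5 ms raised-cosine offset ramp avoids
spectral splatter at the word end.

## Synthetic EEG

Five channels (Fz, FCz, Cz, M1, M2; implicit nose reference) at 500 Hz.
Every stimulus evokes a P1/N1/P2 Gaussian triplet (+1 µV @ 50 ms,
−2 µV @ 100 ms, +1.5 µV @ 200 ms, σ = 20 ms) — invented plumbing whose
only role is realistic component overlap; it cancels exactly in
difference waves. Deviants add a Gaussian MMN (σ = 25 ms) peaking 195 ms
after the deviation onset of their type: 0 ms for first-syllable pitch
and intensity, 50 ms for first-syllable duration (the vowel diverges well
before its end), 175 ms for second-syllable pitch/intensity, 225 ms for
second-syllable duration. The topography splits the signed peak *P* as
κ·P on FCz (scaled 0.8/0.9 on Fz/Cz) and −(1−κ)·P on each mastoid
(κ = 0.7), so mastoid-referenced FCz carries the full component.

**Amplitude convention.** Group and subject amplitudes are calibrated in
measured units: an injected amplitude *A* is *defined* as the mean
amplitude the analysis pipeline extracts from the 70%-of-peak window. The
window-mean of a unit-peak Gaussian over its own 70% window is ≈ 0.8926
(exactly: σ√2π·(2Φ(z)−1)/(2σz) with z = √(2 ln(1/0.7)), evaluated on the
actual 2 ms sample grid per deviant type), so the underlying Gaussian
peak is A divided by that gain. Two consequences: (i) the noiseless
injected-vs-recovered identity through the full chain is exact by
construction, and (ii) group means can be set directly to published
window-mean amplitudes. The per-type gain is computed by running the
package's own window finder on the noiseless unit template — a
calibration, not a test shortcut. `amplitude_mode="peak"` switches to the
raw convention in which *A* is the Gaussian trough itself.

Group defaults place the position marginals (German −1.62/−3.53 µV,
Slavic −2.35/−3.30 µV, with the corresponding SDs) on every cue cell with
zero cue offsets, because only position marginals are published; per-cell
means are config-overridable. Cells are drawn independently per subject —
a simplification that ignores within-subject correlation across cells and
makes the position-difference SD larger than the published one; the
position-difference *means* (1.91 and 0.95 µV) are preserved, and those
are what the recovery tests check.

Noise is Gaussian, spectrally shaped to 1/f^α (α = 1) with exact
per-channel RMS (default 10 µV for continuous recordings). Artifacts are
150 µV, 300 ms half-cosine transients injected on a random channel at a
random 5% of stimulus onsets — deliberately simple, threshold-rejectable
events standing in for blinks and movement; no biophysical artifact
morphology or IC-based cleaning is modeled, so epoch rejection is the
only artifact path the pipeline exercises.

`simulate_cohort_traces` additionally emulates the *subject-level*
mastoid-referenced FCz difference wave directly (MMN term + residual 1/f
noise), which is the scale at which Monte-Carlo calibration runs; the
continuous-recording chain is exercised separately. Cohort replicate
counts in the shipped tests (500 recovery / 200 null cohorts, subject
noise RMS 0.5 and 1.0 µV) were chosen as the package's own
desk-scale study conditions.

## Preprocessing

The bandpass is a Kaiser-window FIR, 0.1–45 Hz, order 9056, β = 5.6533
(the β of a 60 dB Kaiser design; transition ≈ 0.2 Hz at this order),
built as the **difference of two DC-normalized lowpasses**. Both halves
have Σh = 1, so the bandpass has an exact spectral zero at DC; the −6 dB
points sit on the band edges. Measured compliance (passband deviation
≤ 0.001 over 0.3–44.8 Hz, ≥ 60 dB at DC and beyond 45.2 Hz) is asserted
in the tests. Filtering is one-pass with group-delay compensation
(output shifted by order/2; reflective padding), matching common ERP
toolbox behavior and preserving the designed magnitude response exactly —
whether the original analysis compensated delay one-pass or two-pass is
not documented, so one-pass was chosen and fixed here.

Epochs span the half-open interval [−100, 600) ms around each marker —
exactly 350 samples at 500 Hz with t = 0 on the marker sample — and are
baseline-corrected to the mean of [−100, 0) ms per channel. Markers
without full window support are dropped with a warning. Rejection flags
any epoch whose within-epoch peak-to-peak range exceeds 100 µV on any
channel ("amplitude change" read as peak-to-peak, the standard ERP
convention); a range of exactly 100 µV is retained, and retained data are
never altered.

## MMN detection and quantification

Per deviant type, a one-sample two-sided *t*-test across subjects runs on
every sample of 0–600 ms of the mastoid-referenced FCz difference waves;
Benjamini–Hochberg FDR at *q* = 0.05 is applied across the 300 samples of
each type separately (whether the original family pooled types is
unstated; per-type was chosen and documented). Samples with zero
across-subject variance get p = 1 with a warning rather than an error.

The window finder takes the **all-subject** grand average: the peak is
the most negative sample inside (significant region ∩ search range), the
search range defaulting to deviation onset + [100, 350] ms. Window
bounds are the linearly interpolated crossings of 0.7 × peak moving
outward; the averaged samples are those lying inside the crossings, so
every in-window sample is at least as negative as the threshold (the
alternative of snapping the bounds outward would break that invariant and
was rejected). The window is clipped to the contiguous significant region
containing the peak; with multi-lobed negativities only the peak's lobe
is used (logged). No significant negative sample yields an explicit
"no MMN" result, not an exception. `quantify_mmn` fixes the windows from
the full cohort before any group split, so per-group window determination
is impossible through the public path.

## Group statistics

The mixed ANOVA partitions each within-subject stratum separately:
subject means (Group over S(G)), cue profiles (Cue, Group×Cue over
C×S(G)), position profiles (Position, Group×Position over P×S(G)), and
the within-subject interaction residual (Cue×Position, three-way over
C×P×S(G)). The design must be complete within subjects; group sizes may
differ (the same engine serves 4-level between factors such as
proficiency bands). Sphericity corrections are intentionally absent —
uncorrected df are reported — and there is no Type-II/III machinery,
since the within design is balanced by construction. ηG² uses the
observed-effect convention (all subject-related error SS in the
denominator). A zero error stratum yields NaN F/p, flagged undefined.

Follow-up tests: paired contrasts on per-subject cell combinations
(df n−1, Cohen's d = mean/SD of differences; an all-zero difference
vector returns t = 0, p = 1 by convention, a nonzero constant one raises),
pooled-variance independent *t* (Welch behind a flag; d always uses the
pooled SD), and two variants of the within-group position test — a plain
per-group paired *t* (df n_g−1) and a pooled-error version using the
across-group SD of position differences (df N−g), because published
reports of such follow-ups sometimes carry the full between-subject error
df and the exact form is ambiguous. Neither variant claims to reproduce
any specific published value.

The a priori power computation searches the smallest integer per-group n
whose exact two-sided two-sample *t* power (noncentral t, ncp = d·√(n/2),
df 2n−2) reaches the target; minimality (power at n−1 below target) is
asserted in tests against an independent continuous solver.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis relies on — event
timing, MMN latency/topography with mastoid inversion, between-subject
amplitude variability, 1/f noise, threshold-rejectable artifacts — but
not volume conduction, realistic artifact morphology, drifts or channel
faults, overlapping late components (LDN), or cue-specific amplitude
offsets (only position marginals are calibrated). Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated (injected
parameters are recovered, error rates are controlled), not that it would
be robust to every pathology of real recordings. ICA-based cleaning,
channel interpolation, resampling, cluster-based permutation statistics,
and scalp-map interpolation are out of scope.

## Numerical details worth knowing

- Grand averages sort values element-wise before summing, making the mean
  bit-identical under any permutation of the subject list.
- The `all` pipeline mode round-trips recordings through the written
  float32 BrainVision files so that staged and single-shot runs are
  bit-identical.
- BrainVision marker positions follow the format's 1-based data-point
  convention; only BINARY/MULTIPLEXED float32 or int16(+resolution)
  dialects are read, anything else raises an unsupported-dialect error.
- All RNG streams derive from one root seed via `SeedSequence` spawn
  keys; reports contain no timestamps, so identical config + seed gives
  byte-identical output.
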