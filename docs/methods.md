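# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that make results
reproducible.

## The archive dialect and session model

A recording is a zip of per-signal CSVs. Signal files carry the Unix
start time (UTC seconds) in row 1 — repeated once per channel in
multi-channel files — and the sampling frequency in row 2; each
subsequent row covers 1/fs seconds. Native rates are 4 Hz for EDA,
64 Hz for blood volume pulse, 1 Hz for the derived heart-rate channel
and 32 Hz for acceleration; the parser always trusts the frequency row
rather than hard-coding a rate (reported temperature rates differ
between sources, so the file is authoritative). The IBI table is
different: `(seconds since start, interval seconds)` pairs, with the
start time in row 1; a non-numeric label in the second header column is
tolerated because some exports carry one. On write, floats are emitted
at 6 decimal places with values rounded before the integer check, so
write→read→write is byte-stable (a canonical form).

Recordings interrupted on the same day merge into one session. The
off-wrist time is represented as an explicit list of recorded-gap
intervals on each stream, never as interpolated or NaN-padded samples:
fabricating data the device never recorded would silently bias every
downstream mean. Epoching skips windows that overlap a gap, and gapped
streams refuse serialization (the dialect cannot represent them).
Merging is order-insensitive, rejects overlapping recordings, and
rebases beat offsets to the merged start. Display timestamps use an
explicit timezone offset in minutes so behavior never depends on the
host machine's zone.

## EDA pipeline

**Preprocessing.** The signal is linearly interpolated onto an 8 Hz
grid, then filtered with a linear-phase FIR low-pass (33 taps, 1 Hz
cutoff, Hamming window) applied forward-backward. Linear interpolation
is monotone — resampling cannot fabricate a peak. SCR energy lies below
about 1 Hz, and the zero-phase application keeps rise and decay timing
unbiased; the DC gain is 1, so tonic level is preserved. A near-Nyquist
tone is attenuated by more than 20 dB (verified against an FFT oracle).
Sub-4-sample streams pass through unfiltered; downsampling is refused.

**Epoch features.** Each complete 5-s epoch yields its mean, max, min,
maximum absolute first and second difference, and — at the one-second
and half-second wavelet scales — the max, mean and
count-above-threshold of one-level Haar detail coefficients (Haar
detail is the canonical discontinuity detector; the family is
configurable). The decomposition level is chosen from the sampling rate
so a coefficient spans the requested scale (level 3 ≈ 1 s at 8 Hz).

**Artifact classification.** The original classifier for this feature
set is a support vector machine trained on expert-labeled data whose
weights are not public. The package therefore exposes a pluggable
decision function: any linear model over the named features can be
loaded from a JSON file (`weights`, `bias`, `margin`). The shipped
default is an explicit rule set: an epoch is an artifact when the
per-sample slope exceeds 10 µS/s or the epoch's range exceeds 20% of
the device's measurable range (≈ 20 µS within 5 s). Both rules respond
to change, not level, so labels are invariant to a constant offset —
an electrode swap that shifts the baseline does not change artifact
status. The range rule is deliberately anchored to the *device* range,
not the observed per-recording range: anchoring to the observed range
would flag every genuine SCR in an otherwise quiet recording. Scores
just below the artifact boundary (≥ 0.75 by default) map to "unclear"
in ternary mode; binary mode never emits "unclear".

**Validity.** Samples outside 0.01–100 µS — contact loss near zero,
saturation above the ceiling — are masked and excluded from peak
detection and summaries. The floor is exposed as `valid_min` rather
than hard-coded, since published quality rules differ on the exact
"approaching zero" cutoff.

**SCR detection.** Candidate apexes are local maxima with prominence of
at least half the amplitude threshold (plateau edges tracked so
flat-topped apexes resolve exactly); each pairs with the last local
minimum before it. The peak start is that minimum, the onset level is
the signal there, and the amplitude (apex − onset) must reach the
0.005 µS threshold. Amplitude — not height or prominence — is the
thresholded quantity, the standard reading. Half recovery is the first
sample after the apex below onset + amplitude/2, searched only up to
the next peak's start; when found, decay time = half recovery − apex,
width = half recovery − the linearly interpolated half-amplitude
crossing on the rising limb, and AUC is the trapezoidal integral of
(signal − onset) from start to half recovery. When recovery does not
occur before the next peak these three fields are absent rather than
extrapolated. Peaks overlapping artifact epochs or invalid samples are
excluded. Peaks per minute divides the count by valid, artifact-free
time — not wall-clock time — so a noisy recording is not diluted.

On noise-free synthetic trains, amplitudes recover within ~2%
(residual error is corner rounding by the 1 Hz filter); the test
tolerance of 5% covers 8 Hz discretization of arbitrary event times.

## RR filtering and HRV

The plausibility filter applies, in order: (1) hard bounds — intervals
shorter than 60/180 s or longer than the missed-beat ceiling
(2 × 60/40 = 3 s by default) are rejected; (2) a sliding 10-s window
anchored at each accepted beat, rejecting the later member of any
max/min pair whose ratio exceeds 2.2 (re-evaluating after each
rejection — a deterministic tie-break); (3) a single interval above
1.5 s is rejected when its local window ratio also exceeds 1.1
(a lone 30-bpm interval amid 60-bpm beats, with no corroborating
missed-beat context, is implausible). Setting `missed_beat_factor`
to 1 disables the allowance, tightening the ceiling to 1.5 s and the
ratio bound to 1.1. Passes 2–3 iterate to a fixpoint, which makes the
filter idempotent. The precedence of the windowed rule over the
single-interval rule is a documented choice; published descriptions of
these rules do not specify one.

Time-domain measures use the standard definitions over accepted beats:
mean HR = 60/mean(RR), SDNN = sample standard deviation (ms),
RMSSD = √mean(ΔRR²) (ms), pNN50 = % of successive differences strictly
above 50 ms. This is the standard minimal set for wearable reporting.

For spectral analysis the accepted intervals are linearly interpolated
onto a uniform 4 Hz grid spanning first-to-last accepted beat. Band
powers come from a Welch periodogram of the mean-removed tachogram
(Hann window, 120-s segments clipped to the series length, 50%
overlap) integrated over VLF 0.003–0.04, LF 0.04–0.15 and
HF 0.15–0.4 Hz — conventional short-term defaults. Feeding the ms
tachogram yields powers in ms². Total Welch power matches the series
variance within 5% (Parseval check in the suite). Series under 120 s
are refused rather than padded. Wrist HRV is only interpretable at
rest, so interval summaries carry a `movement_present` flag whenever
detected movement overlaps the window; the flag warns, it does not
block. No beat correction or imputation is attempted, and no
non-linear measures are computed.

## Movement and temperature

Magnitude = √(x²+y²+z²)/64 in g (the divisor is the counts-per-g scale
of a ±2g, 8-bit device and is configurable). Movement flagging
thresholds the 1-s centered rolling mean at 1.07 g; whether the
published 1.07 default applies to instantaneous or windowed magnitude
is unstated, and windowing was chosen so single-sample jolts do not
flag. Flagged intervals are maximal, disjoint and sorted. Summaries
(mean/min/max/median) operate on valid samples only.

## Calendar, cutting, batch, report

Calendar tables require the five columns Date (strictly dd-mm-yyyy;
two-digit years are rejected rather than guessed), Start, End
(hh:mm:ss), Text and Color, in delimited text (sniffed) or spreadsheet
form. Unknown color names pass through with a warning so downstream
renderers decide. Events are interpreted in the session's display
timezone and clipped to the session span; tags before the session start
keep their negative offset and are flagged.

The cutter uses half-open bins `[start, start + width)` so no sample
lands twice; `floor(span/width)` bins result and a partial trailing bin
is dropped with a log line. Each bin is itself a valid archive with
row-1 times rebased to the bin start; concatenating bins plus remainder
reproduces the sliced input exactly. Beats are assigned to the bin
containing their offset. The batch runner writes one result container
per archive (JSON summary + CSV tables, zipped, named after the input
stem) plus a run manifest; one corrupt archive is logged and skipped,
never fatal. Results are deterministic — the pipeline has no randomness.

Reports are static self-contained HTML with embedded SVG plots:
EDA (0–20 µS), HR (40–160 bpm), temperature (24–38 °C) and movement
(0.98–1.25 g) panels, calendar shading, optional tag and reference
lines, the calendar table and the summary table. Sessions over 2 h plot
1-minute means instead of raw samples. Every table number is taken
verbatim from the computed summary rows, and output is
byte-deterministic (fixed SVG hash salt, no embedded date, injectable
"generated at" string).

## Synthetic sessions and what passing tests show

The generator emulates the signal structure the pipeline assumes: SCRs
(linear rise, exponential decay — closed-form, so feature extraction is
testable exactly) over a tonic baseline with Gaussian sensor noise;
plausible RR series with optional missed-beat and ectopic defects; a
resting accelerometer (1 g on z) with square movement bursts; a slowly
drifting temperature quantized at 0.02 °C; and a placeholder BVP (sum
of two harmonics at the beat rate — no beat detection is ever run on
it). Defaults describe a quiet resting recording: baseline 2 µS, noise
sd 0.0005 µS (about half the device's ~0.9 nS quantization step — a
sensor cannot be noisier than its resolution), 60 bpm with 20 ms
jitter, 33 °C. Injected artifacts are large device glitches (+10 µS
step, +20 µS spike, dropout to zero) with transitions strictly inside
the target epoch. All randomness derives from the spec's seed through
per-component substreams, so equal specs give identical archives on any
platform.

What the generator does **not** emulate: realistic PPG morphology,
smooth drifts in tonic level, overlapping/compound SCRs, motion-coupled
EDA artifacts, temperature dynamics, or the label noise of real expert
annotation. Passing tests therefore demonstrate that the algorithms
implement their definitions correctly under the stated signal model —
not that the default classifier matches expert judgment on real wrist
recordings, which would require the unpublished labeled corpus.

## Numerical choices and degenerate inputs

Filtering uses `filtfilt` with padding clipped for short segments;
streams shorter than 4 samples skip the filter. Empty streams
preprocess to empty streams; epoch extraction on short streams returns
an empty list; fewer than two accepted beats raises a typed error
rather than returning NaNs. Welch band integration uses trapezoidal
integration over the in-band frequency samples. Slice windows are
half-open with a 1e-9 s tolerance against float drift. Problem sizes in
the test suite (30-minute cut sessions, 300-s tachograms, 100
round-trip archives of 20–40 s, 1000 oracle RR series) were chosen as
the smallest that exercise every code path with wide margins.
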