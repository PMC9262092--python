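# e4physio

Signal analysis for wrist-wearable physiological recordings in the
Empatica E4 archive dialect: electrodermal activity (EDA), blood volume
pulse, heart rate, skin temperature, tri-axial acceleration and
inter-beat intervals (IBI), bundled as a zip of CSVs whose first row is
the Unix start time and second row the sampling frequency.

The package is aimed at clinicians and researchers who collect
physiology in daily life and need the steps between a raw download and
an interpretable number: artifact screening, feature extraction,
synchronization with real-life events, fixed-interval binning and
batch processing — all scriptable, all offline.

## What it computes

**EDA.** The 4 Hz skin-conductance signal is upsampled to 8 Hz and
low-pass filtered (zero-phase FIR, 1 Hz cutoff). Five-second epochs are
classified clean / unclear / artifact by a pluggable linear classifier
(the shipped default is an explicit slope + range rule set); samples
outside the measurable 0.01–100 µS range are masked. Skin-conductance
responses (SCRs) are detected as rise-and-decay peaks with amplitude
≥ 0.005 µS, each described by onset level, amplitude, rise time, maximum
derivative, decay time, width and AUC, and summarized as peaks per
analyzable minute.

**Heart rate.** RR intervals pass physiological plausibility rules —
resting rates of 40–180 bpm bound the interval to [60/180, 60/40] s
(a 1.5 s ceiling; 3 s with a single missed beat allowed), and the
max/min interval ratio over a 10-s window is bounded by 1.1 (2.2 with
the allowance). Accepted beats yield mean HR, SDNN, RMSSD and pNN50,
and, after interpolation to a uniform 4 Hz tachogram, Welch band powers
(VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz). Wrist HRV is flagged
whenever the window overlaps detected movement.

**Movement & temperature.** Acceleration counts become gravity units via
√(x²+y²+z²)/64; intervals whose 1-s mean magnitude exceeds 1.07 g
(7% above rest) are flagged as movement. All signals get
mean/min/max/median summaries.

**Sessions.** Same-day archives merge with recorded gaps (never
fabricated samples); calendar tables (Date, Start, End, Text, Color) and
device tags synchronize to session time; the cutter splits a timeframe
into fixed bins written back as valid archives; the batch runner maps a
folder of archives to result containers; and an HTML report combines the
plots, calendar and summary table.

A fully deterministic synthetic-session generator (`SynthSpec`,
`synth_session_zip`) emits archives in the exact dialect with ground
truth for every detector, so the whole pipeline is testable without any
recording.

## Worked example

```python
from e4physio import (CutSpec, ScrEvent, SynthSpec, cut_session,
                      read_session, summarize_interval, synth_session_zip)

spec = SynthSpec(
    duration=1800.0, seed=1,
    scr_events=tuple(ScrEvent(time=60.0 + i * 120.0, amplitude=0.3)
                     for i in range(8)),
)
zip_path, truth_path = synth_session_zip(spec, "session.zip")
session = read_session(zip_path)

row = summarize_interval(session, 0.0, 1800.0)
print(f"EDA mean {row.eda_mean:.3f} uS, peaks/min {row.peaks_per_min:.3f}")
print(f"HR {row.hr_mean:.1f} bpm, RMSSD {row.rmssd:.1f} ms")
print(f"artifact fraction {row.eda_artifact_fraction:.2f}, "
      f"beat acceptance {row.beat_acceptance_fraction:.2f}")

bins = cut_session(session, CutSpec(start=0.0, end=1800.0, bin_width=300.0))
print(f"{len(bins)} five-minute bins")
```

prints

```
EDA mean 2.007 uS, peaks/min 0.267
HR 60.0 bpm, RMSSD 28.8 ms
artifact fraction 0.00, beat acceptance 1.00
6 five-minute bins
```

Eight injected SCRs over 30 minutes are recovered exactly
(8/30 ≈ 0.267 per minute); the 20 ms beat-to-beat jitter appears as
RMSSD ≈ √2·20 ms; a clean recording shows zero artifact fraction and
full beat acceptance; and the 30-minute frame cuts into six 5-minute
bins.

The same operations are available from the shell:

```sh
e4physio synth --duration 1800 --seed 1 --out session.zip
e4physio report --zip session.zip --out report.html
e4physio cut --zip session.zip --from 0 --to 1800 --bin 300 --out bins/
e4physio batch --in archives/ --out results/
```

## Scope

Beat detection from raw PPG is the device vendor's undisclosed
algorithm and is not reimplemented; the epoch classifier's original
trained weights are unpublished, so the default is the documented rule
set with a loadable linear-model interface; no beat
correction/imputation and no non-linear HRV measures. See
`docs/methods.md` for the model details and limitations.
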