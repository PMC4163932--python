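# lfpmodes

Analysis of diurnal oscillatory modes in multi-channel local field
potential (LFP) recordings — band power in 2-s windows, an
empirical-threshold classifier of slow (0.1–3 Hz) vs theta (3–8 Hz)
dominance, slow-wave-coupled spindle detection, inter-electrode coherence,
and the repeated-measures statistics that test how these measures vary with
zeitgeber time (ZT) and D2-receptor antagonism.  A synthetic session
generator with known ground truth (state intervals, burst times, coherence
tiers) emulates the structure of urethane-anesthetized striatal and
cerebellar recordings, so the whole pipeline runs and is tested without any
data download.

Intended users: systems/circadian neurophysiologists re-analyzing
multi-electrode LFP recordings structured as discrete recording periods
(120 s, four sampled zeitgeber times, pre/post drug), and methodologists who
want a tested reference implementation of the window-threshold mode
classifier and the rectified-envelope spindle detector.

## The measures

For each 2-s window the Hann-tapered periodogram is integrated over five
half-open bands — δ (0.1–3), θ (3–8), α (8–13), β (13–30), γ (30–55 Hz) —
and expressed as a percentage of total 0.1–55 Hz power.  The dominance
difference

```
D_i = %P(0.1–3)_i − %P(3–8)_i
```

is classified per window against a per-session empirical baseline
B = mean{D_i : |D_i| ≤ 10}: windows with D ≥ B + 20 are slow-dominated,
D ≤ B − 15 theta-dominated; occupancies are the percentage of windows per
label.  Spindles are 8–20 Hz bursts whose smoothed rectified envelope
(71 ms boxcar, one 14 Hz cycle) exceeds 2 SD within ±0.25 s of a slow-wave
crest.  Coherence is Welch magnitude-squared coherence per 2-s window
(three Hann-tapered 1-s sub-segments, 50 % overlap, 1 Hz bins), averaged
over band bins and windows.  Time-of-day effects are tested with a one-way
ANOVA over ZT (units as observations), drug-by-time effects with a mixed
two-way ANOVA (ZT between units, pre/post within), Tukey HSD post hoc.

## Worked example

```python
from lfpmodes import spec_for, make_session, classify_session, AnalysisConfig
from lfpmodes.spindles import detect_spindles, spindle_rate

# ZT13 striatal baseline period: slow and theta modes alternate
spec = spec_for(13, "Str", fs=250.0, duration=120.0, seed=42)
session, truth = make_session(spec)

config = AnalysisConfig(fs_target=250.0)
cls = classify_session(session, config)["MStr_a"]
print(f"baseline B = {cls.baseline:+.1f} pp")
print(f"pct_slow   = {cls.pct_slow:.1f} %")
print(f"pct_theta  = {cls.pct_theta:.1f} %")

events = detect_spindles(session.channels[0].data, session.fs)
print(f"spindles   = {spindle_rate(events, session.duration):.1f} per min")
```

prints

```
baseline B = +0.0 pp
pct_slow   = 81.7 %
pct_theta  = 18.3 %
spindles   = 19.0 per min
```

The generator drew a ZT13 striatal state sequence (60 % slow-state
occupancy on average; this seed realized 80 % slow time) and the
classifier recovers it: 81.7 % of windows labelled slow against the
empirical baseline.  The detector finds 38 events — the bursts the
generator nested on slow-wave crests — i.e. 19.0 per minute.

Estimator-style interfaces (`BandPowerTransform`, `ModeClassifier`,
`SpindleDetector`) follow sklearn conventions (`fit`/`transform`/`predict`,
`get_params`, fitted `*_` attributes) and compose with sklearn tooling.

A thin CLI covers the same pipeline from the shell:

```bash
lfpmodes simulate --zt 13 --condition pre --seed 42 -o out/
lfpmodes analyze out/manifest.json -o results/
lfpmodes stats results/summary.csv --measure pct_slow -o summary/
```

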