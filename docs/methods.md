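# Methods

This note documents the models and procedures implemented in `lfpmodes`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Signal conditioning

Signals are assumed to arrive hardware-high-passed (≈0.1 Hz); the package
does not reapply a high-pass.  Decimation (e.g. 30 300 → 2020 Hz, factor
15) uses a polyphase FIR anti-alias filter with `zero_phase=True`; an IIR
Chebyshev design was rejected because its passband ripple exceeds the 1 %
amplitude-preservation budget for in-band tones.  Only integer rate ratios
are supported — arbitrary resampling is out of scope.  The 300 Hz low-pass
is a 4th-order Butterworth applied forward–backward (zero phase), so
spindle/slow-wave timing comparisons carry no group-delay bias.  Analysis
windows are contiguous, non-overlapping 2-s segments; a trailing partial
window is discarded, giving exactly 60 windows per 120-s period.

## Band power

Per window, a Hann-tapered periodogram is integrated over five half-open
bands [lo, hi) — (0.1–3), (3–8), (8–13), (13–30), (30–55) Hz — and
normalized to the total 0.1–55 Hz power, so the five percentages sum to
100 exactly.  Half-open assignment puts a boundary bin (3 Hz) in the upper
band, never in both.  The Hann taper limits leakage from large slow waves
into 3–8 Hz; with 2-s windows the resolution is 0.5 Hz, and taper leakage
into the first neighboring bin is the reason a pure 3 Hz tone shows a
~17 % delta-band residue — the integral, not single bins, is the measure.
"0–3 Hz" and "0.1–3 Hz" are treated as the same band (0.1–3, the delta
band as defined here).

## Mode classification

The dominance difference D = %P(0.1–3) − %P(3–8) is formed per window.
The session baseline B is the mean of D over windows with |D| ≤ 10
percentage points (transition windows).  If a session has none, the
tolerance widens in +5 pp steps to at most 25 pp with a warning;
`compute_baseline` raises beyond that.  At the session level a channel
that still has no transition windows is classified against B = 0 with a
warning — a monomodal period belongs wholly to its dominant mode, and
refusing to classify it would bias multi-session occupancy averages
downward.  Thresholds are B + 20 (slow) and B − 15 (theta); both offsets
are fixed empirical defaults exposed in `ModeThresholds`.  The thresholds
are applied to D, not to the raw delta percentage, because the baseline is
defined on D ≈ 0; this is an interpretive choice.  "0 ± 10" is read as
±10 percentage points of total power, not ±10 % relative.

## Spindle detection

The slow-wave phase reference is the 0.1–3 Hz zero-phase band-passed
signal; crests are positive local maxima separated by ≥ 0.4 s with
prominence ≥ 0.5 slow-band SD.  The prominence floor is our addition (the
crest definition is otherwise underdetermined): without it, sub-SD ripples
near troughs qualify as crests and defeat the ±0.25 s coupling rule.  The
envelope is |band-pass 8–20 Hz| smoothed with a 71 ms boxcar (one cycle of
14 Hz, kernel length rounded to the millisecond) and z-scored over the
whole recording period — the period is the analysis unit, so its
statistics set the threshold.  Candidate events are contiguous ≥ 2 SD
envelope runs; an event is kept iff its envelope peak lies within ±0.25 s
of a crest (equivalently: the two peaks lie within 0.5 s of each other —
one predicate serves both phrasings), and each crest keeps only its
highest-z event so counts are well defined.  Rates are events per minute;
the normalized rate divides by the fraction of time spent in slow-wave
activity (pct_slow/100) and is undefined (raised) at pct_slow = 0.

## Statistics

The observation unit is one electrode (or electrode pair) per recording
period.  Baseline diurnal effects: one-way ANOVA of the measure over ZT
with units as observations, computed from explicit between/within sums of
squares (kept explicit so the oracle comparison in the tests is
meaningful); Tukey HSD (studentized range, scipy) for pairwise ZT
contrasts.  Drug-by-time effects: mixed two-way ANOVA (pingouin), ZT
between units, condition within; Tukey HSD over the eight ZT × condition
cell means.  A literally zero effect (identical pre/post values) yields a
0/0 F in the mixed model and is reported as F = 0, p = 1.  Medial and
lateral striatal rows are poolable in the summary table, mirroring how the
two striatal sites are combined for analysis.  No multiplicity adjustment
is applied across measures or bands (only Tukey within an ANOVA);
α = 0.05 two-sided throughout.

The type-I calibration and power simulations use one synthetic channel per
animal, drawn independently: electrodes recorded in the same session share
a state sequence, and pooling them as observations would correlate the
errors the ANOVA assumes independent.  With 4 independent units per ZT and
no true ZT effect, the one-way test rejects at close to the nominal 5 %
over 400 simulated experiments of 120-s periods (shorter scaled-down
periods leave too few state bouts per session, and the resulting lumpy
observation distribution makes the F-test conservative).  Power
simulations use 120-s periods and 16 units per ZT — the observation counts
implied by the study design's denominator degrees of freedom — and detect
the ZT13-only drug shift as a significant interaction in ≥ 85 % of
replicates.

## The synthetic generator

One master signal drives all channels of a session:

- **States.**  A two-state semi-Markov alternation with
  shifted-exponential dwells.  Dwell means are 2·`mean_dwell`·p (slow) and
  2·`mean_dwell`·(1−p) (theta) so stationary slow occupancy equals p with
  overall mean dwell `mean_dwell` (default 10 s).  Bouts have a 1-s floor,
  and the minority state's mean bout never falls below 0.2·`mean_dwell`
  (the majority mean is raised to preserve p): the minority mode appears
  as discrete multi-second episodes, not sub-window flickers.  The initial
  state is drawn from the stationary distribution, so finite-duration
  occupancy is unbiased.
- **Oscillations.**  Jittered sinusoids: per-cycle frequency jitter (8 %
  SD, clipped to ±25 %) and amplitude jitter (15 %), slow 1 Hz amplitude
  1.0, theta 4.5 Hz amplitude 0.8 (theta is the smaller-amplitude mode).
  Each component also waxes and wanes under a lognormal envelope
  (log-SD 0.18, 4-s correlation length), and each state leaks a reduced
  copy of the other band's oscillation (0.40 of theta during slow states,
  0.20 of slow during theta states).  Envelope modulation and leak are
  what give the per-window dominance values a continuum — matching the
  window-scatter structure of real periods — rather than two disconnected
  clusters; without them the empirical-baseline step has no transition
  windows to average.  Segments are edge-tapered (0.2-s raised cosine) so
  state switches do not inject broadband clicks into the spindle band.
- **Spindles.**  At each slow-wave crest, with probability 0.35, a Hann-
  enveloped 14 Hz burst (0.4 s, amplitude 0.55 — several times the 8–20 Hz
  background envelope) is added, provided the burst fits inside its slow
  bout clear of the edge tapers.  `spindle_offset` moves bursts to a
  fraction of the actual crest-to-crest cycle (0.5 = trough), giving an
  exact negative control for coupling detectors.
- **Channels.**  Each channel is
  `master + rms·(b·N_structure + c·N_pair + d·N_channel + g·N_pink)` with
  frozen gains b = 0.62, c = 0.28, d = 0.18, g = 0.20.  N_structure,
  N_pair and N_channel are independent realizations of broadband
  state-modulated band-limited noise — the whole montage expresses one
  state sequence through partly independent local activity, shared per
  structure (striatum+cortex vs cerebellum), per electrode pair, and
  private per channel.  Structure-level sharing vs independence is what
  caps cross-structure coherence (a second phase-shifted sinusoid would
  not, because magnitude-squared coherence is blind to a fixed phase lag);
  pair- and channel-level components set the within-structure tiers; and
  because the background follows the active band, per-window band
  percentages stay strongly anticorrelated, as in real periods.  Carrier
  bands are capped below 7 Hz (4th-order edges) so state noise never
  masquerades as spindle-band activity.  N_pink is a state-independent
  1/f² floor whose white tail takes over above 30 Hz, where extracellular
  spectra flatten.  The gains were calibrated once by simulation so the
  analyzed 0.1–8 Hz coherence of the default six-channel montage lands on
  the three observed tiers (within pair 0.92, between pair 0.82,
  cross-structure 0.53) and then frozen; the calibration is referenced to
  the 250 Hz analysis rate used throughout the experiment batteries
  (absolute tier values drift by a few hundredths at other rates; the
  ordering does not).
- **Presets.**  Slow-state occupancy defaults: ZT1 0.942 (Str) / 0.869
  (CB); ZT13 0.600 (Str) / 0.423 (CB) (ZT13 is anchored via theta
  occupancies 0.400/0.577, with slow = 1 − theta in the two-state model).
  ZT7 and ZT19 are linear midpoints of the ZT1/ZT13 anchors and are
  flagged `interpolated` — they are stand-ins, not observed values.
  `apply_raclopride` shifts occupancy toward slow by +0.15 at ZT13 and 0
  elsewhere (configurable), clipped to 1.

### What the generator does not emulate

Real LFP features outside its scope: 1/f broadband structure above the
noise floor crossover, asymmetric (non-sinusoidal) slow-wave shapes,
state-dependent spindle morphology, inter-animal variability beyond the
occupancy presets, heart-rate artifacts, and any within-session drift
(anesthesia depth, temperature).  Passing recovery tests therefore shows
that the analysis implements its definitions correctly and is
well-conditioned under realistic spectral structure — not that it is
robust to every artifact of real recordings.

## Problem sizes and numerical choices

Experiment batteries run at 250 Hz sampling (200 Hz for the many-replicate
ANOVA simulations) with 120-s periods; all analysis bands lie far below
Nyquist at those rates and every measure is a band integral, so results
are rate-insensitive (the coherence-tier calibration is rate-referenced as
noted above).  Multi-seed batteries use 10–20 seeds per condition; the
null-calibration uses 400 simulated experiments.  Degenerate inputs raise
rather than return sentinel values: all-zero windows (zero total power),
constant series in the correlation, empty bands, singleton Tukey groups,
unbalanced within-unit designs.  Ties in spindle dedup resolve to the
higher envelope z; equal-z ties keep the first-seen event.

## Known limitations

- The empirical-threshold classifier is not a state-segmentation model; a
  hidden-Markov or changepoint approach would use the temporal structure
  the classifier ignores, but is deliberately out of scope.
- Per-window coherence averages coherence magnitudes across windows
  (literal reading of the period-averaging step); averaging cross-spectra
  before forming coherence is a defensible alternative that would give
  slightly lower, less biased values.
- With three half-overlapped 1-s segments per 2-s window, the coherence
  estimator carries a large positive small-sample bias (independent inputs
  average ≈ 0.35–0.40, below the 0.45 bound the tests assert); reported
  coherence values are only comparable between estimators with the same
  segmentation.
- Exact replication of the study's denominator degrees of freedom is not
  attempted; the unit-of-analysis reading (electrodes/pairs as
  observations) reproduces their structure but not every reported df.
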