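"""Synthetic multi-channel LFP sessions with known ground truth.

The generator emulates the statistical structure of 120-s urethane-state
recording periods: a semi-Markov alternation between a slow (~1 Hz) and a
theta-like (4–5 Hz) oscillatory state with exponential dwell times rescaled
to a target slow-state occupancy; jittered-sinusoid oscillations; 8–20 Hz
Hann-enveloped spindle bursts added at slow-wave peaks with fixed
probability; and channels formed as tier-weighted mixtures of a shared
master signal plus broadband state-modulated components shared per
structure and per electrode pair and private per channel, producing the
within-pair > between-pair > cross-structure coherence ordering.

Occupancy presets are anchored to the study conditions at ZT1 and ZT13
(slow-state occupancy 94.2 % Str / 86.9 % CB at ZT1; theta-state occupancy
40.0 % Str / 57.7 % CB at ZT13); ZT7 and ZT19 defaults are interpolated
intermediates and flagged as such.  A D2-antagonist ("post") session shifts
occupancy toward the slow state by 15 percentage points at ZT13 only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import REGIONS, STRUCTURE_GROUP, Channel, RecordingSession, write_session
from .spectral import pair_relation

__all__ = [
    "MixingParams",
    "SimulationSpec",
    "GroundTruth",
    "zt_preset",
    "apply_raclopride",
    "spec_for",
    "make_session",
    "draw_state_intervals",
    "write_ground_truth",
    "DEFAULT_LAYOUT",
    "SAMPLED_ZT",
]

SAMPLED_ZT = (1, 7, 13, 19)

#: Slow-state occupancy presets (fraction of time).  ZT1 and ZT13 anchor to
#: the study conditions; ZT7/ZT19 are linear midpoints on the ZT1<->ZT13 axis
#: (the study reports them only graphically) and are flagged interpolated.
_ZT_SLOW_OCCUPANCY = {
    "Str": {1: 0.942, 13: 0.600},
    "CB": {1: 0.869, 13: 0.423},
}

#: Default six-channel montage: one medial-striatal pair, one
#: lateral-striatal pair, one cerebellar pair.
DEFAULT_LAYOUT = (
    ("MStr_a", "MStr", "p1"),
    ("MStr_b", "MStr", "p1"),
    ("LStr_a", "LStr", "p2"),
    ("LStr_b", "LStr", "p2"),
    ("CB_a", "CB", "p3"),
    ("CB_b", "CB", "p3"),
)


@dataclass(frozen=True)
class MixingParams:
    """Shared-source gains and noise levels, relative to the master-signal RMS.

    Channels are ``master + rms·(structure_gain·N_structure +
    pair_gain·N_pair + channel_noise_sd·N_channel + pink_gain·N_pink)``.
    N_structure, N_pair and N_channel are unit-variance broadband
    state-modulated components — independent realizations of the session's
    state sequence, shared per structure, per electrode pair, and private
    per channel respectively — so the background follows the active band
    and window band-percentages stay anticorrelated as in real periods.
    N_pink is a private state-independent 1/f^exponent floor (white above
    ``noise_crossover`` Hz).  The defaults were calibrated once by
    simulation so the analyzed 0.1–8 Hz coherence of the default montage at
    the 250 Hz analysis rate lands on the three observed tiers (within pair
    0.92, between pair 0.82, cross-structure 0.53), then frozen.
    """

    structure_gain: float = 0.62
    pair_gain: float = 0.28
    channel_noise_sd: float = 0.18
    pink_gain: float = 0.20
    noise_exponent: float = 2.0
    noise_crossover: float = 30.0

    def __post_init__(self) -> None:
        for name in ("structure_gain", "pair_gain", "channel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_crossover <= 0:
            raise ValueError("noise_crossover must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic recording period.

    ``spindle_offset`` places bursts away from the slow-wave crest as a
    fraction of the actual crest-to-crest cycle (0 = on the crest, the
    physiological default; 0.5 = at the trough, a negative control for
    coupling detectors).
    """

    zt: int = 1
    condition: str = "pre"
    duration: float = 120.0
    fs: float = 2020.0
    slow_occupancy: float = 0.9
    mean_dwell: float = 10.0
    slow_freq: float = 1.0
    theta_freq: float = 4.5
    slow_amp: float = 1.0
    theta_amp: float = 0.8
    freq_jitter: float = 0.08
    amp_jitter: float = 0.15
    amp_mod_sigma: float = 0.18
    amp_mod_timescale: float = 4.0
    slow_theta_leak: float = 0.40
    theta_slow_leak: float = 0.20
    spindle_prob: float = 0.35
    spindle_freq: float = 14.0
    spindle_dur: float = 0.4
    spindle_amp: float = 0.55
    spindle_offset: float = 0.0
    channel_layout: tuple[tuple[str, str, str], ...] = DEFAULT_LAYOUT
    mixing: MixingParams = field(default_factory=MixingParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.zt not in SAMPLED_ZT:
            raise ValueError(f"zt must be one of {SAMPLED_ZT}, got {self.zt}")
        if self.condition not in ("pre", "post"):
            raise ValueError("condition must be 'pre' or 'post'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.slow_occupancy <= 1.0:
            raise ValueError("slow_occupancy must lie in [0, 1]")
        if self.slow_amp < 0 or self.theta_amp < 0 or self.spindle_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.slow_amp == 0 and self.theta_amp == 0:
            raise ValueError("at least one oscillation amplitude must be positive")
        highest = max(self.theta_freq, self.spindle_freq)
        if self.fs <= 2 * highest:
            raise ValueError(f"fs {self.fs} too low for content up to {highest} Hz")
        for _, region, _ in self.channel_layout:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} in channel_layout")

    @property
    def theta_occupancy(self) -> float:
        return 1.0 - self.slow_occupancy


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    state_intervals: list[tuple[float, float, str]]
    spindle_times: dict[str, list[float]]
    tier_map: dict[str, str]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _normalize_region(region: str) -> str:
    if region in ("Str", "MStr", "LStr"):
        return "Str"
    if region == "CB":
        return "CB"
    raise ValueError(f"unknown region {region!r}; expected Str/MStr/LStr or CB")


def zt_preset(zt: int, region: str) -> dict:
    """Slow/theta occupancy defaults for a sampled zeitgeber time.

    Returns ``{"slow_occupancy", "theta_occupancy", "interpolated"}``.
    ZT1 and ZT13 carry the observed values; ZT7/ZT19 are interpolated
    midpoints (``interpolated=True``).  Unsampled times are an error —
    no silent extrapolation.
    """
    if zt not in SAMPLED_ZT:
        raise ValueError(f"zt {zt} was not sampled; choose one of {SAMPLED_ZT}")
    region = _normalize_region(region)
    anchors = _ZT_SLOW_OCCUPANCY[region]
    if zt in anchors:
        slow = anchors[zt]
        interpolated = False
    else:
        slow = 0.5 * (anchors[1] + anchors[13])
        interpolated = True
    return {
        "slow_occupancy": slow,
        "theta_occupancy": round(1.0 - slow, 10),
        "interpolated": interpolated,
    }


def spec_for(
    zt: int,
    region: str = "Str",
    condition: str = "pre",
    **overrides,
) -> SimulationSpec:
    """Build a SimulationSpec with the occupancy preset for ``(zt, region)``."""
    preset = zt_preset(zt, region)
    spec = SimulationSpec(
        zt=zt, condition="pre", slow_occupancy=preset["slow_occupancy"], **overrides
    )
    if condition == "post":
        spec = apply_raclopride(spec)
    return spec


def apply_raclopride(
    spec: SimulationSpec,
    shift_zt13: float = 0.15,
    shift_other: float = 0.0,
) -> SimulationSpec:
    """Return the post-drug version of a baseline spec.

    D2-receptor antagonism shifts occupancy toward the slow state by about
    15 percentage points at ZT13 (where the slow mode is weakest); at the
    other sampled times the default shift is zero, matching the observed
    significance pattern.  Occupancy is clipped to 1.
    """
    if spec.condition != "pre":
        raise ValueError("spec is already a post-drug spec")
    shift = shift_zt13 if spec.zt == 13 else shift_other
    new_occ = min(1.0, spec.slow_occupancy + shift)
    return replace(spec, condition="post", slow_occupancy=new_occ)


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

SLOW, THETA = "SLOW", "THETA"


def draw_state_intervals(
    rng: np.random.Generator,
    duration: float,
    slow_occupancy: float,
    mean_dwell: float = 10.0,
) -> list[tuple[float, float, str]]:
    """Semi-Markov two-state alternation with exponential dwell times.

    Dwell means are ``2·mean_dwell·p`` (slow) and ``2·mean_dwell·(1−p)``
    (theta) so the stationary slow-state occupancy equals ``p`` while the
    mean dwell over both states stays ``mean_dwell``.  At extreme
    occupancies the minority state keeps a floor of ``0.4·mean_dwell`` on
    its mean bout length (``0.2·mean_dwell``; the majority mean is raised to
    preserve the occupancy): the minority mode appears as discrete episodes,
    as in real recordings, rather than sub-window flickers.  The initial
    state is drawn from the stationary distribution.  Intervals tile
    [0, duration].
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = slow_occupancy
    if p >= 1.0:
        return [(0.0, duration, SLOW)]
    if p <= 0.0:
        return [(0.0, duration, THETA)]
    floor = 0.2 * mean_dwell
    mean_slow = max(2.0 * mean_dwell * p, floor)
    mean_theta = max(2.0 * mean_dwell * (1.0 - p), floor)
    # restore exact stationary occupancy p = m_s / (m_s + m_t)
    if mean_slow / (mean_slow + mean_theta) < p:
        mean_slow = mean_theta * p / (1.0 - p)
    else:
        mean_theta = mean_slow * (1.0 - p) / p
    state = SLOW if rng.random() < p else THETA
    t = 0.0
    intervals = []
    # shifted-exponential dwells: a state shorter than one slow cycle is not
    # meaningful, so bouts have a 1-s floor (means are preserved)
    min_bout = 1.0
    while t < duration:
        mean = mean_slow if state == SLOW else mean_theta
        floor_s = min(min_bout, 0.5 * mean)
        dwell = floor_s + rng.exponential(mean - floor_s)
        end = min(duration, t + dwell)
        if end > t:
            intervals.append((t, end, state))
        t = end
        state = THETA if state == SLOW else SLOW
    return intervals


# ---------------------------------------------------------------------------
# oscillation synthesis
# ---------------------------------------------------------------------------

def _jittered_oscillation(
    rng: np.random.Generator,
    n: int,
    fs: float,
    f0: float,
    amp: float,
    freq_jitter: float,
    amp_jitter: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoid with cycle-to-cycle frequency and amplitude jitter.

    Returns ``(signal, peak_times)`` where peak times are the within-segment
    times (s) at which the instantaneous phase passes π/2 (the wave crest).
    """
    if n == 0 or amp == 0:
        return np.zeros(n), np.array([])
    seg_len = n / fs
    n_cycles = int(np.ceil(seg_len * f0 * 2)) + 4
    freqs = f0 * (1.0 + freq_jitter * rng.standard_normal(n_cycles))
    freqs = np.clip(freqs, 0.75 * f0, 1.25 * f0)
    amps = amp * (1.0 + amp_jitter * rng.standard_normal(n_cycles))
    amps = np.clip(amps, 0.2 * amp, 2.0 * amp)

    cycle_dur = 1.0 / freqs
    bounds = np.r_[0.0, np.cumsum(cycle_dur)]  # cycle start times
    t = np.arange(n) / fs
    k = np.searchsorted(bounds, t, side="right") - 1
    k = np.clip(k, 0, n_cycles - 1)
    phase = 2 * np.pi * (k + (t - bounds[k]) * freqs[k])
    x = amps[k] * np.sin(phase)

    crest = bounds[:-1] + 0.25 * cycle_dur  # phase = pi/2 within each cycle
    peaks = crest[crest < seg_len]
    return x, peaks


def _pink_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    exponent: float = 2.0,
    f_floor: float = 0.1,
    crossover: float = 30.0,
) -> np.ndarray:
    """Unit-variance noise with power ∝ 1/f^exponent above ``f_floor``.

    A white floor takes over above ``crossover`` Hz (where extracellular
    spectra flatten), keeping the high bands non-degenerate without
    flooding the spindle band with white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f = np.maximum(freqs, f_floor)
    gain = np.sqrt(f ** (-exponent) + crossover ** (-exponent))
    gain[0] = 0.0  # no DC
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_envelope(
    rng: np.random.Generator,
    n: int,
    fs: float,
    sigma: float,
    timescale: float,
) -> np.ndarray:
    """Log-normal waxing-and-waning amplitude envelope, unit mean.

    ``sigma`` is the SD of the log-amplitude; ``timescale`` (s) the
    correlation length.  Real urethane-state oscillations wax and wane over
    seconds, which spreads the per-window band percentages into a continuum
    instead of two tight clusters."""
    if sigma <= 0:
        return np.ones(n)
    # Gaussian smoothing in the frequency domain (circular), O(n log n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * (2 * np.pi * freqs * timescale) ** 2)
    g = np.fft.irfft(spec, n=n)
    sd = g.std()
    if sd > 0:
        g = g / sd
    return np.exp(sigma * g - 0.5 * sigma**2)


def _hann(n: int) -> np.ndarray:
    if n <= 1:
        return np.ones(max(n, 0))
    m = np.arange(n)
    return 0.5 - 0.5 * np.cos(2 * np.pi * m / (n - 1))


def _render_state_noise(
    rng: np.random.Generator,
    intervals: list[tuple[float, float, str]],
    spec: "SimulationSpec",
    n_total: int,
) -> np.ndarray:
    """State-modulated band-limited noise with the oscillation's spectral
    footprint but no phase locking to the master signal.

    Used as the structure-level shared component: both structures express
    the same state sequence, but through partly independent local circuits,
    so their shared activity must occupy the oscillation bands while
    decorrelating across independent realizations — band-limited noise does,
    a second sinusoid would not (magnitude-squared coherence ignores a fixed
    phase lag)."""
    from scipy import signal as sps

    def _band_carrier(f0: float) -> np.ndarray:
        lo = max(0.2, 0.5 * f0)
        # capped below the spindle band so state noise never masquerades
        # as 8-20 Hz burst activity
        hi = min(2.2 * f0, 7.0, spec.fs / 2 * 0.9)
        sos = sps.butter(4, (lo, hi), btype="band", fs=spec.fs, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(n_total))
        sd = x.std()
        return x / sd if sd > 0 else x

    carrier_slow = _band_carrier(spec.slow_freq)
    carrier_theta = _band_carrier(spec.theta_freq)
    # matched-variance amplitudes: a sinusoid of amplitude A has RMS A/sqrt(2)
    rms_slow = spec.slow_amp / np.sqrt(2)
    rms_theta = spec.theta_amp / np.sqrt(2)
    env_slow = _smooth_envelope(rng, n_total, spec.fs, spec.amp_mod_sigma, spec.amp_mod_timescale)
    env_theta = _smooth_envelope(rng, n_total, spec.fs, spec.amp_mod_sigma, spec.amp_mod_timescale)

    x = np.zeros(n_total)
    for start, end, state in intervals:
        i0, i1 = int(round(start * spec.fs)), int(round(end * spec.fs))
        i1 = min(i1, n_total)
        if i1 <= i0:
            continue
        if state == SLOW:
            comps = (
                (carrier_slow, rms_slow, env_slow),
                (carrier_theta, spec.slow_theta_leak * rms_theta, env_theta),
            )
        else:
            comps = (
                (carrier_theta, rms_theta, env_theta),
                (carrier_slow, spec.theta_slow_leak * rms_slow, env_slow),
            )
        for carrier, rms, env in comps:
            x[i0:i1] += rms * carrier[i0:i1] * env[i0:i1]
    sd = x.std()
    return x / sd if sd > 0 else x


def _render_oscillation(
    rng: np.random.Generator,
    intervals: list[tuple[float, float, str]],
    spec: "SimulationSpec",
    n_total: int,
) -> tuple[np.ndarray, list[float]]:
    """One realization of the state-driven oscillation (no spindles).

    Each state emits its primary jittered sinusoid plus a leak of the other
    band's oscillation, both under independent waxing/waning envelopes.
    Returns the signal and the slow-wave crest times of SLOW intervals.
    """
    x = np.zeros(n_total)
    env_slow = _smooth_envelope(rng, n_total, spec.fs, spec.amp_mod_sigma, spec.amp_mod_timescale)
    env_theta = _smooth_envelope(rng, n_total, spec.fs, spec.amp_mod_sigma, spec.amp_mod_timescale)

    slow_peaks: list[float] = []
    for start, end, state in intervals:
        i0, i1 = int(round(start * spec.fs)), int(round(end * spec.fs))
        i1 = min(i1, n_total)
        if i1 <= i0:
            continue
        if state == SLOW:
            primary = (spec.slow_freq, spec.slow_amp, env_slow)
            leak = (spec.theta_freq, spec.slow_theta_leak * spec.theta_amp, env_theta)
        else:
            primary = (spec.theta_freq, spec.theta_amp, env_theta)
            leak = (spec.slow_freq, spec.theta_slow_leak * spec.slow_amp, env_slow)
        n_seg = i1 - i0
        # raised-cosine on/off ramps so state switches do not inject
        # broadband clicks into the spindle band
        n_ramp = min(int(round(0.2 * spec.fs)), n_seg // 4)
        taper = np.ones(n_seg)
        if n_ramp > 0:
            ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_ramp) / n_ramp)
            taper[:n_ramp] = ramp
            taper[-n_ramp:] = ramp[::-1]
        for f0, amp, env in (primary, leak):
            if amp <= 0:
                continue
            seg, peaks = _jittered_oscillation(
                rng, n_seg, spec.fs, f0, amp, spec.freq_jitter, spec.amp_jitter
            )
            x[i0:i1] += seg * env[i0:i1] * taper
            if state == SLOW and f0 == spec.slow_freq:
                slow_peaks.extend(start + peaks)
    return x, slow_peaks


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def make_session(
    spec: SimulationSpec,
    animal: str = "sim",
) -> tuple[RecordingSession, GroundTruth]:
    """Generate one synthetic recording period and its ground truth.

    Identical spec and seed give bit-identical output.
    """
    # separate substreams: the state sequence consumes its own stream, so
    # two specs differing only in occupancy (e.g. pre vs post drug at the
    # same seed) share their underlying dwell draws and signal noise —
    # paired comparisons then isolate the occupancy shift
    ss = np.random.SeedSequence(spec.seed) if spec.seed is not None else np.random.SeedSequence()
    rng_states, rng = (np.random.default_rng(c) for c in ss.spawn(2))
    n_total = int(round(spec.duration * spec.fs))

    intervals = draw_state_intervals(rng_states, spec.duration, spec.slow_occupancy, spec.mean_dwell)

    master, slow_peaks = _render_oscillation(rng, intervals, spec, n_total)

    # spindle bursts nested at slow-wave crests
    spindle_times: list[float] = []
    n_burst = int(round(spec.spindle_dur * spec.fs))
    envelope = _hann(n_burst)
    slow_bounds = [(s, e) for s, e, st in intervals if st == SLOW]
    # the whole burst must stay inside the slow bout that owns the peak,
    # clear of the 0.2-s on/off ramps at the bout edges
    margin = 0.5 * spec.spindle_dur + 0.3

    def _contained(peak: float, center: float) -> bool:
        for s, e in slow_bounds:
            if s <= peak < e:
                return center - margin >= s and center + margin <= e
        return False

    peaks_arr = np.asarray(slow_peaks)
    for p_idx, peak in enumerate(slow_peaks):
        if spec.spindle_prob <= 0 or rng.random() >= spec.spindle_prob:
            continue
        if spec.spindle_offset == 0.0:
            center = peak
        else:
            # offset is a fraction of the actual crest-to-crest cycle, so an
            # offset of 0.5 sits at the trough regardless of cycle jitter
            if p_idx + 1 >= len(peaks_arr):
                continue
            cycle = peaks_arr[p_idx + 1] - peak
            if not 0 < cycle < 2.0 / spec.slow_freq:
                continue
            center = peak + spec.spindle_offset * cycle
        if not _contained(peak, center):
            continue
        c_idx = int(round(center * spec.fs))
        i0 = c_idx - n_burst // 2
        i1 = i0 + n_burst
        if i0 < 0 or i1 > n_total:
            continue
        t_rel = (np.arange(i0, i1) - c_idx) / spec.fs
        master[i0:i1] += spec.spindle_amp * envelope * np.sin(
            2 * np.pi * spec.spindle_freq * t_rel
        )
        spindle_times.append(center)

    rms = master.std()
    if rms == 0:
        rms = 1.0

    mix = spec.mixing
    structure_groups = sorted({STRUCTURE_GROUP[r] for _, r, _ in spec.channel_layout})
    pair_ids = sorted({p for _, _, p in spec.channel_layout})

    def _noise() -> np.ndarray:
        return _pink_noise(
            rng, n_total, spec.fs, mix.noise_exponent, crossover=mix.noise_crossover
        )

    # shared activity at every level is state-modulated broadband noise:
    # the whole montage expresses one state sequence through partly
    # independent local circuits.  Structure-level sharing vs independence
    # caps cross-structure coherence; pair- and channel-level components
    # set the within-structure tiers; because all of it follows the state's
    # band, window band-percentages stay strongly anticorrelated as in real
    # periods.  A small state-independent 1/f^2 floor adds broadband
    # realism without diluting band dominance.
    struct_noise = {
        g: _render_state_noise(rng, intervals, spec, n_total) for g in structure_groups
    }
    pair_noise = {p: _render_state_noise(rng, intervals, spec, n_total) for p in pair_ids}

    channels = []
    for name, region, pair_id in spec.channel_layout:
        x = master + rms * (
            mix.structure_gain * struct_noise[STRUCTURE_GROUP[region]]
            + mix.pair_gain * pair_noise[pair_id]
            + mix.channel_noise_sd * _render_state_noise(rng, intervals, spec, n_total)
            + mix.pink_gain * _noise()
        )
        channels.append(Channel(name=name, region=region, pair_id=pair_id, data=x))

    session = RecordingSession(
        animal=animal, zt=spec.zt, condition=spec.condition, fs=spec.fs, channels=channels
    )

    tier_map = {}
    for i in range(len(channels)):
        for j in range(i + 1, len(channels)):
            a, b = channels[i], channels[j]
            tier_map[f"{a.name}|{b.name}"] = pair_relation(
                a.region, a.pair_id, b.region, b.pair_id
            )
    truth = GroundTruth(
        state_intervals=intervals,
        spindle_times={ch.name: list(spindle_times) for ch in channels},
        tier_map=tier_map,
    )
    return session, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Serialize ground truth as JSON next to the session files."""
    path = Path(path)
    payload = {
        "state_intervals": [[s, e, st] for s, e, st in truth.state_intervals],
        "spindle_times": truth.spindle_times,
        "tier_map": truth.tier_map,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def simulate_to_dir(
    spec: SimulationSpec,
    outdir: str | Path,
    fmt: str = "f32",
    animal: str = "sim",
) -> Path:
    """Generate a session, write signals + manifest + ground truth; return
    the manifest path."""
    session, truth = make_session(spec, animal=animal)
    manifest = write_session(session, outdir, fmt=fmt)
    write_ground_truth(truth, Path(outdir) / "ground_truth.json")
    return manifest
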