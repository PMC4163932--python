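"""End-to-end simulation experiments: generate → analyze → measure.

These drivers glue the synthetic generator to the analysis layers and return
the recovered quantities (mode occupancies, drug shifts, coherence tiers,
spindle detection performance, ANOVA calibration and power).  They are what
the reproduction script and the heavier property tests run.  Sessions are
the study's 120-s periods; sampling rates default to reduced values
(250 Hz for signal-level experiments, 200 Hz for the many-replicate ANOVA
simulations) chosen so full experiment batteries complete in minutes while
leaving every band edge below Nyquist — all measures are band integrals
far below Nyquist, so they are insensitive to the rate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .modes import band_power_correlation, classify_session
from .preprocess import AnalysisConfig, segment_windows
from .simulate import (
    SimulationSpec,
    apply_raclopride,
    make_session,
    spec_for,
)
from .spectral import BandPowerTransform, relation_summary, session_coherence
from .spindles import SpindleParams, detect_spindles
from .stats import oneway_anova_zt, twoway_rm_anova

__all__ = [
    "SINGLE_STR_LAYOUT",
    "SINGLE_CB_LAYOUT",
    "measure_occupancy",
    "occupancy_recovery",
    "raclopride_shift",
    "coherence_tiers",
    "spindle_performance",
    "mixed_session_correlations",
    "simulated_zt_experiment",
    "null_type1_rate",
    "interaction_power",
]

SINGLE_STR_LAYOUT = (("Str_0", "MStr", "p1"),)
SINGLE_CB_LAYOUT = (("CB_0", "CB", "p1"),)

_LAYOUTS = {"Str": SINGLE_STR_LAYOUT, "CB": SINGLE_CB_LAYOUT}


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def measure_occupancy(spec: SimulationSpec, config: AnalysisConfig | None = None):
    """Generate one session and run the dominance classifier on its first
    channel; returns (pct_slow, pct_theta)."""
    config = config or AnalysisConfig(fs_target=spec.fs, lowpass_cutoff=min(300.0, spec.fs / 2 * 0.9))
    session, _ = make_session(spec)
    cls = classify_session(session, config)[session.channels[0].name]
    return cls.pct_slow, cls.pct_theta


def occupancy_recovery(
    zt: int,
    region: str,
    n_seeds: int = 20,
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 120.0,
) -> dict:
    """Mean recovered pct_slow / pct_theta for a ZT preset over seeds."""
    seeds = _child_seeds(seed, n_seeds)
    slows, thetas = [], []
    for s in seeds:
        spec = spec_for(zt, region, fs=fs, duration=duration,
                        channel_layout=_LAYOUTS[region], seed=int(s))
        ps, pt = measure_occupancy(spec)
        slows.append(ps)
        thetas.append(pt)
    from .simulate import zt_preset

    preset = zt_preset(zt, region)
    return {
        "pct_slow": float(np.mean(slows)),
        "pct_theta": float(np.mean(thetas)),
        "target_slow": 100.0 * preset["slow_occupancy"],
        "target_theta": 100.0 * preset["theta_occupancy"],
    }


def raclopride_shift(
    n_seeds: int = 20,
    seed: int = 0,
    zt: int = 13,
    region: str = "Str",
    fs: float = 250.0,
    duration: float = 120.0,
) -> dict:
    """Mean pre→post change in pct_slow and pct_theta at one ZT.

    Pre and post sessions share a seed (common random numbers): the state
    sequences are drawn from the same underlying stream with rescaled dwell
    means, so the paired difference isolates the occupancy shift instead of
    stacking two sessions' sampling noise.
    """
    seeds = _child_seeds(seed, n_seeds)
    d_slow, d_theta = [], []
    for s in seeds:
        pre = spec_for(zt, region, fs=fs, duration=duration,
                       channel_layout=_LAYOUTS[region], seed=int(s))
        post = apply_raclopride(pre)
        ps0, pt0 = measure_occupancy(pre)
        ps1, pt1 = measure_occupancy(post)
        d_slow.append(ps1 - ps0)
        d_theta.append(pt1 - pt0)
    return {"d_pct_slow": float(np.mean(d_slow)), "d_pct_theta": float(np.mean(d_theta))}


def coherence_tiers(
    n_seeds: int = 10,
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 120.0,
    zt: int = 1,
    band: str = "0.1-8",
) -> dict:
    """Analyzed mean coherence per anatomical tier of the default montage.

    Returns per-tier means over seeds plus ``ordered_every_seed``: whether
    within_pair > between_pair > str_cb held in every single session.
    """
    seeds = _child_seeds(seed, n_seeds)
    per_seed = []
    for s in seeds:
        spec = spec_for(zt, "Str", fs=fs, duration=duration, seed=int(s))
        session, _ = make_session(spec)
        coh = session_coherence(session)
        summary = relation_summary(coh, bands=(band,))
        vals = summary.set_index("relation")["mean_coherence"]
        per_seed.append(vals)
    table = pd.DataFrame(per_seed)
    ordered = bool(
        ((table["within_pair"] > table["between_pair"])
         & (table["between_pair"] > table["str_cb"])).all()
    )
    return {
        "within_pair": float(table["within_pair"].mean()),
        "between_pair": float(table["between_pair"].mean()),
        "str_cb": float(table["str_cb"].mean()),
        "ordered_every_seed": ordered,
    }


def spindle_performance(
    n_seeds: int = 20,
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 120.0,
    spindle_offset: float = 0.0,
    match_window: float = 0.15,
    spindle_prob: float = 0.35,
) -> dict:
    """Recall/precision of spindle detection against generator burst times.

    A detection matches a ground-truth burst when the envelope peak lies
    within ``match_window`` seconds of the burst center; each truth event can
    be matched once.
    """
    seeds = _child_seeds(seed, n_seeds)
    tp = fp = fn = 0
    total_detected = 0
    for s in seeds:
        spec = spec_for(1, "Str", fs=fs, duration=duration,
                        channel_layout=SINGLE_STR_LAYOUT, seed=int(s),
                        spindle_prob=spindle_prob, spindle_offset=spindle_offset)
        session, truth = make_session(spec)
        ch = session.channels[0]
        events = detect_spindles(ch.data, fs, SpindleParams(), channel=ch.name)
        detected = np.array([ev.peak_time for ev in events])
        total_detected += len(detected)
        truth_times = np.array(truth.spindle_times[ch.name])
        matched_truth = np.zeros(len(truth_times), dtype=bool)
        for t_det in detected:
            if len(truth_times) == 0:
                fp += 1
                continue
            d = np.abs(truth_times - t_det)
            cand = int(np.argmin(np.where(matched_truth, np.inf, d)))
            if not matched_truth[cand] and d[cand] <= match_window:
                matched_truth[cand] = True
                tp += 1
            else:
                fp += 1
        fn += int((~matched_truth).sum())
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_detected": total_detected,
        "n_true": tp + fn,
    }


def spindle_offset_control(
    n_seeds: int = 20,
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 120.0,
    spindle_offset: float = 0.5,
) -> int:
    """Total detections when bursts sit at slow-wave troughs.

    Constructed negative control isolating the ±proximity predicate: bursts
    are placed half a slow cycle away from every crest, on a low-mixing-noise
    montage whose slow-wave crests are unambiguous.  The expected count is
    zero.
    """
    from .simulate import MixingParams

    mix = MixingParams(structure_gain=0.15, pair_gain=0.1, channel_noise_sd=0.15)
    seeds = _child_seeds(seed, n_seeds)
    total = 0
    for s in seeds:
        spec = spec_for(1, "Str", fs=fs, duration=duration,
                        channel_layout=SINGLE_STR_LAYOUT, seed=int(s),
                        spindle_offset=spindle_offset, mixing=mix)
        session, _ = make_session(spec)
        total += len(detect_spindles(session.channels[0].data, fs, SpindleParams()))
    return total


def mixed_session_correlations(
    n_seeds: int = 10,
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 120.0,
) -> list[float]:
    """Pearson r between per-window slow and theta percents, one mixed-state
    (ZT13-like) session per seed."""
    seeds = _child_seeds(seed, n_seeds)
    out = []
    for s in seeds:
        spec = spec_for(13, "Str", fs=fs, duration=duration,
                        channel_layout=SINGLE_STR_LAYOUT, seed=int(s))
        session, _ = make_session(spec)
        config = AnalysisConfig(fs_target=fs)
        windows = segment_windows(session.channels[0].data, fs, config.window_len)
        percents = BandPowerTransform(fs=fs, config=config).transform(windows)
        r, _ = band_power_correlation(percents[:, 0], percents[:, 1])
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# simulated multi-animal experiments for the statistics layer
# ---------------------------------------------------------------------------

def simulated_zt_experiment(
    seed: int,
    occupancy_by_zt: dict[int, float] | None = None,
    n_units: int = 4,
    duration: float = 120.0,
    fs: float = 200.0,
    conditions: tuple[str, ...] = ("pre",),
    raclopride_shift_zt13: float = 0.15,
) -> pd.DataFrame:
    """Simulate one multi-animal experiment → tidy pct_slow summary table.

    Each unit is an independent single-channel session (one per animal ×
    condition), so observations are statistically independent — the premise
    of treating units as observations in the ANOVAs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for zt in (1, 7, 13, 19):
        for u in range(n_units):
            animal = f"zt{zt}_a{u}"
            if occupancy_by_zt is None:
                from .simulate import zt_preset

                occ = zt_preset(zt, "Str")["slow_occupancy"]
            else:
                occ = occupancy_by_zt[zt]
            for condition in conditions:
                occ_c = occ
                if condition == "post" and zt == 13:
                    occ_c = min(1.0, occ + raclopride_shift_zt13)
                spec = SimulationSpec(
                    zt=zt,
                    condition="pre",
                    duration=duration,
                    fs=fs,
                    slow_occupancy=occ_c,
                    channel_layout=SINGLE_STR_LAYOUT,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if condition == "post":
                    spec = replace(spec, condition="post")
                ps, pt = measure_occupancy(spec)
                rows.append(
                    {
                        "animal": animal,
                        "zt": zt,
                        "condition": condition,
                        "unit": f"u{u}",
                        "measure": "pct_slow",
                        "band": "",
                        "value": ps,
                    }
                )
    return pd.DataFrame(rows)


def null_type1_rate(
    n_experiments: int = 400,
    seed: int = 0,
    n_units: int = 4,
    duration: float = 120.0,
    fs: float = 200.0,
    occupancy: float = 0.6,
    alpha: float = 0.05,
) -> dict:
    """False-positive rate of the baseline ZT ANOVA with no true ZT effect.

    Every ZT level uses the same generator occupancy, so rejections are pure
    type-I errors.
    """
    seeds = _child_seeds(seed, n_experiments)
    flat = {zt: occupancy for zt in (1, 7, 13, 19)}
    rejections = 0
    for s in seeds:
        summary = simulated_zt_experiment(int(s), occupancy_by_zt=flat,
                                          n_units=n_units, duration=duration, fs=fs)
        res = oneway_anova_zt(summary, "pct_slow")
        if res.p < alpha:
            rejections += 1
    return {"rate": rejections / n_experiments, "n": n_experiments}


def interaction_power(
    n_reps: int = 20,
    seed: int = 0,
    n_units: int = 16,
    duration: float = 120.0,
    fs: float = 200.0,
    alpha: float = 0.05,
) -> dict:
    """Detection rates for the drug × time-of-day interaction.

    Simulates experiments with the study presets and a 15 pp slow shift at
    ZT13 only; returns the fraction of replicates with a significant
    interaction and the fraction where Tukey flags the ZT13 pre-vs-post cell
    pair while flagging no other within-ZT pre/post pair.
    """
    seeds = _child_seeds(seed, n_reps)
    hits = 0
    zt13_only = 0
    for s in seeds:
        summary = simulated_zt_experiment(
            int(s), n_units=n_units, duration=duration, fs=fs, conditions=("pre", "post")
        )
        res = twoway_rm_anova(summary, "pct_slow")
        if res.interaction.p < alpha:
            hits += 1
        if len(res.cell_tukey):
            tk = res.cell_tukey

            def _pair_p(zt: int) -> float:
                mask = (
                    tk["group_i"].str.startswith(f"ZT{zt}:")
                    & tk["group_j"].str.startswith(f"ZT{zt}:")
                )
                return float(tk.loc[mask, "p_adj"].min())

            if _pair_p(13) < alpha and all(_pair_p(z) >= alpha for z in (1, 7, 19)):
                zt13_only += 1
    return {
        "interaction_rate": hits / n_reps,
        "zt13_posthoc_rate": zt13_only / n_reps,
        "n": n_reps,
    }
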