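"""Per-window band power and inter-electrode coherence.

Band power is the Hann-tapered periodogram of each 2-s window, integrated
over half-open frequency bands ``[lo, hi)`` and expressed as a percentage of
the total 0.1–55 Hz power; the five default bands tile that range so each
window's percentages sum to 100.  Coherence is Welch magnitude-squared
coherence computed within each 2-s window from three Hann-tapered 1-s
sub-segments with 50 % overlap (1 Hz resolution), then averaged over the
bins of a band and over the windows of a recording period.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import STRUCTURE_GROUP, AnalysisConfig, RecordingSession, segment_windows

__all__ = [
    "BandPowerTransform",
    "window_band_percent",
    "period_band_power",
    "window_coherence",
    "band_coherence",
    "pair_relation",
    "session_band_power",
    "session_coherence",
    "relation_summary",
    "RELATION_LABELS",
]

RELATION_LABELS = (
    "within_pair",
    "between_pair",
    "str_cb",
    "ctx_str_vertical",
    "ctx_str_offset",
    "ctx_cb",
)


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Boolean mask of frequency bins in the half-open band [lo, hi)."""
    lo, hi = band
    return (freqs >= lo) & (freqs < hi)


def window_band_percent(
    window: Sequence[float],
    fs: float,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Integrated percent power per band for a single analysis window.

    Returns one percentage per configured band, relative to the total power
    in ``config.total_band`` (0.1–55 Hz by default).  Bands are half-open
    ``[lo, hi)`` so a boundary bin (e.g. 3 Hz) is never counted twice.
    """
    config = config or AnalysisConfig()
    window = np.asarray(window, dtype=float)
    freqs, pxx = sps.periodogram(window, fs=fs, window="hann", detrend="constant")
    total = pxx[_band_slice(freqs, config.total_band)].sum()
    if total <= 0:
        raise ValueError("zero total power in window")
    return np.array(
        [100.0 * pxx[_band_slice(freqs, band)].sum() / total for band in config.band_edges]
    )


class BandPowerTransform(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: windows → percent band power.

    Parameters
    ----------
    fs : float
        Sampling rate of the windows, Hz.
    config : AnalysisConfig, optional
        Band edges and total band; the defaults are the five canonical bands
        tiling 0.1–55 Hz.
    """

    def __init__(self, fs: float = 2020.0, config: AnalysisConfig | None = None):
        self.fs = fs
        self.config = config

    def fit(self, X: np.ndarray, y=None) -> "BandPowerTransform":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of shape (n_windows, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return an array of shape (n_windows, n_bands) of percentages."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of shape (n_windows, n_samples)")
        config = self.config or AnalysisConfig()
        return np.vstack([window_band_percent(w, self.fs, config) for w in X])


def period_band_power(values: Sequence[float]) -> float:
    """Arithmetic mean across the windows of one recording period."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no windows to average")
    return float(values.mean())


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def window_coherence(
    x_win: Sequence[float],
    y_win: Sequence[float],
    fs: float,
    subseg_len: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of one window pair at 1 Hz resolution.

    Welch estimate over Hann-tapered sub-segments of ``subseg_len`` seconds
    with 50 % overlap — three segments for a 2-s window, the coarsest
    division that still resolves 1 Hz bins for the slow band.  Returns
    ``(freqs, coherence)``.
    """
    x_win = np.asarray(x_win, dtype=float)
    y_win = np.asarray(y_win, dtype=float)
    if x_win.shape != y_win.shape:
        raise ValueError(f"length mismatch: {x_win.shape} vs {y_win.shape}")
    nperseg = int(round(subseg_len * fs))
    freqs, coh = sps.coherence(
        x_win, y_win, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, coh


def band_coherence(freqs: np.ndarray, coh: np.ndarray, band: tuple[float, float]) -> float:
    """Mean coherence over the bins of a half-open band [lo, hi)."""
    mask = _band_slice(np.asarray(freqs), band)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(np.asarray(coh)[mask].mean())


def pair_relation(region_a: str, pair_a: str, region_b: str, pair_b: str) -> str:
    """Label an electrode pair by anatomical relation.

    within_pair: same electrode pair (0.5 mm tip separation);
    between_pair: different pairs within the same structure (MStr–LStr or the
    two cerebellar pairs); str_cb: striatum vs cerebellum; the ctx_* labels
    cover the neocortical control montage.
    """
    regions = {region_a, region_b}
    if "Ctx" in regions:
        other = (regions - {"Ctx"}).pop() if len(regions) > 1 else "Ctx"
        if other == "CB":
            return "ctx_cb"
        if other in ("MStr", "LStr"):
            return "ctx_str_vertical" if pair_a == pair_b else "ctx_str_offset"
        # Ctx–Ctx: treat like a within-structure comparison
        return "within_pair" if pair_a == pair_b else "between_pair"
    group_a = STRUCTURE_GROUP[region_a]
    group_b = STRUCTURE_GROUP[region_b]
    if group_a != group_b:
        return "str_cb"
    return "within_pair" if pair_a == pair_b else "between_pair"


# ---------------------------------------------------------------------------
# session-level drivers
# ---------------------------------------------------------------------------

def session_band_power(
    session: RecordingSession,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-window band-power table for every channel of a session.

    Columns: animal, zt, condition, channel, region, window_index, band,
    percent.  Band labels are ``"lo-hi"`` strings.
    """
    config = config or AnalysisConfig()
    bpt = BandPowerTransform(fs=session.fs, config=config)
    rows = []
    for ch in session.channels:
        windows = segment_windows(ch.data, session.fs, config.window_len)
        percents = bpt.transform(windows)
        for w_idx in range(percents.shape[0]):
            for b_idx, (lo, hi) in enumerate(config.band_edges):
                rows.append(
                    {
                        "animal": session.animal,
                        "zt": session.zt,
                        "condition": session.condition,
                        "channel": ch.name,
                        "region": ch.region,
                        "window_index": w_idx,
                        "band": f"{lo:g}-{hi:g}",
                        "percent": percents[w_idx, b_idx],
                    }
                )
    return pd.DataFrame(rows)


def session_coherence(
    session: RecordingSession,
    config: AnalysisConfig | None = None,
    bands: Iterable[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-window band coherence for every channel pair of a session.

    Columns: animal, zt, condition, pair, relation, window_index, band,
    value.  ``bands`` defaults to the slow/theta analysis bands plus the
    pooled 0.1–8 and 0.1–55 Hz summary ranges.
    """
    config = config or AnalysisConfig()
    if bands is None:
        bands = [config.slow_band, config.theta_band, (0.1, 8.0), (0.1, 55.0)]
    bands = list(bands)

    windows = {
        ch.name: segment_windows(ch.data, session.fs, config.window_len)
        for ch in session.channels
    }
    rows = []
    chans = session.channels
    for i in range(len(chans)):
        for j in range(i + 1, len(chans)):
            a, b = chans[i], chans[j]
            relation = pair_relation(a.region, a.pair_id, b.region, b.pair_id)
            wa, wb = windows[a.name], windows[b.name]
            for w_idx in range(wa.shape[0]):
                freqs, coh = window_coherence(wa[w_idx], wb[w_idx], session.fs)
                for band in bands:
                    rows.append(
                        {
                            "animal": session.animal,
                            "zt": session.zt,
                            "condition": session.condition,
                            "pair": f"{a.name}|{b.name}",
                            "relation": relation,
                            "window_index": w_idx,
                            "band": f"{band[0]:g}-{band[1]:g}",
                            "value": band_coherence(freqs, coh, band),
                        }
                    )
    return pd.DataFrame(rows)


def relation_summary(
    coherence: pd.DataFrame,
    bands: Iterable[str] = ("0.1-8", "0.1-55"),
) -> pd.DataFrame:
    """Mean coherence per relation label and band range.

    Input is the tidy table from :func:`session_coherence` (possibly
    concatenated over sessions).  Unknown relation labels are an error.
    """
    bad = set(coherence["relation"].unique()) - set(RELATION_LABELS)
    if bad:
        raise ValueError(f"unknown relation labels: {sorted(bad)}")
    sub = coherence[coherence["band"].isin(list(bands))]
    if sub.empty:
        raise ValueError(f"no rows for bands {list(bands)}")
    out = (
        sub.groupby(["relation", "band"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean_coherence"})
    )
    return out
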