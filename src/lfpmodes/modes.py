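"""Window-level classification of slow (0.1–3 Hz) vs theta (3–8 Hz) dominance.

For each 2-s window the dominance difference D = percent(0.1–3) −
percent(3–8) is formed from the integrated FFT percentages.  Windows where D
sits near zero (|D − 0| ≤ 10 percentage points) are transition windows; their
mean defines a per-session baseline B.  A window is labelled SLOW when
D ≥ B + 20 and THETA when D ≤ B − 15 — empirical offsets chosen as the most
conservative levels at which either oscillation is reliably detected —
otherwise it stays unclassified.  Occupancy percentages are the fraction of
windows carrying each label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import AnalysisConfig, RecordingSession, segment_windows
from .spectral import BandPowerTransform

__all__ = [
    "SLOW",
    "THETA",
    "NONE",
    "ModeThresholds",
    "ModeClassification",
    "ModeClassifier",
    "dominance_difference",
    "compute_baseline",
    "classify_windows",
    "band_power_correlation",
    "classify_session",
]

SLOW, THETA, NONE = "SLOW", "THETA", "NONE"


@dataclass(frozen=True)
class ModeThresholds:
    """Baseline-eligibility tolerance and classification offsets.

    ``tol``: half-width (percentage points) of the near-zero band of D used
    to compute the baseline.  ``up``/``down``: offsets from the baseline for
    the SLOW and THETA thresholds.
    """

    tol: float = 10.0
    up: float = 20.0
    down: float = -15.0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (self.up > 0 > self.down):
            raise ValueError("need up > 0 > down")


@dataclass
class ModeClassification:
    """Per-window dominance values, labels and occupancy percentages."""

    D: np.ndarray
    labels: np.ndarray
    baseline: float
    thresholds: ModeThresholds
    pct_slow: float
    pct_theta: float


def dominance_difference(p03: Sequence[float], p38: Sequence[float]) -> np.ndarray:
    """D_i = slow-band percent minus theta-band percent, per window."""
    p03 = np.asarray(p03, dtype=float)
    p38 = np.asarray(p38, dtype=float)
    if p03.shape != p38.shape:
        raise ValueError(f"length mismatch: {p03.shape} vs {p38.shape}")
    return p03 - p38


def compute_baseline(
    D: Sequence[float],
    tol: float = 10.0,
    max_tol: float = 25.0,
    widen_step: float = 5.0,
) -> float:
    """Mean of D over near-zero (transition) windows.

    If no window satisfies |D| ≤ tol the tolerance is widened stepwise up to
    ``max_tol`` with a warning — a session locked in a single mode has no
    transition windows at the default tolerance.  Failing even at ``max_tol``
    is an error.
    """
    D = np.asarray(D, dtype=float)
    t = float(tol)
    while t <= max_tol + 1e-12:
        eligible = np.abs(D) <= t
        if eligible.any():
            if t > tol:
                warnings.warn(
                    f"no transition windows at |D| <= {tol}; widened tolerance to {t}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return float(D[eligible].mean())
        t += widen_step
    raise ValueError(
        f"no transition windows with |D| <= {max_tol}: session does not alternate"
    )


def classify_windows(
    D: Sequence[float],
    thresholds: ModeThresholds | None = None,
    baseline: float | None = None,
) -> ModeClassification:
    """Label each window SLOW / THETA / NONE against baseline-offset thresholds."""
    thresholds = thresholds or ModeThresholds()
    D = np.asarray(D, dtype=float)
    B = compute_baseline(D, thresholds.tol) if baseline is None else float(baseline)
    labels = np.full(D.shape, NONE, dtype=object)
    labels[D >= B + thresholds.up] = SLOW
    labels[D <= B + thresholds.down] = THETA
    n = len(D)
    return ModeClassification(
        D=D,
        labels=labels,
        baseline=B,
        thresholds=thresholds,
        pct_slow=100.0 * np.count_nonzero(labels == SLOW) / n,
        pct_theta=100.0 * np.count_nonzero(labels == THETA) / n,
    )


class ModeClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the empirical-threshold classifier.

    ``fit`` learns the session baseline from the dominance differences (a 1-D
    array or an ``(n_windows, 1)`` column); ``predict`` labels windows.

    Attributes
    ----------
    baseline_ : float
        Mean of D over transition windows.
    classes_ : ndarray
        The three labels.
    """

    def __init__(self, tol: float = 10.0, up: float = 20.0, down: float = -15.0):
        self.tol = tol
        self.up = up
        self.down = down

    def _thresholds(self) -> ModeThresholds:
        return ModeThresholds(tol=self.tol, up=self.up, down=self.down)

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected dominance differences as a 1-D array or a single column")
        return X

    def fit(self, X, y=None) -> "ModeClassifier":
        D = self._as_1d(X)
        self.baseline_ = compute_baseline(D, self._thresholds().tol)
        self.classes_ = np.array([NONE, SLOW, THETA])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "baseline_"):
            raise AttributeError("ModeClassifier is not fitted yet")
        D = self._as_1d(X)
        result = classify_windows(D, self._thresholds(), baseline=self.baseline_)
        return result.labels


def band_power_correlation(p03: Sequence[float], p38: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, p) between per-window slow and theta percents.

    Because the two modes alternate rather than co-occur, real sessions show
    a strong negative correlation between the bands.
    """
    p03 = np.asarray(p03, dtype=float)
    p38 = np.asarray(p38, dtype=float)
    if p03.shape != p38.shape:
        raise ValueError("length mismatch")
    if len(p03) < 3:
        raise ValueError("need at least 3 windows")
    if np.std(p03) == 0 or np.std(p38) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = spstats.pearsonr(p03, p38)
    return float(r), float(p)


def classify_session(
    session: RecordingSession,
    config: AnalysisConfig | None = None,
    thresholds: ModeThresholds | None = None,
    monomodal_fallback: bool = True,
) -> dict[str, ModeClassification]:
    """Run band power → dominance → classification for every channel.

    A channel that spends the whole period in one mode has no transition
    windows and therefore no empirical baseline; with
    ``monomodal_fallback`` (default) such channels are classified against a
    zero baseline — the session belongs wholly to its dominant mode — with a
    warning, instead of raising.
    """
    config = config or AnalysisConfig()
    bpt = BandPowerTransform(fs=session.fs, config=config)
    out = {}
    for ch in session.channels:
        windows = segment_windows(ch.data, session.fs, config.window_len)
        percents = bpt.transform(windows)
        D = dominance_difference(percents[:, 0], percents[:, 1])
        try:
            out[ch.name] = classify_windows(D, thresholds)
        except ValueError:
            if not monomodal_fallback:
                raise
            warnings.warn(
                f"channel {ch.name!r}: no transition windows; classifying "
                "against a zero baseline (monomodal session)",
                RuntimeWarning,
                stacklevel=2,
            )
            out[ch.name] = classify_windows(D, thresholds, baseline=0.0)
    return out
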