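"""Session containers, readers and signal conditioning.

The analysis operates on continuous multi-channel voltage traces that are
low-pass filtered, optionally decimated to a common sampling rate, and cut
into contiguous non-overlapping analysis windows (2 s by default, giving 60
windows per 120-s recording period).  Everything downstream — band power,
mode classification, coherence, spindles — consumes the output of this
module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "REGIONS",
    "Channel",
    "RecordingSession",
    "AnalysisConfig",
    "read_session",
    "write_session",
    "decimate_signal",
    "lowpass",
    "segment_windows",
]

#: Fixed vocabulary of recording-site labels: medial dorsal striatum, lateral
#: dorsal striatum, cerebellar cortex (Crus2/Paramedian granule-cell layer)
#: and sensorimotor neocortex.
REGIONS = ("MStr", "LStr", "CB", "Ctx")

#: Regions grouped by structure, used for coherence-relation labelling and for
#: the generator's shared-noise hierarchy.  Neocortical sites couple to the
#: striatum like a within-structure site (cortico-striatal coherence matches
#: the striatal tiers), so Ctx shares the striatal group.
STRUCTURE_GROUP = {"MStr": "STR", "LStr": "STR", "Ctx": "STR", "CB": "CB"}


@dataclass
class Channel:
    """One electrode: a name, its region label, its electrode-pair id and
    the recorded trace (volts or arbitrary units)."""

    name: str
    region: str
    pair_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r} for channel {self.name!r}; "
                f"expected one of {REGIONS}"
            )
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError(f"channel {self.name!r}: signal must be 1-D")


@dataclass
class RecordingSession:
    """A labelled multi-channel recording period.

    Parameters
    ----------
    animal : str
        Animal identifier.
    zt : int
        Zeitgeber time of the recording, hours after lights-on.
    condition : str
        ``"pre"`` or ``"post"`` (D2-antagonist administration).
    fs : float
        Sampling rate in Hz, common to all channels.
    channels : list of Channel
        Equal-length traces.
    """

    animal: str
    zt: int
    condition: str
    fs: float
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in ("pre", "post"):
            raise ValueError(f"condition must be 'pre' or 'post', got {self.condition!r}")
        lengths = {len(ch.data) for ch in self.channels}
        if len(lengths) > 1:
            raise ValueError(f"length mismatch across channels: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].data) if self.channels else 0

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def channel(self, name: str) -> Channel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Spectral-analysis settings shared across the pipeline.

    Bands are half-open ``[lo, hi)`` in Hz; the five defaults tile the total
    0.1–55 Hz range (delta, theta, alpha, beta, gamma), so per-window percent
    power over the five bands sums to 100 by construction.
    """

    fs_target: float = 2020.0
    lowpass_cutoff: float = 300.0
    window_len: float = 2.0
    band_edges: tuple[tuple[float, float], ...] = (
        (0.1, 3.0),
        (3.0, 8.0),
        (8.0, 13.0),
        (13.0, 30.0),
        (30.0, 55.0),
    )
    total_band: tuple[float, float] = (0.1, 55.0)

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        prev_hi = 0.0
        for lo, hi in self.band_edges:
            if not (0.0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("bands must be non-overlapping and ordered")
            if hi > self.fs_target / 2:
                raise ValueError(f"band ({lo}, {hi}) exceeds Nyquist {self.fs_target / 2}")
            prev_hi = hi

    @property
    def slow_band(self) -> tuple[float, float]:
        return self.band_edges[0]

    @property
    def theta_band(self) -> tuple[float, float]:
        return self.band_edges[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_session(
    session: RecordingSession,
    outdir: str | Path,
    fmt: str = "f32",
) -> Path:
    """Write a session as signal files plus a JSON manifest.

    ``fmt="f32"`` writes one raw little-endian float32 file per channel;
    ``fmt="csv"`` writes a single delimited file with one named column per
    channel.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    if fmt == "f32":
        for ch in session.channels:
            fname = f"{ch.name}.f32"
            ch.data.astype("<f4").tofile(outdir / fname)
            entries.append(
                {"name": ch.name, "region": ch.region, "pair_id": ch.pair_id, "file": fname}
            )
    elif fmt == "csv":
        fname = "signals.csv"
        df = pd.DataFrame({ch.name: ch.data for ch in session.channels})
        df.to_csv(outdir / fname, index=False)
        for ch in session.channels:
            entries.append(
                {
                    "name": ch.name,
                    "region": ch.region,
                    "pair_id": ch.pair_id,
                    "file": fname,
                    "column": ch.name,
                }
            )
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'f32' or 'csv'")

    manifest = {
        "animal": session.animal,
        "zt": session.zt,
        "condition": session.condition,
        "fs": session.fs,
        "channels": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def _read_signal(path: Path, entry: dict) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".f32", ".bin", ".dat", ".raw"):
        return np.fromfile(path, dtype="<f4").astype(float)
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        col = entry.get("column", entry["name"])
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
        return df[col].to_numpy(dtype=float)
    if suffix == ".edf":
        import mne  # optional dependency, EDF input only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        name = entry.get("column", entry["name"])
        if name not in raw.ch_names:
            raise ValueError(f"EDF channel {name!r} not found in {path.name}")
        return raw.get_data(picks=[name])[0]
    raise ValueError(f"unrecognized signal file type: {path.name}")


def read_session(manifest_path: str | Path) -> RecordingSession:
    """Load a session from a JSON manifest.

    The manifest gives animal id, zeitgeber time, condition, sampling rate and
    a channel list; each channel entry names its region, electrode pair and
    signal file (raw float32, delimited text or EDF).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent

    channels = []
    for entry in manifest["channels"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"missing signal file: {fpath}")
        data = _read_signal(fpath, entry)
        channels.append(
            Channel(name=entry["name"], region=entry["region"],
                    pair_id=entry.get("pair_id", ""), data=data)
        )
    return RecordingSession(
        animal=str(manifest["animal"]),
        zt=int(manifest["zt"]),
        condition=manifest["condition"],
        fs=float(manifest["fs"]),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def decimate_signal(x: Sequence[float], fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate ``x`` from ``fs_in`` to ``fs_out`` with anti-alias filtering.

    The rate ratio must be an integer (e.g. 30300 → 2020 Hz is a factor of
    15); arbitrary resampling is out of scope.  The trailing remainder of the
    input is discarded so the output length is ``floor(len(x) / factor)``.
    """
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"fs_in/fs_out must be an integer factor, got {ratio}")
    if factor == 1:
        return x.copy()
    n_keep = (len(x) // factor) * factor
    if n_keep == 0:
        raise ValueError("signal too short to decimate")
    # FIR anti-alias filter: flat passband (IIR cheby1 ripple exceeds 1%)
    return sps.decimate(x[:n_keep], factor, ftype="fir", zero_phase=True)


def lowpass(x: Sequence[float], fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward–backward, no group delay)."""
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def bandpass(x: Sequence[float], fs: float, band: tuple[float, float], order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass used by spindle detection."""
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band {band} at fs {fs}")
    sos = sps.butter(order, (lo, hi), btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def segment_windows(x: Sequence[float], fs: float, window_len: float = 2.0) -> np.ndarray:
    """Cut ``x`` into contiguous non-overlapping windows of ``window_len`` s.

    Returns an array of shape ``(n_windows, window_samples)``.  A trailing
    partial window is discarded; a signal shorter than one window is an error.
    """
    x = np.asarray(x, dtype=float)
    n_win_samples = int(round(window_len * fs))
    if n_win_samples <= 0:
        raise ValueError("window_len too short for this sampling rate")
    n_windows = len(x) // n_win_samples
    if n_windows < 1:
        raise ValueError(
            f"signal of {len(x) / fs:.3f} s is shorter than one {window_len} s window"
        )
    return x[: n_windows * n_win_samples].reshape(n_windows, n_win_samples)
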