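"""Pan-Tompkins-style QRS detection.

The classic chain: zero-phase band-pass filtering, five-point
derivative, squaring, moving-window integration, then adaptive
signal/noise thresholding with a refractory period and RR-based
search-back. Reported R-peak indices are refined to the local maximum
of the band-passed signal, so downstream fiducial search windows are
centred on the actual R deflection.

All thresholds are relative, so detection is invariant to constant
amplitude scaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ConfigError


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the detector.

    Defaults are the canonical Pan-Tompkins values: pass-band 5–15 Hz
    (QRS energy), 150 ms integration window (maximal QRS width plus
    slope), 200 ms refractory period (physiological minimum between
    beats), running-estimate update fraction 0.125, and search-back
    triggered at 1.66 x the running RR average.
    """

    band_low: float = 5.0
    band_high: float = 15.0
    integ_window_ms: float = 150.0
    refractory_ms: float = 200.0
    threshold_update: float = 0.125
    searchback_factor: float = 1.66

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ConfigError("need 0 < band_low < band_high")
        if self.band_high >= fs / 2:
            raise ConfigError(
                f"band_high {self.band_high} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.integ_window_ms <= 0 or self.refractory_ms <= 0:
            raise ConfigError("window and refractory must be positive")
        if not 0 < self.threshold_update < 1:
            raise ConfigError("threshold_update must lie in (0, 1)")


@dataclass(frozen=True)
class RPeakList:
    """Strictly increasing R-peak sample indices with their sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        d = np.diff(self.indices)
        if len(d) and d.min() <= 0:
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def bandpass_filter(samples: np.ndarray, fs: float,
                    cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input."""
    cfg.validate(fs)
    x = np.asarray(samples, float)
    b, a = butter(2, [cfg.band_low, cfg.band_high], btype="band", fs=fs)
    padlen = min(3 * (max(len(a), len(b)) - 1), len(x) - 1)
    return filtfilt(b, a, x, padlen=padlen)


def derivative_squaring_integration(
    filtered: np.ndarray, fs: float,
    cfg: DetectorConfig = DetectorConfig(),
) -> np.ndarray:
    """Detection envelope: moving mean of the squared 5-point derivative.

    The derivative kernel is the Pan-Tompkins five-point transfer
    function (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]) scaled by fs,
    applied with centred alignment so the envelope is not lag-shifted.
    """
    x = np.asarray(filtered, float)
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    padded = np.concatenate([x[:1].repeat(2), x, x[-1:].repeat(2)])
    deriv = np.convolve(padded, kernel, mode="valid")
    squared = deriv ** 2
    w = max(1, int(round(cfg.integ_window_ms / 1000 * fs)))
    return np.convolve(squared, np.ones(w) / w, mode="same")


def detect_r_peaks(signal, cfg: DetectorConfig = DetectorConfig(),
                   fs: float | None = None) -> RPeakList:
    """Detect R-peaks with adaptive thresholding and search-back.

    Parameters
    ----------
    signal : ECGRecord, MinuteSegment, or array
        When an array is passed, ``fs`` must be given.
    cfg : DetectorConfig
    fs : float, optional

    Returns
    -------
    RPeakList
        Indices refined to the local band-passed maximum within
        +-integ_window_ms of the envelope peak; empty (with a warning)
        when nothing crosses threshold.
    """
    samples = getattr(signal, "samples", signal)
    fs = float(getattr(signal, "fs", fs) or 0)
    if fs <= 0:
        raise ValueError("sampling rate required")
    x = np.asarray(samples, float)
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    cfg.validate(fs)

    filtered = bandpass_filter(x, fs, cfg)
    env = derivative_squaring_integration(filtered, fs, cfg)

    refractory = int(round(cfg.refractory_ms / 1000 * fs))
    cand, _ = find_peaks(env, distance=max(1, refractory))
    if len(cand) == 0 or env.max() <= 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return RPeakList(np.array([], dtype=int), fs)

    # learning phase: initial signal/noise levels from the first 2 s
    learn = env[: int(2 * fs)]
    spki = 0.25 * learn.max()
    npki = 0.5 * learn.mean()
    tu = cfg.threshold_update

    accepted: list[int] = []
    rr_recent: list[float] = []

    def rr_average() -> float:
        return float(np.mean(rr_recent[-8:])) if rr_recent else fs  # 60 bpm prior

    def accept(idx: int, level: float) -> None:
        nonlocal spki
        if accepted:
            rr_recent.append(idx - accepted[-1])
        accepted.append(idx)
        spki = tu * level + (1 - tu) * spki

    i = 0
    while i < len(cand):
        p = cand[i]
        thr1 = npki + 0.25 * (spki - npki)
        if env[p] >= thr1:
            accept(p, env[p])
        else:
            npki = tu * env[p] + (1 - tu) * npki
            # search-back: a beat was probably missed
            if accepted and p - accepted[-1] > cfg.searchback_factor * rr_average():
                window = [c for c in cand[: i + 1]
                          if accepted[-1] + refractory < c <= p]
                if window:
                    best = max(window, key=lambda c: env[c])
                    if env[best] >= 0.5 * thr1:
                        accept(best, env[best])
        i += 1

    if not accepted:
        warnings.warn("no peak crossed the adaptive threshold", stacklevel=2)
        return RPeakList(np.array([], dtype=int), fs)

    # refine to the local band-passed maximum
    half = int(round(cfg.integ_window_ms / 1000 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(filtered[lo:hi])))
    refined = np.unique(refined)

    # collapse refined peaks closer than the refractory, keeping the larger
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if filtered[r] > filtered[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return RPeakList(np.asarray(keep, dtype=int), fs)
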