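"""The 12 per-segment time-domain features.

Five R-related features — mean RR interval (mRR), mean heart rate
(mHR), SDNN, RMSSD and mean QRS duration (mQRSd) — plus seven
morphology features: the standard deviation of QRS duration (sdQRSd)
and mean/SD of the Q, R and S amplitudes relative to the per-beat
isoelectric baseline (the signal value at Qon).

Conventions
-----------
* mHR defaults to 60 / mean(RR in seconds); the mean of the
  instantaneous 60/RRi values is available via ``hr_method="inst"``.
* Normaliser defaults to the number of summed terms (m intervals for
  mRR/SDNN, m-1 successive differences for RMSSD); ``denominator="beats"``
  divides by the beat count n = m + 1 instead, for strict reproduction
  of formulations that normalise by total beats.
* SDNN and all sd* statistics are population-style (divide by the
  number of terms, no Bessel correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .fiducial_points import FiducialSet, delineate
from .qrs_detection import DetectorConfig, RPeakList, detect_r_peaks
from .record_io import FEATURE_NAMES, MinuteSegment


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the detection + delineation + feature chain."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    q_window_ms: float = 100.0
    s_window_ms: float = 100.0
    slope_eps: float = 0.025
    max_extend_ms: float = 80.0
    qrsd_min_ms: float = 40.0
    qrsd_max_ms: float = 200.0
    denominator: str = "terms"     # {"terms", "beats"}
    hr_method: str = "mean_rr"     # {"mean_rr", "inst"}
    min_valid_beats: int = 2


@dataclass(frozen=True)
class FeatureVector:
    """The 12 features of one segment, in canonical order."""

    mRR: float
    mHR: float
    SDNN: float
    RMSSD: float
    mQRSd: float
    sdQRSd: float
    mQamp: float
    sdQamp: float
    mRamp: float
    sdRamp: float
    mSamp: float
    sdSamp: float
    n_beats: int = 0

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def rr_intervals(r_peaks, fs: float | None = None) -> np.ndarray:
    """Successive R-to-R intervals in seconds."""
    if isinstance(r_peaks, RPeakList):
        fs = r_peaks.fs
        idx = r_peaks.indices
    else:
        idx = np.asarray(r_peaks, float)
    if fs is None or fs <= 0:
        raise ValueError("sampling rate required")
    if len(idx) < 2:
        warnings.warn("fewer than 2 R-peaks; no RR intervals", stacklevel=2)
        return np.array([])
    return np.diff(idx) / fs


def _denom(rr: np.ndarray, n_terms: int, denominator: str) -> int:
    if denominator == "terms":
        return n_terms
    if denominator == "beats":
        return len(rr) + 1
    raise ValueError(f"unknown denominator convention {denominator!r}")


def compute_hr(rr: np.ndarray, hr_method: str = "mean_rr") -> float:
    """Mean heart rate in beats/min from RR intervals in seconds."""
    rr = np.asarray(rr, float)
    if len(rr) == 0:
        return float("nan")
    if (rr <= 0).any():
        raise DataError("non-positive RR interval")
    if hr_method == "mean_rr":
        return 60.0 / float(np.mean(rr))
    if hr_method == "inst":
        return float(np.mean(60.0 / rr))
    raise ValueError(f"unknown hr_method {hr_method!r}")


def compute_mrr(rr: np.ndarray, denominator: str = "terms") -> float:
    """Mean RR interval in seconds."""
    rr = np.asarray(rr, float)
    if len(rr) == 0:
        return float("nan")
    return float(np.sum(rr) / _denom(rr, len(rr), denominator))


def compute_rmssd(rr: np.ndarray, denominator: str = "terms") -> float:
    """Root mean square of successive RR differences, in seconds."""
    rr = np.asarray(rr, float)
    if len(rr) < 2:
        return float("nan")
    d = np.diff(rr)
    return float(np.sqrt(np.sum(d ** 2) / _denom(rr, len(d), denominator)))


def compute_sdnn(rr: np.ndarray, denominator: str = "terms") -> float:
    """Population-style standard deviation of RR intervals, in seconds."""
    rr = np.asarray(rr, float)
    if len(rr) == 0:
        return float("nan")
    if len(rr) == 1:
        return 0.0
    dev = rr - np.mean(rr)
    return float(np.sqrt(np.sum(dev ** 2) / _denom(rr, len(rr), denominator)))


def compute_qrs_amplitude_features(samples: np.ndarray, fs: float,
                                   fiducials: FiducialSet) -> dict[str, float]:
    """QRS-duration and Q/R/S-amplitude statistics over valid beats.

    Amplitudes are measured on the raw (de-outliered) signal relative to
    the per-beat baseline, taken as the signal value at Qon. Standard
    deviations are population-style.
    """
    x = np.asarray(samples, float)
    m = fiducials.valid
    if not m.any():
        raise DataError("no valid beats for amplitude features")
    qon, soff = fiducials.qon[m], fiducials.soff[m]
    q, r, s = fiducials.q[m], fiducials.r[m], fiducials.s[m]
    qrsd = (soff - qon) / fs
    baseline = x[qon]
    qamp = x[q] - baseline
    ramp = x[r] - baseline
    samp = x[s] - baseline

    def pop_sd(v: np.ndarray) -> float:
        return float(np.std(v))  # population (ddof=0)

    return {
        "mQRSd": float(np.mean(qrsd)), "sdQRSd": pop_sd(qrsd),
        "mQamp": float(np.mean(qamp)), "sdQamp": pop_sd(qamp),
        "mRamp": float(np.mean(ramp)), "sdRamp": pop_sd(ramp),
        "mSamp": float(np.mean(samp)), "sdSamp": pop_sd(samp),
    }


def extract_feature_vector(segment: MinuteSegment,
                           cfg: FeatureConfig = FeatureConfig()
                           ) -> FeatureVector | None:
    """Detect, delineate and compute the 12 features for one segment.

    Returns None (with a warning) when fewer than ``cfg.min_valid_beats``
    beats survive detection and validation; deterministic for a fixed
    input and configuration.
    """
    peaks = detect_r_peaks(segment, cfg.detector)
    if len(peaks) < 2:
        warnings.warn(
            f"segment {segment.record_id}/{segment.index_in_record}: "
            "fewer than 2 beats detected; dropped", stacklevel=2,
        )
        return None
    fset = delineate(
        segment.samples, segment.fs, peaks.indices,
        cfg.q_window_ms, cfg.s_window_ms, cfg.slope_eps, cfg.max_extend_ms,
    )
    if fset.n_valid < cfg.min_valid_beats:
        warnings.warn(
            f"segment {segment.record_id}/{segment.index_in_record}: "
            f"only {fset.n_valid} valid beats; dropped", stacklevel=2,
        )
        return None
    # RR statistics use all detected R-peaks; morphology uses valid beats only
    rr = rr_intervals(peaks)
    amp = compute_qrs_amplitude_features(segment.samples, segment.fs, fset)
    return FeatureVector(
        mRR=compute_mrr(rr, cfg.denominator),
        mHR=compute_hr(rr, cfg.hr_method),
        SDNN=compute_sdnn(rr, cfg.denominator),
        RMSSD=compute_rmssd(rr, cfg.denominator),
        n_beats=len(peaks),
        **amp,
    )
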