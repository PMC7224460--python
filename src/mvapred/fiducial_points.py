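"""Per-beat fiducial points: Q, S, Q-wave onset and S-wave offset.

Q and S are the local minima inside backward/forward search windows
around each detected R-peak. The onset (Qon) and offset (Soff) are the
nearest points, scanning outward from Q and S, whose slope is "nearly
zero" — quantified as a small fraction of the beat's maximal absolute
slope. A validator rejects beats whose fiducials are mis-ordered or
whose QRS duration falls outside physiological bounds; invalid beats
are excluded from all downstream feature computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices and validity flags."""

    r: np.ndarray
    q: np.ndarray
    s: np.ndarray
    qon: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    soff: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    valid: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        n = len(self.r)
        if len(self.qon) == 0:
            self.qon = np.copy(self.q)
        if len(self.soff) == 0:
            self.soff = np.copy(self.s)
        if len(self.valid) == 0:
            self.valid = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.r)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def locate_q_s(samples: np.ndarray, fs: float, r_peaks: np.ndarray,
               q_window_ms: float = 100.0,
               s_window_ms: float = 100.0) -> FiducialSet:
    """Locate Q and S as windowed local minima around each R-peak.

    The backward window [r - q_window, r) and forward window
    (r, r + s_window] are clipped at the segment edges and at the
    neighbouring R-peaks; a beat whose window is empty after clipping is
    marked invalid.
    """
    if len(r_peaks) == 0:
        raise ValueError("r_peaks must be non-empty")
    if q_window_ms <= 0 or s_window_ms <= 0:
        raise ValueError("search windows must be positive")
    x = np.asarray(samples, float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    qw = int(round(q_window_ms / 1000 * fs))
    sw = int(round(s_window_ms / 1000 * fs))

    n = len(r_peaks)
    q = np.zeros(n, dtype=int)
    s = np.zeros(n, dtype=int)
    valid = np.ones(n, dtype=bool)
    for i, r in enumerate(r_peaks):
        lo = max(0, r - qw, (r_peaks[i - 1] + 1) if i > 0 else 0)
        if lo >= r:
            valid[i] = False
            q[i] = s[i] = r
            continue
        q[i] = lo + int(np.argmin(x[lo:r]))
        hi = min(len(x), r + sw + 1,
                 r_peaks[i + 1] if i + 1 < n else len(x))
        if r + 1 >= hi:
            valid[i] = False
            s[i] = r
            continue
        s[i] = r + 1 + int(np.argmin(x[r + 1:hi]))
    return FiducialSet(r=r_peaks, q=q, s=s, valid=valid)


def locate_onset_offset(samples: np.ndarray, fs: float, q_idx: int,
                        s_idx: int, slope_eps: float = 0.025,
                        max_extend_ms: float = 80.0
                        ) -> tuple[int, int, bool]:
    """Find Qon and Soff for one beat by near-zero-slope scanning.

    Scans backward from Q (forward from S) for the first sample whose
    centred slope magnitude is at most ``slope_eps`` times the beat's
    maximal absolute slope, bounded by ``max_extend_ms``. Returns
    ``(qon, soff, found)``; when no such point exists within the bound,
    the bound index is returned and ``found`` is False.
    """
    x = np.asarray(samples, float)
    ext = max(1, int(round(max_extend_ms / 1000 * fs)))
    lo = max(0, q_idx - ext)
    hi = min(len(x) - 1, s_idx + ext)

    slope = np.zeros(len(x))
    slope[1:-1] = (x[2:] - x[:-2]) * fs / 2.0
    region = np.abs(slope[lo:hi + 1])
    max_slope = region.max() if len(region) else 0.0
    tol = slope_eps * max_slope

    qon, q_found = lo, False
    for i in range(q_idx, lo - 1, -1):
        if abs(slope[i]) <= tol:
            qon, q_found = i, True
            break
    soff, s_found = hi, False
    for i in range(s_idx, hi + 1):
        if abs(slope[i]) <= tol:
            soff, s_found = i, True
            break
    return qon, soff, q_found and s_found


def delineate(samples: np.ndarray, fs: float, r_peaks: np.ndarray,
              q_window_ms: float = 100.0, s_window_ms: float = 100.0,
              slope_eps: float = 0.025,
              max_extend_ms: float = 80.0) -> FiducialSet:
    """Full per-beat delineation: Q/S windows, onset/offset, validation."""
    fset = locate_q_s(samples, fs, r_peaks, q_window_ms, s_window_ms)
    qon = np.copy(fset.q)
    soff = np.copy(fset.s)
    for i in range(len(fset)):
        if not fset.valid[i]:
            continue
        qi, si, found = locate_onset_offset(
            samples, fs, int(fset.q[i]), int(fset.s[i]),
            slope_eps, max_extend_ms,
        )
        qon[i], soff[i] = qi, si
        if not found:
            fset.valid[i] = False
    fset.qon, fset.soff = qon, soff
    return validate_fiducials(fset, fs)


def validate_fiducials(fset: FiducialSet, fs: float,
                       qrsd_min_ms: float = 40.0,
                       qrsd_max_ms: float = 200.0) -> FiducialSet:
    """Mark beats with mis-ordered fiducials or implausible QRSd invalid.

    Valid beats satisfy qon <= q < r < s <= soff and a QRS duration
    (soff - qon) within [qrsd_min_ms, qrsd_max_ms].
    """
    ordering = (
        (fset.qon <= fset.q) & (fset.q < fset.r)
        & (fset.r < fset.s) & (fset.s <= fset.soff)
    )
    qrsd_ms = (fset.soff - fset.qon) / fs * 1000.0
    duration_ok = (qrsd_ms >= qrsd_min_ms) & (qrsd_ms <= qrsd_max_ms)
    fset.valid = fset.valid & ordering & duration_ok
    if len(fset) and fset.n_valid == 0:
        warnings.warn("all beats failed fiducial validation", stacklevel=2)
    return fset
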