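"""Ground-truthed synthetic ECG records and two-class feature tables.

Each beat is a sum of Gaussian bumps for the P, Q, R, S and T waves;
RR intervals are drawn as mean_rr plus Gaussian jitter truncated at
three standard deviations. A pre-arrhythmic record is emulated by a
linear parameter drift toward the annotated onset (RR shortening and
QRS widening — the pre-onset changes the prediction task exploits),
followed after onset by a coarse fibrillation-like oscillation. The
generator emits exact per-beat ground truth (R sample, Q/S centres,
QRS on/offset bounds), so every downstream stage can be scored against
known values without any data download.

``synth_dataset`` skips the signal level entirely and draws two-class
feature tables directly: class-conditional unit-variance Gaussians with
a stated per-feature mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .record_io import FEATURE_NAMES, ECGRecord, FeatureTable

#: Gaussian wave widths (seconds); QRS component widths scale with the
#: requested QRS duration instead.
_P_SIGMA = 0.020   # P wave ~40 ms wide
_T_SIGMA = 0.060   # T wave ~120 ms wide
_P_OFFSET = -0.22
_T_OFFSET = 0.30
_P_AMP = 0.12
_T_AMP = 0.30


@dataclass(frozen=True)
class DriftSpec:
    """Linear pre-onset trend: fractional change reached at onset."""

    rr_shorten_frac: float = 0.15
    qrs_widen_frac: float = 0.20


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic record.

    Amplitudes in mV, durations in seconds unless suffixed ``_ms``.
    ``onset_minute`` marks the record pre-arrhythmic with an annotated
    onset at that minute; ``drift`` then ramps mean RR down and QRS
    width up linearly from the record start to the onset.
    ``snr_db``, when set, overrides ``noise_sd`` so that the additive
    white noise yields the stated signal-to-noise ratio.
    """

    fs: float = 250.0
    duration_s: float = 60.0
    mean_rr: float = 0.8
    rr_jitter_sd: float = 0.03
    qrs_width_ms: float = 90.0
    q_amp: float = -0.15
    r_amp: float = 1.1
    s_amp: float = -0.25
    noise_sd: float = 0.0
    snr_db: float | None = None
    seed: int = 0
    record_id: str = "synth"
    onset_minute: float | None = None
    drift: DriftSpec | None = field(default_factory=DriftSpec)

    def __post_init__(self) -> None:
        if self.mean_rr < 0.2:
            raise ConfigError("mean_rr below 0.2 s is not physiological")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("fs and duration must be positive")
        if not np.isfinite([self.q_amp, self.r_amp, self.s_amp]).all():
            raise ConfigError("amplitudes must be finite")


@dataclass
class GroundTruth:
    """Per-beat truth emitted alongside a synthetic record."""

    r_samples: np.ndarray
    q_samples: np.ndarray
    s_samples: np.ndarray
    qon_samples: np.ndarray
    soff_samples: np.ndarray
    qrs_width_s: np.ndarray

    def __len__(self) -> int:
        return len(self.r_samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r": self.r_samples, "q": self.q_samples, "s": self.s_samples,
            "qon": self.qon_samples, "soff": self.soff_samples,
            "qrs_width_s": self.qrs_width_s,
        })


def _add_bump(x: np.ndarray, fs: float, center_s: float, sigma_s: float,
              amp: float) -> None:
    lo = max(0, int((center_s - 4 * sigma_s) * fs))
    hi = min(len(x), int((center_s + 4 * sigma_s) * fs) + 1)
    if lo >= hi:
        return
    t = np.arange(lo, hi) / fs
    x[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def synth_ecg_record(spec: SynthSpec) -> tuple[ECGRecord, GroundTruth]:
    """Generate one synthetic record with exact beat-level ground truth.

    Reproducible per seed: the same spec yields bit-identical samples.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    x = np.zeros(n)
    onset_s = (spec.onset_minute * 60.0
               if spec.onset_minute is not None else None)

    def progress(t: float) -> float:
        if onset_s is None or spec.drift is None or onset_s <= 0:
            return 0.0
        return min(1.0, max(0.0, t / onset_s))

    r_times: list[float] = []
    widths: list[float] = []
    t = 0.35  # leave room for the first beat's P wave
    while t < spec.duration_s - 0.35:
        if onset_s is not None and t >= onset_s:
            break
        p = progress(t)
        drift = spec.drift or DriftSpec()
        rr_mean_t = spec.mean_rr * (1.0 - drift.rr_shorten_frac * p)
        w_t = (spec.qrs_width_ms / 1000.0) * (1.0 + drift.qrs_widen_frac * p)
        r_times.append(t)
        widths.append(w_t)
        jitter = rng.normal(0.0, spec.rr_jitter_sd) if spec.rr_jitter_sd else 0.0
        jitter = float(np.clip(jitter, -3 * spec.rr_jitter_sd,
                               3 * spec.rr_jitter_sd))
        t += max(0.25, rr_mean_t + jitter)

    q_off, s_off = [], []
    for t_r, w in zip(r_times, widths):
        # QRS: narrow Gaussians; Q and S centred at +-0.32 w around R
        sigma_r = w / 7.0
        sigma_qs = w / 14.0
        _add_bump(x, fs, t_r, sigma_r, spec.r_amp)
        _add_bump(x, fs, t_r - 0.32 * w, sigma_qs, spec.q_amp)
        _add_bump(x, fs, t_r + 0.32 * w, sigma_qs, spec.s_amp)
        _add_bump(x, fs, t_r + _P_OFFSET, _P_SIGMA, _P_AMP)
        _add_bump(x, fs, t_r + _T_OFFSET, _T_SIGMA, _T_AMP)
        q_off.append(0.32 * w)
        s_off.append(0.32 * w)

    if onset_s is not None:
        # coarse fibrillation-like oscillation after onset
        i0 = int(onset_s * fs)
        if i0 < n:
            tt = np.arange(n - i0) / fs
            freq = 5.0 + 1.5 * np.sin(2 * np.pi * 0.3 * tt)
            x[i0:] = 0.9 * np.sin(2 * np.pi * freq * tt)

    noise_sd = spec.noise_sd
    if spec.snr_db is not None:
        rms = float(np.sqrt(np.mean(x ** 2)))
        noise_sd = rms / (10.0 ** (spec.snr_db / 20.0))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)

    r_arr = np.array([int(round(t_r * fs)) for t_r in r_times], dtype=int)
    w_arr = np.asarray(widths)
    truth = GroundTruth(
        r_samples=r_arr,
        q_samples=np.round(r_arr - np.asarray(q_off) * fs).astype(int),
        s_samples=np.round(r_arr + np.asarray(s_off) * fs).astype(int),
        qon_samples=np.round(r_arr - 0.5 * w_arr * fs).astype(int),
        soff_samples=np.round(r_arr + 0.5 * w_arr * fs).astype(int),
        qrs_width_s=w_arr,
    )
    rec = ECGRecord(
        record_id=spec.record_id, samples=x, fs=fs,
        source_class="pre_vtvf" if onset_s is not None else "normal",
        onset_sample=int(onset_s * fs) if onset_s is not None else None,
    )
    return rec, truth


def synth_corpus(n_normal: int = 9, n_pre: int = 9, seed: int = 0,
                 duration_min: float = 35.0, fs_normal: float = 128.0,
                 fs_pre: float = 250.0, onset_minute: float = 30.0,
                 noise_sd: float = 0.01,
                 ) -> list[tuple[ECGRecord, GroundTruth]]:
    """A study-shaped corpus: normal records at 128 Hz plus pre-onset
    records at 250 Hz with drift toward an annotated onset.

    Per-record physiology (mean RR, jitter, amplitudes) varies across
    records via sub-seeded draws so the two classes are not trivially
    separable by any single constant.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_normal):
        spec = SynthSpec(
            fs=fs_normal, duration_s=duration_min * 60.0,
            mean_rr=float(rng.uniform(0.7, 1.0)),
            rr_jitter_sd=float(rng.uniform(0.02, 0.05)),
            qrs_width_ms=float(rng.uniform(80, 100)),
            r_amp=float(rng.uniform(0.9, 1.3)),
            q_amp=float(rng.uniform(-0.2, -0.1)),
            s_amp=float(rng.uniform(-0.3, -0.15)),
            noise_sd=noise_sd, seed=int(rng.integers(2 ** 31)),
            record_id=f"n{i:02d}", drift=None,
        )
        out.append(synth_ecg_record(spec))
    for i in range(n_pre):
        spec = SynthSpec(
            fs=fs_pre, duration_s=duration_min * 60.0,
            mean_rr=float(rng.uniform(0.7, 1.0)),
            rr_jitter_sd=float(rng.uniform(0.02, 0.05)),
            qrs_width_ms=float(rng.uniform(80, 100)),
            r_amp=float(rng.uniform(0.9, 1.3)),
            q_amp=float(rng.uniform(-0.2, -0.1)),
            s_amp=float(rng.uniform(-0.3, -0.15)),
            noise_sd=noise_sd, seed=int(rng.integers(2 ** 31)),
            record_id=f"v{i:02d}", onset_minute=onset_minute,
        )
        out.append(synth_ecg_record(spec))
    return out


def synth_dataset(n_per_class: int, effect, seed: int = 0) -> FeatureTable:
    """Two-class feature table with per-feature mean shifts.

    Features are class-conditional Gaussians with unit variance; class 0
    is centred at zero and class 1 shifted by ``effect`` (a scalar
    applied to all 12 features, or a mapping feature name -> shift in SD
    units). Positives get minutes-before-onset tags uniform over
    (0, 25] and both classes carry minute indices for matching.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(effect):
        shifts = np.full(len(FEATURE_NAMES), float(effect))
    else:
        shifts = np.array([float(effect.get(f, 0.0)) for f in FEATURE_NAMES])
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, len(FEATURE_NAMES)))
    X1 = rng.normal(0.0, 1.0, size=(n_per_class, len(FEATURE_NAMES))) + shifts
    mbo = rng.uniform(0.0, 25.0, size=n_per_class)
    mbo = np.where(mbo == 0.0, 25.0, mbo)  # half-open (0, 25]
    frame = pd.DataFrame(np.vstack([X0, X1]), columns=list(FEATURE_NAMES))
    frame["label"] = np.repeat([0, 1], n_per_class)
    frame["minutes_before_onset"] = np.concatenate(
        [np.full(n_per_class, np.nan), mbo])
    frame["record_id"] = (
        [f"n{i % 9:02d}" for i in range(n_per_class)]
        + [f"v{i % 9:02d}" for i in range(n_per_class)]
    )
    frame["segment_index"] = np.tile(np.arange(n_per_class) % 35, 2)
    return FeatureTable(frame)
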