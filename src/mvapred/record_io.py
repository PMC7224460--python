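"""Reading, curating and partitioning ECG records, and feature-table I/O.

An :class:`ECGRecord` is the unit of ingestion: a single-lead amplitude
sequence in millivolt with its sampling rate and, for pre-arrhythmic
records, the annotated sample index of the first sustained VT/VF onset.
Records are truncated to a common length, cleaned of impulsive outliers,
and partitioned into non-overlapping one-minute segments; every retained
segment from a pre-arrhythmic record is tagged with how many minutes
before onset it ends.

Two on-disk dialects are supported:

* a WFDB-style pair ``<name>.hea`` / ``<name>.dat`` (16-bit little-endian
  two's-complement samples, gain in ADC units per mV), with the VT/VF
  onset taken from a binary MIT annotation file ``<name>.atr`` or a
  plain-text ``<name>.onset`` sidecar holding one sample index;
* a plain CSV with ``# key=value`` header lines (``fs`` required) and one
  sample per row, assumed to be in mV already.

Feature tables are plain CSV with the canonical 12-feature header.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import AnnotationError, FormatError, SchemaError

#: Canonical ordering of the 12 per-segment features.
FEATURE_NAMES: tuple[str, ...] = (
    "mRR", "mHR", "SDNN", "RMSSD",
    "mQRSd", "sdQRSd",
    "mQamp", "sdQamp", "mRamp", "sdRamp", "mSamp", "sdSamp",
)

#: Records retained by the study's inclusion rule: the nine pre-VT/VF
#: records with identifiable QRS complexes before onset, and nine
#: normal-sinus-rhythm records.
STUDY_RECORD_IDS: Mapping[str, tuple[str, ...]] = {
    "vfdb": ("420", "421", "422", "423", "425", "426", "427", "605", "612"),
    "nsrdb": (
        "16265", "16272", "16273", "16420", "16483",
        "16539", "16773", "16786", "17052",
    ),
}

#: Consistency of the MAD with the standard deviation under normality.
_MAD_SCALE = 1.4826

#: MIT annotation code for ventricular-flutter/fibrillation onset ('[').
_ATR_VFON = 32


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead ECG signal with sampling rate and onset annotation.

    Parameters
    ----------
    record_id : str
        Identifier of the record (e.g. ``"420"``).
    samples : numpy.ndarray
        Amplitudes in mV, 0-based sample indexing.
    fs : float
        Sampling frequency in Hz.
    source_class : str
        ``"normal"`` or ``"pre_vtvf"``.
    onset_sample : int or None
        Sample index of the first annotated sustained VT/VF onset.
        Absent for normal records.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    source_class: str = "normal"
    onset_sample: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.samples) == 0:
            raise ValueError("samples must be non-empty")
        if self.source_class not in ("normal", "pre_vtvf"):
            raise ValueError(f"unknown source_class {self.source_class!r}")
        if self.onset_sample is not None:
            if self.source_class == "normal":
                raise ValueError("normal records carry no onset annotation")
            if not 0 <= self.onset_sample < len(self.samples):
                raise AnnotationError(
                    f"onset sample {self.onset_sample} outside signal of "
                    f"length {len(self.samples)}"
                )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class MinuteSegment:
    """One-minute window of a record, tagged for classification.

    ``minutes_before_onset`` is measured from the *end* of the segment
    (the most recent data available when a prediction would be issued);
    it is present exactly for segments labelled pre-arrhythmic (label 1).
    """

    record_id: str
    index_in_record: int
    samples: np.ndarray
    fs: float
    minutes_before_onset: float | None = None
    label: int = 0

    def __post_init__(self) -> None:
        if len(self.samples) != round(60 * self.fs):
            raise ValueError("segment must contain exactly one minute of samples")
        if (self.label == 1) != (self.minutes_before_onset is not None):
            raise ValueError("label 1 iff minutes_before_onset present")


@dataclass
class FeatureTable:
    """Per-segment feature rows with labels and onset tags.

    Thin wrapper around a :class:`pandas.DataFrame` whose columns are the
    canonical feature names plus ``label`` and optional bookkeeping
    columns (``minutes_before_onset``, ``record_id``, ``segment_index``,
    ``n_beats``).
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.frame):
            missing = [c for c in (*FEATURE_NAMES, "label") if c not in self.frame]
            if missing:
                raise SchemaError(f"feature table missing columns: {missing}")
            bad = set(self.frame["label"].unique()) - {0, 1}
            if bad:
                raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame.loc[:, list(FEATURE_NAMES)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(int)


# ---------------------------------------------------------------------------
# record loading


def load_record(path: str | Path, format: str = "wfdb") -> ECGRecord:
    """Read an ECG record from disk.

    Parameters
    ----------
    path : path-like
        For ``format="wfdb"``, the header file or the record stem; for
        ``format="csv"``, the CSV file.
    format : {"wfdb", "csv"}

    Returns
    -------
    ECGRecord
        Amplitudes in mV, onset populated from an annotation file when
        one exists next to the record.
    """
    path = Path(path)
    if format == "wfdb":
        return _load_wfdb(path)
    if format == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _load_csv(path: Path) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                values.append(float(line.split(",")[0]))
            except ValueError as exc:
                raise FormatError(f"{path}: unparsable sample line {line!r}") from exc
    if "fs" not in meta:
        raise FormatError(f"{path}: header does not supply fs")
    fs = float(meta["fs"])
    onset = int(meta["onset_sample"]) if "onset_sample" in meta else None
    source_class = meta.get(
        "source_class", "pre_vtvf" if onset is not None else "normal"
    )
    return ECGRecord(
        record_id=meta.get("record_id", path.stem),
        samples=np.asarray(values, float),
        fs=fs,
        source_class=source_class,
        onset_sample=onset,
    )


def _load_wfdb(path: Path) -> ECGRecord:
    stem = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    hea = stem.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}")
    record_id = head[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if n_sig < 1:
        raise FormatError(f"{hea}: no signals declared")
    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1]
    if fmt.split("+")[0] != "16":
        raise FormatError(f"{hea}: unsupported signal format {fmt!r} (only 16)")
    gain_field = sig[2] if len(sig) > 2 else "200"
    gain_part = gain_field.split("/")[0]
    if "(" in gain_part:
        gain_s, base_s = gain_part.rstrip(")").split("(")
        gain, baseline = float(gain_s), int(base_s)
    else:
        gain, baseline = float(gain_part), 0
    if gain == 0:
        gain = 200.0
    raw = np.fromfile(stem.with_suffix(".dat"), dtype="<i2")
    if n_sig > 1:
        raw = raw.reshape(-1, n_sig)[:, 0]
    raw = raw[:n_samples]
    samples = (raw.astype(float) - baseline) / gain

    onset = _read_onset_annotation(stem, n_samples)
    return ECGRecord(
        record_id=record_id,
        samples=samples,
        fs=fs,
        source_class="pre_vtvf" if onset is not None else "normal",
        onset_sample=onset,
    )


def _read_onset_annotation(stem: Path, n_samples: int) -> int | None:
    atr = stem.with_suffix(".atr")
    txt = stem.with_suffix(".onset")
    onset: int | None = None
    if atr.exists():
        for t, code in _iter_atr(atr.read_bytes()):
            if code == _ATR_VFON:
                onset = t
                break
    elif txt.exists():
        onset = int(txt.read_text().strip())
    if onset is not None and onset >= n_samples:
        raise AnnotationError(
            f"annotated onset {onset} beyond signal length {n_samples}"
        )
    return onset


def _iter_atr(buf: bytes):
    """Yield (time, code) pairs from a MIT annotation byte stream."""
    t = 0
    i = 0
    while i + 1 < len(buf):
        word = struct.unpack_from("<H", buf, i)[0]
        i += 2
        code = word >> 10
        operand = word & 0x3FF
        if word == 0:          # end of annotations
            return
        if code == 59:         # SKIP: 4-byte time operand follows
            t += struct.unpack_from("<i", buf, i)[0] if i + 4 <= len(buf) else 0
            i += 4
        elif code == 63:       # AUX: operand = byte count (padded to even)
            i += operand + (operand & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            t += operand
            yield t, code


def write_record(rec: ECGRecord, stem: str | Path, format: str = "wfdb",
                 gain: float = 400.0) -> Path:
    """Write a record in a dialect :func:`load_record` reads back.

    For WFDB output the signal is quantised to 16-bit integers at
    ``gain`` ADC units per mV, so the round trip is exact to within one
    quantisation step (1/gain mV).
    """
    stem = Path(stem)
    if format == "csv":
        path = stem if stem.suffix == ".csv" else stem.with_suffix(".csv")
        with open(path, "w") as fh:
            fh.write(f"# record_id={rec.record_id}\n# fs={rec.fs:g}\n")
            fh.write(f"# source_class={rec.source_class}\n")
            if rec.onset_sample is not None:
                fh.write(f"# onset_sample={rec.onset_sample}\n")
            np.savetxt(fh, rec.samples, fmt="%.6f")
        return path
    if format != "wfdb":
        raise ValueError(f"unknown format {format!r}")
    stem.parent.mkdir(parents=True, exist_ok=True)
    adc = np.clip(np.round(rec.samples * gain), -32768, 32767).astype("<i2")
    stem.with_suffix(".dat").write_bytes(adc.tobytes())
    stem.with_suffix(".hea").write_text(
        f"{rec.record_id} 1 {rec.fs:g} {len(adc)}\n"
        f"{stem.name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0])} 0 0 ECG\n"
    )
    if rec.onset_sample is not None:
        _write_onset_atr(stem.with_suffix(".atr"), rec.onset_sample)
    return stem.with_suffix(".hea")


def _write_onset_atr(path: Path, onset: int) -> None:
    out = bytearray()
    t = onset
    # large times need SKIP words (10-bit interval field otherwise)
    if t > 1023:
        out += struct.pack("<H", 59 << 10)
        out += struct.pack("<i", t)
        t = 0
    out += struct.pack("<H", (_ATR_VFON << 10) | t)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# curation, truncation, outlier replacement, segmentation


def curate_records(records: Iterable[ECGRecord]) -> list[ECGRecord]:
    """Apply the study's inclusion rule to a record collection.

    Retained are pre-VT/VF records with an onset annotation (identifiable
    normal QRS complexes preceding the episode) and normal-sinus-rhythm
    records; anything else — e.g. a nominally pre-arrhythmic record with
    no usable onset — is excluded.
    """
    kept = []
    for rec in records:
        if rec.source_class == "pre_vtvf" and rec.onset_sample is None:
            continue
        kept.append(rec)
    return kept


def study_record_ids() -> dict[str, tuple[str, ...]]:
    """Record identifiers retained by the inclusion rule, per database."""
    return dict(STUDY_RECORD_IDS)


def truncate_record(rec: ECGRecord, max_minutes: float = 35.0) -> ECGRecord:
    """Truncate a record to at most ``max_minutes`` minutes.

    The onset annotation is dropped if the truncation removes it.
    """
    if max_minutes <= 0:
        raise ValueError("max_minutes must be positive")
    n = round(max_minutes * 60 * rec.fs)
    if len(rec.samples) <= n:
        return rec
    onset = rec.onset_sample
    source = rec.source_class
    if onset is not None and onset >= n:
        onset = None
        source = "normal"
        warnings.warn(
            f"record {rec.record_id}: onset beyond {max_minutes} min dropped",
            stacklevel=2,
        )
    return replace(rec, samples=rec.samples[:n], onset_sample=onset,
                   source_class=source)


def replace_outliers(rec: ECGRecord, window_s: float = 1.0,
                     n_mad: float = 3.0) -> ECGRecord:
    """Replace impulsive outliers with their nearest preceding clean value.

    A sample is an outlier when it deviates from the sliding-window
    median by more than ``n_mad`` scaled median absolute deviations of
    the window. A constant window (MAD = 0) declares no outliers. The
    first sample is never replaced; output length is unchanged. The
    detection/replacement pass is iterated to a fixed point, so the
    operation is idempotent.
    """
    w = int(round(window_s * rec.fs))
    if w < 3:
        raise ValueError("window_s * fs must be at least 3")
    if w % 2 == 0:
        w += 1

    def one_pass(x: np.ndarray) -> np.ndarray:
        med = median_filter(x, size=w, mode="reflect")
        mad = _MAD_SCALE * median_filter(np.abs(x - med), size=w,
                                         mode="reflect")
        outlier = np.abs(x - med) > n_mad * mad
        outlier &= mad > 0      # degenerate (constant) windows: keep
        outlier[0] = False
        if not outlier.any():
            return x
        # index of the nearest preceding clean sample, per position
        idx = np.where(outlier, -1, np.arange(len(x)))
        idx = np.maximum.accumulate(idx)
        return x[idx]

    x = rec.samples
    for _ in range(20):  # fixed-point iteration; converges in a few passes
        cleaned = one_pass(x)
        if cleaned is x:
            break
        x = cleaned
    if x is rec.samples:
        return rec
    return replace(rec, samples=x)


def segment_record(rec: ECGRecord) -> list[MinuteSegment]:
    """Partition a record into consecutive one-minute segments.

    For pre-arrhythmic records, the segment containing the onset and all
    later segments are excluded; retained segments carry
    ``minutes_before_onset`` measured from the segment end. Normal
    records yield label-0 segments with no onset tag.
    """
    n_seg_samples = round(60 * rec.fs)
    n = len(rec.samples) // n_seg_samples
    if n == 0:
        warnings.warn(
            f"record {rec.record_id} shorter than one minute; no segments",
            stacklevel=2,
        )
        return []
    segments: list[MinuteSegment] = []
    for i in range(n):
        start = i * n_seg_samples
        end = start + n_seg_samples
        if rec.onset_sample is not None:
            if rec.onset_sample < end:
                break  # onset falls inside (or at the start of) this window
            mbo = (rec.onset_sample - end) / (60 * rec.fs)
            segments.append(MinuteSegment(
                record_id=rec.record_id, index_in_record=i,
                samples=rec.samples[start:end], fs=rec.fs,
                minutes_before_onset=mbo, label=1,
            ))
        else:
            segments.append(MinuteSegment(
                record_id=rec.record_id, index_in_record=i,
                samples=rec.samples[start:end], fs=rec.fs,
            ))
    return segments


# ---------------------------------------------------------------------------
# feature tables

_META_COLUMNS = ("label", "minutes_before_onset", "record_id",
                 "segment_index", "n_beats")


def read_feature_table(path: str | Path, dialect: str = "csv",
                       column_map: Mapping[str, str] | None = None
                       ) -> FeatureTable:
    """Read a feature table from CSV.

    ``column_map`` renames source columns to canonical names, to absorb
    external tables whose headers differ (e.g. supplementary datasets).
    """
    if dialect not in ("csv", "mat-style"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else r"\s+"
    frame = pd.read_csv(path, sep=sep)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in (*FEATURE_NAMES, "label") if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    unknown = [c for c in frame.columns
               if c not in FEATURE_NAMES and c not in _META_COLUMNS]
    if unknown:
        raise SchemaError(f"feature table has unresolvable columns: {unknown}")
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV, 7 significant digits per value."""
    path = Path(path)
    ordered = [c for c in (*FEATURE_NAMES, *_META_COLUMNS)
               if c in table.frame.columns]
    table.frame.loc[:, ordered].to_csv(path, index=False, float_format="%.7g")
    return path
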