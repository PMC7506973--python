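"""Readers and writers for the tabular formats the pipeline touches.

Everything is plain CSV (UTF-8, ``.`` decimal separator):

* Empatica-E4-style EDA exports — two header lines (epoch start time,
  sampling rate in Hz) followed by one conductance sample (µS) per line;
* stimulus-event tables with columns ``label,onset,duration``;
* SAM (self-assessment manikin) arousal response tables with columns
  ``participant_id,segment_label,arousal``;
* the per-segment "feature sheet" holding the 23 scalar features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genre -> (style, style); the two musical styles realising each genre.
GENRE_STYLES: dict[str, tuple[str, str]] = {
    "rock_jazz": ("twist", "swing"),
    "cuban": ("bolero", "habanera"),
    "spanish_folklore": ("pasodoble", "murcian_jota"),
    "flamenco": ("fandango", "petenera"),
}

#: style -> genre reverse lookup.
STYLE_TO_GENRE: dict[str, str] = {
    style: genre for genre, styles in GENRE_STYLES.items() for style in styles
}

GENRES: tuple[str, ...] = tuple(GENRE_STYLES)

NEUTRAL_LABEL = "neutral"

KNOWN_LABELS = frozenset(STYLE_TO_GENRE) | frozenset(GENRES) | {NEUTRAL_LABEL}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class EmptyRecordingError(ValueError):
    """A recording holds fewer than two samples."""


@dataclass
class EDASignal:
    """A uniformly sampled skin-conductance trace.

    Parameters
    ----------
    samples : conductance values in µS.
    fs : sampling rate in Hz (> 0).
    t0 : recording start, epoch seconds.
    label : free-text channel/session tag.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise EmptyRecordingError(
                f"need a 1-d series of at least 2 samples, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span between first and last sample, seconds: (n - 1) / fs."""
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to t0."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation: a labelled window of the recording."""

    label: str
    onset: float  # seconds from the start of the recording
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SAMResponse:
    """A participant's self-reported arousal for one segment (1–9 scale)."""

    participant_id: str
    segment_label: str
    arousal: int
    scale: tuple[int, int] = (1, 9)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not lo <= self.arousal <= hi:
            raise ValueError(
                f"arousal {self.arousal} outside scale [{lo}, {hi}]"
            )


@dataclass
class QualityReport:
    """Per-file data-quality bookkeeping from :func:`read_e4_eda`."""

    n_samples: int = 0
    n_interpolated: int = 0
    notes: list[str] = field(default_factory=list)


def read_e4_eda(path: str | Path, label: str = "") -> tuple[EDASignal, QualityReport]:
    """Read an Empatica-E4-style EDA CSV.

    The dialect is two header lines — epoch start time then sampling rate —
    followed by one float sample per line.  Non-finite samples are replaced
    by linear interpolation (downstream filtering needs a gapless uniform
    series) and counted in the returned :class:`QualityReport`.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected two header lines (t0, fs), got {len(lines)} line(s)")
    try:
        t0 = float(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a number (t0): {lines[0]!r}") from exc
    try:
        fs = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a number (fs): {lines[1]!r}") from exc
    if len(lines) < 4:
        raise EmptyRecordingError(f"{path}: fewer than 2 sample lines")
    try:
        samples = np.array([float(x) for x in lines[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample line: {exc}") from exc

    report = QualityReport(n_samples=samples.size)
    bad = ~np.isfinite(samples)
    if bad.any():
        if bad.all():
            raise FormatError(f"{path}: every sample is non-finite")
        idx = np.arange(samples.size)
        samples[bad] = np.interp(idx[bad], idx[~bad], samples[~bad])
        report.n_interpolated = int(bad.sum())
        report.notes.append(f"interpolated {report.n_interpolated} non-finite sample(s)")
    return EDASignal(samples, fs=fs, t0=t0, label=label or path.stem), report


def read_timed_csv(path: str | Path, label: str = "") -> tuple[EDASignal, QualityReport]:
    """Read a generic two-column ``time,value`` CSV (for non-E4 devices).

    Times must be uniformly spaced; fs is inferred from the median step.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (time, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise EmptyRecordingError(f"{path}: fewer than 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-3, atol=1e-9):
        raise FormatError(f"{path}: time column is not uniformly spaced")
    report = QualityReport(n_samples=v.size)
    bad = ~np.isfinite(v)
    if bad.any():
        idx = np.arange(v.size)
        v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
        report.n_interpolated = int(bad.sum())
    return EDASignal(v, fs=1.0 / dt, t0=float(t[0]), label=label or Path(path).stem), report


def validate_events(events: list[StimulusEvent]) -> list[StimulusEvent]:
    """Sort events by onset and reject overlaps."""
    events = sorted(events, key=lambda e: e.onset)
    for a, b in zip(events, events[1:]):
        if b.onset < a.end - 1e-9:
            raise ValueError(
                f"overlapping events: {a.label} [{a.onset}, {a.end}) and "
                f"{b.label} [{b.onset}, {b.end})"
            )
    return events


def read_events(path: str | Path) -> list[StimulusEvent]:
    """Read a stimulus-event CSV with columns ``label,onset,duration``.

    Events come back sorted by onset; overlapping events raise; unknown
    labels warn but are kept.
    """
    df = pd.read_csv(path)
    missing = {"label", "onset", "duration"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty event table", stacklevel=2)
        return []
    events = [
        StimulusEvent(str(r.label), float(r.onset), float(r.duration))
        for r in df.itertuples(index=False)
    ]
    for ev in events:
        if ev.label not in KNOWN_LABELS:
            warnings.warn(f"unknown event label {ev.label!r} (kept)", stacklevel=2)
    return validate_events(events)


def write_events(events: list[StimulusEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.label, e.onset, e.duration) for e in events],
        columns=["label", "onset", "duration"],
    ).to_csv(path, index=False)


def read_sam(path: str | Path) -> list[SAMResponse]:
    """Read a SAM response CSV with columns ``participant_id,segment_label,arousal``."""
    df = pd.read_csv(path)
    missing = {"participant_id", "segment_label", "arousal"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        SAMResponse(str(r.participant_id), str(r.segment_label), int(r.arousal))
        for r in df.itertuples(index=False)
    ]


def write_sam(responses: list[SAMResponse], path: str | Path) -> None:
    pd.DataFrame(
        [(r.participant_id, r.segment_label, r.arousal) for r in responses],
        columns=["participant_id", "segment_label", "arousal"],
    ).to_csv(path, index=False)


def write_feature_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    """Write a feature sheet: key columns + the 23 features in fixed order.

    The column order is frozen (M … F3) so sheets are comparable across
    runs; values round-trip through :func:`read_feature_sheet` losslessly
    to 12 significant digits.
    """
    from .features import FEATURE_NAMES

    keys = ["participant_id", "segment_label"]
    expected = keys + list(FEATURE_NAMES)
    missing = set(expected) - set(sheet.columns)
    if missing:
        raise ValueError(f"feature sheet missing column(s): {sorted(missing)}")
    extra_meta = [c for c in sheet.columns if c not in expected]
    sheet[expected + extra_meta].to_csv(path, index=False, float_format="%.17g")


def read_feature_sheet(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_NAMES

    df = pd.read_csv(path)
    missing = {"participant_id", "segment_label", *FEATURE_NAMES} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_e4_eda(signal: EDASignal, path: str | Path) -> None:
    """Write an :class:`EDASignal` in the E4 dialect read by :func:`read_e4_eda`."""
    with open(path, "w") as fh:
        fh.write(f"{signal.t0:.6f}\n{signal.fs:.6f}\n")
        for v in signal.samples:
            fh.write(f"{v:.9f}\n")
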