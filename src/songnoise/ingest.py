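"""Read and validate field inputs: SLM CSV exports, WAV audio, song metadata.

The sound-level-meter (SLM) export schema used by this package is::

    time_s, laeq_db, band_2000, band_2500, ..., band_8000

one row per 100-ms sample: an A-weighted broadband LAeq column plus one
Z-weighted Leq column per nominal 1/3-octave band centre.  Vendors name
columns differently, so :func:`read_slm_csv` accepts a dialect config
mapping vendor headers onto this schema.

Songs and the noise segments used for background subtraction are carved
out of a recording by time interval; all times are seconds from recording
start, intervals half-open ``[onset, offset)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustics import (
    BandLevelSeries,
    LevelSeries,
    nominal_center,
    third_octave_bands,
)

__all__ = [
    "SlmRecording",
    "SongRecord",
    "NoiseSegment",
    "SlmCsvDialect",
    "read_slm_csv",
    "write_slm_csv",
    "read_song_wav",
    "read_song_table",
    "find_noise_segment",
    "validate_recording",
    "MEASURABILITY_REASONS",
]

#: why a song's amplitude may be unmeasurable in the field: sound path
#: obstructed, lateral head movement, bird not facing the microphone, or
#: bird not perched at microphone height
MEASURABILITY_REASONS = ("obstructed", "head_movement", "not_facing", "height_mismatch")

#: band centres in which white-crowned sparrow songs occur
DEFAULT_BAND_RANGE = (2000.0, 8000.0)

#: songs recorded above this wind speed are flagged
WIND_SPEED_LIMIT = 1.0  # m/s


@dataclass
class SongRecord:
    """One song's interval, distance, and measurability within a recording."""

    song_id: str
    recording_id: str
    bird_id: str
    onset: float
    offset: float
    measurable_amplitude: bool = True
    unmeasurable_reasons: tuple[str, ...] = ()
    distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValueError(f"song {self.song_id}: onset must precede offset")
        if self.offset - self.onset > 10.0:
            raise ValueError(f"song {self.song_id}: duration exceeds 10 s sanity bound")
        for r in self.unmeasurable_reasons:
            if r not in MEASURABILITY_REASONS:
                raise ValueError(f"unknown measurability reason {r!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class NoiseSegment:
    """A song-free window serving one song's background-noise estimate."""

    song_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        d = self.end - self.start
        if not (3.0 <= d <= 15.0 + 1e-9):
            raise ValueError(
                f"noise segment for {self.song_id}: duration {d:.2f} s outside [3, 15] s"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SlmRecording:
    """One sound-level-meter recording: broadband LAeq + per-band Z Leq series."""

    recording_id: str
    bird_id: str
    broadband: LevelSeries
    bands: BandLevelSeries
    site: str = ""  # {"rural", "urban"}
    location: str = ""
    distance: Optional[float] = None
    wind_speed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.broadband.step != self.bands.step:
            raise ValueError("broadband and band series must share the sampling step")
        if self.broadband.start_time != self.bands.start_time:
            raise ValueError("broadband and band series must share start_time")
        if self.distance is not None and self.distance <= 0:
            raise ValueError("distance must be positive when present")

    @property
    def duration(self) -> float:
        return self.broadband.duration


@dataclass
class SlmCsvDialect:
    """Maps vendor CSV headers onto the package schema.

    ``band_pattern`` is a regex whose single group captures the band-centre
    label in a band column name (e.g. ``band_2000`` or ``1/3 LZeq 2000Hz``).
    """

    time_column: str = "time_s"
    broadband_column: str = "laeq_db"
    band_pattern: str = r"band_(\d+(?:\.\d+)?)"


def _parse_band_columns(columns: Sequence[str], dialect: SlmCsvDialect) -> dict[float, str]:
    pat = re.compile(dialect.band_pattern)
    out: dict[float, str] = {}
    for col in columns:
        m = pat.fullmatch(col.strip())
        if m:
            out[nominal_center(float(m.group(1)))] = col
    return out


def read_slm_csv(
    path: str | Path,
    dialect: SlmCsvDialect | None = None,
    recording_id: str = "",
    bird_id: str = "",
    band_range: tuple[float, float] = DEFAULT_BAND_RANGE,
    **meta,
) -> SlmRecording:
    """Read an SLM CSV export into a validated :class:`SlmRecording`.

    Requires uniform timestamps and one column per nominal band centre in
    ``band_range``; extra band columns outside the range are ignored.
    """
    dialect = dialect or SlmCsvDialect()
    path = Path(path)
    df = pd.read_csv(path)
    for col in (dialect.time_column, dialect.broadband_column):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    t = df[dialect.time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least 2 samples")
    steps = np.diff(t)
    step = float(np.median(steps))
    if np.any(np.abs(steps - step) > 1e-6 + 1e-4 * step):
        raise ValueError(f"{path.name}: non-uniform timestamps")

    required = third_octave_bands(*band_range)
    col_by_center = _parse_band_columns(df.columns, dialect)
    missing = [b.center for b in required if b.center not in col_by_center]
    if missing:
        raise ValueError(f"{path.name}: missing band columns for centres {missing}")

    start = float(t[0])
    broadband = LevelSeries(
        start_time=start,
        step=step,
        levels=df[dialect.broadband_column].to_numpy(dtype=float),
        weighting="A",
        metric="Leq",
    )
    series = [
        LevelSeries(
            start_time=start,
            step=step,
            levels=df[col_by_center[b.center]].to_numpy(dtype=float),
            weighting="Z",
            metric="Leq",
        )
        for b in required
    ]
    return SlmRecording(
        recording_id=recording_id or path.stem,
        bird_id=bird_id,
        broadband=broadband,
        bands=BandLevelSeries(list(required), series),
        **meta,
    )


def write_slm_csv(recording: SlmRecording, path: str | Path) -> None:
    """Write an :class:`SlmRecording` back to the package CSV schema."""
    data = {
        "time_s": recording.broadband.times,
        "laeq_db": np.round(recording.broadband.levels, 4),
    }
    for b, s in zip(recording.bands.bands, recording.bands.series):
        data[f"band_{b.center:g}"] = np.round(s.levels, 4)
    pd.DataFrame(data).to_csv(path, index=False)


def read_song_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file into a normalised float waveform in [-1, 1].

    Integer PCM is scaled by its full-scale value; float audio is passed
    through.  Stereo files are reduced to the first channel with a warning.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise ValueError(f"unreadable WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multichannel audio, taking first channel")
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        wave = data.astype(np.float64) / scale
    else:
        wave = data.astype(np.float64)
    return wave, int(rate)


def read_song_table(path: str | Path) -> list[SongRecord]:
    """Read the per-song metadata CSV (song_id, recording_id, bird_id,
    onset_s, offset_s, measurable, reasons, distance_m)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        reasons = ()
        raw = row.get("reasons")
        if isinstance(raw, str) and raw.strip():
            reasons = tuple(r.strip() for r in raw.split(";"))
        dist = row.get("distance_m")
        records.append(
            SongRecord(
                song_id=str(row["song_id"]),
                recording_id=str(row["recording_id"]),
                bird_id=str(row["bird_id"]),
                onset=float(row["onset_s"]),
                offset=float(row["offset_s"]),
                measurable_amplitude=bool(row.get("measurable", True)),
                unmeasurable_reasons=reasons,
                distance=float(dist) if dist is not None and np.isfinite(dist) else None,
            )
        )
    return records


def find_noise_segment(
    recording: SlmRecording,
    song: SongRecord,
    all_songs: Sequence[SongRecord],
    min_duration: float = 3.0,
    max_duration: float = 15.0,
) -> NoiseSegment:
    """Locate the song-free window nearest in time to a focal song.

    Searches the gaps between songs before and after the focal song,
    takes as long a window as possible (capped at ``max_duration``) abutting
    the gap edge closest to the focal song, and returns the closer of the
    qualifying before/after candidates.
    """
    t0 = recording.broadband.start_time
    t1 = t0 + recording.duration
    if not (t0 <= song.onset and song.offset <= t1):
        raise ValueError(f"recording does not cover song {song.song_id}")

    intervals = sorted(
        (s.onset, s.offset) for s in all_songs if s.recording_id == recording.recording_id
    )
    # merge overlapping song intervals
    merged: list[list[float]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # gaps between songs (and recording edges)
    edges = [t0] + [x for ab in merged for x in ab] + [t1]
    gaps = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]

    candidates: list[tuple[float, NoiseSegment]] = []
    for ga, gb in gaps:
        if gb - ga < min_duration:
            continue
        length = min(gb - ga, max_duration)
        if gb <= song.onset + 1e-9:  # gap before the song: abut its end
            seg = NoiseSegment(song.song_id, gb - length, gb)
            dist = song.onset - gb
        elif ga >= song.offset - 1e-9:  # gap after: abut its start
            seg = NoiseSegment(song.song_id, ga, ga + length)
            dist = ga - song.offset
        else:
            continue
        candidates.append((max(dist, 0.0), seg))
    if not candidates:
        raise ValueError(
            f"no song-free window of >= {min_duration} s available for song {song.song_id}"
        )
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def validate_recording(recording: SlmRecording) -> list[str]:
    """Quality-control flags for a recording (never raises).

    Flags high wind (songs should be recorded below 1 m/s), a missing
    recordist distance, and a sampling step other than the nominal 100 ms.
    """
    flags = []
    if recording.wind_speed is not None and recording.wind_speed >= WIND_SPEED_LIMIT:
        flags.append(f"wind_speed {recording.wind_speed} m/s >= {WIND_SPEED_LIMIT} m/s")
    if recording.distance is None:
        flags.append("distance missing")
    if abs(recording.broadband.step - 0.1) > 1e-9:
        flags.append(f"step {recording.broadband.step} s != 0.1 s")
    return flags
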