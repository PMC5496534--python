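"""Environmental-noise metrics at three time scales.

For each song the pipeline characterises the noise environment with:

* **instantaneous** -- the Leq of the broadband A-weighted samples in the
  10 s immediately before song onset (the level the bird just heard);
* **bout background** -- the LAF90 over the song bout, i.e. the level
  exceeded 90% of the time, a background statistic robust to transient
  events such as passing traffic;
* **territory** -- the median of per-recording Leq values across all
  recordings on the bird's territory, capturing the noise regime over
  hours to days.

A per-bout 1/3-octave L90 spectrum is also provided for spectral profiles
of the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .acoustics import energetic_mean, exceedance_level
from .ingest import SlmRecording, SongRecord

__all__ = [
    "NoiseMetrics",
    "instantaneous_noise",
    "bout_background",
    "territory_noise",
    "bout_band_spectrum",
    "noise_metrics_table",
    "INSTANTANEOUS_WINDOW",
    "MIN_PRESONG_WINDOW",
    "MIN_BOUT_DURATION",
]

#: nominal pre-song averaging window (s)
INSTANTANEOUS_WINDOW = 10.0
#: minimum usable pre-song window before erroring (field recordings truncate)
MIN_PRESONG_WINDOW = 5.0
#: minimum bout duration for a meaningful L90 (s)
MIN_BOUT_DURATION = 10.0


@dataclass
class NoiseMetrics:
    """The three per-song noise measures plus the bout band-L90 spectrum."""

    song_id: str
    bird_id: str
    instantaneous: float
    bout_background: float
    territory: float
    band_centers: tuple[float, ...] = ()
    band_l90: tuple[float, ...] = ()


def instantaneous_noise(
    recording: SlmRecording,
    song: SongRecord,
    window: float = INSTANTANEOUS_WINDOW,
    min_window: float = MIN_PRESONG_WINDOW,
) -> float:
    """Average LAeq over the ``window`` seconds immediately before the song.

    The window is half-open ``[onset - window, onset)``: samples at or
    after song onset never contribute.  If the recording provides less
    than ``min_window`` seconds before the song, an error names the song.
    """
    t0 = max(song.onset - window, recording.broadband.start_time)
    available = song.onset - t0
    if available < min_window - 1e-9:
        raise ValueError(
            f"song {song.song_id}: only {available:.1f} s of pre-song noise "
            f"available (< {min_window} s minimum)"
        )
    pre = recording.broadband.slice(t0, song.onset)
    return energetic_mean(pre.levels)


def bout_background(
    recording: SlmRecording,
    bout_interval: tuple[float, float],
    min_duration: float = MIN_BOUT_DURATION,
) -> float:
    """LAF90 over a song bout: the level exceeded 90% of the time."""
    t0, t1 = bout_interval
    if t1 - t0 < min_duration:
        raise ValueError(
            f"bout [{t0}, {t1}] shorter than {min_duration} s; L90 unreliable"
        )
    bout = recording.broadband.slice(t0, t1)
    return exceedance_level(bout.levels, 90.0)


def territory_noise(
    recordings: Sequence[SlmRecording],
    pool_samples: bool = False,
) -> float:
    """Territory-level noise: median LAeq across a bird's recordings.

    Each recording is first reduced to its Leq (energetic mean of the
    100-ms samples); the median is then taken across recordings, midpoint
    convention for even counts.  With ``pool_samples=True`` the median is
    instead taken over the pooled 100-ms samples of all recordings.
    """
    if not recordings:
        raise ValueError("territory noise requires at least one recording")
    if pool_samples:
        pooled = np.concatenate([r.broadband.levels for r in recordings])
        return float(np.median(pooled))
    leqs = [energetic_mean(r.broadband.levels) for r in recordings]
    return float(np.median(leqs))


def bout_band_spectrum(
    recording: SlmRecording,
    bout_interval: tuple[float, float],
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-band L90 over the bout, in ascending band order.

    Returns (band centres, L90 values) -- the spectral profile of the
    background noise during the bout.
    """
    if recording.bands is None:
        raise ValueError("recording has no band series")
    sliced = recording.bands.slice(*bout_interval)
    centers = tuple(b.center for b in sliced.bands)
    l90 = tuple(exceedance_level(s.levels, 90.0) for s in sliced.series)
    return centers, l90


def noise_metrics_table(metrics: Sequence[NoiseMetrics]) -> pd.DataFrame:
    """Tidy per-song noise table (one row per song, band L90 columns last)."""
    rows = []
    for m in metrics:
        row = {
            "song_id": m.song_id,
            "bird_id": m.bird_id,
            "instantaneous_dBA": m.instantaneous,
            "bout_l90_dBA": m.bout_background,
            "territory_median_dBA": m.territory,
        }
        for c, v in zip(m.band_centers, m.band_l90):
            row[f"l90_band_{c:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
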