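"""Song source-level estimation from 1/3-octave band series.

The chain, per song:

1. average background level per band over a nearby song-free noise
   segment (band Leq);
2. sound exposure level (SEL) per band over the song segment;
3. per band, subtract the background-noise energy expected over the song
   window (noise Leq scaled to the song duration) from the song-segment
   SEL; bands not separable from noise are dropped and reported;
4. sum the surviving bands' song-only SELs energetically;
5. back-calculate to 1 m with the spherical-spreading distance
   correction.

The result is the song's SEL at 1 m in dB(Z) SPL re 20 uPa -- unweighted
within bands, because only the bands the species sings in (2-8 kHz
centres) enter the sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .acoustics import (
    DEFAULT_SNR_MARGIN_DB,
    BandLevelSeries,
    NoiseDominatedError,
    energetic_mean,
    energy_subtract,
    energy_sum,
    sel_from_series,
    spherical_spreading_correction,
)
from .ingest import NoiseSegment, SlmRecording, SongRecord

import numpy as np

__all__ = [
    "SongAmplitudeResult",
    "band_noise_levels",
    "band_song_sel",
    "subtract_background",
    "estimate_song_amplitude",
]


@dataclass
class SongAmplitudeResult:
    """Per-song source-level estimate with its band-level bookkeeping."""

    song_id: str
    sel_at_1m: float  # dB(Z) SPL re 20 uPa, SEL at the 1-m reference
    distance_used: float
    band_centers: tuple[float, ...]
    band_song_sel: dict[float, float]  # noise-subtracted, surviving bands only
    band_noise_leq: dict[float, float]
    bands_dropped: dict[float, str] = field(default_factory=dict)

    @property
    def n_bands_used(self) -> int:
        return len(self.band_song_sel)


def band_noise_levels(
    noise_bands: BandLevelSeries,
    min_duration: float = 3.0,
    max_duration: float = 15.0,
) -> dict[float, float]:
    """Average noise level (Leq) per band over a noise segment."""
    dur = noise_bands.series[0].duration
    if not (min_duration - 1e-9 <= dur <= max_duration + 1e-9):
        raise ValueError(
            f"noise segment duration {dur:.2f} s outside [{min_duration}, {max_duration}] s"
        )
    return {
        b.center: energetic_mean(s.levels)
        for b, s in zip(noise_bands.bands, noise_bands.series)
    }


def band_song_sel(song_bands: BandLevelSeries) -> dict[float, float]:
    """Sound exposure level per band over the song segment."""
    return {
        b.center: sel_from_series(s)
        for b, s in zip(song_bands.bands, song_bands.series)
    }


def subtract_background(
    song_sel: dict[float, float],
    noise_leq: dict[float, float],
    song_duration: float,
    min_snr_margin: float = DEFAULT_SNR_MARGIN_DB,
) -> tuple[dict[float, float], dict[float, str]]:
    """Remove background-noise energy from each band's song-segment SEL.

    The background contributes energy throughout the song window, so each
    band's noise Leq is first converted to the SEL it would accumulate
    over ``song_duration``: ``noise_leq + 10*log10(duration / 1 s)``.
    Bands whose song-segment SEL does not exceed that noise SEL by the
    SNR margin are dropped (noise-dominated) and reported with a reason.

    Returns (song-only SEL per surviving band, dropped bands with reasons).
    """
    if set(song_sel) != set(noise_leq):
        raise ValueError("song and noise band sets differ")
    if song_duration <= 0:
        raise ValueError("song duration must be positive")
    out: dict[float, float] = {}
    dropped: dict[float, str] = {}
    noise_window_db = 10.0 * np.log10(song_duration)
    for center in sorted(song_sel):
        noise_sel = (
            -np.inf
            if noise_leq[center] == -np.inf
            else noise_leq[center] + noise_window_db
        )
        try:
            out[center] = energy_subtract(song_sel[center], noise_sel, min_snr_margin)
        except NoiseDominatedError as exc:
            dropped[center] = str(exc)
    if not out:
        raise ValueError("song not separable from noise: all bands dropped")
    return out, dropped


def estimate_song_amplitude(
    song: SongRecord,
    recording: SlmRecording,
    noise: NoiseSegment,
    min_snr_margin: float = DEFAULT_SNR_MARGIN_DB,
) -> SongAmplitudeResult:
    """Full source-level chain: band SELs -> noise subtraction -> band sum
    -> distance correction to 1 m.

    Requires a measurable song (unobstructed, facing, no head movement,
    height-matched) and a known recordist distance.
    """
    if not song.measurable_amplitude:
        reasons = ", ".join(song.unmeasurable_reasons) or "unspecified"
        raise ValueError(f"song {song.song_id} amplitude not measurable ({reasons})")
    distance = song.distance if song.distance is not None else recording.distance
    if distance is None:
        raise ValueError(f"song {song.song_id}: no recordist distance available")

    song_bands = recording.bands.slice(song.onset, song.offset)
    noise_bands = recording.bands.slice(noise.start, noise.end)

    noise_leq = band_noise_levels(noise_bands)
    song_sel = band_song_sel(song_bands)
    song_only, dropped = subtract_background(
        song_sel, noise_leq, song.duration, min_snr_margin
    )
    total_sel = energy_sum(list(song_only.values()))
    sel_1m = spherical_spreading_correction(total_sel, distance)
    return SongAmplitudeResult(
        song_id=song.song_id,
        sel_at_1m=sel_1m,
        distance_used=float(distance),
        band_centers=tuple(b.center for b in recording.bands.bands),
        band_song_sel=song_only,
        band_noise_leq=noise_leq,
        bands_dropped=dropped,
    )
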