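"""Synthetic field data with known ground truth.

Generates every input the pipeline consumes, at three levels:

* **waveforms** -- a stylised sparrow-like song (a pure-whistle component
  at the target minimum frequency plus a louder, higher trill component)
  and a shaped-noise soundscape with a prescribed 1/3-octave floor
  spectrum and optional transient events (traffic-like, more energy at
  low frequencies when given a 1/f shape);
* **sound-level-meter series** -- the renderer scales a song to a known
  source SEL at 1 m, applies spherical spreading for a chosen recordist
  distance, mixes it into the soundscape, band-filters the mixture into
  the seven 2-8 kHz 1/3-octave bands, and integrates 100-ms Leq samples
  per band plus an A-weighted broadband series, exactly as the meter in
  the field would;
* **whole studies** -- per-song trait tables drawn from a known
  generating model (amplitude quadratic in instantaneous noise plus a
  distance effect and a by-bird random intercept; minimum frequency from
  per-bird means), with unbalanced per-bird song counts drawn to resemble
  the field sampling.

Everything is deterministic under a fixed seed; ground truth is returned
alongside every dataset so recovery can be asserted, not assumed.

The internal amplitude convention maps waveform sample values to pascals:
SPL = 10*log10(mean(x^2) / (20 uPa)^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .acoustics import (
    P_REF,
    BandLevelSeries,
    LevelSeries,
    ThirdOctaveBand,
    a_weight_correction,
    third_octave_bands,
)
from .ingest import NoiseSegment, SlmRecording, SongRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RenderedRecording",
    "synth_song_waveform",
    "synth_noise_waveform",
    "render_slm_series",
    "render_recovery_case",
    "simulate_study",
    "load_male_sampling",
    "waveform_sel",
]

DEFAULT_SAMPLE_RATE = 25000
DEFAULT_BAND_RANGE = (2000.0, 8000.0)


@dataclass
class SimConfig:
    """Study-level simulation parameters with field-realistic defaults.

    The amplitude-generating rule is
    ``amp = b0 + b_noise*N + b_noise2*N^2 + b_distance*D + bird + resid``
    with ``N`` the instantaneous noise (dB(A)) and ``D`` the recordist
    distance (m).  Default coefficients are the field estimates for this
    system (noise -1.6 dB/dB, noise^2 0.022 dB/dB^2, distance 0.14 dB/m),
    with the intercept chosen so songs fall in the observed 77-86 dB(Z)
    range over 30-54 dB(A) noise.
    """

    seed: int = 0
    n_birds: int = 17
    songs_per_bird: Optional[Sequence[int]] = None  # None -> field-like skew
    distance_range: tuple[float, float] = (2.0, 16.0)
    noise_range: tuple[float, float] = (30.0, 54.0)  # instantaneous dB(A)
    # amplitude model (dB(Z) SEL at 1 m)
    beta0: float = 105.0
    beta_noise: float = -1.6
    beta_noise2: float = 0.022
    beta_distance: float = 0.14
    bird_intercept_sd: float = 1.5
    residual_sd: float = 1.5
    # minimum-frequency model (Hz)
    minfreq_mean: float = 4000.0
    minfreq_between_sd: float = 250.0
    minfreq_within_sd: float = 100.0
    minfreq_noise_effect: float = 0.0  # Hz per dB; 0 = the null world

    def __post_init__(self) -> None:
        if self.n_birds < 2:
            raise ValueError("need at least 2 birds")
        for sd in (self.bird_intercept_sd, self.residual_sd,
                   self.minfreq_between_sd, self.minfreq_within_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


@dataclass
class GroundTruth:
    """Generating parameters and per-song true values for one dataset."""

    coefficients: dict
    per_song: pd.DataFrame  # song_id, bird_id, true values

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "per_song": self.per_song.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class RenderedRecording:
    """An audio-rendered recording plus its known ground truth."""

    recording: SlmRecording
    song: SongRecord
    noise_segment: NoiseSegment
    mixture: np.ndarray
    sample_rate: int
    truth: dict


def waveform_sel(wave: np.ndarray, sample_rate: float) -> float:
    """Sound exposure level of a waveform under the pascal convention."""
    energy = np.sum(np.asarray(wave, dtype=float) ** 2) / sample_rate
    return float(10.0 * np.log10(energy / (P_REF ** 2)))


def synth_song_waveform(
    min_freq: float,
    duration: float = 2.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> np.ndarray:
    """Deterministic sparrow-like song whose measured minimum frequency
    (256-pt spectrogram, -36 dB re peak) lands within one bin of ``min_freq``.

    Two components: a whistle at ``min_freq`` (~12 dB below the peak, so
    its window-leakage sidelobes fall below the -36 dB threshold) and a
    louder amplitude-modulated trill component 1.5 kHz higher that carries
    the spectral peak.

    The whistle is snapped onto the 256-point analysis bin grid, one bin
    above the requested value: a bin-centred Hann tone leaks exactly one
    bin downward at the -36 dB criterion, so the measured edge lands on
    the grid point nearest ``min_freq``.
    """
    if not (2000.0 <= min_freq <= 6000.0):
        raise ValueError(f"min_freq {min_freq} Hz outside the 2000-6000 Hz song range")
    if not (1.0 <= duration <= 3.0):
        raise ValueError(f"duration {duration} s outside [1, 3] s")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    bin_width = sample_rate / 256.0
    whistle_freq = (np.round(min_freq / bin_width) + 1.0) * bin_width
    # the trill carries the spectral peak; place it at the nominal band
    # centre nearest min_freq + 1.5 kHz so the renderer's band filters see
    # it mid-band rather than at an edge
    centers = np.array([b.center for b in third_octave_bands(*DEFAULT_BAND_RANGE)])
    trill_freq = float(centers[np.argmin(np.abs(np.log(centers / (min_freq + 1500.0))))])
    # 30-Hz AM on the trill: sidebands stay well inside one 97.7-Hz bin
    trill = (1.0 + 0.4 * np.sin(2 * np.pi * 30.0 * t)) * np.sin(2 * np.pi * trill_freq * t)
    whistle = 0.25 * np.sin(2 * np.pi * whistle_freq * t)
    wave = trill + whistle
    # 10-ms raised-cosine onset/offset ramps
    ramp = min(int(0.01 * sample_rate), n // 4)
    env = np.ones(n)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    return wave * env


def synth_noise_waveform(
    band_floor_spectrum: dict[float, float],
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    event_rate: float = 0.0,
    event_gain_db: float = 15.0,
    event_duration: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise whose per-band Leq matches a requested floor spectrum.

    ``band_floor_spectrum`` maps 1/3-octave band centres (Hz) to target
    Leq (dB re 20 uPa).  White noise is shaped in the frequency domain
    with a piecewise gain so each band carries the requested power;
    outside the specified bands the gain rolls off.  Optional transient
    events (amplitude bursts ``event_gain_db`` above the floor, mean rate
    ``event_rate`` per second) emulate passing traffic.
    """
    rng = rng or np.random.default_rng()
    centers = sorted(band_floor_spectrum)
    if not centers:
        raise ValueError("band floor spectrum is empty")
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)

    gain = np.zeros_like(freqs)
    bands = [ThirdOctaveBand(c) for c in centers]
    for b in bands:
        target_power = (P_REF ** 2) * 10.0 ** (band_floor_spectrum[b.center] / 10.0)
        # white noise with unit variance has one-sided PSD 2/fs per Hz... the
        # calibration below is exact for the in-band mean-square value:
        # band mean-square = (W / (fs/2)) * g^2  for unit-variance white noise
        g = np.sqrt(target_power * (sample_rate / 2.0) / b.width)
        sel = (freqs >= b.lower_edge) & (freqs < b.upper_edge)
        gain[sel] = g
    # gentle roll-off outside the specified bands instead of a hard zero
    lo, hi = bands[0].lower_edge, bands[-1].upper_edge
    below = freqs < lo
    above = freqs >= hi
    g_lo = gain[np.searchsorted(freqs, lo)]
    g_hi = gain[np.searchsorted(freqs, hi) - 1]
    with np.errstate(divide="ignore"):
        gain[below] = g_lo * np.clip(freqs[below] / lo, 0.0, 1.0) ** 2
        gain[above] = g_hi * np.clip(hi / freqs[above], 0.0, 1.0) ** 2

    wave = np.fft.irfft(spec * gain, n=n)

    if event_rate > 0:
        n_events = rng.poisson(event_rate * duration)
        factor = 10.0 ** (event_gain_db / 20.0)
        ev_len = int(event_duration * sample_rate)
        for _ in range(n_events):
            start = rng.integers(0, max(n - ev_len, 1))
            env = np.hanning(ev_len)
            wave[start:start + ev_len] *= 1.0 + (factor - 1.0) * env[: len(wave[start:start + ev_len])]
    return wave


def _band_filters(bands: Sequence[ThirdOctaveBand], sample_rate: float) -> list:
    nyq = sample_rate / 2.0
    return [
        butter(4, [b.lower_edge / nyq, min(b.upper_edge / nyq, 0.999)], btype="band", output="sos")
        for b in bands
    ]


def _level_series_from_wave(
    wave: np.ndarray, sample_rate: float, step: float, weighting: str
) -> LevelSeries:
    block = int(round(step * sample_rate))
    n_blocks = wave.size // block
    x = wave[: n_blocks * block].reshape(n_blocks, block)
    msq = np.mean(x ** 2, axis=1)
    levels = 10.0 * np.log10(np.maximum(msq, 1e-30) / P_REF ** 2)
    return LevelSeries(start_time=0.0, step=step, levels=levels,
                       weighting=weighting, metric="Leq")


def render_slm_series(
    song_waveform: np.ndarray,
    noise_waveform: np.ndarray,
    source_sel_1m: float,
    distance: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    song_onset: float = 12.0,
    step: float = 0.1,
    band_range: tuple[float, float] = DEFAULT_BAND_RANGE,
    song_id: str = "song",
    bird_id: str = "bird",
    recording_id: str = "rec",
) -> RenderedRecording:
    """Render a virtual field recording as the sound-level meter saw it.

    The song is scaled so its SEL at 1 m equals ``source_sel_1m``,
    attenuated by spherical spreading (``1/distance`` in pressure), and
    mixed into the noise bed starting at ``song_onset``.  The mixture is
    band-filtered (zero-phase 4th-order Butterworth per 1/3-octave band)
    and integrated into 100-ms per-band Leq series; the broadband
    A-weighted series is formed by A-weighted energetic summation of the
    band series.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    song = np.asarray(song_waveform, dtype=float)
    noise = np.asarray(noise_waveform, dtype=float)
    current_sel = waveform_sel(song, sample_rate)
    song_scaled = song * 10.0 ** ((source_sel_1m - current_sel) / 20.0) / distance

    onset_idx = int(round(song_onset * sample_rate))
    if onset_idx + song.size > noise.size:
        raise ValueError("noise bed too short for the requested song placement")
    mixture = noise.copy()
    mixture[onset_idx:onset_idx + song.size] += song_scaled
    if np.max(np.abs(mixture)) > 1.0:
        raise ValueError("mixture clips the representable range")

    bands = third_octave_bands(*band_range)
    series = []
    for b, sos in zip(bands, _band_filters(bands, sample_rate)):
        filtered = sosfiltfilt(sos, mixture)
        series.append(_level_series_from_wave(filtered, sample_rate, step, "Z"))
    band_series = BandLevelSeries(list(bands), series)

    # broadband LAeq by A-weighted band summation
    weights = np.array([a_weight_correction(b.center) for b in bands])
    stacked = np.stack([s.levels for s in series])  # (n_bands, n_blocks)
    la = 10.0 * np.log10(np.sum(10.0 ** ((stacked + weights[:, None]) / 10.0), axis=0))
    broadband = LevelSeries(start_time=0.0, step=step, levels=la,
                            weighting="A", metric="Leq")

    recording = SlmRecording(
        recording_id=recording_id,
        bird_id=bird_id,
        broadband=broadband,
        bands=band_series,
        distance=distance,
    )
    duration = song.size / sample_rate
    song_record = SongRecord(
        song_id=song_id,
        recording_id=recording_id,
        bird_id=bird_id,
        onset=song_onset,
        offset=song_onset + duration,
        distance=distance,
    )
    # noise window immediately before the song, as long as available (<= 15 s)
    ns_start = max(song_onset - 15.0, 0.0)
    noise_segment = NoiseSegment(song_id=song_id, start=ns_start, end=song_onset)
    truth = {
        "source_sel_1m": float(source_sel_1m),
        "distance": float(distance),
        "song_onset": float(song_onset),
        "song_duration": float(duration),
    }
    return RenderedRecording(
        recording=recording,
        song=song_record,
        noise_segment=noise_segment,
        mixture=mixture,
        sample_rate=int(sample_rate),
        truth=truth,
    )


def render_recovery_case(
    rng: np.random.Generator,
    source_sel_1m: float,
    distance: float,
    min_freq: float = 4000.0,
    duration: float = 2.0,
    band_snr_db: float = 24.0,
    noise_duration: float = 30.0,
) -> RenderedRecording:
    """Render one randomized amplitude-recovery case.

    The noise-floor spectrum is placed ``band_snr_db`` below the song's
    received total band level, which keeps even the quietest song band
    (the whistle, ~12 dB below the total) at least ~10 dB above the
    background so every song band survives subtraction cleanly.
    """
    song = synth_song_waveform(min_freq, duration=duration)
    received = source_sel_1m - 20.0 * np.log10(distance) - 10.0 * np.log10(duration)
    floor_db = received - band_snr_db
    floor = {b.center: floor_db for b in third_octave_bands(*DEFAULT_BAND_RANGE)}
    noise = synth_noise_waveform(floor, duration=noise_duration, rng=rng)
    return render_slm_series(
        song, noise, source_sel_1m=source_sel_1m, distance=distance
    )


def load_male_sampling() -> pd.DataFrame:
    """Per-male song counts for the two analyses (packaged fixture).

    Columns: site, location, bird, n_minfreq, n_amplitude.  Used both as
    study bookkeeping and as the skewed per-bird sampling distribution the
    simulator draws from.
    """
    with resources.files("songnoise.data").joinpath("male_sampling.csv").open() as fh:
        return pd.read_csv(fh)


def simulate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a whole study: noise, amplitude, and min-freq tables.

    Returns (noise_table, amplitude_table, minfreq_table, ground_truth),
    all keyed by ``song_id``/``bird_id``.  Per-song amplitude follows the
    quadratic generating rule exactly before bird and residual noise is
    added; minimum frequency follows the per-bird model with an optional
    linear noise effect (zero by default -- the null world for the
    min-freq analysis).
    """
    rng = np.random.default_rng(config.seed)
    if config.songs_per_bird is not None:
        counts = list(config.songs_per_bird)
        if len(counts) != config.n_birds:
            raise ValueError("songs_per_bird length must equal n_birds")
    else:
        # field-like right-skewed per-bird counts (range ~1-16)
        pool = load_male_sampling()["n_minfreq"].to_numpy()
        counts = [int(rng.choice(pool)) for _ in range(config.n_birds)]

    bird_ids = [f"bird{i + 1:02d}" for i in range(config.n_birds)]
    bird_intercepts = rng.normal(0.0, config.bird_intercept_sd, config.n_birds)
    bird_minfreq_means = rng.normal(
        config.minfreq_mean, config.minfreq_between_sd, config.n_birds
    )

    rows_noise, rows_amp, rows_mf, rows_truth = [], [], [], []
    song_counter = 0
    for i, bird in enumerate(bird_ids):
        territory = rng.uniform(*config.noise_range)
        for _ in range(counts[i]):
            song_counter += 1
            sid = f"song{song_counter:04d}"
            inst = rng.uniform(*config.noise_range)
            # bout background sits below the instantaneous level (L90 vs Leq)
            bout = inst - rng.uniform(0.0, 6.0)
            dist = rng.uniform(*config.distance_range)
            mean_amp = (
                config.beta0
                + config.beta_noise * inst
                + config.beta_noise2 * inst ** 2
                + config.beta_distance * dist
            )
            amp = mean_amp + bird_intercepts[i] + rng.normal(0.0, config.residual_sd)
            mf_mean = (
                bird_minfreq_means[i] + config.minfreq_noise_effect * (inst - 42.0)
            )
            mf = mf_mean + rng.normal(0.0, config.minfreq_within_sd)
            rows_noise.append(
                dict(song_id=sid, bird_id=bird, instantaneous=inst,
                     bout_background=bout, territory=territory)
            )
            rows_amp.append(
                dict(song_id=sid, bird_id=bird, song_amplitude=amp,
                     distance=dist, instantaneous=inst,
                     bout_background=bout, territory=territory)
            )
            rows_mf.append(
                dict(song_id=sid, bird_id=bird, min_freq=mf,
                     instantaneous=inst, bout_background=bout,
                     territory=territory)
            )
            rows_truth.append(
                dict(song_id=sid, bird_id=bird, mean_amplitude=mean_amp,
                     bird_intercept=bird_intercepts[i], true_minfreq_mean=mf_mean)
            )

    truth = GroundTruth(
        coefficients=dict(
            beta0=config.beta0,
            beta_noise=config.beta_noise,
            beta_noise2=config.beta_noise2,
            beta_distance=config.beta_distance,
            bird_intercept_sd=config.bird_intercept_sd,
            residual_sd=config.residual_sd,
            minfreq_noise_effect=config.minfreq_noise_effect,
        ),
        per_song=pd.DataFrame(rows_truth),
    )
    return (
        pd.DataFrame(rows_noise),
        pd.DataFrame(rows_amp),
        pd.DataFrame(rows_mf),
        truth,
    )
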