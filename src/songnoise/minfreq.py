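"""Song minimum frequency from spectrograms at a relative threshold.

The minimum frequency of a song is the lowest frequency at which the
spectrum still holds appreciable energy, measured at a stated threshold
below the peak-amplitude frequency (-36 dB here).  The spectrogram uses a
256-point transform with non-overlapping frames, giving a frequency
resolution of ~97.7 Hz and a time resolution of ~10.2 ms at a 25-kHz
sampling rate.

The threshold is applied to the time-averaged power spectrum by default
(robust to frame-level dropouts); a maximum-envelope variant is available
via ``method="max"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "Spectrogram",
    "MinFreqResult",
    "compute_spectrogram",
    "minimum_frequency",
    "DEFAULT_THRESHOLD_DB",
    "DEFAULT_LOW_FREQ_BOUND",
]

DEFAULT_THRESHOLD_DB = -36.0
#: analysis floor (Hz) excluding low-frequency rumble
DEFAULT_LOW_FREQ_BOUND = 500.0


@dataclass
class Spectrogram:
    """Magnitude-squared short-time spectrum of a waveform."""

    frequencies: np.ndarray  # bin centres, Hz
    times: np.ndarray  # frame times, s
    power: np.ndarray  # (n_bins, n_frames), linear power, >= 0
    window_size: int
    sample_rate: float

    @property
    def frequency_resolution(self) -> float:
        return self.sample_rate / self.window_size


@dataclass
class MinFreqResult:
    """Minimum and peak frequency of one song at a relative threshold."""

    song_id: str
    min_freq: float
    peak_freq: float
    threshold_db: float = DEFAULT_THRESHOLD_DB

    def __post_init__(self) -> None:
        if self.min_freq > self.peak_freq:
            raise ValueError("min_freq cannot exceed peak_freq")


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    window_size: int = 256,
    overlap: float = 0.0,
) -> Spectrogram:
    """Short-time power spectrum with a Hann window.

    ``overlap`` is the fractional frame overlap; the default 0 gives
    non-overlapping frames (hop = window size), matching a 10.2-ms time
    resolution for 256 samples at ~25 kHz.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if waveform.size < window_size:
        raise ValueError(
            f"waveform ({waveform.size} samples) shorter than the "
            f"{window_size}-point analysis window"
        )
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    hop = max(int(round(window_size * (1.0 - overlap))), 1)
    win = get_window("hann", window_size, fftbins=True)
    # frames lie fully inside the waveform; trailing partial frame discarded
    frames = np.lib.stride_tricks.sliding_window_view(waveform, window_size)[::hop]
    z = np.fft.rfft(frames * win, axis=1)
    power = (np.abs(z) ** 2).T  # (n_bins, n_frames)
    times = (np.arange(frames.shape[0]) * hop + window_size / 2) / sample_rate
    freqs = np.fft.rfftfreq(window_size, d=1.0 / sample_rate)
    return Spectrogram(
        frequencies=freqs,
        times=times,
        power=power,
        window_size=window_size,
        sample_rate=float(sample_rate),
    )


def minimum_frequency(
    spec: Spectrogram,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    low_freq_bound: float = DEFAULT_LOW_FREQ_BOUND,
    song_id: str = "",
    method: str = "mean",
) -> MinFreqResult:
    """Lowest frequency whose power reaches ``threshold_db`` re the peak.

    The spectrogram is collapsed over time (``method="mean"``: average
    spectrum; ``method="max"``: per-bin maximum envelope), restricted to
    frequencies at or above ``low_freq_bound``.  The peak frequency is the
    bin of maximum collapsed power; the minimum frequency is the lowest
    bin, scanning upward from the analysis floor, whose power is within
    ``threshold_db`` of the peak.  The threshold is relative, so the
    result is invariant to overall gain.
    """
    if method == "mean":
        collapsed = spec.power.mean(axis=1)
    elif method == "max":
        collapsed = spec.power.max(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    in_range = spec.frequencies >= low_freq_bound
    if not in_range.any():
        raise ValueError("no frequency bins above the analysis floor")
    freqs = spec.frequencies[in_range]
    pw = collapsed[in_range]
    peak_power = pw.max()
    if peak_power <= 0.0:
        raise ValueError("silent spectrogram: no peak to reference the threshold to")
    peak_freq = float(freqs[int(np.argmax(pw))])
    thresh = peak_power * 10.0 ** (threshold_db / 10.0)
    above = np.nonzero(pw >= thresh)[0]
    min_freq = float(freqs[above[0]])
    return MinFreqResult(
        song_id=song_id,
        min_freq=min_freq,
        peak_freq=peak_freq,
        threshold_db=threshold_db,
    )
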