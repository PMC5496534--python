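"""Decibel/energy arithmetic, frequency weighting, and 1/3-octave band tools.

Every downstream stage (noise metrics, song-amplitude estimation, the
synthetic renderer) builds on the primitives here: energetic averaging of
sound pressure levels, exceedance statistics (L90), sound exposure levels
(SEL), energy-domain subtraction of background noise, A-weighting, and the
nominal 1/3-octave band grid.

All levels are sound pressure levels in dB re 20 uPa.  Internally every
operation converts to linear power units (``10**(L/10)``), does its
arithmetic there, and converts back to dB only at the boundary, so repeated
operations do not accumulate log/exp rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "DecibelLevel",
    "LevelSeries",
    "ThirdOctaveBand",
    "BandLevelSeries",
    "NoiseDominatedError",
    "P_REF",
    "DEFAULT_SNR_MARGIN_DB",
    "energetic_mean",
    "exceedance_level",
    "sel_from_series",
    "energy_subtract",
    "energy_sum",
    "a_weight_correction",
    "third_octave_bands",
    "nominal_center",
    "spherical_spreading_correction",
]

#: reference sound pressure, 20 micropascal
P_REF = 20e-6

#: minimum margin (dB) by which a total level must exceed the background
#: before energy subtraction is considered valid
DEFAULT_SNR_MARGIN_DB = 0.5

# Nominal 1/3-octave band centres (IEC 61260 preferred values), 25 Hz - 20 kHz.
_NOMINAL_CENTERS = (
    25.0, 31.5, 40.0, 50.0, 63.0, 80.0, 100.0, 125.0, 160.0, 200.0, 250.0,
    315.0, 400.0, 500.0, 630.0, 800.0, 1000.0, 1250.0, 1600.0, 2000.0,
    2500.0, 3150.0, 4000.0, 5000.0, 6300.0, 8000.0, 10000.0, 12500.0,
    16000.0, 20000.0,
)


class NoiseDominatedError(ValueError):
    """Raised when a band's total level is not separable from background noise."""


@dataclass(frozen=True)
class DecibelLevel:
    """A sound pressure level with explicit weighting and metric tags.

    Conversions between weightings or metrics are always explicit; no
    operation in this package silently reinterprets the tags.
    """

    value: float
    weighting: str = "Z"  # {"A", "Z"}
    metric: str = "instant"  # {"instant", "Leq", "Lx", "SEL"}

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"level must be finite, got {self.value!r}")
        if self.weighting not in ("A", "Z"):
            raise ValueError(f"weighting must be 'A' or 'Z', got {self.weighting!r}")
        if self.metric not in ("instant", "Leq", "Lx", "SEL"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class LevelSeries:
    """Time series of dB samples at a fixed step sharing one weighting/metric.

    Parameters
    ----------
    start_time : float
        Seconds from the recording start to the first sample.
    step : float
        Sampling interval in seconds (0.1 s for sound-level-meter data).
    levels : ndarray
        Sound pressure levels in dB.
    weighting, metric : str
        Tags shared by every sample in the series.
    """

    start_time: float
    step: float
    levels: np.ndarray
    weighting: str = "A"
    metric: str = "Leq"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.levels.size == 0:
            raise ValueError("level series must be non-empty")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("level series contains non-finite values")

    @property
    def duration(self) -> float:
        return self.levels.size * self.step

    @property
    def times(self) -> np.ndarray:
        """Sample start times (seconds from recording start)."""
        return self.start_time + self.step * np.arange(self.levels.size)

    def slice(self, t0: float, t1: float) -> "LevelSeries":
        """Samples whose start times fall in the half-open window [t0, t1)."""
        t = self.times
        mask = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        if not mask.any():
            raise ValueError(f"no samples in window [{t0}, {t1})")
        return LevelSeries(
            start_time=float(t[mask][0]),
            step=self.step,
            levels=self.levels[mask],
            weighting=self.weighting,
            metric=self.metric,
        )


@dataclass(frozen=True)
class ThirdOctaveBand:
    """One nominal 1/3-octave band: IEC centre label, base-2 computed edges."""

    center: float
    lower_edge: float = field(default=0.0)
    upper_edge: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("band center must be positive")
        if self.lower_edge == 0.0:
            object.__setattr__(self, "lower_edge", self.center * 2 ** (-1 / 6))
        if self.upper_edge == 0.0:
            object.__setattr__(self, "upper_edge", self.center * 2 ** (1 / 6))
        if not (self.lower_edge < self.center < self.upper_edge):
            raise ValueError("band edges must straddle the center")

    @property
    def width(self) -> float:
        return self.upper_edge - self.lower_edge


@dataclass
class BandLevelSeries:
    """Per-band level series over an ascending list of 1/3-octave bands.

    All per-band series share start_time, step, and length.
    """

    bands: list[ThirdOctaveBand]
    series: list[LevelSeries]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.series):
            raise ValueError("one series per band required")
        if not self.bands:
            raise ValueError("band list must be non-empty")
        centers = [b.center for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("bands must be strictly ascending by center")
        s0 = self.series[0]
        for s in self.series[1:]:
            if s.levels.size != s0.levels.size or s.step != s0.step or s.start_time != s0.start_time:
                raise ValueError("all band series must share start_time, step, and length")

    @property
    def step(self) -> float:
        return self.series[0].step

    @property
    def start_time(self) -> float:
        return self.series[0].start_time

    def slice(self, t0: float, t1: float) -> "BandLevelSeries":
        return BandLevelSeries(self.bands, [s.slice(t0, t1) for s in self.series])

    def band(self, center: float) -> LevelSeries:
        for b, s in zip(self.bands, self.series):
            if b.center == center:
                return s
        raise KeyError(f"no band with center {center}")


def _as_levels(levels: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(levels) if not isinstance(levels, np.ndarray) else levels, dtype=float)
    if arr.size == 0:
        raise ValueError("no samples in window")
    if not np.all(np.isfinite(arr)):
        raise ValueError("levels contain non-finite values")
    return arr


def energetic_mean(levels: Iterable[float]) -> float:
    """Equivalent continuous level (Leq) of a set of dB samples.

    The constant level containing the same acoustic energy as the varying
    samples: ``10*log10(mean(10**(L/10)))``.
    """
    arr = _as_levels(levels)
    return float(10.0 * np.log10(np.mean(10.0 ** (arr / 10.0))))


def exceedance_level(levels: Iterable[float], percent: float) -> float:
    """Level exceeded `percent` percent of the time (Lx statistic).

    L90 (percent=90) is the 10th percentile of the level distribution and is
    the standard background-noise statistic.  Linear interpolation between
    the closest order statistics.
    """
    if not (0.0 < percent < 100.0):
        raise ValueError(f"percent must be in (0, 100), got {percent}")
    arr = _as_levels(levels)
    return float(np.percentile(arr, 100.0 - percent, method="linear"))


def sel_from_series(series: LevelSeries) -> float:
    """Sound exposure level of a level series, normalised to t_ref = 1 s.

    ``10*log10(sum_t 10**(L_t/10) * step / 1 s)`` -- the total energy of the
    event compressed into one second.
    """
    energy = np.sum(10.0 ** (series.levels / 10.0)) * series.step
    return float(10.0 * np.log10(energy))


def energy_subtract(total: float, noise: float,
                    min_snr_margin: float = DEFAULT_SNR_MARGIN_DB) -> float:
    """Remove background-noise energy from a total level, in the energy domain.

    Returns ``10*log10(10**(total/10) - 10**(noise/10))``.

    Raises
    ------
    NoiseDominatedError
        If ``total <= noise + min_snr_margin`` -- the band is dominated by
        noise and the caller should drop it.
    """
    if noise == -np.inf:
        return float(total)
    if total <= noise + min_snr_margin:
        raise NoiseDominatedError(
            f"band dominated by noise: total {total:.2f} dB <= "
            f"noise {noise:.2f} dB + margin {min_snr_margin} dB"
        )
    return float(10.0 * np.log10(10.0 ** (total / 10.0) - 10.0 ** (noise / 10.0)))


def energy_sum(levels: Iterable[float]) -> float:
    """Energetic (incoherent) sum of dB levels: ``10*log10(sum 10**(L/10))``."""
    arr = _as_levels(levels)
    return float(10.0 * np.log10(np.sum(10.0 ** (arr / 10.0))))


def a_weight_correction(f: float | np.ndarray) -> float | np.ndarray:
    """Standard A-weighting gain R_A(f) in dB, 0 dB at 1 kHz.

    The closed-form IEC 61672 response; approximates human (and roughly
    avian) hearing sensitivity.  Applied as a per-frequency gain at band
    centres when combining Z-weighted band levels into a broadband
    A-weighted level.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    f2 = f ** 2
    num = 12194.0 ** 2 * f2 ** 2
    den = (
        (f2 + 20.6 ** 2)
        * np.sqrt((f2 + 107.7 ** 2) * (f2 + 737.9 ** 2))
        * (f2 + 12194.0 ** 2)
    )
    ra = num / den
    # normalise so the gain is exactly 0 dB at 1 kHz
    fk = 1000.0 ** 2
    ra_1k = (12194.0 ** 2 * fk ** 2) / (
        (fk + 20.6 ** 2)
        * np.sqrt((fk + 107.7 ** 2) * (fk + 737.9 ** 2))
        * (fk + 12194.0 ** 2)
    )
    out = 20.0 * np.log10(ra / ra_1k)
    return float(out) if out.ndim == 0 else out


def nominal_center(f: float, tolerance: float = 0.06) -> float:
    """Snap a frequency to the nearest nominal 1/3-octave centre label.

    Raises if no nominal centre is within the relative tolerance (default
    6%, i.e. well inside half a band).
    """
    centers = np.asarray(_NOMINAL_CENTERS)
    idx = int(np.argmin(np.abs(np.log(centers) - np.log(f))))
    c = float(centers[idx])
    if abs(f - c) / c > tolerance:
        raise ValueError(f"{f} Hz is not near a nominal 1/3-octave centre")
    return c


def third_octave_bands(f_low: float, f_high: float) -> list[ThirdOctaveBand]:
    """Nominal 1/3-octave bands whose centres fall in [f_low, f_high].

    Centres are the IEC nominal labels (matching how sound-level-meter
    exports name their band columns); edges are computed base-2 as
    ``center * 2**(+/-1/6)``.
    """
    if f_low <= 0:
        raise ValueError("f_low must be positive")
    if f_low > f_high:
        raise ValueError(f"inverted band range: {f_low} > {f_high}")
    centers = [c for c in _NOMINAL_CENTERS if f_low <= c <= f_high]
    if not centers:
        raise ValueError(f"no nominal 1/3-octave centres in [{f_low}, {f_high}]")
    return [ThirdOctaveBand(center=c) for c in centers]


def spherical_spreading_correction(level_at_d: float, distance: float) -> float:
    """Back-calculate the level at 1 m assuming spherical spreading.

    A point source loses 6 dB per doubling of distance, so the level at the
    1-m reference is ``level_at_d + 20*log10(distance / 1 m)``.  No excess
    attenuation term is applied.
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    return float(level_at_d + 20.0 * np.log10(distance))
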