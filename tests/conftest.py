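"""Shared fixtures: small synthetic recordings and tables."""

from __future__ import annotations

import numpy as np
import pytest

from songnoise import (
    BandLevelSeries,
    LevelSeries,
    SimConfig,
    SlmRecording,
    third_octave_bands,
    simulate_study,
)

BAND_CENTERS = (2000.0, 2500.0, 3150.0, 4000.0, 5000.0, 6300.0, 8000.0)


def make_recording(
    duration: float = 60.0,
    step: float = 0.1,
    broadband_level: float = 45.0,
    band_levels: dict[float, float] | None = None,
    distance: float = 8.0,
    wind_speed: float = 0.5,
    recording_id: str = "rec1",
    bird_id: str = "bird1",
) -> SlmRecording:
    """Constant-level recording with the seven 2-8 kHz bands."""
    n = int(round(duration / step))
    bands = third_octave_bands(2000, 8000)
    band_levels = band_levels or {b.center: broadband_level - 5.0 for b in bands}
    broadband = LevelSeries(0.0, step, np.full(n, broadband_level), "A", "Leq")
    series = [
        LevelSeries(0.0, step, np.full(n, band_levels[b.center]), "Z", "Leq")
        for b in bands
    ]
    return SlmRecording(
        recording_id=recording_id,
        bird_id=bird_id,
        broadband=broadband,
        bands=BandLevelSeries(list(bands), series),
        distance=distance,
        wind_speed=wind_speed,
    )


@pytest.fixture
def flat_recording() -> SlmRecording:
    return make_recording()


@pytest.fixture
def sim_tables():
    """Small simulated study (8 birds, fixed counts) with ground truth."""
    cfg = SimConfig(seed=42, n_birds=8, songs_per_bird=[4] * 8)
    return simulate_study(cfg)
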