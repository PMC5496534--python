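"""SLM CSV round-trips, WAV reading, and segment carving."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from songnoise import (
    SongRecord,
    find_noise_segment,
    read_slm_csv,
    read_song_table,
    read_song_wav,
    validate_recording,
    write_slm_csv,
)
from songnoise.ingest import NoiseSegment, SlmCsvDialect

from conftest import make_recording


def _write_csv(tmp_path, n_rows=100, step=0.1, drop_band=None):
    rng = np.random.default_rng(3)
    data = {
        "time_s": np.arange(n_rows) * step,
        "laeq_db": rng.uniform(40, 50, n_rows),
    }
    for c in (2000, 2500, 3150, 4000, 5000, 6300, 8000):
        if c != drop_band:
            data[f"band_{c}"] = rng.uniform(30, 45, n_rows)
    path = tmp_path / "slm.csv"
    pd.DataFrame(data).to_csv(path, index=False)
    return path


class TestSlmCsv:
    def test_read_fixture(self, tmp_path):
        rec = read_slm_csv(_write_csv(tmp_path))
        assert rec.duration == pytest.approx(10.0)
        assert len(rec.bands.bands) == 7

    def test_missing_band_column_errors(self, tmp_path):
        with pytest.raises(ValueError, match="missing band columns"):
            read_slm_csv(_write_csv(tmp_path, drop_band=4000))

    def test_nonstandard_step_accepted(self, tmp_path):
        rec = read_slm_csv(_write_csv(tmp_path, step=0.2))
        assert rec.broadband.step == pytest.approx(0.2)

    def test_nonuniform_timestamps_error(self, tmp_path):
        path = _write_csv(tmp_path)
        df = pd.read_csv(path)
        df.loc[50, "time_s"] += 0.05
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-uniform"):
            read_slm_csv(path)

    def test_roundtrip_value_identical(self, tmp_path):
        rec = read_slm_csv(_write_csv(tmp_path))
        out = tmp_path / "roundtrip.csv"
        write_slm_csv(rec, out)
        rec2 = read_slm_csv(out)
        np.testing.assert_allclose(
            rec.broadband.levels, rec2.broadband.levels, atol=0.01
        )
        for s1, s2 in zip(rec.bands.series, rec2.bands.series):
            np.testing.assert_allclose(s1.levels, s2.levels, atol=0.01)

    def test_vendor_dialect_mapping(self, tmp_path):
        rng = np.random.default_rng(0)
        data = {"Time (s)": np.arange(50) * 0.1, "LAeq": rng.uniform(40, 50, 50)}
        for c in (2000, 2500, 3150, 4000, 5000, 6300, 8000):
            data[f"1/3 LZeq {c}Hz"] = rng.uniform(30, 45, 50)
        path = tmp_path / "vendor.csv"
        pd.DataFrame(data).to_csv(path, index=False)
        dialect = SlmCsvDialect(
            time_column="Time (s)",
            broadband_column="LAeq",
            band_pattern=r"1/3 LZeq (\d+)Hz",
        )
        rec = read_slm_csv(path, dialect=dialect)
        assert [b.center for b in rec.bands.bands] == [2000, 2500, 3150, 4000, 5000, 6300, 8000]


class TestWav:
    def test_synthetic_tone_sample_count(self, tmp_path):
        path = tmp_path / "tone.wav"
        t = np.arange(50000) / 25000
        wavfile.write(path, 25000, (0.5 * np.sin(2 * np.pi * 4000 * t)).astype(np.float32))
        wave, rate = read_song_wav(path)
        assert wave.size == 50000 and rate == 25000
        assert np.max(np.abs(wave)) <= 1.0

    def test_int16_normalised(self, tmp_path):
        path = tmp_path / "pcm.wav"
        wavfile.write(path, 25000, (np.ones(1000) * 16384).astype(np.int16))
        wave, _ = read_song_wav(path)
        assert np.max(wave) == pytest.approx(0.5, rel=1e-3)

    def test_stereo_takes_first_channel(self, tmp_path):
        path = tmp_path / "stereo.wav"
        data = np.stack([np.ones(1000), -np.ones(1000)], axis=1).astype(np.float32)
        wavfile.write(path, 25000, data)
        with pytest.warns(UserWarning, match="first channel"):
            wave, _ = read_song_wav(path)
        assert np.all(wave == 1.0)

    def test_zero_length_errors(self, tmp_path):
        path = tmp_path / "empty.wav"
        wavfile.write(path, 25000, np.zeros(0, dtype=np.float32))
        with pytest.raises(ValueError):
            read_song_wav(path)


class TestSongRecord:
    def test_onset_before_offset(self):
        with pytest.raises(ValueError):
            SongRecord("s1", "r1", "b1", onset=5.0, offset=4.0)

    def test_duration_sanity_bound(self):
        with pytest.raises(ValueError, match="10 s"):
            SongRecord("s1", "r1", "b1", onset=0.0, offset=12.0)

    def test_song_table_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "song_id": ["s1", "s2"],
                "recording_id": ["r1", "r1"],
                "bird_id": ["b1", "b1"],
                "onset_s": [10.0, 30.0],
                "offset_s": [12.0, 32.0],
                "measurable": [True, False],
                "reasons": ["", "head_movement;not_facing"],
                "distance_m": [8.0, 8.0],
            }
        )
        path = tmp_path / "songs.csv"
        df.to_csv(path, index=False)
        songs = read_song_table(path)
        assert songs[0].measurable_amplitude
        assert songs[1].unmeasurable_reasons == ("head_movement", "not_facing")


class TestFindNoiseSegment:
    def test_long_silence_gives_15s_abutting(self):
        rec = make_recording(duration=60.0)
        song = SongRecord("s1", "rec1", "b1", onset=30.0, offset=32.0)
        seg = find_noise_segment(rec, song, [song])
        assert seg.duration == pytest.approx(15.0)
        assert seg.end == pytest.approx(30.0)  # abuts the song

    def test_short_gap_taken_when_closer(self):
        rec = make_recording(duration=60.0)
        focal = SongRecord("s1", "rec1", "b1", onset=2.0, offset=4.0)
        nxt = SongRecord("s2", "rec1", "b1", onset=8.0, offset=10.0)
        seg = find_noise_segment(rec, focal, [focal, nxt])
        # only 4 s of silence before the next song; the abutting 4-s window
        # wins over the longer but more distant gap after that song
        assert seg.start == pytest.approx(4.0)
        assert seg.duration == pytest.approx(4.0)

    def test_wall_to_wall_songs_error(self):
        rec = make_recording(duration=10.0)
        songs = [
            SongRecord(f"s{i}", "rec1", "b1", onset=2.0 * i, offset=2.0 * i + 2.0)
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="no song-free window"):
            find_noise_segment(rec, songs[2], songs)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=0, max_value=110), min_size=1, max_size=8), st.integers(0, 7))
    def test_never_overlaps_any_song(self, onsets, focal_idx):
        """Whatever the song layout, the chosen window is song-free."""
        rec = make_recording(duration=120.0)
        songs = [
            SongRecord(f"s{i}", "rec1", "b1", onset=o, offset=o + 2.0)
            for i, o in enumerate(sorted(onsets))
        ]
        focal = songs[min(focal_idx, len(songs) - 1)]
        try:
            seg = find_noise_segment(rec, focal, songs)
        except ValueError:
            return  # layouts without a 3-s gap legitimately fail
        for s in songs:
            assert seg.end <= s.onset + 1e-6 or seg.start >= s.offset - 1e-6


class TestValidateRecording:
    def test_clean_recording_unflagged(self):
        assert validate_recording(make_recording()) == []

    def test_wind_flag(self):
        flags = validate_recording(make_recording(wind_speed=1.5))
        assert any("wind" in f for f in flags)

    def test_missing_distance_flag(self):
        flags = validate_recording(make_recording(distance=None))
        assert any("distance" in f for f in flags)


class TestNoiseSegmentInvariants:
    @pytest.mark.parametrize("dur", [2.0, 16.0])
    def test_duration_bounds(self, dur):
        with pytest.raises(ValueError):
            NoiseSegment("s1", 0.0, dur)
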