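"""Dual-range fusion, validation and the file dialects."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from trailgait.sensor_io import (G, LOW_G_LSB, AxisMap, ImuRecording,
                                 SensorLoadError, fuse_accelerometers,
                                 read_gpx, read_imu_csv, read_pressure_csv,
                                 write_gpx, write_imu_csv,
                                 write_pressure_csv)


def _rec(accel_low, accel_high, t=None, t_high=None):
    n, m = len(accel_low), len(accel_high)
    t = np.arange(n) / 1125.0 if t is None else t
    t_high = np.arange(m) / 1600.0 if t_high is None else t_high
    return ImuRecording(t=t, accel_low=np.asarray(accel_low, float),
                        t_high=t_high,
                        accel_high=np.asarray(accel_high, float),
                        gyro=np.zeros((n, 3)))


class TestFusion:
    def test_saturated_sample_takes_interpolated_high_g(self):
        low = np.zeros((5, 3))
        low[2, 1] = 16.0 * G                      # railed vertical sample
        high = np.zeros((8, 3))
        high[:, 1] = 34.2 * G                     # constant high-g reading
        fused = fuse_accelerometers(_rec(low, high))
        assert fused.accel[2, 1] == pytest.approx(34.2 * G)
        assert fused.substituted[2, 1]
        # neighbours below the rail stay low-g
        assert fused.accel[1, 1] == 0.0 and not fused.substituted[1, 1]

    def test_unsaturated_passes_low_g_through_bitwise(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0.0, 0.5 * G, (200, 3))
        high = rng.normal(0.0, 0.5 * G, (300, 3))
        fused = fuse_accelerometers(_rec(low, high))
        assert not fused.substituted.any()
        assert np.array_equal(fused.accel, low)

    def test_substitution_count_matches_brute_force_scan(self, processed_lap):
        """On a lap with clipping episodes the mask equals a linear scan."""
        imu = processed_lap["imu"]
        fused = processed_lap["fused"]
        thresh = 16.0 * G - LOW_G_LSB / 2
        brute = np.abs(imu.accel_low) >= thresh     # sample-by-sample scan
        assert fused.substituted.sum() == brute.sum()
        assert fused.substituted.sum() > 0          # clipping did occur
        assert np.array_equal(fused.substituted, brute)

    def test_fusion_idempotent_and_bounded(self, processed_lap):
        fused = processed_lap["fused"]
        assert np.all(np.abs(fused.accel) <= 200.0 * G + 1e-9)
        refused = fuse_accelerometers(ImuRecording(
            t=fused.t, accel_low=np.clip(fused.accel, -16 * G, 16 * G),
            t_high=processed_lap["imu"].t_high,
            accel_high=processed_lap["imu"].accel_high,
            gyro=processed_lap["imu"].gyro))
        assert np.allclose(refused.accel[fused.substituted],
                           fused.accel[fused.substituted])

    def test_no_temporal_overlap_is_an_error(self):
        rec = _rec(np.zeros((5, 3)), np.zeros((5, 3)),
                   t_high=np.arange(5) / 1600.0 + 100.0)
        with pytest.raises(SensorLoadError, match="overlap"):
            fuse_accelerometers(rec)

    @given(level=st.floats(0.0, 15.0))
    def test_below_threshold_never_substituted(self, level):
        low = np.full((4, 3), level * G * 0.999)
        fused = fuse_accelerometers(_rec(low, np.zeros((6, 3))))
        assert not fused.substituted.any()


class TestValidation:
    def test_validate_passes_on_synthetic_lap(self, lap_bundle):
        lap_bundle["imu"].validate()
        lap_bundle["pressure"].validate()
        lap_bundle["gps"].validate()

    def test_rate_mismatch_rejected(self):
        n = 1000
        rec = _rec(np.zeros((n, 3)), np.zeros((n, 3)),
                   t=np.arange(n) / 900.0)  # 900 Hz instead of 1125
        with pytest.raises(SensorLoadError, match="rate"):
            rec.validate()

    def test_eversion_sign_by_side(self):
        assert AxisMap(side="right").eversion_sign == 1.0
        assert AxisMap(side="left").eversion_sign == -1.0
        with pytest.raises(ValueError):
            _ = AxisMap(side="dorsal").eversion_sign


class TestDialects:
    def test_imu_csv_round_trip(self, tmp_path, lap_bundle):
        imu = lap_bundle["imu"]
        write_imu_csv(imu, tmp_path / "m.csv", tmp_path / "h.csv")
        back = read_imu_csv(tmp_path / "m.csv", tmp_path / "h.csv")
        assert np.allclose(back.accel_low, imu.accel_low, atol=1e-4 * G)
        assert np.allclose(back.gyro, imu.gyro, atol=1e-5)
        assert np.allclose(back.t, imu.t, atol=1e-6)

    def test_repeated_timestamp_deduplicated_with_warning(self, tmp_path):
        import pandas as pd
        t = np.arange(100) / 1125.0
        t[50] = t[49]
        df = pd.DataFrame({"t_unix": t, "ax": 0.0, "ay": 0.0, "az": 0.0,
                           "gx": 0.0, "gy": 0.0, "gz": 0.0})
        df.to_csv(tmp_path / "m.csv", index=False)
        df[["t_unix", "ax", "ay", "az"]].to_csv(tmp_path / "h.csv",
                                                index=False)
        with pytest.warns(UserWarning, match="duplicated"):
            rec = read_imu_csv(tmp_path / "m.csv", tmp_path / "h.csv")
        assert len(rec.t) == 99

    def test_shuffled_rows_rejected(self, tmp_path):
        import pandas as pd
        rng = np.random.default_rng(1)
        t = rng.permutation(np.arange(50) / 1125.0)
        df = pd.DataFrame({"t_unix": t, "ax": 0.0, "ay": 0.0, "az": 0.0,
                           "gx": 0.0, "gy": 0.0, "gz": 0.0})
        df.to_csv(tmp_path / "m.csv", index=False)
        df[["t_unix", "ax", "ay", "az"]].to_csv(tmp_path / "h.csv",
                                                index=False)
        with pytest.raises(SensorLoadError, match="non-monotone"):
            read_imu_csv(tmp_path / "m.csv", tmp_path / "h.csv")

    def test_pressure_csv_round_trip(self, tmp_path, lap_bundle):
        rec = lap_bundle["pressure"]
        write_pressure_csv(rec, tmp_path / "p.csv")
        back = read_pressure_csv(tmp_path / "p.csv")
        assert back.grid_shape == rec.grid_shape
        assert np.allclose(back.frames, rec.frames, atol=0.01)

    def test_gpx_round_trip(self, tmp_path, lap_bundle):
        gps = lap_bundle["gps"]
        write_gpx(gps, tmp_path / "t.gpx")
        back = read_gpx(tmp_path / "t.gpx")
        assert np.allclose(back.lat, gps.lat, atol=1e-7)
        assert np.allclose(back.lon, gps.lon, atol=1e-7)
        assert np.allclose(back.heart_rate, gps.heart_rate)
        assert np.allclose(back.t, gps.t, atol=1.0)
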