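"""Outlier handling, 6:2:2 splitting, windowing, latency arithmetic."""

import numpy as np
import pytest

from emdtcn.emd import FeatureMatrix
from emdtcn.errors import ConfigurationError, ContractError, InputTooShortError
from emdtcn.preprocess import (
    ColumnScaler,
    WindowSpec,
    correct_outliers,
    detect_outliers,
    latency_ms,
    make_windows,
    split_622,
)
from emdtcn.synth import ArtifactSpec, SyntheticConfig, generate_trajectory, inject_artifacts
from emdtcn.trajectory import Trajectory


def _jaccard(a, b):
    sa, sb = set(), set()
    for s, e in a:
        sa.update(range(s, e))
    for s, e in b:
        sb.update(range(s, e))
    return len(sa & sb) / len(sa | sb) if (sa | sb) else 1.0


@pytest.fixture(scope="module")
def long_traj():
    return generate_trajectory(SyntheticConfig(duration_samples=10_000, seed=0))


class TestDetectOutliers:
    def test_clean_sinusoid_yields_no_flags(self):
        cfg = SyntheticConfig(
            duration_samples=4000, amplitude_drift_sd=0.0, period_jitter_sd=0.0,
            baseline_drift_sd=0.0, noise_sd=0.02, waveform_exponent=1.0, seed=4,
        )
        traj = generate_trajectory(cfg)
        report = detect_outliers(traj, seed=0)
        assert report.flagged_intervals == []

    def test_injected_burst_is_found(self, long_traj):
        corrupted, truth = inject_artifacts(
            long_traj, ArtifactSpec(n_bursts=1, seed=0)
        )
        report = detect_outliers(corrupted, seed=0)
        assert _jaccard(truth, report.flagged_intervals) >= 0.5

    def test_deterministic_under_seed(self, long_traj):
        corrupted, _ = inject_artifacts(long_traj, ArtifactSpec(n_bursts=2, seed=5))
        a = detect_outliers(corrupted, seed=9)
        b = detect_outliers(corrupted, seed=9)
        assert a.flagged_intervals == b.flagged_intervals
        assert np.array_equal(a.score_trace, b.score_trace)

    def test_short_trajectory_rejected(self):
        with pytest.raises(InputTooShortError):
            detect_outliers(Trajectory(np.zeros(100) + np.sin(np.arange(100))), seed=0)


class TestCorrectOutliers:
    def test_empty_flags_is_identity(self, long_traj):
        report = detect_outliers(long_traj, seed=0)
        report.flagged_intervals = []
        fixed = correct_outliers(report)
        assert np.array_equal(fixed.values, long_traj.values)

    def test_burst_recovery_improves_rmse(self, long_traj):
        corrupted, truth = inject_artifacts(
            long_traj, ArtifactSpec(n_bursts=1, seed=0)
        )
        report = detect_outliers(corrupted, seed=0)
        fixed = correct_outliers(report)
        bad = np.zeros(len(long_traj), dtype=bool)
        for s, e in truth:
            bad[s:e] = True
        rmse = lambda a, b: float(np.sqrt(np.mean((a - b) ** 2)))
        before = rmse(corrupted.values[bad], long_traj.values[bad])
        after = rmse(fixed.values[bad], long_traj.values[bad])
        assert after < before
        # unflagged samples are bit-identical
        flag = np.zeros(len(long_traj), dtype=bool)
        for s, e in report.flagged_intervals:
            flag[s:e] = True
        assert np.array_equal(fixed.values[~flag], corrupted.values[~flag])

    def test_conservative_on_clean_trajectory(self, long_traj):
        report = detect_outliers(long_traj, seed=0)
        fixed = correct_outliers(report)
        changed = np.sum(fixed.values != long_traj.values)
        assert changed <= 0.001 * len(long_traj)

    def test_boundary_interval_falls_back_to_fill(self):
        x = np.sin(np.arange(500) * 0.1) * 5
        traj = Trajectory(x)
        report = detect_outliers(traj, seed=0)
        report.flagged_intervals = [(0, 10)]
        fixed = correct_outliers(report)
        assert np.all(np.isfinite(fixed.values))
        assert np.array_equal(fixed.values[10:], x[10:])


class TestSplit622:
    def test_printed_lengths(self):
        spec = split_622(10_000)
        assert spec.train_range == (0, 6000)
        assert spec.valid_range == (6000, 8000)
        assert spec.test_range == (8000, 10_000)

    def test_minimum_length(self):
        spec = split_622(10)
        sizes = [e - s for s, e in spec.as_dict().values()]
        assert sizes == [6, 2, 2]

    @pytest.mark.parametrize("n", [10, 17, 100, 1001, 9999])
    def test_partition_covers_range_disjointly(self, n):
        spec = split_622(n)
        (t0, t1), (v0, v1), (s0, s1) = (
            spec.train_range, spec.valid_range, spec.test_range
        )
        assert t0 == 0 and t1 == v0 and v1 == s0 and s1 == n
        assert abs((t1 - t0) - 0.6 * n) <= 1
        assert abs((v1 - v0) - 0.2 * n) <= 1

    def test_too_short_rejected(self):
        with pytest.raises(InputTooShortError):
            split_622(9)


class TestLatency:
    def test_paper_mapping_at_26hz(self):
        assert latency_ms(13, 26) == 500.0
        assert latency_ms(0, 26) == 0.0
        assert latency_ms(10, 26) == pytest.approx(384.6153846, abs=1e-6)

    def test_invalid_fs(self):
        with pytest.raises(ConfigurationError):
            latency_ms(3, 0)


class TestMakeWindows:
    @pytest.fixture()
    def setup(self):
        n, w = 400, 4
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(columns=rng.standard_normal((n, w)))
        raw = Trajectory(rng.standard_normal(n))
        return fm, raw

    def test_window_count_formula(self, setup):
        fm, raw = setup
        spec = WindowSpec(input_len=50, lead=10, stride=1)
        ds = make_windows(fm, raw, spec, (0, 100))
        assert len(ds) == 41
        # brute-force enumeration oracle
        count = sum(
            1
            for start in range(0, 100)
            if start + 50 - 1 + 10 < 100
        )
        assert len(ds) == count

    def test_single_window_at_boundary(self, setup):
        fm, raw = setup
        spec = WindowSpec(input_len=90, lead=10, stride=1)
        ds = make_windows(fm, raw, spec, (0, 100))
        assert len(ds) == 1

    def test_targets_replay_raw_series(self, setup):
        fm, raw = setup
        spec = WindowSpec(input_len=30, lead=7, stride=3)
        ds = make_windows(fm, raw, spec, (100, 300))
        rng = np.random.default_rng(0)
        for k in rng.integers(0, len(ds), size=20):
            end = ds.end_indices[k]
            assert ds.targets[k] == raw.values[end + 7]
            assert np.array_equal(ds.features[k], fm.columns[end - 29 : end + 1])

    def test_no_leakage_and_partition_isolation(self, setup):
        fm, raw = setup
        spec = WindowSpec(input_len=30, lead=7, stride=1)
        for part in [(0, 240), (240, 320), (320, 400)]:
            ds = make_windows(fm, raw, spec, part)
            for k in range(len(ds)):
                end = ds.end_indices[k]
                # all feature indices strictly precede the target index
                assert end < end + 7
                assert part[0] <= end - 29 and end + 7 < part[1]

    def test_too_short_partition_warns_and_returns_empty(self, setup):
        fm, raw = setup
        spec = WindowSpec(input_len=90, lead=20, stride=1)
        with pytest.warns(UserWarning):
            ds = make_windows(fm, raw, spec, (0, 100))
        assert len(ds) == 0


class TestColumnScaler:
    def test_standardizes_nonconstant_columns(self):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((500, 4)) * [1, 5, 0.1, 2] + [0, 3, -1, 9]
        sc = ColumnScaler().fit(rows)
        z = sc.transform(rows)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-6)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        rows = rng.standard_normal((100, 3)) * 7 + 2
        sc = ColumnScaler().fit(rows)
        back = sc.inverse_transform(sc.transform(rows))
        assert np.allclose(back, rows, rtol=1e-10)

    def test_zero_variance_column_rule(self):
        rows = np.column_stack([np.zeros(50), np.arange(50.0)])
        sc = ColumnScaler().fit(rows)
        z = sc.transform(rows)
        # identically-zero padded column stays identically zero
        assert np.all(z[:, 0] == 0.0)

    def test_serialization_round_trip(self):
        rows = np.random.default_rng(1).standard_normal((50, 3))
        sc = ColumnScaler().fit(rows)
        sc2 = ColumnScaler.from_dict(sc.to_dict())
        assert np.allclose(sc2.transform(rows), sc.transform(rows))


class TestWindowedPersistence:
    def test_npz_round_trip_with_sidecar(self, tmp_path):
        from emdtcn.preprocess import load_windowed, save_windowed

        rng = np.random.default_rng(0)
        fm = FeatureMatrix(columns=rng.standard_normal((300, 3)))
        raw = Trajectory(rng.standard_normal(300))
        spec = WindowSpec(input_len=40, lead=5, stride=2)
        ds = make_windows(fm, raw, spec, (0, 200))
        sc = ColumnScaler().fit(fm.columns[:120])
        save_windowed(ds, tmp_path / "train.npz", scaler=sc, partition="train")
        back, meta = load_windowed(tmp_path / "train.npz")
        assert np.array_equal(back.features, ds.features)
        assert np.array_equal(back.targets, ds.targets)
        assert np.array_equal(back.end_indices, ds.end_indices)
        assert np.array_equal(back.last_observed, ds.last_observed)
        assert back.spec == ds.spec
        assert meta["partition"] == "train"
        sc2 = ColumnScaler.from_dict(meta["scaler"])
        assert np.allclose(sc2.transform(fm.columns), sc.transform(fm.columns))
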