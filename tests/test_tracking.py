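"""Detection, linking, MSD estimators, anomalous fits, bimodality, regions."""

import numpy as np
import pandas as pd
import pytest

from nucphase.config import SimConfig
from nucphase.sim import PopulationSpec, gen_trajectories, render_movie
from nucphase.tracks import TrajectorySet
from nucphase.tracking import (
    AnomalousFit,
    MSDCurve,
    amplitude_distribution,
    classify_region,
    detect_spots,
    fit_anomalous,
    link,
    msd_ensemble,
    msd_pairwise,
    msd_single,
)


def _single_track(xy, dt=1.0):
    n = len(xy)
    d = pd.DataFrame(
        {
            "track_id": 0,
            "frame": np.arange(n),
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
        }
    )
    return TrajectorySet(d, dt)


class TestDetection:
    def test_single_spot_subpixel_accuracy(self):
        """A rendered Gaussian spot is recovered within 0.1 px of the
        analytic centroid at high SNR."""
        cfg = SimConfig(seed=7, frame_interval=0.1, image_shape=(64, 64))
        truth = pd.DataFrame(
            {"track_id": 0, "frame": [0], "x_um": [4.0131], "y_um": [3.907]}
        )
        stack = render_movie(TrajectorySet(truth, 0.1), 0.17, 100, cfg)
        det = detect_spots(stack.frames[0], 1.0, pixel_size=cfg.pixel_size)
        assert len(det) == 1
        err_px = np.hypot(det.x_um[0] - 4.0131, det.y_um[0] - 3.907) / cfg.pixel_size
        assert err_px < 0.1

    def test_uniform_image_no_detections(self):
        assert len(detect_spots(np.full((64, 64), 7.0))) == 0

    def test_pure_noise_no_detections(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(100, (128, 128)).astype(float)
        assert len(detect_spots(img, 1.0)) == 0

    def test_crowded_field_recall_at_snr10(self):
        """>= 95% of 50 rendered particles at SNR 10 matched within 1 px
        (greedy nearest matching to stored ground truth)."""
        matched = total = 0
        for seed in range(3):
            cfg = SimConfig(seed=seed, frame_interval=0.1)
            ts = gen_trajectories([PopulationSpec(50, 20, 0.05, 1.0)], cfg)
            stack = render_movie(ts, 0.17, 10, cfg)
            for f in range(0, 20, 5):
                det = detect_spots(
                    stack.frames[f], 1.0, pixel_size=cfg.pixel_size
                )
                truth = ts.data[ts.data.frame == f]
                for _, r in truth.iterrows():
                    d = np.hypot(det.x_um - r.x_um, det.y_um - r.y_um)
                    total += 1
                    if len(d) and d.min() < cfg.pixel_size:
                        matched += 1
        assert matched / total >= 0.95

    def test_empty_track_set_renders_and_detects_nothing(self):
        cfg = SimConfig(seed=1, image_shape=(32, 32))
        empty = TrajectorySet(
            pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"]), 0.1
        )
        stack = render_movie(empty, 0.17, 10, cfg)
        assert len(detect_spots(stack.frames[0], 1.0)) == 0


class TestLinking:
    def test_single_detection_per_frame_one_track(self):
        dets = [
            pd.DataFrame({"x_um": [1.0 + 0.01 * f], "y_um": [2.0]})
            for f in range(10)
        ]
        ts = link(dets, max_disp_um=0.5, frame_interval=0.1)
        assert ts.n_tracks == 1
        assert len(ts.data) == 10

    def test_two_separated_walkers_no_switches(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + [5.0, 5.0]
        b = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + [20.0, 20.0]
        dets = [
            pd.DataFrame(
                {"x_um": [a[f, 0], b[f, 0]], "y_um": [a[f, 1], b[f, 1]]}
            )
            for f in range(30)
        ]
        ts = link(dets, max_disp_um=1.0, frame_interval=0.1)
        assert ts.n_tracks == 2
        # each reconstructed track stays near one ground-truth start
        for _, _, xy in ts.iter_tracks():
            ref = a if np.hypot(*(xy[0] - a[0])) < 1 else b
            assert np.hypot(*(xy - ref).T).max() < 0.5

    def test_gap_bridged_with_memory(self):
        dets = [
            pd.DataFrame({"x_um": [1.0], "y_um": [1.0]}) if f != 5 else
            pd.DataFrame({"x_um": [], "y_um": []})
            for f in range(12)
        ]
        no_mem = link(dets, 0.5, 0.1, memory=0)
        with_mem = link(dets, 0.5, 0.1, memory=1)
        assert no_mem.n_tracks == 2
        assert with_mem.n_tracks == 1

    def test_crossing_ambiguity_counted_in_qc(self):
        dets = [
            pd.DataFrame(
                {"x_um": [1.0 + 0.1 * f, 2.0 - 0.1 * f], "y_um": [1.0, 1.0]}
            )
            for f in range(11)
        ]
        _, qc = link(dets, max_disp_um=2.0, frame_interval=0.1, return_qc=True)
        assert qc["ambiguous_assignments"] > 0


class TestMsd:
    def test_stationary_track_zero_msd(self):
        ts = _single_track([(1.0, 1.0)] * 20)
        curve = msd_single(
            ts.data[["x_um", "y_um"]].to_numpy(), 1.0, max_lag_fraction=1.0
        )
        assert np.allclose(curve.msd, 0.0)

    def test_hand_enumerated_linear_track(self):
        """(0,0),(1,0),(2,0) at 1 s spacing: MSD(1)=1, MSD(2)=4 um^2."""
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        curve = msd_single(xy, 1.0, max_lag_fraction=1.0, min_track_len=3)
        assert np.allclose(curve.lags, [1.0, 2.0])
        assert np.allclose(curve.msd, [1.0, 4.0])
        assert list(curve.n_pairs) == [2, 1]

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="minimum"):
            msd_single(np.zeros((5, 2)), 1.0)

    def test_ensemble_within_3se_of_truth(self):
        cfg = SimConfig(seed=31, frame_interval=0.1)
        ts = gen_trajectories([PopulationSpec(200, 300, 0.1, 1.0)], cfg)
        curve = msd_ensemble(ts)
        expected = 0.1 * curve.lags
        assert np.all(np.abs(curve.msd - expected) <= 3 * curve.sem)

    def test_pairwise_common_translation_cancels(self):
        """Two tracks moving with identical velocity: pairwise MSD == 0."""
        t = np.arange(20, dtype=float)
        xy_a = np.column_stack([0.3 * t, 0.1 * t])
        xy_b = xy_a + [5.0, 0.0]
        d = pd.concat(
            [
                pd.DataFrame(
                    {"track_id": i, "frame": np.arange(20),
                     "x_um": xy[:, 0], "y_um": xy[:, 1]}
                )
                for i, xy in enumerate([xy_a, xy_b])
            ],
            ignore_index=True,
        )
        curve = msd_pairwise(TrajectorySet(d, 1.0), max_lag_fraction=1.0)
        assert np.allclose(curve.msd, 0.0)

    def test_pairwise_drift_immunity_exact(self):
        """Adding uniform drift leaves the pairwise MSD bit-identical."""
        cfg = SimConfig(seed=5, frame_interval=0.1)
        ts = gen_trajectories([PopulationSpec(30, 80, 0.1, 1.0)], cfg)
        drifted = ts.with_drift((0.05, 0.02))
        base = msd_pairwise(ts)
        moved = msd_pairwise(drifted)
        assert np.allclose(base.msd, moved.msd, rtol=0, atol=1e-12)

    def test_pairwise_matches_ensemble_for_independent_diffusers(self):
        cfg = SimConfig(seed=23, frame_interval=0.1)
        ts = gen_trajectories([PopulationSpec(60, 200, 0.1, 1.0)], cfg)
        pw = msd_pairwise(ts)
        en = msd_ensemble(ts)
        n = min(len(pw.lags), len(en.lags))
        se = np.sqrt(pw.sem[:n] ** 2 + en.sem[:n] ** 2)
        assert np.all(np.abs(pw.msd[:n] - en.msd[:n]) <= 3 * se)

    def test_pairwise_requires_two_tracks(self):
        ts = _single_track([(0.0, 0.0)] * 15)
        with pytest.raises(ValueError):
            msd_pairwise(ts)

    def test_lags_strictly_increasing_invariant(self):
        with pytest.raises(ValueError):
            MSDCurve(
                np.array([0.1, 0.1]), np.array([1.0, 2.0]),
                np.array([3, 3]), "single_point",
            )


class TestAnomalousFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        lags = np.linspace(0.1, 2.0, 20)
        curve = MSDCurve(lags, 0.2 * lags**0.75, np.full(20, 10), "ensemble")
        fit = fit_anomalous(curve)
        assert abs(fit.alpha - 0.75) < 1e-12
        assert abs(fit.D - 0.2) < 1e-12
        assert fit.r_squared > 1 - 1e-12

    def test_agrees_with_grid_search_oracle(self):
        """OLS fit matches brute-force (log D, alpha) grid minimization of
        squared log-residuals on 20 random noisy curves."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            D = 10.0 ** rng.uniform(-2, 0)
            alpha = rng.uniform(0.3, 1.5)
            lags = np.linspace(0.1, 3.0, 25)
            msd = D * lags**alpha * np.exp(rng.normal(0, 0.05, 25))
            curve = MSDCurve(lags, msd, np.full(25, 5), "ensemble")
            fit = fit_anomalous(curve)

            def objective(logD, a):
                return np.sum((np.log(msd) - (logD + a * np.log(lags))) ** 2)

            grids = np.meshgrid(
                np.linspace(np.log(D) - 1, np.log(D) + 1, 201),
                np.linspace(max(alpha - 0.5, 0.05), alpha + 0.5, 201),
            )
            vals = np.array(
                [
                    objective(ld, a)
                    for ld, a in zip(grids[0].ravel(), grids[1].ravel())
                ]
            )
            assert objective(np.log(fit.D), fit.alpha) <= vals.min() + 1e-6

    def test_noise_offset_flag_removes_floor(self):
        """Subtracting a known localization floor restores the exact
        exponent that the raw fit underestimates."""
        lags = np.linspace(0.1, 2.0, 20)
        floor = 2 * 0.05**2
        curve = MSDCurve(
            lags, 0.05 * lags**0.8 + floor, np.full(20, 10), "ensemble"
        )
        raw = fit_anomalous(curve)
        corrected = fit_anomalous(curve, noise_offset=floor)
        assert raw.alpha < 0.8 - 0.01
        assert abs(corrected.alpha - 0.8) < 1e-10
        assert abs(corrected.D - 0.05) < 1e-10

    def test_too_few_positive_lags_rejected(self):
        lags = np.linspace(0.1, 1.0, 6)
        msd = np.array([1.0, -1.0, -1.0, -1.0, 2.0, 3.0])
        curve_vals = np.where(msd > 0, msd, 1.0)
        curve = MSDCurve(lags, curve_vals, np.full(6, 2), "ensemble")
        with pytest.raises(ValueError):
            fit_anomalous(curve, fit_window=(0.1, 0.3))


class TestAmplitudeDistribution:
    def test_identical_tracks_unimodal(self):
        xy = np.cumsum(np.full((100, 2), 0.05), axis=0)
        d = pd.concat(
            [
                pd.DataFrame(
                    {"track_id": i, "frame": np.arange(100),
                     "x_um": xy[:, 0] + i, "y_um": xy[:, 1]}
                )
                for i in range(25)
            ],
            ignore_index=True,
        )
        ad = amplitude_distribution(TrajectorySet(d, 0.1), 0.1)
        assert ad.modality == "unimodal"

    def test_tenfold_mixture_bimodal_with_fractions(self):
        """50/50 mixture with 10x separated MSD amplitudes: bimodal call,
        mixing fractions within +-0.1."""
        cfg = SimConfig(seed=41, frame_interval=0.1)
        ts = gen_trajectories(
            [
                PopulationSpec(100, 300, 0.02, 0.5, fraction=0.5),
                PopulationSpec(100, 300, 0.63, 1.0, fraction=0.5),
            ],
            cfg,
        )
        ad = amplitude_distribution(ts, 0.1)
        assert ad.modality == "bimodal"
        assert np.all(np.abs(ad.mixing_fractions - 0.5) < 0.1)
        assert ad.component_means[1] / ad.component_means[0] > 5

    def test_undetermined_below_twenty_tracks(self):
        cfg = SimConfig(seed=2, frame_interval=0.1)
        ts = gen_trajectories([PopulationSpec(10, 50, 0.1, 1.0)], cfg)
        ad = amplitude_distribution(ts, 0.1)
        assert ad.modality == "undetermined"

    def test_unresolvable_lag_rejected(self):
        cfg = SimConfig(seed=2, frame_interval=0.1)
        ts = gen_trajectories([PopulationSpec(25, 50, 0.1, 1.0)], cfg)
        with pytest.raises(ValueError, match="resolvable"):
            amplitude_distribution(ts, 0.04)


class TestRegionClassification:
    def _disk_mask(self, n=64, radius=20):
        yy, xx = np.mgrid[0:n, 0:n]
        return (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= radius**2

    def test_center_track_interior(self):
        mask = self._disk_mask()
        px = 0.133
        center = 32 * px
        d = pd.DataFrame(
            {"track_id": 0, "frame": range(10),
             "x_um": center, "y_um": center}
        )
        labels, dropped = classify_region(TrajectorySet(d, 0.1), mask, px)
        assert dropped == 0
        assert labels.iloc[0]["region"] == "interior"

    def test_edge_track_periphery(self):
        mask = self._disk_mask()
        px = 0.133
        # 1 px inside the disk rim
        d = pd.DataFrame(
            {"track_id": 0, "frame": range(10),
             "x_um": (32 + 19) * px, "y_um": 32 * px}
        )
        labels, _ = classify_region(TrajectorySet(d, 0.1), mask, px)
        assert labels.iloc[0]["region"] == "periphery"

    def test_outside_tracks_dropped_and_counted(self):
        mask = self._disk_mask()
        px = 0.133
        d = pd.DataFrame(
            {"track_id": 0, "frame": range(10), "x_um": 0.5, "y_um": 0.5}
        )
        labels, dropped = classify_region(TrajectorySet(d, 0.1), mask, px)
        assert dropped == 1 and len(labels) == 0
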