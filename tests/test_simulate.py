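"""Synthetic generator: walks, placement, rendering, survival tables."""

import numpy as np
import pandas as pd
import pytest

import ivmotion as m
from ivmotion.simulate import distance_to_bone, distance_to_vessels


class TestSimulateTracks:
    def test_zero_speed_gives_constant_tracks(self, small_cohort_config):
        cfg = small_cohort_config(
            "arrested",
            regimes={"arrested": m.RegimeParams(target_speed=0.0)},
        )
        truth = m.simulate_tracks(cfg)
        assert np.allclose(np.diff(truth.positions, axis=1), 0.0)
        assert np.allclose(truth.mean_speeds(), 0.0)

    def test_speed_calibration_both_regimes(self):
        """Sample mean of true speeds within 10% of target over 100 cells."""
        for regime, target in (("motile", 1.5), ("arrested", 0.5)):
            cfg = m.SimulationConfig.cohort(
                regime, n_cells=100, n_frames=61, field_size=(400.0, 400.0, 40.0),
                seed=7,
            )
            speeds = m.simulate_tracks(cfg).mean_speeds()
            assert speeds.mean() == pytest.approx(target, rel=0.10)

    def test_regime_separation_at_group_level(self, small_cohort_config):
        for seed in (1, 2, 3):
            motile = m.simulate_tracks(small_cohort_config("motile", seed=seed))
            arrested = m.simulate_tracks(small_cohort_config("arrested", seed=seed))
            assert arrested.mean_speeds().mean() < motile.mean_speeds().mean()

    def test_determinism(self, small_cohort_config):
        a = m.simulate_tracks(small_cohort_config("motile", seed=9))
        b = m.simulate_tracks(small_cohort_config("motile", seed=9))
        assert np.array_equal(a.positions, b.positions)
        assert a.regimes == b.regimes

    def test_tracks_stay_in_field(self, small_cohort_config):
        cfg = small_cohort_config("motile", seed=4, n_frames=200)
        pos = m.simulate_tracks(cfg).positions
        for ax in range(2):
            assert (pos[..., ax] >= 0).all()
            assert (pos[..., ax] <= cfg.field_size[ax]).all()

    def test_true_speed_is_path_length_over_time(self, small_cohort_config):
        truth = m.simulate_tracks(small_cohort_config("motile", seed=3))
        i = 2
        steps = np.linalg.norm(np.diff(truth.positions[i], axis=0), axis=1)
        expected = steps.sum() / ((truth.n_frames - 1) * truth.frame_interval)
        assert truth.mean_speeds()[i] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs", [{"n_frames": 1}, {"frame_interval": 0.0}, {"n_cells": 0}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            m.SimulationConfig.cohort("motile", **kwargs)


class TestPlaceCells:
    BONE = m.BoneSpec(position=8.0)
    VESSEL = m.VesselSpec(point=(0.0, 60.0, 30.0), direction=(1.0, 0.0, 0.0), radius=8.0)

    def _config(self, rules, n_cells=10, seed=0):
        return m.SimulationConfig(
            n_cells=n_cells,
            cell_regimes=("arrested",) * n_cells,
            mode="3d",
            field_size=(128.0, 128.0, 60.0),
            voxel_size=(1.0, 1.0, 2.0),
            bone=self.BONE,
            vessels=(self.VESSEL,),
            placement_rules=tuple(rules),
            seed=seed,
        )

    def test_forced_bone_placement(self):
        cfg = self._config([m.PlacementRule("bone", 15.0, 1.0)])
        pos = m.place_cells(cfg)
        assert (distance_to_bone(pos, self.BONE) <= 15.0).all()

    def test_exact_vessel_count(self):
        cfg = self._config([m.PlacementRule("vessel", 5.0, 0.6)], n_cells=10)
        pos = m.place_cells(cfg)
        d = distance_to_vessels(pos, (self.VESSEL,))
        assert (d <= 5.0).sum() == 6

    def test_counts_are_rounded_n_times_f(self):
        for n, f in ((7, 0.5), (9, 0.33), (12, 0.25)):
            cfg = self._config([m.PlacementRule("bone", 15.0, f)], n_cells=n)
            d = distance_to_bone(m.place_cells(cfg), self.BONE)
            assert (d <= 15.0).sum() == round(n * f)

    def test_vessel_rule_without_vessels_rejected(self):
        with pytest.raises(ValueError, match="no vessels"):
            m.SimulationConfig(
                n_cells=4,
                cell_regimes=("arrested",) * 4,
                placement_rules=(m.PlacementRule("vessel", 5.0, 0.5),),
            )

    def test_threshold_beyond_field_rejected(self):
        with pytest.raises(ValueError, match="exceeds field"):
            self._config([m.PlacementRule("bone", 500.0, 0.5)])

    def test_min_separation_respected(self):
        cfg = self._config([], n_cells=12, seed=5)
        pos = m.place_cells(cfg)
        dist = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= cfg.min_separation


class TestRenderMovie:
    def test_static_cell_identical_frames_without_noise(self):
        cfg = m.SimulationConfig.cohort(
            "still", n_cells=1, n_frames=4, field_size=(40.0, 40.0, 20.0),
            voxel_size=(1.0, 1.0, 2.0),
            regimes={"still": m.RegimeParams(0.0, protrusion_amplitude=0.0)},
            noise=m.NoiseModel(background=0.0, signal=100.0, shot_noise=False),
        )
        movie = m.render_movie(m.simulate_tracks(cfg), cfg)
        green = movie.channel("green")
        for t in range(1, 4):
            assert np.array_equal(green[t], green[0])

    def test_intensity_centroid_tracks_truth(self):
        """Noise-free single cell: centroid within half a pixel of truth."""
        cfg = m.SimulationConfig.cohort(
            "motile", n_cells=1, n_frames=6, field_size=(60.0, 60.0, 20.0),
            voxel_size=(1.0, 1.0, 2.0), seed=3,
            noise=m.NoiseModel(background=0.0, signal=100.0, shot_noise=False),
        )
        truth = m.simulate_tracks(cfg)
        movie = m.render_movie(truth, cfg)
        green = movie.mip("green").astype(float)
        yy, xx = np.mgrid[: green.shape[1], : green.shape[2]]
        for t in range(6):
            w = green[t]
            cy = ((yy + 0.5) * w).sum() / w.sum()
            cx = ((xx + 0.5) * w).sum() / w.sum()
            assert abs(cx - truth.positions[0, t, 0]) < 0.5
            assert abs(cy - truth.positions[0, t, 1]) < 0.5

    def test_determinism_bitwise(self, small_cohort_config):
        cfg = small_cohort_config("motile", seed=11)
        a = m.render_movie(m.simulate_tracks(cfg), cfg)
        b = m.render_movie(m.simulate_tracks(cfg), cfg)
        assert np.array_equal(a.data, b.data)

    def test_subresolution_warns(self):
        cfg = m.SimulationConfig.cohort(
            "motile", n_cells=1, n_frames=2, cell_diameter=3.0,
            field_size=(80.0, 80.0, 20.0), voxel_size=(4.0, 4.0, 4.0),
        )
        with pytest.warns(UserWarning, match="sub-resolution"):
            m.render_movie(m.simulate_tracks(cfg), cfg)

    def test_channel_roles_cover_three(self, small_cohort_config):
        movie = m.render_movie(
            m.simulate_tracks(small_cohort_config("motile")),
            small_cohort_config("motile"),
        )
        assert sorted(movie.channels) == ["blue", "green", "red"]


class TestSimulateSurvival:
    def test_schema_and_censoring(self):
        df = m.simulate_survival({"a": 0.05, "b": 0.15}, 20, follow_up=60.0, seed=1)
        assert set(df.columns) == {"time_days", "event", "group"}
        assert (df.time_days > 0).all()
        assert df.event.isin((0, 1)).all()
        assert (df.loc[df.event == 0, "time_days"] == 60.0).all()
        assert len(df) == 40

    def test_hazard_ratio_orders_medians(self):
        """Hazard ratio 3: the high-hazard arm dies earlier almost surely."""
        wins = 0
        for seed in range(200):
            df = m.simulate_survival({"hi": 0.15, "lo": 0.05}, 20, 365.0, seed=seed)
            med = df.groupby("group").time_days.median()
            wins += med["hi"] < med["lo"]
        assert wins >= 190

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_survival({"a": 0.1}, 10, follow_up=0.0)
        with pytest.raises(ValueError):
            m.simulate_survival({"a": -0.1, "b": 0.1}, 10, follow_up=10.0)

    def test_determinism(self):
        a = m.simulate_survival({"a": 0.1, "b": 0.2}, 15, 30.0, seed=5)
        b = m.simulate_survival({"a": 0.1, "b": 0.2}, 15, 30.0, seed=5)
        pd.testing.assert_frame_equal(a, b)
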