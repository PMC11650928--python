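import math

import numpy as np
import pytest

from patchid import annotations_io as aio
from patchid import synthetic_sharks as ss
from patchid.exceptions import ConfigError, RenderError

from conftest import TEST_BODY_LENGTH, TEST_IMAGE_SIZE


class TestMakePopulation:
    def test_study_counts(self):
        specs = ss.make_population(8, 4, 5, seed=7)
        assert len(specs) == 17
        assert sum(s.life_stage == "adult" for s in specs) == 8
        assert sum(s.life_stage == "juvenile" for s in specs) == 4
        assert sum(s.life_stage == "neonate" for s in specs) == 5

    def test_empty(self):
        assert ss.make_population(0, 0, 0, seed=1) == []

    def test_seeded_determinism(self):
        a = ss.make_population(2, 1, 1, seed=3)
        b = ss.make_population(2, 1, 1, seed=3)
        assert a == b

    def test_unique_ids(self):
        specs = ss.make_population(8, 4, 5, seed=9)
        ids = [s.shark_id for s in specs]
        assert len(set(ids)) == len(ids)

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            ss.make_population(-1, 0, 0, seed=1)

    def test_default_drift_rates(self):
        specs = ss.make_population(1, 1, 1, seed=5)
        by_stage = {s.life_stage: s.drift_rate for s in specs}
        assert by_stage == {"adult": 0.0, "juvenile": 0.02, "neonate": 0.08}


class TestDriftPattern:
    def test_zero_rate_fixed_point(self, adult_spec):
        base = ss.drift_pattern(adult_spec, 0)
        for t in (1, 3, 10):
            later = ss.drift_pattern(adult_spec, t)
            np.testing.assert_array_equal(base.xy, later.xy)
            np.testing.assert_array_equal(base.radii, later.radii)
            np.testing.assert_array_equal(base.ids, later.ids)

    def test_deterministic(self, neonate_spec):
        a = ss.drift_pattern(neonate_spec, 5)
        b = ss.drift_pattern(neonate_spec, 5)
        np.testing.assert_array_equal(a.xy, b.xy)
        np.testing.assert_array_equal(a.ids, b.ids)

    def test_displacement_matches_monte_carlo_oracle(self):
        # oracle: an independent simulation of the stated walk (Gaussian
        # steps, survivors only), run over many seeds
        t, rate, L = 5, 0.08, TEST_BODY_LENGTH
        sigma = rate * L
        orng = np.random.default_rng(999)
        oracle_means = []
        for _ in range(2000):
            pos = np.zeros(2)
            alive = True
            for _step in range(t):
                pos = pos + orng.normal(0.0, sigma, size=2)
                if orng.random() < rate:
                    alive = False
                    break
            if alive:
                oracle_means.append(np.hypot(*pos))
        oracle = np.mean(oracle_means)
        oracle_se = np.std(oracle_means) / math.sqrt(len(oracle_means))

        impl = []
        for seed in range(400):
            spec = ss.IndividualSpec(
                shark_id=f"X{seed}", life_stage="neonate", base_seed=seed,
                n_spots=12, spot_radius_range=(2.0, 3.0),
                body_length=L, drift_rate=rate,
            )
            base = ss.drift_pattern(spec, 0)
            after = ss.drift_pattern(spec, t)
            surv = np.isin(after.ids, base.ids)
            orig = {i: xy for i, xy in zip(base.ids, base.xy)}
            for sid, xy in zip(after.ids[surv], after.xy[surv]):
                impl.append(np.hypot(*(xy - orig[sid])))
        impl_mean = np.mean(impl)
        impl_se = np.std(impl) / math.sqrt(len(impl))
        assert impl_mean == pytest.approx(oracle, abs=3 * math.hypot(oracle_se, impl_se))

    def test_survival_fraction_binomial(self):
        # expected survivor fraction after t steps is (1 - rate)^t
        t, rate = 4, 0.08
        survived = total = 0
        for seed in range(600):
            spec = ss.IndividualSpec(
                shark_id=f"X{seed}", life_stage="neonate", base_seed=seed,
                n_spots=10, spot_radius_range=(2.0, 3.0),
                body_length=TEST_BODY_LENGTH, drift_rate=rate,
            )
            base = ss.drift_pattern(spec, 0)
            after = ss.drift_pattern(spec, t)
            survived += int(np.isin(base.ids, after.ids).sum())
            total += len(base.ids)
        p = (1 - rate) ** t
        se = math.sqrt(p * (1 - p) / total)
        assert survived / total == pytest.approx(p, abs=2.58 * se)  # 99% CI

    def test_negative_t_rejected(self, adult_spec):
        with pytest.raises(ConfigError):
            ss.drift_pattern(adult_spec, -1)


class TestRender:
    def test_nuisance_only_variation(self, adult_spec, render_cfg):
        from dataclasses import replace

        a = ss.render(adult_spec, 0, render_cfg)
        b = ss.render(adult_spec, 0, replace(render_cfg, render_seed=77))
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.boxes == b.boxes
        assert not np.array_equal(a.image, b.image)  # different noise fields

    def test_adult_time_stability(self, adult_spec, render_cfg):
        a = ss.render(adult_spec, 0, render_cfg)
        b = ss.render(adult_spec, 4, render_cfg)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    @pytest.mark.parametrize("view_angle", [0.0, 17.5, -33.0, 181.0])
    def test_box_angle_equals_view_angle(self, adult_spec, view_angle):
        cfg = ss.RenderConfig(image_size=TEST_IMAGE_SIZE, view_angle=view_angle)
        sample = ss.render(adult_spec, 0, cfg)
        for box in sample.boxes:
            assert math.degrees(box.angle) % 360 == pytest.approx(view_angle % 360, abs=1e-6)

    def test_all_four_boxes_present_once(self, rendered_sample):
        assert sorted(b.patch_type for b in rendered_sample.boxes) == sorted(aio.PATCH_TYPES)

    def test_pattern_only_inside_mask(self, adult_spec):
        # with plain background and no nuisance, everything outside the mask
        # must be the flat background value: spots never leak outside
        cfg = ss.RenderConfig(image_size=TEST_IMAGE_SIZE, view_angle=20.0)
        s = ss.render(adult_spec, 0, cfg)
        outside = s.image[s.mask == 0]
        assert np.all(outside == outside[0])

    def test_boxes_inside_image_and_mask_bbox(self, adult_spec):
        for angle in (0.0, 45.0, 120.0):
            cfg = ss.RenderConfig(image_size=TEST_IMAGE_SIZE, view_angle=angle)
            s = ss.render(adult_spec, 0, cfg)
            ys, xs = np.nonzero(s.mask)
            pad_y = 0.1 * (ys.max() - ys.min())
            pad_x = 0.1 * (xs.max() - xs.min())
            H, W = cfg.image_size
            for box in s.boxes:
                c, sn = math.cos(box.angle), math.sin(box.angle)
                for dx, dy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    x = box.cx + dx * box.w / 2 * c - dy * box.h / 2 * sn
                    y = box.cy + dx * box.w / 2 * sn + dy * box.h / 2 * c
                    assert 0 <= x < W and 0 <= y < H
                    assert xs.min() - pad_x <= x <= xs.max() + pad_x
                    assert ys.min() - pad_y <= y <= ys.max() + pad_y

    def test_body_too_large_raises(self):
        spec = ss.IndividualSpec(
            shark_id="S", life_stage="adult", base_seed=1, n_spots=5,
            spot_radius_range=(2.0, 3.0), body_length=300.0,
        )
        with pytest.raises(RenderError):
            ss.render(spec, 0, ss.RenderConfig(image_size=(128, 128)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ss.RenderConfig(image_size=(100, 100))
        with pytest.raises(ConfigError):
            ss.RenderConfig(gamma=0.0)
        with pytest.raises(ConfigError):
            ss.RenderConfig(blur_sigma=-1.0)


class TestWriteDataset:
    def test_row_counting_baseline_only(self, tmp_path):
        population = ss.make_population(8, 4, 1, seed=2, body_length=TEST_BODY_LENGTH)
        manifest = ss.write_dataset(population, 4, 0, tmp_path, seed=5,
                                    image_size=TEST_IMAGE_SIZE)
        rows = aio.read_manifest(manifest)
        assert len(rows) == 52
        assert all(r.series == "baseline" for r in rows)

    def test_time_markers(self, tiny_dataset):
        rows = aio.read_manifest(tiny_dataset["manifest"])
        for spec in tiny_dataset["population"]:
            markers = sorted(
                r.time_marker for r in rows
                if r.shark_id == spec.shark_id and r.series == "time"
            )
            assert markers == ["T0", "T1"]

    def test_rerun_byte_identical_manifest(self, tmp_path):
        population = ss.make_population(1, 1, 0, seed=3, body_length=TEST_BODY_LENGTH)
        m1 = ss.write_dataset(population, 2, 1, tmp_path / "a", seed=9,
                              image_size=TEST_IMAGE_SIZE)
        m2 = ss.write_dataset(population, 2, 1, tmp_path / "b", seed=9,
                              image_size=TEST_IMAGE_SIZE)
        assert m1.read_bytes() == m2.read_bytes()

    def test_annotations_round_trip_exactly(self, tiny_dataset):
        root = tiny_dataset["root"]
        rows = aio.read_manifest(tiny_dataset["manifest"])
        spec_by_id = {s.shark_id: s for s in tiny_dataset["population"]}
        row = rows[0]
        boxes = aio.read_rolabelimg(root / row.annotation_path)
        assert sorted(b.patch_type for b in boxes) == sorted(aio.PATCH_TYPES)
        # written values are repr() round-trips: exact
        assert all(0 <= b.angle < 2 * math.pi for b in boxes)
        assert spec_by_id[row.shark_id].life_stage == row.life_stage

    def test_requires_replicates(self, tmp_path):
        with pytest.raises(ConfigError):
            ss.write_dataset([], 0, 0, tmp_path, seed=1)
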