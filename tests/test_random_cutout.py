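import numpy as np
import pytest
from scipy import stats

from wheatear import (
    BoundingBox,
    CutoutConfig,
    SceneSpec,
    apply_cutout_baseline,
    apply_random_cutout,
    apply_random_erasing_baseline,
    build_probability_map,
    generate_scene,
    normalize_to_distribution,
    propose_centers,
    sample_rectangle_size,
)


def erased_mask(before, after):
    return np.any(before.pixels != after.pixels, axis=2)


def rect_union_mask(rects, shape):
    mask = np.zeros(shape, dtype=bool)
    for r in rects:
        r0, r1, c0, c1 = r.extent(shape)
        mask[r0:r1, c0:c1] = True
    return mask


class TestProposeCenters:
    def test_zero_draws(self, dense_scene):
        pmap = build_probability_map(dense_scene.shape, dense_scene.boxes)
        assert propose_centers(pmap, 0, seed=1).shape == (0, 2)

    def test_exhaustive_draw_covers_every_pixel(self):
        pmap = build_probability_map((6, 7), [])
        pts = propose_centers(pmap, 42, seed=3)
        assert len({(r, c) for r, c in map(tuple, pts)}) == 42

    def test_too_many_centers_rejected(self):
        pmap = build_probability_map((4, 4), [])
        with pytest.raises(ValueError):
            propose_centers(pmap, 17, seed=0)

    def test_in_box_frequency_matches_region_mass(self):
        """Single-draw sampling hits the boxed region at its normalized mass."""
        pmap = build_probability_map((32, 32), [BoundingBox(8, 8, 10, 10)])
        dist = normalize_to_distribution(pmap)
        mass = dist[8:18, 8:18].sum()
        pts = propose_centers(pmap, 10_000, seed=42, replace=True)
        inside = np.mean((pts[:, 0] >= 8) & (pts[:, 0] < 18) & (pts[:, 1] >= 8) & (pts[:, 1] < 18))
        se = np.sqrt(mass * (1 - mass) / 10_000)
        assert abs(inside - mass) <= 3 * se

    def test_chi_square_against_exact_distribution(self):
        scene = generate_scene(SceneSpec(image_size=(96, 96), n_ears=20, seed=5))
        pmap = build_probability_map(scene.shape, scene.boxes)
        dist = normalize_to_distribution(pmap)
        pts = propose_centers(pmap, 10_000, seed=17, replace=True)
        # bin into 8x8 spatial blocks so every expected count is large
        blocks_obs = np.zeros((8, 8))
        np.add.at(blocks_obs, (pts[:, 0] // 12, pts[:, 1] // 12), 1)
        blocks_exp = dist.reshape(8, 12, 8, 12).sum(axis=(1, 3)) * 10_000
        stat = ((blocks_obs - blocks_exp) ** 2 / blocks_exp).sum()
        p = stats.chi2.sf(stat, df=63)
        assert p > 0.01


class TestSampleRectangleSize:
    def test_degenerate_interval(self, rng):
        boxes = [BoundingBox(0, 0, 20, 40)] * 3  # all ears 40 high, 20 wide
        for _ in range(5):
            h, w = sample_rectangle_size(boxes, 4, rng)
            assert (h, w) == (10.0, 5.0)

    def test_uniform_mean_on_height_interval(self, rng):
        boxes = [BoundingBox(0, 0, 10, 20), BoundingBox(0, 0, 10, 60)]
        hs = [sample_rectangle_size(boxes, 4, rng)[0] for _ in range(10_000)]
        assert all(5.0 <= h <= 15.0 for h in hs)
        assert abs(np.mean(hs) - 10.0) <= 0.2

    def test_floor_at_one_pixel(self, rng):
        boxes = [BoundingBox(0, 0, 4, 4)]
        assert sample_rectangle_size(boxes, 4, rng) == (1.0, 1.0)

    def test_empty_box_list_is_an_error(self, rng):
        with pytest.raises(ValueError):
            sample_rectangle_size([], 4, rng)


class TestRandomCutout:
    def test_rectangle_count_law(self):
        # 8 ears -> 2 rectangles; 3 ears -> floor gives 0, raised to 1
        for n_ears, expected in [(8, 2), (3, 1), (17, 4)]:
            scene = generate_scene(SceneSpec(image_size=(96, 96), n_ears=n_ears, seed=n_ears))
            _, rects = apply_random_cutout(scene, CutoutConfig(seed=1))
            assert len(rects) == expected

    def test_annotations_pass_through_unchanged(self, dense_scene):
        aug, _ = apply_random_cutout(dense_scene, CutoutConfig(seed=2))
        assert [b.as_tuple() for b in aug.boxes] == [b.as_tuple() for b in dense_scene.boxes]

    def test_erased_pixels_equal_reported_rectangles(self, dense_scene):
        aug, rects = apply_random_cutout(dense_scene, CutoutConfig(seed=3))
        union = rect_union_mask(rects, dense_scene.shape)
        assert np.all(aug.pixels[union] == 255)
        assert np.array_equal(aug.pixels[~union], dense_scene.pixels[~union])
        # scene pixels never reach 255, so the changed set is exactly the union
        assert np.array_equal(erased_mask(dense_scene, aug), union)

    def test_sizes_respect_per_image_bounds(self, dense_scene):
        hs = [b.height for b in dense_scene.boxes]
        ws = [b.width for b in dense_scene.boxes]
        for seed in range(20):
            _, rects = apply_random_cutout(dense_scene, CutoutConfig(seed=seed))
            for r in rects:
                assert min(hs) / 4 <= r.height <= max(hs) / 4
                assert min(ws) / 4 <= r.width <= max(ws) / 4

    def test_deterministic_under_seed(self, dense_scene):
        a, ra = apply_random_cutout(dense_scene, CutoutConfig(seed=7))
        b, rb = apply_random_cutout(dense_scene, CutoutConfig(seed=7))
        assert np.array_equal(a.pixels, b.pixels)
        assert [(r.center, r.height, r.width) for r in ra] == \
               [(r.center, r.height, r.width) for r in rb]

    def test_empty_image_returned_unchanged(self):
        scene = generate_scene(SceneSpec(n_ears=0, seed=1))
        aug, rects = apply_random_cutout(scene, CutoutConfig(seed=1))
        assert rects == [] and np.array_equal(aug.pixels, scene.pixels)

    def test_spatial_bias_toward_dense_cluster(self):
        """Erasure lands in the crowded quadrant more often than elsewhere."""
        rng = np.random.default_rng(0)
        boxes = [BoundingBox(float(rng.uniform(0, 44)), float(rng.uniform(0, 44), ), 20.0, 20.0)
                 for _ in range(16)]  # cluster in the top-left 64x64 quadrant
        boxes += [BoundingBox(100.0, 100.0, 10.0, 10.0)]  # one lone ear elsewhere
        pixels = np.full((128, 128, 3), 50, dtype=np.uint8)
        from wheatear.annotations import AnnotatedImage

        scene = AnnotatedImage("cluster", (128, 128), boxes, pixels)
        freq = np.zeros((128, 128))
        for seed in range(150):
            aug, rects = apply_random_cutout(scene, CutoutConfig(seed=seed))
            freq += rect_union_mask(rects, scene.shape)
        in_cluster = freq[:64, :64].mean()
        background = freq[64:, 64:].mean()
        assert in_cluster > background

    def test_rarely_occludes_an_ear_completely(self):
        """Adaptive sizing keeps >= 95%-covered ears below 5% of boxes."""
        covered = total = 0
        for seed in range(60):
            scene = generate_scene(SceneSpec(image_size=(128, 128), n_ears=25, seed=seed))
            aug, rects = apply_random_cutout(scene, CutoutConfig(seed=seed + 1000))
            union = rect_union_mask(rects, scene.shape)
            for b in scene.boxes:
                r0, r1 = int(np.ceil(b.ymin)), int(np.ceil(b.ymax))
                c0, c1 = int(np.ceil(b.xmin)), int(np.ceil(b.xmax))
                area = max((r1 - r0) * (c1 - c0), 1)
                if union[r0:r1, c0:c1].sum() >= 0.95 * area:
                    covered += 1
            total += len(scene.boxes)
        assert covered / total < 0.05


class TestBaselines:
    def test_cutout_identity_when_n_zero(self, dense_scene):
        out = apply_cutout_baseline(dense_scene, 0, 8, seed=1)
        assert np.array_equal(out.pixels, dense_scene.pixels)

    def test_cutout_full_image_square_whitens_everything(self, dense_scene):
        out = apply_cutout_baseline(dense_scene, 1, 4 * max(dense_scene.shape), seed=1)
        assert np.all(out.pixels == 255)

    def test_cutout_erased_area_bounded(self, dense_scene):
        n, size = 5, 16
        out = apply_cutout_baseline(dense_scene, n, size, seed=2)
        changed = erased_mask(dense_scene, out).sum()
        assert changed <= n * size * size

    def test_random_erasing_identity_and_determinism(self, dense_scene):
        assert np.array_equal(
            apply_random_erasing_baseline(dense_scene, 0, (8, 16), (0.5, 2.0), seed=1).pixels,
            dense_scene.pixels)
        a = apply_random_erasing_baseline(dense_scene, 3, (8, 16), (0.5, 2.0), seed=9)
        b = apply_random_erasing_baseline(dense_scene, 3, (8, 16), (0.5, 2.0), seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_random_erasing_noise_mean(self):
        from wheatear.annotations import AnnotatedImage

        pixels = np.zeros((128, 128, 3), dtype=np.uint8)
        scene = AnnotatedImage("flat", (128, 128), [], pixels)
        out = apply_random_erasing_baseline(scene, 6, (40, 60), (1.0, 1.0), seed=3)
        noise = out.pixels[erased_mask(scene, out)]
        assert noise.size >= 10_000
        assert abs(noise.mean() - 127.5) <= 3.0
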