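import numpy as np
import pytest

import pombex as px
from pombex.classify import (AMBIGUOUS, BACKGROUND, INTERIOR, MEMBRANE,
                             PixelClassMap, classify_pixels, initial_contours,
                             membrane_edge_map, resolve_ambiguous,
                             smooth_classes)

B, C, M, X = BACKGROUND, INTERIOR, MEMBRANE, AMBIGUOUS


def cmap_from(labels):
    return PixelClassMap(labels=np.asarray(labels, dtype=np.uint8))


# ---------------------------------------------------------------------------
# classify_pixels

class TestClassifyPixels:
    def test_noiseless_scene_membrane_and_interior_separate(
            self, noiseless_scene):
        scene = noiseless_scene
        spec = scene.spec
        trans = scene.images.trans
        mu_b = spec.background_level
        mu_n = mu_b + spec.nucleus_lift
        truth_bg = scene.instances == 0
        cmap = classify_pixels(trans, truth_bg, mu_n, mu_b)
        # core (non-anti-aliased) pixels sit exactly at the three levels
        membrane_core = trans == mu_b - spec.membrane_depth
        interior_core = trans == mu_b + spec.interior_lift
        assert membrane_core.sum() > 0 and interior_core.sum() > 0
        assert np.all(cmap.labels[membrane_core] == M)
        assert np.all(cmap.labels[interior_core] == C)

    def test_intensity_exactly_at_nucleus_mean_is_ambiguous(self):
        img = np.array([[10.0, 10.0], [0.0, 20.0]])
        bg = np.zeros((2, 2), bool)
        cmap = classify_pixels(img, bg, mu_n=10.0, mu_b=5.0)
        assert cmap.labels[0, 0] == X     # i == mu_N: strict inequality
        assert cmap.labels[1, 1] == C

    def test_noisy_membrane_never_interior(self, small_scene):
        scene = px.generate_scene(
            px.SceneSpec(shape=(256, 256), n_cells=8, noise_sigma=5.0,
                         seed=5))
        spec = scene.spec
        trans = scene.images.trans
        mu_b = spec.background_level
        mu_n = mu_b + spec.nucleus_lift
        cmap = classify_pixels(trans, scene.instances == 0, mu_n, mu_b)
        truth_m = scene.class_map.mask(M)
        got = cmap.labels[truth_m]
        assert np.mean((got == M) | (got == X)) >= 0.90
        assert np.sum(got == C) == 0

    def test_blank_field_empty_membrane(self, caplog):
        img = np.full((8, 8), 10.0)
        cmap = classify_pixels(img, np.zeros((8, 8), bool), 10.0, 5.0)
        assert np.sum(cmap.labels == M) == 0

    def test_partition_is_total(self, small_scene):
        spec = small_scene.spec
        trans = small_scene.images.trans
        cmap = classify_pixels(trans, small_scene.instances == 0,
                               spec.background_level + spec.nucleus_lift,
                               spec.background_level)
        assert np.isin(cmap.labels, (B, C, M, X)).all()


# ---------------------------------------------------------------------------
# smooth_classes

class TestSmoothClasses:
    def test_isolated_pixel_removed(self):
        labels = np.full((9, 9), C, dtype=np.uint8)
        labels[4, 4] = M
        out = smooth_classes(cmap_from(labels), 1)
        assert out.labels[4, 4] != M

    def test_solid_block_unchanged(self):
        labels = np.full((24, 24), B, dtype=np.uint8)
        labels[2:22, 2:22] = C
        out = smooth_classes(cmap_from(labels), 1)
        np.testing.assert_array_equal(out.labels[4:20, 4:20], C)

    def test_one_pixel_spur_removed(self):
        labels = np.full((20, 20), B, dtype=np.uint8)
        labels[5:15, 5:12] = C
        labels[9, 12:18] = C            # 1-px-wide spur
        out = smooth_classes(cmap_from(labels), 1)
        assert np.all(out.labels[9, 14:18] != C)


# ---------------------------------------------------------------------------
# resolve_ambiguous

def brute_force_resolve_steps(labels):
    """Independent trace of the distance-transform region growing, with
    explicit O(N^2) distance computation and scalar rule application."""
    labels = np.asarray(labels, dtype=np.uint8).copy()
    h, w = labels.shape

    def dist_to(cls):
        pts = np.argwhere(labels == cls)
        d = np.full((h, w), np.inf)
        for r in range(h):
            for c in range(w):
                for pr, pc in pts:
                    d[r, c] = min(d[r, c],
                                  np.hypot(r - pr, c - pc))
        return d

    steps = []
    while True:
        amb = np.argwhere(labels == X)
        if len(amb) == 0:
            break
        d_b, d_c, d_m = dist_to(B), dist_to(C), dist_to(M)
        changed = False
        new = labels.copy()
        for r, c in amb:
            if d_b[r, c] <= d_c[r, c] and d_b[r, c] < d_m[r, c]:
                new[r, c] = B
                changed = True
            elif d_c[r, c] < d_b[r, c] and d_c[r, c] < d_m[r, c]:
                new[r, c] = C
                changed = True
        if not changed:
            break
        labels = new
        steps.append(labels.copy())
    labels[labels == X] = M
    steps.append(labels.copy())
    return steps


def worked_15x15_instance():
    """B frame, membrane square ring, interior seed, ambiguous elsewhere."""
    labels = np.full((15, 15), X, dtype=np.uint8)
    labels[0:2, :] = B
    labels[-2:, :] = B
    labels[:, 0:2] = B
    labels[:, -2:] = B
    labels[5, 5:10] = M
    labels[9, 5:10] = M
    labels[5:10, 5] = M
    labels[5:10, 9] = M
    labels[7, 7] = C
    return labels


class TestResolveAmbiguous:
    def test_rule_application(self):
        # X at distance 1 from C, far from B and M -> C
        labels = np.full((7, 7), X, dtype=np.uint8)
        labels[3, 2] = C
        labels[0, 0] = B
        labels[6, 6] = M
        out = resolve_ambiguous(cmap_from(labels))
        assert out.labels[3, 3] == C

    def test_tie_between_background_and_interior_goes_to_background(self):
        labels = np.full((3, 5), X, dtype=np.uint8)
        labels[1, 0] = B
        labels[1, 4] = C
        out = resolve_ambiguous(cmap_from(labels))
        assert out.labels[1, 2] == B   # equidistant: tie -> background

    def test_matches_brute_force_trace_step_for_step(self):
        start = worked_15x15_instance()
        result, steps = resolve_ambiguous(cmap_from(start), record_steps=True)
        oracle_steps = brute_force_resolve_steps(start)
        assert len(steps) == len(oracle_steps)
        for got, want in zip(steps, oracle_steps):
            np.testing.assert_array_equal(got, want)
        assert result.n_ambiguous == 0

    def test_membrane_enclosed_corridor_exits_as_membrane(self):
        start = worked_15x15_instance()
        result = resolve_ambiguous(cmap_from(start))
        # pixels adjacent to the ring on the outside are nearer membrane
        # than either grown region and must end as membrane
        assert result.labels[4, 7] == M

    def test_only_ambiguous_pixels_relabelled(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([B, C, M, X], size=(40, 40),
                            p=[0.3, 0.2, 0.2, 0.3]).astype(np.uint8)
        out = resolve_ambiguous(cmap_from(labels))
        fixed = labels != X
        np.testing.assert_array_equal(out.labels[fixed], labels[fixed])
        assert out.n_ambiguous == 0

    def test_no_ambiguous_is_identity(self):
        labels = np.full((10, 10), B, dtype=np.uint8)
        labels[4:6, 4:6] = C
        out = resolve_ambiguous(cmap_from(labels))
        np.testing.assert_array_equal(out.labels, labels)


# ---------------------------------------------------------------------------
# initial_contours / membrane_edge_map

class TestInitialContours:
    def test_disk_traced_within_one_pixel(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (xx - 32) ** 2 + (yy - 32) ** 2 <= 20 ** 2
        labels = np.where(disk, C, B).astype(np.uint8)
        contours = initial_contours(cmap_from(labels), min_area=50)
        assert len(contours) == 1
        r = np.hypot(contours[0].x - 32, contours[0].y - 32)
        assert np.abs(r - 20).max() <= 1.0

    def test_two_components_two_contours(self):
        labels = np.full((50, 50), B, dtype=np.uint8)
        labels[5:15, 5:15] = C
        labels[30:40, 30:40] = C
        assert len(initial_contours(cmap_from(labels), min_area=50)) == 2

    def test_min_area_filter_boundary(self):
        labels = np.full((30, 30), B, dtype=np.uint8)
        labels[5:12, 5:12] = C          # 49 px^2
        assert initial_contours(cmap_from(labels), min_area=50) == []
        assert len(initial_contours(cmap_from(labels), min_area=49)) == 1

    def test_empty_interior_empty_list(self):
        labels = np.full((20, 20), B, dtype=np.uint8)
        assert initial_contours(cmap_from(labels)) == []


class TestMembraneEdgeMap:
    def test_empty_membrane_zero_map(self):
        f = membrane_edge_map(cmap_from(np.full((16, 16), B, np.uint8)))
        np.testing.assert_array_equal(f, 0.0)

    def test_single_pixel_unique_maximum(self):
        labels = np.full((17, 17), B, dtype=np.uint8)
        labels[8, 8] = M
        f = membrane_edge_map(cmap_from(labels))
        assert np.unravel_index(np.argmax(f), f.shape) == (8, 8)
        assert f.max() == pytest.approx(1.0)

    def test_normalised_to_unit_maximum(self, small_scene):
        f = membrane_edge_map(small_scene.class_map)
        assert f.max() == pytest.approx(1.0)
        assert f.min() >= 0.0
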