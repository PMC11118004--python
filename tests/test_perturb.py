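"""Perturbation operators and the target-IoU corruption procedure."""

import numpy as np
import pytest
from scipy import ndimage

from glottisqc import PerturbationConfig, compute_iou, perturb_pairs, perturb_to_target
from glottisqc import data
from glottisqc.perturb import (
    break_mask,
    build_perturbed_dataset,
    copy_mask,
    dilate_mask,
    erode_mask,
    insert_ellipse,
    rotate_mask,
    sample_target_iou,
)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestRotate:
    def test_zero_angle_is_identity(self):
        m = disk_mask((32, 32), (16, 16), 5)
        np.testing.assert_array_equal(rotate_mask(m, 0.0), m)

    def test_empty_mask_passes_through(self):
        m = np.zeros((16, 16), dtype=bool)
        np.testing.assert_array_equal(rotate_mask(m, 45.0), m)

    @pytest.mark.parametrize("angle", [30.0, 90.0, 137.0])
    def test_disk_is_rotation_invariant(self, angle):
        m = disk_mask((64, 64), (32, 32), 12)
        assert compute_iou(rotate_mask(m, angle), m) >= 0.95

    def test_bar_rotation_matches_coordinate_oracle(self):
        """Rotating a 3x21 bar 90 deg about its centroid, compared against
        an explicit pixel-coordinate rotation of the same mask."""
        m = np.zeros((31, 31), dtype=bool)
        m[14:17, 5:26] = True  # centroid at (15, 15)
        got = rotate_mask(m, 90.0)
        cy, cx = ndimage.center_of_mass(m)
        oracle = np.zeros_like(m)
        for r, c in zip(*np.nonzero(m)):
            # inverse nearest-neighbour map: for binary blocks, forward
            # rotation of each pixel center by -90 deg lands on grid points
            rr = round(cy + (c - cx))
            cc = round(cx - (r - cy))
            if 0 <= rr < 31 and 0 <= cc < 31:
                oracle[rr, cc] = True
        assert compute_iou(got, m) == compute_iou(oracle, m)


class TestDilateErode:
    def test_dilate_empty_stays_empty(self):
        m = np.zeros((8, 8), dtype=bool)
        assert not dilate_mask(m, 3).any()

    def test_single_pixel_square_dilation_is_block(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        out = dilate_mask(m, 3, element="square")
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_dilation_never_shrinks(self, phantom_pairs_64):
        for _, m in phantom_pairs_64[:10]:
            assert dilate_mask(m, 5).sum() >= m.sum()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            dilate_mask(np.ones((4, 4), bool), 4)

    def test_block_erodes_to_center_pixel(self):
        m = np.zeros((7, 7), dtype=bool)
        m[2:5, 2:5] = True
        out = erode_mask(m, 3, element="square")
        assert out.sum() == 1 and out[3, 3]

    def test_single_pixel_erodes_to_empty(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        assert not erode_mask(m, 3).any()

    def test_closing_covers_original_on_convex_masks(self):
        for radius in (4, 7):
            m = disk_mask((40, 40), (20, 20), radius)
            closed = erode_mask(dilate_mask(m, 5), 5)
            assert (m & ~closed).sum() == 0


class TestBreak:
    def test_output_is_subset_of_input(self, phantom_pairs_64):
        rng = np.random.default_rng(0)
        for _, m in phantom_pairs_64[:10]:
            out = break_mask(m, 3, (2.0, 6.0), rng)
            assert not (out & ~m).any()

    def test_huge_blob_can_empty_the_mask(self):
        m = disk_mask((32, 32), (16, 16), 6)
        out = break_mask(m, 1, (100.0, 100.0), np.random.default_rng(1))
        assert not out.any()

    def test_area_loss_equals_mask_blob_intersection(self):
        m = disk_mask((32, 32), (16, 16), 8)
        rng = np.random.default_rng(2)
        out = break_mask(m, 2, (3.0, 5.0), rng)
        removed = (m & ~out).sum()
        assert out.sum() == m.sum() - removed

    def test_empty_mask_passes_through(self):
        m = np.zeros((8, 8), dtype=bool)
        assert not break_mask(m, 2, (1.0, 2.0), np.random.default_rng(0)).any()


class TestCopy:
    def test_identity_offset_and_scale(self):
        m = disk_mask((32, 32), (16, 16), 5)
        np.testing.assert_array_equal(copy_mask(m, (0, 0), 1.0), m)

    def test_disjoint_copy_doubles_area_and_halves_iou(self):
        m = np.zeros((40, 40), dtype=bool)
        m[4:10, 4:10] = True
        out = copy_mask(m, (20, 20), 1.0)
        assert out.sum() == 2 * m.sum()
        assert compute_iou(m, out) == pytest.approx(0.5)

    def test_half_scale_disjoint_copy_area(self):
        m = np.zeros((64, 64), dtype=bool)
        m[2:22, 2:22] = True  # 20x20 block
        out = copy_mask(m, (30, 30), 0.5)
        assert out.sum() == pytest.approx(1.25 * m.sum(), rel=0.02)

    def test_copy_never_shrinks_in_union_mode(self, phantom_pairs_64):
        rng = np.random.default_rng(3)
        for _, m in phantom_pairs_64[:10]:
            out = copy_mask(m, (rng.integers(-20, 20), rng.integers(-20, 20)), 1.2)
            assert out.sum() >= m.sum()


class TestEllipse:
    def test_subset_ellipse_is_identity(self):
        m = disk_mask((32, 32), (16, 16), 10)
        out = insert_ellipse(m, (16, 16), (3, 3), 0.0)
        np.testing.assert_array_equal(out, m)

    def test_disjoint_ellipse_adds_exact_area(self):
        m = np.zeros((64, 64), dtype=bool)
        m[2:8, 2:8] = True
        lone = insert_ellipse(np.zeros_like(m), (45, 45), (6, 4), 30.0)
        out = insert_ellipse(m, (45, 45), (6, 4), 30.0)
        assert out.sum() == m.sum() + lone.sum()

    def test_candidate_on_empty_gt_scores_zero(self):
        gt = np.zeros((32, 32), dtype=bool)
        cand = insert_ellipse(gt, (16, 16), (5, 3), 0.0)
        assert compute_iou(cand, gt) == 0.0

    def test_off_grid_ellipse_rejected(self):
        with pytest.raises(ValueError, match="off the grid"):
            insert_ellipse(np.zeros((16, 16), bool), (100, 100), (2, 2), 0.0)


class TestTargetSampling:
    def test_degenerate_bin_probability_forces_first_bin(self):
        cfg = PerturbationConfig(bin_probabilities=(1, 0, 0, 0, 0, 0))
        rng = np.random.default_rng(0)
        draws = [sample_target_iou(cfg, rng) for _ in range(200)]
        assert all(0.0 <= d < 0.1 for d in draws)

    def test_uniform_bins_frequencies_within_3_sigma(self):
        cfg = PerturbationConfig(bin_probabilities=(1 / 6,) * 6)
        rng = np.random.default_rng(1)
        n = 6000
        draws = np.array([sample_target_iou(cfg, rng) for _ in range(n)])
        counts, _ = np.histogram(draws, bins=np.asarray(cfg.bin_edges))
        sigma = np.sqrt(n * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - n / 6) <= 3 * sigma)

    def test_all_draws_in_unit_interval(self):
        cfg = PerturbationConfig()
        rng = np.random.default_rng(2)
        assert all(0 <= sample_target_iou(cfg, rng) <= 1 for _ in range(500))

    def test_bad_bin_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PerturbationConfig(bin_probabilities=(0.5, 0.5, 0.5, 0, 0, 0))
        with pytest.raises(ValueError, match="ascending"):
            PerturbationConfig(bin_edges=(0, 0.1, 0.1, 0.5, 0.7, 0.9, 1.0))


class TestProcedure:
    def test_target_one_returns_pristine_mask(self, phantom_pairs_64):
        _, gt = phantom_pairs_64[0]
        cfg = PerturbationConfig()
        cand, iou = perturb_to_target(gt, 1.0, cfg, np.random.default_rng(0))
        assert iou == 1.0
        np.testing.assert_array_equal(cand, gt)

    def test_empty_gt_target_zero_reaches_zero(self):
        gt = np.zeros((64, 64), dtype=bool)
        cfg = PerturbationConfig()
        cand, iou = perturb_to_target(gt, 0.0, cfg, np.random.default_rng(1))
        assert iou == 0.0 and cand.any()

    def test_labels_always_equal_recomputed_iou(self, phantom_pairs_64):
        cfg = PerturbationConfig()
        rng = np.random.default_rng(2)
        samples = perturb_pairs(phantom_pairs_64[:12], cfg, rng, samples_per_pair=2)
        for s in samples:
            assert s.iou == compute_iou(s.candidate_mask, s.gt_mask)

    def test_area_monotonicity_per_operator(self, phantom_pairs_64):
        from glottisqc.perturb import GROWING_OPS, SHRINKING_OPS

        cfg = PerturbationConfig()
        rng = np.random.default_rng(3)
        log = []
        for _, gt in phantom_pairs_64[:8]:
            perturb_to_target(gt, sample_target_iou(cfg, rng), cfg, rng, log=log)
        assert log, "procedure applied no operators"
        for name, before, after in log:
            if name in SHRINKING_OPS:
                assert after <= before
            elif name in GROWING_OPS:
                assert after >= before

    def test_zero_probabilities_leave_masks_pristine(self, phantom_pairs_64):
        cfg = PerturbationConfig(
            op_probabilities={k: 0.0 for k in ("rotate", "dilate", "erode", "break", "copy", "ellipse")}
        )
        samples = perturb_pairs(phantom_pairs_64[:5], cfg, np.random.default_rng(4))
        assert all(s.iou == 1.0 for s in samples)

    def test_procedure_deterministic_under_fixed_seed(self, phantom_pairs_64):
        cfg = PerturbationConfig()
        s1 = perturb_pairs(phantom_pairs_64[:6], cfg, np.random.default_rng(7))
        s2 = perturb_pairs(phantom_pairs_64[:6], cfg, np.random.default_rng(7))
        for a, b in zip(s1, s2):
            assert a.iou == b.iou
            np.testing.assert_array_equal(a.candidate_mask, b.candidate_mask)

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            perturb_pairs([], PerturbationConfig(), np.random.default_rng(0))


class TestDatasetRoundTrip:
    def test_build_and_reload_validates_labels(self, tmp_path):
        from glottisqc import GlottisPhantomParams, generate_dataset

        params = GlottisPhantomParams(image_size=48, seed=5, closed_probability=0.0)
        pair_manifest = generate_dataset(4, params, tmp_path / "pairs")
        cfg = PerturbationConfig()
        scored = build_perturbed_dataset(
            pair_manifest, cfg, np.random.default_rng(5), tmp_path / "scored",
            samples_per_pair=2,
        )
        assert len(scored) == 8
        # load_scored_samples re-validates every stored IoU on construction
        samples = data.load_scored_samples(tmp_path / "scored" / "manifest.csv")
        assert len(samples) == 8

    def test_config_json_round_trip(self, tmp_path):
        cfg = PerturbationConfig(target_tolerance=0.03, max_restarts=2)
        cfg.to_json(tmp_path / "cfg.json")
        back = PerturbationConfig.from_json(tmp_path / "cfg.json")
        assert back == cfg
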