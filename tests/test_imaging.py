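"""Syt2 coverage quantification and the axon segmentation pipeline."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from sklearn.metrics import adjusted_rand_score

from pupdyn import (
    PhantomDesign,
    cluster_branches,
    generate_axon_movie,
    generate_syt2_image,
    skeletonize_axons,
    syt2_coverage,
    threshold_max_entropy,
    validate_branches,
)

warnings.filterwarnings("ignore", category=FutureWarning)

BG_ROI = (slice(0, 6), slice(0, 6))


class TestSyt2Coverage:
    def test_blank_image_zero(self):
        stack = np.zeros((8, 40, 40))
        res = syt2_coverage(stack, 0.5, BG_ROI)
        assert res.coverage_percent == 0.0 and res.n_particles == 0

    def test_one_square_micron_in_100_field(self):
        """A single 1 µm² particle in a 100 µm² field is 1% coverage."""
        stack = np.zeros((8, 20, 20))  # 0.5 µm px -> 100 µm² field
        stack[0, 10:12, 10:12] = 5.0   # 2x2 px = 1 µm²
        res = syt2_coverage(stack, 0.5, BG_ROI, rolling_ball_radius_px=5)
        assert res.coverage_percent == pytest.approx(1.0)
        assert res.n_particles == 1

    def test_size_filter_exact(self):
        """Particles of 0.2 and 6 µm² are rejected; 1 µm² is kept."""
        stack, truth = generate_syt2_image(
            PhantomDesign(shape=(64, 64), particle_areas_um2=[0.2, 1.0, 6.0],
                          noise_sd=0.0, seed=1)
        )
        res = syt2_coverage(stack, 0.156, BG_ROI)
        assert res.n_particles == 1
        assert np.all((res.particle_areas_um2 >= 0.4) & (res.particle_areas_um2 <= 4.0))

    def test_phantom_coverage_within_10_percent(self):
        stack, truth = generate_syt2_image(
            PhantomDesign(shape=(96, 96), particle_areas_um2=[1.0, 0.6, 2.0, 1.5, 0.8],
                          noise_sd=0.05, seed=2)
        )
        res = syt2_coverage(stack, 0.156, BG_ROI)
        assert res.coverage_percent == pytest.approx(truth["coverage_percent"], rel=0.10)

    def test_intensity_scaling_invariance(self):
        stack, _ = generate_syt2_image(
            PhantomDesign(shape=(64, 64), particle_areas_um2=[1.0, 2.0], noise_sd=0.02, seed=3)
        )
        r1 = syt2_coverage(stack, 0.156, BG_ROI)
        r2 = syt2_coverage(stack * 7.3, 0.156, BG_ROI)
        assert r1.coverage_percent == pytest.approx(r2.coverage_percent)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            syt2_coverage(np.zeros((8, 20, 20)), 0.5, (slice(0, 0), slice(0, 0)))

    def test_max_entropy_threshold_separates_bimodal(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.1, 0.02, (64, 64))
        fg = np.zeros((64, 64), bool)
        fg[20:30, 20:30] = True
        img[fg] = rng.normal(0.9, 0.02, int(fg.sum()))
        thr = threshold_max_entropy(img)
        assert (img[fg] > thr).all()
        assert (img[~fg] > thr).mean() < 0.05


class TestSkeletonizeAxons:
    def test_straight_branch_recovered(self):
        """A single straight branch gives one skeleton branch overlapping the
        ground-truth centerline (Dice > 0.7 after 1-px dilation)."""
        movie, truth = generate_axon_movie(
            PhantomDesign(shape=(100, 64, 64), branches=[[(10, 5), (10, 58)]],
                          noise_sd=0.02, seed=4)
        )
        bs = skeletonize_axons(movie)
        assert len(bs.branches) == 1
        mask = np.zeros((64, 64), bool)
        mask[bs.branches[0][:, 0], bs.branches[0][:, 1]] = True
        a = binary_dilation(mask)
        b = binary_dilation(truth["masks"][0])
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.7

    def test_y_shape_splits_into_three(self):
        ybr = [[(10, 32), (32, 32)], [(32, 32), (54, 16)], [(32, 32), (54, 48)]]
        movie, _ = generate_axon_movie(
            PhantomDesign(shape=(100, 64, 64), branches=ybr, noise_sd=0.01, seed=5)
        )
        assert len(skeletonize_axons(movie).branches) == 3

    def test_noise_only_movie_no_branches(self):
        movie, _ = generate_axon_movie(
            PhantomDesign(shape=(50, 64, 64), branches=[], noise_sd=0.05, seed=6)
        )
        assert len(skeletonize_axons(movie).branches) == 0

    def test_short_movie_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_axons(np.zeros((5, 32, 32)))


class TestValidateBranches:
    def test_uniform_branch_kept(self):
        movie, _ = generate_axon_movie(
            PhantomDesign(shape=(100, 64, 64), branches=[[(10, 5), (10, 58)]],
                          noise_sd=0.02, seed=7)
        )
        bs = skeletonize_axons(movie)
        assert validate_branches(movie, bs.branches).all()

    def test_partially_lit_branch_rejected(self):
        """A branch bright on only a fifth of its length has a strongly
        skewed pixel distribution and fails the uniformity test."""
        n_px = 45
        coords = np.array([(10, x + 5) for x in range(n_px)])
        movie = np.full((20, 64, 64), 0.05)
        movie[:, 10, 5 : 5 + 9] = 1.0  # only the first fifth illuminates
        from scipy.stats import skew

        pixels = movie[0, coords[:, 0], coords[:, 1]]
        assert abs(skew(pixels)) > 1.0  # construction check
        flags = validate_branches(movie, [coords], skew_max=1.0)
        assert not flags[0]

    def test_constant_branch_kept_by_convention(self):
        coords = np.array([(10, x) for x in range(5, 40)])
        movie = np.full((20, 64, 64), 0.5)
        assert validate_branches(movie, [coords])[0]

    def test_short_branch_auto_rejected(self):
        coords = np.array([(10, 5), (10, 6), (10, 7)])
        movie = np.full((20, 64, 64), 0.5)
        assert not validate_branches(movie, [coords])[0]


class TestClusterBranches:
    def test_two_groups_recovered_exactly(self):
        rng = np.random.default_rng(8)
        t1, t2 = rng.random(200), rng.random(200)
        traces = np.stack(
            [t1 + 0.02 * rng.standard_normal(200) for _ in range(4)]
            + [t2 + 0.02 * rng.standard_normal(200) for _ in range(4)]
        )
        labels = cluster_branches(traces, seed=0)
        assert adjusted_rand_score([0] * 4 + [1] * 4, labels) == 1.0

    def test_identical_traces_single_cluster(self):
        t = np.random.default_rng(9).random(100)
        traces = np.stack([t + 1e-3 * np.random.default_rng(i).random(100) for i in range(5)])
        labels = cluster_branches(traces, seed=0)
        assert len(set(labels)) == 1

    def test_constant_traces_all_singletons(self):
        traces = np.ones((4, 50))
        labels = cluster_branches(traces, seed=0)
        assert len(set(labels)) == 4

    def test_seed_reproducibility_up_to_permutation(self):
        rng = np.random.default_rng(10)
        t1, t2 = rng.random(150), rng.random(150)
        traces = np.stack(
            [t1 + 0.05 * rng.standard_normal(150) for _ in range(5)]
            + [t2 + 0.05 * rng.standard_normal(150) for _ in range(5)]
        )
        l1 = cluster_branches(traces, seed=3)
        l2 = cluster_branches(traces, seed=3)
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_branches(np.ones((1, 50)))
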