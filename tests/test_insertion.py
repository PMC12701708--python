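"""Quadrant logic, interior-mask erosion and the three insertion modes."""

import numpy as np
import pytest
from scipy import stats

from breastvit.insertion import (
    QUADRANTS,
    InsertionPolicy,
    auto_insert,
    interior_mask,
    manual_insert,
    quadrant_labels,
    sample_center,
    sample_quadrant,
    semi_auto_insert,
)
from breastvit.lesion import generate_lesion
from breastvit.phantom import (
    ADIPOSE_INDEX,
    AIR_INDEX,
    DEFAULT_MATERIALS,
    LESION_INDEX,
    Phantom,
)


def ball_phantom(n=40, r_frac=0.45, index=6):
    """Cube-grid phantom with a centered ball breast of uniform composition."""
    vox = np.full((n, n, n), AIR_INDEX, dtype=np.uint8)
    c = (n - 1) / 2
    xs = np.arange(n)
    r2 = ((xs - c) ** 2)[:, None, None] + ((xs - c) ** 2)[None, :, None] + ((xs - c) ** 2)[None, None, :]
    mask = r2 <= (r_frac * n) ** 2
    vox[mask] = index
    return Phantom(voxels=vox, material_table=dict(DEFAULT_MATERIALS), breast_mask=mask, voxel_mm=1.0)


NIPPLE = (20, 20, 20)  # center voxel of the 40-cube ball


class TestQuadrants:
    def test_partition_covers_breast_exactly_once(self):
        ph = ball_phantom()
        labels = quadrant_labels(ph, NIPPLE)
        assert ((labels >= 0) == ph.breast_mask).all()

    def test_symmetric_mask_gives_equal_counts(self):
        ph = ball_phantom()
        labels = quadrant_labels(ph, NIPPLE)
        counts = np.array([(labels == k).sum() for k in range(4)])
        assert counts.max() - counts.min() <= 0.02 * counts.sum()

    def test_laterality_mirror_swaps_outer_inner_exactly(self):
        ph = ball_phantom()
        left = quadrant_labels(ph, NIPPLE, laterality="L")
        right = quadrant_labels(ph, NIPPLE, laterality="R")
        for a, b in ((0, 1), (2, 3)):  # UO<->UI, LO<->LI
            assert (left == a).sum() == (right == b).sum()
            assert (left == b).sum() == (right == a).sum()

    def test_nipple_outside_mask_rejected(self):
        ph = ball_phantom()
        with pytest.raises(ValueError, match="outside"):
            quadrant_labels(ph, (0, 0, 0))


class TestSampleQuadrant:
    def test_degenerate_policy(self, rng):
        policy = InsertionPolicy(quadrant_probs={"UO": 1.0, "UI": 0.0, "LO": 0.0, "LI": 0.0})
        assert all(sample_quadrant(policy, rng) == "UO" for _ in range(20))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            InsertionPolicy(quadrant_probs={q: 0.0 for q in QUADRANTS})

    def test_published_frequencies_renormalized(self):
        """Raw 58.5/15.7/8.4/9.9 renormalize over 92.5; UO frequency -> 0.6324."""
        policy = InsertionPolicy()
        p = policy.normalized_probs()
        assert p.sum() == pytest.approx(1.0)
        assert p[0] == pytest.approx(0.585 / 0.925, abs=1e-12)
        rng = np.random.default_rng(123)
        draws = rng.choice(4, size=100_000, p=p)
        freq = np.bincount(draws, minlength=4) / draws.size
        assert freq[0] == pytest.approx(0.6324, abs=0.01)
        # empirical ordering matches the published ordering UO > UI > LI > LO
        assert freq[0] > freq[1] > freq[3] > freq[2]


class TestInteriorMask:
    def test_full_fraction_is_identity(self):
        ph = ball_phantom()
        assert (interior_mask(ph.breast_mask, 1.0) == ph.breast_mask).all()

    def test_ninety_percent_erosion_on_ball(self):
        ph = ball_phantom(n=50)
        inner = interior_mask(ph.breast_mask, 0.9)
        ratio = inner.sum() / ph.breast_mask.sum()
        assert 0.88 <= ratio <= 0.90
        assert not np.any(inner & ~ph.breast_mask)

    def test_eroded_voxels_strictly_interior(self):
        ph = ball_phantom(n=40)
        inner = interior_mask(ph.breast_mask, 0.9)
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            shifted = np.roll(ph.breast_mask, (dx, dy, dz), axis=(0, 1, 2))
            assert np.all(shifted[inner])

    def test_degenerate_fractions_rejected(self):
        ph = ball_phantom(n=20)
        with pytest.raises(ValueError):
            interior_mask(ph.breast_mask, 0.0)
        with pytest.raises(ValueError):
            interior_mask(np.zeros((5, 5, 5), bool), 0.9)


class TestAutoInsert:
    def test_support_restriction(self, rng):
        """With glandular weight only in one octant (and no floor), centers land there."""
        ph = ball_phantom(index=ADIPOSE_INDEX)
        ph.voxels[20:, 20:, 20:][ph.breast_mask[20:, 20:, 20:]] = 11
        policy = InsertionPolicy(weight_floor=0.0,
                                 quadrant_probs={"UO": 1.0, "UI": 0.0, "LO": 0.0, "LI": 0.0})
        labels = quadrant_labels(ph, NIPPLE)
        inner = interior_mask(ph.breast_mask, policy.interior_fraction)
        for _ in range(50):
            (x, y, z), q = sample_center(ph, policy, NIPPLE, rng, labels=labels, interior=inner)
            assert q == "UO" and x >= 20 and z >= 20

    def test_uniform_density_gives_uniform_centers(self, rng):
        """Chi-square on octant bins of centers drawn in a uniform phantom."""
        ph = ball_phantom(index=6)
        policy = InsertionPolicy(quadrant_probs={"UO": 1.0, "UI": 0.0, "LO": 0.0, "LI": 0.0})
        labels = quadrant_labels(ph, NIPPLE)
        inner = interior_mask(ph.breast_mask, policy.interior_fraction)
        admissible = inner & (labels == 0)
        # bin admissible voxels by (x<30, y<20, z<30) octants within the quadrant
        draws = np.array([
            sample_center(ph, policy, NIPPLE, rng, labels=labels, interior=inner)[0]
            for _ in range(2000)
        ])
        xs, ys, zs = np.nonzero(admissible)
        def binify(x, y, z):
            return (np.asarray(x) >= 30) * 4 + (np.asarray(y) >= 20) * 2 + (np.asarray(z) >= 30)
        expected = np.bincount(binify(xs, ys, zs), minlength=8) / xs.size
        observed = np.bincount(binify(*draws.T), minlength=8)
        keep = expected > 0
        p = stats.chisquare(observed[keep], 2000 * expected[keep] / expected[keep].sum()).pvalue
        assert p > 1e-3

    def test_density_proportional_sampling(self, rng):
        """Two-region quadrant with w 0.8 vs 0.2 draws centers ~4:1."""
        ph = ball_phantom(index=3)  # w = 0.2 everywhere
        ph.voxels[20:, :, :][ph.breast_mask[20:, :, :]] = 9  # w = 0.8 on x >= 20
        policy = InsertionPolicy(weight_floor=0.0,
                                 quadrant_probs={"UO": 1.0, "UI": 0.0, "LO": 0.0, "LI": 0.0})
        labels = quadrant_labels(ph, (20, 20, 20))
        inner = interior_mask(ph.breast_mask, policy.interior_fraction)
        admissible = inner & (labels == 0)
        n_hi = (admissible & (np.arange(40)[:, None, None] >= 20)).sum()
        n_lo = admissible.sum() - n_hi
        draws = np.array([
            sample_center(ph, policy, (20, 20, 20), rng, labels=labels, interior=inner)[0][0]
            for _ in range(4000)
        ])
        hi = (draws >= 20).sum()
        expect_hi = 0.8 * n_hi / (0.8 * n_hi + 0.2 * n_lo)
        se = np.sqrt(expect_hi * (1 - expect_hi) / 4000)
        assert hi / 4000 == pytest.approx(expect_hi, abs=4 * se)

    def test_insert_writes_lesion_and_reports_quadrant(self):
        ph = ball_phantom()
        les = generate_lesion(4.0, 1, seed=2, voxel_mm=1.0)
        res = auto_insert(ph, les, InsertionPolicy(), NIPPLE, seed=1)
        assert res.quadrant in QUADRANTS
        assert (res.phantom.voxels == LESION_INDEX).sum() == les.voxel_count()
        # no lesion voxel outside the breast
        assert not np.any((res.phantom.voxels == LESION_INDEX) & ~ph.breast_mask)

    def test_untouched_voxels_bitwise_identical(self):
        ph = ball_phantom()
        les = generate_lesion(4.0, 1, seed=2, voxel_mm=1.0)
        res = auto_insert(ph, les, InsertionPolicy(), NIPPLE, seed=3)
        changed = res.phantom.voxels != ph.voxels
        assert changed.sum() <= les.voxel_count()

    def test_impossible_quadrant_errors_after_retries(self):
        ph = ball_phantom()
        les = generate_lesion(4.0, 1, seed=2, voxel_mm=1.0)
        # demand a quadrant then erode it away with an enormous lesion
        big = generate_lesion(60.0, 1, seed=2, voxel_mm=1.0)
        with pytest.raises(ValueError, match="failed after"):
            auto_insert(ph, big, InsertionPolicy(), NIPPLE, seed=1)


class TestManualAndSemiAuto:
    def test_manual_center_conservation(self):
        ph = ball_phantom()
        les = generate_lesion(5.0, 1, seed=1, voxel_mm=1.0)
        res = manual_insert(ph, les, NIPPLE, nipple=NIPPLE)
        assert (res.phantom.voxels == LESION_INDEX).sum() == les.voxel_count()

    def test_subcutaneous_center_rejected(self):
        ph = ball_phantom()
        les = generate_lesion(4.0, 1, seed=1, voxel_mm=1.0)
        surface = (20, 20, 37)  # on the ball surface
        with pytest.raises(ValueError, match="interior mask"):
            manual_insert(ph, les, surface)

    def test_reinsert_same_center_idempotent_for_method_1(self):
        ph = ball_phantom()
        les = generate_lesion(5.0, 1, seed=1, voxel_mm=1.0)
        once = manual_insert(ph, les, NIPPLE).phantom
        twice = manual_insert(once, les, NIPPLE).phantom
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_all_axes_fixed_equals_manual(self):
        ph = ball_phantom()
        les = generate_lesion(4.0, 1, seed=1, voxel_mm=1.0)
        semi = semi_auto_insert(ph, les, {"x": 20, "y": 20, "z": 20}, seed=0)
        manual = manual_insert(ph, les, (20, 20, 20))
        np.testing.assert_array_equal(semi.phantom.voxels, manual.phantom.voxels)
        assert semi.center == (20, 20, 20)

    def test_fixed_depth_holds_z(self):
        ph = ball_phantom(n=30)
        les = generate_lesion(3.0, 1, seed=1, voxel_mm=1.0)
        deep = {"x": (10, 19), "y": (10, 19)}  # keep the lesion body clear of the surface
        centers = [
            semi_auto_insert(ph, les, {"z": 15}, ranges=deep, seed=s).center
            for s in range(30)
        ]
        assert all(c[2] == 15 for c in centers)
        assert len({c[:2] for c in centers}) > 1

    def test_free_axes_uniform(self):
        """Free x over many draws matches the admissible-voxel distribution."""
        ph = ball_phantom(n=30)
        les = generate_lesion(3.0, 1, seed=1, voxel_mm=1.0)
        lo, hi = 9, 20  # interior x-range with full clearance for the lesion body
        admissible_x = np.arange(lo, hi + 1)
        rng = np.random.default_rng(0)
        xs = np.array([
            semi_auto_insert(
                ph, les, {"y": 15, "z": 15}, ranges={"x": (lo, hi)}, seed=rng
            ).center[0]
            for _ in range(400)
        ])
        counts = np.array([(xs == x).sum() for x in admissible_x])
        assert counts.sum() == 400  # every draw lands on an admissible voxel
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_empty_admissible_set_rejected(self):
        ph = ball_phantom(n=30)
        les = generate_lesion(3.0, 1, seed=1, voxel_mm=1.0)
        with pytest.raises(ValueError, match="admissible"):
            semi_auto_insert(ph, les, {"x": 0, "y": 0, "z": 0})
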