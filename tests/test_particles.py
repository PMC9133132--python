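"""Particle detection, association, distances and averaged anchored crops."""

from collections import deque

import numpy as np
import pytest

from polpause.particles import (
    ChannelImage,
    ParticleSet,
    Particle,
    associate,
    associate_by_distance,
    average_anchored_image,
    center_distances,
    detect_particles,
)


def flood_fill_oracle(mask):
    """Independent BFS 8-connected labeling; returns {label: set of pixels}."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < mask.shape[0]
                                and 0 <= nx < mask.shape[1]
                                and mask[ny, nx]
                                and not seen[ny, nx]
                            ):
                                seen[ny, nx] = True
                                q.append((ny, nx))
                comps.append(comp)
    return comps


def image(arr, **kw):
    return ChannelImage(np.asarray(arr, float), **kw)


def square_image(size=30, lo=10, hi=15, value=100.0):
    arr = np.zeros((size, size))
    arr[lo:hi, lo:hi] = value
    return arr


class TestDetection:
    def test_blank_image_yields_no_particles(self):
        assert len(detect_particles(image(np.zeros((20, 20))), threshold=1.0)) == 0

    def test_uniform_square_area_and_centroid(self):
        ps = detect_particles(image(square_image()), threshold=50.0)
        assert len(ps) == 1
        p = ps.particles[0]
        assert p.area == 25
        assert p.centroid == pytest.approx((12.0, 12.0))
        assert p.mean_intensity == pytest.approx(100.0)
        assert p.total_intensity == pytest.approx(2500.0)

    def test_sub_threshold_gap_separates_particles(self):
        arr = np.zeros((20, 20))
        arr[5:8, 5:8] = 100
        arr[5:8, 9:12] = 100  # one sub-threshold column between
        assert len(detect_particles(image(arr), threshold=50.0)) == 2

    def test_diagonal_touch_is_one_particle(self):
        arr = np.zeros((10, 10))
        arr[2, 2] = arr[3, 3] = 100
        assert len(detect_particles(image(arr), threshold=50.0, min_area=1)) == 1

    def test_min_area_filters_specks(self):
        arr = square_image()
        arr[0, 0] = 100
        ps = detect_particles(image(arr), threshold=50.0, min_area=4)
        assert len(ps) == 1
        assert ps.label_image[0, 0] == 0  # speck removed from label image too

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            ChannelImage(np.zeros((0, 5)))

    def test_matches_flood_fill_oracle(self, rng):
        arr = (rng.random((60, 60)) < 0.25).astype(float) * 100
        ps = detect_particles(image(arr), threshold=50.0)
        oracle = flood_fill_oracle(arr >= 50.0)
        got = sorted(
            frozenset(zip(*np.nonzero(ps.label_image == p.label)))
            for p in ps.particles
        )
        assert got == sorted(frozenset(c) for c in oracle)

    def test_total_area_shrinks_monotonically_with_threshold(self, rng):
        arr = rng.random((50, 50)) * 100
        areas = []
        for thr in (10, 30, 50, 70, 90):
            ps = detect_particles(image(arr), threshold=thr)
            areas.append(sum(p.area for p in ps.particles))
        assert areas == sorted(areas, reverse=True)


def particle_pair(offset_cols):
    """Anchor 10x10 square, partner 10x10 square shifted by offset_cols."""
    a = np.zeros((40, 60))
    a[10:20, 10:20] = 100
    p = np.zeros((40, 60))
    p[10:20, 10 + offset_cols : 20 + offset_cols] = 100
    anchors = detect_particles(image(a, channel_name="anchor"), threshold=50)
    partners = detect_particles(image(p, channel_name="partner"), threshold=50)
    return anchors, partners


class TestAssociation:
    def test_identical_masks_fully_occupied(self):
        anchors, partners = particle_pair(0)
        res = associate(anchors, partners)
        assert res.occupied_fraction[1] == 1.0
        assert res.anchor_frequency == 1.0

    def test_disjoint_masks_not_associated(self):
        anchors, partners = particle_pair(25)
        res = associate(anchors, partners)
        assert res.occupied_fraction[1] == 0.0
        assert res.pairs == []
        assert res.anchor_frequency == 0.0

    def test_quarter_overlap(self):
        # 100 px anchor, partner overlapping half the columns: 50 px overlap
        anchors, partners = particle_pair(5)
        res = associate(anchors, partners)
        assert res.occupied_fraction[1] == pytest.approx(0.5)
        assert len(res.pairs) == 1

    def test_min_overlap_threshold(self):
        anchors, partners = particle_pair(9)  # 10 px overlap (one column)
        assert associate(anchors, partners, min_overlap_px=11).pairs == []
        assert len(associate(anchors, partners, min_overlap_px=10).pairs) == 1

    def test_overlap_is_symmetric(self):
        anchors, partners = particle_pair(5)
        fwd = associate(anchors, partners)
        rev = associate(partners, anchors)
        assert {(a, p) for a, p, _ in fwd.pairs} == {
            (p, a) for a, p, _ in rev.pairs
        }

    def test_empty_anchor_set_flagged(self):
        anchors, partners = particle_pair(0)
        empty = ParticleSet(
            particles=[], label_image=np.zeros_like(anchors.label_image), channel="anchor"
        )
        res = associate(empty, partners)
        assert res.anchor_frequency is None

    def test_partner_side_counts(self):
        anchors, partners = particle_pair(5)
        res = associate(anchors, partners)
        assert res.n_associated_partners == 1
        assert res.partner_frequency == 1.0


class TestDistances:
    @staticmethod
    def fake_set(centroids, channel):
        particles = [
            Particle(i + 1, channel, 10, 100.0, 10.0, c) for i, c in enumerate(centroids)
        ]
        return ParticleSet(particles, np.zeros((1, 1), int), channel)

    def test_concentric_distance_zero(self):
        anchors, partners = particle_pair(0)
        res = associate(anchors, partners)
        (d,) = center_distances(res, anchors, partners)
        assert d == pytest.approx(0.0)

    def test_three_four_five(self):
        from polpause.particles import AssociationResult

        a = self.fake_set([(0.0, 0.0)], "anchor")
        p = self.fake_set([(3.0, 4.0)], "partner")
        res = AssociationResult([(1, 1, 1)], {1: 1.0}, 1, 1, 1, 1)
        assert center_distances(res, a, p, pixel_size=1.0) == [pytest.approx(5.0)]
        assert center_distances(res, a, p, pixel_size=0.1) == [pytest.approx(0.5)]

    def test_distance_based_association_radius(self):
        a = self.fake_set([(0.0, 0.0)], "anchor")
        p = self.fake_set([(0.0, 4.0)], "partner")
        near = associate_by_distance(a, p, pixel_size=0.1, radius_um=0.5)
        far = associate_by_distance(a, p, pixel_size=0.2, radius_um=0.5)
        assert len(near.pairs) == 1
        assert far.pairs == []


class TestAnchoredAverage:
    def test_single_anchor_returns_its_own_crop(self):
        arr = np.zeros((30, 30))
        arr[12:17, 12:17] = 100.0
        anchors = detect_particles(image(arr, channel_name="a"), threshold=50)
        out = average_anchored_image({"a": arr}, anchors, half_width=5)
        r, c = (int(round(x)) for x in anchors.particles[0].centroid)
        np.testing.assert_allclose(out.crops["a"], arr[r - 5 : r + 6, c - 5 : c + 6])
        assert out.n_used == 1

    def test_uniform_image_gives_uniform_crop(self):
        arr = np.full((40, 40), 7.0)
        anchors = self_anchor_set([(10.0, 10.0), (25.0, 30.0)])
        out = average_anchored_image({"a": arr}, anchors, half_width=4)
        np.testing.assert_allclose(out.crops["a"], 7.0)

    def test_symmetric_displacements_average_to_symmetry(self):
        partner = np.zeros((50, 50))
        partner[20, 23] = 10.0  # +3 px from anchor 1 at (20, 20)
        partner[35, 27] = 10.0  # -3 px from anchor 2 at (35, 30)
        anchors = self_anchor_set([(20.0, 20.0), (35.0, 30.0)])
        out = average_anchored_image({"partner": partner}, anchors, half_width=5)
        prof = out.profiles["partner"]
        np.testing.assert_allclose(prof, prof[::-1])
        assert prof[5 + 3] == pytest.approx(5.0)

    def test_edge_anchors_skipped(self):
        arr = np.zeros((20, 20))
        anchors = self_anchor_set([(1.0, 1.0), (10.0, 10.0)])
        out = average_anchored_image({"a": arr}, anchors, half_width=5)
        assert out.n_used == 1 and out.n_skipped == 1

    def test_all_anchors_skipped_is_an_error(self):
        arr = np.zeros((8, 8))
        anchors = self_anchor_set([(1.0, 1.0)])
        with pytest.raises(ValueError, match="skipped"):
            average_anchored_image({"a": arr}, anchors, half_width=5)


def self_anchor_set(centroids):
    particles = [
        Particle(i + 1, "anchor", 1, 1.0, 1.0, c) for i, c in enumerate(centroids)
    ]
    return ParticleSet(particles, np.zeros((1, 1), int), "anchor")
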