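import itertools

import numpy as np
import pytest

from conftest import disk_image
from phagoflux.segtrack import (
    Detection,
    LinkParams,
    SegParams,
    assign_engulfment,
    build_events,
    link_cost,
    link_frames,
    segment_particles,
)


def det(x, y, area, frame=0):
    return Detection(
        frame_index=frame,
        centroid_um=(x, y),
        area_um2=area,
        mean_intensity=1.0,
        bbox_offset=(0, 0),
        local_mask=np.ones((1, 1), bool),
    )


class TestSegmentation:
    def test_blank_image_yields_nothing(self):
        assert segment_particles(np.zeros((64, 64)), 0.1) == []

    def test_min_area_filter_drops_small_disk(self):
        """Two disks of area ~3.14 and ~0.79 um^2: only the first survives
        the 1.5 um^2 size filter."""
        img = disk_image(1.0, 0.05, shape=(96, 192), center_px=(48, 48))
        img = np.maximum(img, disk_image(0.5, 0.05, shape=(96, 192), center_px=(48, 144)))
        dets = segment_particles(img, 0.05, SegParams(min_area=1.5))
        assert len(dets) == 1
        assert dets[0].area_um2 == pytest.approx(np.pi, rel=0.05)

    def test_area_within_2pct_of_supersampled_oracle(self):
        r, px = 1.5, 0.05
        img = disk_image(r, px, shape=(96, 96))
        dets = segment_particles(img, px)
        assert len(dets) == 1
        # oracle: pixel-center disk membership at 10x resolution
        fine = 10
        n = int(np.ceil(2 * r / (px / fine))) + 4
        yy, xx = np.mgrid[0:n, 0:n]
        c = n / 2
        oracle = np.sum(np.hypot(yy - c, xx - c) * px / fine <= r) * (px / fine) ** 2
        assert dets[0].area_um2 == pytest.approx(oracle, rel=0.02)

    def test_centroid_within_one_pixel_of_truth(self):
        img = disk_image(1.5, 0.1, shape=(96, 96), center_px=(40, 55))
        d = segment_particles(img, 0.1)[0]
        assert d.centroid_um[0] == pytest.approx(5.5, abs=0.1)
        assert d.centroid_um[1] == pytest.approx(4.0, abs=0.1)

    def test_detection_count_monotone_in_min_area(self):
        rng = np.random.default_rng(4)
        img = np.full((200, 200), 10.0)
        for cy, cx, r in [(40, 40, 0.6), (40, 150, 1.0), (150, 40, 1.4), (150, 150, 1.9)]:
            img = np.maximum(img, disk_image(r, 0.1, (200, 200), (cy, cx)))
        img += rng.normal(0, 2, img.shape)
        counts = [
            len(segment_particles(img, 0.1, SegParams(min_area=a)))
            for a in [0.5, 1.5, 4.0, 8.0, 13.0]
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 4

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            segment_particles(np.zeros((8, 8)), 0.0)


class TestLinking:
    def test_stationary_detection_matches_itself_cost_zero(self):
        a = [det(5, 5, 7.0)]
        pairs, ua, ub = link_frames(a, a)
        assert pairs == [(0, 0)] and not ua and not ub
        assert link_cost(a[0], a[0], LinkParams()) == 0.0

    def test_gating_prevents_distant_swap(self):
        a = [det(0, 0, 7.0), det(10, 0, 7.0)]
        b = [det(0.3, 0, 7.0), det(10.3, 0, 7.0)]
        pairs, _, _ = link_frames(a, b, LinkParams(max_displacement=2.0))
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_unmatched_reported_as_starts_and_ends(self):
        a = [det(0, 0, 7.0)]
        b = [det(30, 30, 7.0)]
        pairs, ua, ub = link_frames(a, b, LinkParams(max_displacement=2.0))
        assert pairs == [] and ua == [0] and ub == [0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_minimum_cost_assignment(self, seed):
        """The solved matching equals brute-force enumeration over all
        permutations for 5 jittered particles."""
        rng = np.random.default_rng(seed)
        pos = rng.uniform(3, 27, size=(5, 2))
        areas = rng.uniform(5, 9, size=5)
        a = [det(x, y, s) for (x, y), s in zip(pos, areas)]
        jitter = rng.normal(0, 0.4, size=(5, 2))
        b = [
            det(x + dx, y + dy, s * rng.uniform(0.95, 1.05))
            for (x, y), (dx, dy), s in zip(pos, jitter, areas)
        ]
        params = LinkParams(cost_threshold=10.0)
        pairs, _, _ = link_frames(a, b, params)
        got = sum(link_cost(a[i], b[j], params) for i, j in pairs)
        best = min(
            sum(link_cost(a[i], b[j], params) for i, j in enumerate(perm))
            for perm in itertools.permutations(range(5))
        )
        assert got == pytest.approx(best)
        assert len(pairs) == 5

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(3, 27, size=(4, 2))
        a = [det(x, y, 7.0) for x, y in pos]
        b = [det(x + 0.2, y - 0.1, 7.1) for x, y in pos]
        ref, _, _ = link_frames(a, b)
        perm = [2, 0, 3, 1]
        shuffled, _, _ = link_frames(a, [b[k] for k in perm])
        remapped = sorted((i, perm[j]) for i, j in shuffled)
        assert remapped == sorted(ref)


class TestEvents:
    def make_frames(self, present):
        """present: dict frame -> list of (x, y)."""
        return {
            f: [det(x, y, 7.0, frame=f) for x, y in pts]
            for f, pts in present.items()
        }

    def test_persistent_particle_single_full_event(self):
        frames = self.make_frames({f: [(5.0, 5.0)] for f in range(8)})
        events = build_events(frames)
        assert len(events) == 1
        assert events[0].frames == list(range(8))

    def test_long_disappearance_splits_event(self):
        present = {f: [(5.0, 5.0)] for f in list(range(4)) + list(range(7, 12))}
        present[4] = present[5] = present[6] = []
        events = build_events(self.make_frames(present), LinkParams(max_frame_gap=1))
        assert len(events) == 2

    def test_short_events_discarded(self):
        frames = self.make_frames({0: [(5, 5)], 1: [(5, 5)]})
        assert build_events(frames, LinkParams(min_event_length=3)) == []

    def test_three_particle_scene_recovers_ground_truth_tracks(self, single_particle_scene):
        from phagoflux.simulate import ParticleSpec, SceneConfig, generate_timelapse
        from phagoflux.profiles import KineticProfile

        flat = KineticProfile(0, 0, 0, 0, e_max=1.0)
        parts = [
            ParticleSpec((5.0, 5.0), 1.5, 1, {"reporter": flat}),
            ParticleSpec((13.0, 5.5), 1.2, 1, {"reporter": flat}),
            ParticleSpec((9.0, 13.5), 1.8, 1, {"reporter": flat}),
        ]
        cfg = SceneConfig(particles=parts, n_frames=12, image_shape=(192, 192))
        stack, truth = generate_timelapse(cfg, 11)
        frames = {
            f: segment_particles(stack[f, 0], cfg.pixel_size)
            for f in range(cfg.n_frames)
        }
        events = build_events(frames)
        assert len(events) == 3
        for ev in events:
            assert ev.frames == list(range(12))
            med = ev.centroid_median_um()
            truths = [o["centers_um"][0] for o in truth.objects]
            d = [np.hypot(med[0] - x, med[1] - y) for x, y in truths]
            k = int(np.argmin(d))
            assert d[k] < 0.1  # within one pixel of the true center
            # area within 2% of rendered truth
            area = np.median([dd.area_um2 for dd in ev.detections])
            assert area == pytest.approx(truth.objects[k]["area_um2"], rel=0.02)

    def test_engulfment_annotation_attached_and_validated(self):
        frames = self.make_frames({f: [(5.0, 5.0)] for f in range(6)})
        events = build_events(frames)
        assign_engulfment(events, [{"x_um": 5.1, "y_um": 5.0, "engulfment_frame": 2}])
        assert events[0].engulfment_frame == 2
        with pytest.raises(ValueError, match="outside"):
            assign_engulfment(events, [{"x_um": 5.0, "y_um": 5.0, "engulfment_frame": 99}])
        with pytest.raises(ValueError, match="matches no event"):
            assign_engulfment(events, [{"x_um": 50.0, "y_um": 50.0, "engulfment_frame": 1}])
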