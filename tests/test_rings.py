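import numpy as np
import pytest

from conftest import disk_image
from phagoflux.pipeline import analyze_timelapse, annotations_from_ground_truth
from phagoflux.profiles import KineticProfile, get_preset
from phagoflux.rings import (
    EnrichmentTrace,
    RingGeometry,
    aggregate_cohort,
    fold_enrichment,
    make_ring_masks,
    measure_event,
)
from phagoflux.segtrack import segment_particles


def disk_mask(r_um, px, shape=(128, 128)):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - h // 2, xx - w // 2) * px <= r_um


class TestRingMasks:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            RingGeometry(inner_gap=0.85, outer_gap=0.85)
        with pytest.raises(ValueError):
            RingGeometry(ring_thickness=0.0)
        with pytest.raises(ValueError):
            RingGeometry(inner_gap=0.6, ring_thickness=0.35, outer_gap=0.85)

    def test_masks_disjoint_and_exclude_particle(self):
        mask = disk_mask(1.5, 0.05)
        inner, outer, _ = make_ring_masks(mask, RingGeometry(), 0.05)
        assert not np.any(inner & outer)
        assert not np.any(inner & mask)
        assert not np.any(outer & mask)

    def test_inner_ring_area_matches_analytic_annulus(self):
        """Ring area within 3% of pi[(r+gap+t)^2 - (r+gap)^2]."""
        r, px = 1.5, 0.05
        inner, _, _ = make_ring_masks(disk_mask(r, px, (160, 160)), RingGeometry(), px)
        analytic = np.pi * ((r + 0.55) ** 2 - (r + 0.2) ** 2)
        assert inner.sum() * px**2 == pytest.approx(analytic, rel=0.03)

    def test_ring_area_error_shrinks_with_resolution(self):
        r = 1.5
        analytic = np.pi * ((r + 0.55) ** 2 - (r + 0.2) ** 2)
        errors = []
        for px in [0.2, 0.1, 0.05]:
            n = int(2 * (r + 1.5) / px)
            inner, _, _ = make_ring_masks(disk_mask(r, px, (n, n)), RingGeometry(), px)
            errors.append(abs(inner.sum() * px**2 - analytic) / analytic)
        assert errors[2] < errors[0]
        assert errors[2] < 0.03

    def test_border_clipping_reported(self):
        mask = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[0:40, 0:40]
        mask[np.hypot(yy - 5, xx - 20) * 0.1 <= 1.0] = True  # near top edge
        _, _, clipped = make_ring_masks(mask, RingGeometry(), 0.1)
        assert clipped > 0.1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            make_ring_masks(np.zeros((10, 10), bool), RingGeometry(), 0.1)


class TestMeasureAndFold:
    def _measured(self, single_particle_scene, profile, noise, n_frames=30):
        from phagoflux.segtrack import build_events, assign_engulfment

        stack, truth, cfg = single_particle_scene(
            profile=profile, noise=noise, n_frames=n_frames
        )
        frames = {
            f: segment_particles(stack[f, 0], cfg.pixel_size)
            for f in range(cfg.n_frames)
        }
        events = assign_engulfment(
            build_events(frames), annotations_from_ground_truth(truth)
        )
        meas = measure_event(
            stack[:, :, :, :],
            events[0],
            pixel_size=cfg.pixel_size,
            frame_interval=cfg.frame_interval,
            channels=list(cfg.channels),
        )
        return meas, cfg

    def test_uniform_reporter_inner_equals_outer(self, single_particle_scene):
        flat = KineticProfile(0, 0, 0, 0, e_max=1.0)
        meas, _ = self._measured(single_particle_scene, flat, noise=0.0)
        assert np.allclose(meas["reporter_inner"], meas["reporter_outer"], rtol=1e-6)

    def test_noiseless_peak_recovers_e_max_within_2pct(self, single_particle_scene):
        prof = KineticProfile(60, 90, 150, 210, e_max=2.5)
        meas, _ = self._measured(single_particle_scene, prof, noise=0.0)
        trace = fold_enrichment(meas)
        assert trace.values.max() == pytest.approx(2.5, rel=0.02)

    def test_outer_ring_background_stays_constant(self, single_particle_scene):
        """The outer (cytosol) ring is a background control: its CV over
        time stays within the noise-predicted bound."""
        prof = KineticProfile(60, 90, 150, 210, e_max=2.5)
        meas, cfg = self._measured(single_particle_scene, prof, noise=0.05)
        outer = meas["reporter_outer"].to_numpy()
        n_px = meas["n_outer_px"].iloc[0]
        predicted_sd = 0.05 * cfg.cytosol_mean / np.sqrt(n_px)
        assert outer.std() < 4 * predicted_sd
        assert abs(outer.mean() - cfg.cytosol_mean) < 0.02 * cfg.cytosol_mean

    def test_fold_is_one_at_reference_and_constant_trace_flat(self, single_particle_scene):
        flat = KineticProfile(0, 0, 0, 0, e_max=1.0)
        meas, _ = self._measured(single_particle_scene, flat, noise=0.0)
        trace = fold_enrichment(meas)
        ref_idx = np.argmin(np.abs(trace.times - (-10.0)))
        assert trace.values[ref_idx] == 1.0
        assert np.allclose(trace.values, 1.0, rtol=1e-6)

    def test_missing_pre_engulfment_frame_errors(self, single_particle_scene):
        prof = KineticProfile(60, 90, 150, 210, e_max=2.5)
        meas, _ = self._measured(single_particle_scene, prof, noise=0.0)
        post_only = meas[meas["t_rel"] > 0]
        with pytest.raises(ValueError, match="reference"):
            fold_enrichment(post_only)

    def test_gain_invariance_of_fold_enrichment(self, single_particle_scene):
        """Multiplying the whole stack by a constant leaves the trace
        unchanged: the ratio-of-ratios cancels detector gain."""
        prof = KineticProfile(60, 90, 150, 210, e_max=2.5)
        stack, truth, cfg = single_particle_scene(profile=prof, noise=0.03, seed=5)
        traces = {}
        for gain in (1.0, 3.7):
            scaled = (stack.astype(float) * gain)
            _, trs, _ = analyze_timelapse(
                scaled,
                pixel_size=cfg.pixel_size,
                frame_interval=cfg.frame_interval,
                channels=list(cfg.channels),
                engulfment_annotations=annotations_from_ground_truth(truth),
            )
            traces[gain] = trs[0]
        assert np.allclose(traces[1.0].values, traces[3.7].values, rtol=1e-9)


def synthetic_trace(values, experiment, condition, step=10.0, event_id=0):
    t = np.arange(len(values)) * step - 30.0
    return EnrichmentTrace(
        event_id=event_id, times=t, values=np.asarray(values, float),
        condition=condition, experiment=experiment,
    )


class TestCohort:
    def test_identical_experiments_have_zero_sem(self):
        vals = [1, 1, 1.5, 2.5, 2.0, 1.2]
        traces = [synthetic_trace(vals, f"e{k}", "wt") for k in range(3)]
        df = aggregate_cohort(traces)
        assert np.allclose(df["sem"], 0.0)
        assert (df["n_experiments"] == 3).all()

    def test_single_experiment_sem_absent_not_zero(self):
        traces = [synthetic_trace([1, 1, 2, 2, 1], "e0", "wt")]
        df = aggregate_cohort(traces)
        assert df["sem"].isna().all()

    def test_experiment_level_averaging_not_event_level(self):
        # experiment A has 9 events at 2.0, experiment B one event at 1.0:
        # cohort mean must be 1.5 (mean of experiment means), not 1.9
        traces = [synthetic_trace([2, 2, 2, 2, 2], "A", "wt", event_id=i) for i in range(9)]
        traces += [synthetic_trace([1, 1, 1, 1, 1], "B", "wt", event_id=9)]
        df = aggregate_cohort(traces)
        assert np.allclose(df["mean"], 1.5)

    def test_null_type_one_error_rate_near_5pct(self):
        """Two conditions drawn from the same flat model: per-timepoint
        t-tests reject at ~ the nominal 5% rate."""
        rng = np.random.default_rng(42)
        n_tp, rejections, total = 12, 0, 0
        for rep in range(200):
            traces = []
            for cond in ("a", "b"):
                for e in range(3):
                    vals = 1.0 + 0.05 * rng.standard_normal(n_tp)
                    traces.append(synthetic_trace(vals, f"{cond}{e}", cond))
            df = aggregate_cohort(traces)
            p = df[df["condition"] == "a"]["p_value"].to_numpy()
            rejections += int((p < 0.05).sum())
            total += p.size
        rate = rejections / total
        assert abs(rate - 0.05) < 0.015

    def test_real_effect_detected_at_peak(self):
        """A 2.5-fold responder vs a flat control cohort at matched noise
        is significant at the peak timepoint (power check, 3 vs 3)."""
        rng = np.random.default_rng(3)
        prof = get_preset("snxa_macropinosome")
        t = np.arange(-30, 400, 10.0)
        traces = []
        for cond, p in (("wt", prof), ("null", None)):
            for e in range(3):
                base = p(t) if p else np.ones_like(t)
                vals = base + 0.05 * rng.standard_normal(t.size)
                traces.append(
                    EnrichmentTrace(0, t, vals, condition=cond, experiment=f"{cond}{e}")
                )
        df = aggregate_cohort(traces)
        at_peak = df[(df["condition"] == "wt") & (np.isclose(df["t_s"], 240.0))]
        assert float(at_peak["p_value"].iloc[0]) < 0.01
        assert "p_holm_extension" in df.columns
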