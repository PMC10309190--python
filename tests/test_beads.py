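import numpy as np
import pandas as pd
import pytest

from phagoflux.beads import (
    KD_PRESETS,
    fit_binding,
    measure_bead_probe,
    one_site,
    segment_bead_rings,
    selectivity_ratio,
)
from phagoflux.simulate import generate_bead_field, generate_lipid_panel


def titration_frame(kd, bmax, ns, concs, n_beads, noise, seed, n_exp=1):
    """Per-bead intensities straight from the binding model (no imaging)."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_exp):
        for c in concs:
            mu = one_site(c, kd, bmax, ns)
            vals = mu * (1 + noise * rng.standard_normal(n_beads)) if noise else np.full(n_beads, mu)
            rows += [{"conc": c, "intensity": v, "experiment": e} for v in vals]
    return pd.DataFrame(rows)


CONCS = [10, 30, 100, 200, 400, 800, 1400, 2000]


class TestBeadDetection:
    def test_blank_image_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no circles"):
            assert segment_bead_rings(np.zeros((64, 64)), 0.2) == []

    def test_rendered_beads_detected_with_accurate_radii(self):
        img, truth = generate_bead_field(200.0, 1.0, 0.0, 100.0, 5, seed=1)
        dets = segment_bead_rings(img[0], 0.2)
        assert len(dets) == 5
        for d in dets:
            assert d.radius_um == pytest.approx(5.0, rel=0.05)
        # detected centers match ground truth one-to-one
        gt = np.array([o["center_um"] for o in truth.objects])
        got = np.array([d.center_um for d in dets])
        dist = np.hypot(*(gt[:, None, :] - got[None, :, :]).transpose(2, 0, 1))
        assert dist.min(axis=1).max() < 0.3

    def test_overlapping_beads_both_rejected(self):
        # two nearly concentric circles: distinct components whose
        # circles overlap -> both must be rejected
        yy, xx = np.mgrid[0:80, 0:80] * 0.2
        d0 = np.hypot(yy - 8.0, xx - 8.0)
        d1 = np.hypot(yy - 8.0, xx - 8.3)
        mem = np.zeros((80, 80))
        mem[np.abs(d0 - 4.3) <= 0.2] = 1.0
        mem[np.abs(d1 - 5.7) <= 0.2] = 1.0
        with pytest.warns(UserWarning, match="overlapping"):
            dets = segment_bead_rings(mem, 0.2)
        assert dets == []


class TestProbeMeasurement:
    def test_uniform_probe_measures_zero_after_background(self):
        img, _ = generate_bead_field(200.0, 1.0, 0.0, 100.0, 4, seed=2, noise=0.0)
        dets = segment_bead_rings(img[0], 0.2)
        uniform = np.full(img.shape[1:], 0.37)
        vals = measure_bead_probe(uniform, dets, 0.2)
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_half_saturation_measures_half_bmax(self):
        img, _ = generate_bead_field(200.0, 1.0, 0.0, 200.0, 4, seed=2, noise=0.0)
        dets = segment_bead_rings(img[0], 0.2)
        vals = measure_bead_probe(img[1], dets, 0.2)
        assert np.allclose(vals, 0.5, atol=0.02)

    def test_noisy_field_mean_within_clt_bound(self):
        img, truth = generate_bead_field(200.0, 1.0, 0.0, 400.0, 30, seed=3, noise=0.05)
        dets = segment_bead_rings(img[0], 0.2)
        vals = measure_bead_probe(img[1], dets, 0.2)
        expected = 1.0 * 400 / 600
        assert abs(vals.mean() - expected) < 2 * 0.05 * expected / np.sqrt(30) + 0.01


class TestBindingFit:
    @pytest.mark.parametrize("kd,bmax", [(10.0, 0.1), (200.0, 1.0), (2000.0, 10.0)])
    def test_noiseless_fit_exact(self, kd, bmax):
        df = titration_frame(kd, bmax, 0.0, CONCS, 5, 0.0, 0)
        fit = fit_binding(df)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)
        assert fit.residual_norm < 1e-8

    def test_gain_equivariance(self):
        df = titration_frame(200.0, 1.0, 0.1, CONCS, 10, 0.03, 1)
        f1 = fit_binding(df)
        df2 = df.assign(intensity=df["intensity"] * 2.0)
        f2 = fit_binding(df2)
        assert f2.kd == pytest.approx(f1.kd, rel=1e-6)
        assert f2.bmax == pytest.approx(2 * f1.bmax, rel=1e-6)

    def test_per_experiment_sd_used_when_labels_present(self):
        df = titration_frame(187.3, 1.0, 0.0, CONCS, 30, 0.05, 2, n_exp=3)
        fit = fit_binding(df)
        assert len(fit.kd_per_experiment) == 3
        assert fit.kd == pytest.approx(np.mean(fit.kd_per_experiment))
        assert fit.kd == pytest.approx(187.3, rel=0.1)
        assert abs(fit.kd - 187.3) < 2 * fit.kd_error + 5.0

    def test_equal_concentrations_rejected(self):
        df = pd.DataFrame({"conc": [100.0] * 8, "intensity": np.arange(8.0)})
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_binding(df)

    def test_no_binding_flag_on_flat_titration(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"conc": np.repeat(CONCS, 10),
             "intensity": 0.01 * rng.standard_normal(80)}
        )
        fit = fit_binding(df)
        assert fit.no_binding

    def test_two_sd_interval_coverage_at_least_90pct(self):
        """Over 200 seeded noisy titrations (3 experiments each) the
        +/- 2*SD interval around the mean Kd contains the truth >= 90%."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            df = titration_frame(187.3, 1.0, 0.0, CONCS, 30, 0.05, 10_000 + rep, n_exp=3)
            fit = fit_binding(df)
            hits += abs(fit.kd - 187.3) <= 2 * fit.kd_error
        assert hits / n_rep >= 0.90


class TestSelectivity:
    def test_equal_lipids_ratio_one(self):
        df = generate_lipid_panel(fold_preference=1.0, noise=0.0, seed=0)
        assert selectivity_ratio(df).ratio == pytest.approx(1.0)

    def test_twenty_fold_panel_at_5pct_noise_at_least_18(self):
        df = generate_lipid_panel(fold_preference=20.0, noise=0.05, seed=1)
        assert selectivity_ratio(df).ratio >= 18.0

    def test_zero_target_gives_zero_ratio(self):
        df = pd.DataFrame(
            {"lipid": ["PI(3,5)P2"] * 3 + ["PI3P"] * 3, "intensity": [0.0] * 3 + [1.0] * 3}
        )
        assert selectivity_ratio(df).ratio == 0.0

    def test_single_lipid_rejected(self):
        df = pd.DataFrame({"lipid": ["PI(3,5)P2"] * 3, "intensity": [1.0] * 3})
        with pytest.raises(ValueError, match="2 lipids"):
            selectivity_ratio(df)

    def test_negative_means_clipped_with_warning(self):
        df = pd.DataFrame(
            {"lipid": ["PI(3,5)P2"] * 2 + ["PI3P"] * 2 + ["PI4P"] * 2,
             "intensity": [20.0, 20.0, -0.5, -0.4, 0.9, 1.1]}
        )
        with pytest.warns(UserWarning, match="clipped"):
            res = selectivity_ratio(df)
        assert res.strongest_other == "PI4P"


def test_end_to_end_kd_preset_recovery_image_pipeline():
    """Images -> circles -> ring intensities -> saturation fit recovers
    the full-length probe's Kd within 2 SD across 3 experiments."""
    preset = KD_PRESETS["snxa_full_length"]
    rows = []
    for e in range(3):
        for ci, c in enumerate(CONCS):
            img, _ = generate_bead_field(
                preset["kd"], preset["bmax"], preset["nonspecific"], c, 12,
                seed=500 + 100 * e + ci,
            )
            dets = segment_bead_rings(img[0], 0.2)
            for v in measure_bead_probe(img[1], dets, 0.2):
                rows.append({"conc": c, "intensity": v, "experiment": e})
    fit = fit_binding(pd.DataFrame(rows))
    assert abs(fit.kd - preset["kd"]) <= 2 * fit.kd_error + 5.0
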