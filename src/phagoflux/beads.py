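"""Membrane-coated-bead binding quantification and affinity fitting.

Equatorial sections of membrane-coated silica beads show each bead as a
bright circle in the membrane-dye channel.  Circles are detected,
their circumference masks transferred to the probe channel, and probe
intensity per bead measured after subtracting the off-bead background.
Titrating probe concentration at fixed membrane gives a one-site
saturation curve

    I(c) = nonspecific + Bmax * c / (Kd + c)

whose apparent Kd is fit by nonlinear least squares; with experiment
labels the Kd uncertainty is the SD across per-experiment fits,
otherwise a seeded bootstrap over beads.

Lipid-array selectivity: the ratio of the target lipid's mean spot
intensity to the strongest other lipid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "BeadDetection",
    "BindingFit",
    "SelectivityResult",
    "KD_PRESETS",
    "segment_bead_rings",
    "measure_bead_probe",
    "fit_binding",
    "selectivity_ratio",
    "one_site",
]

#: Ground-truth binding presets for the two probe constructs, used by
#: the synthetic titrations (apparent Kd in nM; Bmax and nonspecific in
#: arbitrary intensity units).
KD_PRESETS: dict[str, dict] = {
    "snxa_full_length": {"kd": 187.3, "bmax": 1.0, "nonspecific": 0.0},
    "px2_tandem": {"kd": 217.5, "bmax": 1.0, "nonspecific": 0.0},
}


@dataclass
class BeadDetection:
    """A detected bead circle plus its segmented circumference mask.

    The mask (local boolean patch + offset) holds the thresholded
    membrane-channel ring pixels; probe intensity is measured over
    exactly these pixels, as in mask-transfer workflows.
    """

    center_um: tuple[float, float]
    radius_um: float
    bbox_offset: tuple[int, int] | None = None
    local_mask: np.ndarray | None = None

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.bbox_offset
        h, w = self.local_mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.local_mask
        return out


@dataclass
class BindingFit:
    """One-site saturation fit result (apparent Kd in nM)."""

    kd: float
    kd_error: float | None
    bmax: float
    nonspecific: float
    residual_norm: float
    n_points: int
    kd_per_experiment: list[float] = field(default_factory=list)
    no_binding: bool = False


@dataclass
class SelectivityResult:
    per_lipid_mean: dict[str, float]
    target: str
    ratio: float
    strongest_other: str


def one_site(c, kd, bmax, nonspecific):
    return nonspecific + bmax * c / (kd + c)


def segment_bead_rings(
    membrane_image: np.ndarray,
    pixel_size: float,
    radius_bounds: tuple[float, float] = (4.0, 6.0),
    max_radial_sd_um: float = 0.6,
) -> list[BeadDetection]:
    """Detect equatorial bead circles in the membrane-dye channel.

    Bright pixels are grouped into connected components; for each, the
    circle center is the component centroid and the radius the mean
    pixel distance from it.  Components are kept when the radius lies in
    ``radius_bounds`` (um) and the radial spread is small (a closed,
    near-circular ring).  Pairs of detections whose circles overlap are
    both rejected.  An image with no circles yields an empty list with
    a warning.
    """
    img = np.asarray(membrane_image, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("no circles found: image is constant")
        return []
    thr = threshold_otsu(img)
    labels = sk_label(img > thr, connectivity=2)
    dets = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        if rows.size < 10:
            continue
        cy, cx = rows.mean() * pixel_size, cols.mean() * pixel_size
        r = np.hypot(rows * pixel_size - cy, cols * pixel_size - cx)
        r_mean, r_sd = float(r.mean()), float(r.std())
        if radius_bounds[0] <= r_mean <= radius_bounds[1] and r_sd <= max_radial_sd_um:
            r0, r1 = rows.min(), rows.max() + 1
            c0, c1 = cols.min(), cols.max() + 1
            dets.append(
                BeadDetection(
                    center_um=(float(cx), float(cy)),
                    radius_um=r_mean,
                    bbox_offset=(int(r0), int(c0)),
                    local_mask=comp[r0:r1, c0:c1],
                )
            )
    # reject overlapping beads (both of each offending pair)
    bad = set()
    for i in range(len(dets)):
        for j in range(i + 1, len(dets)):
            di, dj = dets[i], dets[j]
            dist = np.hypot(
                di.center_um[0] - dj.center_um[0], di.center_um[1] - dj.center_um[1]
            )
            if dist < di.radius_um + dj.radius_um:
                bad.update((i, j))
    if bad:
        warnings.warn(f"rejected {len(bad)} overlapping bead(s)")
        dets = [d for k, d in enumerate(dets) if k not in bad]
    if not dets:
        warnings.warn("no circles found")
    return dets


def measure_bead_probe(
    probe_image: np.ndarray,
    detections: list[BeadDetection],
    pixel_size: float,
    ring_thickness_um: float = 0.6,
) -> np.ndarray:
    """Mean probe intensity on each bead's circumference ring,
    background-subtracted.

    Measures over each detection's segmented ring mask (the membrane-
    channel mask transferred onto the probe channel); a geometric
    annulus of ``ring_thickness_um`` is used when a detection carries no
    mask.  Background is the median probe intensity over pixels far
    from every bead (outside radius + 2 x ring thickness).
    """
    img = np.asarray(probe_image, dtype=float)
    h, w = img.shape
    yy = np.arange(h)[:, None] * pixel_size
    xx = np.arange(w)[None, :] * pixel_size
    off_bead = np.ones_like(img, dtype=bool)
    means = []
    for det in detections:
        cx, cy = det.center_um
        d = np.hypot(yy - cy, xx - cx)
        if det.local_mask is not None:
            ring = det.full_mask(img.shape)
        else:
            ring = np.abs(d - det.radius_um) <= ring_thickness_um / 2
        means.append(img[ring].mean())
        off_bead &= d > det.radius_um + 2 * ring_thickness_um
    background = float(np.median(img[off_bead])) if off_bead.any() else 0.0
    return np.asarray(means) - background


def _fit_once(conc, intensity, seed=None):
    conc = np.asarray(conc, float)
    intensity = np.asarray(intensity, float)
    p0 = (
        max(float(np.median(conc)), 1e-3),
        max(float(intensity.max() - intensity.min()), 1e-6),
        float(intensity.min()),
    )
    popt, pcov = curve_fit(
        one_site,
        conc,
        intensity,
        p0=p0,
        bounds=([1e-9, 0.0, -np.inf], [1e9, np.inf, np.inf]),
        maxfev=20000,
    )
    return popt, pcov


def fit_binding(
    points: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> BindingFit:
    """Fit the one-site model to per-bead titration data.

    ``points`` needs columns ``conc`` (nM) and ``intensity``; an
    optional ``experiment`` column switches the Kd uncertainty from a
    seeded bead bootstrap to the SD of independent per-experiment fits
    (the convention for titrations repeated across experiments).  A fit
    whose Bmax is indistinguishable from 0 (|Bmax| < 2 SE) is flagged
    ``no_binding``: the Kd is then unidentifiable.
    """
    conc = points["conc"].to_numpy(float)
    if np.unique(conc).size < 2:
        raise ValueError("all concentrations equal: Kd unidentifiable")
    if np.unique(conc).size < 4:
        warnings.warn("fewer than 4 distinct concentrations: Kd poorly constrained")
    intensity = points["intensity"].to_numpy(float)
    try:
        popt, pcov = _fit_once(conc, intensity)
    except RuntimeError as err:
        raise RuntimeError(
            f"binding fit did not converge ({err}); check that concentrations "
            "span the saturation curve"
        ) from err
    kd, bmax, ns = (float(x) for x in popt)
    resid = intensity - one_site(conc, *popt)
    bmax_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    no_binding = bmax < 2 * bmax_se

    kd_per_exp: list[float] = []
    if "experiment" in points.columns and points["experiment"].nunique() > 1:
        for _, grp in points.groupby("experiment"):
            p, _ = _fit_once(grp["conc"].to_numpy(float), grp["intensity"].to_numpy(float))
            kd_per_exp.append(float(p[0]))
        kd_error = float(np.std(kd_per_exp, ddof=1))
        kd = float(np.mean(kd_per_exp))
    else:
        rng = np.random.default_rng(seed)
        boots = []
        n = conc.size
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                p, _ = _fit_once(conc[idx], intensity[idx])
                boots.append(p[0])
            except RuntimeError:
                continue
        kd_error = float(np.std(boots, ddof=1)) if len(boots) > 1 else None
    return BindingFit(
        kd=kd,
        kd_error=kd_error,
        bmax=bmax,
        nonspecific=ns,
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        n_points=int(conc.size),
        kd_per_experiment=kd_per_exp,
        no_binding=bool(no_binding),
    )


def selectivity_ratio(
    panel: pd.DataFrame,
    target: str = "PI(3,5)P2",
    floor_frac: float = 1e-6,
) -> SelectivityResult:
    """Fold-preference of the target lipid over the strongest other.

    ``panel`` is tidy (lipid, intensity) with intensities already
    background-subtracted; negative lipid means are clipped to a small
    positive floor (``floor_frac`` of the largest mean) before the
    ratio, with a warning.
    """
    means = panel.groupby("lipid")["intensity"].mean().to_dict()
    if target not in means:
        raise ValueError(f"target lipid {target!r} not in panel")
    if len(means) < 2:
        raise ValueError("selectivity requires at least 2 lipids")
    floor = floor_frac * max(abs(v) for v in means.values())
    clipped = {}
    for lip, v in means.items():
        if v < floor:
            warnings.warn(f"lipid {lip!r} mean {v:.3g} clipped to floor {floor:.3g}")
            v = floor
        clipped[lip] = v
    others = {l: v for l, v in clipped.items() if l != target}
    strongest = max(others, key=others.get)
    ratio = means[target] / others[strongest] if means[target] > 0 else max(means[target], 0.0)
    return SelectivityResult(
        per_lipid_mean=means, target=target, ratio=float(ratio), strongest_other=strongest
    )
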